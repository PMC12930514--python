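# baskethta

Weighted, modular, dynamic partitioned survival modelling for the
cost-effectiveness of tumour-agnostic (biomarker-defined) oncology
therapies.

## The problem

Therapies licensed on a molecular alteration rather than a tumour site are
evaluated on basket trials: small, heterogeneous cohorts per tumour type
sharing one biomarker. Conventional health-economic models — one tumour,
one comparator, one partitioned survival model (PSM) — do not fit this
evidence. `baskethta` implements a framework for health-economists and HTA
analysts in which each tumour site is a three-state PSM submodel, evidence
can be pooled across sites or site-specific, and site results are combined
by epidemiological weights into one aggregated decision quantity that can
be re-estimated as evidence matures.

## The model

Per site *i*, state occupancy at time *t* comes directly from the survival
endpoints:

```
pf(t) = PFS(t)          progression-free
pd(t) = OS(t) − PFS(t)  progressed
d(t)  = 1 − OS(t)       dead
```

Kaplan–Meier curves (reconstructed to pseudo-IPD from published step
coordinates and numbers at risk when patient data are unavailable) are
fitted with parametric families (exponential, Weibull, Gompertz,
log-normal, log-logistic, generalized gamma), ranked by AIC, extrapolated
to a lifetime horizon and optionally constrained by general-population
mortality (per-cycle hazard = max of model and life-table hazard).
State-specific costs and utilities give discounted incremental costs ΔC_i
and QALYs ΔE_i per site.

The aggregation rule — the framework's core — applies weights w_i
(each site's share of the biomarker-positive population) to the
*increments*, never to the ratios:

```
ΔC = Σ w_i ΔC_i,   ΔE = Σ w_i ΔE_i,   ICER = ΔC / ΔE,
NMB(λ) = λ·ΔE − ΔC
```

because ICERs cannot be meaningfully averaged. A site whose own evidence
matures is "broken out" onto site-specific inputs while every structural
assumption (grid, discounting, conventions) stays shared; each re-analysis
is an immutable, checksummed model version. Uncertainty is propagated with
deterministic (tornado) and probabilistic sensitivity analysis in which
shared parameters are drawn once per iteration and written to every site
jointly, site-specific parameters independently; CEACs report
P(NMB(λ) > 0).

## Worked example

Two sites with equal weights, ΔC/ΔE of 100 000/2.0 and 50 000/0.5
(site ICERs 50 000 and 100 000 per QALY):

```bash
python examples/04_weighted_aggregation.py
```

```
weighted sums: dC 75,000, dQALY 1.25
aggregated ICER (ratio of weighted sums): 60,000
mean of the site ICERs (never do this):   75,000
```

At a 70 000-per-QALY threshold the two conventions imply opposite
reimbursement decisions on identical evidence — weights belong on the
increments. The other scripts in `examples/` walk through curve fitting
and extrapolation, KM reconstruction, a single-site PSM, dynamic break-out
with version diffs, PSA/tornado output and background-mortality
adjustment; each prints the quantities it computes.

A `baskethta` command-line tool mirrors the workflow
(`simulate | fit | run | aggregate | breakout | psa | dsa | diff |
report`); every command writes JSON/CSV results stamped with the spec hash
and seed, so identical inputs give byte-identical outputs.

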