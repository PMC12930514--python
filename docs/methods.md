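# Methods

## Model structure

Each tumour site is a three-state partitioned survival model
(progression-free, progressed, dead). Occupancy is read directly off the
endpoint curves — pf(t) = PFS(t), pd(t) = OS(t) − PFS(t),
dead(t) = 1 − OS(t) — so no transition probabilities are estimated and the
model consumes exactly what trials report. Because OS and PFS are
extrapolated independently, the curves can cross; the engine repairs a
crossing by clipping PFS to OS (`pf = min(PFS, OS)`) and reports the number
of clipped grid points rather than rejecting the input, since crossings are
a known artefact of independent extrapolation that the analyst must see,
not a reason to abort. This clip also means PFS is implicitly capped at
OS after background-mortality adjustment, which is applied to OS only.

Occupancy is stored point-in-time at the n+1 cycle boundaries. Per-cycle
quantities use the boundary average (trapezoid), which makes area-under-
curve quantities second-order accurate in the cycle length: life-years and
QALYs move by well under 1 % when the default 1-month cycle is halved, and
the exponential life-expectancy check (mean 1/h) holds at 2 % without
resorting to very fine grids. The `half_cycle_correction` flag controls
only the discount-time convention: per-cycle values are discounted at
(1+r)^(−t/12) with t at the cycle start (off) or midpoint (on). Costs and
effects may use different annual rates.

Cost categories: drug and administration accrue while progression-free and
on treatment (optionally capped at `max_treatment_cycles`; default is
treat-to-progression), disease management accrues by state, adverse-event
cost is a one-off at model start, end-of-life cost attaches to incident
deaths Δdead_k at the cycle of death. Deaths beyond the horizon are not
charged — a deliberate, conservative choice. Utilities are state-constant
in [0, 1], so QALYs ≤ life-years by construction.

## Survival fitting and extrapolation

Six families are supported: exponential (rate), Weibull (shape, scale),
Gompertz (shape ∈ ℝ, rate > 0; negative shape implies a surviving
fraction), log-normal (μ, σ), log-logistic (shape, scale) and generalized
gamma (μ, σ, Q; Q→0 is log-normal, Q=1 Weibull). Time is in months
everywhere. Fitting maximises the right-censored log-likelihood
Σ[d·log f(t) + (1−d)·log S(t)] by Nelder–Mead on a transformed scale (log
for positive parameters), with three starting points for the generalized
gamma and Gompertz; the exponential uses its closed form
(rate = events/exposure, var(log rate) = 1/events). The covariance of the
transformed estimates comes from the inverse numerical Hessian and is the
sampling distribution used by the PSA; sampling on the transformed scale
keeps every draw in the parameter domain, so monotonicity rejections are
effectively never needed (a counter is still kept). Natural-scale standard
errors are delta-method. AIC ranks candidates; ties break toward fewer
parameters. The ranking is advisory — distribution choice in an appraisal
also weighs visual fit and clinical plausibility, so callers can override.

Background mortality uses the hazard-max convention: per cycle, the applied
hazard is max(model hazard, cohort life-table hazard at the attained age),
with annual probabilities converted by h = −ln(1−q)/12 and the sexes
collapsed by a fixed cohort mix. Hazard-max (rather than additive hazards)
guarantees the adjusted curve never beats the general population, is
idempotent, and is recorded in the curve metadata.

## Kaplan–Meier reconstruction

Pseudo-IPD is rebuilt from published step coordinates plus the
numbers-at-risk table by the standard iterative interval algorithm: within
each risk-table interval the number censored is adjusted until the implied
number at risk matches the next published value, censoring times are spread
uniformly, and events are recovered from the survival drops. Two numerical
details matter at small n: survival drops are rounded against the running
product (re-anchoring after each event), and a small local search over the
censor count (±2) and placement offset picks the allocation whose
reconstructed curve best matches the published steps among those that still
hit the risk-table boundary. Digitisation wobble (survival rising) is
clipped to non-increasing with a warning. If `total_events` is known, the
final interval's censoring is calibrated to it; otherwise subjects still at
risk after the last step are censored there. Typical round-trip accuracy
on simulated curves (n = 50–200, up to ~30 % censoring, risk table every 6
months) is sup-distance ≲ 0.02 with event counts within ~5 %.

## Weighted aggregation, break-out and versions

Weights are site counts normalised to 1 — by default biomarker-positive
population counts; trial-enrolment counts are accepted as an alternative
source and the choice is echoed in output metadata (which source is
canonical is genuinely open). Weights are applied to incremental costs
and QALYs, and the aggregated ICER is the ratio of the weighted sums; site
ICERs are never averaged (an average of ratios has no decision meaning,
and the mediant inequality keeps the ratio-of-sums inside the site ICER
range whenever all ΔE_i > 0). Aggregation of absolute per-arm totals is
available as an option; increments are the default.

Pooled evidence is constructed by stacking IPD across the pooled sites and
fitting one curve per arm and endpoint — pooling at the patient level, not
averaging of fitted curves, because the former has a testable estimand
under homogeneity. Breaking a site out replaces only that site's inputs
and flips its evidence level; grid, discounting and conventions remain
shared, so break-out is local by construction. Every evaluation worth
keeping is recorded as a model version: an immutable snapshot (from which
results are reproducible bit-for-bit), the per-site evidence registry and
the results. The persisted log is append-only JSON-lines with a per-record
SHA-256 checksum so corruption is detected on load. The re-analysis
trigger implemented is the concrete sample-size rule (a site is due when it
has accumulated at least `min_new_n` new subjects since the last version,
boundary inclusive); `min_new_n = 50` is a placeholder default, not an
evidence-based threshold — richer triggers are config hooks left inert.

## Uncertainty analysis

`ParameterSpec` carries a dotted target (`intervention.*`, `comparator.*`,
`both.*`, `econ.*`), a distribution (beta for utilities, gamma/log-normal
for costs — enforced so draws respect each parameter's support), a scope
and DSA bounds. In PSA, shared-scope parameters are drawn once per
iteration and written to every site; site-specific ones are drawn
independently; survival-parameter resampling (multivariate normal on the
fitting scale, one draw per distinct fitted object so pooled sites move
jointly) is opt-in via `resample_survival`, which keeps the all-fixed
collapse to the deterministic result exact. Only the two sharing extremes
are implemented; partial cross-site correlation is not. Results are
reported both as the deterministic base case and as PSA means, labelled.
CEAC probability at λ is the fraction of iterations with λ·ΔE − ΔC
strictly positive (ties count against). The tornado re-evaluates the
aggregate NMB at each parameter's low/high bound one at a time, shared
parameters moving all sites simultaneously, sorted by NMB range.
Structural uncertainty (alternative families, scenario overrides) is
expressed as named scenarios in the spec, never sampled.

## Synthetic data

The generator emulates a basket trial. Per subject, three latent times are
drawn independently: progression T_p, pre-progression death T_d, and
post-progression survival T_pp; then PFS-time = min(T_p, T_d) and OS-time =
T_d if death precedes progression else T_p + T_pp. This coupling makes
PFS ≤ OS per subject, so the generated population is internally coherent
even though the analysis extrapolates the endpoints independently.
Censoring is min(exponential dropout, administrative cut-off); both OS and
PFS rows of a subject share one censoring time and a subject identifier.

Built-in scenarios use three sites (lung, colorectal, thyroid) with
comparator median PFS of about 5, 7 and 9 months, pre-progression death
hazards 0.005–0.012/month, post-progression hazards 4–6 times higher,
dropout 0.005/month, 36 months of follow-up, 100 subjects per arm per site
(10 for the thin site in `small_n_site`), biomarker-positive counts
600/300/100, and a treatment hazard ratio of 0.6 on progression and death
(`heterogeneous` sets thyroid's to 1.0). Costs and utilities are plausible
late-stage oncology values in EUR per monthly cycle (drug 8 000 vs 2 500,
end-of-life 10 000, utilities 0.80/0.65), horizon 240 months, discounting
3 %, willingness to pay 100 000 per QALY. The scenarios' analysis configs
restrict candidate families to exponential and Weibull: with 36 months of
follow-up and ~100 subjects per arm, flexible three-parameter tails are
poorly identified and family flip-flops between re-fits would swamp the
quantities under study; the richer families remain available via the spec.

What the generator does not emulate: diagnostic misclassification of
biomarker status, treatment sequencing and post-progression therapy lines,
non-proportional or time-varying effects, informative censoring, and
real-world heterogeneity in cost structures. Passing tests therefore
demonstrate correctness of the machinery (estimation, weighting,
versioning, uncertainty propagation) under a coherent data-generating
process — not that any particular extrapolation is clinically right.
End-to-end recovery tests use a configuration with equal pre- and
post-progression death hazards, which makes true OS and PFS exactly
exponential (memorylessness) and gives closed-form oracle curves; this
deliberately isolates pipeline correctness from extrapolation
misspecification, which is exercised separately.

## Numerical choices and limitations

Default grid: 1-month cycles, 480-month horizon (240 in the built-in
scenarios, whose cohorts are essentially extinct well before that).
Zero survival times are nudged to 1e-8 months for log-time families.
AIC ties break by parameter count then family order. Occupancy
conservation is enforced at 1e-9; weight normalisation at 1e-12. The
model spec is YAML (JSON accepted); currency and the month time-unit are
declared once globally and echoed, never converted. Known limitations:
no spline/cure/relative-survival models, no covariate adjustment, no
treatment sequencing, no EVPI, no partial cross-site correlation in PSA,
and reconstruction/digitisation uncertainty is not propagated into PSA.
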