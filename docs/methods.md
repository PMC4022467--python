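# Methods

## The model

`lymphkin` implements a whole-organism compartment model of the
recirculation of thoracic-duct lymphocytes (TDLs) — in the reference
setting, ⁵¹Cr-labeled cells adoptively transferred into rats.  The state
is the percentage of the injected label in each pool:

* **blood** — the hub connecting all tissues;
* **lung**, **liver**, **spleen** — single first-order compartments
  (exponentially distributed transit times);
* **subcutaneous lymph nodes (SCLNs)**, **mesenteric lymph nodes
  (MLNs)**, **Peyer's patches (PPs)** — chains of `k` serial
  sub-compartments with a common per-stage rate `m`, so transit times are
  gamma-distributed with shape `k` and mean `k/m` (the linear chain
  trick).  The sub-compartments are a mathematical device for
  non-exponential residence times, not anatomical claims.

Flows are linear: the blood feeds organ `i` at entry rate `s_i` (per
minute) and organ `i` returns cells at exit rate `m_i`, with two
anatomical exceptions:

* PP efflux drains into the first MLN sub-compartment, never directly to
  blood;
* SCLN efflux returns via the thoracic duct with probability `f`
  (default 0.5) and via the right lymphatic duct with probability `1-f`.

A removal rate `μ` drains the blood into death/unsampled tissues; a
fraction `φ` of that flux is deposited in the liver as dead cells, which
the label still counts (the measured liver signal is live + dead).  Two
bookkeeping pools (`removed`, `duct_collected`) absorb all outflows, so
the state always sums to the injected 100% — the conservation invariant
every simulation is tested against at 1e-6.

**Cannulation mode** models thoracic-duct cannulation: the terminal MLN
efflux and the fraction `f` of terminal SCLN efflux are harvested into
`duct_collected` instead of returning to blood (the right-duct share
still returns), and every LN/PP chain rate decays as `m·e^{-νt}`,
representing the progressive loss of node cellularity the cannula
causes.  `ν` applies uniformly to all chain transitions, including the
PP→MLN step; lung/liver/spleen rates are untouched.

## Numerics

Outside cannulation (or with `ν = 0`) the system is linear
time-invariant and is propagated exactly with the matrix exponential
(`scipy.linalg.expm`, stepping between output times).  The Padé/
scaling-squaring algorithm is used rather than eigendecomposition
because the equal-rate chains make the rate matrix defective.  With
`ν > 0` the system is time-varying and is integrated with LSODA at
rtol 1e-9 / atol 1e-12 — the rates span three orders of magnitude
(2.17 to 0.0034 per minute), so a stiff-capable integrator is required.
Solver failure raises; NaNs are never returned silently.

Steady states use the closed-form balance: per unit of blood content,
each simple organ holds `s_i/m_i`, and each of the `k` stages of a chain
holds `throughput/m`, where the MLN throughput includes the PP efflux it
receives.  Removal is forced to zero (no steady state exists otherwise)
and the seven organ percentages are normalized to 100.  The closed form
is cross-checked against long-run simulation (`t = 1e6–1e7` min) to
0.1 percentage points in the tests.

## Reference parameters

`reference_parameters()` carries the published point estimates for rat
TDLs (entry rates 1.83, 0.41, 0.056, 0.026, 0.0106, 0.0053 per minute
for lung, liver, spleen, SCLN, MLN, PP; exit rates 2.17, 1.14, 0.007 and
a shared LN/PP per-stage rate of 0.0034 per minute; `k = 2`, the chain
length that described the source migration data best).  The published
table does not separately print `μ` and `φ`; here they are calibrated to
the reported whole-body recovery — about 90% of label still accounted
for in the seven organs at 24 h — giving `μ = 0.0048`/min with
`φ = 0.5`.  The even split sends ~10% of the label into the liver-dead
pool by 24 h, on the scale of the late-time liver accumulation the
dying-cell pool exists to explain.  Steady-state predictions are
insensitive to this choice (they force `μ = 0`); the 45-h cannulation
total is not, and with this calibration the model collects 79.8% of the
bolus in 45 h (the published prediction is 78%).

## Estimation

* **Migration data alone** — nonlinear least squares on the raw percent
  records (fitting percents or log-percents gave the original analysis
  nearly identical estimates; we fit percents).  Twelve free parameters
  in the shared-exit model: six entries, four exits, `μ`, `φ`.
* **Joint migration + cannulation** — a generalized likelihood with
  dataset-specific normal error variances σ₁², σ₂².  Profiling the
  variances analytically (σ̂ᵢ² = SSRᵢ/nᵢ) reduces the objective to
  `(n₁/2)·log(SSR₁/n₁) + (n₂/2)·log(SSR₂/n₂)`, which is minimized by
  iteratively reweighted least squares: weighted trust-region LS
  alternating with variance updates until the profiled log-likelihood
  stabilizes (tolerance 1e-9).  The cannulation predictions run the
  model in cannulation mode with the free decline rate `ν`; the
  migration predictions ignore `ν`.  The routing fraction `f` is fixed
  at 0.5 by default and can be freed.

Rates are optimized on the log scale and fractions (`φ`, `f`) on the
logit scale, so positivity and the [0, 1] bounds hold by construction.
`fit(starts=n)` runs `n` optimizations from log-normally jittered starts
(σ = 0.3 in transformed space) and keeps the best — a guard against
local minima of the 12+ parameter landscape.  Default starting values
are order-of-magnitude physiological guesses (fast lung/liver rates,
slow lymphoid rates).

Model comparison offers the nested F-test
`F = ((SSR_r − SSR_f)/Δp)/(SSR_f/(n − p_f))` and the least-squares AIC
`n·log(SSR/n) + 2p` (additive constant dropped; comparisons are only
meaningful within one dataset).  Shared-exit vs per-organ-exit nesting
is recognized structurally, not by parameter-name matching.

Confidence intervals come from a residual-resampling bootstrap:
residuals are resampled with replacement within each dataset, added to
the fitted values (clamped at zero), and the model refitted warm-started
at the point estimate; 2.5/97.5 percentiles are reported.  The bootstrap
is bit-reproducible under a fixed seed; refit failures are counted and
more than 10% raises a warning flag.

## Virtual experiments

* **Cannulation forecast** — duct output rate
  `60·m·e^{-νt}·(f·SCLN_k + MLN_k)` percent/h and its running integral,
  tracked as an ODE pool (exact to integration tolerance).
* **Steady-state scenarios** — named multiplicative perturbations:
  lung inflammation (lung exit ÷20), anti-CD62L-like entry blockade
  (LN/PP entries ÷20), FTY720-like exit blockade (LN/PP exits ÷5).
* **Stimulated popliteal node** — an auxiliary `k`-stage chain driven by
  the blood trajectory of the fixed global model; the node holds well
  under 1% of the label, so it does not feed back on the blood.  Node
  content is linear in the entry rate, which is profiled analytically;
  the exit rate is a 1-D bounded optimization.  An F-test compares
  per-node exits against a shared exit.  A time-varying entry/exit
  extension is deliberately not implemented: fitted exponential-in-time
  trends proved biologically unrealistic in the original analysis.
* **Entry blockade** — the system is pre-equilibrated at the closed
  (μ = 0) steady state, LN/PP entries are multiplied by `1 − efficacy`,
  and the SCLN decay is summarized the way blockade experiments are
  analyzed: a no-offset single exponential `A·e^{-rt}` fitted over the
  window.  With partial blockade the pool decays toward a non-zero
  equilibrium, so the apparent rate underestimates the true exit rate;
  with `k = 2` the decay is a sum of exponentials that a single
  exponential still fits with R² > 0.98 over 48 h — exponential-looking
  decay is not evidence of exponential residence times.
* **Vascular pass counting** — each blood departure is a Bernoulli
  trial with success = entering a secondary lymphoid organ
  (`p = (s_spleen + s_scln + s_mln + s_pp)/Σs`); the expected number of
  lung/liver passes before the first success is `(1 − p)/p`.  Removal is
  excluded from the denominator by default (the split of interest is
  lung/liver vs lymphoid tissue).  Reference rates give `p ≈ 0.042`,
  i.e. ~23 passes.

## Synthetic data

The generator emulates the two source experiments: migration time
courses on the original 13-point grid (1, 2, 5, 10, 30 min; 1, 2.5, 6,
9, 12, 15, 18, 24 h) and thoracic-duct collections at 90-min intervals
over 45 h, each with i.i.d. additive normal noise.  Negative draws are
clamped at zero and counted (`clamp_negative=False` raises instead).

Noise defaults: σ₁ = 0.5 percentage points for migration data, chosen so
that a single synthetic dataset carries the information the published
intervals imply — the resulting lung-entry estimator SE (~0.22/min)
matches the published 95% CI half-width (1.34–2.25 around 1.83).  The
emulated measurements are averages over ≥5 animals, which is why the
scatter is this small.  σ₂ = 0.1 %/h, about 5% of the peak duct output.
The generator does not model per-animal variation, label decay or
counting error, and its noise is homoscedastic — so passing recovery
tests demonstrate correctness of the inference machinery under the
assumed error model, not robustness to the heteroscedasticity real
organ-to-organ signals likely have.

A caution on identifiability: the lung and liver equilibrate with the
blood within ~15–60 s, faster than the first sampling time, so their
entry/exit rates are individually informed only by the earliest points
while their ratio is well determined throughout.  At noise levels much
above the calibrated default, single-dataset estimates of these two
rates can drift large together; the recovery tests therefore average
over replicate datasets where a point estimate is compared to the
published value.

## Test problem sizes

The statistical calibration studies run at sizes chosen to balance
Monte-Carlo error against runtime: bootstrap coverage uses 200 synthetic
datasets × 60 resamples with only the parameter under study free
(binomial SE at 95% coverage ≈ 1.5%); the F-test null calibration uses
500 datasets with the three LN/PP exit rates free (SE ≈ 1%).  The full
12-parameter machinery is exercised separately by the recovery and
acceptance fits.

## Known limitations

* Organ signals mix vasculature and parenchyma; the rates are
  whole-organ averages.  A lung vasculature/parenchyma split is out of
  scope.
* Lymphatic transit to the blood is instantaneous in the model; duct
  transit times (~minutes) are negligible against LN residence (~10 h).
* LN chains are pooled; per-node resolution is not modeled.
* The bootstrap resamples pooled residuals within a dataset, assuming
  exchangeability across organs and times.
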