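# Methods

## Kinetic model

All regional kinetics follow the one-tissue-compartment (1TC) model

    dC_T/dt = K1·C_p(t) − k2·C_T(t),   V_T = K1/k2,

with K1 (mL·cm⁻³·min⁻¹) the perfusion-weighted delivery constant, k2
(min⁻¹) the tissue efflux constant, and C_p the metabolite-corrected
arterial input. Time is in minutes throughout; activity units are
arbitrary (every reported outcome is a ratio). TAC values are treated as
decay-corrected; only the noise model sees physical ¹¹C decay
(λ = ln2/20.4 min⁻¹).

**Plasma input.** The bolus input is a tri-exponential,

    C_p(t) = A1·(t−τ)·e^(−λ1(t−τ)) + A2·e^(−λ2(t−τ)) + A3·e^(−λ3(t−τ)),  t ≥ τ,

with defaults τ = 0.5 min, A1 = 40 min⁻¹·(kBq/mL), λ1 = 4 min⁻¹,
A2 = 3, λ2 = 0.45 min⁻¹, A3 = 1, λ3 = 0.012 min⁻¹: a sharp first-pass
peak (~0.75 min), a distribution phase, and a slow terminal tail. The
parameters are configurable; only the shape class matters for the ratio
outcomes studied here.

**Exact curve algebra.** Plasma and tissue curves are represented as sums
of (polynomial × exponential) terms (`ExpSum`), for which convolution
with e^(−k2·t), pointwise evaluation, and definite integration are all
closed-form. Simulated TACs and their frame averages are therefore exact
to machine precision; a composite-trapezoid fallback (2.5×10⁻³ min
resolution) handles arbitrary callables. The degenerate case k2 = λ is
handled exactly via quadratic-coefficient terms.

**Frame schedule.** The 27-frame, 90-min dynamic schedule
(6×0.5, 3×1, 2×2, 16×5 min). Frame values are the true frame means
(1/Δt)·∫C_T dt.

**Noise model.** Frame-wise independent Gaussian noise with variance

    σ²(frame) = scale²·C(t_mid)·e^(λ·t_mid)/Δt_frame,

i.e. count-limited noise growing with physical decay and shrinking with
frame duration. This is a pragmatic stand-in for reconstruction noise; it
has no spatial structure and no motion component.

**1TC fitting** is weighted nonlinear least squares on
log-parameterized (K1, k2) with Levenberg–Marquardt, an early-uptake K1
initialization, k2₀ = 0.05 min⁻¹, and three jittered restarts (fixed
restart seeds). Default weights are decay-duration weights
w = Δt·e^(−λ·t_mid); the pipeline passes full inverse-variance weights
w = Δt·e^(−λ·t_mid)/C(t_mid) built from the measured TAC (floored at 5 %
of the peak). Non-convergence returns a `FitFailure` record, never an
exception, so cohort batches survive single bad fits.

## Reference-tissue models

SRTM expresses a target TAC through the reference TAC:

    C_T(t) = R1·C_R(t) + R1·(k2′ − k2a)·∫₀ᵗ C_R(s)·e^(−k2a(t−s)) ds,

with R1 = K1/K1′, k2′ the reference efflux, k2a the apparent target
efflux; BPND = R1·k2′/k2a − 1 and DVR = BPND + 1. When both regions are
1TC with a shared input the equation is exact (algebraic identity), with
k2a equal to the true target efflux — the basis of the exactness tests.

**Fitting** is by basis functions: 128 log-spaced k2a values in
[0.006, 0.6] min⁻¹ (configurable), a weighted linear solve per basis
(two coefficients for SRTM, one for SRTM2 with k2′ fixed), minimum
weighted RSS wins, ties to the smallest k2a. Because the grid spacing
(~3.7 %) exceeds the 1 % accuracy demanded of DVR, the grid argmin is
polished by a bounded Brent search between its neighbours (`refine=True`;
pure grid mode available). The reference curve is linearly interpolated
through (0, 0) and its exponential convolution accumulated segment-wise
in closed form. The fit window defaults to 0–60 min; frames must lie
wholly inside the window. Negative BPND is reported as-is, never clipped.

**Reference efflux k2′.** Three strategies:

* `reference-1tc` (pipeline default): fit each subject's
  whole-cerebellum TAC with the 1TC model against the known plasma input
  and fix that subject's own k2. Rationale: with a reference region that
  binds as avidly as the targets (DVR ≈ 1 everywhere), the θ₂ term of
  SRTM is nearly zero and k2′ = k2/R1 is close to unidentifiable, so
  first-pass SRTM pooling is noise-fragile; the historical route for such
  tracers likewise derived k2′ from direct 1TC modelling of the
  cerebellum.
* `median`: median first-pass SRTM k2′ over fits with BPND above a
  threshold. The classical threshold (0.5) assumes high-binding regions
  exist; when none clears it the median over all converged fits is used,
  and the pipeline sets the threshold to 0 outright — with DVR ≈ 1 a
  high-BPND filter selects only subjects whose sampled DVR is large,
  i.e. whose reference efflux is atypically fast, and biases k2′ upward
  (observed ~35 % on a noiseless default cohort).
* `fixed`: a configured constant.

## SUVR

SUVR over a window is the duration-weighted mean target activity divided
by the duration-weighted mean reference activity over the frames in the
window — equal, up to a factor that cancels in the ratio, to summing the
frames. Unweighted duration combination is the default (a decay-weighted
variant would change nothing detectable in the ratio of decay-corrected
TACs; the open choice is noted in the code). Windows that cut frames are
prorated by overlap with a warning. The nine standard windows are
30–60, 40–70, 50–80, 60–90, 30–50, 40–60, 50–70, 60–80 and 70–90 min.
Instantaneous target/reference ratios are evaluated at frame midpoints by
default; continuous curves are accepted for the equilibrium analyses.

## Synthetic cohort generator

The generator emulates the *structure* of a two-group clinical cohort —
16 CN and 31 AD subjects, eight cortical/limbic target regions plus the
whole-cerebellum reference — not any measured participant data. All
kinetic values are synthetic defaults.

Per region the config holds CN means (K1, V_T) and AD fractional
reductions in V_T (density) and K1 (perfusion). CN means put regional
DVR in 0.79–1.08 with cerebellar K1 = 0.32, V_T = 14. AD density
reductions are 5–12 %; perfusion reductions are ~1.5× the density
reduction in lateral/posterior cortex but ~0.6× in
hippocampus/entorhinal cortex (medial-temporal synaptic loss leads
perfusion loss, and it is in exactly those regions that short-window
outcomes gain nothing over DVR), with a 1 % cerebellar perfusion
reduction so R1 differences are offset slightly from raw K1 differences.

Between-subject dispersion is structured rather than a single CV:

* a **global delivery factor** per subject (lognormal, mean 1, CV 10 %)
  scaling K1 and V_T together — a free-fraction/availability effect that
  cancels exactly in DVR and R1;
* **regional delivery residuals** (CV 6 %… default 9 %) on K1;
* an **efflux time** τ = 1/k2 drawn per region (CV 5 %) so that
  E[V_T] = E[K1·τ] equals the configured mean; V_T ≡ K1/k2 holds exactly
  per subject, hence true DVR = V_T/V_T(cerebellum) by construction.

This split keeps DVR dispersion (~14 % CV) and reference-efflux
dispersion (~5 % CV) separately realistic. A single independent
K1/V_T lognormal was rejected during design: it implies ~17 % CV on both
DVR and k2′, which makes population-k2′ SRTM2 fail in ways clean clinical
data do not show. Lognormals are mean-parameterized
(μ = ln m − σ²/2). The default TAC noise scale is 0.02 (≈2–4 % frame CV
mid-scan for whole-ROI TACs). Reproducibility: a master `SeedSequence`
spawns the parameter stream and per-subject×region noise sub-seeds;
identical config + seed is bit-identical, and the on-disk manifest stores
the config hash and seed so a cohort can be regenerated exactly.

**What passing tests do and do not show.** The generator has no
partial-volume effects, no motion, no reconstruction covariance between
frames or regions, and its groups differ only in mean kinetics. Results
on it validate the estimator chain and the direction of the perfusion
confound; they do not certify effect-size magnitudes on real scanners.

## Perfusion simulation

For each scenario p ∈ {0, 10, 20, 30, 40} % the AD hippocampal K1 values
are multiplied by one factor chosen so the AD group mean equals
(1 − p/100)× the CN mean (preserving each subject's relative deviation);
k2 is co-scaled so V_T — and therefore true DVR — is untouched, isolating
the perfusion confound (a k2-fixed variant that lets V_T drift is behind
a flag). All TACs are then simulated noiselessly (group differences come
from the parameter spread; optional noise is seeded), and at each late
5-min frame midpoint (12.5–87.5 min) the per-subject target/reference
ratio yields the CN-vs-AD percentage difference 100·(CN−AD)/CN (positive
= reduction in AD) and Cohen d, tabulated against the scenario's R1
percentage difference and the constant true-DVR percentage difference.
Windowed SUVRs over the nine standard windows are emitted alongside.
Cohen d on a dispersion-free cohort is undefined (zero pooled SD) and is
emitted as NaN in these tables.

## Statistics

Cohen d uses the classic pooled-SD form (no small-sample correction),
sign convention CN − AD. Regressions are ordinary least squares of SUVR
on DVR with Pearson r and two-tailed p from the t transform with n−2 df;
strata are all / CN / AD plus per-region fits. Identity-line bias is
reported as slope−1, intercept, and the mean signed deviation of the
fitted line from y = x over the observed DVR range. The effect-size
table computes region-wise Cohen d per outcome (nine windows + DVR) and,
per window, the Pearson r of its region-wise d against DVR's, plus
mean ± SD of d across the full configured region list. No
multiple-testing correction is applied. Output ordering is fixed
(window order, then DVR) and every written table carries the run's
config hash in a header comment, so repeated runs are byte-identical.

## Known limitations

* Windowed SUVR computed from low-noise TACs is nearly as precise a
  group-difference statistic as SRTM2-estimated DVR, and the SRTM2
  estimate pays a small noise-induced cost (its nonlinear estimator
  compresses group mean differences slightly under noise). On this
  generator the mean Cohen d of the DVR outcome therefore lands at, or
  just below, the late-window SUVR d rather than strictly between late
  and early windows; the early > late ordering itself is robust. Closing
  that last gap appears to require data features outside a TAC-level
  emulation (voxel-level parametric-image noise, late-scan motion).
* The 1TC/SRTM2 chain is exact by construction here; model mismatch
  (2TC behaviour, reference-region specific binding) is out of scope.
* The plasma input is shared across subjects; inter-subject input-shape
  variability would mostly cancel in ratios but is not modelled.
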