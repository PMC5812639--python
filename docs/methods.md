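# Methods

## Model

`irrevkin` quantifies PET radioligands that bind irreversibly on the scan
time scale (exemplar: a ¹¹C-labelled covalent enzyme inhibitor for FAAH).
The tissue time-activity curve (TAC) follows the irreversible two-tissue
compartment model (2TCMi, k4 = 0) with metabolite-corrected arterial plasma
input Ca(t) and whole-blood activity Cb(t):

    CT(t) = (1−VB)·(K1·k3/θ)·∫₀ᵗ Ca dτ + (1−VB)·(K1·k2/θ)·e^{−θt}⊗Ca(t) + VB·Cb(t),
    θ = k2 + k3.

Macroparameters: net influx rate Ki = K1·k3/θ; the flow-insensitive binding
index λk3 = (K1/k2)·k3 (proportional to enzyme concentration); VND = K1/k2.
All curves are decay-corrected; physical decay enters only through the
noise model.

### Estimators

* **Basis-function fit** (the package's core): the model is linear in
  (φ1, φ2) = ((1−VB)K1k3/θ, (1−VB)K1k2/θ) once θ is fixed, so a family of
  basis curves BF_j = e^{−θ_j t}⊗Ca (θ_j log-spaced on [θmin, θmax],
  default [0.06, 3] min⁻¹, n = 50) turns fitting into n small weighted
  linear solves; the θ_j with minimal weighted residual sum of squares
  wins (exact ties, which arise only in degenerate data, resolve to the
  smallest θ for determinism). With **fixed VB** (default 5%) the vascular
  signal is subtracted first and the solve has two unknowns; with
  **variable VB** the Cb column joins the design and VB is the third
  coefficient. Designs are QR-factorized once per basis and reused across
  fits; the solves are unconstrained, so negative coefficients are
  reported as-is (an optional clamp exists for map display only) — adding
  positivity constraints would change the noise-induced bias/CoV behaviour
  that the Monte Carlo machinery is meant to characterize.
* **Patlak plot**: OLS slope of (CT − VB·Cb)/Ca against ∫Ca/Ca over frames
  with midpoint ≥ t* (default 27.25 min, a required user parameter because
  the equilibration criterion behind it is data-dependent). The slope of
  the vascular-corrected plot estimates (1−VB)·Ki, so the reported Ki is
  slope/(1−VB), putting all estimators on one scale. The regression is
  unweighted: the transformation invalidates frame-variance weights.
* **Nonlinear reference fit**: trust-region least squares over (K1, k2, k3)
  with VB fixed, bounds [0,2]×[0,1]×[0,1], five multiplicative restarts
  around (0.3, 0.1, 0.05) — nonlinear fits of this model are prone to local
  minima, which the restarts mitigate.

### Numerics

Continuous-time work happens on a uniform 1-s grid. Input curves are
interpolated linearly, taken as 0 before their first sample, and never
extrapolated past their last sample (hard error instead — silent
extrapolation corrupts ∫Ca). The exponential convolution uses the exact
one-step recursion for a piecewise-linear input (`scipy.signal.lfilter`),
which stays accurate up to θ = 3 min⁻¹ where naive quadrature degrades; at
θ = 0 it reduces to the running trapezoidal integral, so the θ→0 limit is
continuous. Frame values are time-averages of the continuous model over
each frame (PET frames report mean activity); an instantaneous-midpoint
mode is available (`sampling="midpoint"`) since either convention is
defensible for simulated data.

## Monte Carlo machinery

Frame noise is zero-mean Gaussian with

    SD_i = sf · e^{λc·(t_end,i + t_start,i)/2} · sqrt(C_i/(t_end,i − t_start,i)),

λc = 0.0339 min⁻¹ (¹¹C), C_i the noise-free frame value, sf a unitless
scale factor. Fit weights are normalized inverse variances; frames with
SD = 0 under sf > 0 (the empty pre-arrival frame) carry weight 0. A
scenario simulates the noise-free TAC once, draws nc replicates (default
5000; the error of the mean is E = 100·zc·Sx/(x̄·√nc), zc = 1.96), fits
each, and summarizes mean, SD, relative/absolute bias, CoV, skewness and
kurtosis per parameter. Kurtosis is reported non-excess (normal ≈ 3).
When |x̄| < 3·SE(x̄) the CoV and E are reported as NaN (unstable means occur
for the graphical method at the highest noise). Replicates share one
noise-free TAC rather than re-simulating, isolating the estimator's noise
response. Fitting several estimator configurations inside one scenario
reuses the identical noisy replicates, which is what makes paired
variability comparisons (e.g. Patlak vs basis-function CoV ratios) sharp.

## Synthetic study inputs

No subject data ship with the package; the generator produces inputs with
the statistical structure the analysis assumes, not a reconstruction of any
measured curve.

* **Input function**: Feng-type tri-exponential bolus,
  (A1·u − A2 − A3)e^{−4u} + A2·e^{−0.12u} + A3·e^{−0.01u}, u = t − 0.5 min,
  sampled at 1 s out to 62.5 min. The tail amplitudes (A2 = 4, A3 = 1; see
  `InputFunctionSpec`) were chosen so that the simulated
  gray-matter TAC peaks 120–260 s post injection with a plateau near 0.9 of
  the peak, the fast basis member (θ = 0.2 min⁻¹) peaks before 180 s and
  the slow one (θ = 0.02 min⁻¹) after 500 s — the qualitative fingerprints
  of this tracer class. Parameterizations that break the TAC-peak window
  trigger a warning.
* **Amplitude calibration**: the sf values are nominal labels
  (7 ≈ ROI, 20 ≈ very small ROI, 100–120 ≈ HRRT voxel). Because SD_i
  depends on the absolute activity scale, the input-function peak is
  normalized to a calibration constant (6×10⁵ nominal units) fixed once so
  that the fixed-VB fit at sf = 120 under baseline gray-matter kinetics
  yields CoV(Ki) ≈ 40%, the voxel-noise anchor for this tracer/scanner
  combination. Under this convention sf = 7/20/120 give mean percent noise
  (100·ΣSD/ΣC) of ≈3.5/10/59%. This is a unit convention, not a claim of
  equivalence to any scanner's count statistics; the absolute mapping of
  sf to a physical scanner is unrecoverable from published information.
* **Whole blood**: Cb = (Ca/pf)/R with parent fraction
  pf(t) = 0.8·e^{−t/10} + 0.2 and plasma-to-whole-blood ratio R = 1.19 —
  fixed plausible values; metabolite kinetics are out of scope.
* **Frame schedule**: 22 frames — 30 s (standing in for the scanner's
  variable-length pre-arrival frame), 5×30 s, 45 s, 2×60 s, 90 s, 120 s,
  210 s, 10×300 s — truncated so the last frame ends at 60 min (the printed
  sequence sums to 62.75 min).
* **Phantom**: labeled slabs (baseline gray matter; blocked gray matter
  with k3×0.1; white matter with K1 = 0.16, k2 = k3 = 0.06; a pure-blood
  vessel with VB = 1; zero background) with per-voxel independent frame
  noise, written as NIfTI-1 plus a BIDS-style frame-timing sidecar together
  with ground-truth parameter maps.

## What passing tests do and do not show

The synthetic system satisfies the model exactly: Gaussian, uncorrelated
frame noise on a TAC that lies in the estimator's model class. Real data
add reconstruction-correlated and non-Gaussian noise, motion, delay and
dispersion of the arterial input, metabolite-correction error and tissue
heterogeneity — none simulated here. Results at intermediate noise levels
transfer best; headline high-noise magnitudes depend on the (unpublished)
subject input function and should be read as regimes, not constants.

Two quantitative notes from our own validation runs:

* The blood-volume mismatch sensitivity is structurally attenuated in this
  synthetic system: fitting with VB = 5% when the data carry 10% shifts the
  Ki bias by ≈ −1.5 to −2.5 points rather than the ≈ −5 expected from pure
  (1−VB) scaling, because the un-subtracted blood leftover has a slow late
  tail (a consequence of the parent-fraction model above) that the ∫Ca
  design column partially absorbs as apparent trapping. The direction and
  ordering of the effect (negative for over-assumed VB_TAC, positive for
  under-assumed, growing with the error) are robust; the magnitude is
  input-function-dependent.
* At sf→0 with n = 50 the only residual bias is θ-grid discretization
  (≈ −1% on Ki for baseline kinetics); a denser grid removes it. At very
  low noise more basis members are needed, consistent with the general
  behaviour of grid methods.

## Default problem sizes

Monte Carlo defaults to nc = 5000 (E ≪ 5% in the stable scenarios); the
test suite uses 2000–5000 replicates per scenario and a 16×16×6 phantom,
sizes at which every summary statistic asserted is stable to well inside
its tolerance. The 32×32×8 default phantom maps in a few seconds on one
CPU; per-voxel cost is n small back-substitutions against the shared
factorized basis.
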