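# Methods

This note records the models behind each analysis stage, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical choices made where the design was genuinely open.

## Sensor calibration

The force sensor is a 29-residue flagelliform-silk peptide acting as an
entropic spring between a FRET dye pair. Two relations define the
calibration:

- spring law: `F(r) = (r − b·n − c) / (a·n)` with compliance slope
  `a = 0.0122 nm/pN`, per-residue offset `b = 0.044 nm`, construct
  constant `c = 2.4 nm`, `n = 29` residues. The zero-force separation is
  `r0 = b·n + c = 3.676 nm`.
- Förster relation: `E(r) = (1 + (r/R0)^6)^−1` with `R0 = 5.1 nm`, giving
  a zero-force efficiency `E0 ≈ 0.877`.

`F(E)` composes the closed-form inverse `r(E) = R0·(1/E − 1)^{1/6}` with
the spring law; a numeric root-finder serves only as a test oracle.
Efficiencies above `E0` map to negative forces and are returned as-is —
clamping happens only in the PDF stage, where negative *densities* are
clipped, never values. Units are fixed package-wide (nm, pN, s, μm).

Uncertainty propagation maps a grid of forces (default 100 points on
[0, 9] pN) to efficiencies, shifts each down by ΔE and re-inverts:
`ΔF_i = F(E_i − ΔE) − F_i`. For ΔE = 0.005 the maximum is ≈ 0.13 pN,
attained at the largest grid force, where `|dF/dE|` is steepest.

## Synthetic data

The trajectory generator emulates the statistical structure the analysis
relies on, with per-track ground truth attached:

- **Efficiency noise.** Force-free observations draw from
  `N(μ0 = 0.865, σ0 = 0.164)`; force-bearing tracks from `N(E(F), σ0)`.
  The noise is Gaussian and force-independent because the analysis itself
  only ever rescales the width of the no-force peak.
- **Motion.** Mobile tracks are free Brownian walks with
  `D = 0.7 μm²/s`; immobilized tracks are static plus localization jitter
  (default 0.02 μm). The frame interval defaults to 0.1 s, a typical
  single-molecule tracking cadence for this kind of TIRF experiment.
  Force-bearing tracks are always immobilized: a freely diffusing anchor
  cannot sustain tension, and the generator rejects scenarios with
  `phi_force > phi_immobile`.
- **Track lengths.** Geometric with configurable mean (default 10
  observations), reflecting bleaching-limited observation. The true
  track-length law of real data is not known to us; the geometric choice
  is a stand-in, and minimum-length filtering is a downstream concern.
- **Intensities.** Total intensity is log-normal; donor/acceptor split
  binomially by the (clipped) efficiency. This produces shot-noise-like
  structure for the preprocessing tests without claiming a camera model.
- **Seeding.** A single scenario seed spawns all stream seeds through
  `numpy.random.SeedSequence`; the seed is recorded in the output
  metadata and outputs are bit-reproducible.

The lifetime generator draws bond lifetimes exponentially, discretizes to
frames (ceil), and bleaches with a fixed per-frame probability; the
observed frame count is geometric with per-frame survival
`exp(−Δt/τ_bond)·(1 − p_bleach)`, which is exactly the competing-risk
structure the lifetime fit assumes.

Not emulated: raw images, camera noise, localization error in the FRET
channel registration, drift, bilayer heterogeneity, force dynamics within
a track, or correlated efficiency noise along a track. Passing tests
therefore demonstrate correctness of the estimators under the stated
statistical model, not robustness to every artifact of real recordings.

## Preprocessing

Corrected FRET follows the community-standard ALEX convention: sensitized
emission `F_corr = I_A − bt·I_D − de·I_A^aex`, efficiency
`F_corr/(γ·I_D + F_corr)`, stoichiometry
`(γ·I_D + F_corr)/(γ·I_D + F_corr + I_A^aex/β)`. Factors default to
identity/zero (the efficiency then reduces exactly to the proximity
ratio) and are config-settable, since the appropriate values are
instrument-specific. Negative corrected intensities are kept (they are
noise) but counted in the provenance log; zero-denominator observations
are dropped with a log entry.

Filters, each logging its removal count:

- proximity: both members of any same-frame pair closer than the neighbor
  radius are removed (default 0.8 μm, ~2× a typical PSF sigma at 160 nm
  pixels; instrument-specific, config-exposed);
- efficiency window [−0.5, 1.5] and stoichiometry window [0.3, 0.7]
  (stand-in defaults, config-exposed; the stoichiometry filter is skipped
  when no acceptor-excitation channel exists);
- minimum track length 5 observations;
- single-emitter filter: tracks whose summed intensity shows more than
  one significant downward mean shift are removed. Changepoints come from
  binary segmentation with a robust noise scale (MAD of successive
  differences) and a z-threshold of 4; the goal (single-step appearance
  and disappearance) fixes the contract, not the algorithm.

## High-force fraction

`q_f` is the empirical `f = 0.05` quantile of cell-free efficiencies,
using linear interpolation between order statistics (the common default;
the definition is config-visible). The corrected fraction
`n_low/n_total − f` subtracts the expected false positives and is
reported unclamped — negative point estimates are legitimate sampling
noise and clamping would bias the mean. Uncertainty comes from
resampling whole tracks with replacement to the original track count
(default 1000 resamples); summaries use quartiles with 1.5·IQR whiskers,
plus mean and bootstrap SD as the standard error.

## Force PDF by scaled subtraction

Both efficiency PDFs are average shifted histograms on [−0.5, 1.5] with
40 shifts; the coarse bin count follows Sturges's rule
`1 + ceil(log2 n)` computed from the *cell* sample size and applied to
both PDFs so the grids match (matching grids make the subtraction
pointwise; the alternative of independent grids would require an extra
interpolation with no benefit). The ASH is computed as a triangular
kernel on the fine grid and renormalized to integrate to 1 over the
range (edge truncation would otherwise lose mass).

The cell-free PDF graph is mapped by `x → anchor + s_width·(x − anchor)`,
`y → s_height·y` and fitted to the cell PDF by unweighted least squares
(`scipy.optimize.least_squares`) on grid points with E > 0.75, starting
from (1, 1) with bounds (0, 5] on both scales. The anchor 0.87 is a
config constant deliberately distinct from the calibration's zero-force
efficiency 0.877: it anchors the width scaling of the *measured* peak.
After subtraction, negative densities are clipped to zero. If the
residual mass falls below a config floor (default 1e-3, which cleanly
flags the self-subtraction case) the result is an explicit "no detectable
force" rather than meaningless quartiles.

The residual is converted to force with the analytic Jacobian
`f_F(F) = f_E(E(F))·|dE/dF|`, dropping grid points with efficiencies
outside (0, 1) or mapping to negative force before renormalizing;
quartiles come from inverse-CDF interpolation on the force grid. In
recovery tests the PDF median lands within ±0.5 pN of a 5 pN injected
force; the reconstructed IQR of ~2.4 pN reflects the propagated
efficiency noise σ0, not genuine force spread.

## Mobility

The smallest enclosing circle is computed by a deterministic incremental
construction (points in input order, no randomized shuffling) so results
are reproducible; a brute-force oracle over all 2- and 3-point support
circles verifies it to 1e-9 on random point sets. For free diffusion the
squared radius grows linearly with time, so the reduced radius
`radius/√duration` is diffusion-scale-free; tracks below 0.35 μm·s^−0.5
are immobilized. Duration uses timestamps (last − first), not frame
counts, matching the unit of the threshold and remaining correct for
tracks with gaps. Tracks with fewer than 5 observations are `too_short`
and excluded from all denominators; zero-duration tracks are immobilized
by convention and logged.

## Hypothesis tests

Statistic: `D⁺ = max_x (CDF_A(x) − CDF_B(x))` evaluated at the pooled
sorted unique values (signed max at pooled points; ties are thereby
handled deterministically). The null is generated by reassigning whole
tracks between groups, preserving group track counts. Monte-Carlo
p-values use the add-one estimator `(1 + #{perm ≥ obs})/(1 + N)` so p is
never zero; when the number of distinct assignments `C(T, T_A)` is at
most 20000 the null is enumerated exactly and the p-value is the exact
tail proportion (which includes the identity, so it is also never zero).
With all tracks of length 1 the test reduces to the ordinary permutation
KS test, which is the oracle used in the tests. Default 9999 resamples;
significance stars at 0.05/0.01/0.001. No multiple-testing correction is
applied across conditions.

## Bond lifetimes

Model: unbinding is a rate `k_off = 1/τ_bond` independent of imaging;
bleaching is a fixed per-frame risk, hence a rate `k_b/Δt` that grows
with the frame rate. Apparent lifetimes follow
`τ_app(Δt) = 1/(k_off + k_b/Δt)`, which is linear in rate space
(`1/τ_app` vs `1/Δt`) — that linear fit seeds a weighted
`scipy.optimize.curve_fit` on the τ scale with per-interval standard
errors.

Per-interval estimation: observed frame counts of frame-discretized
events are geometric, so for short events (mean < 10 frames) the MLE of
the per-frame survival `q` is converted via `τ_app = −Δt/ln q̂`; for long
events the shifted-exponential MLE `τ_app = mean − Δt` (left truncation
at the one-frame detection minimum) is equivalent and is exposed as an
explicit method. Right-censored events (still bound at the end of the
movie) contribute their full duration to the geometric likelihood.
Standard errors come from the observed information. Degenerate inputs
fail informatively: all events one frame long → advise a longer
recording interval; a flat τ_app curve → the fit returns the weighted
mean apparent lifetime flagged as non-identifiable instead of failing.

Recovery: across a (τ_bond, p_bleach) grid at 1000 events per interval
and five intervals (0.5–8 s), the median relative error of τ_bond stays
below 10%. Ignoring bleaching (pooling all events) underestimates the
bond lifetime, as expected.

## Pipeline and QC

`run_pipeline` executes simulate → preprocess → force → mobility → stats
→ qc, writing each stage's outputs under the run directory; a resumed
run reloads existing stage outputs. All stage seeds derive from the
single config seed, and identical config + seed gives byte-identical
result JSON. QC gates give an explicit verdict per criterion: absence of
force events in no-cell data (|corrected fraction| ≤ 0.02, about three
null standard errors at the default sample size), predominant mobility
on fluid bilayers without cells (mobile fraction ≥ 0.5), near-absence of
immobilized no-cell signals (≤ 0.1), and — for runs flagged as positive
controls — a clear force excess (≥ 0.04, half the smallest reliably
detectable signal under the default conditions). Missing metrics yield
"not-evaluable" and flag the run.

## Problem sizes

Default analyses use a few hundred to a few thousand synthetic tracks
(10^3–10^4 observations), 1000 bootstrap resamples and 9999 permutation
resamples; Monte-Carlo calibration checks in the test suite run 400–1000
simulations at ~2000 points each. These sizes give standard errors
comfortably below the assertion tolerances while keeping the full suite
fast.

## Known limitations

- The efficiency noise model is homoscedastic and Gaussian; real
  correction pipelines produce slightly asymmetric, intensity-dependent
  noise.
- The force PDF method resolves a single dominant force scale; it is not
  a deconvolution and cannot separate close force subpopulations.
- The single-emitter filter is a mean-shift changepoint counter; gradual
  photophysical decays are outside its contract.
- Stoichiometry-based filtering is only exercised when an
  acceptor-excitation channel is present; the synthetic generator does
  not simulate one.
- The discussion-level relation between a given force and "extension" of
  the spring admits two reference points (with or without the zero-force
  offset); the package implements the spring law exactly as calibrated
  and takes no position on that wording.
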