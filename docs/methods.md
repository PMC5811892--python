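# Methods

This note documents the models, conventions, numerical choices and known
limitations of `mrsmm`.

## Signal model and conventions

An FID is a complex time series sampled at `t_k = k·dwell` (2,048 points
at 6,000 Hz bandwidth by default, 7 T proton transmitter 297.2 MHz).
The chemical-shift axis is `ppm = reference + f/f0` with the water
reference at 4.7 ppm; the referencing convention is declared, not
inferred from any external convention.  Spectra are stored in display
order (ppm decreasing left to right).  `fid_to_spectrum` is a plain
centered DFT; halving of the first FID point (a common baseline-offset
remedy) is available via `halve_first_point` but off by default so the
exact DFT identities (Parseval, lossless round trip) hold.  An
acquisition delay TE\* shows up as a first-order phase ramp of
360·TE\*·f0 degrees per ppm about the reference, which `phase_correct`
removes; within a single line the delay mostly rephases the peak by
2πf·TE\* and mixes a Lorentzian factor into its envelope.

Peak measurement refines the real-part maximum with a three-point
parabola (the raw grid is 2.93 Hz/bin, too coarse for line-width maps),
interpolates the half-height crossings linearly for the FWHM, and
defines SNR as height over twice the noise SD of the real part in a
peak-free window.

## Synthetic data: what it emulates, what it does not

The generators provide every input the pipeline needs, with full ground
truth:

* **Metabolite basis FIDs.** Weak-coupling line lists (shift + relative
  amplitude per proton group, unit-normalized, T₂\* 60 ms) simulated by
  a hard-pulse model on a 5× oversampled grid (30 kHz), with the first
  39 oversampled points dropped — 39/30 kHz = 1.3 ms, the acquisition
  delay — and decimated back.  At TE\* = 1.3 ms J-evolution is
  negligible, which is what makes the line-list model adequate; no
  density-matrix simulation is attempted.  The 17 simulated compounds
  include choline (GPC, PCho) and creatine (Cr, PCr) constituents
  individually; tCho and tCr are reported as sums.  The line lists are
  standard literature shifts entered as synthetic fixtures.
* **Metabolite-nulled MM spectra.** Nine Gaussian components pinned to
  the canonical MM1–MM9 shifts.  Only the positions are canonical;
  amplitudes (MM1 ≥ MM9 ≥ MM5 > others, MM1 = 1) and widths (0.04–0.12
  ppm) are fixture choices and are never treated as validated values.
  Optional narrow residual lines (NAA 2.01, Ins 3.52, Glu 2.30, Gln
  2.45, tCr 3.98 ppm; FWHM 0.02 ppm) emulate imperfect nulling.
* **FID-MRSI phantoms.** Square power-of-two matrices (64×64 default)
  with an elliptical "head" (~64% of voxels), a WM core / GM cortex /
  central CSF tissue pattern, per-voxel amplitudes that are affine in
  the CSF-free GM fraction `g = f_GM/(f_GM+f_WM)` (`amp = intercept +
  slope·g` per component; MM8 is configured higher in WM, all other MM
  components higher in GM), two broad Lorentzian lipids (0.9/1.3 ppm,
  FWHM 0.15 ppm, 10× MM1) in the outermost 2-voxel rim, per-voxel
  frequency offsets (±2 Hz), and complex white Gaussian noise.  SNR
  helper functions translate a target spectral SNR into a time-domain
  noise SD via the `height/(2σ)` convention.

The phantoms deliberately omit B₀ inhomogeneity beyond per-voxel
offsets, lineshape distortion, motion, residual water, and spatial
correlation of noise.  Passing tests therefore demonstrate correctness
of the estimators on data drawn from their own model class plus noise —
not robustness to in vivo artifacts.

## MM parameterization

**Prior-knowledge route (AMARES-style).**  Bounded trust-region
least squares over centers (±0.08 ppm around the canonical shifts) and
FWHMs (5–60 Hz), with amplitudes and phases solved exactly at every step
by variable projection (complex least squares under the default free-
phase policy; non-negative least squares for fixed/shared phases).  The
Jacobian over the nonlinear parameters is finite-difference; the
Fisher information used for CRLBs is built from analytic model
derivatives, with the noise variance estimated from the last 10% of the
FID.  Metabolite residuals are removed by fitting the five narrow lines
jointly with nine broad MM stand-ins and subtracting only the narrow
components.

**Hankel-SVD route (HLSVD-style).**  The FID fills a Hankel matrix
(n/2 rows), a full SVD truncates to 13 components (a Lanczos partial SVD
is an efficiency device only; at this size the full SVD is equivalent),
poles follow from the shift invariance of the left singular subspace,
and amplitudes from linear least squares.  Poles that do not represent
the MM contribution are discarded by an explicit rule — outside 0.5–4.0
ppm, Lorentzian FWHM above 100 Hz, or farther than 0.13 ppm from every
canonical MM shift — since the published workflow identifies them only
verbally.  Because a Gaussian peak is often represented by two nearly
degenerate Lorentzian poles, surviving poles are grouped per MM peak;
each cluster is then refined by two sweeps of signal-space deflation
(subtract all other clusters, re-decompose the remainder), which removes
most of the bias neighboring peaks induce on weak, broad components
(MM4 in particular).  A component's basis FID is the coherent sum of its
poles.  Growing poles (|z| > 1) are kept and flagged, never silently
dropped.

A lineshape-mismatch property follows from the two model classes: the
Lorentzian-mixture components place a larger fraction of their spectral
energy outside the line core than the Gaussian components (the
"elevated baseline" effect), even though their half-height widths are
typically *smaller* — a least-squares Lorentzian matches a Gaussian's
core and pays in the tails.  The test suite asserts the tail-energy
direction; the half-height comparison is not a reliable direction on
Gaussian truth.

## Basis sets and ratio priors

Seven variants: the full measured-analog MM spectrum (average of
residual-cleaned nulled FIDs) as one component; nine individual
components from either parameterization; four groups (MM1–MM4, MM5–MM6,
MM7–MM8, MM9) formed by complex summation of the as-fitted member FIDs
so intra-group amplitudes and phases stay frozen; and the individual
components with soft ratio priors.  Individual MM entries are normalized
to unit model amplitude when they enter a basis (the parameterized
amplitudes are kept in `BasisSet.mm_scale`), so a fitted amplitude is on
the same scale as the parameterization and as the ratio priors.

Ratio priors MM(XX)/MM1 use MM1 as denominator (easy to quantify, no
metabolite overlap): expected value and SD are the across-spectra mean
and sample SD of the fitted amplitude ratios over ≥2 (typically six)
nulled spectra, with the SD floored at 10% of the mean so noiseless
fixtures cannot create degenerate hard constraints.  The priors are data
the user can edit; no iterative auto-tuning of the prior values is
performed.

## Linear-combination fitting

Real-part fitting after phase optimization: the data are phased by
`e^{-i(φ₀+φ₁(ppm−ref))}` (φ₁ off by default — basis and data carry the
same truncation ramp) and fitted by non-negative amplitudes times the
real parts of the shifted/broadened basis spectra plus a cubic B-spline
baseline with knots every 0.4 ppm over 0.2–4.2 ppm.  At every step of
the outer bounded search (φ₀, shared Gaussian broadening γ ∈ [0, 20] Hz,
global shift ±0.05 ppm, optional per-component shifts ±0.01 ppm, lipids
±0.05 ppm) the linear subproblem is solved exactly: the spline subspace
is projected out with a precomputed orthonormal basis and the amplitudes
follow from NNLS on the projected system.  Data residuals are whitened
by the spectral noise SD estimated in a peak-free window (default −3 to
−1 ppm), which makes the fit scale-invariant and gives the dimensionless
ratio penalty `((aₓ − rₓ·a_MM1)/(σₓ·a_MM1))²` its natural weight
(`ratio_prior_weight`, default 1, exposed).  The penalty is linearized
in `a_MM1` at the unpenalized solution during the search and
re-linearized three times at the final point.  Setting
`per_component_shift_ppm = 0` freezes the per-component shifts onto the
global shift — appropriate whenever each voxel has a single frequency
offset, as in the phantoms — and is used for grid-scale runs.

Amplitude CRLBs: `100·sqrt((MᵀPM)⁻¹)ⱼⱼ·σ / aⱼ` with `P` the spline
annihilator and σ a robust (MAD) estimate from the fit residual;
entries fitted at zero report the sentinel 999%.  Priors are not folded
into the reported CRLBs.

## Pipeline and statistics

QA is conjunctive and strict: auto-exclusion only when CRLB\_NAA > 30%
**and** FWHM\_NAA > 20 Hz; voxels failing one criterion are flagged for
visual inspection but never auto-excluded, keeping the pipeline
deterministic.  Maps hide voxels whose component CRLB exceeds 30%.
Tissue fractions at MRSI resolution come from k-space truncation of the
high-resolution segmentation (centered crop at index n/2, 0-based
row-major; optional elliptical k-mask), which preserves the image mean
exactly before the [0, 1] clip.  "GM fraction" means the CSF-free
fraction f\_GM/(f\_GM+f\_WM); GM regressions exclude voxels with CSF
fraction above 20%.

Method comparison averages amplitudes per subject and method, then runs
a per-metabolite one-way repeated-measures ANOVA (no sphericity
correction by default; a Greenhouse–Geisser option exists) and paired
tests of each method against `full_MM`, Bonferroni-corrected by the
number of non-reference methods.  No correction is applied across
metabolites.  Percent differences are positive when a method reads
higher than `full_MM`.  A corpus generator plants qualitative
over-parameterization patterns for workflow demonstrations; its effect
sizes are fixtures, not measurements.

## Problem sizes and determinism

The test suite exercises: 20-seed parameterization recovery at SNR 50;
50-seed single-voxel Monte Carlo at SNR 40 for the prior-stabilization
comparison; 200 replicates at SNR 30 for CRLB validation; a 32×32
phantom slice at SNR 40 for the end-to-end check (the generator also
produces the native 64×64); and 500 null-corpus replicates for error
control.  All generators are pure functions of their parameters and a
seed; `scripts/acceptance.py` derives everything from `--seed`.

## Known limitations

* Estimators are validated on self-consistent synthetic data; in vivo
  lineshapes, baseline distortions and residual water are out of scope.
* The Hankel-SVD route inherits the Lorentzian model class; on Gaussian
  peaks its components are intrinsically biased toward narrower cores
  with heavier tails, and weak broad peaks are the least accurate.
* LCModel's exact baseline regularization and CHRATO weighting are
  proprietary; the spline spacing and prior weight here are declared
  analogs with exposed knobs.
* Absolute (water-scaled) quantification, eddy-current correction,
  multi-slice handling and partial-volume correction of amplitudes are
  not implemented.
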