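# Methods

This note documents the models behind each pdquant module, the defaults
and why they were chosen, what the synthetic-data generators do and do
not emulate, and the numerical choices that matter for reproducing or
extending the analyses.

## Synthetic data: what the generators emulate

All validation in this package runs against generators with known ground
truth. They emulate the *statistical structure* of each acquisition, not
the instrument physics:

- **Cell mosaics / membrane stacks** (`make_cell_mosaic`,
  `render_membrane_stack`). Epidermal tissue is approximated by a seeded
  Voronoi tessellation; the plasma-membrane (PM) signal is painted on
  cell–cell interfaces (pixels whose 3×3 neighborhood spans ≥2 cell
  labels) and extruded through z. Plasmodesmata-like puncta are placed at
  Poisson-sampled boundary positions (mean density `pd_per_100um` per
  100 µm of interface, default pixel size 0.1 µm) with a minimum
  separation of 8 px, an interior margin so their blurred support stays
  in-frame, and z confined to the interior planes. The optics are a
  single isotropic Gaussian PSF (default σ = 1 px); noise is Poisson shot
  noise on the photon image followed by additive Gaussian read noise.
  The blur uses a reflect boundary, which conserves total photon mass
  exactly — the basis of the photon-conservation test. Not emulated:
  vectorial/asymmetric PSFs, spectral bleed-through, 3D cell shape,
  depth-dependent attenuation. Passing tests therefore demonstrate
  correct recovery under idealized optics, not robustness to real
  aberrations.
- **Punctum amplitude calibration.** Each punctum is painted pre-blur as
  a flat disk (radius 2 px) whose amplitude is solved per site so that,
  in the blurred noiseless image, the mean over the canonical PD disk
  equals `pd_index_true` × the local PM level in the 3–7 px boundary
  annulus. The constructed truth is thus expressed in exactly the
  quantity `compute_pd_index` measures. A consequence is that the
  punctum *peak* overshoots `pd_index_true` × plateau (a blurred disk's
  peak exceeds its disk mean); the generator contract is the disk mean.
- **TCSPC decays** (`simulate_decay`). Expected counts per bin follow a
  sum of exponentials convolved with a Gaussian IRF under periodic
  excitation (default 25 ns period, i.e. 40 MHz): the tail of each pulse
  wraps into the next period and is summed explicitly (12 wraps, ample
  for τ ≤ ~8 ns). A uniform background fraction models dark counts and
  ambient light. Counts are Poisson. The true instrument response of a
  TCSPC system is not Gaussian and is not published for this class of
  experiment; the fit accepts a measured IRF histogram as an
  alternative (circular convolution on the bin grid).
- **Polarized pairs** (`simulate_polarized_pair`). The anisotropy
  formula is inverted analytically for the intensity split at a given
  total, so the noiseless pair reproduces `r_true` exactly; Poisson
  noise is applied per channel. Representable `r_true` is bounded by
  the formula's pole (r < 1/(1−3L₂)) and non-negativity.
- **FRAP traces** (`simulate_frap`). Single-exponential recovery toward
  the mobile plateau — the minimal identifiable model when only a 60 s
  endpoint is reported — with an instantaneous bleach, a shared
  multiplicative acquisition-photobleaching decay on all fluorescent
  channels, and background/reference channels. Gaussian noise, default
  2 s frames, 5 prebleach frames.
- **Luminescence** (`simulate_luminescence`). Baseline plus either a
  rectangular burst (half-open [onset, onset+width), which makes the
  trapezoidal integral of a grid-aligned rectangle exact) or a shape-2
  gamma kernel peaking at `burst_amplitude` — a reasonable luminol
  ROS-burst shape (onset ~minutes, peak ~10 min). Defaults: 1 min
  sampling over 30 min.
- **Bombardment counts** (`simulate_bombardment`). A scored site always
  shows the bombarded cell; the number of *additional* cells reached by
  GFP is negative binomial, so n_cells = 1 + NB(mean = µ − 1, size = k).
  This respects n_cells ≥ 1 exactly, hits the stated group means
  (µ_mock, µ_mock × treatment_ratio) exactly, and is overdispersed for
  finite k (k → ∞ gives a shifted Poisson with variance µ − 1). Default
  µ_mock = 5 cells/site, k = 5, 90 sites/group, six replicates —
  matching the scale of published bombardment experiments (n ≥ 84
  sites/group).

All generators take a mandatory integer seed and are bit-reproducible;
there is no hidden global random state.

## Spot detection (`image_quant.detect_spots`)

Pipeline: Gaussian smoothing (σ = 1 px; skipped along z for single-plane
stacks) → in-plane white top-hat with a radius-5 px disk (suppresses
diffuse background wider than a punctum) → global threshold → 3D
connected components (26-connectivity) → size gate (3–200 voxels).
Spot statistics — intensity-weighted centroid, voxel count, integrated
and mean intensity — are computed on the **original** voxels so the
reported fluorescence is unaffected by the detection filters. Spots are
sorted by integrated intensity (descending), ties by (z, y, x).

Numerical choices that required judgment:

- **Threshold.** The default `otsu` mode uses the *upper* threshold of a
  three-class multi-Otsu partition. Membrane images contain three
  intensity populations (dark cell interior, PM ridge, puncta); a
  two-class Otsu lands between interior and ridge, which merges the
  ridge and every punctum into one giant connected component and drives
  recall to zero. With three classes the upper threshold cleanly
  separates puncta from the ridge. `absolute` and `percentile` modes are
  available for manual control.
- **Border rule.** Components touching the lateral image border are
  discarded: their intensity support is truncated, and in synthetic
  renders the reflect boundary inflates border-adjacent ridge segments.
- **Monotonicity domain.** "Raising the absolute threshold never
  increases the spot count" holds in the punctum regime (thresholds at
  or above the automatic operating point, where single-peak puncta have
  nested level sets). Below the ridge level it is genuinely false for
  any pipeline with an upper size gate: the merged ridge component is
  filtered at low thresholds and fragments into countable pieces as the
  threshold rises. Tests assert the property on its valid domain.

Degenerate inputs: an all-zero stack yields an empty spot set (not an
error); a constant saturated stack yields an empty set with a warning.

## PD index (`derive_rois`, `compute_pd_index`)

PD ROIs are discrete disks (default radius 2 px) at spot centroids —
detected or annotated; the recovery tests annotate from generator truth,
mirroring manual ROI placement. PM ROIs are boundary pixels in the
3–7 px annulus around each spot, excluding every PD disk; spots whose
annulus is empty are dropped with a warning. The index is the pooled
mean over all PD pixels divided by the pooled mean over all PM pixels,
on a single user-selected plane (plasmodesmal enrichment is scored on
single-plane confocal images). Noiseless recovery at enrichment 2.0 is
accurate to better than ±0.1; residual bias comes from PSF spill of the
ridge into the PD disk and local boundary curvature.

## Anisotropy (`photophysics`)

Default ("standard") grouping:

r = (I∥ − G·I⊥) / ((1 − 3L₂)·I∥ + (2 − 3L₁)·G·I⊥)

This is the standard objective-NA-corrected form: G corrects the
detection-channel sensitivity ratio wherever I⊥ appears, and L₁/L₂ mix
polarizations to account for wide-aperture collection. It reduces
exactly to (I∥ − I⊥)/(I∥ + 2I⊥) at G = 1, L₁ = L₂ = 0. Published
versions of this equation are often typeset ambiguously; two alternative
groupings are selectable (`variant="literal"` drops G on the denominator
I⊥ term; `variant="classic"` ignores L₁/L₂) for sensitivity analysis.
Calibration defaults G = 0.481, L₁ = 0.013, L₂ = 0.037 correspond to a
63×/1.2 water-immersion objective with external polarized detectors.
Frame series are merged by summation; per-ROI anisotropy sums photons
over the ROI *before* taking the ratio (mean-of-pixel-r is biased at low
counts).

## Lifetime fitting and FRET (`fit_decay`, `delta_fret`)

The model per bin is Σᵢ Aᵢ·pᵢ(t; τᵢ) + B, where pᵢ are unit-mass
periodic IRF-convolved decay profiles, with Aᵢ, B > 0 enforced by log
parameterization. The exponential–Gaussian convolution uses the scaled
complementary error function (erfcx) with an asymptotic branch for deep
tails, so profiles remain finite across the full 25 ns window.

- **Poisson MLE, not least squares**: TCSPC bins in the tail hold few
  counts, where Gaussian weighting is wrong. The reported deviance is
  the Poisson deviance 2Σ[µ − c + c·ln(c/µ)].
- **Multi-start**: lifetimes start from the grid {0.5, 1, 2, 4} ns (all
  pairs for two components). The best one-component solution also seeds
  a degenerate two-component start (τ₂ = τ₁, split amplitudes), which
  guarantees the two-component deviance never exceeds the one-component
  deviance.
- **Bounds**: τ ∈ [0.02, 50] ns; fits failing from every start raise a
  fit-failure error with diagnostics. Histograms under 100 photons are
  rejected.
- τ_av is amplitude-weighted (Σατ/Σα), the convention in which
  pre-exponential factors count molecules; an intensity-weighted variant
  (Σατ²/Σατ) is provided.
- FRET efficiency E = 1 − τ_DA/τ_D; negative values are reported with a
  warning rather than clipped. Condition contrasts (`delta_fret`)
  average per-ROI efficiencies and report a seeded 2000-resample
  percentile bootstrap CI.

The acceptance computation simulates FRET conditions as a two-population
donor: a quenched component at 0.8 ns mixed with unquenched 2.9 ns
donors, with the mixing fraction solved so the amplitude-weighted τ_av
encodes the requested mean efficiency. The quenched lifetime value is a
free modeling choice; recovery of the efficiency *change* is insensitive
to it because both conditions share it. Problem size — 50 decays per
condition at 10⁵ photons, 256 bins — was chosen to match per-ROI photon
budgets typical of FLIM imaging while keeping the full chain under a
minute of CPU.

## FRAP (`kinetics`)

Double normalization (formula in the README) requires F_pre > B_pre and
R > B at every frame; violations raise a normalization error rather than
returning silently biased values. The mobile fraction defaults to the
60 s endpoint (mean of the 3 frames nearest t = 60 s postbleach) with
bleach-depth correction Mf = 100·(F̄ − F₀)/(1 − F₀); a single-exponential
plateau fit (`method="exp_fit"`) is provided for sensitivity checks and
agrees with the endpoint within 2 points when recovery is fast relative
to the window. Values outside [0, 100] are reported and flagged, not
clipped. Group comparisons use Welch t-tests (unequal variances across
constructs are expected); groups under n = 3 are excluded with a
warning.

## ROS integration (`integrate_luminescence`)

Trapezoidal integration of (signal − background) over the window
(default 0–25 min after elicitation), with linear interpolation at
window edges; plate-reader sampling is coarse and need not align with
the window. Background modes: mean of samples up to the window opening
(default), a paired water-control integral, or none (raw integral, which
is exactly additive over adjacent windows — the corrected integral is
not, because each window re-estimates its own baseline).

## Bombardment statistics (`connectivity_stats`)

Counts are normalized to the mock mean within genotype (mock mean = 1 by
construction, making treatment effects comparable across genotypes).
The default mock-vs-treated test is the two-sided Mann-Whitney rank-sum
— counts are small, discrete, and overdispersed, so rank tests are
preferable to t-tests — with a 10⁴-shuffle permutation test on the mean
difference as a cross-check. Measured type-I error at the default
conditions is ≈5.6% at nominal 5% (mild anticonservatism under heavy
ties). Replicate labels are carried but the default test pools sites,
as per-site analyses of this assay do.

Boxplot summaries use type-7 (linear interpolation) quartiles — stated
explicitly because quartile conventions differ across tools — whiskers
at the most extreme points within 1.5×IQR of the box (collapsing to the
box edge when every point on one side is an outlier), and notches at
median ± 1.58·IQR/√n, the standard approximate 95% CI of the median.

Multi-group comparisons: one-way ANOVA, Tukey HSD (scipy), and a compact
letter display built by insert-and-absorb — start with one letter shared
by all groups sorted by descending mean, split every letter containing a
significantly different pair, absorb subset letters. By construction two
groups share a letter iff their Tukey p ≥ α; the test suite verifies
this bipartite consistency exhaustively on every random instance.

## Pipeline and CLI

`pipeline.validate_config` merges a nested dict with defaults, rejects
unknown keys, and reports every range violation at once.
`run_pipeline` executes simulate → callose → compare; per-item failures
are logged in the report and skipped. Reports embed the package version,
seed and a SHA-256 config hash, and are byte-identical for identical
config + seed. The `pdquant` CLI is a thin click wrapper; all tabular
outputs are CSV with header rows and structured outputs JSON.

## Known limitations

- Gaussian-PSF, 2D-extruded synthetic tissue: detection performance on
  real aberrated stacks will be worse than the synthetic recall/precision
  figures.
- The decay model assumes a stationary IRF and uniform background; no
  afterpulsing or pile-up correction.
- No diffusion-coefficient estimation from FRAP (bleach geometry is not
  modeled) and no kinetic modeling of the ROS burst shape.
- Replicate structure is not modeled hierarchically by default; a
  replicate-stratified analysis would need mixed models outside the
  present scope.
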