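"""Ground-truth simulators for every input modality analyzed by pdquant.

None of the analyses in this package ship with raw microscope exports,
so each one is validated against a generator that emulates the relevant
acquisition with known ground truth:

* epidermal cell mosaics with plasma-membrane (PM) signal confined to
  cell-cell interfaces and puncta restricted to those interfaces, under
  Poisson shot noise and Gaussian read noise;
* TCSPC photon decays under 40 MHz pulsed excitation (25 ns period,
  wrapped tails) convolved with a Gaussian instrument response;
* polarized intensity pairs realizing an exact target anisotropy;
* FRAP recoveries with background/reference channels and acquisition
  photobleaching;
* luminol ROS-burst kinetics over a baseline;
* overdispersed (negative binomial) per-site bombardment counts with
  genotype x treatment effects.

All generators take a mandatory seed and are bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import InvalidArgumentError
from .image_quant import ImageStack
from .kinetics import FrapTrace, LumTrace
from .photophysics import (
    CalibrationConstants,
    DecayHistogram,
    IRFModel,
    PolarizedPair,
    decay_model_probabilities,
    invert_anisotropy,
)

__all__ = [
    "MosaicGroundTruth",
    "DecaySimSpec",
    "FrapSimSpec",
    "CountSimSpec",
    "make_cell_mosaic",
    "render_membrane_stack",
    "simulate_decay",
    "simulate_polarized_pair",
    "simulate_frap",
    "simulate_luminescence",
    "simulate_bombardment",
]


# ---------------------------------------------------------------------------
# Cell mosaic and membrane stack
# ---------------------------------------------------------------------------

@dataclass
class MosaicGroundTruth:
    """Ground truth for a rendered epidermal mosaic."""

    cell_label_image: np.ndarray  # (y, x) positive integer labels
    boundary_mask: np.ndarray  # (y, x) bool: pixels adjacent to >= 2 cells
    spot_truth: list = field(default_factory=list)  # (z, y, x, amplitude)
    pd_index_true: float = 1.0
    pm_intensity: float = 0.0  # photons / pixel painted on the boundary


def make_cell_mosaic(width: int, height: int, n_cells: int, seed: int) -> MosaicGroundTruth:
    """Voronoi tessellation of the field into ``n_cells`` cells.

    Seed points are drawn uniformly; every pixel is labeled by its
    nearest seed (labels 1..n_cells).  The boundary mask marks pixels
    whose 3x3 neighborhood contains more than one label, i.e. the
    cell-cell interfaces where the PM signal and plasmodesmata live.
    """
    if width < 32 or height < 32:
        raise InvalidArgumentError("width and height must be >= 32")
    if n_cells < 1:
        raise InvalidArgumentError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    seeds = np.column_stack(
        [rng.uniform(0, height, n_cells), rng.uniform(0, width, n_cells)]
    )
    yy, xx = np.mgrid[0:height, 0:width]
    _, idx = cKDTree(seeds).query(np.column_stack([yy.ravel(), xx.ravel()]))
    labels = (idx + 1).reshape(height, width).astype(np.int32)
    if n_cells == 1:
        boundary = np.zeros((height, width), dtype=bool)
    else:
        boundary = (
            ndimage.maximum_filter(labels, size=3) != ndimage.minimum_filter(labels, size=3)
        )
    return MosaicGroundTruth(cell_label_image=labels, boundary_mask=boundary)


def _gaussian_blur(img: np.ndarray, sigma) -> np.ndarray:
    # 'reflect' boundary conserves total mass for the symmetric kernel
    return ndimage.gaussian_filter(img, sigma, mode="reflect")


def _unit_punctum_profile(psf_sigma: float, spot_radius: int, n_z: int) -> np.ndarray:
    """PSF-blurred image of a unit-amplitude flat disk punctum.

    The punctum is painted as a flat in-plane disk (radius
    ``spot_radius``) in a single z-plane, then blurred with the same
    Gaussian PSF as the full render; additivity of the blur lets the
    full image be assembled by pasting scaled copies of this patch.
    """
    half = int(np.ceil(4 * psf_sigma)) + spot_radius + 1
    size = 2 * half + 1
    nz = min(n_z, size) if n_z > 1 else 1
    patch = np.zeros((nz, size, size))
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
    disk = (yy**2 + xx**2) <= spot_radius**2
    patch[nz // 2][disk] = 1.0
    sig_z = psf_sigma if nz > 1 else 0.0
    return ndimage.gaussian_filter(patch, (sig_z, psf_sigma, psf_sigma), mode="constant")


def render_membrane_stack(
    mosaic: MosaicGroundTruth,
    n_z: int,
    pd_per_100um: float,
    pd_index_true: float,
    pm_intensity: float,
    psf_sigma: float = 1.0,
    read_noise_sd: float = 2.0,
    seed: int = 0,
    pixel_size_xy: float = 0.1,
    z_step: float = 0.5,
    spot_radius: int = 2,
    pm_band: tuple = (3, 7),
    min_spot_separation: float = 8.0,
    shot_noise: bool = True,
):
    """Render a fluorescence z-stack over a cell mosaic with known puncta.

    PM signal (``pm_intensity`` photons/px) is painted on the boundary
    mask through all z-planes.  Puncta are placed at Poisson-sampled
    boundary positions at a mean linear density of ``pd_per_100um`` per
    100 um of interface.  Each punctum's amplitude is calibrated so
    that, in the blurred noiseless image, the mean over the canonical PD
    disk (radius ``spot_radius``) at the punctum equals
    ``pd_index_true`` times the local PM level in the ``pm_band``
    annulus — i.e. the constructed PD index is the requested one.

    Poisson shot noise is applied to the photon image (disable with
    ``shot_noise=False``) followed by additive Gaussian read noise.
    Returns ``(ImageStack, MosaicGroundTruth)`` with ``spot_truth``
    filled with (z, y, x, added peak amplitude).
    """
    if n_z < 1:
        raise InvalidArgumentError("n_z must be >= 1")
    if pm_intensity <= 0:
        raise InvalidArgumentError("pm_intensity must be > 0")
    if pd_index_true < 1:
        raise InvalidArgumentError("pd_index_true must be >= 1 for enriched puncta")
    rng = np.random.default_rng(seed)
    bmask = mosaic.boundary_mask
    h, w = bmask.shape

    pm_img = np.zeros((n_z, h, w))
    pm_img[:, bmask] = pm_intensity
    sig_z = psf_sigma if n_z > 1 else 0.0
    pm_blur = ndimage.gaussian_filter(pm_img, (sig_z, psf_sigma, psf_sigma), mode="reflect")

    # Poisson-placed puncta on the boundary, kept away from image edges so
    # the pasted punctum patches (and hence photon mass) stay in-frame.
    profile = _unit_punctum_profile(psf_sigma, spot_radius, n_z)
    margin = profile.shape[1] // 2 + 1
    cand = np.argwhere(bmask)
    cand = cand[
        (cand[:, 0] >= margin)
        & (cand[:, 0] < h - margin)
        & (cand[:, 1] >= margin)
        & (cand[:, 1] < w - margin)
    ]
    boundary_len_um = bmask.sum() * pixel_size_xy
    n_spots = rng.poisson(pd_per_100um * boundary_len_um / 100.0)

    positions = []
    if n_spots > 0 and len(cand) > 0:
        order = rng.permutation(len(cand))
        for i in order:
            y, x = cand[i]
            if all((y - py) ** 2 + (x - px) ** 2 >= min_spot_separation**2
                   for py, px in positions):
                positions.append((int(y), int(x)))
            if len(positions) == n_spots:
                break
    if n_spots > len(positions):
        warnings.warn(
            f"placed {len(positions)}/{n_spots} puncta (boundary too crowded)",
            stacklevel=2,
        )

    # calibration geometry matching image_quant.derive_rois defaults
    yy, xx = np.mgrid[0:h, 0:w]
    pz = profile.shape[0] // 2
    p_half = profile.shape[1] // 2
    dyy, dxx = np.mgrid[-p_half : p_half + 1, -p_half : p_half + 1]
    disk_local = (dyy**2 + dxx**2) <= spot_radius**2
    m_blob = profile[pz][disk_local].mean()

    # puncta are painted pre-blur as flat disks and blurred with the same
    # reflect-boundary Gaussian as the PM, so total photon mass is conserved
    z_margin = min(int(np.ceil(2 * psf_sigma)), (n_z - 1) // 2) if n_z > 1 else 0
    spot_img = np.zeros_like(pm_img)
    spot_truth = []
    pending = []
    for (y, x) in positions:
        z = int(rng.integers(z_margin, n_z - z_margin))
        d2 = (yy - y) ** 2 + (xx - x) ** 2
        disk = d2 <= spot_radius**2
        annulus = bmask & (d2 > pm_band[0] ** 2) & (d2 <= pm_band[1] ** 2)
        local_pm = pm_blur[z][annulus].mean() if annulus.any() else pm_blur[z][bmask].mean()
        m_ridge = pm_blur[z][disk].mean()
        amp = max((pd_index_true * local_pm - m_ridge) / m_blob, 0.0)
        spot_img[z][disk] += amp
        pending.append((z, y, x, amp))
    spot_blur = ndimage.gaussian_filter(
        spot_img, (sig_z, psf_sigma, psf_sigma), mode="reflect"
    )
    for z, y, x, amp in pending:
        spot_truth.append((z, y, x, amp * profile[pz, p_half, p_half]))
    noiseless = pm_blur + spot_blur

    img = noiseless
    if shot_noise:
        img = rng.poisson(img).astype(float)
    if read_noise_sd > 0:
        img = img + rng.normal(0.0, read_noise_sd, img.shape)
    img = np.clip(img, 0.0, None)

    truth = MosaicGroundTruth(
        cell_label_image=mosaic.cell_label_image,
        boundary_mask=bmask,
        spot_truth=spot_truth,
        pd_index_true=pd_index_true,
        pm_intensity=pm_intensity,
    )
    stack = ImageStack(img, pixel_size_xy=pixel_size_xy, z_step=z_step,
                       channel_name="membrane")
    return stack, truth


def render_noiseless_membrane_stack(mosaic, n_z, pd_per_100um, pd_index_true,
                                    pm_intensity, psf_sigma=1.0, seed=0, **kw):
    """Convenience wrapper: render with shot and read noise disabled."""
    return render_membrane_stack(
        mosaic, n_z, pd_per_100um, pd_index_true, pm_intensity,
        psf_sigma=psf_sigma, read_noise_sd=0.0, seed=seed, shot_noise=False, **kw
    )


# ---------------------------------------------------------------------------
# TCSPC decay simulation
# ---------------------------------------------------------------------------

@dataclass
class DecaySimSpec:
    """Parameters of a simulated multi-exponential TCSPC decay."""

    lifetimes: tuple = (2.5,)  # ns
    amplitude_fractions: tuple = (1.0,)  # sum to 1
    repetition_period: float = 25.0  # ns (40 MHz)
    irf_sigma: float = 0.1  # ns
    irf_center: float = 2.0  # ns
    n_photons: int = 100_000
    n_bins: int = 256
    background_fraction: float = 0.0

    def __post_init__(self):
        lt = np.asarray(self.lifetimes, dtype=float)
        af = np.asarray(self.amplitude_fractions, dtype=float)
        if lt.size != af.size or lt.size == 0:
            raise InvalidArgumentError("lifetimes/amplitude_fractions size mismatch")
        if np.any(lt <= 0):
            raise InvalidArgumentError("lifetimes must be positive")
        if np.any(af <= 0):
            raise InvalidArgumentError("amplitude fractions must be positive")
        if abs(af.sum() - 1.0) > 1e-9:
            raise InvalidArgumentError("amplitude fractions must sum to 1")
        if self.irf_sigma < 0:
            raise InvalidArgumentError("irf_sigma must be >= 0")
        if self.n_photons < 0:
            raise InvalidArgumentError("n_photons must be >= 0")
        if self.n_bins < 2:
            raise InvalidArgumentError("n_bins must be >= 2")
        if not 0 <= self.background_fraction < 1:
            raise InvalidArgumentError("background_fraction must be in [0, 1)")


def expected_decay_counts(spec: DecaySimSpec) -> tuple:
    """(bin_centers, expected counts per bin) for a decay spec."""
    dt = spec.repetition_period / spec.n_bins
    centers = (np.arange(spec.n_bins) + 0.5) * dt
    irf = IRFModel(kind="gaussian", center=spec.irf_center, sigma=spec.irf_sigma)
    p = np.zeros(spec.n_bins)
    for tau, frac in zip(spec.lifetimes, spec.amplitude_fractions):
        p += frac * decay_model_probabilities(centers, tau, irf, spec.repetition_period)
    expected = spec.n_photons * (
        (1.0 - spec.background_fraction) * p
        + spec.background_fraction / spec.n_bins
    )
    return centers, expected


def simulate_decay(spec: DecaySimSpec, seed: int) -> DecayHistogram:
    """Draw a Poisson TCSPC histogram from the expected counts of a DecaySimSpec."""
    centers, expected = expected_decay_counts(spec)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(expected)
    return DecayHistogram(bin_centers=centers, counts=counts,
                          repetition_period=spec.repetition_period)


# ---------------------------------------------------------------------------
# Polarized pair
# ---------------------------------------------------------------------------

def simulate_polarized_pair(
    r_true: float,
    total_counts: float,
    calib: CalibrationConstants | None = None,
    noise: str = "none",
    seed: int = 0,
    variant: str = "standard",
) -> PolarizedPair:
    """Produce (I_par, I_perp) whose noiseless anisotropy is exactly r_true.

    The anisotropy formula is inverted for the intensity ratio at the
    requested total; with ``noise='poisson'`` both channels are then
    Poisson-sampled (channel counts are independent photon counts).
    """
    if noise not in ("none", "poisson"):
        raise InvalidArgumentError(f"unknown noise mode {noise!r}")
    calib = calib or CalibrationConstants()
    p, q = invert_anisotropy(r_true, total_counts, calib, variant)
    if noise == "poisson":
        rng = np.random.default_rng(seed)
        p = float(rng.poisson(p))
        q = float(rng.poisson(q))
    return PolarizedPair(I_par=p, I_perp=q, n_frames_merged=1)


# ---------------------------------------------------------------------------
# FRAP
# ---------------------------------------------------------------------------

@dataclass
class FrapSimSpec:
    """Single-exponential FRAP recovery with acquisition photobleaching."""

    prebleach_level: float = 1000.0  # a.u.
    bleach_depth: float = 0.3  # fraction of prebleach remaining at t=0+
    mobile_fraction_true: float = 50.0  # percent
    recovery_tau: float = 10.0  # s
    acquisition_bleach_rate: float = 0.0  # 1/s
    noise_sd: float = 0.0  # a.u.
    frame_interval: float = 2.0  # s
    n_pre: int = 5
    n_post: int = 35
    background_level: float = 50.0  # a.u.

    def __post_init__(self):
        if not 0 <= self.mobile_fraction_true <= 100:
            raise InvalidArgumentError("mobile_fraction_true must be in [0, 100]")
        if self.recovery_tau <= 0:
            raise InvalidArgumentError("recovery_tau must be > 0")
        if not 0 <= self.bleach_depth < 1:
            raise InvalidArgumentError("bleach_depth must be in [0, 1)")
        if self.acquisition_bleach_rate < 0 or self.noise_sd < 0:
            raise InvalidArgumentError("rates and noise must be >= 0")
        if self.n_pre < 2 or self.n_post < 1:
            raise InvalidArgumentError("need n_pre >= 2 and n_post >= 1")
        if self.frame_interval <= 0:
            raise InvalidArgumentError("frame_interval must be > 0")


def simulate_frap(spec: FrapSimSpec, seed: int) -> FrapTrace:
    """Simulate a FRAP trace with background and reference channels.

    The normalized noiseless recovery is
    F(t) = F0 + (Mf/100)(1 - F0)(1 - exp(-t/tau)), with F0 the bleach
    depth; all fluorescent channels are multiplied by
    exp(-acquisition_bleach_rate * t_total) for imaging-induced
    photobleaching, which double normalization against the reference
    removes.  Gaussian noise of ``noise_sd`` is added per channel.
    """
    if spec.n_post * spec.frame_interval < spec.recovery_tau / 10.0:
        warnings.warn(
            "postbleach window shorter than recovery_tau/10: recovery "
            "unidentifiable", stacklevel=2,
        )
    n = spec.n_pre + spec.n_post
    t = np.arange(n) * spec.frame_interval
    t_post = t[spec.n_pre :] - t[spec.n_pre]

    f0 = spec.bleach_depth
    mf = spec.mobile_fraction_true / 100.0
    rec = f0 + mf * (1.0 - f0) * (1.0 - np.exp(-t_post / spec.recovery_tau))
    f_norm = np.concatenate([np.ones(spec.n_pre), rec])

    acq = np.exp(-spec.acquisition_bleach_rate * t)
    bleach = spec.background_level + spec.prebleach_level * f_norm * acq
    reference = spec.background_level + spec.prebleach_level * acq
    background = np.full(n, spec.background_level)

    rng = np.random.default_rng(seed)
    if spec.noise_sd > 0:
        bleach = bleach + rng.normal(0, spec.noise_sd, n)
        reference = reference + rng.normal(0, spec.noise_sd, n)
        background = background + rng.normal(0, spec.noise_sd / 4.0, n)
    return FrapTrace(
        time=t,
        bleach_roi=bleach,
        background_roi=background,
        reference_roi=reference,
        bleach_frame_index=spec.n_pre,
    )


# ---------------------------------------------------------------------------
# Luminescence
# ---------------------------------------------------------------------------

def simulate_luminescence(
    baseline: float = 50.0,
    burst_amplitude: float = 500.0,
    burst_onset: float = 2.0,
    burst_shape: str = "gamma",
    duration: float = 30.0,
    interval: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    burst_width: float = 10.0,
    well_id: str = "",
    treatment: str = "chitin",
    genotype: str = "Col-0",
) -> LumTrace:
    """Simulate a plate-reader luminescence trace (times in minutes).

    'gamma' bursts rise and decay like a chitin-triggered ROS burst
    (shape-2 gamma kernel scaled to peak at ``burst_amplitude``);
    'rect' bursts are ``burst_amplitude`` on [onset, onset + burst_width)
    — the half-open convention makes the trapezoidal integral of a
    grid-aligned rectangle exact.
    """
    if burst_amplitude < 0:
        raise InvalidArgumentError("burst_amplitude must be >= 0")
    if interval <= 0:
        raise InvalidArgumentError("interval must be > 0")
    if duration < 25.0:
        raise InvalidArgumentError("duration must cover >= 25 min")
    if burst_shape not in ("gamma", "rect"):
        raise InvalidArgumentError(f"unknown burst_shape {burst_shape!r}")
    t = np.arange(0.0, duration + interval / 2.0, interval)
    if burst_shape == "rect":
        sig = np.where((t >= burst_onset) & (t < burst_onset + burst_width),
                       burst_amplitude, 0.0)
    else:
        u = np.clip(t - burst_onset, 0.0, None)
        theta = burst_width / 2.0
        kern = (u / theta) ** 2 * np.exp(-u / theta)
        peak = 4.0 * np.exp(-2.0)  # max of (u/theta)^2 exp(-u/theta)
        sig = burst_amplitude * kern / peak
    rlu = baseline + sig
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        rlu = rlu + rng.normal(0, noise_sd, rlu.shape)
    return LumTrace(time=t, rlu=rlu, well_id=well_id, treatment=treatment,
                    genotype=genotype)


# ---------------------------------------------------------------------------
# Bombardment counts
# ---------------------------------------------------------------------------

@dataclass
class CountSimSpec:
    """Shifted negative-binomial per-site GFP-spread counts.

    A scored site always shows the bombarded cell itself; the number of
    *additional* cells reached by GFP movement is the random part and is
    drawn negative-binomial, so n_cells = 1 + NB(mean = mu - 1, size = k).
    Group means are then exactly ``mu_mock`` (mock) and
    ``mu_mock * treatment_ratio`` (treated).  ``dispersion`` is the NB
    size parameter k; k -> infinity recovers a shifted Poisson.
    """

    mu_mock: float = 5.0  # mean cells / site under mock
    treatment_ratio: float = 0.6  # multiplicative treatment effect
    dispersion: float = 5.0  # NB size parameter k > 0
    n_sites_per_group: int = 90
    genotypes: tuple = ("Col-0",)
    treatment: str = "chitin"
    n_replicates: int = 6

    def __post_init__(self):
        if self.mu_mock <= 0 or self.treatment_ratio <= 0 or self.dispersion <= 0:
            raise InvalidArgumentError("mu_mock, treatment_ratio, dispersion must be > 0")
        if self.mu_mock < 1 or self.mu_mock * self.treatment_ratio < 1:
            raise InvalidArgumentError(
                "group means must be >= 1 (each site shows at least one cell)"
            )
        if self.n_sites_per_group < 1:
            raise InvalidArgumentError("n_sites_per_group must be >= 1")


def _nb_draw(rng, mu, k, size):
    # numpy's negative_binomial(n, p): mean = n(1-p)/p; set n=k, p=k/(k+mu)
    if mu <= 0:
        return np.zeros(size, dtype=int)
    return rng.negative_binomial(k, k / (k + mu), size)


def simulate_bombardment(spec: CountSimSpec, seed: int) -> pd.DataFrame:
    """Per-site count table (genotype, treatment, replicate, n_cells)."""
    rng = np.random.default_rng(seed)
    rows = []
    for genotype in spec.genotypes:
        for treatment, mu in (
            ("mock", spec.mu_mock),
            (spec.treatment, spec.mu_mock * spec.treatment_ratio),
        ):
            counts = 1 + _nb_draw(rng, mu - 1.0, spec.dispersion, spec.n_sites_per_group)
            reps = rng.integers(1, spec.n_replicates + 1, spec.n_sites_per_group)
            for c, r in zip(counts, reps):
                rows.append(
                    {"genotype": genotype, "treatment": treatment,
                     "replicate": int(r), "n_cells": int(c)}
                )
    return pd.DataFrame(rows, columns=["genotype", "treatment", "replicate", "n_cells"])
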