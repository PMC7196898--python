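"""Steady-state anisotropy and TCSPC lifetime analysis.

Two photophysical readouts of receptor association in the plasma membrane
are implemented here:

* **Homo-FRET via steady-state anisotropy.**  Polarization-resolved
  intensities (parallel / perpendicular to the excitation polarization)
  are combined into the anisotropy ``r`` with a G-factor correcting the
  relative detection-channel sensitivity and two mixing terms (``L1``,
  ``L2``) correcting depolarization by the high-NA objective.  Lower
  ``r`` for an immobile tagged protein indicates energy transfer between
  identical fluorophores, i.e. clustering.

* **Hetero-FRET via fluorescence lifetime.**  TCSPC photon-arrival
  histograms are fitted with a multi-exponential decay convolved with
  the instrument response function under periodic pulsed excitation.
  Donor quenching by an acceptor shortens the amplitude-weighted average
  lifetime tau_av, from which the FRET efficiency E = 1 - tau_DA/tau_D
  follows.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import erfcx

from .errors import (
    FitFailureError,
    InvalidArgumentError,
    LowCountError,
    UndefinedRatioError,
)

__all__ = [
    "CalibrationConstants",
    "PolarizedPair",
    "DecayHistogram",
    "IRFModel",
    "LifetimeFit",
    "merge_frames",
    "compute_anisotropy",
    "invert_anisotropy",
    "anisotropy_by_roi",
    "decay_model_probabilities",
    "fit_decay",
    "amplitude_weighted_lifetime",
    "fret_efficiency",
    "delta_fret",
]

ANISOTROPY_VARIANTS = ("standard", "literal", "classic")


@dataclass(frozen=True)
class CalibrationConstants:
    """Polarization calibration: G-factor and high-NA mixing terms.

    Defaults are the constants calibrated for the 63x/1.2 water-immersion
    objective used for the Citrine/GFP anisotropy measurements.
    """

    G: float = 0.481
    L1: float = 0.013
    L2: float = 0.037

    def __post_init__(self):
        if not self.G > 0:
            raise InvalidArgumentError(f"G must be > 0, got {self.G}")
        for name, value in (("L1", self.L1), ("L2", self.L2)):
            if not (0.0 <= value < 1.0 / 3.0):
                raise InvalidArgumentError(
                    f"{name} must lie in [0, 1/3), got {value}"
                )


@dataclass
class PolarizedPair:
    """Parallel / perpendicular detection-channel intensities.

    Scalars for a single ROI or equally shaped per-pixel maps.
    """

    I_par: np.ndarray | float
    I_perp: np.ndarray | float
    n_frames_merged: int = 1


@dataclass
class DecayHistogram:
    """TCSPC photon counts per arrival-time bin within one laser period."""

    bin_centers: np.ndarray  # ns, ascending, equally spaced
    counts: np.ndarray  # non-negative integers
    repetition_period: float  # ns

    def __post_init__(self):
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.bin_centers.ndim != 1 or self.bin_centers.size < 2:
            raise InvalidArgumentError("need >= 2 time bins")
        diffs = np.diff(self.bin_centers)
        if not np.all(diffs > 0):
            raise InvalidArgumentError("bin_centers must be ascending")
        if not np.allclose(diffs, diffs[0], rtol=1e-6):
            raise InvalidArgumentError("bins must be equally spaced")
        if self.counts.shape != self.bin_centers.shape:
            raise InvalidArgumentError("counts/bin_centers shape mismatch")
        if np.any(self.counts < 0):
            raise InvalidArgumentError("counts must be non-negative")
        span = self.bin_centers[-1] - self.bin_centers[0] + diffs[0]
        if span > self.repetition_period * (1 + 1e-9):
            raise InvalidArgumentError("bin span exceeds repetition period")

    @property
    def bin_width(self) -> float:
        return float(self.bin_centers[1] - self.bin_centers[0])


@dataclass
class IRFModel:
    """Instrument response function: analytic Gaussian or a measured histogram."""

    kind: str = "gaussian"  # {"gaussian", "measured"}
    center: float = 0.0  # ns
    sigma: float = 0.0  # ns, >= 0
    measured: np.ndarray | None = None  # counts on the decay's bin grid

    def __post_init__(self):
        if self.kind not in ("gaussian", "measured"):
            raise InvalidArgumentError(f"unknown IRF kind {self.kind!r}")
        if self.kind == "gaussian" and self.sigma < 0:
            raise InvalidArgumentError("IRF sigma must be >= 0")
        if self.kind == "measured":
            if self.measured is None:
                raise InvalidArgumentError("measured IRF requires a histogram")
            m = np.asarray(self.measured, dtype=float)
            total = m.sum()
            if total <= 0:
                raise InvalidArgumentError("measured IRF must have positive area")
            self.measured = m / total


@dataclass
class LifetimeFit:
    """Result of a multi-exponential Poisson-MLE decay fit."""

    amplitudes: np.ndarray  # fractions, sum to 1
    lifetimes: np.ndarray  # ns, ascending
    background: float  # counts per bin
    tau_av: float  # ns, amplitude-weighted
    fit_deviance: float
    n_components: int
    n_photons_fit: float = 0.0
    converged: bool = True


# ---------------------------------------------------------------------------
# Anisotropy
# ---------------------------------------------------------------------------

def merge_frames(frames) -> PolarizedPair:
    """Sum a frame series into one pair (photon-count accumulation)."""
    frames = list(frames)
    if len(frames) == 0:
        raise InvalidArgumentError("need at least one frame")
    par = np.asarray(frames[0].I_par, dtype=float).copy()
    perp = np.asarray(frames[0].I_perp, dtype=float).copy()
    for f in frames[1:]:
        p = np.asarray(f.I_par, dtype=float)
        q = np.asarray(f.I_perp, dtype=float)
        if p.shape != par.shape or q.shape != perp.shape:
            raise InvalidArgumentError("frame shapes do not match")
        par += p
        perp += q
    if par.ndim == 0:
        par, perp = float(par), float(perp)
    return PolarizedPair(par, perp, n_frames_merged=len(frames))


def _anisotropy_terms(I_par, I_perp, calib: CalibrationConstants, variant: str):
    if variant not in ANISOTROPY_VARIANTS:
        raise InvalidArgumentError(
            f"variant must be one of {ANISOTROPY_VARIANTS}, got {variant!r}"
        )
    G, L1, L2 = calib.G, calib.L1, calib.L2
    num = I_par - G * I_perp
    if variant == "standard":
        den = (1.0 - 3.0 * L2) * I_par + (2.0 - 3.0 * L1) * G * I_perp
    elif variant == "literal":
        # As printed in some method sections: no G on the denominator term.
        den = (1.0 - 3.0 * L2) * I_par + (2.0 - 3.0 * L1) * I_perp
    else:  # classic
        den = I_par + 2.0 * G * I_perp
    return num, den


def compute_anisotropy(
    pair: PolarizedPair,
    calib: CalibrationConstants | None = None,
    variant: str = "standard",
):
    """High-NA-corrected steady-state anisotropy.

    Default ("standard") form::

        r = (I_par - G I_perp) / ((1 - 3 L2) I_par + (2 - 3 L1) G I_perp)

    which reduces to the textbook (I_par - I_perp) / (I_par + 2 I_perp)
    at G = 1, L1 = L2 = 0.  The "literal" variant drops the G on the
    denominator's perpendicular term; "classic" ignores L1/L2 entirely.
    """
    calib = calib or CalibrationConstants()
    I_par = np.asarray(pair.I_par, dtype=float)
    I_perp = np.asarray(pair.I_perp, dtype=float)
    num, den = _anisotropy_terms(I_par, I_perp, calib, variant)
    if np.any(den == 0):
        raise UndefinedRatioError("anisotropy denominator is zero")
    r = num / den
    if r.ndim == 0:
        return float(r)
    return r


def invert_anisotropy(
    r_true: float,
    total_counts: float,
    calib: CalibrationConstants | None = None,
    variant: str = "standard",
):
    """Solve for (I_par, I_perp) with I_par + I_perp = total and anisotropy r_true.

    Raises InvalidArgumentError when no non-negative intensity pair attains
    r_true under the configured formula.
    """
    calib = calib or CalibrationConstants()
    G, L1, L2 = calib.G, calib.L1, calib.L2
    if variant == "standard":
        a_par, a_perp = (1.0 - 3.0 * L2), (2.0 - 3.0 * L1) * G
    elif variant == "literal":
        a_par, a_perp = (1.0 - 3.0 * L2), (2.0 - 3.0 * L1)
    elif variant == "classic":
        a_par, a_perp = 1.0, 2.0 * G
    else:
        raise InvalidArgumentError(f"unknown variant {variant!r}")
    # r (a_par p + a_perp q) = p - G q  with  p + q = total
    c_num = G + r_true * a_perp  # p/q = c_num / c_den
    c_den = 1.0 - r_true * a_par
    if c_den <= 0 or c_num < 0:
        raise InvalidArgumentError(
            f"r_true={r_true} is outside the representable range of the "
            f"{variant} anisotropy formula"
        )
    ratio = c_num / c_den
    q = total_counts / (1.0 + ratio)
    p = total_counts - q
    return p, q


def anisotropy_by_roi(
    pair: PolarizedPair,
    rois,
    calib: CalibrationConstants | None = None,
    variant: str = "standard",
) -> dict:
    """Photon-weighted per-ROI anisotropy.

    Intensities are summed over each ROI's pixels *before* the ratio is
    taken; averaging per-pixel r would be biased at low counts.  ``rois``
    is an :class:`~pdquant.image_quant.ROISet` or any iterable of objects
    with ``label`` and ``pixels`` ((N, 2) array of (y, x)) attributes.
    Empty ROIs are skipped with a warning.
    """
    calib = calib or CalibrationConstants()
    par = np.asarray(pair.I_par, dtype=float)
    perp = np.asarray(pair.I_perp, dtype=float)
    if par.ndim != 2 or par.shape != perp.shape:
        raise InvalidArgumentError("per-pixel pair must be two congruent 2D maps")
    roi_list = getattr(rois, "rois", rois)
    out = {}
    for roi in roi_list:
        pix = np.asarray(roi.pixels)
        if pix.size == 0:
            warnings.warn(f"ROI {roi.label!r} is empty; skipped", stacklevel=2)
            continue
        ys, xs = pix[:, 0], pix[:, 1]
        if ys.min() < 0 or ys.max() >= par.shape[0] or xs.min() < 0 or xs.max() >= par.shape[1]:
            raise InvalidArgumentError(f"ROI {roi.label!r} exceeds image bounds")
        summed = PolarizedPair(float(par[ys, xs].sum()), float(perp[ys, xs].sum()))
        out[roi.label] = compute_anisotropy(summed, calib, variant)
    return out


# ---------------------------------------------------------------------------
# TCSPC decay model and fitting
# ---------------------------------------------------------------------------

_SQRT2 = math.sqrt(2.0)


def _exp_conv_gauss(t, tau, sigma):
    """Normalized (1/tau) exp(-t/tau) H(t) convolved with N(0, sigma^2).

    Numerically stable via erfcx for arguments far into the tail.
    """
    t = np.asarray(t, dtype=float)
    if sigma <= 0:
        out = np.zeros_like(t)
        pos = t >= 0
        out[pos] = np.exp(-t[pos] / tau) / tau
        return out
    b = (sigma / tau - t / sigma) / _SQRT2
    out = np.empty_like(t)
    safe = b > -6.0
    out[safe] = (0.5 / tau) * np.exp(-0.5 * (t[safe] / sigma) ** 2) * erfcx(b[safe])
    ts = t[~safe]
    out[~safe] = (1.0 / tau) * np.exp(0.5 * (sigma / tau) ** 2 - ts / tau)
    return out


def decay_model_probabilities(
    bin_centers: np.ndarray,
    tau: float,
    irf: IRFModel,
    repetition_period: float,
    n_wraps: int = 12,
) -> np.ndarray:
    """Per-bin probabilities of a single-exponential decay under periodic
    pulsed excitation, convolved with the IRF; normalized to sum to 1.

    Periodic excitation wraps the tail of each pulse into the next
    period, so the observed decay in one period is the geometric sum of
    shifted copies; ``n_wraps`` copies are summed explicitly (ample for
    lifetimes a few times shorter than the period).
    """
    if tau <= 0:
        raise InvalidArgumentError("lifetime must be positive")
    t = np.asarray(bin_centers, dtype=float)
    if irf.kind == "gaussian":
        offsets = repetition_period * np.arange(n_wraps + 1)
        shifted = t[None, :] + offsets[:, None] - irf.center
        p = _exp_conv_gauss(shifted.ravel(), tau, irf.sigma).reshape(shifted.shape).sum(0)
    else:
        # Measured IRF: circular convolution on the bin grid, which is the
        # natural operation under periodic excitation.
        offsets = repetition_period * np.arange(n_wraps + 1)
        shifted = t[None, :] + offsets[:, None] - t[0]
        base = _exp_conv_gauss(shifted.ravel(), tau, 0.0).reshape(shifted.shape).sum(0)
        p = np.real(np.fft.ifft(np.fft.fft(base) * np.fft.fft(irf.measured)))
        p = np.clip(p, 0.0, None)
    total = p.sum()
    if total <= 0:
        raise FitFailureError("decay model has zero mass on the bin grid")
    return p / total


def _model_counts(x, basis_taus_cache, hist, irf):
    """Expected counts per bin from the packed parameter vector
    (log tau_1..k, log A_1..k, log B); k inferred from the length."""
    k = (len(x) - 1) // 2
    log_taus = x[:k]
    log_amps = x[k : 2 * k]
    log_bg = x[-1]
    mu = np.full(hist.counts.shape, math.exp(log_bg))
    for lt, la in zip(log_taus, log_amps):
        tau = math.exp(lt)
        key = round(lt, 12)
        if key not in basis_taus_cache:
            basis_taus_cache[key] = decay_model_probabilities(
                hist.bin_centers, tau, irf, hist.repetition_period
            )
        mu = mu + math.exp(la) * basis_taus_cache[key]
    return mu


def _poisson_deviance(counts, mu):
    mu = np.clip(mu, 1e-12, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(counts > 0, counts * np.log(counts / mu), 0.0)
    return float(2.0 * np.sum(mu - counts + term))


def fit_decay(
    hist: DecayHistogram,
    irf: IRFModel,
    n_components: int = 2,
) -> LifetimeFit:
    """Poisson maximum-likelihood fit of a 1- or 2-exponential decay.

    The model per bin is ``sum_i A_i p_i(t; tau_i) + B`` with ``p_i`` the
    periodic IRF-convolved decay probabilities, amplitudes ``A_i`` and a
    uniform background ``B`` all constrained positive by a log
    parameterization.  Optimization is multi-start over a lifetime grid
    {0.5, 1, 2, 4} ns; for two components the best single-component
    solution additionally seeds a degenerate start so the two-component
    deviance can never exceed the one-component deviance.
    """
    if n_components not in (1, 2):
        raise InvalidArgumentError("n_components must be 1 or 2")
    counts = np.asarray(hist.counts, dtype=float)
    total = counts.sum()
    if total < 100:
        raise LowCountError(f"need >= 100 photons to fit, got {total:g}")

    cache: dict = {}
    nbins = counts.size

    def nll(x):
        mu = _model_counts(x, cache, hist, irf)
        mu = np.clip(mu, 1e-12, None)
        return float(np.sum(mu) - np.sum(counts * np.log(mu)))

    grid = [0.5, 1.0, 2.0, 4.0]
    bg0 = max(total * 0.01 / nbins, 1e-3)

    def starts_1():
        for tau in grid:
            yield np.array([math.log(tau), math.log(max(total - bg0 * nbins, 1.0)), math.log(bg0)])

    def run(x0):
        # keep lifetimes in a physically sensible window, amplitudes finite
        k = (len(x0) - 1) // 2
        bounds = (
            [(math.log(0.02), math.log(50.0))] * k
            + [(-5.0, math.log(10.0 * total) + 1.0)] * k
            + [(-20.0, math.log(total) + 1.0)]
        )
        res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8})
        return res

    diagnostics = {"starts": 0, "messages": []}

    def best_of(starts):
        best = None
        for x0 in starts:
            diagnostics["starts"] += 1
            res = run(x0)
            if not np.isfinite(res.fun):
                diagnostics["messages"].append(str(res.message))
                continue
            if best is None or res.fun < best.fun:
                best = res
        return best

    if n_components == 1:
        best = best_of(starts_1())
    else:
        one = best_of(starts_1())
        starts = []
        from itertools import combinations

        for t1, t2 in combinations(grid, 2):
            a = max((total - bg0 * nbins) / 2.0, 1.0)
            starts.append(np.array([math.log(t1), math.log(t2),
                                    math.log(a), math.log(a), math.log(bg0)]))
        if one is not None:
            lt, la, lb = one.x
            starts.append(np.array([lt, lt, la - math.log(2.0), la - math.log(2.0), lb]))
        best = best_of(starts)

    if best is None:
        raise FitFailureError("decay fit failed from every start", diagnostics)

    x = best.x
    taus = np.exp(x[:n_components])
    amps = np.exp(x[n_components : 2 * n_components])
    bg = math.exp(x[-1])
    order = np.argsort(taus)
    taus, amps = taus[order], amps[order]
    fracs = amps / amps.sum()
    tau_av = float(np.sum(fracs * taus))
    mu = _model_counts(x, cache, hist, irf)
    dev = _poisson_deviance(counts, mu)
    return LifetimeFit(
        amplitudes=fracs,
        lifetimes=taus,
        background=bg,
        tau_av=tau_av,
        fit_deviance=dev,
        n_components=n_components,
        n_photons_fit=float(amps.sum()),
        converged=bool(best.success),
    )


def amplitude_weighted_lifetime(fit: LifetimeFit) -> float:
    """tau_av = sum(alpha_i tau_i) / sum(alpha_i).

    The amplitude weighting matches the convention in which each decay
    component's pre-exponential factor counts excited molecules; an
    intensity-weighted variant would weight by alpha_i tau_i instead.
    """
    alphas = np.asarray(fit.amplitudes, dtype=float)
    taus = np.asarray(fit.lifetimes, dtype=float)
    s = alphas.sum()
    if s == 0:
        raise UndefinedRatioError("amplitude sum is zero")
    return float(np.sum(alphas * taus) / s)


def intensity_weighted_lifetime(fit: LifetimeFit) -> float:
    """tau = sum(alpha_i tau_i^2) / sum(alpha_i tau_i) (optional convention)."""
    alphas = np.asarray(fit.amplitudes, dtype=float)
    taus = np.asarray(fit.lifetimes, dtype=float)
    s = np.sum(alphas * taus)
    if s == 0:
        raise UndefinedRatioError("intensity weight sum is zero")
    return float(np.sum(alphas * taus**2) / s)


def fret_efficiency(tau_da: float, tau_d: float) -> float:
    """E = 1 - tau_DA / tau_D; negative values (tau_DA > tau_D) are
    reported as-is with a warning so apparent 'negative FRET' can be
    inspected rather than silently clipped."""
    if tau_d <= 0:
        raise InvalidArgumentError("donor-only lifetime must be positive")
    if tau_da < 0:
        raise InvalidArgumentError("donor-acceptor lifetime must be >= 0")
    e = 1.0 - tau_da / tau_d
    if e < 0:
        warnings.warn(
            f"negative FRET efficiency {e:.4f} (tau_DA > tau_D)", stacklevel=2
        )
    return e


def delta_fret(
    tau_d: float,
    tau_da_condition_a,
    tau_da_condition_b,
    n_boot: int = 2000,
    seed: int = 0,
):
    """Difference in mean FRET efficiency between two conditions.

    Each condition is a list of per-ROI amplitude-weighted lifetimes.
    Returns (delta_E_percent, (ci_low, ci_high)) where the CI is a
    seeded percentile bootstrap over ROIs (2.5/97.5 percentiles).
    """
    if tau_d <= 0:
        raise InvalidArgumentError("donor-only lifetime must be positive")
    a = np.asarray(list(tau_da_condition_a), dtype=float)
    b = np.asarray(list(tau_da_condition_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidArgumentError("both condition lists must be non-empty")
    e_a = 1.0 - a / tau_d
    e_b = 1.0 - b / tau_d
    delta = 100.0 * (e_a.mean() - e_b.mean())
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        ra = rng.choice(e_a, size=e_a.size, replace=True)
        rb = rng.choice(e_b, size=e_b.size, replace=True)
        boots[i] = 100.0 * (ra.mean() - rb.mean())
    ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    return float(delta), ci
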