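"""FRAP mobile-fraction estimation and ROS-burst luminescence integration.

FRAP traces carry three channels: the bleached ROI, a background ROI and
an unbleached reference ROI of the same structure.  Double normalization
divides out both background and acquisition photobleaching (tracked by
the reference) and rescales so the prebleach mean is 1; the mobile
fraction is then the bleach-depth-corrected recovery either at a fixed
evaluation time (default 60 s postbleach) or from the plateau of a
single-exponential fit.

ROS bursts measured by luminol chemiluminescence are summarized as the
background-corrected trapezoidal integral of the signal over a fixed
window after elicitation (default the first 25 min).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import (
    FitFailureError,
    InvalidArgumentError,
    NormalizationError,
)

__all__ = [
    "FrapTrace",
    "MobileFractionResult",
    "LumTrace",
    "normalize_frap",
    "mobile_fraction",
    "compare_mobile_fractions",
    "integrate_luminescence",
]


@dataclass
class FrapTrace:
    """Time series of a FRAP experiment (times in seconds)."""

    time: np.ndarray
    bleach_roi: np.ndarray
    background_roi: np.ndarray
    reference_roi: np.ndarray
    bleach_frame_index: int

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.bleach_roi = np.asarray(self.bleach_roi, dtype=float)
        self.background_roi = np.asarray(self.background_roi, dtype=float)
        self.reference_roi = np.asarray(self.reference_roi, dtype=float)
        n = self.time.size
        for name in ("bleach_roi", "background_roi", "reference_roi"):
            if getattr(self, name).size != n:
                raise InvalidArgumentError(f"{name} length does not match time")
        if not np.all(np.diff(self.time) > 0):
            raise InvalidArgumentError("time must be strictly increasing")
        if not 0 < self.bleach_frame_index < n:
            raise InvalidArgumentError("bleach_frame_index out of range")
        if self.bleach_frame_index < 2:
            raise InvalidArgumentError("need >= 2 prebleach frames")


@dataclass
class MobileFractionResult:
    mobile_fraction: float  # percent; flagged if outside [0, 100]
    method: str  # {"endpoint", "exp_fit"}
    normalized_trace: np.ndarray
    recovery_tau: float | None = None  # s, exp_fit only
    plateau: float | None = None  # normalized units, exp_fit only
    out_of_range: bool = False


@dataclass
class LumTrace:
    """Plate-reader luminescence time series (times in minutes)."""

    time: np.ndarray
    rlu: np.ndarray
    well_id: str = ""
    treatment: str = "mock"  # {"mock", "chitin"}
    genotype: str = ""

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.rlu = np.asarray(self.rlu, dtype=float)
        if self.rlu.size != self.time.size:
            raise InvalidArgumentError("rlu length does not match time")
        if not np.all(np.diff(self.time) > 0):
            raise InvalidArgumentError("time must be strictly increasing")
        if not np.all(np.isfinite(self.rlu)):
            raise InvalidArgumentError("rlu must be finite")


def normalize_frap(trace: FrapTrace) -> np.ndarray:
    """Double normalization against background and reference channels.

    F_norm(t) = [(F(t) - B(t)) / (R(t) - B(t))] * [(R_pre - B_pre) / (F_pre - B_pre)]

    where the ``pre`` values are means over prebleach frames.  The
    reference ratio divides out acquisition photobleaching; the final
    factor rescales so the prebleach mean of F_norm is exactly 1.
    """
    k = trace.bleach_frame_index
    f, b, r = trace.bleach_roi, trace.background_roi, trace.reference_roi
    f_pre = f[:k].mean()
    b_pre = b[:k].mean()
    r_pre = r[:k].mean()
    if f_pre <= b_pre:
        raise NormalizationError("prebleach signal does not exceed background")
    if np.any(r - b <= 0):
        raise NormalizationError("reference does not exceed background at all frames")
    return ((f - b) / (r - b)) * ((r_pre - b_pre) / (f_pre - b_pre))


def mobile_fraction(
    trace: FrapTrace,
    t_eval: float = 60.0,
    method: str = "endpoint",
    endpoint_window: int = 3,
) -> MobileFractionResult:
    """Mobile fraction (%) from a FRAP trace.

    endpoint (default): Mf = 100 (F_eval - F0) / (1 - F0) on the
    normalized trace, with F0 the first postbleach frame and F_eval the
    mean of ``endpoint_window`` frames nearest ``t_eval`` seconds after
    the bleach.  exp_fit: fit F0 + (P - F0)(1 - exp(-t/tau)) postbleach
    and use the plateau P instead of F_eval.
    """
    if method not in ("endpoint", "exp_fit"):
        raise InvalidArgumentError(f"unknown method {method!r}")
    fn = normalize_frap(trace)
    k = trace.bleach_frame_index
    t_post = trace.time[k:] - trace.time[k]
    f_post = fn[k:]
    f0 = f_post[0]
    if f0 >= 1.0:
        warnings.warn("no detectable bleach depth; mobile fraction ill-defined", stacklevel=2)

    if method == "endpoint":
        if t_post[-1] < t_eval:
            raise InvalidArgumentError(
                f"trace ends at {t_post[-1]:g} s, before t_eval={t_eval:g} s"
            )
        order = np.argsort(np.abs(t_post - t_eval))
        idx = np.sort(order[: min(endpoint_window, t_post.size)])
        f_eval = f_post[idx].mean()
        mf = 100.0 * (f_eval - f0) / (1.0 - f0)
        result = MobileFractionResult(mf, "endpoint", fn)
    else:
        def model(t, plateau, tau):
            return f0 + (plateau - f0) * (1.0 - np.exp(-t / tau))

        try:
            popt, _ = optimize.curve_fit(
                model, t_post, f_post,
                p0=[min(f_post[-1], 1.0), max(t_post[-1] / 4.0, 1e-3)],
                bounds=([f0 - 1.0, 1e-6], [2.0, np.inf]),
                maxfev=10000,
            )
        except RuntimeError as exc:
            raise FitFailureError(f"FRAP recovery fit failed: {exc}") from exc
        plateau, tau = popt
        mf = 100.0 * (plateau - f0) / (1.0 - f0)
        result = MobileFractionResult(mf, "exp_fit", fn, recovery_tau=float(tau),
                                      plateau=float(plateau))
    if not 0.0 <= result.mobile_fraction <= 100.0:
        result.out_of_range = True
    return result


def compare_mobile_fractions(groups: dict) -> "pd.DataFrame":
    """Pairwise Welch t-tests between mobile-fraction groups.

    ``groups`` maps condition name -> list of per-cell Mf values.
    Groups with n < 3 are excluded with a warning.  Returns a DataFrame
    with one row per pair: group labels, means, standard errors, Welch t
    and two-sided p.
    """
    import pandas as pd

    usable = {}
    for name, vals in groups.items():
        v = np.asarray(list(vals), dtype=float)
        if v.size < 3:
            warnings.warn(f"group {name!r} has n={v.size} < 3; excluded", stacklevel=2)
            continue
        usable[name] = v
    if len(usable) < 2:
        raise InvalidArgumentError("need >= 2 groups with n >= 3")
    names = list(usable)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = usable[names[i]], usable[names[j]]
            t, p = stats.ttest_ind(a, b, equal_var=False)
            rows.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "mean_a": a.mean(),
                    "mean_b": b.mean(),
                    "se_a": a.std(ddof=1) / np.sqrt(a.size),
                    "se_b": b.std(ddof=1) / np.sqrt(b.size),
                    "t": float(t),
                    "p_value": float(p),
                }
            )
    return pd.DataFrame(rows)


def integrate_luminescence(
    trace: LumTrace,
    window: tuple = (0.0, 25.0),
    background_mode: str = "pre_window_mean",
    paired_mock: LumTrace | None = None,
) -> float:
    """Background-corrected trapezoidal integral of luminescence (RLU*min).

    background_mode 'pre_window_mean' (default) subtracts the mean signal
    recorded up to the window opening; 'paired_mock_mean' subtracts the
    raw integral of a paired water-control trace over the same window;
    'none' integrates the raw signal (additive over adjacent windows).
    """
    t0, t1 = window
    if t1 <= t0:
        raise InvalidArgumentError("window must have positive width")
    t, y = trace.time, trace.rlu
    if t[0] > t0 + 1e-9 or t[-1] < t1 - 1e-9:
        raise InvalidArgumentError(
            f"trace [{t[0]:g}, {t[-1]:g}] does not span window [{t0:g}, {t1:g}]"
        )

    def raw_integral(tt, yy):
        # integrate on [t0, t1] with linear interpolation at the edges
        grid = np.unique(np.concatenate([[t0, t1], tt[(tt > t0) & (tt < t1)]]))
        vals = np.interp(grid, tt, yy)
        return float(np.trapezoid(vals, grid))

    if background_mode == "pre_window_mean":
        # samples up to and including the window opening carry no burst signal
        pre = y[t <= t0 + 1e-12]
        bg = float(pre.mean()) if pre.size else 0.0
        return raw_integral(t, y) - bg * (t1 - t0)
    elif background_mode == "paired_mock_mean":
        if paired_mock is None:
            raise InvalidArgumentError("paired_mock trace required for this mode")
        return raw_integral(t, y) - raw_integral(paired_mock.time, paired_mock.rlu)
    elif background_mode == "none":
        return raw_integral(t, y)
    raise InvalidArgumentError(f"unknown background_mode {background_mode!r}")
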