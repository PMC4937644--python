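"""Arterial input-function extraction from dynamic planar angiography.

The automatic pipeline locates the ascending-aorta input ROI at the pixel
with the highest single-frame count, extracts its time-activity curve,
separates the pulmonary (first) from the aortic (second) bolus peak, fits a
gamma variate to the aortic peak, and integrates the fitted curve
analytically to obtain the input counts. The same extraction primitives
serve the Patlak method's manually-placed ROIs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import find_peaks

from .core_model import ROI, DynamicPlanarSeries, TimeActivityCurve, roi_mask
from .synthetic_acquisition import GammaParams, gamma_integral, gamma_values

__all__ = [
    "GammaFit",
    "PeakSplit",
    "detect_aorta_roi",
    "extract_tac",
    "split_peaks",
    "fit_gamma",
    "input_counts",
]


@dataclass
class GammaFit:
    """A fitted gamma variate and its analytic integral (the input counts)."""

    params: GammaParams
    rss: float
    converged: bool
    integral_counts: float

    @classmethod
    def from_params(cls, params: GammaParams, rss: float = 0.0, converged: bool = True
                    ) -> "GammaFit":
        return cls(params=params, rss=rss, converged=converged,
                   integral_counts=gamma_integral(params))


@dataclass
class PeakSplit:
    """Frame-index windows (half-open) for the two bolus peaks of a TAC."""

    first_peak_window: tuple[int, int]
    second_peak_window: tuple[int, int]
    valley_index: int
    first_peak_index: int = 0
    second_peak_index: int = 0

    def __post_init__(self) -> None:
        f0, f1 = self.first_peak_window
        s0, s1 = self.second_peak_window
        if not (f0 < f1 <= s0 < s1):
            raise ValueError("peak windows must be ordered, disjoint and nonempty")


def detect_aorta_roi(
    series: DynamicPlanarSeries,
    search_window: tuple[int, int] | None = None,
    diameter_px: int = 4,
) -> ROI:
    """Locate the input ROI at the maximum-count pixel of the series.

    Scans all frames (or ``search_window``) and centers a circular ROI of
    ``diameter_px`` on the pixel attaining the largest single-frame count.
    Ties go to the earlier frame, then to the smaller (row, col).
    """
    w0, w1 = search_window if search_window is not None else (0, series.n_frames)
    frames = series.frames[w0:w1]
    vmax = frames.max()
    if vmax <= 0:
        raise ValueError("no signal: series is identically zero in the search window")
    # np.argwhere returns indices in lexicographic (frame, row, col) order,
    # which is exactly the documented tie-break
    t, r, c = np.argwhere(frames == vmax)[0]
    return roi_mask((int(r), int(c)), diameter_px, series.grid_shape)


def extract_tac(series: DynamicPlanarSeries, roi: ROI) -> TimeActivityCurve:
    """Total ROI counts per frame, sampled at frame midpoints."""
    if roi.mask.shape != series.grid_shape:
        raise ValueError("ROI mask does not match the series grid")
    counts = series.frames[:, roi.mask].sum(axis=1)
    return TimeActivityCurve(times_s=series.frame_midtimes(), counts=counts, roi=roi)


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y.astype(float)
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(y.astype(float), pad, mode="edge")
    out = np.convolve(padded, kernel, mode="same")[pad: pad + len(y)]
    return out


def split_peaks(
    tac: TimeActivityCurve,
    smooth_window: int = 3,
    tail_fraction: float = 0.3,
    min_prominence_frac: float = 0.05,
) -> PeakSplit:
    """Separate the pulmonary (first) and aortic (second) bolus peaks.

    The curve is smoothed with a short moving average, the two most
    prominent local maxima are taken in time order, and the valley between
    them starts the aortic window. The window ends where the curve falls
    below ``tail_fraction`` of the aortic peak (truncating recirculation).
    """
    y = _smooth(tac.counts, smooth_window)
    peaks, props = find_peaks(y, prominence=min_prominence_frac * float(y.max()))
    if len(peaks) < 2:
        raise ValueError(
            "fewer than two peaks detected in the TAC; supply manual fit "
            "windows via the configuration"
        )
    order = np.argsort(props["prominences"])[::-1][:2]
    p1, p2 = sorted(int(peaks[i]) for i in order)
    valley = p1 + int(np.argmin(y[p1: p2 + 1]))
    if y[valley] > 0.9 * y[p1]:
        warnings.warn(
            "bolus peaks are heavily overlapped (valley above 90% of the "
            "first peak); the gamma fit may be biased",
            stacklevel=2,
        )
    below = np.nonzero(y[p2:] < tail_fraction * y[p2])[0]
    end = p2 + int(below[0]) if len(below) else len(y)
    rise = np.nonzero(y[:p1] >= tail_fraction * y[p1])[0]
    start = int(rise[0]) if len(rise) else 0
    return PeakSplit(
        first_peak_window=(start, valley),
        second_peak_window=(valley, end),
        valley_index=valley,
        first_peak_index=p1,
        second_peak_index=p2,
    )


def _loglinear_init(t: np.ndarray, y: np.ndarray, t0: float) -> np.ndarray:
    """Initial (K, alpha, beta) from log-linearizing ln y = ln K +
    a ln(tau) - tau/b on the positive samples."""
    tau = t - t0
    ok = (tau > 0) & (y > 0)
    if ok.sum() < 3:
        return np.array([float(max(y.max(), 1e-6)), 2.0, 2.0])
    design = np.column_stack([np.ones(ok.sum()), np.log(tau[ok]), -tau[ok]])
    coef, *_ = np.linalg.lstsq(design, np.log(y[ok]), rcond=None)
    lnk, alpha, inv_beta = coef
    alpha = float(np.clip(alpha, 0.05, 9.5))
    beta = float(np.clip(1.0 / inv_beta if inv_beta > 1e-6 else 2.0, 0.05, 50.0))
    k = float(np.clip(np.exp(lnk), 1e-9, 1e12))
    return np.array([k, alpha, beta])


def fit_gamma(
    tac: TimeActivityCurve,
    window: tuple[int, int] | None = None,
    init: GammaParams | None = None,
    n_restarts: int = 3,
) -> GammaFit:
    """Nonlinear least-squares gamma-variate fit on a sample window.

    Parameters are (K, alpha, beta, t0) with bounds alpha in (0, 10],
    beta in (0, 60] s, t0 in [0, peak time); the default initial guess comes
    from a log-linearization of the windowed samples and is perturbed for up
    to ``n_restarts`` multi-start attempts on failure.
    """
    w0, w1 = window if window is not None else (0, len(tac))
    t = tac.times_s[w0:w1]
    y = tac.counts[w0:w1]
    if len(t) < 5:
        raise ValueError("fit window must contain at least 5 samples")
    t_peak = float(t[np.argmax(y)])

    def residuals(theta: np.ndarray) -> np.ndarray:
        k, a, b, t0 = theta
        return gamma_values(GammaParams(max(k, 1e-12), a, b, t0), t) - y

    dt = float(t[1] - t[0]) if len(t) > 1 else 1.0
    if init is not None:
        x0 = np.array(
            [init.k_scale, init.alpha_shape, init.beta_scale_s, init.t0_s]
        )
    else:
        t0_guess = max(float(t[0]) - dt, 0.0)
        x0 = np.append(_loglinear_init(t, y, t0_guess), t0_guess)

    lower = np.array([1e-12, 1e-3, 1e-3, 0.0])
    upper = np.array([1e15, 10.0, 60.0, max(t_peak - 1e-6, 1e-6)])
    x0 = np.clip(x0, lower + 1e-9, upper - 1e-9)

    rng = np.random.default_rng(0)
    best = None
    for attempt in range(n_restarts):
        start = x0 if attempt == 0 else np.clip(
            x0 * rng.uniform(0.5, 2.0, size=4), lower + 1e-9, upper - 1e-9
        )
        res = least_squares(
            residuals, start, bounds=(lower, upper),
            xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=5000,
        )
        if best is None or res.cost < best.cost:
            best = res
        if best.success and np.isfinite(best.cost):
            break
    if best is None or not (best.success and np.isfinite(best.cost)):
        raise ValueError(
            f"gamma fit failed to converge after {n_restarts} starts "
            f"(status={getattr(best, 'status', None)}, cost={getattr(best, 'cost', None)})"
        )
    k, a, b, t0 = best.x
    params = GammaParams(float(k), float(a), float(b), float(t0))
    return GammaFit(
        params=params,
        rss=float(2.0 * best.cost),
        converged=True,
        integral_counts=gamma_integral(params),
    )


def input_counts(fit: GammaFit) -> float:
    """Input counts: the analytic [t0, inf) integral of the fitted gamma."""
    if not fit.converged:
        raise ValueError("cannot integrate an unconverged gamma fit")
    return fit.integral_counts
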