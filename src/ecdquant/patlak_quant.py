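"""Patlak-plot quantification: aortic/hemispheric TACs -> BPI -> mCBF -> rCBF.

For an irreversibly trapped flow tracer, plotting the tissue-to-input count
ratio Cb(t)/Ca(t) against the normalized integrated input
int_0^t Ca dtau / Ca(t) yields a straight line whose slope Ku is the
unidirectional uptake rate. Ku, normalized, is the brain perfusion index
(BPI); a 133Xe-derived regression line converts BPI to mean CBF, and the
regional distribution follows the Lassen-corrected SPECT counts anchored so
that the basal-ganglia value equals mCBF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.stats import linregress

from .core_model import AnalysisConfig, TimeActivityCurve
from .ibur_quant import LassenParams, RegionalCBF, lassen_correct

__all__ = [
    "PP_SLOPE",
    "PP_INTERCEPT",
    "PatlakPlot",
    "BpiResult",
    "patlak_transform",
    "estimate_ku",
    "ku_to_bpi",
    "bpi_to_mcbf",
    "distribute_rcbf_pp",
]

# 133Xe-derived calibration of the brain perfusion index:
# mCBF (ml/100g/min) = 2.60 * BPI + 19.8
PP_SLOPE = 2.60
PP_INTERCEPT = 19.8


@dataclass
class PatlakPlot:
    """Patlak coordinates: x = int Ca / Ca (s), y = Cb / Ca, with the
    original sample times retained for window selection."""

    x: np.ndarray
    y: np.ndarray
    times_s: np.ndarray
    input_peak_time_s: float
    fit_window: tuple[int, int] | None = None
    ku: float | None = None
    intercept: float | None = None
    r2: float | None = None


@dataclass
class BpiResult:
    """Brain perfusion index: a normalized Patlak slope."""

    bpi: float
    ku: float
    scale: float

    def __post_init__(self) -> None:
        if abs(self.bpi - self.scale * self.ku) > 1e-9 * max(1.0, abs(self.bpi)):
            raise ValueError("bpi must equal scale * ku")


def patlak_transform(
    brain_tac: TimeActivityCurve,
    input_tac: TimeActivityCurve,
    min_input_frac: float = 0.05,
) -> PatlakPlot:
    """Build the Patlak coordinates from a tissue and an input TAC.

    The input integral is the cumulative trapezoid of the raw input curve.
    Samples where the input falls below ``min_input_frac`` of its peak are
    dropped (the ratio coordinates blow up as Ca -> 0).
    """
    if len(brain_tac) != len(input_tac) or not np.allclose(
        brain_tac.times_s, input_tac.times_s
    ):
        raise ValueError("brain and input TACs must share a timebase")
    t = input_tac.times_s
    ca = input_tac.counts
    cb = brain_tac.counts
    integral = cumulative_trapezoid(ca, t, initial=0.0)
    valid = ca >= min_input_frac * float(ca.max())
    if not valid.any():
        raise ValueError("no valid Patlak points: input curve has no support")
    x = integral[valid] / ca[valid]
    y = cb[valid] / ca[valid]
    peak_time = float(t[int(np.argmax(ca))])
    return PatlakPlot(x=x, y=y, times_s=t[valid], input_peak_time_s=peak_time)


def estimate_ku(
    plot: PatlakPlot, fit_window: tuple[int, int] | None = None
) -> tuple[float, float, float]:
    """Ordinary least squares on the Patlak points; returns (ku, intercept, r2).

    The default window is the post-bolus linear phase: all points after the
    input-curve peak.
    """
    if fit_window is not None:
        w0, w1 = fit_window
        sel = np.zeros(len(plot.x), dtype=bool)
        sel[w0:w1] = True
    else:
        sel = plot.times_s > plot.input_peak_time_s
    x, y = plot.x[sel], plot.y[sel]
    if len(x) < 3:
        raise ValueError("need at least 3 points in the Patlak fit window")
    if np.ptp(x) <= 0 or np.var(x) == 0:
        raise ValueError("degenerate abscissa: Patlak x has zero variance")
    res = linregress(x, y)
    ku, intercept = float(res.slope), float(res.intercept)
    r2 = float(res.rvalue) ** 2
    plot.fit_window = fit_window
    plot.ku, plot.intercept, plot.r2 = ku, intercept, r2
    return ku, intercept, r2


def ku_to_bpi(ku: float, scale: float = 100.0) -> BpiResult:
    """Normalize the Patlak slope into the brain perfusion index."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    return BpiResult(bpi=scale * ku, ku=ku, scale=scale)


def bpi_to_mcbf(bpi: float) -> float:
    """Apply the 133Xe-derived calibration line mCBF = 2.60*BPI + 19.8."""
    if bpi < 0:
        raise ValueError("BPI must be nonnegative")
    return PP_SLOPE * bpi + PP_INTERCEPT


def distribute_rcbf_pp(
    spect_counts_map: dict[str, float], mcbf: float, config: AnalysisConfig
) -> RegionalCBF:
    """Distribute mCBF regionally by the Lassen-corrected SPECT counts.

    Segment counts are linearized against the basal-ganglia reference and
    scaled so the basal-ganglia (normal side) mean equals ``mcbf`` exactly.
    """
    bg = config.basal_ganglia_full_names()
    missing = [s for s in bg if s not in spect_counts_map]
    if missing:
        raise ValueError(f"basal-ganglia segments absent from counts: {missing}")
    corrected = lassen_correct(
        spect_counts_map,
        LassenParams(alpha=config.lassen_alpha, reference_segments=tuple(bg)),
    )
    anchor = float(np.mean([corrected[s] for s in bg]))
    per_segment = {s: mcbf * c / anchor for s, c in corrected.items()}
    return RegionalCBF(
        method="PP", per_segment=per_segment, mcbf=float(mcbf),
        normal_side=config.normal_side,
    )
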