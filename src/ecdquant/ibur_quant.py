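"""IBUR quantification: SPECT counts + integrated input -> rBUR -> rCBF.

The improved brain-uptake-ratio method divides Lassen-linearized regional
SPECT counts by the integrated arterial input (from the gamma-variate fit of
the ascending-aorta curve), cross-calibrates planar and tomographic counts
with a phantom-derived factor (CCF), and converts the resulting uptake
ratio to flow with an H2(15)O-PET-derived regression line. Mean CBF is the
average over the basal-ganglia segments of the normal hemisphere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core_model import AnalysisConfig, RegionTemplate, SpectVolume

__all__ = [
    "IBUR_SLOPE",
    "IBUR_INTERCEPT",
    "RegionalCBF",
    "LassenParams",
    "segment_mean_counts",
    "lassen_correct",
    "compute_rbur",
    "rbur_to_rcbf",
    "mcbf_ibur",
    "estimate_ccf",
]

# H2(15)O-PET-derived calibration of the brain uptake ratio:
# rCBF (ml/100g/min) = 3.23 * BUR + 4.66
IBUR_SLOPE = 3.23
IBUR_INTERCEPT = 4.66


@dataclass
class RegionalCBF:
    """Per-segment rCBF (ml/100g/min) plus the summary mCBF, for one method."""

    method: str  # "IBUR" or "PP"
    per_segment: dict[str, float]
    mcbf: float
    normal_side: str

    def __post_init__(self) -> None:
        bad = [s for s, v in self.per_segment.items() if not np.isfinite(v) or v < 0]
        if bad:
            raise ValueError(f"non-finite or negative rCBF for segments {bad}")


@dataclass
class LassenParams:
    """Lassen linearization: alpha and the reference region (segment names
    whose mean count defines C_r)."""

    alpha: float
    reference_segments: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not self.reference_segments:
            raise ValueError("reference_segments must be nonempty")
        self.reference_segments = tuple(self.reference_segments)


def segment_mean_counts(
    volume: SpectVolume, template: RegionTemplate
) -> dict[str, float]:
    """Mean voxel count per nonbackground template segment."""
    if volume.voxels.shape != template.labels.shape:
        raise ValueError(
            f"grid mismatch: volume {volume.voxels.shape} vs "
            f"template {template.labels.shape}"
        )
    out: dict[str, float] = {}
    for name, label in template.label_of.items():
        mask = template.labels == label
        if not mask.any():
            raise ValueError(f"segment {name!r} is empty in the template")
        out[name] = float(volume.voxels[mask].mean())
    return out


def lassen_correct(
    counts_map: Mapping[str, float], params: LassenParams
) -> dict[str, float]:
    """Linearize flow-tracer uptake: C -> C_r * a*(C/C_r) / (1 + a - C/C_r).

    C_r is the mean count over the reference segments; the map is the
    identity at C = C_r and approaches the identity everywhere as a -> inf.
    """
    missing = [s for s in params.reference_segments if s not in counts_map]
    if missing:
        raise ValueError(f"reference segments absent from counts map: {missing}")
    c_r = float(np.mean([counts_map[s] for s in params.reference_segments]))
    if c_r <= 0:
        raise ValueError("reference-region mean count must be positive")
    alpha = params.alpha
    out: dict[str, float] = {}
    for s, c in counts_map.items():
        x = c / c_r
        if x >= 1.0 + alpha:
            raise ValueError(
                f"segment {s!r}: count ratio {x:.3f} >= 1 + alpha = "
                f"{1 + alpha:.3f} (outside the Lassen domain)"
            )
        out[s] = c_r * alpha * x / (1.0 + alpha - x)
    return out


def compute_rbur(
    segment_counts: Mapping[str, float], input_counts: float, ccf: float
) -> dict[str, float]:
    """Regional brain uptake ratio: CCF * counts / integrated input."""
    if input_counts <= 0:
        raise ValueError("input_counts must be positive")
    if ccf <= 0:
        raise ValueError("ccf must be positive")
    return {s: ccf * c / input_counts for s, c in segment_counts.items()}


def rbur_to_rcbf(rbur):
    """Apply the PET-derived calibration line rCBF = 3.23*BUR + 4.66."""
    rbur = np.asarray(rbur, dtype=float) if not np.isscalar(rbur) else rbur
    if np.any(np.asarray(rbur) < 0):
        raise ValueError("rBUR must be nonnegative")
    return IBUR_SLOPE * rbur + IBUR_INTERCEPT


def mcbf_ibur(regional: Mapping[str, float], config: AnalysisConfig) -> float:
    """Mean CBF: unweighted mean rCBF over the configured basal-ganglia
    segments on the normal side."""
    names = config.basal_ganglia_full_names()
    missing = [n for n in names if n not in regional]
    if missing:
        raise ValueError(f"basal-ganglia segments absent from results: {missing}")
    return float(np.mean([regional[n] for n in names]))


def estimate_ccf(
    planar_phantom_counts: Sequence[float] | np.ndarray,
    spect_phantom_counts: Sequence[float] | np.ndarray,
) -> float:
    """Cross-calibration factor from a paired uniform-phantom acquisition:
    the ratio of mean planar to mean SPECT counts."""
    planar = np.asarray(planar_phantom_counts, dtype=float)
    spect = np.asarray(spect_phantom_counts, dtype=float)
    if planar.size == 0 or spect.size == 0:
        raise ValueError("phantom count arrays must be nonempty")
    if spect.mean() <= 0:
        raise ValueError("SPECT phantom mean must be positive")
    return float(planar.mean() / spect.mean())
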