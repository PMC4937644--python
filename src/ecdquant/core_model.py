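"""Domain types, standard-format I/O and configuration for the CBF pipelines.

The pipeline works on three kinds of images:

* a dynamic planar radionuclide angiogram of the chest/head (the bolus
  first pass, typically 120 frames at 1 s/frame), stored as 4D NIfTI with a
  small YAML sidecar carrying the timebase;
* a reconstructed brain SPECT volume (3D NIfTI);
* an integer label template parcellating the brain into the standard
  stereotaxic 24 segments, 12 per hemisphere (3D NIfTI plus a YAML sidecar
  naming the labels).

Time-activity curves are exported/imported as two-column CSV
(``time_s, counts``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SEGMENT_BASE_NAMES",
    "SIDES",
    "default_segment_names",
    "DynamicPlanarSeries",
    "SpectVolume",
    "RegionTemplate",
    "ROI",
    "TimeActivityCurve",
    "AnalysisConfig",
    "roi_mask",
    "read_dynamic_series",
    "write_dynamic_series",
    "read_volume_and_template",
    "write_spect_volume",
    "write_region_template",
    "read_tac_csv",
    "write_tac_csv",
]

#: The 12 segments of the stereotaxic ROI template, per hemisphere, in the
#: conventional order (labels 1..12 left, 13..24 right).
SEGMENT_BASE_NAMES = (
    "anterior",
    "precentral",
    "central",
    "parietal",
    "angular",
    "temporal",
    "occipital",
    "pericallosal",
    "lenticular_nucleus",
    "thalamus",
    "hippocampus",
    "cerebellum",
)

SIDES = ("left", "right")


def default_segment_names() -> list[str]:
    """Ordered 24-segment name list; index i corresponds to label i+1."""
    return [f"{base}_{side}" for side in SIDES for base in SEGMENT_BASE_NAMES]


def _side_of_name(name: str) -> str:
    for side in SIDES:
        if name.endswith(f"_{side}"):
            return side
    raise ValueError(f"segment name {name!r} does not end in _left/_right")


@dataclass
class DynamicPlanarSeries:
    """A dynamic planar frame stack: ``frames[t, row, col]`` are counts."""

    frames: np.ndarray
    frame_duration_s: float
    start_time_s: float = 0.0
    pixel_size_mm: float = 4.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3D (frame, row, col) array")
        if self.frame_duration_s <= 0:
            raise ValueError("frame_duration_s must be positive")
        if np.any(self.frames < 0):
            raise ValueError("frame counts must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def frame_midtimes(self) -> np.ndarray:
        """Sample times: midpoint of each frame, in seconds."""
        idx = np.arange(self.n_frames)
        return self.start_time_s + (idx + 0.5) * self.frame_duration_s


@dataclass
class SpectVolume:
    """A reconstructed SPECT count volume."""

    voxels: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (6.0, 6.0, 6.0)
    scan_midtime_min: float = 30.0

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if np.any(self.voxels < 0):
            raise ValueError("voxel counts must be nonnegative")


@dataclass
class RegionTemplate:
    """Integer label volume aligned to a SPECT grid, 12 segments per side.

    ``labels == 0`` is background; label ``i`` maps to ``segment_names[i-1]``.
    """

    labels: np.ndarray
    segment_names: Sequence[str] = field(default_factory=default_segment_names)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.allclose(self.labels, np.round(self.labels)):
                raise ValueError("labels must be integral")
            self.labels = np.round(self.labels).astype(int)
        self.segment_names = list(self.segment_names)
        per_side: dict[str, set[str]] = {s: set() for s in SIDES}
        for name in self.segment_names:
            side = _side_of_name(name)
            base = name[: -(len(side) + 1)]
            per_side[side].add(base)
        for side in SIDES:
            if per_side[side] != set(SEGMENT_BASE_NAMES):
                raise ValueError(
                    f"template must declare the 12 standard segments on the "
                    f"{side} side; got {sorted(per_side[side])}"
                )

    @property
    def side_of(self) -> dict[str, str]:
        return {name: _side_of_name(name) for name in self.segment_names}

    @property
    def label_of(self) -> dict[str, int]:
        return {name: i + 1 for i, name in enumerate(self.segment_names)}

    def mask_of(self, name: str) -> np.ndarray:
        return self.labels == self.label_of[name]


@dataclass
class ROI:
    """A circular region of interest on the planar grid."""

    center: tuple[int, int]
    diameter_px: int
    mask: np.ndarray

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def roi_mask(
    center: tuple[float, float], diameter_px: int, grid_shape: tuple[int, int]
) -> ROI:
    """Discrete disc ROI: pixels whose centers lie within ``diameter_px/2``
    of ``center`` (Euclidean, inclusive), clipped to the grid."""
    if diameter_px < 1:
        raise ValueError("diameter_px must be >= 1")
    r0, c0 = center
    n_rows, n_cols = grid_shape
    if not (0 <= r0 < n_rows and 0 <= c0 < n_cols):
        raise ValueError(f"ROI center {center} lies outside grid {grid_shape}")
    rows, cols = np.ogrid[:n_rows, :n_cols]
    radius = diameter_px / 2.0
    mask = (rows - r0) ** 2 + (cols - c0) ** 2 <= radius**2 + 1e-12
    return ROI(center=(int(round(r0)), int(round(c0))), diameter_px=diameter_px, mask=mask)


@dataclass
class TimeActivityCurve:
    """(time, counts) samples for one ROI.

    ``counts`` are ROI *totals* per frame (summed over the mask), sampled at
    frame midpoints.
    """

    times_s: np.ndarray
    counts: np.ndarray
    roi: ROI | None = None

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.times_s.shape != self.counts.shape or self.times_s.ndim != 1:
            raise ValueError("times_s and counts must be 1D arrays of equal length")
        if len(self.times_s) and np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times_s must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    def __len__(self) -> int:
        return len(self.times_s)


@dataclass
class AnalysisConfig:
    """Tunable parameters of both quantification pipelines.

    lassen_alpha
        Linearization constant of Lassen's flow/uptake correction
        (dimensionless; 1.5 is the classical value).
    ccf
        Cross-calibration factor between planar angiographic counts and
        reconstructed SPECT counts (dimensionless; scanner-specific,
        determined from a uniform phantom).
    basal_ganglia_segments
        Deep gray-matter segments averaged for mCBF and used as the Lassen
        reference region.
    normal_side
        Clinically normal hemisphere; mCBF and the reference region are
        taken on this side.
    bpi_scale
        Normalization constant mapping the Patlak slope Ku (1/s) to the
        brain perfusion index.
    """

    lassen_alpha: float = 1.5
    ccf: float = 1.0
    basal_ganglia_segments: tuple[str, ...] = ("lenticular_nucleus", "thalamus")
    normal_side: str = "left"
    bpi_scale: float = 100.0
    patlak_fit_window: tuple[int, int] | None = None
    seed: int = 0
    # Manual ROIs for the Patlak-plot method (row, col pixel coordinates).
    arch_roi_center: tuple[int, int] | None = None
    arch_roi_diameter_px: int = 6
    hemisphere_roi_center: tuple[int, int] | None = None
    hemisphere_roi_diameter_px: int = 12
    # "trapezoid": Patlak input integral from the raw TAC; "gamma": from a
    # gamma-variate fit of the arterial peak.
    pp_input_model: str = "trapezoid"
    smoothing_window: int = 3
    second_peak_tail_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.lassen_alpha <= 0:
            raise ValueError("lassen_alpha must be positive")
        if self.ccf <= 0:
            raise ValueError("ccf must be positive")
        if not self.basal_ganglia_segments:
            raise ValueError("basal_ganglia_segments must be nonempty")
        if self.normal_side not in SIDES:
            raise ValueError(f"normal_side must be one of {SIDES}")
        self.basal_ganglia_segments = tuple(self.basal_ganglia_segments)

    def basal_ganglia_full_names(self) -> list[str]:
        """Configured basal-ganglia segments on the normal side."""
        return [f"{b}_{self.normal_side}" for b in self.basal_ganglia_segments]

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["basal_ganglia_segments"] = list(self.basal_ganglia_segments)
        for key in ("arch_roi_center", "hemisphere_roi_center", "patlak_fit_window"):
            if d[key] is not None:
                d[key] = list(d[key])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("arch_roi_center", "hemisphere_roi_center", "patlak_fit_window"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        if d.get("basal_ganglia_segments") is not None:
            d["basal_ganglia_segments"] = tuple(d["basal_ganglia_segments"])
        return cls(**d)


# ---------------------------------------------------------------------------
# NIfTI / YAML / CSV I/O
# ---------------------------------------------------------------------------


def _sidecar_path(path: str | Path) -> Path:
    p = Path(path)
    name = p.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return p.with_name(name[: -len(suffix)] + ".yaml")
    return p.with_suffix(".yaml")


def write_dynamic_series(series: DynamicPlanarSeries, path: str | Path) -> None:
    """Write a 4D NIfTI (row, col, 1, frame) plus a YAML timing sidecar."""
    data = np.transpose(series.frames, (1, 2, 0))[:, :, np.newaxis, :]
    affine = np.diag([series.pixel_size_mm, series.pixel_size_mm, 1.0, 1.0])
    img = nib.Nifti1Image(data.astype(np.float64), affine)
    img.header["pixdim"][4] = series.frame_duration_s
    nib.save(img, str(path))
    sidecar = {
        "frame_duration_s": float(series.frame_duration_s),
        "start_time_s": float(series.start_time_s),
        "pixel_size_mm": float(series.pixel_size_mm),
    }
    _sidecar_path(path).write_text(yaml.safe_dump(sidecar))


def read_dynamic_series(
    path: str | Path, sidecar_path: str | Path | None = None
) -> DynamicPlanarSeries:
    """Read a 4D NIfTI dynamic series; timing from YAML sidecar or header."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(
            f"expected 4D dynamic series (got {data.ndim}D image {path.name})"
        )
    if data.shape[2] != 1:
        raise ValueError("dynamic planar series must be single-slice (row, col, 1, t)")
    frames = np.transpose(data[:, :, 0, :], (2, 0, 1))
    sidecar = Path(sidecar_path) if sidecar_path is not None else _sidecar_path(path)
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text())
        duration = float(meta["frame_duration_s"])
        start = float(meta.get("start_time_s", 0.0))
        pixel = float(meta.get("pixel_size_mm", abs(img.affine[0, 0])))
    else:
        duration = float(img.header["pixdim"][4])
        start = 0.0
        pixel = float(abs(img.affine[0, 0]))
    if duration <= 0:
        raise ValueError("nonpositive frame duration in metadata")
    return DynamicPlanarSeries(
        frames=frames, frame_duration_s=duration, start_time_s=start, pixel_size_mm=pixel
    )


def write_spect_volume(volume: SpectVolume, path: str | Path) -> None:
    affine = np.diag(list(volume.voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(volume.voxels.astype(np.float64), affine), str(path))


def write_region_template(template: RegionTemplate, path: str | Path) -> None:
    """Write the label volume plus a YAML sidecar naming the labels."""
    affine = np.eye(4)
    nib.save(nib.Nifti1Image(template.labels.astype(np.int16), affine), str(path))
    _sidecar_path(path).write_text(
        yaml.safe_dump({"segment_names": list(template.segment_names)})
    )


def read_volume_and_template(
    vol_path: str | Path,
    tpl_path: str | Path,
    names_path: str | Path | None = None,
) -> tuple[SpectVolume, RegionTemplate]:
    """Read a SPECT volume and its aligned label template, verifying grids."""
    vol_img = nib.load(str(vol_path))
    tpl_img = nib.load(str(tpl_path))
    vox = np.asarray(vol_img.dataobj, dtype=float)
    labels = np.asarray(tpl_img.dataobj)
    if vox.ndim != 3 or labels.ndim != 3:
        raise ValueError("volume and template must both be 3D")
    if vox.shape != labels.shape:
        raise ValueError(
            f"grid mismatch: volume {vox.shape} vs template {labels.shape}"
        )
    names_file = Path(names_path) if names_path is not None else _sidecar_path(tpl_path)
    if names_file.exists():
        names = yaml.safe_load(names_file.read_text())["segment_names"]
    else:
        names = default_segment_names()
    present = set(np.unique(labels).astype(int)) - {0}
    declared = set(range(1, len(names) + 1))
    undeclared = sorted(present - declared)
    if undeclared:
        raise ValueError(
            f"template contains labels {undeclared} with no declared segment name"
        )
    absent = sorted(declared - present)
    if absent:
        missing = [names[i - 1] for i in absent]
        raise ValueError(f"template is missing segments: {missing}")
    zooms = vol_img.header.get_zooms()[:3]
    volume = SpectVolume(voxels=vox, voxel_size_mm=tuple(float(z) for z in zooms))
    template = RegionTemplate(labels=labels, segment_names=names)
    return volume, template


def write_tac_csv(tac: TimeActivityCurve, path: str | Path) -> None:
    pd.DataFrame({"time_s": tac.times_s, "counts": tac.counts}).to_csv(
        path, index=False
    )


def read_tac_csv(path: str | Path) -> TimeActivityCurve:
    df = pd.read_csv(path)
    return TimeActivityCurve(
        times_s=df["time_s"].to_numpy(), counts=df["counts"].to_numpy()
    )
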