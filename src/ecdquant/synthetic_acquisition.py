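"""Synthetic first-pass angiography + SPECT generator with known ground truth.

The forward model emulates a 99mTc-ECD study:

* a **pulmonary** bolus peak (early, fast gamma variate) partially
  overlapping the ascending-aorta region, so that the aortic time-activity
  curve genuinely shows two peaks;
* an **ascending aorta** spot following a gamma-variate bolus, whose
  brightest pixel is the global count maximum of the series (the premise of
  the automatic input-ROI search);
* an **aortic arch** region with the same bolus shape (the manual input ROI
  of the Patlak method);
* **brain** activity following microsphere kinetics — irreversible trapping
  proportional to flow, so tissue activity is Ku times the running integral
  of the arterial curve and the Patlak plot is exactly linear with slope Ku;
* a SPECT volume whose per-segment counts are the *inverse* Lassen
  transform of the true regional flows, cross-calibrated to the planar
  counts by a known factor, so that the forward quantification pipelines
  recover the truth exactly in the noiseless limit;
* optional Poisson counting noise on both modalities.

Everything is reproducible from an integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import brentq

from .core_model import (
    AnalysisConfig,
    DynamicPlanarSeries,
    RegionTemplate,
    SpectVolume,
    TimeActivityCurve,
    default_segment_names,
    roi_mask,
    write_dynamic_series,
    write_region_template,
    write_spect_volume,
)

__all__ = [
    "GammaParams",
    "GroundTruth",
    "GridSpec",
    "SubjectBundle",
    "gamma_curve",
    "gamma_values",
    "gamma_integral",
    "gamma_peak_time",
    "make_ground_truth",
    "simulate_subject",
    "simulate_cohort",
    "write_subject",
]

# Calibration lines shared with the quantification modules (duplicated
# constants would let the simulator and the analysis drift apart).
from .ibur_quant import IBUR_INTERCEPT, IBUR_SLOPE  # noqa: E402
from .patlak_quant import PP_INTERCEPT, PP_SLOPE  # noqa: E402


@dataclass
class GammaParams:
    """Gamma-variate bolus model C(t) = K (t-t0)^a exp(-(t-t0)/b), t > t0."""

    k_scale: float
    alpha_shape: float
    beta_scale_s: float
    t0_s: float

    def __post_init__(self) -> None:
        if self.k_scale <= 0:
            raise ValueError("k_scale must be positive")
        if self.alpha_shape <= 0:
            raise ValueError("alpha_shape must be positive")
        if self.beta_scale_s <= 0:
            raise ValueError("beta_scale_s must be positive")
        if self.t0_s < 0:
            raise ValueError("t0_s must be nonnegative")


def gamma_values(params: GammaParams, times: np.ndarray) -> np.ndarray:
    """Evaluate the gamma variate; zero at and before the appearance time."""
    t = np.asarray(times, dtype=float)
    tau = t - params.t0_s
    out = np.zeros_like(tau)
    pos = tau > 0
    out[pos] = (
        params.k_scale
        * tau[pos] ** params.alpha_shape
        * np.exp(-tau[pos] / params.beta_scale_s)
    )
    return out


def gamma_curve(params: GammaParams, times: np.ndarray) -> TimeActivityCurve:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    return TimeActivityCurve(times_s=times, counts=gamma_values(params, times))


def gamma_peak_time(params: GammaParams) -> float:
    """The mode: t0 + alpha * beta."""
    return params.t0_s + params.alpha_shape * params.beta_scale_s


def gamma_peak_value(params: GammaParams) -> float:
    ab = params.alpha_shape * params.beta_scale_s
    return params.k_scale * ab**params.alpha_shape * math.exp(-params.alpha_shape)


def gamma_integral(params: GammaParams) -> float:
    """Analytic integral over [t0, inf): K * beta^(alpha+1) * Gamma(alpha+1)."""
    return (
        params.k_scale
        * params.beta_scale_s ** (params.alpha_shape + 1)
        * math.gamma(params.alpha_shape + 1)
    )


@dataclass
class GroundTruth:
    """Hidden truth of one simulated subject, for recovery tests.

    ``segment_flow`` holds true rCBF per template segment; ``true_mcbf`` is
    the basal-ganglia normal-side mean flow. ``pp_mcbf_true`` is the flow on
    the Patlak method's own calibration scale (the two methods are known to
    sit on different scales clinically; the simulator encodes that offset).
    ``input_params`` are the aortic bolus parameters at the scale of the
    standard 4-pixel input ROI, so a gamma fit of the extracted aortic TAC
    should recover them directly; ``input_counts_roi`` is their analytic
    integral (counts*s captured by that ROI).
    """

    segment_flow: dict[str, float]
    true_mcbf: float
    input_params: GammaParams
    pulmonary_params: GammaParams
    ccf_true: float
    lassen_alpha_true: float
    ku_true: float
    pp_mcbf_true: float = 0.0
    input_counts_roi: float = 0.0
    aorta_center: tuple[int, int] = (0, 0)
    segment_counts: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(f < 0 for f in self.segment_flow.values()):
            raise ValueError("segment flows must be nonnegative")
        if self.ku_true <= 0:
            raise ValueError("ku_true must be positive")


@dataclass
class GridSpec:
    """Image-grid sizes; defaults are desk-scale (full clinical matrices are
    available by passing planar_shape=(128, 128))."""

    planar_shape: tuple[int, int] = (64, 64)
    n_frames: int = 120
    frame_duration_s: float = 1.0
    pixel_size_mm: float = 4.0
    spect_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: float = 6.0


@dataclass
class SubjectBundle:
    """One simulated subject: images, template, truth and a matched config."""

    series: DynamicPlanarSeries
    spect: SpectVolume
    template: RegionTemplate
    truth: GroundTruth
    config: AnalysisConfig


# --- scene layout, as fractions of the planar grid -------------------------
_AORTA_FRAC = (0.5625, 0.50)  # ascending aorta spot
_ARCH_FRAC = (0.40625, 0.328125)  # aortic arch spot, clear of the lung field
_PULM_FRAC = (0.625, 0.625)  # pulmonary blob, overlaps the ascending aorta
_BRAIN_FRAC = (0.21875, 0.50)  # brain ellipse center
_BRAIN_SEMI_FRAC = (0.140625, 0.21875)
_HEMI_ROI_FRAC = (0.21875, 0.390625)  # left-hemisphere output ROI

_AORTA_SIGMA_FRAC = 1.0 / 64
_ARCH_SIGMA_FRAC = 1.5 / 64
_PULM_SIGMA_FRAC = 6.0 / 64

# Default bolus shapes (seconds): the pulmonary transit precedes and decays
# well before the aortic peak, as in a right-heart -> lung -> left-heart pass.
_PULM_SHAPE = (2.0, 0.9, 2.5)  # alpha, beta, t0
_AORTA_SHAPE = (3.0, 1.8, 9.0)

_AORTA_ROI_PEAK = 1000.0  # target counts/frame in the 4-px input ROI at peak
_PULM_PIXEL_PEAK_FRAC = 0.5  # pulmonary max pixel relative to aortic max pixel
_ARCH_PIXEL_PEAK_FRAC = 0.6
_PULM_OVERLAP_TRUNC_SIGMAS = 3.0

_DEFAULT_CCF = 120.0
_DEFAULT_LASSEN_ALPHA = 1.5
_INPUT_ROI_DIAMETER = 4

# Empirical between-method mCBF relation (IBUR-scale vs PP-scale flows)
# used to place the simulated Patlak truth on the PP calibration scale.
_IBUR_VS_PP_SLOPE = 1.25
_IBUR_VS_PP_INTERCEPT = -17.5


def _gaussian_blob(
    shape: tuple[int, int], center: tuple[float, float], sigma: float
) -> np.ndarray:
    rows, cols = np.ogrid[: shape[0], : shape[1]]
    d2 = (rows - center[0]) ** 2 + (cols - center[1]) ** 2
    w = np.exp(-d2 / (2.0 * sigma**2))
    w[d2 > (_PULM_OVERLAP_TRUNC_SIGMAS * sigma) ** 2] = 0.0
    return w


def _scaled_center(frac: tuple[float, float], shape: tuple[int, int]) -> tuple[int, int]:
    return (int(round(frac[0] * shape[0])), int(round(frac[1] * shape[1])))


def make_ground_truth(
    true_mcbf: float,
    seed: int = 0,
    segment_names: list[str] | None = None,
    basal_ganglia: tuple[str, ...] = ("lenticular_nucleus", "thalamus"),
    normal_side: str = "left",
    bpi_scale: float = 100.0,
    flow_cv: float = 0.12,
    ccf_true: float = _DEFAULT_CCF,
    lassen_alpha_true: float = _DEFAULT_LASSEN_ALPHA,
) -> GroundTruth:
    """Draw a per-segment flow map around a target mean CBF.

    Segment flows vary around ``true_mcbf`` with coefficient of variation
    ``flow_cv``; the basal-ganglia segments of the normal side are pinned to
    a +/-3% split so their mean equals ``true_mcbf`` exactly.
    """
    rng = np.random.default_rng(seed)
    names = segment_names if segment_names is not None else default_segment_names()
    flows = {
        name: float(np.clip(true_mcbf * (1.0 + rng.normal(0.0, flow_cv)), 8.0, 90.0))
        for name in names
    }
    bg = [f"{b}_{normal_side}" for b in basal_ganglia]
    for i, name in enumerate(bg):
        offset = 0.03 if len(bg) > 1 else 0.0
        flows[name] = true_mcbf * (1.0 + offset * (1 if i % 2 == 0 else -1))
    if len(bg) % 2 == 1 and len(bg) > 1:
        flows[bg[-1]] = true_mcbf
    pp_mcbf = (true_mcbf - _IBUR_VS_PP_INTERCEPT) / _IBUR_VS_PP_SLOPE
    ku = (pp_mcbf - PP_INTERCEPT) / (PP_SLOPE * bpi_scale)
    if ku <= 0:
        raise ValueError(
            f"true_mcbf={true_mcbf} implies a nonpositive Patlak slope; "
            "use a flow above ~8 ml/100g/min"
        )
    pa, pb, pt0 = _PULM_SHAPE
    aa, ab_, at0 = _AORTA_SHAPE
    return GroundTruth(
        segment_flow=flows,
        true_mcbf=float(true_mcbf),
        input_params=GammaParams(1.0, aa, ab_, at0),  # amplitude set by simulate
        pulmonary_params=GammaParams(1.0, pa, pb, pt0),
        ccf_true=ccf_true,
        lassen_alpha_true=lassen_alpha_true,
        ku_true=float(ku),
        pp_mcbf_true=float(pp_mcbf),
    )


def _build_template(shape: tuple[int, int, int]) -> RegionTemplate:
    """Geometric stand-in parcellation: an ellipsoidal brain split into left
    and right halves and 12 axial bands per side (synthetic; not anatomical)."""
    ni, nj, nk = shape
    ci, cj, ck = (ni - 1) / 2, (nj - 1) / 2, (nk - 1) / 2
    ri, rj, rk = 0.62 * ci, 0.75 * cj, 0.62 * ck
    ii, jj, kk = np.ogrid[:ni, :nj, :nk]
    inside = ((ii - ci) / ri) ** 2 + ((jj - cj) / rj) ** 2 + ((kk - ck) / rk) ** 2 <= 1.0
    labels = np.zeros(shape, dtype=np.int16)
    occupied = np.nonzero(inside.any(axis=(1, 2)))[0]
    bands = np.array_split(occupied, 12)
    left = kk < ck  # broadcastable along k
    for b, band in enumerate(bands):
        band_mask = np.zeros(shape, dtype=bool)
        band_mask[band, :, :] = True
        band_mask &= inside
        labels[band_mask & np.broadcast_to(left, shape)] = b + 1
        labels[band_mask & np.broadcast_to(~left, shape)] = b + 13
    tpl = RegionTemplate(labels=labels)
    counts = np.bincount(labels.ravel(), minlength=25)
    if np.any(counts[1:25] == 0):
        raise ValueError("degenerate grid: some template segments are empty")
    return tpl


def _lassen_inverse_counts(
    linear: Mapping[str, float], alpha: float, reference_segments: list[str]
) -> dict[str, float]:
    """Given target *linearized* counts, find raw counts such that Lassen
    correction against the reference-region mean reproduces them exactly.

    Solves for the reference level C_r with mean_{s in ref} C_s = C_r, where
    each raw count is C_s = C_r * L_s (1+a) / (C_r a + L_s).
    """
    l_ref = np.array([linear[s] for s in reference_segments])

    def mean_ratio_minus_one(c_r: float) -> float:
        x = l_ref * (1.0 + alpha) / (c_r * alpha + l_ref)
        return float(np.mean(x) - 1.0)

    lo = 1e-9 * float(np.min(l_ref))
    hi = 1e6 * float(np.max(l_ref))
    c_r = brentq(mean_ratio_minus_one, lo, hi, xtol=1e-12, rtol=1e-14)
    return {
        s: c_r * (l * (1.0 + alpha) / (c_r * alpha + l)) for s, l in linear.items()
    }


def simulate_subject(
    truth: GroundTruth,
    grid: GridSpec | None = None,
    noise: str = "none",
    seed: int = 0,
) -> SubjectBundle:
    """Run the forward model for one subject.

    Returns the dynamic planar series, SPECT volume, label template, the
    completed ground truth (aortic amplitude and input counts filled in) and
    an :class:`AnalysisConfig` carrying the true calibration constants and
    the manual Patlak ROIs.
    """
    if noise not in ("none", "poisson"):
        raise ValueError("noise must be 'none' or 'poisson'")
    grid = grid or GridSpec()
    shape = grid.planar_shape
    rng = np.random.default_rng(seed)
    scale = shape[0] / 64.0

    aorta_c = _scaled_center(_AORTA_FRAC, shape)
    arch_c = _scaled_center(_ARCH_FRAC, shape)
    pulm_c = _scaled_center(_PULM_FRAC, shape)
    brain_c = _scaled_center(_BRAIN_FRAC, shape)
    hemi_c = _scaled_center(_HEMI_ROI_FRAC, shape)

    # -- spatial weights --------------------------------------------------
    w_aorta = _gaussian_blob(shape, aorta_c, _AORTA_SIGMA_FRAC * shape[0])
    w_arch = _gaussian_blob(shape, arch_c, _ARCH_SIGMA_FRAC * shape[0])
    w_pulm = _gaussian_blob(shape, pulm_c, _PULM_SIGMA_FRAC * shape[0])
    rows, cols = np.ogrid[: shape[0], : shape[1]]
    brain_mask = (
        ((rows - brain_c[0]) / (_BRAIN_SEMI_FRAC[0] * shape[0])) ** 2
        + ((cols - brain_c[1]) / (_BRAIN_SEMI_FRAC[1] * shape[1])) ** 2
    ) <= 1.0

    aa, ab_, at0 = (
        truth.input_params.alpha_shape,
        truth.input_params.beta_scale_s,
        truth.input_params.t0_s,
    )
    shape_peak_aorta = (aa * ab_) ** aa * math.exp(-aa)
    pp_ = truth.pulmonary_params
    shape_peak_pulm = (
        (pp_.alpha_shape * pp_.beta_scale_s) ** pp_.alpha_shape
        * math.exp(-pp_.alpha_shape)
    )

    # scale the aorta blob so the standard input ROI holds _AORTA_ROI_PEAK
    # counts/frame at the bolus peak
    input_roi = roi_mask(aorta_c, _INPUT_ROI_DIAMETER, shape)
    captured = float(w_aorta[input_roi.mask].sum())
    amp_aorta = w_aorta * (_AORTA_ROI_PEAK / shape_peak_aorta) / captured
    aorta_px_peak = float(amp_aorta.max()) * shape_peak_aorta

    amp_pulm = (
        w_pulm
        * (_PULM_PIXEL_PEAK_FRAC * aorta_px_peak / shape_peak_pulm)
        / float(w_pulm.max())
    )
    amp_arch = (
        w_arch
        * (_ARCH_PIXEL_PEAK_FRAC * aorta_px_peak / shape_peak_aorta)
        / float(w_arch.max())
    )

    # brain amplitude: the configured hemispheric ROI integrates to Ku times
    # the arch input-ROI curve (microsphere model at the ROI level)
    hemi_diam = max(4, int(round(12 * scale)))
    hemi_roi = roi_mask(hemi_c, hemi_diam, shape)
    arch_diam = max(2, int(round(6 * scale)))
    arch_roi = roi_mask(arch_c, arch_diam, shape)
    s_arch = float(amp_arch[arch_roi.mask].sum())
    n_hemi = int((hemi_roi.mask & brain_mask).sum())
    b0 = truth.ku_true * s_arch / n_hemi
    amp_brain = np.where(brain_mask, b0, 0.0)

    # -- temporal curves ---------------------------------------------------
    times = (np.arange(grid.n_frames) + 0.5) * grid.frame_duration_s
    unit_aorta = GammaParams(1.0, aa, ab_, at0)
    g_a = gamma_values(unit_aorta, times)
    g_p = gamma_values(GammaParams(1.0, pp_.alpha_shape, pp_.beta_scale_s, pp_.t0_s), times)
    # discrete microsphere integral, matching the trapezoidal quadrature the
    # Patlak transform uses downstream
    big_g = cumulative_trapezoid(g_a, times, initial=0.0)

    frames = (
        g_a[:, None, None] * (amp_aorta + amp_arch)[None]
        + g_p[:, None, None] * amp_pulm[None]
        + big_g[:, None, None] * amp_brain[None]
    )
    if noise == "poisson":
        frames = rng.poisson(frames).astype(float)

    series = DynamicPlanarSeries(
        frames=frames,
        frame_duration_s=grid.frame_duration_s,
        pixel_size_mm=grid.pixel_size_mm,
    )

    # -- SPECT volume ------------------------------------------------------
    template = _build_template(grid.spect_shape)
    missing = set(truth.segment_flow) - set(template.segment_names)
    if missing:
        raise ValueError(f"truth segments absent from template: {sorted(missing)}")

    k_roi = float(amp_aorta[input_roi.mask].sum())
    input_params = GammaParams(k_roi, aa, ab_, at0)
    input_counts = gamma_integral(input_params)

    rbur_true = {
        s: (f - IBUR_INTERCEPT) / IBUR_SLOPE for s, f in truth.segment_flow.items()
    }
    if any(v <= 0 for v in rbur_true.values()):
        raise ValueError("segment flow at or below the calibration floor")
    linear = {
        s: v * input_counts / truth.ccf_true for s, v in rbur_true.items()
    }
    bg_names = [
        s
        for s in template.segment_names
        if s in ("lenticular_nucleus_left", "thalamus_left")
    ]
    seg_counts = _lassen_inverse_counts(linear, truth.lassen_alpha_true, bg_names)

    voxels = np.zeros(grid.spect_shape, dtype=float)
    for name, c in seg_counts.items():
        voxels[template.mask_of(name)] = c
    if noise == "poisson":
        voxels = rng.poisson(voxels).astype(float)
    vs = grid.voxel_size_mm
    spect = SpectVolume(voxels=voxels, voxel_size_mm=(vs, vs, vs))

    truth = replace(
        truth,
        input_params=input_params,
        input_counts_roi=input_counts,
        aorta_center=aorta_c,
        pulmonary_params=GammaParams(
            float(amp_pulm.max()), pp_.alpha_shape, pp_.beta_scale_s, pp_.t0_s
        ),
        segment_counts=seg_counts,
    )
    config = AnalysisConfig(
        lassen_alpha=truth.lassen_alpha_true,
        ccf=truth.ccf_true,
        normal_side="left",
        arch_roi_center=arch_c,
        arch_roi_diameter_px=arch_diam,
        hemisphere_roi_center=hemi_c,
        hemisphere_roi_diameter_px=hemi_diam,
        seed=seed,
    )
    return SubjectBundle(
        series=series, spect=spect, template=template, truth=truth, config=config
    )


def simulate_cohort(
    n_subjects: int = 15,
    flow_range: tuple[float, float] = (19.0, 45.0),
    seed: int = 0,
    grid: GridSpec | None = None,
    noise: str = "none",
) -> list[SubjectBundle]:
    """Simulate a cohort with true mCBF drawn uniformly from ``flow_range``."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    lo, hi = flow_range
    if not (10.0 <= lo <= hi <= 70.0):
        raise ValueError("flow_range must lie within 10-70 ml/100g/min and be nonempty")
    rng = np.random.default_rng(seed)
    bundles = []
    for _ in range(n_subjects):
        f = float(rng.uniform(lo, hi))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        truth = make_ground_truth(f, seed=sub_seed)
        bundles.append(simulate_subject(truth, grid=grid, noise=noise, seed=sub_seed))
    return bundles


def write_subject(bundle: SubjectBundle, outdir: str | Path) -> dict[str, Path]:
    """Write one subject to disk in the formats the readers expect."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "series": outdir / "dynamic.nii.gz",
        "spect": outdir / "spect.nii.gz",
        "template": outdir / "template.nii.gz",
        "config": outdir / "config.yaml",
        "truth": outdir / "truth.yaml",
    }
    write_dynamic_series(bundle.series, paths["series"])
    write_spect_volume(bundle.spect, paths["spect"])
    write_region_template(bundle.template, paths["template"])
    bundle.config.to_yaml(paths["config"])
    t = bundle.truth
    truth_doc = {
        "true_mcbf": t.true_mcbf,
        "pp_mcbf_true": t.pp_mcbf_true,
        "ku_true": t.ku_true,
        "ccf_true": t.ccf_true,
        "lassen_alpha_true": t.lassen_alpha_true,
        "input_counts_roi": t.input_counts_roi,
        "aorta_center": list(t.aorta_center),
        "segment_flow": {k: float(v) for k, v in t.segment_flow.items()},
    }
    paths["truth"].write_text(yaml.safe_dump(truth_doc, sort_keys=False))
    return paths
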