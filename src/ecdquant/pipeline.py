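"""End-to-end orchestration of the two quantification methods.

These functions wire the extraction, fitting and calibration operations
into the two complete pipelines and into cohort-level method comparisons;
the CLI and the reproduction script are thin wrappers around them.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .comparison_stats import MethodComparison
from .core_model import (
    AnalysisConfig,
    DynamicPlanarSeries,
    RegionTemplate,
    SpectVolume,
    roi_mask,
)
from .ibur_quant import (
    LassenParams,
    RegionalCBF,
    compute_rbur,
    lassen_correct,
    mcbf_ibur,
    rbur_to_rcbf,
    segment_mean_counts,
)
from .patlak_quant import (
    PatlakPlot,
    bpi_to_mcbf,
    distribute_rcbf_pp,
    estimate_ku,
    ku_to_bpi,
    patlak_transform,
)
from .tac_extraction import (
    GammaFit,
    PeakSplit,
    detect_aorta_roi,
    extract_tac,
    fit_gamma,
    input_counts,
    split_peaks,
)

__all__ = ["IburResult", "PatlakResult", "analyze_ibur", "analyze_pp",
           "compare_cohort", "regional_to_frame"]


@dataclass
class IburResult:
    regional: RegionalCBF
    rbur: dict[str, float]
    mean_counts: dict[str, float]
    fit: GammaFit
    split: PeakSplit
    input_counts: float


@dataclass
class PatlakResult:
    regional: RegionalCBF
    plot: PatlakPlot
    ku: float
    bpi: float
    mean_counts: dict[str, float]


def analyze_ibur(
    series: DynamicPlanarSeries,
    spect: SpectVolume,
    template: RegionTemplate,
    config: AnalysisConfig,
) -> IburResult:
    """Full automatic IBUR pipeline for one subject."""
    roi = detect_aorta_roi(series)
    tac = extract_tac(series, roi)
    split = split_peaks(
        tac,
        smooth_window=config.smoothing_window,
        tail_fraction=config.second_peak_tail_fraction,
    )
    fit = fit_gamma(tac, window=split.second_peak_window)
    inp = input_counts(fit)
    means = segment_mean_counts(spect, template)
    corrected = lassen_correct(
        means,
        LassenParams(
            alpha=config.lassen_alpha,
            reference_segments=tuple(config.basal_ganglia_full_names()),
        ),
    )
    rbur = compute_rbur(corrected, inp, config.ccf)
    per_segment = {s: float(rbur_to_rcbf(v)) for s, v in rbur.items()}
    mcbf = mcbf_ibur(per_segment, config)
    regional = RegionalCBF(
        method="IBUR", per_segment=per_segment, mcbf=mcbf,
        normal_side=config.normal_side,
    )
    return IburResult(
        regional=regional, rbur=rbur, mean_counts=means, fit=fit, split=split,
        input_counts=inp,
    )


def analyze_pp(
    series: DynamicPlanarSeries,
    spect: SpectVolume,
    template: RegionTemplate,
    config: AnalysisConfig,
) -> PatlakResult:
    """Full Patlak-plot pipeline for one subject (manual ROIs from config)."""
    if config.arch_roi_center is None or config.hemisphere_roi_center is None:
        raise ValueError(
            "Patlak analysis needs arch_roi_center and hemisphere_roi_center "
            "in the configuration"
        )
    arch_roi = roi_mask(
        config.arch_roi_center, config.arch_roi_diameter_px, series.grid_shape
    )
    hemi_roi = roi_mask(
        config.hemisphere_roi_center,
        config.hemisphere_roi_diameter_px,
        series.grid_shape,
    )
    input_tac = extract_tac(series, arch_roi)
    brain_tac = extract_tac(series, hemi_roi)
    if config.pp_input_model == "gamma":
        from .core_model import TimeActivityCurve
        from .synthetic_acquisition import gamma_values

        try:
            split = split_peaks(input_tac, smooth_window=config.smoothing_window)
            fit = fit_gamma(input_tac, window=split.second_peak_window)
        except ValueError:
            fit = fit_gamma(input_tac)
        input_tac = TimeActivityCurve(
            times_s=input_tac.times_s,
            counts=gamma_values(fit.params, input_tac.times_s),
        )
    plot = patlak_transform(brain_tac, input_tac)
    ku, _, _ = estimate_ku(plot, fit_window=config.patlak_fit_window)
    bpi = ku_to_bpi(ku, scale=config.bpi_scale)
    mcbf = bpi_to_mcbf(bpi.bpi)
    means = segment_mean_counts(spect, template)
    regional = distribute_rcbf_pp(means, mcbf, config)
    return PatlakResult(
        regional=regional, plot=plot, ku=ku, bpi=bpi.bpi, mean_counts=means
    )


def compare_cohort(bundles) -> tuple[MethodComparison, MethodComparison]:
    """Run both pipelines over simulated subjects; return (mCBF, rCBF)
    paired comparisons with one pair per subject / per subject x segment."""
    mcbf_pairs: list[tuple[str, float, float]] = []
    rcbf_pairs: list[tuple[str, float, float]] = []
    for i, b in enumerate(bundles):
        ib = analyze_ibur(b.series, b.spect, b.template, b.config)
        pp = analyze_pp(b.series, b.spect, b.template, b.config)
        mcbf_pairs.append((f"subj{i:02d}", pp.regional.mcbf, ib.regional.mcbf))
        for seg in b.template.segment_names:
            rcbf_pairs.append(
                (
                    f"subj{i:02d}:{seg}",
                    pp.regional.per_segment[seg],
                    ib.regional.per_segment[seg],
                )
            )
    return (
        MethodComparison(pairs=mcbf_pairs, level="mcbf"),
        MethodComparison(pairs=rcbf_pairs, level="rcbf"),
    )


def regional_to_frame(result: RegionalCBF, extra: dict | None = None) -> pd.DataFrame:
    """Tabulate a regional result as (segment, side, rcbf) rows."""
    rows = []
    for seg, v in result.per_segment.items():
        side = "left" if seg.endswith("_left") else "right"
        row = {"segment": seg, "side": side, "rcbf": v}
        if extra:
            for key, mapping in extra.items():
                row[key] = mapping.get(seg)
        rows.append(row)
    return pd.DataFrame(rows)
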