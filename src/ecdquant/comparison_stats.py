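"""Between-method comparison statistics for paired CBF measurements.

Reproduces the standard method-comparison machinery for two quantification
techniques measured on the same subjects/segments: ordinary least-squares
regression with Pearson correlation, paired two-tailed tests (Student t and
Wilcoxon signed-rank), and box-plot style summary tables with PP/IBUR
ratios of minima, maxima and variances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MethodComparison",
    "SummaryTable",
    "LinearFit",
    "linear_fit",
    "summarize_pair",
    "paired_test",
    "scatter_figure",
    "box_figure",
]


@dataclass
class MethodComparison:
    """Paired (PP, IBUR) values at the mCBF (per subject) or rCBF
    (per subject x segment) level."""

    pairs: list[tuple[str, float, float]]  # (id, value_pp, value_ibur)
    level: str  # "mcbf" | "rcbf"

    def __post_init__(self) -> None:
        if self.level not in ("mcbf", "rcbf"):
            raise ValueError("level must be 'mcbf' or 'rcbf'")
        for pid, a, b in self.pairs:
            if not (np.isfinite(a) and np.isfinite(b)):
                raise ValueError(f"non-finite value for pair {pid!r}")

    @property
    def pp(self) -> np.ndarray:
        return np.array([p[1] for p in self.pairs], dtype=float)

    @property
    def ibur(self) -> np.ndarray:
        return np.array([p[2] for p in self.pairs], dtype=float)


class LinearFit(NamedTuple):
    slope: float
    intercept: float
    pearson_r: float
    p_value: float


def linear_fit(x_values, y_values) -> LinearFit:
    """OLS line y = a*x + b with Pearson r and its two-sided p-value
    (t distribution, n-2 df)."""
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points for a regression")
    if np.ptp(x) == 0:
        raise ValueError("degenerate x: zero variance")
    if np.ptp(y) == 0:
        # a constant response: slope and correlation are both zero
        return LinearFit(0.0, float(y[0]), 0.0, 1.0)
    res = stats.linregress(x, y)
    return LinearFit(
        float(res.slope), float(res.intercept), float(res.rvalue), float(res.pvalue)
    )


def _describe(values: np.ndarray) -> dict[str, float]:
    return {
        "n": int(len(values)),
        "mean": float(np.mean(values)),
        "sd": float(np.std(values, ddof=1)) if len(values) > 1 else 0.0,
        "variance": float(np.var(values, ddof=1)) if len(values) > 1 else 0.0,
        "min": float(np.min(values)),
        "max": float(np.max(values)),
        "median": float(np.median(values)),
        "p25": float(np.percentile(values, 25)),  # linear interpolation
        "p75": float(np.percentile(values, 75)),
    }


@dataclass
class SummaryTable:
    """Box-plot summary per method plus PP/IBUR ratios and paired p-values."""

    level: str
    stats_pp: dict[str, float]
    stats_ibur: dict[str, float]
    min_ratio: float
    max_ratio: float
    variance_ratio: float
    p_ttest: float
    p_wilcoxon: float

    def __post_init__(self) -> None:
        for d in (self.stats_pp, self.stats_ibur):
            if not (d["p25"] <= d["median"] <= d["p75"]):
                raise ValueError("quartiles out of order")
            if not (d["min"] <= d["median"] <= d["max"]):
                raise ValueError("median outside the data range")

    def to_frame(self) -> pd.DataFrame:
        rows = ["n", "mean", "sd", "variance", "min", "max", "median", "p25", "p75"]
        df = pd.DataFrame(
            {
                "PP": [self.stats_pp[r] for r in rows],
                "IBUR": [self.stats_ibur[r] for r in rows],
            },
            index=rows,
        )
        df.loc["min_ratio_pp_over_ibur"] = [self.min_ratio, np.nan]
        df.loc["max_ratio_pp_over_ibur"] = [self.max_ratio, np.nan]
        df.loc["variance_ratio_pp_over_ibur"] = [self.variance_ratio, np.nan]
        df.loc["p_paired_t"] = [self.p_ttest, np.nan]
        df.loc["p_wilcoxon"] = [self.p_wilcoxon, np.nan]
        return df


def summarize_pair(comparison: MethodComparison) -> SummaryTable:
    """All box-plot statistics plus PP/IBUR ratios of min, max and variance.

    Percentiles use linear interpolation; variances use the n-1 denominator.
    """
    pp, ib = comparison.pp, comparison.ibur
    if len(pp) == 0:
        raise ValueError("empty comparison")
    spp, sib = _describe(pp), _describe(ib)
    var_ratio = spp["variance"] / sib["variance"] if sib["variance"] > 0 else np.nan
    return SummaryTable(
        level=comparison.level,
        stats_pp=spp,
        stats_ibur=sib,
        min_ratio=spp["min"] / sib["min"] if sib["min"] != 0 else np.nan,
        max_ratio=spp["max"] / sib["max"] if sib["max"] != 0 else np.nan,
        variance_ratio=var_ratio,
        p_ttest=paired_test(pp, ib, kind="t"),
        p_wilcoxon=paired_test(pp, ib, kind="wilcoxon"),
    )


def paired_test(values_a, values_b, kind: str = "wilcoxon") -> float:
    """Two-tailed paired test p-value; ``kind`` is 't' or 'wilcoxon'.

    Identical pairs (all differences zero) are the no-difference degenerate
    case and return p = 1 with a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1D arrays of equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 pairs")
    diffs = a - b
    if np.all(diffs == 0):
        warnings.warn("all paired differences are zero; returning p = 1", stacklevel=2)
        return 1.0
    if kind == "t":
        if np.ptp(diffs) == 0:
            # constant nonzero difference: zero-variance t statistic diverges
            warnings.warn(
                "paired differences have zero variance; treating as a "
                "maximal-evidence shift (p = 0)",
                stacklevel=2,
            )
            return 0.0
        return float(stats.ttest_rel(a, b).pvalue)
    if kind == "wilcoxon":
        res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
        return float(res.pvalue)
    raise ValueError("kind must be 't' or 'wilcoxon'")


def scatter_figure(comparison: MethodComparison, path) -> None:
    """Scatter of IBUR vs PP values with the OLS line, saved to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fit = linear_fit(comparison.pp, comparison.ibur)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(comparison.pp, comparison.ibur, s=18, alpha=0.7)
    xs = np.linspace(comparison.pp.min(), comparison.pp.max(), 50)
    ax.plot(xs, fit.slope * xs + fit.intercept, "k-", lw=1)
    ax.set_xlabel(f"PP {comparison.level} (ml/100g/min)")
    ax.set_ylabel(f"IBUR {comparison.level} (ml/100g/min)")
    ax.set_title(
        f"y = {fit.slope:.2f}x + {fit.intercept:.1f} (r = {fit.pearson_r:.2f})"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def box_figure(comparison: MethodComparison, path) -> None:
    """Side-by-side box plots of the two methods, saved to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 5))
    ax.boxplot([comparison.pp, comparison.ibur], tick_labels=["PP", "IBUR"])
    ax.set_ylabel(f"{comparison.level} (ml/100g/min)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
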