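"""Method-agreement statistics for paired species size estimates.

Bland-Altman analysis summarises the bias between two measurement methods
by the mean of the per-item differences (diff-bar) and the SD of the
differences (s), plotted against the per-item means.  The sign convention
is ``cytometer - literature``: a negative mean difference means the
literature sizes run larger.  Limit lines are drawn at diff-bar, +-1 SD
and +-2 SD.  Pearson correlation and OLS fits (optionally on
log10-transformed literature sizes) rank the agreement across literature
sources; correlation alone never establishes agreement, which is why the
Bland-Altman summary comes first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

LITERATURE_SOURCES = ("beug", "pollen_wiki", "ecological_flora")


@dataclass
class AgreementResult:
    """Bland-Altman summary for n paired sizes (um)."""

    n: int
    mean_diff_um: float
    sd_diff_um: float
    lines: Dict[str, float]
    diffs: np.ndarray
    means: np.ndarray


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int


@dataclass
class FitResult:
    """Simple OLS fit with adjusted R^2 and df = n - 2."""

    slope: float
    intercept: float
    r2_adj: float
    df: int
    p_value: float
    log10_x: bool = False


def _paired(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D arrays")
    return x, y


def bland_altman(size_ifc, size_lit) -> AgreementResult:
    """Bland-Altman summary of cytometer vs literature sizes.

    diff_i = size_ifc_i - size_lit_i; mean_i is the average of the two.
    Requires at least 2 pairs.
    """
    x, y = _paired(size_ifc, size_lit)
    if len(x) < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    diffs = x - y
    means = (x + y) / 2.0
    d = float(diffs.mean())
    s = float(diffs.std(ddof=1))
    lines = {
        "zero": 0.0,
        "mean_diff": d,
        "minus_1sd": d - s, "plus_1sd": d + s,
        "minus_2sd": d - 2 * s, "plus_2sd": d + 2 * s,
    }
    return AgreementResult(n=len(x), mean_diff_um=d, sd_diff_um=s,
                           lines=lines, diffs=diffs, means=means)


def group_diff_summary(
    pairs: pd.DataFrame,
    group: str = "family_label",
    ifc_col: str = "size_ifc_um",
    lit_col: str = "size_lit_um",
) -> pd.DataFrame:
    """Per-group mean +- SD of the differences with counts (e.g. per plant
    family).  Groups of size 1 report SD as NaN."""
    if group not in pairs.columns:
        raise ValueError(f"missing group column {group!r}")
    diffs = pairs[ifc_col].astype(float) - pairs[lit_col].astype(float)
    out = []
    for g, idx in pairs.groupby(group).groups.items():
        d = diffs.loc[idx]
        out.append({
            group: g,
            "n": int(len(d)),
            "mean_diff_um": float(d.mean()),
            "sd_diff_um": float(d.std(ddof=1)) if len(d) > 1 else np.nan,
        })
    return pd.DataFrame(out)


def pearson_r(x, y) -> CorrelationResult:
    """Product-moment correlation with a two-sided t-based p-value."""
    x, y = _paired(x, y)
    if len(x) < 3:
        raise ValueError("Pearson correlation needs at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue),
                             n=len(x))


def ols_fit(x, y, log10_x: bool = False) -> FitResult:
    """Least-squares line ``y = slope * x + intercept`` (x optionally
    log10-transformed), with adjusted R^2 and df = n - 2."""
    x, y = _paired(x, y)
    if len(x) < 3:
        raise ValueError("OLS needs at least 3 points")
    if log10_x:
        if np.any(x <= 0):
            raise ValueError("log10 transform requires positive x")
        x = np.log10(x)
    if np.std(x) == 0:
        raise ValueError("degenerate (constant) predictor")
    res = stats.linregress(x, y)
    n = len(x)
    r2 = res.rvalue ** 2
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return FitResult(slope=float(res.slope), intercept=float(res.intercept),
                     r2_adj=float(r2_adj), df=n - 2,
                     p_value=float(res.pvalue), log10_x=log10_x)


def read_pairs(path) -> pd.DataFrame:
    """Read a paired-size CSV (species_label, family_label, size_ifc_um,
    size_lit_um, source)."""
    df = pd.read_csv(path)
    required = {"species_label", "size_ifc_um", "size_lit_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"paired CSV missing columns: {sorted(missing)}")
    if (df["size_ifc_um"] <= 0).any() or (df["size_lit_um"] <= 0).any():
        raise ValueError("sizes must be positive")
    return df


def plot_bland_altman(result: AgreementResult, path) -> None:
    """Write a Bland-Altman plot (difference vs mean with limit lines)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(result.means, result.diffs, s=18, alpha=0.7)
    styles = {"zero": ("-", "0.7"), "mean_diff": ("-", "tab:green"),
              "minus_1sd": ("--", "tab:olive"), "plus_1sd": ("--", "tab:olive"),
              "minus_2sd": (":", "0.4"), "plus_2sd": (":", "0.4")}
    for name, yv in result.lines.items():
        ls, color = styles[name]
        ax.axhline(yv, linestyle=ls, color=color, linewidth=1)
    ax.set_xlabel("mean of methods (um)")
    ax.set_ylabel("difference IFC - literature (um)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
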