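"""Per-cell differentiation scoring from image-quantification tables.

Works on per-object mean-intensity tables as produced by an upstream image
quantification pipeline (CellProfiler-style CSV).  The score is the ratio of
Cdx2 to Oct4 mean fluorescence per cell: the two transcription factors
repress each other, so pluripotent cells score near zero and differentiating
cells score high.  Conditions are compared with a two-tailed Mann-Whitney
test, and histograms use a capped axis with a final overflow bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

__all__ = [
    "score_cells",
    "summarize_scores",
    "compare_conditions",
    "positive_fraction",
    "read_intensity_table",
    "ScoreSummary",
    "HISTOGRAM_CAP",
]

HISTOGRAM_CAP = 3.5  # scores above this aggregate into the overflow bin
_EXACT_N_MAX = 50


@dataclass
class ScoreSummary:
    """Score distribution summaries per condition."""

    n_cells: dict[str, int]
    n_excluded: dict[str, int]
    median: dict[str, float]
    mean: dict[str, float]
    box: dict[str, dict[str, float]]  # p01/p25/p75/p99 whisker-box stats
    hist_edges: np.ndarray  # on [0, cap]; final bin is the overflow count
    hist_counts: dict[str, np.ndarray]
    mann_whitney_p: float | None = None
    extras: dict = field(default_factory=dict)


def read_intensity_table(
    path: str | Path,
    oct4_col: str = "oct4",
    cdx2_col: str = "cdx2",
    condition_col: str = "condition",
) -> pd.DataFrame:
    """Load a per-object intensity CSV, renaming configurable column names
    to the canonical oct4/cdx2/condition."""
    df = pd.read_csv(path)
    rename = {oct4_col: "oct4", cdx2_col: "cdx2", condition_col: "condition"}
    missing = [c for c in rename if c not in df.columns]
    if missing:
        raise KeyError(f"intensity table lacks column(s): {', '.join(missing)}")
    return df.rename(columns=rename)


def score_cells(
    table: pd.DataFrame,
    oct4_floor_frac: float = 0.01,
) -> tuple[np.ndarray, int]:
    """Per-cell differentiation score cdx2/oct4.

    Cells whose Oct4 signal falls below ``oct4_floor_frac`` times the table's
    median Oct4 are excluded (unbounded ratios from near-zero denominators)
    and counted.  Returns (scores, n_excluded).
    """
    for col in ("oct4", "cdx2"):
        if col not in table.columns:
            raise KeyError(f"intensity table lacks column {col!r}")
    oct4 = table["oct4"].to_numpy(dtype=float)
    cdx2 = table["cdx2"].to_numpy(dtype=float)
    if (oct4 < 0).any() or (cdx2 < 0).any():
        raise ValueError("intensities must be non-negative")
    floor = oct4_floor_frac * float(np.median(oct4)) if len(oct4) else 0.0
    keep = oct4 > max(floor, 0.0)
    if not keep.any():
        raise ValueError("all cells excluded by the Oct4 floor")
    return cdx2[keep] / oct4[keep], int((~keep).sum())


def _box_stats(scores: np.ndarray) -> dict[str, float]:
    q = np.percentile(scores, [1, 25, 50, 75, 99])
    return {"p01": q[0], "p25": q[1], "p50": q[2], "p75": q[3], "p99": q[4]}


def summarize_scores(
    scores_by_condition: Mapping[str, np.ndarray],
    n_excluded: Mapping[str, int] | None = None,
    cap: float = HISTOGRAM_CAP,
    bin_width: float = 0.1,
) -> ScoreSummary:
    """Medians, means, box-plot stats and capped histograms per condition.

    The histogram covers [0, cap]; its final bin holds every score > cap.
    Box stats follow the 1st/99th-percentile-whisker convention.
    """
    if not scores_by_condition:
        raise ValueError("no conditions to summarize")
    inner = np.arange(0.0, cap + bin_width / 2, bin_width)
    edges = np.append(inner, np.inf)  # overflow bin
    summary = ScoreSummary(
        n_cells={}, n_excluded=dict(n_excluded or {}), median={}, mean={},
        box={}, hist_edges=edges, hist_counts={},
    )
    for cond, scores in scores_by_condition.items():
        s = np.asarray(scores, dtype=float)
        if s.size == 0:
            raise ValueError(f"condition {cond!r} has no scored cells")
        summary.n_cells[cond] = int(s.size)
        summary.median[cond] = float(np.median(s))
        summary.mean[cond] = float(np.mean(s))
        summary.box[cond] = _box_stats(s)
        counts, _ = np.histogram(s, bins=edges)
        summary.hist_counts[cond] = counts
    if len(scores_by_condition) == 2:
        a, b = scores_by_condition.values()
        summary.mann_whitney_p = compare_conditions(a, b)[0]
    return summary


def compare_conditions(
    scores_a: np.ndarray, scores_b: np.ndarray
) -> tuple[float, dict[str, float]]:
    """Two-tailed Mann-Whitney U comparison of two score distributions.

    Exact enumeration when both groups have <= 50 cells and the pooled
    scores are tie-free; otherwise the normal approximation with tie
    correction.  Returns (p, fold summaries of medians and means).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >=2 cells per condition")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (max(a.size, b.size) <= _EXACT_N_MAX and no_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    folds = {
        "median_fold": float(np.median(a) / np.median(b)) if np.median(b) else float("inf"),
        "mean_fold": float(np.mean(a) / np.mean(b)) if np.mean(b) else float("inf"),
    }
    return float(res.pvalue), folds


def positive_fraction(
    values: np.ndarray,
    control_values: np.ndarray,
    quantile: float = 0.995,
) -> tuple[float, float]:
    """Marker-positive fraction against a negative-control threshold.

    The threshold is the control's empirical quantile (same rule as the flow
    positivity gates); returns (fraction positive, threshold).  Used for
    single-marker readouts such as a Sox17-positive endoderm fraction.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    control = np.asarray(control_values, dtype=float)
    v = np.asarray(values, dtype=float)
    if control.size == 0 or v.size == 0:
        raise ValueError("empty values or control")
    thr = float(np.quantile(control, quantile))
    return float((v > thr).mean()), thr
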