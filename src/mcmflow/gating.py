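"""Gating hierarchy and cell-cycle phase taxonomy for chromatin flow data.

The hierarchy mirrors standard practice for DAPI/EdU/MCM panels: a scatter
gate (FS-area vs SS-area), a singlet gate on the DAPI area-vs-height ratio,
then antibody positivity thresholds derived from a matched
no-primary-antibody negative control.  Non-excluded cells are partitioned
into three classes: S-phase cells with DNA-loaded MCM (EdU+/MCM+), G1 cells
with loaded MCM (EdU-/MCM+/G1 DNA content), and MCM-negative G1/G2/M cells.
"Early S" flags EdU+ cells whose DNA content is still within the G1 window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter1d
from scipy.stats import ttest_ind

from .flow_io import EventTable

__all__ = [
    "GatingConfig",
    "Thresholds",
    "PhaseCall",
    "derive_thresholds",
    "find_g1_peak",
    "classify_phases",
    "split_s_by_mcm",
    "SplitResult",
    "phase_fractions",
    "summarize_channel_by_phase",
    "compare_phase_summaries",
    "G1_MCM_POS",
    "S_MCM_POS",
    "MCM_NEG",
    "EXCLUDED",
]

G1_MCM_POS = "G1_MCM_POS"
S_MCM_POS = "S_MCM_POS"
MCM_NEG = "MCM_NEG_G1G2M"
EXCLUDED = "EXCLUDED"


@dataclass(frozen=True)
class GatingConfig:
    """Tunable gate geometry.

    ``control_quantile`` sets the antibody positivity threshold as an
    empirical quantile of the negative control.  DNA windows are relative to
    the G1 DAPI peak.  The singlet window is a relative band on the
    dna_h/dna_a ratio around its mode.  ``scatter_gate`` is an optional
    dict of per-channel (low, high) bounds on fsc_a/ssc_a.
    """

    control_quantile: float = 0.995
    g1_window: tuple[float, float] = (0.85, 1.15)
    g2_window: tuple[float, float] = (1.70, 2.30)
    singlet_ratio_window: tuple[float, float] = (0.75, 1.25)
    scatter_gate: dict[str, tuple[float, float]] | None = None
    s_mcm_low_quantile: float = 0.10

    def __post_init__(self) -> None:
        if not 0 < self.control_quantile < 1:
            raise ValueError("control_quantile must be in (0, 1)")
        if not 0 < self.s_mcm_low_quantile < 1:
            raise ValueError("s_mcm_low_quantile must be in (0, 1)")
        for name in ("g1_window", "g2_window", "singlet_ratio_window"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be ordered (low < high)")
        if self.g1_window[1] >= self.g2_window[0]:
            raise ValueError("g1_window and g2_window must not overlap")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GatingConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("g1_window", "g2_window", "singlet_ratio_window"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if raw.get("scatter_gate"):
            raw["scatter_gate"] = {k: tuple(v) for k, v in raw["scatter_gate"].items()}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


class Thresholds(NamedTuple):
    """Positivity thresholds in raw intensity units."""

    edu: float
    mcm: float


@dataclass
class PhaseCall:
    """Per-cell phase labels and flags for one sample.

    ``label`` partitions non-excluded cells into the three-class taxonomy;
    ``is_early_s`` marks EdU+ cells with G1 DNA content; ``is_g1`` marks all
    EdU-negative cells with G1 DNA content regardless of MCM (the
    conventional G1 share of the cycle).  ``counts`` reports exclusions and
    anomalies (e.g. EdU+/MCM- events, folded into the MCM-negative class).
    """

    label: pd.Series
    is_early_s: pd.Series
    is_g1: pd.Series
    g1_peak: float
    thresholds: Thresholds
    counts: dict[str, int] = field(default_factory=dict)
    s_mcm_class: pd.Series | None = None

    def mask(self, label: str) -> np.ndarray:
        return (self.label == label).to_numpy()

    @property
    def n_non_excluded(self) -> int:
        return int((self.label != EXCLUDED).sum())


def _smoothed_mode(values: np.ndarray, bins: int = 256, sigma: float = 2.0) -> float:
    """Location of the dominant mode of a kernel-smoothed histogram."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot locate a mode of an empty distribution")
    lo, hi = float(values.min()), float(values.max())
    if hi - lo <= max(abs(lo), abs(hi), 1.0) * 1e-9:
        return 0.5 * (lo + hi)  # numerically degenerate spread
    counts, edges = np.histogram(values, bins=bins, range=(lo, hi))
    smooth = gaussian_filter1d(counts.astype(float), sigma=sigma)
    if smooth.max() <= 0:
        raise ValueError("no detectable mode (flat distribution)")
    centers = 0.5 * (edges[:-1] + edges[1:])
    return float(centers[int(np.argmax(smooth))])


def derive_thresholds(control: EventTable, config: GatingConfig | None = None) -> Thresholds:
    """Positivity thresholds from a matched negative-control sample.

    Threshold = empirical ``control_quantile`` of the control's channel; a
    stained sub-population accidentally present in the control shows up as
    bimodality and triggers a (non-fatal) warning.
    """
    config = config or GatingConfig()
    if not control.metadata.get("is_negative_control", False):
        warnings.warn("control sample is not flagged is_negative_control", stacklevel=2)
    if len(control) == 0:
        raise ValueError("empty negative control")
    if len(control) < 500:
        warnings.warn(
            f"negative control has only {len(control)} events; >=500 recommended",
            stacklevel=2,
        )
    control.require("edu", "mcm")
    out = {}
    for ch in ("edu", "mcm"):
        values = control.channel(ch)
        _warn_if_bimodal(values, ch)
        out[ch] = float(np.quantile(values, config.control_quantile))
    return Thresholds(edu=out["edu"], mcm=out["mcm"])


def _warn_if_bimodal(values: np.ndarray, name: str) -> None:
    v = values[values > 0]
    if v.size < 100 or v.min() == v.max():
        return
    logv = np.log(v)
    counts, _ = np.histogram(logv, bins=64)
    smooth = gaussian_filter1d(counts.astype(float), sigma=2.0)
    interior = slice(1, -1)
    peaks = np.flatnonzero(
        (smooth[interior] > np.roll(smooth, 1)[interior])
        & (smooth[interior] >= np.roll(smooth, -1)[interior])
    )
    prominent = [p for p in peaks if smooth[p + 1] > 0.25 * smooth.max()]
    if len(prominent) > 1 and (max(prominent) - min(prominent)) > 8:
        warnings.warn(
            f"negative control {name} channel looks bimodal; "
            "it may contain stained events",
            stacklevel=3,
        )


def find_g1_peak(dna: np.ndarray) -> float:
    """DAPI-area location of the G1 (2N) peak.

    The dominant mode of a kernel-smoothed histogram; a consistency check
    looks for a secondary (G2/M) mode near twice the peak and warns when it
    is absent.  Fewer than ~1000 events gives an unstable estimate.
    """
    dna = np.asarray(dna, dtype=float)
    if dna.size == 0:
        raise ValueError("empty DNA distribution")
    if dna.size < 1000:
        warnings.warn("G1 peak estimate from <1000 events is unstable", stacklevel=2)
    peak = _smoothed_mode(dna)
    if dna.min() != dna.max():
        # G2 consistency: any local maximum within [1.7, 2.3] x peak
        counts, edges = np.histogram(dna, bins=256, range=(dna.min(), dna.max()))
        smooth = gaussian_filter1d(counts.astype(float), sigma=2.0)
        centers = 0.5 * (edges[:-1] + edges[1:])
        in_g2 = (centers >= 1.7 * peak) & (centers <= 2.3 * peak)
        if in_g2.any():
            local = smooth[in_g2]
            if local.max() < 0.02 * smooth.max():
                warnings.warn("no secondary mode near 2x the G1 peak", stacklevel=2)
    return peak


def classify_phases(
    events: EventTable,
    thresholds: Thresholds,
    config: GatingConfig | None = None,
    g1_peak: float | None = None,
) -> PhaseCall:
    """Apply the gating hierarchy and three-class phase taxonomy.

    Scatter- and singlet-failing cells are EXCLUDED.  Then, in order:
    MCM <= threshold -> MCM-negative G1/G2/M; EdU+ -> S-MCM+; EdU- with G1
    DNA content -> G1-MCM+; remaining MCM+ anomalies (EdU- with non-G1 DNA)
    are folded into the MCM-negative class and counted.
    """
    config = config or GatingConfig()
    events.require("dna_a", "edu", "mcm")
    n = len(events)
    dna = events.channel("dna_a")
    edu = events.channel("edu")
    mcm = events.channel("mcm")

    excluded = np.zeros(n, dtype=bool)
    counts: dict[str, int] = {}

    if config.scatter_gate:
        for ch, (lo, hi) in config.scatter_gate.items():
            v = events.channel(ch)
            excluded |= (v < lo) | (v > hi)
        counts["excluded_scatter"] = int(excluded.sum())

    if "dna_h" in events.channels:
        ratio = np.divide(
            events.channel("dna_h"), dna, out=np.zeros(n), where=dna > 0
        )
        keep = ~excluded & (ratio > 0)
        if keep.sum() >= 10:
            mode = _smoothed_mode(ratio[keep])
            lo, hi = config.singlet_ratio_window
            singlet_fail = (ratio < lo * mode) | (ratio > hi * mode)
            counts["excluded_doublet"] = int((singlet_fail & ~excluded).sum())
            excluded |= singlet_fail

    if g1_peak is None:
        g1_peak = find_g1_peak(dna[~excluded]) if (~excluded).any() else float("nan")
    g1_lo, g1_hi = config.g1_window[0] * g1_peak, config.g1_window[1] * g1_peak
    in_g1_dna = (dna >= g1_lo) & (dna <= g1_hi)

    mcm_pos = mcm > thresholds.mcm
    edu_pos = edu > thresholds.edu

    label = np.full(n, MCM_NEG, dtype=object)
    label[edu_pos & mcm_pos] = S_MCM_POS
    label[~edu_pos & mcm_pos & in_g1_dna] = G1_MCM_POS
    anomalous = ~edu_pos & mcm_pos & ~in_g1_dna
    counts["anomalous_mcm_pos_non_g1"] = int((anomalous & ~excluded).sum())
    counts["anomalous_edu_pos_mcm_neg"] = int((edu_pos & ~mcm_pos & ~excluded).sum())
    label[excluded] = EXCLUDED

    is_early_s = (label == S_MCM_POS) & in_g1_dna
    is_g1 = ~excluded & ~edu_pos & in_g1_dna

    return PhaseCall(
        label=pd.Series(label, name="label"),
        is_early_s=pd.Series(is_early_s, name="is_early_s"),
        is_g1=pd.Series(is_g1, name="is_g1"),
        g1_peak=float(g1_peak),
        thresholds=thresholds,
        counts=counts,
    )


class SplitResult(NamedTuple):
    """Outcome of the S-phase MCM-high/low split."""

    s_mcm_class: pd.Series  # per-cell: "high" | "low" | "n/a"
    boundary: float
    fraction_low_early_s: float  # headline number: among early-S cells
    fraction_low_all_s: float  # among all S-MCM+ cells (late-S unloading included)


def split_s_by_mcm(
    events: EventTable,
    calls: PhaseCall,
    reference: EventTable,
    reference_calls: PhaseCall,
    config: GatingConfig | None = None,
) -> SplitResult:
    """Classify S-phase cells as having begun S with high or low loaded MCM.

    The boundary is the ``s_mcm_low_quantile`` of the *reference* sample's
    early-S MCM intensities (the matched control condition from the same
    batch).  Whether a cell *began* S underlicensed is only decidable near
    S entry on a one-dimensional MCM axis — later in S every cell unloads
    through the boundary — so the headline fraction-low uses the early-S
    denominator (by construction ~``s_mcm_low_quantile`` in the reference);
    the all-S fraction is reported alongside.  The per-cell class Series is
    also stored on ``calls``.
    """
    config = config or GatingConfig()
    ref_early = reference.channel("mcm")[reference_calls.is_early_s.to_numpy()]
    if ref_early.size == 0:
        raise ValueError("reference sample has no early-S cells")
    boundary = float(np.quantile(ref_early, config.s_mcm_low_quantile))

    s_mask = calls.mask(S_MCM_POS)
    early_mask = calls.is_early_s.to_numpy()
    mcm = events.channel("mcm")
    cls = np.full(len(events), "n/a", dtype=object)
    cls[s_mask & (mcm < boundary)] = "low"
    cls[s_mask & (mcm >= boundary)] = "high"
    series = pd.Series(cls, name="s_mcm_class")
    calls.s_mcm_class = series
    n_s = int(s_mask.sum())
    n_early = int(early_mask.sum())
    low = cls == "low"
    return SplitResult(
        s_mcm_class=series,
        boundary=boundary,
        fraction_low_early_s=float(low[early_mask].sum() / n_early) if n_early else float("nan"),
        fraction_low_all_s=float(low.sum() / n_s) if n_s else float("nan"),
    )


def phase_fractions(calls: PhaseCall) -> dict[str, float]:
    """Label fractions over non-excluded cells, plus the conventional
    percent-G1 (EdU-negative with G1 DNA content, regardless of MCM)."""
    non_excluded = calls.label != EXCLUDED
    total = int(non_excluded.sum())
    if total == 0:
        raise ValueError("all cells excluded; no phase fractions")
    out = {
        lab: float((calls.label[non_excluded] == lab).sum() / total)
        for lab in (G1_MCM_POS, S_MCM_POS, MCM_NEG)
    }
    out["g1_percent_of_total"] = float(100.0 * calls.is_g1[non_excluded].sum() / total)
    return out


def summarize_channel_by_phase(
    events: EventTable,
    calls: PhaseCall,
    channel: str,
    statistic: str = "mean",
) -> dict[str, float]:
    """Per-phase summary (mean or median) of a channel, including the
    early-S subset.  Empty subsets yield NaN and are flagged via a warning."""
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    values = events.channel(channel)
    func = np.mean if statistic == "mean" else np.median
    out: dict[str, float] = {}
    groups = {
        G1_MCM_POS: calls.mask(G1_MCM_POS),
        S_MCM_POS: calls.mask(S_MCM_POS),
        MCM_NEG: calls.mask(MCM_NEG),
        "early_S": calls.is_early_s.to_numpy(),
    }
    if calls.s_mcm_class is not None:
        groups["S_mcm_high"] = (calls.s_mcm_class == "high").to_numpy()
        groups["S_mcm_low"] = (calls.s_mcm_class == "low").to_numpy()
    for name, mask in groups.items():
        if mask.sum() == 0:
            warnings.warn(f"no cells in subset {name}; summary undefined", stacklevel=2)
            out[name] = float("nan")
        else:
            out[name] = float(func(values[mask]))
    return out


def compare_phase_summaries(
    summaries_a: list[float],
    summaries_b: list[float],
    equal_var: bool = True,
) -> tuple[float, float]:
    """Fold change and two-tailed unpaired t-test across replicate summaries.

    ``summaries_a``/``summaries_b`` are per-replicate phase summaries (one
    number per biological replicate).  Requires n >= 2 per group.
    """
    a = np.asarray(summaries_a, dtype=float)
    b = np.asarray(summaries_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("t-test requires >=2 replicate summaries per group")
    if b.mean() == 0:
        raise ZeroDivisionError("reference group mean is zero")
    fold = float(a.mean() / b.mean())
    stat = ttest_ind(a, b, equal_var=equal_var)
    return fold, float(stat.pvalue)
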