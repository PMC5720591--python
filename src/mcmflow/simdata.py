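"""Steady-state population simulator for chromatin flow cytometry.

Generates synthetic fixed-cell snapshots of an asynchronously proliferating,
exponentially growing population together with per-cell ground truth, so that
gating, growth fitting, ergodic rate analysis and subpopulation scoring can be
validated without instrument data.

The generative model: cell age ``a`` in a population growing at rate
``alpha = ln(2)/T_d`` has steady-state density ``2*alpha*exp(-alpha*a)`` on
``[0, T_d]`` (newborns are twice as frequent as dividing cells).  Phases are
laid out by cumulative duration G1 -> S -> G2/M.  DNA-loaded MCM rises
linearly through G1 at ``mcm_load_rate`` up to the licensing target
``mcm_max`` and is unloaded linearly across S; EdU incorporation marks S
phase, scaled by how fully licensed the cell was at S entry; DNA content runs
from 1 (2N) to 2 (4N).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .flow_io import EventTable

__all__ = [
    "PopulationModel",
    "NoiseModel",
    "SimSample",
    "sample_ages",
    "assign_phase_and_signals",
    "simulate_sample",
    "simulate_mixture",
    "simulate_negative_control",
    "simulate_growth_counts",
    "load_scenario",
    "model_hesc",
    "model_npc",
    "model_ipsc",
    "model_rpe",
    "cyclin_e_pair",
]

# default intensity scales (arbitrary units, roughly CyAn-like linear channels)
_FSC_SCALE = 5.0e4
_SSC_SCALE = 3.0e4
_DNA_HEIGHT_RATIO = 0.9


@dataclass(frozen=True)
class PopulationModel:
    """Generative cell-cycle parameters for one steady-state population.

    Durations are hours and must sum to ``doubling_time``.  ``mcm_load_rate``
    is in MCM-units/hour; ``mcm_max`` is the loaded-MCM target at S entry.
    With ``checkpoint_active`` the G1/S transition waits until the target is
    reached (G1 extends so that ``r * T_G1 >= mcm_max``); without it, S entry
    happens at the scheduled ``g1_hours`` regardless of loaded MCM, which is
    how a Cyclin-E-overproduction scenario produces underlicensed S cells.
    """

    doubling_time: float
    g1_hours: float
    s_hours: float
    g2m_hours: float
    mcm_load_rate: float
    mcm_max: float = 200.0
    edu_scale: float = 500.0
    dna_g1_level: float = 100.0
    checkpoint_active: bool = True

    def __post_init__(self) -> None:
        if self.doubling_time <= 0:
            raise ValueError("doubling_time must be positive")
        for name in ("g1_hours", "s_hours", "g2m_hours"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        total = self.g1_hours + self.s_hours + self.g2m_hours
        if not math.isclose(total, self.doubling_time, rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError(
                f"phase durations sum to {total}, expected doubling_time={self.doubling_time}"
            )
        if self.mcm_load_rate <= 0:
            raise ValueError("mcm_load_rate must be positive")
        if self.mcm_max <= 0:
            raise ValueError("mcm_max must be positive")

    @property
    def alpha(self) -> float:
        """Population growth rate ln(2)/T_d (per hour)."""
        return math.log(2.0) / self.doubling_time

    def effective_durations(self) -> tuple[float, float, float]:
        """(T_G1, T_S, T_G2M) after applying the licensing checkpoint.

        If the checkpoint extends G1 past its scheduled length, S and G2/M
        are rescaled proportionally so the cycle still sums to T_d.
        """
        t_g1 = self.g1_hours
        if self.checkpoint_active:
            t_g1 = max(self.g1_hours, self.mcm_max / self.mcm_load_rate)
        remaining = self.doubling_time - t_g1
        if remaining <= 0:
            raise ValueError(
                "checkpoint-extended G1 consumes the whole cycle; "
                "increase mcm_load_rate or doubling_time"
            )
        scale = remaining / (self.s_hours + self.g2m_hours)
        return t_g1, self.s_hours * scale, self.g2m_hours * scale


@dataclass(frozen=True)
class NoiseModel:
    """Measurement model: multiplicative log-normal channel noise plus an
    additive antibody-background draw on the antibody channels (edu, mcm).
    The background distribution is what a no-primary-antibody negative
    control sample measures."""

    channel_cv: Mapping[str, float] = field(
        default_factory=lambda: {
            "fsc_a": 0.25,
            "ssc_a": 0.25,
            "dna_a": 0.06,
            "dna_h": 0.03,
            "edu": 0.25,
            "mcm": 0.18,
        }
    )
    background_median: float = 5.0
    background_cv: float = 0.5
    doublet_fraction: float = 0.03

    def __post_init__(self) -> None:
        if any(cv < 0 for cv in self.channel_cv.values()):
            raise ValueError("channel CVs must be >= 0")
        if self.background_cv < 0 or self.background_median < 0:
            raise ValueError("background parameters must be >= 0")
        if not 0 <= self.doublet_fraction < 1:
            raise ValueError("doublet_fraction must be in [0, 1)")

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        """Identity measurement: channels equal truth, no background, no doublets."""
        return cls(
            channel_cv={k: 0.0 for k in ("fsc_a", "ssc_a", "dna_a", "dna_h", "edu", "mcm")},
            background_median=0.0,
            background_cv=0.0,
            doublet_fraction=0.0,
        )


@dataclass
class SimSample:
    """A simulated stained sample: measured events plus per-cell truth.

    ``events`` and ``truth`` have identical length and row order; doublet
    events carry the truth of their first constituent cell with
    ``is_doublet`` set.
    """

    events: EventTable
    truth: pd.DataFrame
    seed: int

    def __post_init__(self) -> None:
        if len(self.events) != len(self.truth):
            raise ValueError("events and truth must have identical cardinality")


def sample_ages(
    n: int,
    alpha: float,
    doubling_time: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw cell ages from the steady-state density 2*alpha*exp(-alpha*a).

    Inverse-CDF sampling: ``a = -ln(1 - u/2)/alpha`` for ``u ~ U(0, 1)``;
    ``u = 1`` maps exactly to ``a = T_d``.
    """
    if doubling_time <= 0:
        raise ValueError("doubling_time must be positive")
    if not math.isclose(alpha * doubling_time, math.log(2.0), rel_tol=1e-9):
        raise ValueError("alpha must equal ln(2)/doubling_time")
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    u = rng.uniform(0.0, 1.0, size=n)
    return -np.log1p(-u / 2.0) / alpha


def assign_phase_and_signals(ages: np.ndarray, model: PopulationModel) -> pd.DataFrame:
    """Map ages to phase labels and true (noise-free) per-cell signals.

    Returns a frame with columns ``age, phase, dna, mcm, edu, m0`` where
    ``dna`` is relative DNA content (1 = 2N), ``mcm`` the true loaded MCM in
    MCM-units, ``edu`` the true EdU signal and ``m0`` the loaded MCM the cell
    had (or will have) at S entry.
    """
    ages = np.asarray(ages, dtype=float)
    t_g1, t_s, _ = model.effective_durations()
    if ages.size and (ages.min() < 0 or ages.max() > model.doubling_time * (1 + 1e-12)):
        raise ValueError("ages must lie within [0, doubling_time]")

    r = model.mcm_load_rate
    m0 = min(r * t_g1, model.mcm_max)  # loaded MCM at S entry
    phase = np.full(ages.shape, "G2M", dtype=object)
    phase[ages < t_g1] = "G1"
    in_s = (ages >= t_g1) & (ages < t_g1 + t_s)
    phase[in_s] = "S"

    mcm = np.zeros_like(ages)
    dna = np.full_like(ages, 2.0)
    edu = np.zeros_like(ages)

    g1 = phase == "G1"
    mcm[g1] = np.minimum(r * ages[g1], model.mcm_max)
    dna[g1] = 1.0

    s_prog = (ages[in_s] - t_g1) / t_s
    mcm[in_s] = m0 * (1.0 - s_prog)
    dna[in_s] = 1.0 + s_prog
    edu[in_s] = model.edu_scale * min(m0 / model.mcm_max, 1.0)

    return pd.DataFrame(
        {"age": ages, "phase": phase, "dna": dna, "mcm": mcm, "edu": edu,
         "m0": np.full_like(ages, m0)}
    )


def _lognormal_factor(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Unit-mean multiplicative log-normal noise with the given CV."""
    if cv == 0:
        return np.ones(n)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(-0.5 * sigma * sigma, sigma, size=n)


def _background(rng: np.random.Generator, noise: NoiseModel, n: int) -> np.ndarray:
    if noise.background_median == 0:
        return np.zeros(n)
    sigma = math.sqrt(math.log1p(noise.background_cv**2))
    return rng.lognormal(math.log(noise.background_median), sigma, size=n)


def simulate_sample(
    model: PopulationModel,
    noise: NoiseModel,
    n: int,
    seed: int,
    sample_id: str = "sim",
    condition: str = "simulated",
    replicate: int | str = 1,
) -> SimSample:
    """Simulate one stained sample of ``n`` cells.

    Measured antibody channels are ``true * LogNormal(cv) + background``;
    DNA and scatter channels carry multiplicative noise only.  A fraction of
    events are doublets formed by merging two random cells: area channels
    sum, DAPI height takes the larger of the pair, which is what the DAPI
    area-vs-height singlet gate discriminates.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    ages = sample_ages(n, model.alpha, model.doubling_time, rng)
    truth = assign_phase_and_signals(ages, model)

    cv = noise.channel_cv
    dna_a = model.dna_g1_level * truth["dna"].to_numpy() * _lognormal_factor(rng, cv.get("dna_a", 0.0), n)
    dna_h = _DNA_HEIGHT_RATIO * dna_a * _lognormal_factor(rng, cv.get("dna_h", 0.0), n)
    size = 0.7 + 0.3 * truth["dna"].to_numpy()  # cells grow modestly through the cycle
    fsc = _FSC_SCALE * size * _lognormal_factor(rng, cv.get("fsc_a", 0.0), n)
    ssc = _SSC_SCALE * size * _lognormal_factor(rng, cv.get("ssc_a", 0.0), n)
    edu = truth["edu"].to_numpy() * _lognormal_factor(rng, cv.get("edu", 0.0), n) + _background(rng, noise, n)
    mcm = truth["mcm"].to_numpy() * _lognormal_factor(rng, cv.get("mcm", 0.0), n) + _background(rng, noise, n)

    data = pd.DataFrame(
        {"fsc_a": fsc, "ssc_a": ssc, "dna_a": dna_a, "dna_h": dna_h, "edu": edu, "mcm": mcm}
    )
    truth = truth.assign(is_doublet=False)

    n_doublets = int(round(noise.doublet_fraction * n)) if n >= 2 else 0
    if n_doublets:
        idx = rng.permutation(n)
        first, second = idx[:n_doublets], idx[n_doublets : 2 * n_doublets]
        area_cols = ["fsc_a", "ssc_a", "dna_a", "edu", "mcm"]
        data.loc[first, area_cols] = data.loc[first, area_cols].to_numpy() + data.loc[second, area_cols].to_numpy()
        data.loc[first, "dna_h"] = np.maximum(
            data.loc[first, "dna_h"].to_numpy(), data.loc[second, "dna_h"].to_numpy()
        )
        truth.loc[first, "is_doublet"] = True
        keep = np.setdiff1d(np.arange(n), second)
        data = data.iloc[keep].reset_index(drop=True)
        truth = truth.iloc[keep].reset_index(drop=True)

    events = EventTable(
        data,
        metadata={
            "sample_id": sample_id,
            "condition": condition,
            "replicate": replicate,
            "is_negative_control": False,
            "seed": seed,
        },
    )
    return SimSample(events=events, truth=truth, seed=seed)


def simulate_mixture(
    components: list[tuple[PopulationModel, float]],
    noise: NoiseModel,
    n: int,
    seed: int,
    sample_id: str = "sim_mixture",
    condition: str = "mixture",
) -> SimSample:
    """Simulate a heterogeneous sample as a weighted mixture of populations.

    Useful for incompletely penetrant perturbations (e.g. an inducible
    construct expressed in only part of the population).  Weights are
    normalised; component membership is recorded in the truth table.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if not components:
        raise ValueError("need at least one mixture component")
    weights = np.asarray([w for _, w in components], dtype=float)
    if (weights < 0).any() or weights.sum() == 0:
        raise ValueError("weights must be non-negative and not all zero")
    weights = weights / weights.sum()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, weights)
    events_parts, truth_parts = [], []
    for i, ((model, _), n_i) in enumerate(zip(components, counts)):
        if n_i == 0:
            continue
        part = simulate_sample(
            model, noise, int(n_i), seed=int(rng.integers(0, 2**31 - 1)),
            sample_id=sample_id, condition=condition,
        )
        events_parts.append(part.events.data)
        truth_parts.append(part.truth.assign(component=i))
    data = pd.concat(events_parts, ignore_index=True)
    truth = pd.concat(truth_parts, ignore_index=True)
    order = rng.permutation(len(data))
    events = EventTable(
        data.iloc[order].reset_index(drop=True),
        metadata={
            "sample_id": sample_id,
            "condition": condition,
            "replicate": 1,
            "is_negative_control": False,
            "seed": seed,
        },
    )
    return SimSample(events=events, truth=truth.iloc[order].reset_index(drop=True), seed=seed)


def simulate_negative_control(
    model: PopulationModel,
    noise: NoiseModel,
    n: int,
    seed: int,
    sample_id: str = "sim_control",
) -> EventTable:
    """Matched no-primary-antibody control: same population, but the MCM and
    EdU channels measure background only.  Used to derive positivity gates."""
    stained = simulate_sample(model, noise, n, seed, sample_id=sample_id)
    rng = np.random.default_rng(seed + 0x5EED)
    m = len(stained.events)
    data = stained.events.data.copy()
    data["mcm"] = _background(rng, noise, m)
    data["edu"] = _background(rng, noise, m)
    meta = dict(stained.events.metadata)
    meta.update({"sample_id": sample_id, "is_negative_control": True})
    return EventTable(data, metadata=meta)


def simulate_growth_counts(
    n0: float,
    doubling_time: float,
    times: np.ndarray,
    cv: float = 0.0,
    seed: int = 0,
    replicates: int = 1,
) -> pd.DataFrame:
    """Cell-count time course ``count(t) = n0 * 2**(t/T_d) * LogNormal(cv)``.

    Returns a tidy frame (time, replicate, count) suitable for
    :func:`mcmflow.growth.fit_doubling_time`.
    """
    if doubling_time <= 0:
        raise ValueError("doubling_time must be positive")
    if n0 <= 0:
        raise ValueError("n0 must be positive")
    times = np.asarray(times, dtype=float)
    if (times < 0).any():
        raise ValueError("times must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, replicates + 1):
        expected = n0 * 2.0 ** (times / doubling_time)
        counts = expected * _lognormal_factor(rng, cv, times.size)
        rows.append(pd.DataFrame({"time": times, "replicate": rep, "count": counts}))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Preset populations.  Doubling times and G1 shares follow the cell lines the
# analysis was developed on: hESC (15% of a 17 h cycle in G1), NPC (45% of
# 30 h), an RPE1-like epithelial line (~9 h G1 of 24 h) and an iPSC line
# (T_d = 15.64 h, G1 several-fold shorter than its differentiated parent).
# Loading rate defaults to exactly licensing mcm_max over scheduled G1.

def _preset(td: float, g1: float, s: float, g2m: float, **kw) -> PopulationModel:
    return PopulationModel(
        doubling_time=td, g1_hours=g1, s_hours=s, g2m_hours=g2m,
        mcm_load_rate=kw.pop("mcm_load_rate", 200.0 / g1), **kw,
    )


def model_hesc(**kw) -> PopulationModel:
    """Pluripotent hESC-like: short G1, S-dominated cycle, fast loading."""
    return _preset(17.0, 2.55, 11.05, 3.4, **kw)


def model_npc(**kw) -> PopulationModel:
    """Differentiated neural-progenitor-like: long G1, slow loading."""
    return _preset(30.0, 13.5, 11.0, 5.5, **kw)


def model_ipsc(**kw) -> PopulationModel:
    """Reprogrammed iPSC-like: T_d = 15.64 h with a short G1."""
    return _preset(15.64, 2.3, 10.0, 3.34, **kw)


def model_rpe(**kw) -> PopulationModel:
    """Epithelial RPE1-like: ~9 h G1 of a 24 h cycle."""
    return _preset(24.0, 9.0, 10.0, 5.0, **kw)


def load_scenario(path) -> tuple[PopulationModel, NoiseModel, int, int]:
    """Read a simulation scenario from YAML.

    Expected keys: ``model`` (PopulationModel fields or ``preset`` name),
    ``noise`` (NoiseModel fields, optional), ``n`` and ``seed``.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    model_spec = dict(raw.get("model") or {})
    preset = model_spec.pop("preset", None)
    if preset is not None:
        presets = {"hesc": model_hesc, "npc": model_npc, "ipsc": model_ipsc, "rpe": model_rpe}
        if preset not in presets:
            raise ValueError(f"unknown preset {preset!r}")
        model = replace(presets[preset](), **model_spec) if model_spec else presets[preset]()
    else:
        model = PopulationModel(**model_spec)
    noise = NoiseModel(**(raw.get("noise") or {}))
    return model, noise, int(raw.get("n", 20000)), int(raw.get("seed", 0))


def cyclin_e_pair(g1_short: float = 3.0) -> tuple[PopulationModel, PopulationModel]:
    """(control, Cyclin-E-overproduction) scenario pair.

    The perturbed population keeps the control's loading rate but enters S at
    a shortened scheduled G1 with the licensing checkpoint disabled, so cells
    begin S phase underlicensed (m0 < mcm_max).
    """
    control = model_rpe()
    t_total = control.doubling_time - (control.g1_hours - g1_short)
    perturbed = PopulationModel(
        doubling_time=t_total,
        g1_hours=g1_short,
        s_hours=control.s_hours,
        g2m_hours=t_total - g1_short - control.s_hours,
        mcm_load_rate=control.mcm_load_rate,
        mcm_max=control.mcm_max,
        edu_scale=control.edu_scale,
        dna_g1_level=control.dna_g1_level,
        checkpoint_active=False,
    )
    return control, perturbed
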