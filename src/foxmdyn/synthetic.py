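"""Seeded synthetic single-cell FOXM1 reporter data.

This module generates everything the downstream analysis consumes, with the
statistical structure the pipeline assumes: per-cell reporter trajectories on
a 10-min grid over 48 h, drawn from six trajectory archetypes (on-time
cytokinesis, cytokinesis delay, cell-cycle delay, G1 arrest, G2 arrest, cell
death); a 16-inhibitor + DMSO perturbation panel whose drug x dose archetype
mixtures follow the published dose-response trends (see ``calibration.yaml``);
two experimental batches with location/scale shifts; endpoint DAPI/EdU stain
populations with bimodal 2N/4N and EdU-negative/positive components; and
classic perturbation controls (translation shutoff, proteasome inhibition,
mitotic arrest).

Functional forms: peaked archetypes are sums of Gaussian bumps; G2 arrest is
a four-parameter logistic rise to a plateau; cell death rises to a single
bump then decays exponentially.  Cell-to-cell heterogeneity is multiplicative
lognormal jitter (mean 1, coefficient of variation ``cv_cell``) on kinetic
parameters; observation noise is additive Gaussian with SD
``sigma_noise * baseline``; intensities are clamped at zero.

Every generated cell carries its ground-truth archetype label so recovery can
be scored exactly.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .trajectories import Trace, TraceSet, _check_uniform_grid

__all__ = [
    "ARCHETYPES",
    "ArchetypeParams",
    "ConditionSpec",
    "BatchEffect",
    "GeneratorConfig",
    "StainPopulationSpec",
    "default_archetypes",
    "default_time_grid",
    "default_panel_config",
    "simulate_trace",
    "simulate_panel",
    "simulate_stain_population",
    "simulate_perturbation_trace",
    "apply_batch_effect",
    "invert_batch_effect",
    "load_calibration",
]

ARCHETYPES = (
    "on_time_cytokinesis",
    "cytokinesis_delay",
    "cell_cycle_delay",
    "g1_arrest",
    "g2_arrest",
    "cell_death",
)

PHASES = ("G1", "early_S", "late_S", "G2_M")


def default_time_grid() -> np.ndarray:
    """10-min sampling over 48 h: 289 frames."""
    return np.arange(289) / 6.0


@dataclass
class ArchetypeParams:
    """Parameters of one trajectory archetype.

    ``t_peak1``/``a_peak1`` are the first pulse time (h) and height above
    baseline; ``t_peak2``/``a_peak2`` the second pulse where present.  For
    ``g2_arrest`` the curve is a logistic rise: ``t_peak1`` is the rise
    midpoint, ``peak_width`` the logistic time constant and ``plateau_level``
    the asymptotic height above baseline.  For ``cell_death`` the trace decays
    exponentially at ``decay_rate`` (per hour) after the first pulse.
    """

    archetype_name: str
    t_peak1: float
    a_peak1: float = 0.0
    t_peak2: float | None = None
    a_peak2: float | None = None
    peak_width: float = 2.5
    baseline: float = 0.5
    plateau_level: float | None = None
    decay_rate: float | None = None
    t_cytokinesis: float | None = None
    cv_cell: float = 0.05
    sigma_noise: float = 0.03

    def __post_init__(self) -> None:
        if self.archetype_name not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype_name!r}")
        if self.t_peak2 is not None and not self.t_peak1 < self.t_peak2:
            raise ValueError("t_peak1 must precede t_peak2")
        for name in ("a_peak1", "a_peak2", "peak_width", "plateau_level"):
            v = getattr(self, name)
            if v is not None and name in ("peak_width",) and v <= 0:
                raise ValueError(f"{name} must be > 0")
            if v is not None and name != "peak_width" and v < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.cv_cell < 0 or self.sigma_noise < 0:
            raise ValueError("cv_cell and sigma_noise must be >= 0")


def default_archetypes() -> dict[str, ArchetypeParams]:
    """Calibration defaults for the six archetypes.

    The control first pulse sits at 4 h; the second at 24 h (one full cycle
    after the first pulse; a calibration choice, not a measured value).
    Delayed archetypes shift the first pulse to 10 h.  Cytokinesis occurs 2 h
    after the second pulse for on-time dividers and late (32 h) for delayed
    ones.
    """
    return {
        "on_time_cytokinesis": ArchetypeParams(
            "on_time_cytokinesis", t_peak1=4.0, a_peak1=1.8,
            t_peak2=24.0, a_peak2=2.0, t_cytokinesis=26.0,
        ),
        "cytokinesis_delay": ArchetypeParams(
            "cytokinesis_delay", t_peak1=4.0, a_peak1=0.7,
            t_peak2=24.0, a_peak2=2.2, t_cytokinesis=32.0,
        ),
        "cell_cycle_delay": ArchetypeParams(
            "cell_cycle_delay", t_peak1=10.0, a_peak1=1.8,
            t_peak2=30.0, a_peak2=2.0, t_cytokinesis=32.0,
        ),
        "g1_arrest": ArchetypeParams("g1_arrest", t_peak1=10.0, a_peak1=1.8),
        "g2_arrest": ArchetypeParams(
            "g2_arrest", t_peak1=14.0, peak_width=3.0, plateau_level=2.2,
        ),
        "cell_death": ArchetypeParams(
            "cell_death", t_peak1=6.0, a_peak1=2.0, decay_rate=0.03,
        ),
    }


def _bump(t: np.ndarray, a: float, t0: float, w: float) -> np.ndarray:
    return a * np.exp(-((t - t0) ** 2) / (2.0 * w * w))


def archetype_curve(params: ArchetypeParams, t: np.ndarray) -> np.ndarray:
    """Noiseless archetype curve on times ``t`` (hours)."""
    name = params.archetype_name
    if name == "g2_arrest":
        if params.plateau_level is None:
            raise ValueError("g2_arrest requires plateau_level")
        return params.baseline + params.plateau_level / (
            1.0 + np.exp(-(t - params.t_peak1) / params.peak_width)
        )
    if name == "cell_death":
        if params.decay_rate is None:
            raise ValueError("cell_death requires decay_rate")
        y = params.baseline + _bump(t, params.a_peak1, params.t_peak1, params.peak_width)
        after = t > params.t_peak1
        peak_val = params.baseline + params.a_peak1
        y = np.where(after, peak_val * np.exp(-params.decay_rate * (t - params.t_peak1)), y)
        return y
    y = params.baseline + _bump(t, params.a_peak1, params.t_peak1, params.peak_width)
    if params.t_peak2 is not None:
        y = y + _bump(t, float(params.a_peak2 or 0.0), params.t_peak2, params.peak_width)
    return y


def _jitter_factor(rng: np.random.Generator, cv: float) -> float:
    """Lognormal multiplicative factor with mean 1 and CV ``cv``."""
    if cv <= 0:
        return 1.0
    s = math.sqrt(math.log1p(cv * cv))
    return float(rng.lognormal(mean=-0.5 * s * s, sigma=s))


def _jitter_params(params: ArchetypeParams, rng: np.random.Generator) -> ArchetypeParams:
    cv = params.cv_cell
    if cv <= 0:
        return params
    t1 = params.t_peak1 * _jitter_factor(rng, cv)
    updates: dict = {"t_peak1": t1}
    if params.t_peak2 is not None:
        gap = (params.t_peak2 - params.t_peak1) * _jitter_factor(rng, cv)
        updates["t_peak2"] = t1 + gap
    for name in ("a_peak1", "a_peak2", "peak_width", "baseline", "plateau_level", "decay_rate"):
        v = getattr(params, name)
        if v is not None and v > 0:
            updates[name] = v * _jitter_factor(rng, cv)
    if params.t_cytokinesis is not None:
        if params.t_peak2 is not None:
            gap = (params.t_cytokinesis - params.t_peak2) * _jitter_factor(rng, cv)
            updates["t_cytokinesis"] = updates["t_peak2"] + gap
        else:
            updates["t_cytokinesis"] = params.t_cytokinesis * _jitter_factor(rng, cv)
    return replace(params, **updates)


def simulate_trace(
    params: ArchetypeParams,
    time_grid: np.ndarray,
    seed: int | np.random.Generator,
    cell_id: str = "cell",
    drug: str = "DMSO",
    dose: float = 0.0,
    batch: str = "B1",
) -> Trace:
    """Simulate one cell from an archetype; deterministic under a fixed seed."""
    time_grid = np.asarray(time_grid, dtype=float)
    _check_uniform_grid(time_grid)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    cell = _jitter_params(params, rng)
    y = archetype_curve(cell, time_grid)
    if params.sigma_noise > 0:
        y = y + rng.normal(0.0, params.sigma_noise * params.baseline, size=time_grid.size)
    y = np.clip(y, 0.0, None)
    cyto: list[float] = []
    if cell.t_cytokinesis is not None:
        cyto = [float(np.clip(cell.t_cytokinesis, time_grid[0], time_grid[-1]))]
    return Trace(
        cell_id=cell_id, drug=drug, dose=dose, batch=batch,
        times=time_grid, intensities=y, cytokinesis_times=cyto,
        truth_label=params.archetype_name,
    )


DOSE_LADDER_UM = (0.0, 0.3, 0.6, 1.25, 2.5, 5.0, 10.0)


@dataclass
class ConditionSpec:
    """One drug x dose x batch condition of the perturbation panel."""

    drug: str
    dose: float
    archetype_weights: Mapping[str, float]
    batch: str = "B1"
    n_cells: int = 30
    param_modifiers: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not any(math.isclose(self.dose, d, abs_tol=1e-9) for d in DOSE_LADDER_UM):
            raise ValueError(f"dose {self.dose} not in the screening ladder {DOSE_LADDER_UM}")
        total = sum(self.archetype_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"archetype weights for {self.drug} sum to {total}, not 1")
        for name in self.archetype_weights:
            if name not in ARCHETYPES:
                raise ValueError(f"unknown archetype {name!r} in weights")


@dataclass
class BatchEffect:
    """Additive offset and multiplicative scale applied to intensities."""

    offset: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("batch scale must be > 0")


def apply_batch_effect(y: np.ndarray, effect: BatchEffect) -> np.ndarray:
    return effect.scale * y + effect.offset


def invert_batch_effect(y: np.ndarray, effect: BatchEffect) -> np.ndarray:
    return (y - effect.offset) / effect.scale


@dataclass
class GeneratorConfig:
    """Full panel specification: grid, conditions, batch effects, seed."""

    conditions: Sequence[ConditionSpec]
    batch_effects: Mapping[str, BatchEffect] = field(
        default_factory=lambda: {"B1": BatchEffect(0.0, 1.0), "B2": BatchEffect(0.3, 1.15)}
    )
    time_grid: np.ndarray = field(default_factory=default_time_grid)
    archetype_defaults: Mapping[str, ArchetypeParams] = field(default_factory=default_archetypes)
    seed: int = 0

    def __post_init__(self) -> None:
        _check_uniform_grid(np.asarray(self.time_grid, dtype=float))


def _modified_params(
    base: ArchetypeParams, modifiers: Mapping[str, float]
) -> ArchetypeParams:
    """Apply condition-level calibration modifiers to archetype defaults."""
    updates: dict = {}
    scale = modifiers.get("a_peak2_scale")
    if scale is not None and base.a_peak2 is not None:
        updates["a_peak2"] = base.a_peak2 * scale
    shift2 = modifiers.get("t_peak2_shift_h")
    if shift2 is not None and base.t_peak2 is not None:
        updates["t_peak2"] = base.t_peak2 + shift2
    shiftc = modifiers.get("t_cytokinesis_shift_h")
    if shiftc is not None and base.t_cytokinesis is not None:
        updates["t_cytokinesis"] = base.t_cytokinesis + shiftc
    return replace(base, **updates) if updates else base


def simulate_panel(config: GeneratorConfig) -> TraceSet:
    """Simulate the perturbation panel; one Trace per cell, truth label kept."""
    if not config.conditions:
        raise ValueError("empty condition table")
    grid = np.asarray(config.time_grid, dtype=float)
    rng = np.random.default_rng(config.seed)
    traces: list[Trace] = []
    for ci, cond in enumerate(config.conditions):
        names = sorted(cond.archetype_weights)
        weights = np.array([cond.archetype_weights[n] for n in names])
        effect = config.batch_effects.get(cond.batch, BatchEffect())
        draws = rng.choice(len(names), size=cond.n_cells, p=weights / weights.sum())
        for j, k in enumerate(draws):
            base = config.archetype_defaults[names[k]]
            params = _modified_params(base, cond.param_modifiers)
            tr = simulate_trace(
                params, grid, rng,
                cell_id=f"c{ci:03d}_{cond.batch}_{j:04d}",
                drug=cond.drug, dose=cond.dose, batch=cond.batch,
            )
            tr.intensities = np.clip(apply_batch_effect(tr.intensities, effect), 0.0, None)
            traces.append(tr)
    return TraceSet(traces)


# ---------------------------------------------------------------------------
# Calibration table: drug x dose -> archetype weights
# ---------------------------------------------------------------------------

_calibration_cache: dict | None = None


def load_calibration() -> dict:
    """Load the shipped drug x dose calibration table."""
    global _calibration_cache
    if _calibration_cache is None:
        text = importlib.resources.files("foxmdyn").joinpath("calibration.yaml").read_text()
        _calibration_cache = yaml.safe_load(text)
    return _calibration_cache


def _drug_entry(drug: str) -> tuple[str, dict]:
    cal = load_calibration()
    for cls_name, entry in cal["classes"].items():
        if drug in entry["drugs"]:
            return cls_name, entry
    raise KeyError(f"drug {drug!r} not in calibration table")


def panel_drugs() -> list[str]:
    """The 16 inhibitors, in calibration-table order."""
    cal = load_calibration()
    return [d for entry in cal["classes"].values() for d in entry["drugs"]]


def condition_weights(drug: str, dose: float) -> dict[str, float]:
    """Archetype weights for a drug at a ladder dose (dose 0 = control).

    A ``per_drug`` block in the drug's class overrides the class table at the
    doses it lists (drugs within a class are not equipotent).
    """
    cal = load_calibration()
    if drug == cal["control"]["name"] or dose == 0:
        return dict(cal["control"]["weights"])
    _, entry = _drug_entry(drug)
    key = f"{dose:g}"
    override = entry.get("per_drug", {}).get(drug, {})
    if key in override.get("dose_weights", {}):
        return dict(override["dose_weights"][key])
    if key not in entry["dose_weights"]:
        raise KeyError(f"no calibration for {drug} at {dose} uM")
    return dict(entry["dose_weights"][key])


def condition_modifiers(drug: str) -> dict[str, float]:
    """Archetype-parameter modifiers for a drug (per-drug over class-level)."""
    cal = load_calibration()
    if drug == cal["control"]["name"]:
        return {}
    _, entry = _drug_entry(drug)
    override = entry.get("per_drug", {}).get(drug, {})
    if "modifiers" in override:
        return dict(override["modifiers"])
    return dict(entry.get("modifiers", {}))


def screening_dose(drug: str) -> float:
    _, entry = _drug_entry(drug)
    sd = entry["screening_dose_uM"]
    return float(sd[drug] if isinstance(sd, dict) else sd)


def default_panel_config(
    seed: int,
    n_cells: int = 30,
    doses: str = "screening",
    include_control: bool = True,
    batches: Sequence[str] = ("B1", "B2"),
) -> GeneratorConfig:
    """The default 16-inhibitor + DMSO panel across two batches.

    ``doses='screening'`` uses each drug's single screening dose (as in the
    panel-level dynamics comparison); ``doses='all'`` enumerates the full
    0.3-10 uM ladder per drug.
    """
    cal = load_calibration()
    conditions: list[ConditionSpec] = []
    for batch in batches:
        if include_control:
            conditions.append(
                ConditionSpec(
                    drug=cal["control"]["name"], dose=0.0,
                    archetype_weights=dict(cal["control"]["weights"]),
                    batch=batch, n_cells=n_cells,
                )
            )
        for drug in panel_drugs():
            dose_list = (
                [screening_dose(drug)]
                if doses == "screening"
                else [d for d in DOSE_LADDER_UM if d > 0]
            )
            for dose in dose_list:
                conditions.append(
                    ConditionSpec(
                        drug=drug, dose=dose,
                        archetype_weights=condition_weights(drug, dose),
                        batch=batch, n_cells=n_cells,
                        param_modifiers=condition_modifiers(drug),
                    )
                )
    return GeneratorConfig(conditions=conditions, seed=seed)


# ---------------------------------------------------------------------------
# Endpoint stain populations
# ---------------------------------------------------------------------------


@dataclass
class StainPopulationSpec:
    """Lognormal mixture model for an endpoint DAPI/EdU population.

    DAPI log-means correspond to 2N and 4N DNA content; EdU log-means to
    replication-negative and -positive cells.  Phase determines the pair:
    G1 = (2N, EdU-), early S = (2N, EdU+), late S = (4N, EdU+),
    G2/M = (4N, EdU-).
    """

    n_cells: int
    phase_fractions: Mapping[str, float] = field(
        default_factory=lambda: {p: 0.25 for p in PHASES}
    )
    dapi_log_means: tuple[float, float] = (math.log(1000.0), math.log(2000.0))
    edu_log_means: tuple[float, float] = (math.log(100.0), math.log(1000.0))
    log_sd: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        total = sum(self.phase_fractions.get(p, 0.0) for p in PHASES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("phase fractions must sum to 1")
        if self.log_sd <= 0:
            raise ValueError("log_sd must be > 0 (degenerate spec)")
        if self.dapi_log_means[1] <= self.dapi_log_means[0]:
            raise ValueError("4N DAPI log-mean must exceed 2N")
        if self.edu_log_means[1] <= self.edu_log_means[0]:
            raise ValueError("EdU-positive log-mean must exceed negative")


_PHASE_COMPONENTS = {
    "G1": (0, 0),        # (dapi component, edu component): 2N, EdU-
    "early_S": (0, 1),   # 2N, EdU+
    "late_S": (1, 1),    # 4N, EdU+
    "G2_M": (1, 0),      # 4N, EdU-
}


def simulate_stain_population(
    spec: StainPopulationSpec, condition: str = "asynchronous"
) -> pd.DataFrame:
    """Draw a per-cell stain table with ground-truth phase labels.

    Returns a DataFrame with columns cell_id, condition, dapi, edu,
    phase_truth.
    """
    rng = np.random.default_rng(spec.seed)
    fracs = np.array([spec.phase_fractions.get(p, 0.0) for p in PHASES])
    phases = rng.choice(len(PHASES), size=spec.n_cells, p=fracs / fracs.sum())
    rows = []
    for i, k in enumerate(phases):
        phase = PHASES[k]
        di, ei = _PHASE_COMPONENTS[phase]
        dapi = rng.lognormal(spec.dapi_log_means[di], spec.log_sd)
        edu = rng.lognormal(spec.edu_log_means[ei], spec.log_sd)
        rows.append((f"s{i:05d}", condition, dapi, edu, phase))
    return pd.DataFrame(rows, columns=["cell_id", "condition", "dapi", "edu", "phase_truth"])


# ---------------------------------------------------------------------------
# Classic perturbation controls
# ---------------------------------------------------------------------------

PERTURBATION_KINDS = ("cycloheximide", "mg132", "nocodazole")

_PERTURBATION_DEFAULTS: dict[str, dict[str, float]] = {
    # Translation shutoff: pure exponential decay, half-life 0.5 h.
    "cycloheximide": {"baseline": 1.0, "half_life_h": 0.5, "duration_h": 4.0,
                      "sigma_noise": 0.0},
    # Proteasome inhibition: flat at baseline for 12 h, then slow accumulation.
    "mg132": {"baseline": 1.0, "stable_until_h": 12.0, "post_rate_per_h": 0.05,
              "duration_h": 48.0, "sigma_noise": 0.0},
    # Mitotic arrest: saturating rise, ~98% of plateau reached by 20 h.
    "nocodazole": {"baseline": 0.5, "amplitude": 2.0, "tau_h": 5.0,
                   "duration_h": 48.0, "sigma_noise": 0.0},
}


def simulate_perturbation_trace(
    kind: str,
    params: Mapping[str, float] | None = None,
    seed: int = 0,
) -> Trace:
    """Simulate a bulk reporter trace under a classic perturbation."""
    if kind not in PERTURBATION_KINDS:
        raise ValueError(f"unknown perturbation kind {kind!r}")
    p = dict(_PERTURBATION_DEFAULTS[kind])
    if params:
        unknown = set(params) - set(p)
        if unknown:
            raise ValueError(f"unknown parameters for {kind}: {sorted(unknown)}")
        p.update(params)
    n = int(round(p["duration_h"] * 6)) + 1
    t = np.arange(n) / 6.0
    if kind == "cycloheximide":
        y = p["baseline"] * np.exp(-math.log(2.0) / p["half_life_h"] * t)
    elif kind == "mg132":
        y = np.full_like(t, p["baseline"])
        after = t > p["stable_until_h"]
        y[after] = p["baseline"] + p["post_rate_per_h"] * (t[after] - p["stable_until_h"])
    else:  # nocodazole
        y = p["baseline"] + p["amplitude"] * (1.0 - np.exp(-t / p["tau_h"]))
    if p["sigma_noise"] > 0:
        rng = np.random.default_rng(seed)
        y = np.clip(y + rng.normal(0.0, p["sigma_noise"] * p["baseline"], size=n), 0.0, None)
    return Trace(
        cell_id=f"{kind}_bulk", drug=kind, dose=0.0, batch="perturbation",
        times=t, intensities=y,
    )
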