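"""Configuration, fixtures, the main simulation loop, and presets.

A run is described by a :class:`SimulationConfig` (loadable from YAML,
schema-validated, unknown keys rejected). The main loop follows the
hybrid-model flow: solve the quasi-steady microenvironment fields,
derive the adaptive timestep, update the vasculature and therapy, then
step every cell. Runs are fully deterministic given the seed.

Seeding specs mirror the published experiments: ``pure_csc`` (a compact
cluster of ~20 CSCs), ``unsorted`` (200 tumor cells of which 4% are
CSCs), and ``single_csc`` (one CSC with heritable self-renewal mean mu,
used by the heterogeneity cohorts mu in {0.25, 0.5, 0.75}).
"""

from __future__ import annotations

import hashlib
import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import __version__
from .angiogenesis import VesselNetwork, advance_tips, spawn_sprouts
from .cell_automaton import (
    CSC,
    PC,
    TC,
    CellPopulation,
    LineageKinetics,
    StepSample,
    step_population,
)
from .lattice import Lattice, RegionMasks
from .metrics import GrowthRecord
from .microenvironment import (
    compute_timestep,
    compute_velocity,
    solve_drug,
    solve_mde,
    solve_nutrient,
    solve_pressure,
    solve_taf,
    step_ecm,
)
from .params import ParameterSet
from .therapy import (
    TreatmentSchedule,
    TreatmentState,
    apply_drug_kill,
    modulate_cycles,
)

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "load_config",
    "dump_config",
    "make_fixture",
    "run_simulation",
    "list_presets",
    "preset_config",
    "run_heterogeneity_experiment",
]


# ---------------------------------------------------------------------------
# Configuration schema
# ---------------------------------------------------------------------------

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class LatticeConfig(_Strict):
    shape: tuple[int, int, int] = (40, 40, 40)
    spacing: float = 0.1


class SeedingConfig(_Strict):
    """Initial tumor: one of the published seeding specifications."""

    kind: Literal["pure_csc", "unsorted", "single_csc"] = "pure_csc"
    count: int = 20                # pure_csc: number of CSCs
    total: int = 200               # unsorted: total cells
    csc_fraction: float = 0.04     # unsorted: CSC share
    mu: float = 0.5                # single_csc: initiating self-renewal mean
    sigma: float = 0.1             # heterogeneity spread

    @model_validator(mode="after")
    def _check(self):
        if self.count < 0 or self.total < 0:
            raise ValueError("cell counts must be >= 0")
        if not 0.0 <= self.csc_fraction <= 1.0:
            raise ValueError("csc_fraction must lie in [0, 1]")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must lie in [0, 1]")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        return self


class CellsConfig(_Strict):
    base_cycle_time: float = 3.0    # days; scaled per type by A_p
    hypoxia_window: float = 2.0     # days below theta_a before necrosis
    heterogeneity: Optional[bool] = None  # default: on for single_csc seeding


class AngiogenesisConfig(_Strict):
    enabled: bool = False
    threshold: float = 0.2     # TAF level for sprout initiation
    spawn_prob: float = 0.05   # per eligible boundary node per step
    kappa: float = 10.0        # chemotactic bias strength


class TherapyConfig(_Strict):
    start: float = 30.0
    dose: float = 0.5
    duration: Optional[float] = 63.0
    kill_fraction: Optional[float] = None
    cycle_modifiers: tuple[float, float, float] = (0.5, 1.0, 2.0)

    def schedule(self) -> TreatmentSchedule:
        return TreatmentSchedule(
            start=self.start,
            dose=self.dose,
            duration=self.duration,
            kill_fraction=self.kill_fraction,
            cycle_modifiers=self.cycle_modifiers,
        )


class SimulationConfig(_Strict):
    lattice: LatticeConfig = Field(default_factory=LatticeConfig)
    seeding: SeedingConfig = Field(default_factory=SeedingConfig)
    cells: CellsConfig = Field(default_factory=CellsConfig)
    angiogenesis: AngiogenesisConfig = Field(default_factory=AngiogenesisConfig)
    therapy: Optional[TherapyConfig] = None
    microenvironment: dict[str, Any] = Field(default_factory=dict)
    duration: float = 30.0
    seed: int = 0
    max_dt: float = 0.05
    snapshot_interval: Optional[float] = None
    output_dir: Optional[str] = None

    @model_validator(mode="after")
    def _check(self):
        if self.duration < 0:
            raise ValueError("duration must be >= 0")
        if self.max_dt <= 0:
            raise ValueError("max_dt must be > 0")
        # reject unknown parameter names early, before any computation
        ParameterSet.from_dict(dict(self.microenvironment))
        return self

    def parameter_set(self) -> ParameterSet:
        return ParameterSet.from_dict(dict(self.microenvironment))

    def heterogeneity_enabled(self) -> bool:
        if self.cells.heterogeneity is not None:
            return self.cells.heterogeneity
        return self.seeding.kind == "single_csc"

    def canonical_json(self) -> str:
        return json.dumps(self.model_dump(mode="json"), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def load_config(path) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return SimulationConfig.model_validate(data)


def dump_config(config: SimulationConfig, path=None) -> str:
    text = yaml.safe_dump(config.model_dump(mode="json"), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------

def _cluster_nodes(lattice: Lattice, count: int) -> list[int]:
    """The ``count`` nodes nearest the domain center (compact ball)."""
    if count > lattice.n_nodes:
        raise ValueError("cluster larger than lattice")
    nx, ny, nz = lattice.shape
    ci, cj, ck = nx // 2, ny // 2, nz // 2
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    d2 = (ii - ci) ** 2 + (jj - cj) ** 2 + (kk - ck) ** 2
    order = np.argsort(d2.ravel(), kind="stable")
    return [int(v) for v in order[:count]]


def make_fixture(
    seeding: SeedingConfig,
    lattice: Lattice,
    rng: random.Random,
    default_mu: float = 0.6,
) -> CellPopulation:
    """Place the initial cells as a compact centered cluster.

    ``unsorted`` seeds exactly ``round(total * csc_fraction)`` CSCs at
    random positions inside the cluster; the remaining cells alternate
    PC/TC. ``single_csc`` stores the cohort mean mu on the one CSC.
    """
    pop = CellPopulation(lattice)
    if seeding.kind == "pure_csc":
        for node in _cluster_nodes(lattice, seeding.count):
            pop.add_cell(CSC, node, mu=default_mu)
    elif seeding.kind == "unsorted":
        nodes = _cluster_nodes(lattice, seeding.total)
        n_csc = int(round(seeding.total * seeding.csc_fraction))
        csc_slots = set(rng.sample(range(len(nodes)), n_csc)) if n_csc else set()
        toggle = 0
        for slot, node in enumerate(nodes):
            if slot in csc_slots:
                pop.add_cell(CSC, node, mu=default_mu)
            else:
                pop.add_cell(PC if toggle == 0 else TC, node)
                toggle ^= 1
    elif seeding.kind == "single_csc":
        pop.add_cell(CSC, lattice.center_node, mu=seeding.mu)
    else:  # pragma: no cover - schema forbids
        raise ValueError(f"unknown seeding kind {seeding.kind!r}")
    return pop


# ---------------------------------------------------------------------------
# Main loop
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    config: SimulationConfig
    record: GrowthRecord
    population: CellPopulation
    masks: RegionMasks
    fields: dict[str, np.ndarray]
    treatment: TreatmentState | None
    network: VesselNetwork | None
    manifest: dict


def run_simulation(config: SimulationConfig) -> SimulationResult:
    """Execute one full hybrid simulation described by ``config``.

    Per step: rebuild masks -> pressure -> velocity -> nutrient -> TAF
    -> MDE -> adaptive dt -> ECM -> angiogenesis -> therapy -> cell
    automaton -> record. Fields are warm-started from the previous step
    (lagged coupling), initialized to n = 1, p = 0, f = 1.
    """
    lattice = Lattice(tuple(config.lattice.shape), config.lattice.spacing)
    params = config.parameter_set()
    kinetics = LineageKinetics.from_params(
        params, base_cycle_time=config.cells.base_cycle_time
    )
    heterogeneity = config.heterogeneity_enabled()
    sigma = config.seeding.sigma

    master = np.random.default_rng(config.seed)
    fixture_rng = random.Random(int(master.integers(2**31)))
    ca_rng = random.Random(int(master.integers(2**31)))
    ang_rng = random.Random(int(master.integers(2**31)))

    pop = make_fixture(config.seeding, lattice, fixture_rng,
                       default_mu=params.K_CC)
    network = (
        VesselNetwork(lattice) if config.angiogenesis.enabled else None
    )
    treatment = (
        TreatmentState(config.therapy.schedule())
        if config.therapy is not None
        else None
    )

    shape = lattice.shape
    n = np.ones(shape)
    p = np.zeros(shape)
    f = np.ones(shape)
    c = np.zeros(shape)
    m = np.zeros(shape)
    drug = np.zeros(shape)
    tip_speeds: list[float] = []

    times = [0.0]
    samples = [_population_sample(pop, params)]
    t = 0.0
    writer = _SnapshotWriter(config, lattice)
    writer.maybe_write(t, pop, {})

    masks = pop.region_masks(
        network.indicator() if network is not None else None
    )
    while t < config.duration - 1e-12:
        vessel = network.indicator() if network is not None else None
        masks = pop.region_masks(vessel)
        codes = pop.uptake_codes(vessel, host_uptake=params.host_uptake)

        p = solve_pressure(masks, n, params, lattice, x0=p)
        u = compute_velocity(p, lattice.spacing)
        n = solve_nutrient(masks, f, p, codes, params, lattice, x0=n)
        c = solve_taf(masks, params, lattice, x0=c)
        m = solve_mde(masks, params, lattice, x0=m)

        dt = compute_timestep(u, tip_speeds, lattice.spacing,
                              max_dt=config.max_dt)
        dt = min(dt, config.duration - t)

        f = step_ecm(f, m, masks, dt, params)

        if network is not None:
            spawn_sprouts(
                c, network, ang_rng,
                threshold=config.angiogenesis.threshold,
                spawn_prob=config.angiogenesis.spawn_prob,
            )
            tip_speeds = advance_tips(
                network, c, f, ang_rng, dt, kappa=config.angiogenesis.kappa
            )
        else:
            tip_speeds = []

        active_kinetics = kinetics
        if treatment is not None:
            treatment.update(t, pop)
            if treatment.active and treatment.schedule.dose > 0:
                drug = solve_drug(
                    masks, p, codes, treatment.schedule.dose, params,
                    lattice, x0=drug,
                )
                treatment.kills += apply_drug_kill(pop, drug, params)
                treatment.update(t, pop)  # kill-fraction stop fires post-kill
            if treatment.active and treatment.schedule.dose > 0:
                # a zero-dose course has no drug effect to react to
                active_kinetics = modulate_cycles(
                    kinetics, treatment.schedule, True
                )

        sample = step_population(
            pop, n, f, active_kinetics, params, ca_rng, dt,
            heterogeneity=heterogeneity, sigma=sigma,
            hypoxia_window=config.cells.hypoxia_window,
        )
        t += dt
        times.append(t)
        samples.append(sample)
        writer.maybe_write(t, pop, {"n": n, "c": c, "m": m, "f": f, "p": p})

    masks = pop.region_masks(
        network.indicator() if network is not None else None
    )
    record = GrowthRecord(
        times=np.array(times),
        volumes=np.array([s.volume for s in samples]),
        surface_counts=np.array([s.surface_count for s in samples]),
        csc_fractions=np.array([s.csc_fraction for s in samples]),
        cell_counts=np.array([s.n_live for s in samples], dtype=float),
    )
    fields = {"n": n, "c": c, "m": m, "f": f, "p": p, "drug": drug}
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "steps": len(times) - 1,
    }
    writer.finalize(record, pop, fields, manifest)
    return SimulationResult(
        config=config,
        record=record,
        population=pop,
        masks=masks,
        fields=fields,
        treatment=treatment,
        network=network,
        manifest=manifest,
    )


def _population_sample(pop: CellPopulation, params: ParameterSet) -> StepSample:
    n_live = pop.n_live()
    n_csc = pop.n_csc()
    return StepSample(
        n_live=n_live,
        n_csc=n_csc,
        surface_count=pop.surface_count(),
        volume=n_live * params.C_s,
        csc_fraction=(n_csc / n_live) if n_live else 0.0,
        births=0,
        deaths=0,
    )


class _SnapshotWriter:
    """Writes cell tables, field arrays, growth curve and a manifest."""

    def __init__(self, config: SimulationConfig, lattice: Lattice):
        self.interval = config.snapshot_interval
        self.lattice = lattice
        self.outdir = (
            Path(config.output_dir) if config.output_dir is not None else None
        )
        if self.outdir is not None:
            self.outdir.mkdir(parents=True, exist_ok=True)
        self._last = -np.inf

    def maybe_write(self, t: float, pop: CellPopulation, fields: dict) -> None:
        if self.outdir is None or self.interval is None:
            return
        if t - self._last < self.interval - 1e-12:
            return
        self._last = t
        pop.to_dataframe().to_csv(
            self.outdir / f"cells_t{t:08.3f}.csv", index=False
        )

    def write_field(self, name: str, values: np.ndarray) -> None:
        nx, ny, nz = self.lattice.shape
        header = (
            f"field {name}; shape {nx} {ny} {nz}; "
            "flat node order with x fastest"
        )
        np.savetxt(
            self.outdir / f"field_{name}.txt",
            np.asarray(values).ravel(order="F"),
            header=header,
        )

    def finalize(self, record, pop, fields, manifest) -> None:
        if self.outdir is None:
            return
        record.to_csv(self.outdir / "growth.csv")
        pop.to_dataframe().to_csv(self.outdir / "cells_final.csv", index=False)
        for name, values in fields.items():
            self.write_field(name, values)
        with open(self.outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Experiment presets
# ---------------------------------------------------------------------------

_PRESETS = {
    "pure_csc": "~20 pure CSCs, untreated growth",
    "unsorted": "200 unsorted tumor cells, 4% CSCs, untreated growth",
    "treatment": "pure-CSC tumor, then continuous chemotherapy",
    "heterogeneity": "single CSC, self-renewal mean mu (0.25/0.5/0.75 cohorts)",
}


def list_presets() -> dict[str, str]:
    return dict(_PRESETS)


def preset_config(
    name: str,
    *,
    lattice_shape: tuple[int, int, int] = (40, 40, 40),
    seed: int = 0,
    duration: float = 30.0,
    max_dt: float = 0.05,
    mu: float = 0.5,
    sigma: float = 0.1,
    **overrides,
) -> SimulationConfig:
    """Build the configuration for a named experiment preset."""
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    base: dict[str, Any] = {
        "lattice": {"shape": list(lattice_shape)},
        "duration": duration,
        "seed": seed,
        "max_dt": max_dt,
    }
    if name == "pure_csc":
        base["seeding"] = {"kind": "pure_csc", "count": 20}
    elif name == "unsorted":
        base["seeding"] = {"kind": "unsorted", "total": 200,
                           "csc_fraction": 0.04}
    elif name == "treatment":
        base["seeding"] = {"kind": "pure_csc", "count": 20}
        grow = duration
        base["duration"] = grow + 63.0 + 20.0  # grow + 9 weeks + regrowth
        base["therapy"] = {"start": grow, "duration": 63.0, "dose": 0.5}
    elif name == "heterogeneity":
        base["seeding"] = {"kind": "single_csc", "mu": mu, "sigma": sigma}
    base.update(overrides)
    return SimulationConfig.model_validate(base)


def run_heterogeneity_experiment(
    mus=(0.25, 0.5, 0.75),
    *,
    lattice_shape: tuple[int, int, int] = (40, 40, 40),
    n_seeds: int = 5,
    seed: int = 0,
    growth_days: float = 30.0,
    sigma: float = 0.1,
    max_dt: float = 0.05,
    treat: bool = True,
    dose: float = 0.5,
    kill_fraction: float = 0.85,
    post_treatment_days: float = 10.0,
) -> pd.DataFrame:
    """Single-CSC cohorts with different initiating self-renewal means.

    Each cohort grows from one CSC for ``growth_days``; with ``treat``
    the chemo course then runs until ``kill_fraction`` of the
    pre-treatment cells are killed. Returns one row per (mu, replicate)
    with the pre-treatment volume and CSC fraction and, when treated,
    the post-treatment CSC fraction.
    """
    rows = []
    for mu in mus:
        for rep in range(n_seeds):
            run_seed = seed + 7919 * rep + int(round(1000 * mu))
            cfg_kwargs: dict[str, Any] = {}
            duration = growth_days
            if treat:
                duration = growth_days + post_treatment_days
                cfg_kwargs["therapy"] = {
                    "start": growth_days,
                    "dose": dose,
                    "kill_fraction": kill_fraction,
                    "duration": post_treatment_days,
                }
            config = preset_config(
                "heterogeneity",
                lattice_shape=lattice_shape,
                seed=run_seed,
                duration=duration,
                max_dt=max_dt,
                mu=mu,
                sigma=sigma,
                **cfg_kwargs,
            )
            result = run_simulation(config)
            record = result.record
            pre_i = int(
                np.searchsorted(record.times, growth_days, side="right")
            ) - 1
            row = {
                "mu": mu,
                "replicate": rep,
                "seed": run_seed,
                "pre_volume": float(record.volumes[pre_i]),
                "pre_cell_count": float(record.cell_counts[pre_i]),
                "pre_csc_fraction": float(record.csc_fractions[pre_i]),
            }
            if treat and result.treatment is not None:
                state = result.treatment
                if state.stopped_at is None:
                    # course still running at the end of the simulated
                    # span: report the final composition
                    row["post_csc_fraction"] = float(
                        record.csc_fractions[-1]
                    )
                    row["treatment_stopped_at"] = float(record.times[-1])
                else:
                    row["post_csc_fraction"] = state.post_csc_fraction
                    row["treatment_stopped_at"] = state.stopped_at
            rows.append(row)
    return pd.DataFrame(rows)
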