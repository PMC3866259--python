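"""In-silico chemotherapy: scheduling, threshold kill rule, cycle shifts.

The drug diffuses like the nutrient (same equation template) from the
vasculature; any tumor cell whose local drug concentration exceeds its
type-specific survival threshold ``theta_d`` dies outright. CSCs carry
the highest threshold (most resistant), TCs the lowest, so treatment
enriches the CSC fraction. While treatment is active, surviving TCs
cycle slower and CSCs faster (volume-loss activation), mimicking the
observed kinetic response; the modifiers restore exactly on stop.

A schedule runs either for a fixed duration or until a stated fraction
of the pre-treatment tumor has been killed (e.g. stop at 85% killed),
whichever the configuration specifies (both may be given; the first
trigger wins).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .cell_automaton import (
    DEAD,
    QUIESCENT,
    TC,
    CellPopulation,
    LineageKinetics,
)
from .params import ParameterSet

__all__ = [
    "TreatmentSchedule",
    "TreatmentState",
    "apply_drug_kill",
    "modulate_cycles",
    "run_treatment_experiment",
]


@dataclass(frozen=True)
class TreatmentSchedule:
    """When to treat, how hard, and when to stop.

    ``duration`` (days) and ``kill_fraction`` are alternative stop
    rules; at least one must be set. ``cycle_modifiers`` multiply the
    cycle time per type while the drug is on (CSC accelerates with a
    factor < 1, TC slows with a factor > 1).
    """

    start: float
    dose: float = 0.5
    duration: float | None = 63.0  # 9 weeks
    kill_fraction: float | None = None
    cycle_modifiers: tuple[float, float, float] = (0.5, 1.0, 2.0)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError("treatment start must be >= 0")
        if self.dose < 0:
            raise ValueError("dose must be >= 0")
        if self.duration is None and self.kill_fraction is None:
            raise ValueError("a stop rule (duration or kill fraction) is required")
        if self.duration is not None and self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.kill_fraction is not None and not 0 < self.kill_fraction <= 1:
            raise ValueError("kill fraction must lie in (0, 1]")
        if any(m <= 0 for m in self.cycle_modifiers):
            raise ValueError("cycle modifiers must be > 0")


@dataclass
class TreatmentState:
    """Mutable bookkeeping for one treatment course."""

    schedule: TreatmentSchedule
    active: bool = False
    finished: bool = False
    started_at: float | None = None
    stopped_at: float | None = None
    pre_count: int = 0
    pre_csc_fraction: float = 0.0
    post_csc_fraction: float = 0.0
    kills: int = 0

    def update(self, t: float, pop: CellPopulation) -> None:
        """Activate/deactivate the course according to the schedule."""
        sched = self.schedule
        if not self.active and not self.finished and t >= sched.start:
            self.active = True
            self.started_at = t
            self.pre_count = pop.n_live()
            self.pre_csc_fraction = pop.csc_fraction()
            self.kills = 0
        if self.active:
            stop = False
            if (
                sched.duration is not None
                and t >= self.started_at + sched.duration
            ):
                stop = True
            if (
                sched.kill_fraction is not None
                and self.pre_count > 0
                and self.kills >= sched.kill_fraction * self.pre_count
            ):
                stop = True
            if stop:
                self.active = False
                self.finished = True
                self.stopped_at = t
                self.post_csc_fraction = pop.csc_fraction()


def apply_drug_kill(
    pop: CellPopulation, drug: np.ndarray, params: ParameterSet
) -> int:
    """Kill every live tumor cell whose local drug exceeds theta_d(type).

    Killed cells are removed from the viable region and their nodes
    freed. Returns the number of kills.
    """
    d_flat = np.asarray(drug, dtype=float).ravel().tolist()
    theta = params.theta_d
    kills = 0
    for i, s in enumerate(pop.state):
        if s > QUIESCENT:
            continue
        ct = pop.ctype[i]
        if ct > TC:
            continue
        if d_flat[pop.node[i]] > theta[ct]:
            pop.state[i] = DEAD
            pop.occupancy[pop.node[i]] = -1
            kills += 1
    return kills


def modulate_cycles(
    kinetics: LineageKinetics,
    schedule: TreatmentSchedule,
    active: bool,
) -> LineageKinetics:
    """Scale cycle times by the schedule's modifiers while treatment is on.

    Always derives from the passed (untreated) kinetics, so an
    activate-then-deactivate round trip restores it exactly.
    """
    if not active:
        return kinetics
    mods = schedule.cycle_modifiers
    cycle = kinetics.cycle_times
    new_cycle = (
        cycle[0] * mods[0],
        cycle[1] * mods[1],
        cycle[2] * mods[2],
    ) + tuple(cycle[3:])
    return dataclasses.replace(kinetics, cycle_times=new_cycle)


def run_treatment_experiment(config) -> dict:
    """Grow a tumor, treat it per the config schedule, compare CSC fractions.

    Thin orchestration over :func:`stemca.experiments_io.run_simulation`;
    the config must carry a therapy section. Returns the growth record
    plus the before/during/after CSC-fraction and volume comparison.
    """
    from .experiments_io import run_simulation  # deferred: avoid cycle

    if config.therapy is None:
        raise ValueError("config has no therapy section")
    if config.therapy.start <= 0 and config.duration > 0:
        raise ValueError("treatment cannot start before a tumor exists")
    result = run_simulation(config)
    state = result.treatment
    record = result.record
    if state is None or state.started_at is None:
        raise RuntimeError("treatment never started within the simulated span")
    times = np.asarray(record.times)
    pre_i = int(np.searchsorted(times, state.started_at, side="right")) - 1
    if state.stopped_at is not None:
        post_i = int(np.searchsorted(times, state.stopped_at, side="right")) - 1
    else:
        post_i = len(times) - 1
    return {
        "record": record,
        "treatment": state,
        "pre_volume": float(record.volumes[pre_i]),
        "min_volume_during": float(
            np.min(record.volumes[pre_i:post_i + 1])
        ),
        "final_volume": float(record.volumes[-1]),
        "pre_csc_fraction": state.pre_csc_fraction,
        "post_csc_fraction": state.post_csc_fraction,
    }
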