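"""3D cellular automaton of the CSC -> PC -> TC tumor lineage.

Each live cell occupies one lattice node (at most one live cell per
node) and interacts with its six orthogonal neighbors. Per step a cell
may move to a free neighbor with probability weighted by the local
nutrient-to-ECM ratio ``q = n/f`` (high nutrient attracts, dense matrix
holds), then ages, divides if mature, and is checked against hypoxia.

The lineage hierarchy is strictly one-way: CSCs renew symmetrically
(CSC+CSC), differentiate asymmetrically (CSC+PC), convert (PC+PC) or
produce terminal cells (CSC+TC); PCs yield PC+PC or PC+TC; TCs either
duplicate or undergo apoptosis. No operation ever converts a PC or TC
back into a CSC. Division counts are bounded per type; cells without
free space defer division (quiescent-by-crowding) and resume when space
frees. Sustained hypoxia (local nutrient below the type's survival
threshold for a tolerance window) turns a cell necrotic; its node stays
occupied as debris and joins the necrotic region.

Self-renewal heterogeneity: every CSC carries a heritable mean
``mu_p``; each division draws its symmetric-renewal probability from a
Gaussian ``G(mu_p, sigma)`` truncated to [0, 1], and a CSC daughter
samples a fresh ``mu_p`` from the same distribution.

The per-cell state is kept in parallel Python lists (plus a flat
occupancy list) so that the sequential, randomized-order update loop
stays cheap at tens of thousands of cells per step.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .lattice import Lattice, RegionMasks
from .params import (
    CSC,
    PC,
    TC,
    ENDOTHELIAL,
    CELL_TYPE_NAMES,
    QUIESCENT_UPTAKE_INDEX,
    ENDOTHELIAL_UPTAKE_INDEX,
    HOST_UPTAKE_INDEX,
    ParameterSet,
)

__all__ = [
    "VIABLE",
    "QUIESCENT",
    "NECROTIC",
    "DEAD",
    "LineageKinetics",
    "CellPopulation",
    "StepSample",
    "free_neighbors",
    "motion_probabilities",
    "select_option",
    "draw_division_outcome",
    "sample_self_renewal",
    "update_lifecycle",
    "step_population",
]

VIABLE, QUIESCENT, NECROTIC, DEAD = 0, 1, 2, 3
STATE_NAMES = ("VIABLE", "QUIESCENT", "NECROTIC", "DEAD")

# CSC division outcomes, in the order of the probability vector
# [K_CC, K_CCP, K_CP, K_CT].
CSC_SYMMETRIC, CSC_ASYM_PC, CSC_TO_PC_PC, CSC_ASYM_TC = 0, 1, 2, 3
# PC outcomes [K_PP, K_PT]; TC outcomes [K_TT, d_T].
PC_SYMMETRIC, PC_ASYM_TC = 0, 1
TC_SYMMETRIC, TC_APOPTOSIS = 0, 1

_ECM_FLOOR = 1e-6


@dataclass(frozen=True)
class LineageKinetics:
    """Division probabilities, cycle times and generation limits per type."""

    csc_split: tuple[float, float, float, float]
    pc_split: tuple[float, float]
    tc_split: tuple[float, float]
    cycle_times: tuple[float, float, float, float]  # days, per type
    max_generations: tuple[int, int, int]

    def __post_init__(self) -> None:
        for vec in (self.csc_split, self.pc_split, self.tc_split):
            if any(p < 0 for p in vec):
                raise ValueError("division probabilities must be >= 0")
            if abs(sum(vec) - 1.0) > 1e-9:
                raise ValueError(f"probability vector {vec} must sum to 1")
        if any(t <= 0 for t in self.cycle_times):
            raise ValueError("cycle times must be > 0")

    @classmethod
    def from_params(
        cls, params: ParameterSet, base_cycle_time: float = 3.0
    ) -> "LineageKinetics":
        return cls(
            csc_split=params.csc_split,
            pc_split=params.pc_split,
            tc_split=params.tc_split,
            cycle_times=tuple(base_cycle_time * a for a in params.A_p),
            max_generations=tuple(params.G_m),
        )


@dataclass
class StepSample:
    """Population summary recorded after each automaton step."""

    n_live: int
    n_csc: int
    surface_count: int
    volume: float
    csc_fraction: float
    births: int
    deaths: int


class CellPopulation:
    """Struct-of-lists container for automaton agents plus node occupancy."""

    def __init__(self, lattice: Lattice):
        self.lattice = lattice
        self.neighbors = lattice.neighbor_table()
        self.occupancy: list[int] = [-1] * lattice.n_nodes
        self.ids: list[int] = []
        self.ctype: list[int] = []
        self.node: list[int] = []
        self.age: list[float] = []
        self.gen: list[int] = []
        self.state: list[int] = []
        self.mu: list[float] = []
        self.hypoxia: list[float] = []
        self._next_id = 0

    # -- construction ----------------------------------------------------
    def add_cell(
        self,
        ctype: int,
        node: int,
        age: float = 0.0,
        gen: int = 0,
        mu: float = 0.0,
        state: int = VIABLE,
    ) -> int:
        if not 0 <= node < self.lattice.n_nodes:
            raise ValueError(f"node {node} outside lattice")
        if self.occupancy[node] != -1:
            raise ValueError(f"node {node} already occupied")
        if not 0.0 <= mu <= 1.0:
            raise ValueError("self-renewal mean must lie in [0, 1]")
        idx = len(self.ids)
        self.ids.append(self._next_id)
        self._next_id += 1
        self.ctype.append(ctype)
        self.node.append(node)
        self.age.append(age)
        self.gen.append(gen)
        self.state.append(state)
        self.mu.append(mu)
        self.hypoxia.append(0.0)
        if state != DEAD:
            self.occupancy[node] = idx
        return idx

    # -- queries ---------------------------------------------------------
    def live_indices(self) -> list[int]:
        return [i for i, s in enumerate(self.state) if s <= QUIESCENT]

    def n_live(self) -> int:
        return sum(1 for s in self.state if s <= QUIESCENT)

    def n_csc(self) -> int:
        return sum(
            1
            for s, t in zip(self.state, self.ctype)
            if s <= QUIESCENT and t == CSC
        )

    def csc_fraction(self) -> float:
        live = self.n_live()
        return self.n_csc() / live if live else 0.0

    def surface_count(self) -> int:
        """Live cells with at least one empty in-domain orthogonal neighbor."""
        occ = self.occupancy
        nbt = self.neighbors
        count = 0
        for i in self.live_indices():
            for nb in nbt[self.node[i]]:
                if occ[nb] == -1:
                    count += 1
                    break
        return count

    def necrotic_nodes(self) -> list[int]:
        return [
            self.node[i]
            for i, s in enumerate(self.state)
            if s == NECROTIC
        ]

    def check_occupancy(self) -> None:
        """Abort with a diagnostic if two cells claim one node."""
        seen: dict[int, int] = {}
        for i, s in enumerate(self.state):
            if s == DEAD:
                continue
            node = self.node[i]
            if node in seen:
                raise RuntimeError(
                    f"occupancy conflict: cells {self.ids[seen[node]]} and "
                    f"{self.ids[i]} both at node {node}"
                )
            seen[node] = i

    def region_masks(self, neovessel: np.ndarray | None = None) -> RegionMasks:
        """Rebuild viable/necrotic/host masks from the current population."""
        shape = self.lattice.shape
        viable = np.zeros(self.lattice.n_nodes, dtype=bool)
        necrotic = np.zeros(self.lattice.n_nodes, dtype=bool)
        for i, s in enumerate(self.state):
            if s <= QUIESCENT:
                viable[self.node[i]] = True
            elif s == NECROTIC:
                necrotic[self.node[i]] = True
        viable = viable.reshape(shape)
        necrotic = necrotic.reshape(shape)
        host = ~(viable | necrotic)
        if neovessel is None:
            neovessel = np.zeros(shape, dtype=bool)
        return RegionMasks(
            viable=viable, necrotic=necrotic, host=host, neovessel=neovessel
        )

    def uptake_codes(
        self,
        neovessel: np.ndarray | None = None,
        host_uptake: bool = True,
    ) -> np.ndarray:
        """Integer field indexing lambda_un per node.

        Live tumor cells use their type entry (quiescent cells the
        dedicated quiescent entry), neo-vessel nodes the endothelial
        entry, unoccupied non-necrotic nodes the host entry when host
        uptake is enabled, and necrotic debris consumes nothing.
        """
        codes = np.full(
            self.lattice.n_nodes,
            HOST_UPTAKE_INDEX if host_uptake else -1,
            dtype=np.int8,
        )
        if neovessel is not None:
            codes[np.asarray(neovessel).ravel()] = ENDOTHELIAL_UPTAKE_INDEX
        for i, s in enumerate(self.state):
            if s == VIABLE:
                codes[self.node[i]] = self.ctype[i]
            elif s == QUIESCENT:
                codes[self.node[i]] = QUIESCENT_UPTAKE_INDEX
            elif s == NECROTIC:
                codes[self.node[i]] = -1
        return codes.reshape(self.lattice.shape)

    def to_dataframe(self) -> pd.DataFrame:
        """Cell snapshot table (one row per cell, dead cells included)."""
        coords = [self.lattice.unravel_index(n) for n in self.node]
        return pd.DataFrame(
            {
                "id": self.ids,
                "type": [CELL_TYPE_NAMES[t] for t in self.ctype],
                "x": [c[0] for c in coords],
                "y": [c[1] for c in coords],
                "z": [c[2] for c in coords],
                "age": self.age,
                "generation": self.gen,
                "state": [STATE_NAMES[s] for s in self.state],
                "self_renewal_mean": self.mu,
            }
        )


# ---------------------------------------------------------------------------
# Elementary automaton operations
# ---------------------------------------------------------------------------

def free_neighbors(pop: CellPopulation, idx: int) -> list[int]:
    """In-domain, unoccupied orthogonal neighbor nodes of cell ``idx``."""
    occ = pop.occupancy
    return [nb for nb in pop.neighbors[pop.node[idx]] if occ[nb] == -1]


def motion_probabilities(node, free, n_flat, f_flat):
    """Normalized motion weights q_i = n_i / f_i over [stay] + free nodes.

    The stay option competes with moving: all m+1 weights are normalized
    together. ECM is floored before division. Returns a list of length
    ``1 + len(free)``; with no free neighbor the cell stays surely.
    """
    if not free:
        return [1.0]
    q = [n_flat[node] / max(f_flat[node], _ECM_FLOOR)]
    for nb in free:
        q.append(n_flat[nb] / max(f_flat[nb], _ECM_FLOOR))
    total = sum(q)
    if total <= 0.0:
        p = 1.0 / len(q)
        return [p] * len(q)
    return [v / total for v in q]


def select_option(probs, rng) -> int:
    """Inverse-CDF draw over cumulative intervals R_i."""
    r = rng.random()
    cum = 0.0
    last = len(probs) - 1
    for i, p in enumerate(probs):
        cum += p
        if r <= cum:
            return i
    return last


def sample_self_renewal(parent_mean: float, sigma: float, rng) -> float:
    """Draw a self-renewal probability from G(mu_p, sigma) truncated to [0,1]."""
    if not 0.0 <= parent_mean <= 1.0:
        raise ValueError("parent mean must lie in [0, 1]")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0.0:
        return parent_mean
    while True:
        v = rng.gauss(parent_mean, sigma)
        if 0.0 <= v <= 1.0:
            return v


def draw_division_outcome(
    ctype: int,
    kinetics: LineageKinetics,
    rng,
    renewal_p: float | None = None,
) -> int:
    """Draw a division outcome index from the type's probability vector.

    For a CSC with an explicit heritable ``renewal_p`` (heterogeneity
    mode), ``renewal_p`` is the probability of symmetric self-renewal
    and the remaining mass ``1 - renewal_p`` is split over the
    CSC-preserving asymmetric outcomes (CSC+PC, CSC+TC) proportionally
    to [K_CCP, K_CT]. The CSC-eliminating PC+PC conversion is excluded
    here: self-renewal ability modulates how often the stem cell
    renews, not whether the lineage survives — a low-mean cohort keeps
    a (small) stem compartment instead of losing it almost surely.
    The fixed four-outcome vector (including PC+PC) governs whenever
    heterogeneity is off.
    """
    if ctype == CSC:
        probs = kinetics.csc_split
        if renewal_p is not None:
            rest = probs[1] + probs[3]
            if rest <= 0.0:
                probs = (renewal_p, (1 - renewal_p), 0.0, 0.0)
            else:
                scale = (1.0 - renewal_p) / rest
                probs = (
                    renewal_p,
                    probs[1] * scale,
                    0.0,
                    probs[3] * scale,
                )
    elif ctype == PC:
        probs = kinetics.pc_split
    elif ctype == TC:
        probs = kinetics.tc_split
    else:
        raise ValueError(f"type {ctype} does not divide through the lineage")
    return select_option(probs, rng)


def update_lifecycle(
    pop: CellPopulation,
    idx: int,
    n_local: float,
    params: ParameterSet,
    dt: float,
    hypoxia_window: float = 2.0,
) -> None:
    """Age the cell and apply the hypoxia-driven necrosis rule.

    A cell whose local nutrient stays below its type's survival
    threshold ``theta_a`` continuously for ``hypoxia_window`` days turns
    necrotic; any recovery above threshold resets the clock.
    """
    pop.age[idx] += dt
    if pop.state[idx] > QUIESCENT:
        return
    ctype = pop.ctype[idx]
    threshold = params.theta_a[ctype] if ctype < ENDOTHELIAL else 0.0
    if n_local < threshold:
        pop.hypoxia[idx] += dt
        if pop.hypoxia[idx] >= hypoxia_window:
            pop.state[idx] = NECROTIC
    else:
        pop.hypoxia[idx] = 0.0


# ---------------------------------------------------------------------------
# Whole-population step
# ---------------------------------------------------------------------------

def step_population(
    pop: CellPopulation,
    n: np.ndarray,
    f: np.ndarray,
    kinetics: LineageKinetics,
    params: ParameterSet,
    rng,
    dt: float,
    *,
    heterogeneity: bool = False,
    sigma: float = 0.1,
    hypoxia_window: float = 2.0,
    enable_motion: bool = True,
    enable_division: bool = True,
    enable_death: bool = True,
) -> StepSample:
    """Advance every live cell by one step in randomized order.

    Per cell: motion -> aging -> maturity/division -> hypoxia check,
    following the per-step flow of the automaton. The permutation is
    drawn fresh from ``rng`` each step. Returns a population summary;
    region masks should be rebuilt afterwards via
    :meth:`CellPopulation.region_masks`.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    n_flat = np.asarray(n, dtype=float).ravel().tolist()
    f_flat = np.asarray(f, dtype=float).ravel().tolist()
    occ = pop.occupancy
    nbt = pop.neighbors
    ctype_l = pop.ctype
    node_l = pop.node
    age_l = pop.age
    gen_l = pop.gen
    state_l = pop.state
    mu_l = pop.mu
    hyp_l = pop.hypoxia
    cycle = kinetics.cycle_times
    gmax = kinetics.max_generations
    theta_a = params.theta_a
    births = deaths = 0

    order = pop.live_indices()
    rng.shuffle(order)
    for i in order:
        if state_l[i] >= NECROTIC:
            continue  # necrosed earlier this same step
        node = node_l[i]
        ct = ctype_l[i]

        # 1) motion among stay + free neighbors, weighted by n/f
        if enable_motion:
            free = [nb for nb in nbt[node] if occ[nb] == -1]
            if free:
                probs = motion_probabilities(node, free, n_flat, f_flat)
                choice = select_option(probs, rng)
                if choice > 0:
                    new = free[choice - 1]
                    occ[node] = -1
                    occ[new] = i
                    node_l[i] = node = new

        # 2) aging
        age_l[i] += dt

        # 3) division when mature, generation-limited, space permitting
        if (
            enable_division
            and ct <= TC
            and gen_l[i] < gmax[ct]
            and age_l[i] >= cycle[ct]
        ):
            free = [nb for nb in nbt[node] if occ[nb] == -1]
            if not free:
                if state_l[i] == VIABLE:
                    state_l[i] = QUIESCENT  # crowded: division deferred
            else:
                if state_l[i] == QUIESCENT:
                    state_l[i] = VIABLE  # space freed: resume cycling
                renewal_p = None
                if ct == CSC and heterogeneity:
                    renewal_p = sample_self_renewal(mu_l[i], sigma, rng)
                outcome = draw_division_outcome(ct, kinetics, rng, renewal_p)
                if ct == TC and outcome == TC_APOPTOSIS:
                    state_l[i] = DEAD
                    occ[node] = -1
                    deaths += 1
                    continue
                # daughter placement among free nodes, n/f-weighted
                if len(free) == 1:
                    target = free[0]
                else:
                    weights = [
                        n_flat[nb] / max(f_flat[nb], _ECM_FLOOR)
                        for nb in free
                    ]
                    tot = sum(weights)
                    if tot <= 0.0:
                        target = free[int(rng.random() * len(free)) % len(free)]
                    else:
                        r = rng.random() * tot
                        cum = 0.0
                        target = free[-1]
                        for nb, w in zip(free, weights):
                            cum += w
                            if r <= cum:
                                target = nb
                                break
                age_l[i] = 0.0
                gen_l[i] += 1
                if ct == CSC:
                    if outcome == CSC_SYMMETRIC:
                        d_type, d_gen = CSC, gen_l[i]
                        d_mu = (
                            sample_self_renewal(mu_l[i], sigma, rng)
                            if heterogeneity
                            else mu_l[i]
                        )
                    elif outcome == CSC_ASYM_PC:
                        d_type, d_gen, d_mu = PC, 0, 0.0
                    elif outcome == CSC_TO_PC_PC:
                        # the CSC itself differentiates: both cells are PCs
                        d_type, d_gen, d_mu = PC, 0, 0.0
                        ctype_l[i] = PC
                        gen_l[i] = 0
                        mu_l[i] = 0.0
                    else:  # CSC_ASYM_TC
                        d_type, d_gen, d_mu = TC, 0, 0.0
                elif ct == PC:
                    if outcome == PC_SYMMETRIC:
                        d_type, d_gen, d_mu = PC, gen_l[i], 0.0
                    else:
                        d_type, d_gen, d_mu = TC, 0, 0.0
                else:  # TC symmetric
                    d_type, d_gen, d_mu = TC, gen_l[i], 0.0
                pop.add_cell(d_type, target, age=0.0, gen=d_gen, mu=d_mu)
                births += 1

        # 4) hypoxia-driven necrosis
        if enable_death and state_l[i] <= QUIESCENT and ct <= TC:
            if n_flat[node] < theta_a[ct]:
                hyp_l[i] += dt
                if hyp_l[i] >= hypoxia_window:
                    state_l[i] = NECROTIC
                    deaths += 1
            else:
                hyp_l[i] = 0.0

    n_live = pop.n_live()
    n_csc = pop.n_csc()
    return StepSample(
        n_live=n_live,
        n_csc=n_csc,
        surface_count=pop.surface_count(),
        volume=n_live * params.C_s,
        csc_fraction=(n_csc / n_live) if n_live else 0.0,
        births=births,
        deaths=deaths,
    )
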