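"""Minimal TAF-gradient-driven sprouting angiogenesis.

The microenvironment equations only need the neo-vasculature indicator
(the set of lattice nodes carrying new vessels) and the sprout-tip
migration speeds that feed the adaptive timestep. This module provides
both through a deliberately simple biased-walk scheme: the outermost
node layer proxies the pre-existing vasculature; where TAF exceeds an
initiation threshold a sprout tip may form, and tips step to orthogonal
neighbors with probability proportional to
``exp(kappa * dTAF) / max(f, eps)`` (chemotaxis up the TAF gradient,
haptotic resistance from dense ECM), laying down vessel nodes as they
go. Vessel nodes never regress. The module is optional: with it
disabled every vessel-dependent PDE term vanishes and the simulator
still runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .lattice import Lattice

__all__ = ["VesselNetwork", "spawn_sprouts", "advance_tips"]

_ECM_FLOOR = 1e-6


@dataclass
class Tip:
    node: int
    age: float = 0.0


@dataclass
class VesselNetwork:
    """Set of neo-vessel nodes plus active sprout tips and parent links."""

    lattice: Lattice
    nodes: set[int] = field(default_factory=set)
    tips: list[Tip] = field(default_factory=list)
    parents: dict[int, int] = field(default_factory=dict)

    def indicator(self) -> np.ndarray:
        """Boolean chi_SigmaC field over the lattice."""
        out = np.zeros(self.lattice.n_nodes, dtype=bool)
        if self.nodes:
            out[sorted(self.nodes)] = True
        return out.reshape(self.lattice.shape)


def spawn_sprouts(
    c: np.ndarray,
    network: VesselNetwork,
    rng,
    threshold: float = 0.2,
    spawn_prob: float = 0.05,
) -> VesselNetwork:
    """Initiate sprout tips on the boundary layer where TAF is high.

    Each boundary node with ``c > threshold`` and no tip yet sprouts
    with probability ``spawn_prob`` per call; new tips join the vessel
    node set immediately.
    """
    lat = network.lattice
    c_flat = np.asarray(c, dtype=float).ravel()
    boundary = np.flatnonzero(lat.boundary_mask().ravel())
    tipped = {t.node for t in network.tips}
    for node in boundary:
        node = int(node)
        if node in tipped or node in network.nodes:
            continue
        if c_flat[node] > threshold and rng.random() < spawn_prob:
            network.tips.append(Tip(node=node))
            network.nodes.add(node)
    return network


def tip_step_probabilities(
    node: int,
    c_flat,
    f_flat,
    lattice: Lattice,
    kappa: float = 10.0,
) -> tuple[list[int], list[float]]:
    """Softmax move weights for one tip over its in-domain neighbors.

    Weight of neighbor j: exp(kappa * (c_j - c_node) / dl) / max(f_j, eps).
    Returns (neighbor nodes, normalized probabilities).
    """
    nbs = list(lattice.neighbor_table()[node])
    dl = lattice.spacing
    c0 = c_flat[node]
    weights = []
    for nb in nbs:
        z = kappa * (c_flat[nb] - c0) / dl
        weights.append(math.exp(min(z, 700.0)) / max(f_flat[nb], _ECM_FLOOR))
    total = sum(weights)
    if total <= 0:
        p = 1.0 / len(nbs)
        return nbs, [p] * len(nbs)
    return nbs, [w / total for w in weights]


def advance_tips(
    network: VesselNetwork,
    c: np.ndarray,
    f: np.ndarray,
    rng,
    dt: float,
    kappa: float = 10.0,
) -> list[float]:
    """Move every tip one biased step; returns per-tip speeds |dx|/dt.

    Trail nodes are added to the vessel set (monotone growth); tips that
    land on existing vessel nodes simply merge their trails (no explicit
    anastomosis handling).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    lat = network.lattice
    c_flat = np.asarray(c, dtype=float).ravel().tolist()
    f_flat = np.asarray(f, dtype=float).ravel().tolist()
    speeds: list[float] = []
    for tip in network.tips:
        nbs, probs = tip_step_probabilities(tip.node, c_flat, f_flat, lat, kappa)
        r = rng.random()
        cum = 0.0
        chosen = nbs[-1]
        for nb, p in zip(nbs, probs):
            cum += p
            if r <= cum:
                chosen = nb
                break
        network.parents[chosen] = tip.node
        tip.node = chosen
        tip.age += dt
        network.nodes.add(chosen)
        speeds.append(lat.spacing / dt)
    return speeds
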