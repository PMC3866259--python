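"""Regular 3D lattice geometry, scalar fields and region masks.

Scalar microenvironment fields (nutrient, TAF, MDE, ECM, pressure, drug)
are plain ``numpy`` arrays of shape ``lattice.shape``; node ``(0, 0, 0)``
sits at the domain corner and indices are node-centered. Flat node ids
use C order (z fastest), matching ``ndarray.ravel()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = ["Lattice", "RegionMasks"]


@dataclass(frozen=True)
class Lattice:
    """Node-centered uniform grid with spacing ``spacing`` per axis."""

    shape: tuple[int, int, int]
    spacing: float = 0.1

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        if len(shape) != 3 or min(shape) < 5:
            raise ValueError("lattice shape must be a triple with all axes >= 5")
        if not self.spacing > 0:
            raise ValueError("lattice spacing must be > 0")

    @property
    def n_nodes(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    @property
    def center_node(self) -> int:
        nx, ny, nz = self.shape
        return self.ravel_index(nx // 2, ny // 2, nz // 2)

    def ravel_index(self, i: int, j: int, k: int) -> int:
        _, ny, nz = self.shape
        return (i * ny + j) * nz + k

    def unravel_index(self, node: int) -> tuple[int, int, int]:
        _, ny, nz = self.shape
        k = node % nz
        j = (node // nz) % ny
        i = node // (ny * nz)
        return i, j, k

    def boundary_mask(self) -> np.ndarray:
        """Boolean array marking the outermost node layer."""
        m = np.zeros(self.shape, dtype=bool)
        m[0, :, :] = m[-1, :, :] = True
        m[:, 0, :] = m[:, -1, :] = True
        m[:, :, 0] = m[:, :, -1] = True
        return m

    def interior_mask(self) -> np.ndarray:
        return ~self.boundary_mask()

    def neighbor_table(self) -> list[tuple[int, ...]]:
        """Per-node tuple of in-domain orthogonal neighbor ids (6-stencil).

        Cached per (shape,) since it only depends on geometry.
        """
        return _neighbor_table(self.shape)

    def coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical node coordinates along each axis (1D arrays)."""
        return tuple(
            np.arange(n, dtype=float) * self.spacing for n in self.shape
        )


@lru_cache(maxsize=8)
def _neighbor_table(shape: tuple[int, int, int]) -> list[tuple[int, ...]]:
    nx, ny, nz = shape
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    table: list[tuple[int, ...]] = []
    strides = (ny * nz, nz, 1)
    limits = (nx, ny, nz)
    coords = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    for node, (i, j, k) in enumerate(coords):
        nbs = []
        pos = (i, j, k)
        for axis in range(3):
            if pos[axis] > 0:
                nbs.append(node - strides[axis])
            if pos[axis] < limits[axis] - 1:
                nbs.append(node + strides[axis])
        table.append(tuple(nbs))
    return table


@dataclass
class RegionMasks:
    """Indicator fields for the viable, necrotic, host and vessel regions.

    ``viable``, ``necrotic`` and ``host`` partition the domain (pairwise
    disjoint); ``neovessel`` (the new vasculature) may overlap any of them.
    """

    viable: np.ndarray
    necrotic: np.ndarray
    host: np.ndarray
    neovessel: np.ndarray

    @classmethod
    def empty(cls, lattice: Lattice) -> "RegionMasks":
        shape = lattice.shape
        return cls(
            viable=np.zeros(shape, dtype=bool),
            necrotic=np.zeros(shape, dtype=bool),
            host=np.ones(shape, dtype=bool),
            neovessel=np.zeros(shape, dtype=bool),
        )

    def validate(self) -> None:
        if (
            self.viable.shape != self.necrotic.shape
            or self.viable.shape != self.host.shape
            or self.viable.shape != self.neovessel.shape
        ):
            raise ValueError("mask shapes differ")
        overlap = (
            (self.viable & self.necrotic)
            | (self.viable & self.host)
            | (self.necrotic & self.host)
        )
        if overlap.any():
            raise ValueError("viable/necrotic/host must be pairwise disjoint")

    def necrotic_boundary(self) -> np.ndarray:
        """Necrotic nodes with at least one viable orthogonal neighbor."""
        nec, via = self.necrotic, self.viable
        touch = np.zeros_like(nec)
        for axis in range(3):
            for shift in (1, -1):
                touch |= np.roll(via, shift, axis=axis) & _valid_roll(
                    via.shape, axis, shift
                )
        return nec & touch


def _valid_roll(shape: tuple[int, ...], axis: int, shift: int) -> np.ndarray:
    """Mask of positions where np.roll did not wrap around."""
    valid = np.ones(shape, dtype=bool)
    sl = [slice(None)] * len(shape)
    sl[axis] = slice(0, 1) if shift == 1 else slice(-1, None)
    valid[tuple(sl)] = False
    return valid
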