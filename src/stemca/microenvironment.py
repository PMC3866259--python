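"""Quasi-steady reaction-diffusion solvers for the microenvironment.

Five factors live on the lattice: nutrient ``n``, tumor angiogenic factor
``c`` (TAF), matrix-degrading enzyme ``m`` (MDE), extracellular matrix
``f`` (ECM) and tissue pressure ``p``; chemotherapy adds a drug field
``d`` governed by the nutrient template. Because molecular diffusion is
fast relative to cell dynamics, all diffusing fields are solved to
equilibrium (elliptic problems) each simulation step; only the
non-diffusing ECM is integrated in time.

Discretization is a 7-point finite-difference Laplacian on the uniform
node-centered grid. Dirichlet conditions (nutrient ``n = 1``, pressure
``p = 0``, drug ``d = dose``) are imposed on the outermost node layer;
zero-flux (Neumann) conditions use mirrored ghost values. Each elliptic
system is symmetric positive definite and solved by conjugate gradients
with an optional warm start; the assembled sparse system is exposed so
that small problems can be cross-checked against a dense direct solve.

Uptake coefficients are looked up per node through an integer *uptake
code* field indexing the 6-entry ``lambda_un`` vector
([CSC, PC, TC, quiescent, endothelial, host]); code ``-1`` means no
consumer at that node.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .lattice import Lattice, RegionMasks
from .params import ParameterSet, HOST_UPTAKE_INDEX

__all__ = [
    "ConvergenceError",
    "solve_nutrient",
    "solve_taf",
    "solve_mde",
    "solve_pressure",
    "solve_drug",
    "step_ecm",
    "compute_velocity",
    "compute_timestep",
    "assemble_dirichlet_system",
    "assemble_neumann_system",
    "uptake_field",
]

NO_CELL = -1


class ConvergenceError(RuntimeError):
    """Raised when the iterative linear solver fails to reach tolerance."""


# ---------------------------------------------------------------------------
# Cached discrete operators
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _dirichlet_structure(shape: tuple[int, int, int], spacing: float):
    """Interior-node Laplacian with the boundary layer eliminated.

    Returns (L_int, interior_flat_idx, boundary_neighbor_count) where
    ``L_int`` is the (negated-free) Laplacian restricted to interior
    unknowns, scaled by 1/spacing^2, and ``boundary_neighbor_count[i]``
    counts how many of interior node i's six neighbors lie on the fixed
    boundary layer (their known value moves to the right-hand side).
    """
    lat = Lattice(shape, spacing)
    interior = lat.interior_mask().ravel()
    n_int = int(interior.sum())
    full_to_int = -np.ones(lat.n_nodes, dtype=np.int64)
    full_to_int[interior] = np.arange(n_int)
    table = lat.neighbor_table()

    rows, cols, vals = [], [], []
    bcount = np.zeros(n_int, dtype=np.int64)
    inv_h2 = 1.0 / spacing**2
    int_nodes = np.flatnonzero(interior)
    for node in int_nodes:
        i = full_to_int[node]
        rows.append(i)
        cols.append(i)
        vals.append(-6.0 * inv_h2)
        for nb in table[node]:
            j = full_to_int[nb]
            if j >= 0:
                rows.append(i)
                cols.append(j)
                vals.append(inv_h2)
            else:
                bcount[i] += 1
    L = sp.csr_matrix(
        (vals, (rows, cols)), shape=(n_int, n_int), dtype=float
    )
    return L, int_nodes, bcount


@lru_cache(maxsize=8)
def _neumann_laplacian(shape: tuple[int, int, int], spacing: float):
    """Full-grid flux-sum Laplacian with zero flux through the walls.

    Finite-volume form: each in-domain face contributes a symmetric
    (u_nb - u_c)/h^2 pair; wall faces carry no flux. Reaction and source
    terms must be scaled by the boundary cell-volume weights from
    :func:`_neumann_weights` for second-order accuracy.
    """
    lat = Lattice(shape, spacing)
    inv_h2 = 1.0 / spacing**2
    nx, ny, nz = shape
    # per-node half-width flags per axis (True on a wall of that axis)
    idx = np.arange(lat.n_nodes)
    pos = np.stack(
        [idx // (ny * nz), (idx // nz) % ny, idx % nz], axis=1
    )
    half = np.stack(
        [
            (pos[:, a] == 0) | (pos[:, a] == shape[a] - 1)
            for a in range(3)
        ],
        axis=1,
    )
    axis_factor = np.where(half, 0.5, 1.0)  # (n_nodes, 3)
    strides = (ny * nz, nz, 1)
    rows, cols, vals = [], [], []
    diag = np.zeros(lat.n_nodes)
    for axis in range(3):
        has_next = pos[:, axis] < shape[axis] - 1
        i = idx[has_next]
        j = i + strides[axis]
        # face area transverse to `axis`, shared by cells i and j
        other = [a for a in range(3) if a != axis]
        area = axis_factor[i][:, other].prod(axis=1)
        coup = area * inv_h2
        rows.extend(i)
        cols.extend(j)
        vals.extend(coup)
        rows.extend(j)
        cols.extend(i)
        vals.extend(coup)
        np.add.at(diag, i, -coup)
        np.add.at(diag, j, -coup)
    rows.extend(idx)
    cols.extend(idx)
    vals.extend(diag)
    return sp.csr_matrix(
        (vals, (rows, cols)), shape=(lat.n_nodes, lat.n_nodes), dtype=float
    )


@lru_cache(maxsize=8)
def _neumann_weights(shape: tuple[int, int, int]) -> np.ndarray:
    """Cell-volume weights: 1/2 per axis touching a wall (node-centered FV)."""
    w = np.ones(shape, dtype=float)
    for axis in range(3):
        sl = [slice(None)] * 3
        for edge in (0, -1):
            sl[axis] = slice(edge, edge + 1 or None)
            w[tuple(sl)] *= 0.5
    return w


# ---------------------------------------------------------------------------
# Generic SPD solve
# ---------------------------------------------------------------------------

def _solve_spd(A, b, params: ParameterSet, x0=None) -> np.ndarray:
    """CG solve of A x = b (A symmetric positive definite).

    Convergence is declared when the residual max-norm falls below
    ``solver_tol * max(1, ||b||_inf)``.
    """
    bmax = float(np.max(np.abs(b))) if b.size else 0.0
    if bmax == 0.0 and x0 is None:
        return np.zeros_like(b)
    target = params.solver_tol * max(1.0, bmax)
    x, info = spla.cg(
        A, b, x0=x0, rtol=0.0, atol=0.5 * target,
        maxiter=params.solver_maxiter,
    )
    resid = float(np.max(np.abs(b - A @ x)))
    if resid > target:
        raise ConvergenceError(
            f"linear solver residual {resid:.3e} above tolerance "
            f"{target:.3e} after {params.solver_maxiter} iterations"
        )
    return x


def _solve_dirichlet(lattice, diffusion, k, source, bc_value, params, x0=None):
    """Solve -D lap(x) + k x = source with x = bc_value on the boundary.

    ``k`` and ``source`` are full-grid arrays; returns the full field.
    """
    A, b, int_nodes = assemble_dirichlet_system(
        lattice, diffusion, k, source, bc_value
    )
    x0_int = None if x0 is None else np.asarray(x0).ravel()[int_nodes]
    x_int = _solve_spd(A, b, params, x0=x0_int)
    out = np.full(lattice.n_nodes, bc_value, dtype=float)
    out[int_nodes] = x_int
    return out.reshape(lattice.shape)


def assemble_dirichlet_system(lattice, diffusion, k, source, bc_value):
    """Assemble the SPD system for a Dirichlet elliptic problem.

    The PDE is ``0 = D lap(x) - k x + source`` with ``x = bc_value`` on
    the outermost layer; returns ``(A, b, interior_node_ids)`` over the
    interior unknowns with boundary values folded into ``b``.
    """
    L, int_nodes, bcount = _dirichlet_structure(
        lattice.shape, lattice.spacing
    )
    k = np.asarray(k, dtype=float).ravel()[int_nodes]
    src = np.asarray(source, dtype=float).ravel()[int_nodes]
    A = (-diffusion) * L + sp.diags(k)
    b = src + diffusion * bcount * bc_value / lattice.spacing**2
    return A.tocsr(), b, int_nodes


def assemble_neumann_system(lattice, diffusion, k, source):
    """Assemble the SPD system for a zero-flux elliptic problem.

    The PDE is ``0 = D lap(x) - k x + source``; reaction and source are
    volume-weighted at the walls (node-centered finite volumes), which
    keeps the matrix symmetric and the scheme second order. ``k`` must
    be positive somewhere for the system to be nonsingular.
    """
    L = _neumann_laplacian(lattice.shape, lattice.spacing)
    w = _neumann_weights(lattice.shape).ravel()
    k = np.asarray(k, dtype=float).ravel()
    b = w * np.asarray(source, dtype=float).ravel()
    A = (-diffusion) * L + sp.diags(w * k)
    return A.tocsr(), b


def _solve_neumann(lattice, diffusion, k, source, params, x0=None):
    A, b = assemble_neumann_system(lattice, diffusion, k, source)
    if not np.any(b):
        return np.zeros(lattice.shape)
    if float(np.min(np.asarray(k).ravel())) < 0:
        raise ValueError("reaction coefficient must be >= 0")
    x0v = None if x0 is None else np.asarray(x0).ravel()
    x = _solve_spd(A, b, params, x0=x0v)
    return x.reshape(lattice.shape)


# ---------------------------------------------------------------------------
# Field solvers
# ---------------------------------------------------------------------------

def uptake_field(lattice: Lattice, uptake_codes, params: ParameterSet):
    """Per-node uptake rate from an integer code field indexing lambda_un."""
    codes = np.asarray(uptake_codes)
    if codes.shape != lattice.shape:
        codes = codes.reshape(lattice.shape)
    rates = np.asarray(params.lambda_un, dtype=float)
    out = np.zeros(lattice.shape, dtype=float)
    occupied = codes >= 0
    out[occupied] = rates[codes[occupied]]
    return out


def solve_nutrient(
    masks: RegionMasks,
    ecm: np.ndarray,
    pressure: np.ndarray,
    cell_type_field,
    params: ParameterSet,
    lattice: Lattice,
    x0=None,
) -> np.ndarray:
    """Quasi-steady nutrient field with n = 1 on the domain boundary.

    Production occurs everywhere non-necrotic: transfer from pre-existing
    vessels (``lambda_ppn``) plus pressure-damped transfer from the
    neo-vasculature (``lambda_pan (1-p)+``), both saturating via (1-n);
    fibronectin binding adds ``lambda_bn * f``. Uptake is per local cell
    type. The result is clamped to [0, 1].
    """
    nonnecrotic = ~masks.necrotic
    damped = np.clip(1.0 - np.asarray(pressure), 0.0, None)
    prod_coef = nonnecrotic * (
        params.lambda_pan * damped * masks.neovessel + params.lambda_ppn
    )
    upt = uptake_field(lattice, cell_type_field, params)
    upt[masks.necrotic] = 0.0
    k = prod_coef + upt
    source = prod_coef + params.lambda_bn * np.clip(np.asarray(ecm), 0.0, 1.0)
    n = _solve_dirichlet(lattice, params.D_n, k, source, 1.0, params, x0=x0)
    return np.clip(n, 0.0, 1.0)


def solve_taf(
    masks: RegionMasks,
    params: ParameterSet,
    lattice: Lattice,
    neovessel=None,
    x0=None,
) -> np.ndarray:
    """Quasi-steady TAF field with zero-flux boundaries.

    Secreted at the necrotic boundary (``lambda_pNc``) and by viable
    tumor cells (``lambda_pVc``); taken up at neo-vessel nodes
    (``lambda_uc``) and degraded everywhere (``lambda_dc``).
    """
    vessels = masks.neovessel if neovessel is None else neovessel
    k = params.lambda_uc * np.asarray(vessels, dtype=float) + params.lambda_dc
    source = (
        params.lambda_pNc * masks.necrotic_boundary()
        + params.lambda_pVc * masks.viable
    ).astype(float)
    c = _solve_neumann(lattice, params.D_c, k, source, params, x0=x0)
    return np.clip(c, 0.0, None)


def solve_mde(
    masks: RegionMasks,
    params: ParameterSet,
    lattice: Lattice,
    x0=None,
) -> np.ndarray:
    """Quasi-steady MDE field with zero-flux boundaries.

    Viable tumor cells secrete at ``lambda_pm (1-m)`` (saturating) and
    endothelial/vessel nodes at ``lambda_spm``; decay ``lambda_dm``.
    """
    viable = masks.viable.astype(float)
    k = params.lambda_pm * viable + params.lambda_dm
    source = params.lambda_pm * viable + params.lambda_spm * masks.neovessel
    m = _solve_neumann(lattice, params.D_m, k, source, params, x0=x0)
    return np.clip(m, 0.0, None)


def solve_pressure(
    masks: RegionMasks,
    n: np.ndarray,
    params: ParameterSet,
    lattice: Lattice,
    x0=None,
) -> np.ndarray:
    """Tissue pressure: 0 = lap(p) + (n - lambda_a) chi_V - lambda_N chi_N.

    Dirichlet p = 0 on the boundary. Proliferating (viable) regions act
    as a volume source, necrotic regions as a sink.
    """
    source = (
        (np.asarray(n) - params.lambda_a) * masks.viable
        - params.lambda_N * masks.necrotic
    )
    k = np.zeros(lattice.shape)
    return _solve_dirichlet(lattice, 1.0, k, source, 0.0, params, x0=x0)


def solve_drug(
    masks: RegionMasks,
    pressure: np.ndarray,
    cell_type_field,
    dose: float,
    params: ParameterSet,
    lattice: Lattice,
    x0=None,
) -> np.ndarray:
    """Drug field from the nutrient equation template.

    Vascular transfer and the boundary value are scaled by ``dose``; the
    saturation factor becomes (dose - d) so that an uptake-free domain
    equilibrates at the administered dose. Diffusion and transfer reuse
    the nutrient constants; cellular uptake is amplified by
    ``drug_uptake_scale`` (drug is consumed much faster than nutrient,
    so it only reaches a few cell layers into the tumor). Clamped to
    [0, dose].
    """
    if dose < 0:
        raise ValueError("dose must be >= 0")
    if dose == 0:
        return np.zeros(lattice.shape)
    nonnecrotic = ~masks.necrotic
    damped = np.clip(1.0 - np.asarray(pressure), 0.0, None)
    prod_coef = nonnecrotic * (
        params.lambda_pan * damped * masks.neovessel + params.lambda_ppn
    )
    upt = params.drug_uptake_scale * uptake_field(
        lattice, cell_type_field, params
    )
    upt[masks.necrotic] = 0.0
    k = prod_coef + upt
    source = prod_coef * dose
    d = _solve_dirichlet(lattice, params.D_n, k, source, dose, params, x0=x0)
    return np.clip(d, 0.0, dose)


def step_ecm(
    f: np.ndarray,
    m: np.ndarray,
    masks: RegionMasks,
    dt: float,
    params: ParameterSet,
) -> np.ndarray:
    """One Heun (2nd-order TVD Runge-Kutta) step of the pointwise ECM ODE.

    df/dt = lambda_pf (1-f) chi_V + lambda_spf chi_SigmaC - lambda_df f m,
    with no spatial coupling; the result is clamped to [0, 1].
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    f = np.asarray(f, dtype=float)
    m = np.asarray(m, dtype=float)
    viable = masks.viable.astype(float)
    vessel = masks.neovessel.astype(float)

    def rhs(g):
        return (
            params.lambda_pf * (1.0 - g) * viable
            + params.lambda_spf * vessel
            - params.lambda_df * g * m
        )

    f1 = f + dt * rhs(f)
    f2 = f + 0.5 * dt * (rhs(f) + rhs(f1))
    return np.clip(f2, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Velocity and adaptive timestep
# ---------------------------------------------------------------------------

def compute_velocity(p: np.ndarray, spacing: float) -> np.ndarray:
    """Darcy velocity u = -grad p.

    Central differences on interior nodes, one-sided at the boundary;
    returns an array of shape (3, nx, ny, nz).
    """
    grads = np.gradient(np.asarray(p, dtype=float), spacing)
    return -np.stack(grads)


def compute_timestep(
    u,
    tip_speeds,
    spacing: float,
    max_dt: float | None = 0.05,
) -> float:
    """Stability timestep dt = (dl/4) min(1/max|V|, 1/max|u|), capped.

    ``tip_speeds`` are the endothelial sprout-tip migration speeds;
    ``u`` the Darcy cell-velocity field (or None). Empty or all-zero
    speed collections contribute an infinite bound; if both are empty a
    configured cap is required.
    """
    bounds = []
    if u is not None:
        umag = np.sqrt(np.sum(np.asarray(u) ** 2, axis=0))
        umax = float(umag.max()) if umag.size else 0.0
        bounds.append(np.inf if umax == 0.0 else 1.0 / umax)
    speeds = [abs(v) for v in (tip_speeds or [])]
    vmax = max(speeds) if speeds else 0.0
    bounds.append(np.inf if vmax == 0.0 else 1.0 / vmax)
    dt = spacing / 4.0 * min(bounds) if bounds else np.inf
    if np.isinf(dt):
        if max_dt is None:
            raise ValueError(
                "no finite speed bound and no maximum timestep configured"
            )
        return max_dt
    return min(dt, max_dt) if max_dt is not None else dt
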