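"""Model parameter registry.

All quantities are dimensionless: lengths in units where the lattice
spacing is 0.1, time in simulated days, concentrations scaled to the
vascular boundary value (nutrient, drug) or to a secretion/decay balance
(TAF, MDE, ECM).

Vector-valued parameters map to cell types by position:

* ``lambda_un`` (nutrient uptake): [CSC, PC, TC, quiescent, endothelial, host]
* ``theta_a`` (hypoxia survival threshold): [CSC, PC, TC]
* ``theta_d`` (maximum drug concentration for survival): [CSC, PC, TC]
* ``A_p`` (relative proliferation age): [CSC, PC, TC, endothelial]
* ``G_m`` (maximum divisions): [CSC, PC, TC]

CSCs are the most hypoxia-tolerant and the most drug-resistant subtype;
TCs the least on both axes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

__all__ = [
    "CSC",
    "PC",
    "TC",
    "ENDOTHELIAL",
    "QUIESCENT_UPTAKE_INDEX",
    "HOST_UPTAKE_INDEX",
    "CELL_TYPE_NAMES",
    "ParameterSet",
]

# Cell-type codes, shared across the whole package.
CSC, PC, TC, ENDOTHELIAL = 0, 1, 2, 3
CELL_TYPE_NAMES = ("CSC", "PC", "TC", "ENDOTHELIAL")

# Positions in the 6-entry nutrient-uptake vector beyond the tumor types.
QUIESCENT_UPTAKE_INDEX = 3
ENDOTHELIAL_UPTAKE_INDEX = 4
HOST_UPTAKE_INDEX = 5


@dataclass
class ParameterSet:
    """All model rate constants plus solver settings.

    Defaults reproduce the published parameter table; every entry can be
    overridden from the ``microenvironment:`` section of a run config.
    """

    # Diffusion coefficients
    D_n: float = 1.0          # nutrient
    D_c: float = 100.0        # TAF
    D_m: float = 1.0          # MDE

    # Nutrient reaction rates
    lambda_un: tuple[float, ...] = (0.2, 0.5, 0.33, 0.67, 1.0, 1.0)
    lambda_bn: float = 2.5e-3   # binding to fibronectin
    lambda_pan: float = 0.05    # transfer from neo-vasculature
    lambda_ppn: float = 0.01    # transfer from pre-existing vessels

    # TAF rates
    lambda_pNc: float = 0.05    # secretion at the necrotic boundary
    lambda_pVc: float = 0.004   # secretion by viable tumor cells
    lambda_dc: float = 0.01     # natural degradation
    lambda_uc: float = 0.025    # uptake by endothelial cells

    # MDE rates
    lambda_pm: float = 50.0     # secretion by viable tumor cells
    lambda_spm: float = 1.0     # secretion by endothelial cells
    lambda_dm: float = 10.0     # decay

    # ECM rates
    lambda_pf: float = 0.1      # production by viable tumor cells
    lambda_spf: float = 0.01    # production by endothelial cells
    lambda_df: float = 0.01     # degradation by MDE

    # Pressure source/sink strengths
    lambda_a: float = 1e-4      # volume loss by apoptosis
    lambda_N: float = 0.25      # volume loss by necrosis

    # Survival thresholds, by type [CSC, PC, TC]
    theta_a: tuple[float, ...] = (0.1, 0.17, 0.25)
    theta_d: tuple[float, ...] = (0.375, 0.27, 0.25)

    # Lineage kinetics
    K_CC: float = 0.6
    K_CCP: float = 0.25
    K_CP: float = 0.1
    K_CT: float = 0.05
    K_PP: float = 0.25
    K_PT: float = 0.75

    # Proliferation ages and generation limits
    A_p: tuple[float, ...] = (1.0, 0.4, 1.0, 0.2)
    G_m: tuple[int, ...] = (250, 50, 25)

    # Cell-size scaling: tumor volume = live cell count * C_s
    C_s: float = 1e-4

    # Drug field: cellular uptake relative to nutrient uptake. Chemo
    # agents are consumed/bound far faster than nutrient turns over, so
    # the drug only penetrates a few cell layers from the vasculature
    # (interior cells are poorly exposed). Scale 20 gives a penetration
    # depth of ~4 cell diameters at the default uptake rates.
    drug_uptake_scale: float = 20.0

    # Whether unoccupied non-necrotic nodes consume nutrient at the
    # host-tissue rate (6th lambda_un entry).
    host_uptake: bool = True

    # Linear-solver settings
    solver_tol: float = 1e-8
    solver_maxiter: int = 10_000

    def __post_init__(self) -> None:
        self.validate()

    # -- derived entries -------------------------------------------------
    @property
    def K_TT(self) -> float:
        """TC symmetric-division probability, 1 - lambda_a."""
        return 1.0 - self.lambda_a

    @property
    def d_T(self) -> float:
        """TC per-division apoptosis probability, lambda_a."""
        return self.lambda_a

    @property
    def csc_split(self) -> tuple[float, float, float, float]:
        return (self.K_CC, self.K_CCP, self.K_CP, self.K_CT)

    @property
    def pc_split(self) -> tuple[float, float]:
        return (self.K_PP, self.K_PT)

    @property
    def tc_split(self) -> tuple[float, float]:
        return (self.K_TT, self.d_T)

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        for name in ("D_n", "D_c", "D_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"diffusion coefficient {name} must be > 0")
        rate_names = [
            "lambda_bn", "lambda_pan", "lambda_ppn", "lambda_pNc",
            "lambda_pVc", "lambda_dc", "lambda_uc", "lambda_pm",
            "lambda_spm", "lambda_dm", "lambda_pf", "lambda_spf",
            "lambda_df", "lambda_a", "lambda_N",
        ]
        for name in rate_names:
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name} must be >= 0")
        if any(v < 0 for v in self.lambda_un):
            raise ValueError("lambda_un entries must be >= 0")
        if len(self.lambda_un) != 6:
            raise ValueError("lambda_un must have 6 entries")
        if len(self.theta_a) != 3 or len(self.theta_d) != 3:
            raise ValueError("theta_a and theta_d must have 3 entries")
        if len(self.A_p) != 4:
            raise ValueError("A_p must have 4 entries")
        if len(self.G_m) != 3:
            raise ValueError("G_m must have 3 entries")
        for vec, total in (
            ((self.K_CC, self.K_CCP, self.K_CP, self.K_CT), 1.0),
            ((self.K_PP, self.K_PT), 1.0),
            ((self.K_TT, self.d_T), 1.0),
        ):
            if any(p < 0 for p in vec):
                raise ValueError("division probabilities must be >= 0")
            if abs(sum(vec) - total) > 1e-9:
                raise ValueError(
                    f"division probabilities {vec} must sum to {total}"
                )
        if self.drug_uptake_scale < 0:
            raise ValueError("drug_uptake_scale must be >= 0")
        if self.solver_tol <= 0 or self.solver_maxiter < 1:
            raise ValueError("invalid solver settings")

    # -- construction helpers -------------------------------------------
    def replace(self, **overrides) -> "ParameterSet":
        return dataclasses.replace(self, **overrides)

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in dataclasses.fields(cls))

    @classmethod
    def from_dict(cls, overrides: dict) -> "ParameterSet":
        """Build a ParameterSet from a (possibly partial) mapping.

        Unknown keys are rejected so that config typos fail loudly.
        """
        known = set(cls.field_names())
        unknown = set(overrides) - known
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        coerced = {
            k: tuple(v) if isinstance(v, list) else v
            for k, v in overrides.items()
        }
        return cls(**coerced)
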