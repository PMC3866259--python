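"""Tumor-growth analysis: Gompertz fitting and summary indices.

The growth law is the Gompertz curve

    y(t) = y0 * exp(k * (1 - exp(-b * (t - t0))))

with displacement ``k`` and growth speed ``b`` (both positive). From a
fitted curve and the recorded trajectory four indices are derived:

* proliferation potential  PP  = lim_{t->inf} y(t) = y0 * e^k
* time to potential        TtP = first t with y(t) >= (1 - eps) * PP
  (the asymptote is unreachable in finite time, so TtP is reported at a
  small relative tolerance eps, 0.01 by default)
* average aggressive index AAI = mean_i surface_i / count_i
  (surface and volume measured as cell counts on the 6-neighbor
  surface definition)
* average fitting error    AFE = f_obj / N, the mean squared residual
  of the least-squares fit.

Fitting uses bounded nonlinear least squares with five deterministic
multi-starts, keeping the best objective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .params import ParameterSet

__all__ = [
    "GrowthRecord",
    "GompertzFit",
    "gompertz",
    "fit_gompertz",
    "proliferation_potential",
    "time_to_potential",
    "average_aggressive_index",
    "average_fitting_error",
    "sensitivity_scan",
]


@dataclass
class GrowthRecord:
    """Time series of tumor size and composition from one simulation."""

    times: np.ndarray
    volumes: np.ndarray
    surface_counts: np.ndarray
    csc_fractions: np.ndarray
    cell_counts: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.surface_counts = np.asarray(self.surface_counts, dtype=float)
        self.csc_fractions = np.asarray(self.csc_fractions, dtype=float)
        self.cell_counts = np.asarray(self.cell_counts, dtype=float)
        lengths = {
            len(self.times),
            len(self.volumes),
            len(self.surface_counts),
            len(self.csc_fractions),
            len(self.cell_counts),
        }
        if len(lengths) != 1:
            raise ValueError("all record series must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.volumes < 0):
            raise ValueError("volumes must be >= 0")

    @property
    def n_samples(self) -> int:
        return len(self.times)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "volume": self.volumes,
                "surface_count": self.surface_counts,
                "csc_fraction": self.csc_fractions,
                "cell_count": self.cell_counts,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, C_s: float = 1e-4) -> "GrowthRecord":
        df = pd.read_csv(path)
        counts = (
            df["cell_count"]
            if "cell_count" in df
            else np.round(df["volume"] / C_s)
        )
        return cls(
            times=df["time"].to_numpy(),
            volumes=df["volume"].to_numpy(),
            surface_counts=df["surface_count"].to_numpy(),
            csc_fractions=df["csc_fraction"].to_numpy(),
            cell_counts=np.asarray(counts, dtype=float),
        )


@dataclass(frozen=True)
class GompertzFit:
    """Fitted Gompertz parameters plus the least-squares objective."""

    y0: float
    k: float
    b: float
    t0: float
    f_obj: float

    def predict(self, t) -> np.ndarray:
        return gompertz(t, self.y0, self.k, self.b, self.t0)


def gompertz(t, y0, k, b, t0):
    """Gompertz growth curve y0 * exp(k (1 - exp(-b (t - t0))))."""
    t = np.asarray(t, dtype=float)
    return y0 * np.exp(k * (1.0 - np.exp(-b * (t - t0))))


_EPS = 1e-9


def _initial_guesses(t, y):
    """Five deterministic starting points spanning plausible regimes."""
    y_lo = max(float(np.min(y)), _EPS)
    y_hi = max(float(np.max(y)), 2 * _EPS)
    span = max(float(t[-1] - t[0]), _EPS)
    k0 = max(np.log(y_hi / y_lo), 0.1)
    guesses = [
        (y_lo, k0, 1.0 / span, t[0]),
        (y_lo, k0, 4.0 / span, t[0]),
        (y_lo, 0.5 * k0 + 0.5, 2.0 / span, t[0] + 0.25 * span),
        (max(float(y[0]), _EPS), k0 + 1.0, 0.5 / span, t[0] - 0.1 * span),
        (0.5 * y_hi, 1.0, 1.0 / span, t[0] + 0.5 * span),
    ]
    return guesses


def fit_gompertz(record: GrowthRecord | tuple) -> GompertzFit:
    """Least-squares Gompertz fit with 5 deterministic multi-starts.

    Accepts a :class:`GrowthRecord` or a ``(times, volumes)`` pair.
    Requires at least 5 samples; a constant volume series is degenerate
    (k and b are unidentifiable at k -> 0) and rejected. The returned
    parameters are reported in the gauge t0 = times[0].
    """
    if isinstance(record, GrowthRecord):
        t, y = record.times, record.volumes
    else:
        t, y = np.asarray(record[0], float), np.asarray(record[1], float)
    if len(t) < 5:
        raise ValueError("need at least 5 samples to fit")
    if np.allclose(y, y[0]):
        raise ValueError("volume series is constant; Gompertz fit degenerate")

    span = max(float(t[-1] - t[0]), _EPS)
    lower = np.array([_EPS, _EPS, _EPS, t[0] - 2 * span])
    upper = np.array([np.inf, 60.0, np.inf, t[-1] + span])

    def residuals(theta):
        return gompertz(t, *theta) - y

    best = None
    for x0 in _initial_guesses(t, y):
        x0 = np.clip(np.asarray(x0, float), lower + _EPS, upper - _EPS)
        try:
            sol = least_squares(
                residuals, x0, bounds=(lower, upper), method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=2000,
            )
        except Exception:
            continue
        obj = float(np.sum(sol.fun**2))
        if best is None or obj < best[0]:
            best = (obj, sol.x)
    if best is None:
        raise RuntimeError("Gompertz fit failed from every starting point")
    obj, (y0, k, b, t0) = best
    # Gauge normalization: (y0, k, t0) trade off exactly along the same
    # curve (shifting t0 rescales y0 and k), so anchor t0 at the first
    # sample time. The curve, PP and TtP are invariant under this.
    t_anchor = float(t[0])
    s = np.exp(-b * (t_anchor - t0))
    y0, k, t0 = y0 * np.exp(k * (1.0 - s)), k * s, t_anchor
    return GompertzFit(y0=float(y0), k=float(k), b=float(b), t0=float(t0),
                       f_obj=obj)


def proliferation_potential(fit: GompertzFit) -> float:
    """Asymptotic tumor volume PP = y0 * e^k."""
    return fit.y0 * np.exp(fit.k)


def time_to_potential(fit: GompertzFit, epsilon: float = 0.01) -> float:
    """First time the curve reaches (1 - epsilon) of its potential.

    Closed-form inversion of the growth law: the curve equals
    (1-eps) * PP when exp(-b (t - t0)) = -ln(1 - eps) / k, i.e.

        TtP = t0 - ln(-ln(1 - epsilon) / k) / b.

    Since the asymptote is approached but never attained, epsilon > 0 is
    required; epsilon -> 0 sends TtP to infinity.
    """
    if not 0.0 < epsilon < 1.0:
        raise ValueError("epsilon must lie in (0, 1)")
    ratio = -np.log1p(-epsilon) / fit.k
    if ratio >= 1.0:
        # the target level is already reached at or before t0
        return fit.t0
    return fit.t0 - np.log(ratio) / fit.b


def average_aggressive_index(record: GrowthRecord) -> float:
    """Mean surface-to-volume ratio, both measured in cell counts.

    Samples with zero cells are skipped (an empty tumor has no surface).
    """
    surf = record.surface_counts
    count = record.cell_counts
    valid = count > 0
    if not np.any(valid):
        raise ValueError("record contains no non-empty samples")
    return float(np.mean(surf[valid] / count[valid]))


def average_fitting_error(fit: GompertzFit, record: GrowthRecord | tuple) -> float:
    """Mean squared residual AFE = f_obj / N."""
    if isinstance(record, GrowthRecord):
        n = record.n_samples
    else:
        n = len(record[0])
    return fit.f_obj / n


# ---------------------------------------------------------------------------
# One-at-a-time parameter sensitivity
# ---------------------------------------------------------------------------

_BUILTIN_METRICS = {
    "final_volume": lambda result, config: float(result.record.volumes[-1]),
    "final_cell_count": lambda result, config: float(
        result.record.cell_counts[-1]
    ),
    "final_csc_fraction": lambda result, config: float(
        result.record.csc_fractions[-1]
    ),
    "aai": lambda result, config: average_aggressive_index(result.record),
}


def sensitivity_scan(
    base_config,
    parameters,
    metric="final_volume",
    replicates: int = 3,
    levels=(0.9, 1.0, 1.1),
    seeds=None,
) -> pd.DataFrame:
    """One-at-a-time +-10% perturbation scan over model parameters.

    Each named parameter is scaled to each level (vector parameters
    scale elementwise), the simulation re-run with ``replicates`` paired
    seeds (identical seed sets across parameters and levels, so
    replicate noise cancels in comparisons), and the metric summarized.
    ``metric`` is a builtin name or a callable ``(result, config) ->
    float``. Unknown parameter names are rejected before any run.
    """
    from .experiments_io import run_simulation  # deferred: avoid cycle

    known = set(ParameterSet.field_names())
    parameters = list(parameters)
    unknown = [p for p in parameters if p not in known]
    if unknown:
        raise KeyError(f"unknown parameter(s): {unknown}")
    if callable(metric):
        metric_fn = metric
    else:
        try:
            metric_fn = _BUILTIN_METRICS[metric]
        except KeyError:
            raise KeyError(
                f"unknown metric {metric!r}; "
                f"choose from {sorted(_BUILTIN_METRICS)} or pass a callable"
            ) from None
    if seeds is None:
        seeds = [base_config.seed + 1000 * (r + 1) for r in range(replicates)]

    base_params = ParameterSet.from_dict(dict(base_config.microenvironment))
    rows = []
    baseline_mean: dict[str, float] = {}
    for name in parameters:
        base_value = getattr(base_params, name)
        for level in levels:
            if isinstance(base_value, tuple):
                value = tuple(v * level for v in base_value)
            else:
                value = base_value * level
            values = []
            for seed in seeds:
                config = base_config.model_copy(deep=True)
                config.microenvironment = dict(config.microenvironment)
                config.microenvironment[name] = (
                    list(value) if isinstance(value, tuple) else value
                )
                config.seed = seed
                result = run_simulation(config)
                values.append(metric_fn(result, config))
            mean = float(np.mean(values))
            if level == 1.0:
                baseline_mean[name] = mean
            rows.append(
                {
                    "parameter": name,
                    "level": level,
                    "metric_mean": mean,
                    "metric_sd": float(np.std(values, ddof=1))
                    if len(values) > 1
                    else 0.0,
                    "n": len(values),
                }
            )
    df = pd.DataFrame(rows)
    df["relative_change"] = [
        (row.metric_mean - baseline_mean[row.parameter])
        / baseline_mean[row.parameter]
        if baseline_mean.get(row.parameter)
        else np.nan
        for row in df.itertuples()
    ]
    return df
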