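"""Where does the mean-field theory break?  Randomized-community error scan.

Communities are drawn with the fifteen thermal-physiology parameters (five
per trait group: growth r, interspecific a_ij, intraspecific a_ii) sampled
uniformly from configurable ranges.  For each parameter set the analytic and
simulated temperature–richness curves are compared through a normalized RMSE
(RMSE divided by mean simulated richness, removing system-size bias), and
each parameter's Pearson correlation with that error summarizes its effect:
positive means increasing the parameter degrades the mean-field prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .feasibility import (
    CommunityThermalParams,
    analytic_richness_curve,
    default_temperature_grid,
)
from .glv import simulated_richness_curve
from .thermal import EnsembleTPC, ThermalContext

__all__ = [
    "ParameterRanges",
    "SensitivityConfig",
    "DEFAULT_RANGES",
    "sample_parameter_sets",
    "normalized_rmse",
    "parameter_error_correlations",
    "run_sensitivity",
]

logger = logging.getLogger(__name__)

PARAM_NAMES = ("mu_b0", "mu_e", "var_b0", "var_e", "cov_b0e")
TRAIT_KEYS = ("r", "aij", "aii")


@dataclass(frozen=True)
class ParameterRanges:
    """Closed sampling intervals for each of the 15 ensemble parameters.

    Each field maps parameter name -> (low, high).  Defaults span the
    magnitudes of the empirical presets and baseline simulations; they are a
    package choice, not measured values.
    """

    r: dict = field(default_factory=dict)
    aij: dict = field(default_factory=dict)
    aii: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for trait in TRAIT_KEYS:
            intervals = getattr(self, trait)
            for name in PARAM_NAMES:
                if name not in intervals:
                    raise ValueError(f"missing range for {trait}.{name}")
                lo, hi = intervals[name]
                if hi < lo:
                    raise ValueError(f"empty interval for {trait}.{name}")


def _default_trait_ranges(mu_b0_range: tuple[float, float]) -> dict:
    return {
        "mu_b0": mu_b0_range,
        "mu_e": (0.0, 1.5),
        "var_b0": (0.0, 1.0),
        "var_e": (0.0, 0.3),
        "cov_b0e": (-0.5, 0.0),
    }


DEFAULT_RANGES = ParameterRanges(
    r=_default_trait_ranges((-0.5, 0.5)),
    aij=_default_trait_ranges((-7.0, -3.0)),
    aii=_default_trait_ranges((-1.0, 1.0)),
)


@dataclass(frozen=True)
class SensitivityConfig:
    """Scan configuration (small grids keep the Monte-Carlo side tractable)."""

    t_ref_c: float = 13.0
    grid_start_c: float = 0.0
    grid_stop_c: float = 40.0
    grid_step_c: float = 5.0
    threshold: float = 0.5
    replicates: int = 25
    n_max: int = 150  # richness cap applied to both theory and simulation

    @property
    def ctx(self) -> ThermalContext:
        return ThermalContext(t_ref=self.t_ref_c + 273.15)

    @property
    def grid(self) -> np.ndarray:
        return default_temperature_grid(
            self.grid_start_c, self.grid_stop_c, self.grid_step_c
        )


def _sample_ensemble(
    intervals: dict, rng: np.random.Generator, max_retries: int
) -> tuple[EnsembleTPC, int]:
    """Uniform draw of one ensemble; redraw until the covariance is valid."""
    retries = 0
    while True:
        vals = {
            name: rng.uniform(*intervals[name]) for name in PARAM_NAMES
        }
        if vals["cov_b0e"] ** 2 <= vals["var_b0"] * vals["var_e"]:
            return EnsembleTPC(**vals), retries
        retries += 1
        if retries > max_retries:
            raise ValueError(
                "parameter ranges admit no valid covariance after "
                f"{max_retries} retries"
            )


def sample_parameter_sets(
    ranges: ParameterRanges,
    n_sets: int,
    rng: np.random.Generator,
    max_retries: int = 10_000,
) -> list[CommunityThermalParams]:
    """Draw ``n_sets`` community parameterisations (full a_ii ensemble mode).

    Parameter draws violating ``cov^2 <= var_b0 * var_e`` are resampled; the
    total resample count is logged.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    sets = []
    total_resamples = 0
    for _ in range(n_sets):
        r, k1 = _sample_ensemble(ranges.r, rng, max_retries)
        aij, k2 = _sample_ensemble(ranges.aij, rng, max_retries)
        aii, k3 = _sample_ensemble(ranges.aii, rng, max_retries)
        total_resamples += k1 + k2 + k3
        sets.append(CommunityThermalParams(growth=r, inter=aij, intra=aii))
    if total_resamples:
        logger.info(
            "resampled %d invalid covariance draws across %d sets",
            total_resamples,
            n_sets,
        )
    return sets


def normalized_rmse(predicted, simulated) -> float:
    """RMSE between curves divided by mean simulated richness (scale-free)."""
    pred = np.asarray(predicted, dtype=float)
    sim = np.asarray(simulated, dtype=float)
    if pred.shape != sim.shape or pred.size == 0:
        raise ValueError("series must be non-empty and of equal length")
    denom = sim.mean()
    if denom <= 0:
        raise ValueError("mean simulated richness must be positive")
    return float(np.sqrt(np.mean((pred - sim) ** 2)) / denom)


def _flatten_params(params: CommunityThermalParams) -> dict:
    out = {}
    for key, ens in (
        ("r", params.growth),
        ("aij", params.inter),
        ("aii", params.intra),
    ):
        for name in PARAM_NAMES:
            out[f"{key}_{name}"] = getattr(ens, name)
    return out


def parameter_error_correlations(records: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of each parameter column with the ``nrmse`` column.

    Columns with zero variance yield NaN (undefined correlation, reported as
    missing rather than guessed).
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records for correlations")
    rows = []
    for col in records.columns:
        if col == "nrmse":
            continue
        x = records[col].to_numpy(dtype=float)
        y = records["nrmse"].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rho = np.nan
        else:
            rho = pearsonr(x, y).statistic
        rows.append({"parameter": col, "rho": rho, "n_effective": len(records)})
    return pd.DataFrame(rows)


def run_sensitivity(
    ranges: ParameterRanges,
    n_sets: int,
    config: SensitivityConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full scan: sample parameter sets, compute per-set nRMSE, correlate.

    Returns ``(correlations, records)``; with fewer than 3 usable records the
    correlation table is empty (undefined).  Sets whose simulation degenerates
    (e.g. zero mean richness) are dropped and logged.
    """
    ctx, grid = config.ctx, config.grid
    sets = sample_parameter_sets(ranges, n_sets, rng)
    records = []
    n_dropped = 0
    for params in sets:
        try:
            import warnings as _warnings

            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")  # cap warnings expected here
                pred = analytic_richness_curve(
                    params, grid, ctx, config.threshold, n_max=config.n_max
                ).predicted_n
                sim = simulated_richness_curve(
                    params,
                    grid,
                    ctx,
                    threshold=config.threshold,
                    replicates=config.replicates,
                    rng=rng,
                    n_cap=config.n_max,
                )
            row = _flatten_params(params)
            row["nrmse"] = normalized_rmse(pred, sim)
            records.append(row)
        except (ValueError, np.linalg.LinAlgError) as exc:
            n_dropped += 1
            logger.warning("dropping degenerate parameter set: %s", exc)
    if n_dropped:
        logger.info("dropped %d of %d parameter sets", n_dropped, n_sets)
    records_df = pd.DataFrame(records)
    if len(records_df) >= 3:
        result_df = parameter_error_correlations(records_df)
    else:
        result_df = pd.DataFrame(columns=["parameter", "rho", "n_effective"])
    return result_df, records_df
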