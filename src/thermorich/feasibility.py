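"""Mean-field feasibility theory for competitive Lotka–Volterra communities.

An equilibrium of the generalized Lotka–Volterra (GLV) model is *feasible*
when every species has strictly positive abundance — a necessary condition
for coexistence.  Under a mean-field approximation (large community, weak and
weakly-correlated interactions) the equilibrium abundance of species *i* is

    x_i* = r_i / a_ii - (<r> / a_ii) * (N-1)<a> / (1 + (N-1)<a>)

with effective interspecific interaction strength
``<a> = <a_ij> * <1/a_ii>``.  Feasibility of species *i* reduces to its
relative growth rate ``r_i' = r_i / <r>`` exceeding the competition bound
``b = (N-1)<a> / (1 + (N-1)<a>)``, so the probability that an N-species
community is feasible is

    Pfeas(N) = [1 - F(b)]^N

where F is the CDF of the (log-normal) relative growth-rate distribution.
Setting a Pfeas threshold and scanning N yields the maximum feasible
richness; evaluating the trait distributions over a temperature grid yields
the temperature–richness curve.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .thermal import (
    EnsembleTPC,
    LogNormalTraitDist,
    ThermalContext,
    celsius_to_kelvin,
    kelvin_to_celsius,
    trait_distribution,
)

__all__ = [
    "CommunityThermalParams",
    "RichnessCurve",
    "relative_growth_distribution",
    "effective_interaction",
    "competition_bound",
    "feasibility_probability",
    "max_feasible_richness",
    "analytic_richness_curve",
    "mean_field_equilibrium",
    "default_temperature_grid",
]

DEFAULT_THRESHOLD = 0.5
DEFAULT_N_MAX = 10_000


class RichnessCapWarning(UserWarning):
    """Raised when a richness scan hits its upper cap (result is a lower bound)."""


@dataclass(frozen=True)
class CommunityThermalParams:
    """Thermal ensembles of the three GLV trait groups.

    ``growth`` parameterises r (time^-1 at t_ref), ``inter`` the
    interspecific a_ij (volume mass^-1 time^-1 at t_ref).  ``intra`` is either
    ``None`` — intraspecific strength fixed at the constant 1, the default —
    or an :class:`EnsembleTPC` for a_ii.
    """

    growth: EnsembleTPC
    inter: EnsembleTPC
    intra: EnsembleTPC | None = None


@dataclass(frozen=True)
class RichnessCurve:
    """Maximum feasible richness over a temperature grid."""

    temperatures: np.ndarray  # Kelvin
    predicted_n: np.ndarray  # integer species counts
    pfeas_threshold: float
    simulated_n: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.temperatures) != len(self.predicted_n):
            raise ValueError("grid and richness lengths differ")
        if not 0.0 < self.pfeas_threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")

    @property
    def temperatures_c(self) -> np.ndarray:
        return kelvin_to_celsius(np.asarray(self.temperatures))

    def peak(self) -> tuple[float, int, bool]:
        """(temperature_C, richness) at the argmax; ties go to the lower
        temperature and are reported by the boolean third element."""
        n = np.asarray(self.predicted_n)
        i = int(np.argmax(n))
        tied = int(np.sum(n == n[i])) > 1
        return float(self.temperatures_c[i]), int(n[i]), tied

    def to_frame(self):
        import pandas as pd

        data = {
            "temperature_C": np.round(self.temperatures_c, 10),
            "predicted_richness": np.asarray(self.predicted_n, dtype=int),
        }
        if self.simulated_n is not None:
            data["simulated_richness"] = np.asarray(self.simulated_n, dtype=int)
        return pd.DataFrame(data)


def default_temperature_grid(
    start_c: float = 0.0, stop_c: float = 40.0, step_c: float = 0.5
) -> np.ndarray:
    """Temperature grid in Kelvin, specified in Celsius (default 0–40 °C at 0.5 °C)."""
    n_steps = int(round((stop_c - start_c) / step_c))
    grid_c = start_c + step_c * np.arange(n_steps + 1)
    return celsius_to_kelvin(grid_c)


def relative_growth_distribution(r_dist: LogNormalTraitDist) -> LogNormalTraitDist:
    """Distribution of relative growth rate ``r_i' = r_i / <r>``.

    Dividing a log-normal by its mean shifts the log-mean to ``-var/2`` and
    leaves the variance unchanged, so ``E[r'] = 1`` exactly — the location of
    the growth ensemble cancels and only its variance matters for
    feasibility.
    """
    return LogNormalTraitDist(mu=-r_dist.var / 2.0, var=r_dist.var)


def effective_interaction(
    inter_dist: LogNormalTraitDist, intra: LogNormalTraitDist | None = None
) -> float:
    """Effective interspecific interaction strength ``<a> = <a_ij> <1/a_ii>``.

    With the default ``intra is None`` (a_ii = 1): ``exp(mu_ij + var_ij/2)``.
    With an intraspecific distribution the mean of the *inverse* of a_ii gives
    ``exp(mu_ij - mu_ii + (var_ij + var_ii)/2)``.
    """
    if intra is None:
        return math.exp(inter_dist.mu + inter_dist.var / 2.0)
    return math.exp(
        inter_dist.mu - intra.mu + (inter_dist.var + intra.var) / 2.0
    )


def competition_bound(n: int, mean_a: float) -> float:
    """Feasibility bound ``b = (N-1)<a> / (1 + (N-1)<a>)``; in [0, 1)."""
    s = (n - 1) * mean_a
    return s / (1.0 + s)


def feasibility_probability(
    n: int, mean_a: float, r_prime: LogNormalTraitDist
) -> float:
    """Probability that an N-species community is feasible.

    ``Pfeas = [P(r' > b)]^N`` with ``b = (N-1)<a>/(1+(N-1)<a>)`` and r'
    log-normal.  Equals 1 for N = 1 or <a> = 0; non-increasing in both N and
    <a>.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if mean_a < 0:
        raise ValueError("mean_a must be non-negative")
    b = competition_bound(n, mean_a)
    if b <= 0.0:
        return 1.0
    if r_prime.var == 0.0:
        # point mass at exp(mu); b < 1 always, and exp(mu) = 1 for relative rates
        p_single = 1.0 if math.exp(r_prime.mu) > b else 0.0
    else:
        z = (math.log(b) - r_prime.mu) / r_prime.sigma
        p_single = norm.sf(z)
    if p_single <= 0.0:
        return 0.0
    return float(math.exp(n * math.log(p_single)))


def max_feasible_richness(
    mean_a: float,
    r_prime: LogNormalTraitDist,
    threshold: float = DEFAULT_THRESHOLD,
    n_max: int = DEFAULT_N_MAX,
) -> int:
    """Largest N with ``Pfeas(N) >= threshold`` (binary search; Pfeas is
    non-increasing in N).  Always >= 1 since a single species is feasible.

    Warns with :class:`RichnessCapWarning` when the cap ``n_max`` is itself
    feasible, in which case the true maximum exceeds the returned value.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    if feasibility_probability(n_max, mean_a, r_prime) >= threshold:
        warnings.warn(
            f"richness scan hit cap n_max={n_max}; result is a lower bound",
            RichnessCapWarning,
            stacklevel=2,
        )
        return n_max
    lo, hi = 1, n_max  # invariant: Pfeas(lo) >= threshold > Pfeas(hi)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if feasibility_probability(mid, mean_a, r_prime) >= threshold:
            lo = mid
        else:
            hi = mid
    return lo


def temperature_slice(
    params: CommunityThermalParams, t: float, ctx: ThermalContext
) -> tuple[LogNormalTraitDist, float]:
    """Relative growth distribution and effective interaction at one temperature."""
    r_dist = trait_distribution(params.growth, t, ctx)
    r_prime = relative_growth_distribution(r_dist)
    a_dist = trait_distribution(params.inter, t, ctx)
    intra_dist = (
        None if params.intra is None else trait_distribution(params.intra, t, ctx)
    )
    return r_prime, effective_interaction(a_dist, intra_dist)


def analytic_richness_curve(
    params: CommunityThermalParams,
    grid: np.ndarray | None = None,
    ctx: ThermalContext | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    n_max: int = DEFAULT_N_MAX,
) -> RichnessCurve:
    """Predicted maximum feasible richness at each temperature of ``grid`` (Kelvin)."""
    ctx = ctx or ThermalContext()
    grid = default_temperature_grid() if grid is None else np.asarray(grid, dtype=float)
    richness = np.empty(len(grid), dtype=int)
    for i, t in enumerate(grid):
        r_prime, mean_a = temperature_slice(params, t, ctx)
        richness[i] = max_feasible_richness(mean_a, r_prime, threshold, n_max)
    return RichnessCurve(
        temperatures=grid, predicted_n=richness, pfeas_threshold=threshold
    )


def mean_field_equilibrium(
    r: np.ndarray, intra: np.ndarray | float, mean_a: float
) -> np.ndarray:
    """Mean-field equilibrium abundances.

    ``x_i* = r_i/a_ii - (<r>/a_ii) * (N-1)<a> / (1 + (N-1)<a>)`` — the
    carrying-capacity term minus the saturating competition term.  Negative
    components signal infeasibility.  With equal off-diagonal interactions and
    equal intraspecific strengths this is exact (matches the linear solve).
    """
    r = np.asarray(r, dtype=float)
    aii = np.broadcast_to(np.asarray(intra, dtype=float), r.shape)
    if np.any(aii <= 0):
        raise ValueError("intraspecific interaction strengths must be positive")
    n = len(r)
    b = competition_bound(n, mean_a)
    return r / aii - (r.mean() / aii) * b
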