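"""Monte-Carlo GLV communities: sampling, equilibria, feasibility estimates.

Validates the mean-field feasibility theory by brute force: draw whole
communities — a thermal performance curve per species for growth (and
optionally intraspecific strength) and one per ordered species pair for
interspecific interactions — realize the growth vector r and interaction
matrix A at each temperature, solve the equilibrium ``x* = A^-1 r``, and
count the fraction of replicates with all-positive abundances.  Scanning
community sizes and applying the same Pfeas threshold as the theory gives the
simulated maximum richness.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .feasibility import (
    CommunityThermalParams,
    RichnessCapWarning,
    RichnessCurve,
    analytic_richness_curve,
)
from .thermal import ThermalContext, inverse_temp_offset, sample_tpc_params

__all__ = [
    "CommunityRealization",
    "FeasibilityEstimate",
    "MeanFieldDiagnostics",
    "sample_community",
    "realize_at_temperature",
    "solve_equilibrium",
    "is_feasible",
    "estimate_pfeas",
    "simulated_max_richness",
    "simulated_richness_curve",
    "mean_field_diagnostics",
    "default_size_sweep",
]

logger = logging.getLogger(__name__)

DEFAULT_REPLICATES = 50  # replicate communities per (size, temperature)


@dataclass(frozen=True)
class CommunityRealization:
    """One sampled community: coherent TPC parameters for every entity.

    ``growth`` is ``(n, 2)`` (columns log_b0, e); ``inter`` is ``(n, n, 2)``
    with the diagonal unused; ``intra`` is ``(n, 2)`` or ``None`` for the
    constant-1 convention.  Drawn once, the same realization can be evaluated
    at any temperature so each species/pair keeps a coherent TPC across the
    whole gradient.
    """

    growth: np.ndarray
    inter: np.ndarray
    intra: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.growth.shape[0]


@dataclass(frozen=True)
class FeasibilityEstimate:
    """Monte-Carlo feasibility estimate at one (size, temperature)."""

    n: int
    t: float
    n_replicates: int
    n_feasible: int

    @property
    def pfeas_hat(self) -> float:
        return self.n_feasible / self.n_replicates


@dataclass(frozen=True)
class MeanFieldDiagnostics:
    """Community-mean interaction–abundance covariance structure.

    The mean-field theory neglects cov(a_ij, x_j); these diagnostics measure
    it on a realized community so the approximation can be audited.
    """

    cov_a_x: float
    corr_a_x: float
    var_x: float
    var_a: float


def sample_community(
    params: CommunityThermalParams, n: int, rng: np.random.Generator
) -> CommunityRealization:
    """Draw a community: per-species growth (and intra) TPCs, per-ordered-pair
    interaction TPCs (a_ij and a_ji independent; no imposed symmetry)."""
    if n < 2:
        raise ValueError("community size must be >= 2")
    growth = sample_tpc_params(params.growth, n, rng)
    pairs = sample_tpc_params(params.inter, n * (n - 1), rng)
    inter = np.zeros((n, n, 2))
    off = ~np.eye(n, dtype=bool)
    inter[off] = pairs
    intra = (
        None if params.intra is None else sample_tpc_params(params.intra, n, rng)
    )
    return CommunityRealization(growth=growth, inter=inter, intra=intra)


def realize_at_temperature(
    c: CommunityRealization, t: float, ctx: ThermalContext
) -> tuple[np.ndarray, np.ndarray]:
    """Growth vector r and interaction matrix A at temperature ``t`` (Kelvin)."""
    x = inverse_temp_offset(t, ctx)
    r = np.exp(c.growth[:, 0] - c.growth[:, 1] * x)
    a = np.exp(c.inter[..., 0] - c.inter[..., 1] * x)
    if c.intra is None:
        np.fill_diagonal(a, 1.0)
    else:
        np.fill_diagonal(a, np.exp(c.intra[:, 0] - c.intra[:, 1] * x))
    return r, a


def solve_equilibrium(
    r: np.ndarray, a: np.ndarray
) -> tuple[np.ndarray | None, float]:
    """Solve ``A x = r``; returns (x, relative residual) or (None, inf) on a
    singular/non-finite solve (the replicate then counts as infeasible)."""
    try:
        x = np.linalg.solve(a, r)
    except np.linalg.LinAlgError:
        logger.warning("singular interaction matrix; counting replicate infeasible")
        return None, np.inf
    if not np.all(np.isfinite(x)):
        logger.warning("non-finite equilibrium; counting replicate infeasible")
        return None, np.inf
    resid = float(np.linalg.norm(a @ x - r) / max(np.linalg.norm(r), 1e-300))
    return x, resid


def is_feasible(x: np.ndarray | None) -> bool:
    """Strict positivity of every equilibrium abundance."""
    if x is None:
        return False
    x = np.asarray(x)
    if not np.all(np.isfinite(x)):
        warnings.warn("non-finite abundances treated as infeasible", stacklevel=2)
        return False
    return bool(np.all(x > 0.0))


def estimate_pfeas(
    params: CommunityThermalParams,
    n: int,
    t: float,
    ctx: ThermalContext,
    replicates: int = DEFAULT_REPLICATES,
    rng: np.random.Generator | None = None,
) -> FeasibilityEstimate:
    """Proportion of fresh replicate communities of size ``n`` feasible at ``t``."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = rng or np.random.default_rng()
    n_feasible = 0
    for _ in range(replicates):
        c = sample_community(params, n, rng)
        r, a = realize_at_temperature(c, t, ctx)
        x, _ = solve_equilibrium(r, a)
        n_feasible += is_feasible(x)
    return FeasibilityEstimate(
        n=n, t=t, n_replicates=replicates, n_feasible=n_feasible
    )


def default_size_sweep(
    predicted: np.ndarray | int,
    per_point: int = 12,
    window: tuple[float, float] = (0.55, 1.6),
    n_cap: int | None = None,
) -> np.ndarray:
    """Candidate community sizes: union of windows around analytic predictions.

    For each predicted richness the window spans ``window[0]*pred`` to
    ``max(pred+3, window[1]*pred)`` in ~``per_point`` integer steps (always at
    least up to 10), giving ~8% resolution near each prediction without
    sweeping every size from 2 to the global maximum.
    """
    preds = np.atleast_1d(np.asarray(predicted, dtype=float))
    sizes: set[int] = {2}
    for p in preds:
        lo = max(2.0, window[0] * p)
        hi = max(p + 3.0, window[1] * p, 10.0)
        if n_cap is not None:
            hi = min(hi, float(n_cap))
            lo = min(lo, hi)
        sizes.update(int(v) for v in np.linspace(lo, hi, per_point).round())
    return np.array(sorted(s for s in sizes if s >= 2), dtype=int)


def simulated_richness_curve(
    params: CommunityThermalParams,
    grid: np.ndarray,
    ctx: ThermalContext,
    threshold: float = 0.5,
    replicates: int = DEFAULT_REPLICATES,
    n_sweep: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    coherent: bool = True,
    n_cap: int | None = None,
) -> np.ndarray:
    """Simulated maximum richness at each grid temperature.

    For every candidate size, ``replicates`` communities are drawn; in the
    default coherent mode each realization is evaluated across the whole
    temperature grid (every species/pair keeps one TPC along the gradient).
    With ``coherent=False`` fresh communities are drawn per temperature
    instead.  Per temperature, the largest candidate size whose feasible
    fraction meets ``threshold`` is reported (1 when none does).
    """
    rng = rng or np.random.default_rng()
    grid = np.asarray(grid, dtype=float)
    if n_sweep is None:
        pred = analytic_richness_curve(
            params, grid, ctx, threshold, n_max=n_cap or 10_000
        ).predicted_n
        n_sweep = default_size_sweep(pred, n_cap=n_cap)
    n_sweep = np.asarray(n_sweep, dtype=int)
    if len(n_sweep) == 0 or np.any(np.diff(n_sweep) <= 0):
        raise ValueError("n_sweep must be a non-empty strictly increasing set")

    pfeas = np.zeros((len(n_sweep), len(grid)))
    for i, n in enumerate(n_sweep):
        feasible = np.zeros(len(grid), dtype=int)
        for _ in range(replicates):
            if coherent:
                c = sample_community(params, int(n), rng)
            for j, t in enumerate(grid):
                if not coherent:
                    c = sample_community(params, int(n), rng)
                r, a = realize_at_temperature(c, t, ctx)
                x, _ = solve_equilibrium(r, a)
                feasible[j] += is_feasible(x)
        pfeas[i] = feasible / replicates

    result = np.ones(len(grid), dtype=int)
    for j in range(len(grid)):
        ok = np.nonzero(pfeas[:, j] >= threshold)[0]
        if len(ok):
            result[j] = int(n_sweep[ok[-1]])
            if ok[-1] == len(n_sweep) - 1:
                warnings.warn(
                    "top of size sweep still feasible; simulated richness is "
                    "a lower bound",
                    RichnessCapWarning,
                    stacklevel=2,
                )
    return result


def simulated_max_richness(
    params: CommunityThermalParams,
    t: float,
    ctx: ThermalContext,
    threshold: float = 0.5,
    replicates: int = DEFAULT_REPLICATES,
    n_sweep: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> int:
    """Largest candidate size meeting the Pfeas threshold at one temperature."""
    return int(
        simulated_richness_curve(
            params,
            np.array([t]),
            ctx,
            threshold=threshold,
            replicates=replicates,
            n_sweep=n_sweep,
            rng=rng,
        )[0]
    )


def merged_richness_curve(
    params: CommunityThermalParams,
    grid: np.ndarray,
    ctx: ThermalContext,
    threshold: float = 0.5,
    replicates: int = DEFAULT_REPLICATES,
    rng: np.random.Generator | None = None,
    n_max: int = 10_000,
) -> RichnessCurve:
    """Analytic prediction and simulated richness on a shared grid."""
    analytic = analytic_richness_curve(params, grid, ctx, threshold, n_max)
    simulated = simulated_richness_curve(
        params, grid, ctx, threshold=threshold, replicates=replicates, rng=rng
    )
    return RichnessCurve(
        temperatures=np.asarray(grid, dtype=float),
        predicted_n=analytic.predicted_n,
        pfeas_threshold=threshold,
        simulated_n=simulated,
    )


def mean_field_diagnostics(
    c: CommunityRealization, t: float, ctx: ThermalContext
) -> MeanFieldDiagnostics:
    """Interaction–abundance covariance averaged over focal species.

    For each focal species i, the covariance/correlation between its row of
    interspecific strengths a_ij (j != i) and the partner abundances x_j at
    the feasible equilibrium.  Small |corr| is the regime where the mean-field
    closure is trustworthy.
    """
    r, a = realize_at_temperature(c, t, ctx)
    x, _ = solve_equilibrium(r, a)
    if not is_feasible(x):
        raise ValueError("diagnostics require a feasible equilibrium")
    n = c.n
    covs, corrs, vxs, vas = [], [], [], []
    for i in range(n):
        mask = np.arange(n) != i
        ai = a[i, mask]
        xi = x[mask]
        cov = float(np.cov(ai, xi, bias=True)[0, 1])
        va, vx = float(ai.var()), float(xi.var())
        covs.append(cov)
        vas.append(va)
        vxs.append(vx)
        if va > 0 and vx > 0:
            corrs.append(cov / np.sqrt(va * vx))
    return MeanFieldDiagnostics(
        cov_a_x=float(np.mean(covs)),
        corr_a_x=float(np.mean(corrs)) if corrs else 0.0,
        var_x=float(np.mean(vxs)),
        var_a=float(np.mean(vas)),
    )
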