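"""Boltzmann–Arrhenius thermal performance and community-level trait distributions.

A metabolic trait (growth rate, interaction strength) of a mesophile rises
approximately exponentially with temperature inside its operational temperature
range:

    B(T) = B0 * exp(-E * (1/kT - 1/kTref))

where ``B0`` is the trait value at the reference temperature ``Tref``, ``E``
(eV) is the thermal sensitivity, and ``k`` is Boltzmann's constant in eV/K.
Across a community, ``log B0`` and ``E`` are modelled as a bivariate normal;
propagating that variation through the Boltzmann–Arrhenius equation makes the
trait log-normal at every temperature, with a mean that is linear and a
variance that is quadratic in the inverse-temperature offset
``x = 1/kT - 1/kTref``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: Boltzmann constant in eV per Kelvin.
BOLTZMANN_EV = 8.617e-5

#: 0 degrees Celsius in Kelvin.
ZERO_C = 273.15


def celsius_to_kelvin(t_c):
    """Convert Celsius to Kelvin (scalar or array)."""
    return np.asarray(t_c, dtype=float) + ZERO_C if np.ndim(t_c) else float(t_c) + ZERO_C


def kelvin_to_celsius(t_k):
    """Convert Kelvin to Celsius (scalar or array)."""
    return np.asarray(t_k, dtype=float) - ZERO_C if np.ndim(t_k) else float(t_k) - ZERO_C


@dataclass(frozen=True)
class ThermalContext:
    """Reference temperature and Boltzmann constant shared by all thermal maps.

    Parameters
    ----------
    t_ref
        Reference temperature in Kelvin at which ``B0`` is defined.
        Default 286.15 K (13 °C), the centre of the operational temperature
        range of typical mesophilic bacteria.
    """

    t_ref: float = 286.15
    k: float = BOLTZMANN_EV

    def __post_init__(self) -> None:
        if not self.t_ref > 0:
            raise ValueError(f"t_ref must be positive Kelvin, got {self.t_ref}")


@dataclass(frozen=True)
class ArrheniusParams:
    """TPC parameters of a single entity: ``log_b0`` (log trait at t_ref) and ``e`` (eV)."""

    log_b0: float
    e: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.log_b0) and math.isfinite(self.e)):
            raise ValueError("log_b0 and e must be finite")


@dataclass(frozen=True)
class EnsembleTPC:
    """Bivariate-normal distribution of ``(log B0, E)`` across a community.

    ``cov_b0e`` is typically negative for growth rates (thermal
    specialist–generalist trade-off: narrow-range high performers versus
    broad-range low performers).
    """

    mu_b0: float
    mu_e: float
    var_b0: float
    var_e: float
    cov_b0e: float = 0.0

    def __post_init__(self) -> None:
        if self.var_b0 < 0 or self.var_e < 0:
            raise ValueError("variances must be non-negative")
        # valid 2x2 covariance matrix (PSD), with a small numerical slack
        if self.cov_b0e**2 > self.var_b0 * self.var_e * (1 + 1e-12) + 1e-300:
            raise ValueError(
                "invalid covariance: cov_b0e^2 must not exceed var_b0 * var_e"
            )

    @property
    def mean(self) -> np.ndarray:
        return np.array([self.mu_b0, self.mu_e])

    @property
    def cov(self) -> np.ndarray:
        return np.array(
            [[self.var_b0, self.cov_b0e], [self.cov_b0e, self.var_e]]
        )


@dataclass(frozen=True)
class LogNormalTraitDist:
    """Distribution of a trait at one temperature: ``log B ~ N(mu, var)``."""

    mu: float
    var: float

    def __post_init__(self) -> None:
        if self.var < 0:
            raise ValueError("var must be non-negative")

    @property
    def sigma(self) -> float:
        return math.sqrt(self.var)

    def mean(self) -> float:
        """Mean of the log-normal trait, ``exp(mu + var/2)``."""
        return math.exp(self.mu + self.var / 2.0)

    def median(self) -> float:
        return math.exp(self.mu)


def inverse_temp_offset(t, ctx: ThermalContext):
    """Inverse thermal-energy offset ``x = 1/kT - 1/kTref`` in eV^-1.

    Negative for temperatures above the reference; scalar or array ``t``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr <= 0):
        raise ValueError("temperature must be positive Kelvin")
    out = 1.0 / (ctx.k * t_arr) - 1.0 / (ctx.k * ctx.t_ref)
    return out if out.ndim else float(out)


def arrhenius_value(p: ArrheniusParams, t, ctx: ThermalContext):
    """Boltzmann–Arrhenius trait value ``exp(log_b0 - e * x)`` at temperature ``t``."""
    x = inverse_temp_offset(t, ctx)
    return np.exp(p.log_b0 - p.e * np.asarray(x)) if np.ndim(x) else math.exp(
        p.log_b0 - p.e * x
    )


def trait_distribution(ens: EnsembleTPC, t, ctx: ThermalContext) -> LogNormalTraitDist:
    """Temperature-specific log-normal trait distribution induced by an ensemble.

    ``mu(T) = mu_b0 - mu_e * x`` and
    ``var(T) = var_b0 + var_e * x^2 - 2 * cov_b0e * x`` with
    ``x = 1/kT - 1/kTref``.  The variance is a convex quadratic in ``x`` and is
    non-negative everywhere whenever the ensemble covariance matrix is valid.
    """
    x = inverse_temp_offset(t, ctx)
    mu = ens.mu_b0 - ens.mu_e * x
    var = ens.var_b0 + ens.var_e * x * x - 2.0 * ens.cov_b0e * x
    # guard tiny negative round-off at the PSD boundary
    return LogNormalTraitDist(mu=mu, var=max(var, 0.0))


def mean_trait(ens: EnsembleTPC, t, ctx: ThermalContext) -> float:
    """Community-mean trait value at ``t``: log-normal mean ``exp(mu + var/2)``."""
    return trait_distribution(ens, t, ctx).mean()


def min_variance_offset(ens: EnsembleTPC, ctx: ThermalContext | None = None):
    """Offset (and temperature) of minimum across-species trait variance.

    The variance quadratic ``var_b0 + var_e x^2 - 2 cov_b0e x`` has its vertex
    at ``x* = cov_b0e / var_e``.  Negative covariance places the minimum at
    ``x* < 0``, i.e. warmer than the reference temperature.

    Returns
    -------
    x_star, t_star
        ``t_star`` is ``None`` when no context is supplied.

    Raises
    ------
    ValueError
        If ``var_e == 0`` (variance is linear/constant; no interior minimum).
    """
    if ens.var_e <= 0:
        raise ValueError("no interior variance minimum when var_e = 0")
    x_star = ens.cov_b0e / ens.var_e
    if ctx is None:
        return x_star, None
    inv_kt = 1.0 / (ctx.k * ctx.t_ref) + x_star
    if inv_kt <= 0:
        raise ValueError("variance minimum lies outside the physical temperature range")
    return x_star, 1.0 / (ctx.k * inv_kt)


def unimodality_condition(ens: EnsembleTPC) -> bool:
    """Whether sensitivity variation suffices for a unimodal mean trait.

    True iff ``var_e > mu_e + cov_b0e``: the quadratic (variance) term of the
    log-normal mean dominates the linear (mean) term over an ecologically
    relevant offset range, producing a non-monotone community-mean trait.
    """
    return ens.var_e > ens.mu_e + ens.cov_b0e


def sample_tpc_params(
    ens: EnsembleTPC, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` (log_b0, e) pairs from the ensemble's bivariate normal.

    Returns an ``(n, 2)`` array with columns ``log_b0`` and ``e``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return rng.multivariate_normal(ens.mean, ens.cov, size=n, method="svd")
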