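"""Built-in community parameterisations.

``experimental``
    Bivariate-normal MLE estimates from refitted TPCs of experimentally
    measured soil-bacteria growth rates: strong B0 variance and a pronounced
    thermal generalist–specialist trade-off (negative cov).
``synthesis``
    Estimates from a broad literature synthesis of prokaryotic growth TPCs:
    similar B0 variance, weaker sensitivity variance and covariance.
``fig2_baseline``
    The modest-variation baseline used for theory–simulation comparisons.

All presets apply the same thermal ensemble to growth and interspecific
interactions, shifted to normalisation constants mu_r0 = 0.0 and
mu_a0 = -5.0 (keeping simulated richness magnitudes tractable), with
intraspecific strength fixed at 1.  Reference temperature: 13 °C.
"""

from __future__ import annotations

from dataclasses import replace

from .feasibility import CommunityThermalParams
from .thermal import EnsembleTPC, ThermalContext

__all__ = ["ENSEMBLES", "community_preset", "preset_context", "PRESET_NAMES"]

MU_R0 = 0.0
MU_A0 = -5.0
T_REF_C = 13.0

ENSEMBLES = {
    "experimental": EnsembleTPC(
        mu_b0=0.0, mu_e=1.0, var_b0=0.95, var_e=0.25, cov_b0e=-0.42
    ),
    "synthesis": EnsembleTPC(
        mu_b0=0.0, mu_e=0.82, var_b0=1.0, var_e=0.11, cov_b0e=-0.1
    ),
    "fig2_baseline": EnsembleTPC(
        mu_b0=0.0, mu_e=0.6, var_b0=0.2, var_e=0.01, cov_b0e=0.0
    ),
}

PRESET_NAMES = tuple(ENSEMBLES)


def community_preset(name: str) -> CommunityThermalParams:
    """Community parameters for a named preset (intraspecific strength = 1)."""
    try:
        base = ENSEMBLES[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}"
        ) from None
    return CommunityThermalParams(
        growth=replace(base, mu_b0=MU_R0),
        inter=replace(base, mu_b0=MU_A0),
        intra=None,
    )


def preset_context() -> ThermalContext:
    """Reference thermal context used by all presets (Tref = 13 °C)."""
    return ThermalContext(t_ref=T_REF_C + 273.15)
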