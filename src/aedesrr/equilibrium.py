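"""Closed-form wild-type equilibrium of the single-genotype model.

With every transgenic compartment empty the dynamics reduce to one juvenile
class J and one adult class of each sex:

    dJ/dt = lam * F - (mu_J + alpha * J^(beta-1) + nu) * J
    dM/dt = (nu/2) * J - mu_M * M
    dF/dt = (nu/2) * J - mu_F * F

At a positive fixed point F = nu * J / (2 mu_F), so the per-capita balance
for juveniles reads

    lam * nu / (2 mu_F) = mu_J + nu + alpha * J^(beta-1)

which has a (unique) positive root exactly when the density-independent net
reproduction lam * nu / (2 mu_F) exceeds the density-independent loss rate
mu_J + nu.  Release magnitudes are anchored to the analytic M_star so that
the forcing is reproducible and independent of solver settings.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .genetics import N_GENOTYPES, WILDTYPE_POSITION
from .params import ParamSet

__all__ = [
    "Equilibrium",
    "NoPositiveEquilibriumError",
    "wildtype_equilibrium",
    "equilibrium_state",
]


class NoPositiveEquilibriumError(ValueError):
    """Raised when the wild-type population is not self-sustaining."""


@dataclass(frozen=True)
class Equilibrium:
    """Wild-type equilibrium densities (model density units)."""

    J_star: float
    M_star: float
    F_star: float

    def to_dict(self) -> dict:
        return asdict(self)


def wildtype_equilibrium(params: ParamSet) -> Equilibrium:
    """Solve the wild-type equilibrium in closed form.

    Raises
    ------
    NoPositiveEquilibriumError
        If ``lam * nu / (2 mu_F) <= mu_J + nu`` (no positive root).
    """
    net = params.lam * params.nu / (2.0 * params.mu_F) - params.mu_J - params.nu
    if net <= 0.0:
        raise NoPositiveEquilibriumError(
            "no positive wild-type equilibrium: net reproduction "
            f"lam*nu/(2*mu_F) = {params.lam * params.nu / (2 * params.mu_F):.6g} "
            f"does not exceed density-independent losses mu_J + nu = "
            f"{params.mu_J + params.nu:.6g}"
        )
    if params.alpha <= 0.0:
        raise NoPositiveEquilibriumError(
            "alpha must be positive for a finite equilibrium"
        )
    J_star = (net / params.alpha) ** (1.0 / (params.beta - 1.0))
    M_star = params.nu * J_star / (2.0 * params.mu_M)
    F_star = params.nu * J_star / (2.0 * params.mu_F)
    return Equilibrium(J_star=J_star, M_star=M_star, F_star=F_star)


def equilibrium_state(params: ParamSet) -> np.ndarray:
    """Full 27-component state vector with all density in wild-type kkaa."""
    eq = wildtype_equilibrium(params)
    y = np.zeros(3 * N_GENOTYPES)
    y[WILDTYPE_POSITION] = eq.J_star
    y[N_GENOTYPES + WILDTYPE_POSITION] = eq.M_star
    y[2 * N_GENOTYPES + WILDTYPE_POSITION] = eq.F_star
    return y
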