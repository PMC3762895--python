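"""Demographic and genetic parameters of the release model.

All rates are per capita per day; densities are in the model's abstract
density unit (outputs are reported relative to the pre-release baseline, so
the absolute unit never matters).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

__all__ = ["ParamSet"]


@dataclass(frozen=True)
class ParamSet:
    """Parameter set with field-level validation.

    Attributes
    ----------
    mu_J : float
        Density-independent juvenile mortality rate (day^-1).
    mu_M : float
        Adult male mortality rate (day^-1).
    mu_F : float
        Adult female mortality rate (day^-1).
    lam : float
        Per-capita rate at which females produce larvae (day^-1).
    nu : float
        Per-capita juvenile emergence rate (day^-1).
    alpha : float
        Scale of density-dependent juvenile mortality alpha * J^(beta-1).
    beta : float
        Exponent of density-dependent mortality; must exceed 1.  Larger
        beta means stronger regulation and faster recovery after
        perturbation.
    c_K, c_A : float
        Homozygote egg-viability costs of the FK and AP transgenes, in
        [0, 1].
    """

    mu_J: float = 0.03
    mu_M: float = 0.28
    mu_F: float = 0.10
    lam: float = 8.0
    nu: float = 0.14
    alpha: float = 2e-4
    beta: float = 3.4
    c_K: float = 0.0
    c_A: float = 0.0

    def __post_init__(self) -> None:
        errors = []
        for name in ("mu_J", "mu_M", "mu_F", "lam", "nu", "alpha"):
            v = getattr(self, name)
            if not v >= 0.0:
                errors.append(f"{name}={v!r} must be >= 0")
        if not self.beta > 1.0:
            errors.append(f"beta={self.beta!r} must be > 1")
        for name in ("c_K", "c_A"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                errors.append(f"{name}={v!r} must lie in [0, 1]")
        if errors:
            raise ValueError("invalid parameters: " + "; ".join(errors))

    def replace(self, **changes) -> "ParamSet":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
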