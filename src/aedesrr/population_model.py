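"""Genotype-structured ODE model of an *Aedes aegypti* population.

The state holds 27 densities: juveniles J_i, adult males M_i and adult
females F_i for each of the nine two-locus genotypes (canonical order, see
:mod:`aedesrr.genetics`).  The dynamics are

    dJ_i/dt = B_i - (mu_J + alpha * J_tot^(beta-1) + nu) * J_i  [+ iota * J_star for kkaa]
    dM_i/dt = (nu/2) * J_i - mu_M * M_i + R_M,i(t)
    dF_i/dt = gamma_i * (nu/2) * J_i - mu_F * F_i + R_F,i(t)

with a 1:1 sex ratio at birth and female-killing lethality applied at adult
emergence through the viability coefficient gamma_i.  Larval production under
random mating is

    B_i = w_i * lam * sum_m sum_n F_m * (M_n / sum_k M_k) * Pr(i | m, n)

i.e. males contribute in proportion to their frequency (female reproduction
is not male-limited); if no males are present no larvae are produced.
Density-dependent juvenile mortality acts on the total juvenile density
across genotypes — larval competition is genotype-blind.

Release forcing is piecewise constant, so :func:`simulate` integrates
segment by segment, restarting the stiff solver at each forcing
discontinuity; within a segment the forcing is exactly constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import genetics
from .equilibrium import Equilibrium, equilibrium_state, wildtype_equilibrium
from .genetics import (
    GENOTYPE_LABELS,
    N_GENOTYPES,
    VIABLE_POSITIONS,
    WILDTYPE_POSITION,
    build_inheritance_tensor,
    fitness_vector,
    viability_vector,
)
from .params import ParamSet
from .scenarios import ReleaseSchedule

__all__ = [
    "ImmigrationConfig",
    "SimulationError",
    "Trajectory",
    "birth_rates",
    "derivatives",
    "simulate",
]

_J = slice(0, N_GENOTYPES)
_M = slice(N_GENOTYPES, 2 * N_GENOTYPES)
_F = slice(2 * N_GENOTYPES, 3 * N_GENOTYPES)

#: Solver defaults: trajectories are inspected over many orders of magnitude
#: on log-scale plots, so tolerances are tight.
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10
DEFAULT_METHOD = "LSODA"

_NEGATIVE_TOL = -1e-6


class SimulationError(RuntimeError):
    """Raised when integration fails or produces an invalid state."""


@dataclass(frozen=True)
class ImmigrationConfig:
    """Wild-type juvenile immigration.

    ``iota`` is the daily influx expressed as a fraction of the equilibrium
    juvenile density; immigrants enter the kkaa juvenile compartment and are
    subject to the same density-dependent mortality as residents.
    """

    iota: float = 0.0

    def __post_init__(self) -> None:
        if self.iota < 0:
            raise ValueError(f"immigration fraction iota={self.iota!r} must be >= 0")


def birth_rates(
    F: np.ndarray,
    M: np.ndarray,
    tensor: np.ndarray,
    w: np.ndarray,
    lam: float,
) -> np.ndarray:
    """Per-genotype larval production rates B_i under random mating.

    Negative inputs (solver undershoot) are clamped to zero; with no males
    present all rates are zero.
    """
    F = np.maximum(np.asarray(F, dtype=float), 0.0)
    M = np.maximum(np.asarray(M, dtype=float), 0.0)
    M_tot = M.sum()
    if M_tot <= 0.0:
        return np.zeros(N_GENOTYPES)
    p = M / M_tot
    # offspring pool: mothers by density, fathers by frequency
    mates = tensor @ p  # (i, m)
    return w * lam * (mates @ F)


@dataclass
class _Context:
    """Precomputed quantities shared by every right-hand-side evaluation."""

    params: ParamSet
    tensor: np.ndarray
    w: np.ndarray
    gamma: np.ndarray
    forcing: np.ndarray  # constant 27-vector for the current segment


def _rhs(t: float, y: np.ndarray, ctx: _Context) -> np.ndarray:
    if not np.all(np.isfinite(y)):
        raise SimulationError(f"non-finite state encountered at t={t:.3f}")
    p = ctx.params
    J = y[_J]
    M = y[_M]
    F = y[_F]
    B = birth_rates(F, M, ctx.tensor, ctx.w, p.lam)
    J_tot = max(float(J.sum()), 0.0)
    loss = p.mu_J + p.alpha * J_tot ** (p.beta - 1.0) + p.nu
    dy = np.empty_like(y)
    dy[_J] = B - loss * J
    dy[_M] = 0.5 * p.nu * J - p.mu_M * M
    dy[_F] = ctx.gamma * (0.5 * p.nu) * J - p.mu_F * F
    return dy + ctx.forcing


def _forcing_vector(
    t: float,
    schedule: Optional[ReleaseSchedule],
    immigration: ImmigrationConfig,
    J_star: float,
) -> np.ndarray:
    """Constant forcing in effect at time ``t`` (release + immigration)."""
    f = np.zeros(3 * N_GENOTYPES)
    f[WILDTYPE_POSITION] = immigration.iota * J_star
    if schedule is not None:
        male_rate, female_rate = schedule.rates(t)
        pos = schedule.strain_position
        f[N_GENOTYPES + pos] += male_rate
        f[2 * N_GENOTYPES + pos] += female_rate
    return f


def derivatives(
    t: float,
    state: np.ndarray,
    params: ParamSet,
    schedule: Optional[ReleaseSchedule] = None,
    immigration: Optional[ImmigrationConfig] = None,
    equilibrium: Optional[Equilibrium] = None,
) -> np.ndarray:
    """ODE right-hand side at one time point (convenience wrapper).

    :func:`simulate` precomputes the shared quantities once; this wrapper
    rebuilds them on each call and is intended for inspection and testing.
    """
    immigration = immigration or ImmigrationConfig()
    if equilibrium is None and immigration.iota > 0:
        equilibrium = wildtype_equilibrium(params)
    J_star = equilibrium.J_star if equilibrium is not None else 0.0
    ctx = _Context(
        params=params,
        tensor=build_inheritance_tensor(),
        w=fitness_vector(params.c_K, params.c_A),
        gamma=viability_vector(),
        forcing=_forcing_vector(t, schedule, immigration, J_star),
    )
    return _rhs(t, np.asarray(state, dtype=float), ctx)


@dataclass
class Trajectory:
    """Time-indexed states plus the configuration that produced them."""

    times: np.ndarray  # (n_t,) days, strictly increasing
    states: np.ndarray  # (n_t, 27)
    params: ParamSet
    schedule: Optional[ReleaseSchedule]
    immigration: ImmigrationConfig
    equilibrium: Equilibrium
    baseline_female: float  # total adult female density at t = 0
    solver: dict = field(default_factory=dict)

    @property
    def J(self) -> np.ndarray:
        return self.states[:, _J]

    @property
    def M(self) -> np.ndarray:
        return self.states[:, _M]

    @property
    def F(self) -> np.ndarray:
        return self.states[:, _F]

    def total_female(self) -> np.ndarray:
        return np.maximum(self.F, 0.0).sum(axis=1)

    def native_female(self) -> np.ndarray:
        """Females of emergence-viable genotypes (excludes released females).

        Released females carry the FK transgene (gamma = 0 genotypes), which
        can never appear in the female pool through emergence, so genotype
        alone separates released from native females.
        """
        return np.maximum(self.F[:, list(VIABLE_POSITIONS)], 0.0).sum(axis=1)

    def total_juvenile(self) -> np.ndarray:
        return np.maximum(self.J, 0.0).sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy long-format table: time, stage, genotype, density."""
        frames = []
        for stage, block in (("J", self.J), ("M", self.M), ("F", self.F)):
            df = pd.DataFrame(block, columns=list(GENOTYPE_LABELS))
            df.insert(0, "time", self.times)
            df = df.melt(id_vars="time", var_name="genotype", value_name="density")
            df.insert(1, "stage", stage)
            frames.append(df)
        out = pd.concat(frames, ignore_index=True)
        return out.sort_values(["time", "stage", "genotype"], ignore_index=True)

    def metadata(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "schedule": self.schedule.to_dict() if self.schedule else None,
            "immigration": self.immigration.iota,
            "equilibrium": self.equilibrium.to_dict(),
            "baseline_female": self.baseline_female,
            "solver": self.solver,
        }


def simulate(
    params: Optional[ParamSet] = None,
    schedule: Optional[ReleaseSchedule] = None,
    immigration: Optional[ImmigrationConfig] = None,
    t_final: float = 1000.0,
    dt: float = 1.0,
    t_eval: Optional[np.ndarray] = None,
    y0: Optional[np.ndarray] = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = DEFAULT_METHOD,
) -> Trajectory:
    """Integrate the model from the wild-type equilibrium (or ``y0``).

    The integration is split at the release window boundaries so the
    discontinuous forcing never falls inside one solver step.  States are
    returned on a daily grid (``dt``) unless an explicit ``t_eval`` is given.

    Raises
    ------
    SimulationError
        On solver failure or if any output component drops below -1e-6
        (well beyond the expected solver undershoot).
    """
    params = params or ParamSet()
    immigration = immigration or ImmigrationConfig()
    if t_final <= 0:
        raise ValueError("t_final must be positive")
    eq = wildtype_equilibrium(params)
    if y0 is None:
        y0 = equilibrium_state(params)
    else:
        y0 = np.asarray(y0, dtype=float)
        if y0.shape != (3 * N_GENOTYPES,):
            raise ValueError(f"y0 must have shape (27,), got {y0.shape}")

    if t_eval is None:
        t_eval = np.arange(0.0, t_final + 0.5 * dt, dt)
        t_eval[-1] = min(t_eval[-1], t_final)
    t_eval = np.unique(np.asarray(t_eval, dtype=float))
    if t_eval[0] < 0 or t_eval[-1] > t_final:
        raise ValueError("t_eval must lie within [0, t_final]")

    breaks = {0.0, float(t_final)}
    # a zero-rate schedule forces nothing; skipping its breakpoints keeps the
    # run bit-identical to the no-release control
    if schedule is not None and (schedule.male_rate > 0 or schedule.female_rate > 0):
        for b in schedule.breakpoints():
            if 0.0 < b < t_final:
                breaks.add(float(b))
    breaks = sorted(breaks)

    tensor = build_inheritance_tensor()
    w = fitness_vector(params.c_K, params.c_A)
    gamma = viability_vector()

    times = [0.0]
    states = [y0.copy()]
    y = y0.copy()
    for a, b in zip(breaks[:-1], breaks[1:]):
        ctx = _Context(
            params=params,
            tensor=tensor,
            w=w,
            gamma=gamma,
            forcing=_forcing_vector(0.5 * (a + b), schedule, immigration, eq.J_star),
        )
        seg_eval = t_eval[(t_eval > a) & (t_eval < b)]
        seg_eval = np.append(seg_eval, b)
        sol = solve_ivp(
            _rhs,
            (a, b),
            y,
            method=method,
            t_eval=seg_eval,
            rtol=rtol,
            atol=atol,
            args=(ctx,),
        )
        if not sol.success:
            raise SimulationError(
                f"solver failed on segment [{a:.3f}, {b:.3f}]: {sol.message}; "
                f"last state min={y.min():.3e}, max={y.max():.3e}"
            )
        y = sol.y[:, -1].copy()
        keep = sol.t < b if b not in t_eval else np.ones_like(sol.t, dtype=bool)
        times.extend(sol.t[keep])
        states.extend(sol.y[:, keep].T)

    times_arr = np.asarray(times)
    order = np.argsort(times_arr)
    times_arr = times_arr[order]
    states_arr = np.asarray(states)[order]
    # keep only requested output times (0 always included)
    mask = np.isin(times_arr, np.union1d(t_eval, [0.0]))
    times_arr = times_arr[mask]
    states_arr = states_arr[mask]

    min_component = float(states_arr.min())
    if min_component < _NEGATIVE_TOL:
        t_bad = float(times_arr[np.argmin(states_arr.min(axis=1))])
        raise SimulationError(
            f"state component {min_component:.3e} below tolerance at t={t_bad:.1f}"
        )

    return Trajectory(
        times=times_arr,
        states=states_arr,
        params=params,
        schedule=schedule,
        immigration=immigration,
        equilibrium=eq,
        baseline_female=float(np.maximum(y0[_F], 0.0).sum()),
        solver={"method": method, "rtol": rtol, "atol": atol},
    )
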