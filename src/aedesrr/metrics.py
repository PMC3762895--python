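"""Derived outcomes: relative densities, competent vectors, recovery, extinction.

All densities are reported relative to the total adult female density before
releases begin (the trajectory's baseline).  A "competent vector" is an
adult female able to transmit the pathogen; by default one anti-pathogen
allele suffices for refractoriness (dominant mode), so competent females are
those with zero A alleles.  A recessive mode (only AA females refractory) is
available as a sensitivity switch.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np

from .genetics import N_GENOTYPES, enumerate_genotypes
from .population_model import Trajectory

__all__ = [
    "competent_positions",
    "competent_density",
    "rel_total_female",
    "rel_native_female",
    "rel_competent",
    "juvenile_allele_frequencies",
    "min_native_female",
    "RecoveryResult",
    "competent_at_recovery",
    "allele_extinction_day",
    "MetricSet",
    "compute_metrics",
]

_F = slice(2 * N_GENOTYPES, 3 * N_GENOTYPES)


def competent_positions(dominant: bool = True) -> tuple[int, ...]:
    """0-based positions of genotypes whose females are competent vectors."""
    if dominant:
        return tuple(g.index - 1 for g in enumerate_genotypes() if g.n_A == 0)
    return tuple(g.index - 1 for g in enumerate_genotypes() if g.n_A < 2)


def competent_density(state, dominant: bool = True) -> float:
    """Competent-vector density of one state (27-vector or 9 female densities)."""
    y = np.asarray(state, dtype=float)
    if y.shape == (3 * N_GENOTYPES,):
        F = y[_F]
    elif y.shape == (N_GENOTYPES,):
        F = y
    else:
        raise ValueError(f"expected a 27-state or 9 female densities, got {y.shape}")
    return float(np.maximum(F, 0.0)[list(competent_positions(dominant))].sum())


def rel_total_female(traj: Trajectory) -> np.ndarray:
    return traj.total_female() / traj.baseline_female


def rel_native_female(traj: Trajectory) -> np.ndarray:
    return traj.native_female() / traj.baseline_female


def rel_competent(traj: Trajectory, dominant: bool = True) -> np.ndarray:
    pos = list(competent_positions(dominant))
    return np.maximum(traj.F[:, pos], 0.0).sum(axis=1) / traj.baseline_female


def juvenile_allele_frequencies(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Time series of K and A allele frequencies in the juvenile pool.

    Juvenile (not adult) frequencies are reported because adult frequencies
    are dominated by the released individuals themselves while releases run.
    """
    genos = enumerate_genotypes()
    n_K = np.array([g.n_K for g in genos], dtype=float)
    n_A = np.array([g.n_A for g in genos], dtype=float)
    J = np.maximum(traj.J, 0.0)
    tot = J.sum(axis=1)
    if np.any(tot <= 0):
        raise ValueError("juvenile pool empty at some output time; frequency undefined")
    return (J @ n_K) / (2.0 * tot), (J @ n_A) / (2.0 * tot)


def _release_window(traj: Trajectory) -> tuple[float, float]:
    if traj.schedule is None:
        return 0.0, 0.0
    return traj.schedule.start, traj.schedule.end


def min_native_female(traj: Trajectory) -> tuple[float, float]:
    """(minimum relative native-female density, day of the minimum).

    The minimum is taken over times at or after the release start; ties
    break to the earliest day.  Released females never count (they occupy
    emergence-inviable genotypes).
    """
    start, end = _release_window(traj)
    if traj.times[-1] < end:
        raise ValueError(
            f"trajectory ends at day {traj.times[-1]:.1f}, before the release "
            f"window closes at day {end:.1f}"
        )
    sel = traj.times >= start
    series = rel_native_female(traj)[sel]
    times = traj.times[sel]
    k = int(np.argmin(series))
    return float(series[k]), float(times[k])


@dataclass(frozen=True)
class RecoveryResult:
    """Competent-vector density once the population has recovered.

    ``recovered`` is False when native females never return to within
    ``tol`` of baseline inside the simulated horizon (e.g. near-extinction
    scenarios); ``value`` then holds the horizon-end competent density and
    ``day`` the horizon end.
    """

    value: float
    day: float
    recovered: bool


def competent_at_recovery(
    traj: Trajectory, tol: float = 0.01, dominant: bool = True
) -> RecoveryResult:
    """Relative competent density at the first post-release recovery time.

    Recovery is the first output time after the release window where native
    female density is at least (1 - tol) of baseline; the asymptotic
    approach to baseline makes an exact return unattainable, hence the
    default 1% tolerance.
    """
    start, end = _release_window(traj)
    if traj.times[-1] <= end:
        raise ValueError(
            f"trajectory ends at day {traj.times[-1]:.1f}; releases end at "
            f"day {end:.1f}, leaving no recovery phase"
        )
    native = rel_native_female(traj)
    comp = rel_competent(traj, dominant)
    after = traj.times >= end
    recovered = after & (native >= 1.0 - tol)
    if not recovered.any():
        return RecoveryResult(value=float(comp[-1]), day=float(traj.times[-1]),
                              recovered=False)
    k = int(np.argmax(recovered))
    return RecoveryResult(value=float(comp[k]), day=float(traj.times[k]),
                          recovered=True)


def allele_extinction_day(
    times: np.ndarray,
    freqs: np.ndarray,
    after: float = 0.0,
    eps: float = 1e-6,
) -> Optional[float]:
    """First day after ``after`` when the frequency drops below ``eps`` for good.

    Deterministic densities never reach exact zero, so extinction is read as
    the frequency falling (and staying) below a small threshold.  Returns
    None if that never happens within the series.
    """
    times = np.asarray(times, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    sel = times >= after
    t = times[sel]
    f = freqs[sel]
    below = f < eps
    if not below.any():
        return None
    # suffix-AND: below from here to the horizon
    sustained = np.logical_and.accumulate(below[::-1])[::-1]
    if not sustained.any():
        return None
    return float(t[int(np.argmax(sustained))])


@dataclass(frozen=True)
class MetricSet:
    """Scalar outcomes of one simulated scenario."""

    min_native_female: float
    min_native_female_day: float
    competent_at_recovery: float
    recovery_day: float
    recovered: bool
    extinction_day_K: Optional[float]
    extinction_day_A: Optional[float]
    final_rel_competent: float
    final_rel_total_female: float

    def to_dict(self) -> dict:
        return asdict(self)


def compute_metrics(
    traj: Trajectory,
    tol: float = 0.01,
    eps: float = 1e-6,
    dominant: bool = True,
) -> MetricSet:
    """Compute the full scalar outcome set for one trajectory."""
    start, end = _release_window(traj)
    mn, mn_day = min_native_female(traj)
    if traj.times[-1] > end:
        rec = competent_at_recovery(traj, tol=tol, dominant=dominant)
    else:
        rec = RecoveryResult(value=float("nan"), day=float("nan"), recovered=False)
    fK, fA = juvenile_allele_frequencies(traj)
    return MetricSet(
        min_native_female=mn,
        min_native_female_day=mn_day,
        competent_at_recovery=rec.value,
        recovery_day=rec.day,
        recovered=rec.recovered,
        extinction_day_K=allele_extinction_day(traj.times, fK, after=end, eps=eps),
        extinction_day_A=allele_extinction_day(traj.times, fA, after=end, eps=eps),
        final_rel_competent=float(rel_competent(traj, dominant)[-1]),
        final_rel_total_female=float(rel_total_female(traj)[-1]),
    )
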