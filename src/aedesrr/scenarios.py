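"""Release schedules and the bundled experiment designs.

A release programme is piecewise-constant forcing: ``r`` is the weekly
number of released transgenic adults expressed as a multiple of the
pre-release equilibrium wild-type male density M_star, spread uniformly over
the week (factor 7 converts the weekly ratio to a daily rate).  The same
number of individuals is released each week regardless of how the resident
population changes.  Two strains can be released: the Reduce-and-Replace
strain KKAA (homozygous for both the female-killing and anti-pathogen
transgenes) and the female-killing-only strain KKaa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .equilibrium import Equilibrium
from .genetics import genotype_by_label

__all__ = [
    "SEX_MODES",
    "RELEASE_STRAINS",
    "ReleaseSchedule",
    "SweepDesign",
    "ScenarioDesign",
    "make_schedule",
    "fixed_budget_sweep",
    "default_sweep_durations",
    "scenario_catalogue",
]

SEX_MODES = ("male-only", "female-only", "bi-sex")

#: Released strains: Reduce-and-Replace (both transgenes) and FK-only.
RELEASE_STRAINS = ("KKAA", "KKaa")


@dataclass(frozen=True)
class ReleaseSchedule:
    """Constant-rate release over the window [start, start + T).

    ``male_rate`` and ``female_rate`` are daily densities added to the adult
    compartments of the released strain while the window is open.
    """

    strain: str
    sexes: str
    r: float
    T: float
    start: float
    male_rate: float
    female_rate: float

    @property
    def end(self) -> float:
        return self.start + self.T

    @property
    def strain_position(self) -> int:
        """0-based array position of the released genotype."""
        return genotype_by_label(self.strain).index - 1

    def rates(self, t: float) -> tuple[float, float]:
        """(male, female) release rates in force at time ``t`` (days)."""
        if self.start <= t < self.end:
            return self.male_rate, self.female_rate
        return 0.0, 0.0

    def breakpoints(self) -> tuple[float, ...]:
        """Times at which the forcing is discontinuous."""
        return (self.start, self.end)

    def total_released(self) -> float:
        """Total individuals released over the programme (density units)."""
        return (self.male_rate + self.female_rate) * self.T

    def to_dict(self) -> dict:
        return {
            "strain": self.strain,
            "sexes": self.sexes,
            "r": self.r,
            "T": self.T,
            "start": self.start,
            "male_rate": self.male_rate,
            "female_rate": self.female_rate,
        }


def make_schedule(
    strain: str,
    sexes: str,
    r: float,
    T: float,
    start: float = 30.0,
    equilibrium: Optional[Equilibrium] = None,
) -> ReleaseSchedule:
    """Build a release schedule anchored to the analytic equilibrium.

    Single-sex releases deliver ``r * M_star / 7`` adults per day of the one
    sex; bi-sex releases split the same total evenly, ``r * M_star / 14`` of
    each sex, so total release effort at a given ``r`` is identical across
    sex modes.
    """
    if strain not in RELEASE_STRAINS:
        raise ValueError(
            f"unknown release strain {strain!r}; expected one of {RELEASE_STRAINS}"
        )
    if sexes not in SEX_MODES:
        raise ValueError(f"unknown sex mode {sexes!r}; expected one of {SEX_MODES}")
    if r < 0:
        raise ValueError(f"release ratio r={r!r} must be >= 0")
    if T <= 0:
        raise ValueError(f"release duration T={T!r} must be > 0")
    if start < 0:
        raise ValueError(f"release start {start!r} must be >= 0")
    if equilibrium is None:
        raise ValueError("an Equilibrium is required to anchor release rates")
    weekly = r * equilibrium.M_star
    if sexes == "male-only":
        male_rate, female_rate = weekly / 7.0, 0.0
    elif sexes == "female-only":
        male_rate, female_rate = 0.0, weekly / 7.0
    else:  # bi-sex
        male_rate = female_rate = weekly / 14.0
    return ReleaseSchedule(
        strain=strain,
        sexes=sexes,
        r=r,
        T=T,
        start=start,
        male_rate=male_rate,
        female_rate=female_rate,
    )


@dataclass(frozen=True)
class SweepDesign:
    """Fixed-budget design: all (r, T) combinations share r * T = budget."""

    budget: float  # ratio-days
    durations: tuple[float, ...]
    sexes: str
    strain: str

    @property
    def ratios(self) -> tuple[float, ...]:
        return tuple(self.budget / T for T in self.durations)


def default_sweep_durations(n: int = 15) -> tuple[float, ...]:
    """Log-spaced release durations from 20 to 500 days."""
    return tuple(float(T) for T in np.geomspace(20.0, 500.0, n))


def fixed_budget_sweep(
    budget: float,
    durations,
    sexes: str,
    strain: str = "KKAA",
    start: float = 30.0,
    equilibrium: Optional[Equilibrium] = None,
) -> list[ReleaseSchedule]:
    """One schedule per duration with r = budget / T (r * T exact)."""
    if budget <= 0:
        raise ValueError("budget must be positive (ratio-days)")
    schedules = []
    for T in durations:
        if T <= 0:
            raise ValueError(f"duration {T!r} must be positive")
        schedules.append(
            make_schedule(
                strain, sexes, r=budget / T, T=float(T), start=start,
                equilibrium=equilibrium,
            )
        )
    return schedules


@dataclass(frozen=True)
class ScenarioDesign:
    """A bundled experiment design: the cross of the listed factor levels.

    Unlisted factors stay at their defaults (strain KKAA, male-only,
    release start day 30, no immigration, no fitness costs).
    """

    name: str
    description: str
    strains: tuple[str, ...] = ("KKAA",)
    sexes: tuple[str, ...] = ("male-only",)
    ratios: tuple[float, ...] = ()
    durations: tuple[float, ...] = ()
    c_A: tuple[float, ...] = (0.0,)
    immigration: tuple[float, ...] = (0.0,)
    start: float = 30.0
    budget: Optional[float] = None  # ratio-days; set for fixed-budget sweeps
    t_final: float = 1500.0

    def combinations(self):
        """Yield dicts of factor settings, one per run in the design."""
        if self.budget is not None:
            ratio_duration = [(self.budget / T, T) for T in self.durations]
        else:
            ratio_duration = [(r, T) for r in self.ratios for T in self.durations]
        for strain in self.strains:
            for sexes in self.sexes:
                for r, T in ratio_duration:
                    for c_A in self.c_A:
                        for iota in self.immigration:
                            yield {
                                "strain": strain,
                                "sexes": sexes,
                                "r": r,
                                "T": T,
                                "c_A": c_A,
                                "immigration": iota,
                                "start": self.start,
                                "t_final": self.t_final,
                            }


def scenario_catalogue() -> dict[str, ScenarioDesign]:
    """The bundled experiment designs, keyed by a descriptive name."""
    return {
        "ratio-comparison": ScenarioDesign(
            name="ratio-comparison",
            description=(
                "Year-long male-only releases of the R&R and FK strains at "
                "weekly ratios 1-4; the core strategy comparison."
            ),
            strains=("KKAA", "KKaa"),
            ratios=(1.0, 2.0, 3.0, 4.0),
            durations=(365.0,),
            t_final=3000.0,
        ),
        "duration-comparison": ScenarioDesign(
            name="duration-comparison",
            description="Male-only R&R releases at r=2 for 120, 240 or 360 days.",
            ratios=(2.0,),
            durations=(120.0, 240.0, 360.0),
            t_final=3000.0,
        ),
        "fixed-budget-sweep": ScenarioDesign(
            name="fixed-budget-sweep",
            description=(
                "Constant total release effort of 80 ratio-days spread over "
                "durations from 20 to 500 days, for each sex mode."
            ),
            sexes=SEX_MODES,
            durations=default_sweep_durations(),
            budget=80.0,
            t_final=3000.0,
        ),
        "sex-mode-comparison": ScenarioDesign(
            name="sex-mode-comparison",
            description="R&R releases at r=1 for 100 days: male-only, bi-sex, female-only.",
            sexes=SEX_MODES,
            ratios=(1.0,),
            durations=(100.0,),
            t_final=1500.0,
        ),
        "fitness-cost": ScenarioDesign(
            name="fitness-cost",
            description=(
                "Year-long male-only R&R releases at r=2 with anti-pathogen "
                "fitness cost c_A of 0, 0.1 or 0.2."
            ),
            ratios=(2.0,),
            durations=(365.0,),
            c_A=(0.0, 0.1, 0.2),
            t_final=4000.0,
        ),
        "female-only-durations": ScenarioDesign(
            name="female-only-durations",
            description=(
                "Female-only R&R releases at r=1 for 100, 110 or 120 days; "
                "durations beyond ~120 days head towards extinction."
            ),
            sexes=("female-only",),
            ratios=(1.0,),
            durations=(100.0, 110.0, 120.0),
            t_final=3000.0,
        ),
        "immigration": ScenarioDesign(
            name="immigration",
            description=(
                "Male-only R&R releases at r=2 for 100 days with wild-type "
                "juvenile immigration at 0, 0.001, 0.01 or 0.05 of the "
                "equilibrium juvenile density per day."
            ),
            ratios=(2.0,),
            durations=(100.0,),
            immigration=(0.0, 0.001, 0.01, 0.05),
            t_final=6000.0,
        ),
    }
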