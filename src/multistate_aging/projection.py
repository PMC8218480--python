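"""Deterministic cohort-component multi-state population projection.

The model carries a sub-65 feeder population (single-year ages 0-64 by sex)
and an older-adult population (ages 65-100+, by sex and the 12 living
composite health states) forward one calendar year at a time, 2010-2060 by
default.  Within each year the update order is fixed:

    births -> sub-65 survival/migration/aging -> 65+ health-state
    transitions (rates adjusted for the year) -> 65+ age shift ->
    entry at 65 into the intact-active state

Assumption schedules: fertility is frozen at its last observed year (2017);
sub-65 mortality declines 1.5% per annum; 65+ worsening and death
transition probabilities improve 1% per annum from the estimation window's
end (2014), with the freed mass returned to the stay probability.

Dynamics are expected-value stock-flow (fractional persons), not a
microsimulation.  The cognitive kernel is applied before the functional
kernel within a year, and the functional kernel's CI stratum is read off
the post-update cognition — this is how cognitive decline feeds the onset
of functional disability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimation import (
    AGE_MAX,
    AGE_MIN,
    N_AGES,
    STATE_LABELS,
    TransitionRateTable,
)
from .states import CompositeState

__all__ = [
    "DemographicInputs",
    "AssumptionSchedule",
    "ProjectionResult",
    "births",
    "advance_sub65",
    "enter_at_65",
    "adjust_rates_for_year",
    "transition_step",
    "age_shift_65plus",
    "project",
]

FERTILE_AGES = np.arange(15, 50)  # inclusive 15..49


@dataclass
class DemographicInputs:
    """Initial population, fertility, sub-65 life table and migration.

    ``initial_population``: persons by sex (0 male, 1 female) and single
    year of age 0..100 (100 = open interval 100+).
    ``fertility``: {calendar year: rates for ages 15..49} births per woman.
    ``life_table``: annual death probability q(a) by sex for ages 0..64.
    ``migration``: optional {year: net migrants by sex for ages 0..64}.
    """

    initial_population: np.ndarray          # (2, 101)
    fertility: dict[int, np.ndarray]        # year -> (35,)
    life_table: np.ndarray                  # (2, 65)
    migration: dict[int, np.ndarray] = field(default_factory=dict)
    sex_ratio_at_birth: float = 1.05

    def validate(self) -> None:
        if self.initial_population.shape != (2, 101):
            raise ValueError("initial_population must have shape (2, 101)")
        if np.any(self.initial_population < 0):
            raise ValueError("initial population counts must be >= 0")
        if self.life_table.shape != (2, 65):
            raise ValueError("life_table must have shape (2, 65)")
        if np.any((self.life_table < 0) | (self.life_table > 1)):
            raise ValueError("life-table death probabilities must lie in [0, 1]")
        for year, rates in self.fertility.items():
            if len(rates) != len(FERTILE_AGES):
                raise ValueError(f"fertility for {year} must cover ages 15-49")
            if np.any(np.asarray(rates) < 0):
                raise ValueError(f"negative fertility rate in year {year}")

    def fertility_for_year(self, year: int, freeze_year: int) -> np.ndarray:
        """Fertility schedule for a calendar year, frozen after freeze_year."""
        y = min(int(year), int(freeze_year))
        avail = sorted(self.fertility)
        if y in self.fertility:
            return np.asarray(self.fertility[y], dtype=float)
        # clamp to the nearest available year (projection years outside the
        # observed window)
        y = min(max(y, avail[0]), avail[-1])
        nearest = max(a for a in avail if a <= y)
        return np.asarray(self.fertility[nearest], dtype=float)


@dataclass
class AssumptionSchedule:
    """The projection's three assumption schedules plus mechanical knobs."""

    fertility_freeze_year: int = 2017
    mortality_decline_rate: float = 0.015     # per annum, sub-65 life table
    transition_improvement_rate: float = 0.01  # per annum, 65+ worsening/death
    improvement_base_year: int = 2014
    mortality_base_year: int = 2010
    kernel_order: str = "cognitive_first"     # or "functional_first"

    def __post_init__(self) -> None:
        for r in (self.mortality_decline_rate, self.transition_improvement_rate):
            if not 0 <= r < 1:
                raise ValueError("annual rates must lie in [0, 1)")
        if self.kernel_order not in ("cognitive_first", "functional_first"):
            raise ValueError(f"unknown kernel order {self.kernel_order!r}")


def births(
    sub65: np.ndarray, fertility: np.ndarray, sex_ratio_at_birth: float
) -> np.ndarray:
    """Expected births by sex from the female stocks at ages 15-49.

    Returns ``[male_births, female_births]`` with total split
    male : female = sex_ratio_at_birth : 1.
    """
    fertility = np.asarray(fertility, dtype=float)
    if np.any(fertility < 0):
        raise ValueError("fertility rates must be non-negative")
    total = float(sub65[1, FERTILE_AGES] @ fertility)
    female = total / (1.0 + sex_ratio_at_birth)
    return np.array([total - female, female])


def advance_sub65(
    sub65: np.ndarray,
    life_table: np.ndarray,
    migration: np.ndarray | None,
    year: int,
    schedule: AssumptionSchedule,
    newborns: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """One-year update of the feeder population below age 65.

    Each cohort survives with probability
    ``1 - q(a) * (1 - decline)^(year - base)``, receives net migration and
    shifts up one year of age; survivors of age 64 leave as the 65th-
    birthday entrants and newborns enter age 0.

    Returns ``(new_sub65, entrants_by_sex, deaths, net_migration)``.
    """
    factor = (1.0 - schedule.mortality_decline_rate) ** (year - schedule.mortality_base_year)
    q = life_table * factor
    if np.any((q < 0) | (q > 1)):
        raise ValueError(f"effective sub-65 death probability outside [0, 1] in {year}")
    survivors = sub65 * (1.0 - q)
    deaths = float((sub65 * q).sum())
    if migration is None:
        migration = np.zeros_like(sub65)
    after_mig = survivors + migration
    new = np.zeros_like(sub65)
    new[:, 1:] = after_mig[:, :-1]
    new[:, 0] = newborns
    entrants = after_mig[:, 64].copy()
    return new, entrants, deaths, float(migration.sum())


def enter_at_65(entrants: np.ndarray, older: np.ndarray) -> np.ndarray:
    """Add the 65th-birthday entrants to the intact-active state at age 65."""
    if np.any(np.asarray(entrants) < 0):
        raise ValueError("entrants must be non-negative")
    out = older.copy()
    out[:, 0, 0, 0] += entrants
    return out


def adjust_rates_for_year(
    table: TransitionRateTable, year: int, schedule: AssumptionSchedule
) -> TransitionRateTable:
    """Apply the annual transition-improvement schedule to a rate table.

    Worsening and death probabilities are multiplied by
    ``(1 - rate)^(year - base_year)`` (elapsed years clamped at zero) and
    the freed mass is added to the stay probability; recovery probabilities
    are untouched, so rows still sum to one and structural zeros persist.
    """
    elapsed = max(0, year - schedule.improvement_base_year)
    f = (1.0 - schedule.transition_improvement_rate) ** elapsed
    if f == 1.0:
        return table
    cog = table.cog.copy()
    fun = table.fun.copy()
    for arr in (cog, fun):
        n_orig = arr.shape[-2]
        for i in range(n_orig):
            worsen = np.arange(arr.shape[-1]) > i  # severer states and death
            removed = arr[..., i, worsen].sum(axis=-1) * (1.0 - f)
            arr[..., i, worsen] *= f
            arr[..., i, i] += removed
    return TransitionRateTable(cog=cog, fun=fun)


#: CI stratum of each post-update cognitive category (any impairment = 1).
_CI_OF_COG = np.array([0, 1, 1, 1])


def transition_step(
    older: np.ndarray,
    table: TransitionRateTable,
    kernel_order: str = "cognitive_first",
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one year of health-state transitions to the 65+ population.

    ``older`` has shape (2 sexes, 36 ages, 4 cognition, 3 function).  The
    cognitive kernel moves mass across cognitive categories (death
    absorbing); the functional kernel then moves it across functional
    categories within the CI stratum of the *updated* cognition (death
    absorbing).  ``kernel_order='functional_first'`` swaps the two stages,
    reading the CI stratum off the pre-update cognition instead.

    Returns ``(population after transitions, deaths by sex and age)``.
    """
    cogk = table.cog   # (2, 36, 4, 5)
    funk = table.fun   # (2, 36, 2, 3, 4)
    # functional kernel re-indexed by cognitive category via its CI stratum
    funk_by_cog = funk[:, :, _CI_OF_COG]  # (2, 36, 4, 3, 4)

    if kernel_order == "cognitive_first":
        m1 = np.einsum("sacf,sacd->sadf", older, cogk[..., :4])
        deaths = np.einsum("sacf,sac->sa", older, cogk[..., 4])
        out = np.einsum("sadf,sadfg->sadg", m1, funk_by_cog[..., :3])
        deaths = deaths + np.einsum("sadf,sadf->sa", m1, funk_by_cog[..., 3])
    elif kernel_order == "functional_first":
        m1 = np.einsum("sacf,sacfg->sacg", older, funk_by_cog[..., :3])
        deaths = np.einsum("sacf,sacf->sa", older, funk_by_cog[..., 3])
        out = np.einsum("sacg,sacd->sadg", m1, cogk[..., :4])
        deaths = deaths + np.einsum("sacg,sac->sa", m1, cogk[..., 4])
    else:
        raise ValueError(f"unknown kernel order {kernel_order!r}")
    if np.any(out < -1e-12):
        raise RuntimeError("negative population after transitions: corrupted rate table")
    return out, deaths


def age_shift_65plus(older: np.ndarray) -> np.ndarray:
    """Shift every 65+ cohort up one year; 100+ accumulates its survivors."""
    out = np.zeros_like(older)
    out[:, 1:] = older[:, :-1]
    out[:, -1] += older[:, -1]
    return out


@dataclass
class ProjectionResult:
    """Annual stocks and flows of a 2010-2060 projection.

    ``older`` holds persons by (year, sex, age 65..100+, cognition,
    function); ``sub65`` by (year, sex, age 0..64); ``flows`` one row per
    simulated year with births, deaths and entrants.  Stocks are start-of-
    year snapshots; ``flows.loc[y]`` are the events between year y and y+1.
    """

    years: np.ndarray
    sub65: np.ndarray                  # (n_years, 2, 65)
    older: np.ndarray                  # (n_years, 2, 36, 4, 3)
    flows: pd.DataFrame

    def total(self, year: int) -> float:
        i = self._index(year)
        return float(self.sub65[i].sum() + self.older[i].sum())

    def older_population(self, year: int) -> np.ndarray:
        return self.older[self._index(year)]

    def _index(self, year: int) -> int:
        if not self.years[0] <= year <= self.years[-1]:
            raise ValueError(f"year {year} outside projection span")
        return int(year - self.years[0])

    def check_conservation(self, atol: float = 1e-9) -> None:
        """Verify total(t+1) = total(t) + births - deaths + migration."""
        for i, year in enumerate(self.years[:-1]):
            f = self.flows.loc[self.flows["year"] == year].iloc[0]
            expected = (
                self.total(year)
                + f["births"]
                - f["deaths_sub65"]
                - f["deaths_65plus"]
                + f["net_migration"]
            )
            got = self.total(year + 1)
            if abs(got - expected) > atol * max(1.0, abs(expected)):
                raise AssertionError(
                    f"conservation violated in {year}: {got} != {expected}"
                )

    def older_frame(self) -> pd.DataFrame:
        """Tidy (year, age, sex, state, count) frame of the 65+ stocks."""
        recs = []
        sexlab = ("male", "female")
        cogs = STATE_LABELS["cognitive"]
        funs = STATE_LABELS["functional"]
        for i, year in enumerate(self.years):
            for s in (0, 1):
                for a in range(N_AGES):
                    for c in range(4):
                        for fi in range(3):
                            recs.append(
                                (
                                    int(year),
                                    AGE_MIN + a,
                                    sexlab[s],
                                    CompositeState.from_parts(c, fi).code,
                                    self.older[i, s, a, c, fi],
                                )
                            )
        return pd.DataFrame(recs, columns=["year", "age", "sex", "state", "count"])


def project(
    inputs: DemographicInputs,
    table: TransitionRateTable,
    schedule: AssumptionSchedule | None = None,
    start: int = 2010,
    end: int = 2060,
    initial_state_mixture: np.ndarray | None = None,
) -> ProjectionResult:
    """Run the annual projection loop from ``start`` to ``end`` inclusive.

    The 65+ initial population enters the intact-active state unless an
    explicit (4 cognition x 3 function) ``initial_state_mixture`` is given,
    which is applied uniformly across age and sex.
    """
    schedule = schedule or AssumptionSchedule()
    inputs.validate()
    table.validate(atol=1e-9)
    n_years = end - start + 1
    sub65 = np.zeros((n_years, 2, 65))
    older = np.zeros((n_years, 2, N_AGES, 4, 3))

    sub65[0] = inputs.initial_population[:, :65]
    init_older = inputs.initial_population[:, 65:]  # (2, 36)
    if initial_state_mixture is None:
        older[0, :, :, 0, 0] = init_older
    else:
        mix = np.asarray(initial_state_mixture, dtype=float)
        if mix.shape != (4, 3) or abs(mix.sum() - 1.0) > 1e-9 or np.any(mix < 0):
            raise ValueError("initial_state_mixture must be a (4, 3) probability array")
        older[0] = init_older[:, :, None, None] * mix[None, None]

    flow_rows = []
    for i, year in enumerate(range(start, end)):
        try:
            fert = inputs.fertility_for_year(year, schedule.fertility_freeze_year)
            newborns = births(sub65[i], fert, inputs.sex_ratio_at_birth)
            mig = inputs.migration.get(year)
            new_sub65, entrants, deaths_sub, net_mig = advance_sub65(
                sub65[i], inputs.life_table, mig, year, schedule, newborns
            )
            adjusted = adjust_rates_for_year(table, year, schedule)
            transitioned, deaths_old = transition_step(
                older[i], adjusted, schedule.kernel_order
            )
            shifted = age_shift_65plus(transitioned)
            older[i + 1] = enter_at_65(entrants, shifted)
            sub65[i + 1] = new_sub65
        except Exception as exc:
            raise RuntimeError(f"projection failed in year {year}: {exc}") from exc
        flow_rows.append(
            {
                "year": year,
                "births": float(newborns.sum()),
                "deaths_sub65": deaths_sub,
                "deaths_65plus": float(deaths_old.sum()),
                "net_migration": net_mig,
                "entrants": float(entrants.sum()),
            }
        )

    return ProjectionResult(
        years=np.arange(start, end + 1),
        sub65=sub65,
        older=older,
        flows=pd.DataFrame(flow_rows),
    )
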