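"""Synthetic cohorts and demographic inputs with known ground truth.

The survey the transition models were originally estimated from, and the
census-derived demographic inputs, are both restricted; this module
generates structural stand-ins so the whole pipeline is testable.

``generate_survey`` emulates a two-wave panel with a two-year gap: wave-1
states come from a stated mixture, and two sequential *annual* transitions
are then simulated from the truth kernels using the same cognitive-then-
functional combination order as the projection.  Only the two wave states
are recorded — the midpoint is hidden, as in real data — so the midpoint-
imputation estimator is exercised under realistic information loss (a
debug flag exposes the true midpoint for oracle tests).

``generate_demographics`` builds a smooth, schema-complete national
scenario (age pyramid, fertility schedule 2010-2017, sub-65 life table).
It targets structural, not empirical, realism.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .estimation import (
    AGE_MAX,
    AGE_MIN,
    ALLOWED_DESTINATIONS,
    COGNITIVE,
    FUNCTIONAL,
    STATE_LABELS,
    TERMS,
    OriginCoefficients,
    TransitionModelCoefficients,
    TransitionRateTable,
    build_rate_table,
)
from .projection import DemographicInputs, FERTILE_AGES

__all__ = [
    "DemographicScenario",
    "GeneratorConfig",
    "TruthPreset",
    "truth_presets",
    "generate_survey",
    "generate_demographics",
]


@dataclass
class DemographicScenario:
    """Parameters of the synthetic national demographic inputs.

    The defaults sketch a large, already-ageing population: a flat age
    pyramid up to ``pyramid_plateau_age`` tapering linearly to zero at
    ``pyramid_zero_age``; below-replacement fertility declining slightly
    over 2010-2017 and centred at ``mean_age_at_birth``; a sub-65 life
    table with an infant-mortality spike and Gompertz adult mortality.
    """

    name: str = "large_ageing"
    total_population: float = 1.36e9
    male_share: float = 0.512
    pyramid_plateau_age: int = 45
    pyramid_zero_age: int = 98
    tfr_2010: float = 1.65
    tfr_2017: float = 1.60
    mean_age_at_birth: float = 26.0
    sd_age_at_birth: float = 5.5
    infant_q: float = 0.010
    child_min_q: float = 0.0004
    gompertz_a: float = 4.0e-5
    gompertz_b: float = 0.085
    male_mortality_factor: float = 1.15
    sex_ratio_at_birth: float = 1.05
    jitter: float = 0.0  # lognormal sd applied to the pyramid, 0 = none


@dataclass
class GeneratorConfig:
    """Survey-generator knobs.

    Defaults emulate the estimation survey's shape: 1824 respondents aged
    65+, 1010 women / 814 men.  Wave-1 ages follow a Beta(1.2, 2.0) over
    65-100 (old but front-loaded); weights are log-normal unless
    ``weight_dist='unit'`` (the clean option for recovery tests).  Wave-1
    cognitive and functional categories are drawn independently from the
    stated mixtures.
    """

    n_respondents: int = 1824
    female_share: float = 1010 / 1824
    age_beta: tuple[float, float] = (1.2, 2.0)
    weight_dist: str = "lognormal"  # or "unit"
    weight_sigma: float = 0.5
    cognition_mixture: tuple[float, ...] = (0.55, 0.20, 0.15, 0.10)
    function_mixture: tuple[float, ...] = (0.55, 0.28, 0.17)

    def __post_init__(self) -> None:
        if self.n_respondents < 1:
            raise ValueError("n_respondents must be >= 1")
        if not 0 <= self.female_share <= 1:
            raise ValueError("female_share must lie in [0, 1]")
        for mix, k in ((self.cognition_mixture, 4), (self.function_mixture, 3)):
            if len(mix) != k or abs(sum(mix) - 1) > 1e-9 or min(mix) < 0:
                raise ValueError("state mixtures must be probability vectors")
        if self.weight_dist not in ("lognormal", "unit"):
            raise ValueError(f"unknown weight_dist {self.weight_dist!r}")


@dataclass
class TruthPreset:
    """Ground-truth coefficients plus a demographic scenario."""

    name: str
    description: str
    cognitive: TransitionModelCoefficients
    functional: TransitionModelCoefficients
    scenario: DemographicScenario = field(default_factory=DemographicScenario)

    def rate_table(self) -> TransitionRateTable:
        """The truth-implied annual transition-rate table."""
        return build_rate_table(self.cognitive, self.functional)


def _coeffs_from_mapping(mapping: dict, process: str) -> TransitionModelCoefficients:
    model = TransitionModelCoefficients(process=process)
    terms = TERMS[process]
    for origin, dests in ALLOWED_DESTINATIONS[process].items():
        spec = mapping[origin]
        coef = np.zeros((len(dests), len(terms)))
        for d, dest in enumerate(dests):
            vals = spec.get(dest, {})
            for t, term in enumerate(terms):
                if term == "intercept":
                    coef[d, t] = float(vals.get("intercept", -np.inf))
                else:
                    coef[d, t] = float(vals.get(term, 0.0))
        model.origins[origin] = OriginCoefficients(origin, tuple(dests), coef)
    return model


def truth_presets() -> dict[str, TruthPreset]:
    """The named ground-truth presets shipped with the package."""
    raw = yaml.safe_load(
        importlib.resources.files("multistate_aging.data").joinpath("presets.yaml").read_text()
    )
    out = {}
    for name, spec in raw["presets"].items():
        out[name] = TruthPreset(
            name=name,
            description=spec.get("description", "").strip(),
            cognitive=_coeffs_from_mapping(spec["cognitive"], COGNITIVE),
            functional=_coeffs_from_mapping(spec["functional"], FUNCTIONAL),
            scenario=replace(DemographicScenario(), **spec.get("scenario", {})),
        )
    return out


def single_process_mortality_variant(preset: TruthPreset, process: str) -> TruthPreset:
    """Copy of a preset in which only one process's kernel can kill.

    The survey records a single vital outcome, so when both kernels carry
    death the per-process estimators attribute the other process's deaths
    to themselves and are not consistent for their own truth kernel.
    Calibration (coverage) simulations therefore use variants where the
    *other* process's death intercepts are -inf, making the studied
    process's estimator consistent for its truth.
    """
    if process not in (COGNITIVE, FUNCTIONAL):
        raise ValueError(f"unknown process {process!r}")
    import copy

    out = copy.deepcopy(preset)
    other = out.functional if process == COGNITIVE else out.cognitive
    for oc in other.origins.values():
        for d, dest in enumerate(oc.destinations):
            if dest == "DEAD":
                oc.coef[d, 0] = -np.inf
                oc.coef[d, 1:] = 0.0
    return replace(out, name=f"{preset.name}_{process}_mortality_only")


def _draw_categorical(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    """Vectorized categorical draw; ``probs`` is (n, k) rows summing to 1."""
    u = rng.random(len(probs))
    return (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)


def _simulate_year(
    rng: np.random.Generator,
    table: TransitionRateTable,
    sex: np.ndarray,
    age_idx: np.ndarray,
    cog: np.ndarray,
    fun: np.ndarray,
    alive: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One annual transition (cognitive kernel first, then functional)."""
    cog = cog.copy()
    fun = fun.copy()
    alive = alive.copy()
    # one draw per respondent per stage keeps the stream reproducible
    rows = table.cog[sex, age_idx, cog]             # (n, 5)
    dest = _draw_categorical(rng, rows)
    died = alive & (dest == 4)
    cog = np.where(alive & ~died, np.minimum(dest, 3), cog)
    alive = alive & ~died

    ci = (cog != 0).astype(int)
    rows = table.fun[sex, age_idx, ci, fun]         # (n, 4)
    dest = _draw_categorical(rng, rows)
    died = alive & (dest == 3)
    fun = np.where(alive & ~died, np.minimum(dest, 2), fun)
    alive = alive & ~died
    return cog, fun, alive


def generate_survey(
    truth: TruthPreset,
    config: GeneratorConfig | None = None,
    seed: int = 0,
    include_midpoint: bool = False,
) -> pd.DataFrame:
    """Simulate a two-wave survey from a truth preset.

    Each respondent's trajectory is two sequential annual transitions from
    the truth kernels (ages advance one year in between); only the wave
    states are reported unless ``include_midpoint`` adds the hidden
    midpoint columns for oracle tests.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    n = config.n_respondents
    table = truth.rate_table()

    sex = (rng.random(n) < config.female_share).astype(int)
    ages = AGE_MIN + np.floor(
        rng.beta(*config.age_beta, size=n) * (AGE_MAX - AGE_MIN + 1)
    ).astype(int)
    ages = np.clip(ages, AGE_MIN, AGE_MAX)
    if config.weight_dist == "unit":
        weights = np.ones(n)
    else:
        weights = rng.lognormal(mean=0.0, sigma=config.weight_sigma, size=n)

    cog0 = _draw_categorical(rng, np.tile(config.cognition_mixture, (n, 1)))
    fun0 = _draw_categorical(rng, np.tile(config.function_mixture, (n, 1)))
    alive = np.ones(n, dtype=bool)

    a1 = ages - AGE_MIN
    cog1, fun1, alive1 = _simulate_year(rng, table, sex, a1, cog0, fun0, alive)
    a2 = np.minimum(ages + 1, AGE_MAX) - AGE_MIN
    cog2, fun2, alive2 = _simulate_year(rng, table, sex, a2, cog1, fun1, alive1)

    coglab = np.array(STATE_LABELS[COGNITIVE])
    funlab = np.array(STATE_LABELS[FUNCTIONAL])
    df = pd.DataFrame(
        {
            "respondent_id": [f"R{i:06d}" for i in range(n)],
            "sex": np.where(sex == 1, "female", "male"),
            "age_w1": ages,
            "weight": weights,
            "cog_w1": coglab[cog0],
            "fun_w1": funlab[fun0],
            "cog_w2": np.where(alive2, coglab[cog2], ""),
            "fun_w2": np.where(alive2, funlab[fun2], ""),
            "dead_w2": (~alive2).astype(int),
        }
    )
    if include_midpoint:
        df["cog_mid"] = np.where(alive1, coglab[cog1], "")
        df["fun_mid"] = np.where(alive1, funlab[fun1], "")
        df["dead_mid"] = (~alive1).astype(int)
    return df


def generate_demographics(
    scenario: DemographicScenario | None = None, seed: int = 0
) -> DemographicInputs:
    """Build schema-complete synthetic demographic inputs.

    Deterministic for a given scenario (the seed only feeds the optional
    pyramid jitter, which defaults to off).
    """
    scenario = scenario or DemographicScenario()
    rng = np.random.default_rng(seed)

    ages = np.arange(101)
    shape = np.ones(101)
    taper = ages > scenario.pyramid_plateau_age
    span = scenario.pyramid_zero_age - scenario.pyramid_plateau_age
    if span <= 0:
        raise ValueError("pyramid_zero_age must exceed pyramid_plateau_age")
    shape[taper] = np.clip(1.0 - (ages[taper] - scenario.pyramid_plateau_age) / span, 0.0, 1.0)
    if scenario.jitter > 0:
        shape = shape * rng.lognormal(0.0, scenario.jitter, size=101)
    shape /= shape.sum()
    pop = np.vstack(
        [
            scenario.total_population * scenario.male_share * shape,
            scenario.total_population * (1.0 - scenario.male_share) * shape,
        ]
    )

    kernel = np.exp(
        -0.5 * ((FERTILE_AGES - scenario.mean_age_at_birth) / scenario.sd_age_at_birth) ** 2
    )
    kernel /= kernel.sum()
    fertility = {}
    for year in range(2010, 2018):
        tfr = scenario.tfr_2010 + (scenario.tfr_2017 - scenario.tfr_2010) * (year - 2010) / 7.0
        fertility[year] = tfr * kernel

    a = np.arange(65, dtype=float)
    q = scenario.child_min_q + scenario.gompertz_a * np.exp(scenario.gompertz_b * a)
    q[0] += scenario.infant_q
    life_table = np.vstack([q * scenario.male_mortality_factor, q])
    if np.any(life_table >= 1):
        raise ValueError("scenario implies a sub-65 death probability >= 1")

    inputs = DemographicInputs(
        initial_population=pop,
        fertility=fertility,
        life_table=life_table,
        sex_ratio_at_birth=scenario.sex_ratio_at_birth,
    )
    inputs.validate()
    return inputs
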