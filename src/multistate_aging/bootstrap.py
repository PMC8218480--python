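"""Weighted-resampling bootstrap for transition rates and projections.

The design weights are rescaled to sum to one and used as draw
probabilities: each replicate draws n respondents with replacement (a
respondent may appear once, many times or not at all) and re-enters
estimation with unit weight — the design weight has already been consumed
by the sampling probability.  Resampling whole respondents keeps the
within-respondent dependence of the two imputed annual intervals inside
the intervals.  Uncertainty bands are simple percentile intervals over the
replicate distribution; when a demographic scenario is supplied the full
projection is re-run per replicate so projected counts get intervals too.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimation import (
    COGNITIVE,
    FUNCTIONAL,
    EstimationError,
    TransitionModelCoefficients,
    TransitionRateTable,
    build_rate_table,
    build_transition_pairs,
    fit_transition_model,
    validate_survey,
)
from .projection import AssumptionSchedule, DemographicInputs, ProjectionResult, project

logger = logging.getLogger(__name__)

__all__ = ["BootstrapConfig", "BootstrapResult", "rescale_weights", "resample_survey", "run_bootstrap"]


@dataclass
class BootstrapConfig:
    replicates: int = 1000
    base_seed: int = 0
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie in (0, 1)")


def rescale_weights(weights) -> np.ndarray:
    """Rescale positive sampling weights to probabilities summing to one."""
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        raise ValueError("cannot rescale an empty weight vector")
    bad = np.nonzero(~(w > 0))[0]
    if bad.size:
        raise ValueError(f"non-positive sampling weight at respondent index {bad[0]}")
    return w / w.sum()


def resample_survey(
    survey: pd.DataFrame, probabilities: np.ndarray, seed: int
) -> pd.DataFrame:
    """Draw an equal-size replicate survey with replacement.

    Respondents are drawn by ID with the given probabilities; replicate
    records carry weight 1.
    """
    p = np.asarray(probabilities, dtype=float)
    if len(p) != len(survey):
        raise ValueError("probabilities are not aligned with the survey")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("probabilities must sum to 1")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(survey), size=len(survey), replace=True, p=p)
    replicate = survey.iloc[idx].reset_index(drop=True)
    replicate["weight"] = 1.0
    return replicate


@dataclass
class BootstrapResult:
    """Replicate coefficient sets / rate tables and percentile intervals."""

    config: BootstrapConfig
    point_table: TransitionRateTable
    coefficients: list[tuple[TransitionModelCoefficients, TransitionModelCoefficients]]
    cog_stack: np.ndarray               # (R, 2, 36, 4, 5)
    fun_stack: np.ndarray               # (R, 2, 36, 2, 3, 4)
    older_stack: np.ndarray | None = None   # (R, n_years, 2, 36, 4, 3)
    point_projection: ProjectionResult | None = None
    n_redrawn: int = 0
    replicate_seeds: list[int] = field(default_factory=list)

    @property
    def n_replicates(self) -> int:
        return len(self.coefficients)

    def _quantiles(self, stack: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        alpha = 1.0 - self.config.ci_level
        lo = np.quantile(stack, alpha / 2, axis=0)
        hi = np.quantile(stack, 1 - alpha / 2, axis=0)
        return lo, hi

    def rate_intervals(self) -> tuple[TransitionRateTable, TransitionRateTable]:
        """(lower, upper) percentile envelopes of the replicate rate tables."""
        cog_lo, cog_hi = self._quantiles(self.cog_stack)
        fun_lo, fun_hi = self._quantiles(self.fun_stack)
        return (
            TransitionRateTable(cog=cog_lo, fun=fun_lo),
            TransitionRateTable(cog=cog_hi, fun=fun_hi),
        )

    def projection_intervals(self) -> tuple[np.ndarray, np.ndarray]:
        if self.older_stack is None:
            raise ValueError("bootstrap was run without the projection downstream")
        return self._quantiles(self.older_stack)

    def coefficient_frame(self) -> pd.DataFrame:
        """All replicate coefficients as one tidy frame with a replicate column."""
        frames = []
        for r, (cog, fun) in enumerate(self.coefficients):
            for model in (cog, fun):
                f = model.natural_frame()
                f.insert(0, "replicate", r)
                frames.append(f)
        return pd.concat(frames, ignore_index=True)


def run_bootstrap(
    survey: pd.DataFrame,
    config: BootstrapConfig,
    downstream: str = "estimation",
    demographics: DemographicInputs | None = None,
    schedule: AssumptionSchedule | None = None,
    start: int = 2010,
    end: int = 2060,
    max_failure_fraction: float = 0.05,
    on_missing_origin: str = "error",
) -> BootstrapResult:
    """Run the weighted-resampling bootstrap.

    ``downstream='estimation'`` stops at replicate rate tables;
    ``'projection'`` additionally re-runs the full projection per
    replicate (requires ``demographics``).  Replicate r uses seed
    ``base_seed + r``; replicates whose estimation fails are redrawn with
    a shifted seed and counted, and more than ``max_failure_fraction``
    failures is a hard error.
    """
    if downstream not in ("estimation", "projection"):
        raise ValueError(f"unknown downstream {downstream!r}")
    if downstream == "projection" and demographics is None:
        raise ValueError("projection downstream requires demographic inputs")
    survey = validate_survey(survey)
    probs = rescale_weights(survey["weight"].to_numpy())

    # point estimate (also the warm start for every replicate refit)
    rng = np.random.default_rng(config.base_seed)
    point_cog = fit_transition_model(
        build_transition_pairs(survey, COGNITIVE, rng), COGNITIVE,
        on_missing_origin=on_missing_origin,
    )
    point_fun = fit_transition_model(
        build_transition_pairs(survey, FUNCTIONAL, rng), FUNCTIONAL,
        on_missing_origin=on_missing_origin,
    )
    point_table = build_rate_table(point_cog, point_fun)
    point_projection = None
    if downstream == "projection":
        point_projection = project(demographics, point_table, schedule, start, end)

    coefficients = []
    cog_stack = np.empty((config.replicates,) + point_table.cog.shape)
    fun_stack = np.empty((config.replicates,) + point_table.fun.shape)
    older_stack = None
    if downstream == "projection":
        older_stack = np.empty(
            (config.replicates,) + point_projection.older.shape
        )

    seeds_used = []
    n_redrawn = 0
    max_failures = max(1, int(max_failure_fraction * config.replicates))
    for r in range(config.replicates):
        attempt = 0
        while True:
            seed = config.base_seed + r + attempt * (config.replicates + 7919)
            try:
                replicate = resample_survey(survey, probs, seed)
                rep_rng = np.random.default_rng(seed + 1)
                cog = fit_transition_model(
                    build_transition_pairs(replicate, COGNITIVE, rep_rng, validate=False),
                    COGNITIVE,
                    start=point_cog,
                    on_missing_origin=on_missing_origin,
                )
                fun = fit_transition_model(
                    build_transition_pairs(replicate, FUNCTIONAL, rep_rng, validate=False),
                    FUNCTIONAL,
                    start=point_fun,
                    on_missing_origin=on_missing_origin,
                )
                table = build_rate_table(cog, fun)
                break
            except EstimationError as exc:
                n_redrawn += 1
                attempt += 1
                logger.warning("replicate %d redrawn (attempt %d): %s", r, attempt, exc)
                if n_redrawn > max_failures:
                    raise EstimationError(
                        f"more than {max_failure_fraction:.0%} of bootstrap replicates "
                        f"failed to estimate; the estimation is unstable"
                    ) from exc
        seeds_used.append(seed)
        coefficients.append((cog, fun))
        cog_stack[r] = table.cog
        fun_stack[r] = table.fun
        if older_stack is not None:
            older_stack[r] = project(demographics, table, schedule, start, end).older

    return BootstrapResult(
        config=config,
        point_table=point_table,
        coefficients=coefficients,
        cog_stack=cog_stack,
        fun_stack=fun_stack,
        older_stack=older_stack,
        point_projection=point_projection,
        n_redrawn=n_redrawn,
        replicate_seeds=seeds_used,
    )
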