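"""Annual transition-probability estimation from two-wave panel data.

The survey observes each respondent's cognitive and functional category at
two waves two years apart (plus vital status at wave 2).  A midpoint state
is imputed for the unobserved year in between: identical wave states are
carried through; differing states (death included) are resolved by a fair
coin, so every respondent contributes up to two one-year transition pairs.
Each process (cognitive, functional) is then fitted with per-origin
weighted multinomial logits with "stay" as the reference category,

    cognitive:  ln(p_ij / p_ii) = b0 + b1*age + b2*age^2 + b3*sex
    functional: ln(p_ij / p_ii) = b0 + b1*age + b2*sex   + b3*ci

where sex is coded female=1 and ci (any cognitive impairment) with-CI=1.
Improvement transitions out of moderate/severe cognitive impairment and out
of 3+ ADL limitations are structural zeros: they are excluded from the
choice set, not zeroed after the fit.

Age is centred at 80 internally (age and age^2 with ages 65-100 make an
ill-conditioned design); coefficients are exported on the natural scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mnlogit import fit_mnlogit, softmax_reference
from .states import Cognition, CompositeState, Function

logger = logging.getLogger(__name__)

__all__ = [
    "COGNITIVE",
    "FUNCTIONAL",
    "AGE_MIN",
    "AGE_MAX",
    "AGE_CENTER",
    "EstimationError",
    "MissingOriginError",
    "OriginCoefficients",
    "TransitionModelCoefficients",
    "TransitionRateTable",
    "impute_midpoint_state",
    "build_transition_pairs",
    "fit_transition_model",
    "predict_transition_probs",
    "build_rate_table",
    "validate_survey",
]

COGNITIVE = "cognitive"
FUNCTIONAL = "functional"

AGE_MIN = 65
AGE_MAX = 100  # open interval: 100 stands for 100+
AGE_CENTER = 80
N_AGES = AGE_MAX - AGE_MIN + 1

DEAD = "DEAD"

#: Per-process living-state labels, severity order.
STATE_LABELS = {
    COGNITIVE: ("INTACT", "MILD", "MODERATE", "SEVERE"),
    FUNCTIONAL: ("ACTIVE", "ADL12", "ADL3"),
}

#: Design-matrix terms per process (age terms are centred at AGE_CENTER).
TERMS = {
    COGNITIVE: ("intercept", "age", "age2", "sex"),
    FUNCTIONAL: ("intercept", "age", "sex", "ci"),
}

#: Permitted non-stay destinations per origin (structural zeros excluded:
#: no recovery from moderate/severe cognitive impairment or from 3+ ADL).
ALLOWED_DESTINATIONS = {
    COGNITIVE: {
        "INTACT": ("MILD", "MODERATE", "SEVERE", DEAD),
        "MILD": ("INTACT", "MODERATE", "SEVERE", DEAD),
        "MODERATE": ("SEVERE", DEAD),
        "SEVERE": (DEAD,),
    },
    FUNCTIONAL: {
        "ACTIVE": ("ADL12", "ADL3", DEAD),
        "ADL12": ("ACTIVE", "ADL3", DEAD),
        "ADL3": (DEAD,),
    },
}

SURVEY_COLUMNS = (
    "respondent_id",
    "sex",
    "age_w1",
    "weight",
    "cog_w1",
    "fun_w1",
    "cog_w2",
    "fun_w2",
    "dead_w2",
)


class EstimationError(RuntimeError):
    """Raised when a transition model cannot be estimated."""


class MissingOriginError(EstimationError):
    """Raised when an origin state has no transition pairs at all."""


# ---------------------------------------------------------------------------
# survey schema


def validate_survey(survey: pd.DataFrame) -> pd.DataFrame:
    """Validate the two-wave survey schema, dropping lost-to-follow-up rows.

    Respondents with neither a living wave-2 state nor a recorded death are
    dropped with a logged count (their transitions are unobservable).
    """
    missing = [c for c in SURVEY_COLUMNS if c not in survey.columns]
    if missing:
        raise ValueError(f"survey is missing columns {missing}")
    df = survey.copy()
    if (df["weight"] <= 0).any():
        bad = df.loc[df["weight"] <= 0, "respondent_id"].tolist()[:5]
        raise ValueError(f"non-positive sampling weight for respondents {bad}")
    if (df["age_w1"] < AGE_MIN).any():
        bad = df.loc[df["age_w1"] < AGE_MIN, "respondent_id"].tolist()[:5]
        raise ValueError(f"age at wave 1 below {AGE_MIN} for respondents {bad}")
    if not df["sex"].isin(["female", "male"]).all():
        raise ValueError("sex must be 'female' or 'male'")
    dead = df["dead_w2"].astype(int) == 1
    alive = ~dead
    ltfu = alive & (
        ~df["cog_w2"].isin(STATE_LABELS[COGNITIVE])
        | ~df["fun_w2"].isin(STATE_LABELS[FUNCTIONAL])
    )
    if ltfu.any():
        logger.warning("dropping %d respondents lost to follow-up", int(ltfu.sum()))
        df = df.loc[~ltfu].reset_index(drop=True)
    for col, labels in (("cog_w1", STATE_LABELS[COGNITIVE]), ("fun_w1", STATE_LABELS[FUNCTIONAL])):
        if not df[col].isin(labels).all():
            raise ValueError(f"invalid category in {col}")
    return df


# ---------------------------------------------------------------------------
# midpoint imputation and pair building


def impute_midpoint_state(state_w1, state_w2, rng: np.random.Generator):
    """Impute the unobserved midpoint state between two waves.

    Identical wave states are carried through deterministically; differing
    states (wave-2 death included) resolve to the wave-1 or wave-2 value
    with equal probability — the transition is assumed to happen at random
    within the two-year gap.
    """
    if isinstance(state_w1, CompositeState) and state_w1.is_dead:
        raise ValueError("wave-1 state must be a living state")
    if state_w1 == state_w2:
        return state_w1
    return state_w1 if rng.random() < 0.5 else state_w2


def _encode_labels(values: np.ndarray, labels: tuple[str, ...]) -> np.ndarray:
    out = np.full(len(values), -1, dtype=int)
    for i, lab in enumerate(labels):
        out[values == lab] = i
    return out


def build_transition_pairs(
    survey: pd.DataFrame, process: str, rng: np.random.Generator, validate: bool = True
) -> pd.DataFrame:
    """Expand a two-wave survey into one-year transition pairs.

    Each respondent contributes the pair (wave1 -> midpoint) at their
    wave-1 age and, unless the imputed midpoint is death, the pair
    (midpoint -> wave2) at age + 1.  For the functional process the CI
    covariate is measured at the start of each interval: wave-1 cognition
    for the first pair, midpoint cognition for the second.

    Returns a tidy frame with integer-coded ``origin``/``dest`` (death is
    the last index), ``age`` (capped at 100), ``sex`` (female=1), ``ci``
    (functional only, else -1), ``weight`` and ``respondent_id``.
    """
    if process not in (COGNITIVE, FUNCTIONAL):
        raise ValueError(f"unknown process {process!r}")
    df = validate_survey(survey) if validate else survey
    n = len(df)
    cols = ["respondent_id", "origin", "dest", "age", "sex", "ci", "weight"]
    if n == 0:
        logger.warning("empty survey: no transition pairs built")
        return pd.DataFrame(columns=cols)

    labels = STATE_LABELS[process]
    dead_idx = len(labels)

    sex = (df["sex"].to_numpy() == "female").astype(int)
    age1 = np.clip(df["age_w1"].to_numpy().astype(int), AGE_MIN, AGE_MAX)
    age2 = np.minimum(age1 + 1, AGE_MAX)
    weight = df["weight"].to_numpy(dtype=float)
    dead2 = df["dead_w2"].to_numpy().astype(int) == 1

    w1col, w2col = ("cog_w1", "cog_w2") if process == COGNITIVE else ("fun_w1", "fun_w2")
    s1 = _encode_labels(df[w1col].to_numpy(), labels)
    s2 = _encode_labels(df[w2col].to_numpy(), labels)

    # random draws in a fixed order for bit-identical reruns
    u_deathmid = rng.random(n)
    u_mid = rng.random(n)
    if process == FUNCTIONAL:
        u_cogmid = rng.random(n)
        c1 = _encode_labels(df["cog_w1"].to_numpy(), STATE_LABELS[COGNITIVE])
        c2 = _encode_labels(df["cog_w2"].to_numpy(), STATE_LABELS[COGNITIVE])

    mid_dead = dead2 & (u_deathmid < 0.5)
    # living midpoint category: wave-1 value unless waves differ (coin)
    mid = s1.copy()
    switch = (~dead2) & (s1 != s2) & (u_mid >= 0.5)
    mid[switch] = s2[switch]

    if process == FUNCTIONAL:
        cmid = c1.copy()
        cswitch = (~dead2) & (c1 != c2) & (u_cogmid >= 0.5)
        cmid[cswitch] = c2[cswitch]
        ci1 = (c1 != int(Cognition.INTACT)).astype(int)
        ci2 = (cmid != int(Cognition.INTACT)).astype(int)
    else:
        ci1 = np.full(n, -1)
        ci2 = np.full(n, -1)

    first = pd.DataFrame(
        {
            "respondent_id": df["respondent_id"].to_numpy(),
            "origin": s1,
            "dest": np.where(mid_dead, dead_idx, mid),
            "age": age1,
            "sex": sex,
            "ci": ci1,
            "weight": weight,
        }
    )
    keep2 = ~mid_dead
    second = pd.DataFrame(
        {
            "respondent_id": df["respondent_id"].to_numpy()[keep2],
            "origin": mid[keep2],
            "dest": np.where(dead2[keep2], dead_idx, s2[keep2]),
            "age": age2[keep2],
            "sex": sex[keep2],
            "ci": ci2[keep2],
            "weight": weight[keep2],
        }
    )
    return pd.concat([first, second], ignore_index=True)[cols]


# ---------------------------------------------------------------------------
# coefficient containers


@dataclass
class OriginCoefficients:
    """Fitted reference-logit coefficients for one origin state.

    ``coef`` has shape (n_destinations, n_terms) on the age-centred scale
    (age replaced by age - 80).  Rows follow ``destinations`` order.
    """

    origin: str
    destinations: tuple[str, ...]
    coef: np.ndarray
    converged: bool = True
    n_iter: int = 0
    grad_norm: float = 0.0
    note: str = ""


@dataclass
class TransitionModelCoefficients:
    """Per-origin multinomial-logit coefficients for one process."""

    process: str
    origins: dict[str, OriginCoefficients] = field(default_factory=dict)

    @property
    def terms(self) -> tuple[str, ...]:
        return TERMS[self.process]

    def centred_frame(self) -> pd.DataFrame:
        rows = []
        for oc in self.origins.values():
            for d, dest in enumerate(oc.destinations):
                for t, term in enumerate(self.terms):
                    rows.append(
                        {
                            "process": self.process,
                            "origin": oc.origin,
                            "destination": dest,
                            "term": term,
                            "value": oc.coef[d, t],
                        }
                    )
        return pd.DataFrame(rows)

    def natural_frame(self) -> pd.DataFrame:
        """Coefficients on the natural age scale (what the CSVs report)."""
        out = self.centred_frame()
        c = AGE_CENTER
        for (origin, dest), grp in out.groupby(["origin", "destination"]):
            vals = dict(zip(grp["term"], grp["value"]))
            b0 = vals["intercept"]
            b_age = vals["age"]
            b_age2 = vals.get("age2", 0.0)
            sel = (out["origin"] == origin) & (out["destination"] == dest)
            if np.isfinite(b0):
                out.loc[sel & (out["term"] == "intercept"), "value"] = (
                    b0 - c * b_age + c * c * b_age2
                )
                out.loc[sel & (out["term"] == "age"), "value"] = b_age - 2 * c * b_age2
        return out

    @classmethod
    def from_natural_frame(cls, frame: pd.DataFrame, process: str) -> "TransitionModelCoefficients":
        sub = frame[frame["process"] == process]
        model = cls(process=process)
        c = AGE_CENTER
        terms = TERMS[process]
        for origin, dests in ALLOWED_DESTINATIONS[process].items():
            grp = sub[sub["origin"] == origin]
            if grp.empty:
                continue
            coef = np.zeros((len(dests), len(terms)))
            for d, dest in enumerate(dests):
                vals = dict(zip(grp.loc[grp["destination"] == dest, "term"],
                                grp.loc[grp["destination"] == dest, "value"]))
                b_age2 = vals.get("age2", 0.0)
                b_age = vals["age"] + 2 * c * b_age2
                b0 = vals["intercept"] + c * vals["age"] + c * c * b_age2
                for t, term in enumerate(terms):
                    if term == "intercept":
                        coef[d, t] = b0
                    elif term == "age":
                        coef[d, t] = b_age
                    else:
                        coef[d, t] = vals.get(term, 0.0)
            model.origins[origin] = OriginCoefficients(origin, tuple(dests), coef)
        return model


def _design_row(process: str, age: float, sex: int, ci: int | None) -> np.ndarray:
    a = min(max(float(age), AGE_MIN), AGE_MAX) - AGE_CENTER
    if process == COGNITIVE:
        return np.array([1.0, a, a * a, float(sex)])
    if ci is None:
        raise ValueError("the functional process requires the ci indicator")
    return np.array([1.0, a, float(sex), float(ci)])


# ---------------------------------------------------------------------------
# fitting


def fit_transition_model(
    pairs: pd.DataFrame,
    process: str,
    start: TransitionModelCoefficients | None = None,
    on_missing_origin: str = "error",
) -> TransitionModelCoefficients:
    """Fit the per-origin weighted multinomial logits for one process.

    Pairs whose destination is structurally forbidden for their origin are
    dropped with a warning (the choice set excludes them by design).
    Permitted destinations never observed get their intercept fixed at -20
    (probability ~ 0) instead of failing.  ``start`` supplies warm-start
    coefficients, e.g. the point fit when refitting bootstrap replicates.
    An origin with no pairs at all raises by default;
    ``on_missing_origin='pin'`` instead pins all of its destinations at
    -20 (the origin effectively only stays), for degenerate inputs.
    """
    if process not in (COGNITIVE, FUNCTIONAL):
        raise ValueError(f"unknown process {process!r}")
    if on_missing_origin not in ("error", "pin"):
        raise ValueError(f"unknown on_missing_origin {on_missing_origin!r}")
    labels = STATE_LABELS[process]
    terms = TERMS[process]
    dead_idx = len(labels)
    model = TransitionModelCoefficients(process=process)

    for o_idx, origin in enumerate(labels):
        dests = ALLOWED_DESTINATIONS[process][origin]
        sub = pairs[pairs["origin"] == o_idx]
        if len(sub) == 0:
            if on_missing_origin == "pin":
                logger.warning("origin %s has no pairs; pinning all destinations", origin)
                coef = np.zeros((len(dests), len(terms)))
                coef[:, 0] = -20.0
                model.origins[origin] = OriginCoefficients(
                    origin, tuple(dests), coef, note="origin unobserved; pinned"
                )
                continue
            raise MissingOriginError(
                f"no transition pairs with origin {origin}; cannot estimate its model"
            )
        dest_code = {(dead_idx if d == DEAD else labels.index(d)): k + 1 for k, d in enumerate(dests)}
        dest_code[o_idx] = 0  # stay = reference
        known = sub["dest"].isin(dest_code)
        if not known.all():
            logger.warning(
                "dropping %d pairs from origin %s with structurally forbidden destinations",
                int((~known).sum()),
                origin,
            )
            sub = sub[known]
        y = sub["dest"].map(dest_code).to_numpy(dtype=int)
        w = sub["weight"].to_numpy(dtype=float)
        a = sub["age"].to_numpy(dtype=float) - AGE_CENTER
        if process == COGNITIVE:
            X = np.column_stack([np.ones(len(sub)), a, a * a, sub["sex"].to_numpy(dtype=float)])
        else:
            X = np.column_stack(
                [np.ones(len(sub)), a, sub["sex"].to_numpy(dtype=float), sub["ci"].to_numpy(dtype=float)]
            )

        # destinations never observed cannot be fitted: pin them near zero
        observed = [k for k in range(1, len(dests) + 1) if np.any(y == k)]
        note = ""
        if len(observed) < len(dests):
            missing = [dests[k - 1] for k in range(1, len(dests) + 1) if k not in observed]
            note = f"unobserved destinations pinned at -20: {missing}"
            logger.warning("origin %s: %s", origin, note)

        coef = np.zeros((len(dests), len(terms)))
        coef[:, 0] = -20.0
        if observed:
            remap = {k: i + 1 for i, k in enumerate(observed)}
            y_fit = np.array([remap.get(v, 0) for v in y])
            start_beta = None
            if start is not None and origin in start.origins:
                sb = start.origins[origin].coef
                start_beta = np.vstack([sb[k - 1] for k in observed])
                start_beta = np.where(np.isfinite(start_beta), start_beta, -20.0)
            res = fit_mnlogit(
                X, y_fit, weights=w, n_classes=len(observed) + 1, start=start_beta
            )
            if not res.converged:
                raise EstimationError(
                    f"multinomial logit for origin {origin} did not converge "
                    f"(grad norm {res.grad_norm:.2e}); consider enlarging the data"
                )
            for i, k in enumerate(observed):
                coef[k - 1] = res.coef[i]
            model.origins[origin] = OriginCoefficients(
                origin,
                tuple(dests),
                coef,
                converged=res.converged,
                n_iter=res.n_iter,
                grad_norm=res.grad_norm,
                note=note,
            )
        else:
            model.origins[origin] = OriginCoefficients(origin, tuple(dests), coef, note=note)
    return model


def predict_transition_probs(
    coeffs: TransitionModelCoefficients,
    origin: str,
    age: float,
    sex: int,
    ci: int | None = None,
) -> pd.Series:
    """Annual transition probability vector for one origin and covariates.

    Returns a Series over all of the process's states plus DEAD; the stay
    probability is the reference-category softmax complement and
    structurally forbidden destinations are exactly zero.  Ages above 100
    are evaluated at 100 (open age interval).
    """
    labels = STATE_LABELS[coeffs.process]
    if origin not in labels:
        raise ValueError(f"unknown origin {origin!r} for process {coeffs.process}")
    if age < AGE_MIN:
        raise ValueError(f"age must be >= {AGE_MIN}, got {age}")
    oc = coeffs.origins[origin]
    x = _design_row(coeffs.process, age, sex, ci if coeffs.process == FUNCTIONAL else None)
    eta = oc.coef @ x
    p = softmax_reference(eta)  # (1 + D,), stay first
    out = pd.Series(0.0, index=list(labels) + [DEAD])
    out[origin] = p[0]
    for d, dest in enumerate(oc.destinations):
        out[dest] = p[1 + d]
    return out


# ---------------------------------------------------------------------------
# rate tables


def _structural_zero_masks():
    """Boolean (origin, dest) masks of forbidden living-to-living moves."""
    cog = np.zeros((4, 5), dtype=bool)
    for i, origin in enumerate(STATE_LABELS[COGNITIVE]):
        allowed = set(ALLOWED_DESTINATIONS[COGNITIVE][origin]) | {origin}
        for j, dest in enumerate(STATE_LABELS[COGNITIVE] + (DEAD,)):
            cog[i, j] = dest not in allowed
    fun = np.zeros((3, 4), dtype=bool)
    for i, origin in enumerate(STATE_LABELS[FUNCTIONAL]):
        allowed = set(ALLOWED_DESTINATIONS[FUNCTIONAL][origin]) | {origin}
        for j, dest in enumerate(STATE_LABELS[FUNCTIONAL] + (DEAD,)):
            fun[i, j] = dest not in allowed
    return cog, fun


COG_FORBIDDEN, FUN_FORBIDDEN = _structural_zero_masks()


@dataclass
class TransitionRateTable:
    """Annual transition probabilities on the full covariate grid.

    ``cog`` has shape (2 sexes, 36 ages, 4 origins, 5 destinations) and
    ``fun`` (2, 36, 2 CI strata, 3, 4); sex index 1 is female, age index 0
    is 65 and the last destination is death.  Rows are probability vectors.
    """

    cog: np.ndarray
    fun: np.ndarray

    ages = np.arange(AGE_MIN, AGE_MAX + 1)

    def validate(self, atol: float = 1e-12) -> None:
        for name, arr, mask in (
            ("cognitive", self.cog, COG_FORBIDDEN),
            ("functional", self.fun, FUN_FORBIDDEN),
        ):
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValueError(f"{name} table has entries outside [0, 1]")
            rows = arr.sum(axis=-1)
            if not np.allclose(rows, 1.0, atol=atol, rtol=0):
                raise ValueError(f"{name} table rows do not sum to 1")
            if np.any(arr[..., mask] != 0.0):
                raise ValueError(f"{name} table violates a structural zero")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s, sexlab in enumerate(("male", "female")):
            for a_i, age in enumerate(self.ages):
                for i, origin in enumerate(STATE_LABELS[COGNITIVE]):
                    for j, dest in enumerate(STATE_LABELS[COGNITIVE] + (DEAD,)):
                        rows.append(
                            ("cognitive", origin, dest, int(age), sexlab, "", self.cog[s, a_i, i, j])
                        )
                for ci in (0, 1):
                    for i, origin in enumerate(STATE_LABELS[FUNCTIONAL]):
                        for j, dest in enumerate(STATE_LABELS[FUNCTIONAL] + (DEAD,)):
                            rows.append(
                                ("functional", origin, dest, int(age), sexlab, ci, self.fun[s, a_i, ci, i, j])
                            )
        return pd.DataFrame(
            rows, columns=["process", "origin", "destination", "age", "sex", "ci", "value"]
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TransitionRateTable":
        cog = np.zeros((2, N_AGES, 4, 5))
        fun = np.zeros((2, N_AGES, 2, 3, 4))
        sex_idx = {"male": 0, "female": 1}
        cog_o = {s: i for i, s in enumerate(STATE_LABELS[COGNITIVE])}
        cog_d = {s: i for i, s in enumerate(STATE_LABELS[COGNITIVE] + (DEAD,))}
        fun_o = {s: i for i, s in enumerate(STATE_LABELS[FUNCTIONAL])}
        fun_d = {s: i for i, s in enumerate(STATE_LABELS[FUNCTIONAL] + (DEAD,))}
        for row in frame.itertuples(index=False):
            s = sex_idx[row.sex]
            a = int(row.age) - AGE_MIN
            if row.process == "cognitive":
                cog[s, a, cog_o[row.origin], cog_d[row.destination]] = row.value
            else:
                fun[s, a, int(row.ci), fun_o[row.origin], fun_d[row.destination]] = row.value
        table = cls(cog=cog, fun=fun)
        table.validate(atol=1e-9)
        return table


def build_rate_table(
    cog_coeffs: TransitionModelCoefficients,
    fun_coeffs: TransitionModelCoefficients,
) -> TransitionRateTable:
    """Evaluate both fitted models on the full (age, sex[, CI]) grid."""
    if cog_coeffs.process != COGNITIVE or fun_coeffs.process != FUNCTIONAL:
        raise ValueError("pass (cognitive, functional) coefficient sets in that order")
    ages = np.arange(AGE_MIN, AGE_MAX + 1, dtype=float)
    a = ages - AGE_CENTER

    cog = np.zeros((2, N_AGES, 4, 5))
    for s in (0, 1):
        X = np.column_stack([np.ones(N_AGES), a, a * a, np.full(N_AGES, float(s))])
        for i, origin in enumerate(STATE_LABELS[COGNITIVE]):
            oc = cog_coeffs.origins[origin]
            p = softmax_reference(X @ oc.coef.T)  # (N_AGES, 1+D)
            cog[s, :, i, i] = p[:, 0]
            for d, dest in enumerate(oc.destinations):
                j = 4 if dest == DEAD else STATE_LABELS[COGNITIVE].index(dest)
                cog[s, :, i, j] = p[:, 1 + d]

    fun = np.zeros((2, N_AGES, 2, 3, 4))
    for s in (0, 1):
        for ci in (0, 1):
            X = np.column_stack(
                [np.ones(N_AGES), a, np.full(N_AGES, float(s)), np.full(N_AGES, float(ci))]
            )
            for i, origin in enumerate(STATE_LABELS[FUNCTIONAL]):
                oc = fun_coeffs.origins[origin]
                p = softmax_reference(X @ oc.coef.T)
                fun[s, :, ci, i, i] = p[:, 0]
                for d, dest in enumerate(oc.destinations):
                    j = 3 if dest == DEAD else STATE_LABELS[FUNCTIONAL].index(dest)
                    fun[s, :, ci, i, j] = p[:, 1 + d]

    table = TransitionRateTable(cog=cog, fun=fun)
    table.validate()
    return table
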