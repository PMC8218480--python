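"""Health-state taxonomy for the disability / cognitive-impairment model.

Cognitive status is graded from the MMSE total (0-30) into four ordered
categories; functional status from the count of ADL limitations (0-6, six
basic self-care activities) into three.  The cross product gives twelve
living composite states; death is modelled as a thirteenth absorbing
composite value so that every transition-kernel row is a single probability
vector.

For reporting, the living states partition into four impairment classes
(no impairment / ADL only / CI only / CI and ADL), and a state "needs
nursing-home-type care" when it has 3+ ADL limitations or moderate-to-severe
cognitive impairment.
"""

from __future__ import annotations

import enum

import pandas as pd

__all__ = [
    "Cognition",
    "Function",
    "CompositeState",
    "ImpairmentClass",
    "LIVING_STATES",
    "classify_cognition",
    "classify_function",
    "impairment_class",
    "needs_nursing_home_care",
    "codebook",
]


class Cognition(enum.IntEnum):
    """Cognitive category from the MMSE total, ordered by severity."""

    INTACT = 0    # MMSE >= 24
    MILD = 1      # 18-23
    MODERATE = 2  # 10-17
    SEVERE = 3    # <= 9


class Function(enum.IntEnum):
    """Functional category from the ADL limitation count, ordered by severity."""

    ACTIVE = 0     # 0 limitations
    ADL_1_2 = 1    # 1-2 limitations
    ADL_3PLUS = 2  # 3+ limitations


#: Short stable serialization codes used in every CSV.
_FUNCTION_CODE = {Function.ACTIVE: "ACTIVE", Function.ADL_1_2: "ADL12", Function.ADL_3PLUS: "ADL3"}


class CompositeState(enum.Enum):
    """One of the 12 living (cognition, function) states, or absorbing DEAD."""

    INTACT_ACTIVE = (Cognition.INTACT, Function.ACTIVE)
    INTACT_ADL12 = (Cognition.INTACT, Function.ADL_1_2)
    INTACT_ADL3 = (Cognition.INTACT, Function.ADL_3PLUS)
    MILD_ACTIVE = (Cognition.MILD, Function.ACTIVE)
    MILD_ADL12 = (Cognition.MILD, Function.ADL_1_2)
    MILD_ADL3 = (Cognition.MILD, Function.ADL_3PLUS)
    MODERATE_ACTIVE = (Cognition.MODERATE, Function.ACTIVE)
    MODERATE_ADL12 = (Cognition.MODERATE, Function.ADL_1_2)
    MODERATE_ADL3 = (Cognition.MODERATE, Function.ADL_3PLUS)
    SEVERE_ACTIVE = (Cognition.SEVERE, Function.ACTIVE)
    SEVERE_ADL12 = (Cognition.SEVERE, Function.ADL_1_2)
    SEVERE_ADL3 = (Cognition.SEVERE, Function.ADL_3PLUS)
    DEAD = "DEAD"

    @property
    def is_dead(self) -> bool:
        return self is CompositeState.DEAD

    @property
    def cognition(self) -> Cognition:
        if self.is_dead:
            raise ValueError("DEAD has no cognitive category")
        return self.value[0]

    @property
    def function(self) -> Function:
        if self.is_dead:
            raise ValueError("DEAD has no functional category")
        return self.value[1]

    @property
    def code(self) -> str:
        return self.name

    @classmethod
    def from_parts(cls, cognition: Cognition, function: Function) -> "CompositeState":
        return _COMPOSITE_BY_PARTS[(Cognition(cognition), Function(function))]

    @classmethod
    def from_code(cls, code: str) -> "CompositeState":
        try:
            return cls[code]
        except KeyError:
            raise ValueError(f"unknown composite state code {code!r}") from None


_COMPOSITE_BY_PARTS = {
    s.value: s for s in CompositeState if s is not CompositeState.DEAD
}

#: The 12 living states in (cognition-major, function-minor) order.
LIVING_STATES: tuple[CompositeState, ...] = tuple(
    s for s in CompositeState if s is not CompositeState.DEAD
)


class ImpairmentClass(enum.Enum):
    """Reporting partition of the 12 living states."""

    NONE = "NONE"
    ADL_ONLY = "ADL_ONLY"
    CI_ONLY = "CI_ONLY"
    CI_AND_ADL = "CI_AND_ADL"


def classify_cognition(mmse_score: int) -> Cognition:
    """Map an MMSE total (0-30) to a cognitive category.

    Cut-points: >=24 intact, 18-23 mild, 10-17 moderate, <=9 severe.
    """
    score = int(mmse_score)
    if score != mmse_score or not 0 <= score <= 30:
        raise ValueError(f"MMSE score must be an integer in [0, 30], got {mmse_score!r}")
    if score >= 24:
        return Cognition.INTACT
    if score >= 18:
        return Cognition.MILD
    if score >= 10:
        return Cognition.MODERATE
    return Cognition.SEVERE


def classify_function(adl_limitation_count: int) -> Function:
    """Map a count of limited ADL items (0-6) to a functional category."""
    count = int(adl_limitation_count)
    if count != adl_limitation_count or not 0 <= count <= 6:
        raise ValueError(
            f"ADL limitation count must be an integer in [0, 6], got {adl_limitation_count!r}"
        )
    if count == 0:
        return Function.ACTIVE
    if count <= 2:
        return Function.ADL_1_2
    return Function.ADL_3PLUS


def impairment_class(state: CompositeState) -> ImpairmentClass:
    """Impairment class of a living composite state (DEAD is a domain error)."""
    if state.is_dead:
        raise ValueError("impairment_class is undefined for DEAD")
    has_ci = state.cognition != Cognition.INTACT
    has_adl = state.function != Function.ACTIVE
    if has_ci and has_adl:
        return ImpairmentClass.CI_AND_ADL
    if has_ci:
        return ImpairmentClass.CI_ONLY
    if has_adl:
        return ImpairmentClass.ADL_ONLY
    return ImpairmentClass.NONE


def needs_nursing_home_care(state: CompositeState) -> bool:
    """True when the state implies nursing-home-type care needs.

    Defined as 3+ ADL limitations, or moderate-to-severe cognitive
    impairment, or both.
    """
    if state.is_dead:
        raise ValueError("care needs are undefined for DEAD")
    return state.function == Function.ADL_3PLUS or state.cognition in (
        Cognition.MODERATE,
        Cognition.SEVERE,
    )


def codebook() -> pd.DataFrame:
    """Machine-readable codebook for the 13 composite state codes.

    Also records the covariate codings used throughout: sex female=1,
    male=0; CI (any cognitive impairment) with-CI=1.
    """
    rows = []
    for s in LIVING_STATES:
        rows.append(
            {
                "code": s.code,
                "cognition": s.cognition.name,
                "function": _FUNCTION_CODE[s.function],
                "impairment_class": impairment_class(s).value,
                "nursing_home_flag": int(needs_nursing_home_care(s)),
            }
        )
    rows.append(
        {
            "code": CompositeState.DEAD.code,
            "cognition": "",
            "function": "",
            "impairment_class": "",
            "nursing_home_flag": 0,
        }
    )
    return pd.DataFrame(rows)
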