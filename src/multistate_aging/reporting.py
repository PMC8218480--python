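"""Summary metrics and table layouts for projection results.

Counts are reported in millions.  Age groups are 65-74, 75-84 and 85+
(inclusive); "impaired" means any cognitive impairment and/or any ADL
limitation; "care needs" means nursing-home-type care needs (3+ ADL
limitations or moderate-to-severe cognitive impairment or both).  Relative
change over a horizon is (v1/v0 - 1) x 100 and the annual relative change
column is that total divided by the horizon length in years — arithmetic,
not geometric, annualisation, which is the identity the published tables
satisfy.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .projection import ProjectionResult

__all__ = [
    "AGE_GROUPS",
    "aggregate",
    "relative_change",
    "annual_relative_change",
    "fraction_of",
    "care_needs_series",
    "make_tables",
]

MILLION = 1e6

#: Inclusive age-group bounds keyed by label; ages are 65..100+.
AGE_GROUPS = {"all": (65, 100), "65-74": (65, 74), "75-84": (75, 84), "85+": (85, 100)}

_SEX_INDEX = {"all": (0, 1), "male": (0,), "female": (1,)}

# (cognition, function) masks over the (4, 3) state grid
_COG = np.arange(4)[:, None] * np.ones((1, 3), dtype=int)
_FUN = np.ones((4, 1), dtype=int) * np.arange(3)[None, :]
_CLASS_MASKS = {
    "NONE": (_COG == 0) & (_FUN == 0),
    "ADL_ONLY": (_COG == 0) & (_FUN > 0),
    "CI_ONLY": (_COG > 0) & (_FUN == 0),
    "CI_AND_ADL": (_COG > 0) & (_FUN > 0),
}
_CLASS_MASKS["impaired"] = ~_CLASS_MASKS["NONE"]
_CLASS_MASKS["any"] = np.ones((4, 3), dtype=bool)
_CARE_MASK = (_FUN == 2) | (_COG >= 2)
_CLASS_MASKS["care_needs"] = _CARE_MASK
# decomposition of the care-needs set ("dementia" = moderate/severe CI)
_CLASS_MASKS["adl3_only"] = (_FUN == 2) & (_COG < 2)
_CLASS_MASKS["dementia_only"] = (_COG >= 2) & (_FUN < 2)
_CLASS_MASKS["dementia_and_adl3"] = (_COG >= 2) & (_FUN == 2)


def _aggregate_array(older_year: np.ndarray, sex: str, age_group: str, subset: str) -> float:
    """Sum a (2, 36, 4, 3) stock over a subset; result in millions."""
    try:
        lo, hi = AGE_GROUPS[age_group]
    except KeyError:
        raise ValueError(f"unknown age group {age_group!r}") from None
    try:
        sidx = _SEX_INDEX[sex]
    except KeyError:
        raise ValueError(f"unknown population subset {sex!r}") from None
    try:
        mask = _CLASS_MASKS[subset]
    except KeyError:
        raise ValueError(f"unknown grouping key {subset!r}") from None
    block = older_year[list(sidx), lo - 65 : hi - 65 + 1]
    return float(block[..., mask].sum()) / MILLION


def aggregate(
    projection: ProjectionResult,
    year: int,
    sex: str = "all",
    age_group: str = "all",
    subset: str = "any",
) -> float:
    """Older-adult count (millions) in a reporting cell.

    ``subset`` is an impairment class (NONE / ADL_ONLY / CI_ONLY /
    CI_AND_ADL), 'impaired', 'care_needs' (or its decomposition
    'adl3_only' / 'dementia_only' / 'dementia_and_adl3'), or 'any'.
    """
    return _aggregate_array(projection.older_population(year), sex, age_group, subset)


def relative_change(v0: float, v1: float) -> float:
    """Total percent change ((v1/v0) - 1) x 100."""
    if v0 <= 0:
        raise ValueError(f"baseline count must be positive, got {v0}")
    return (v1 / v0 - 1.0) * 100.0


def annual_relative_change(v0: float, v1: float, horizon_years: float = 45) -> float:
    """Arithmetic annualisation: total relative change over the horizon."""
    if horizon_years <= 0:
        raise ValueError("horizon must be positive")
    return relative_change(v0, v1) / horizon_years


def fraction_of(numerator: float, denominator: float) -> float:
    """Composition percentage numerator/denominator x 100."""
    if denominator <= 0:
        raise ValueError(f"denominator must be positive, got {denominator}")
    return numerator / denominator * 100.0


def care_needs_series(projection: ProjectionResult) -> pd.DataFrame:
    """Annual counts (millions) of nursing-home-type care needs.

    Columns decompose the care-needs population into 3+ ADL only (no
    dementia), dementia only (moderate/severe CI without 3+ ADL) and both.
    """
    rows = []
    for year in projection.years:
        rows.append(
            {
                "year": int(year),
                "care_needs_total": aggregate(projection, year, subset="care_needs"),
                "adl3_only": aggregate(projection, year, subset="adl3_only"),
                "dementia_only": aggregate(projection, year, subset="dementia_only"),
                "dementia_and_adl3": aggregate(projection, year, subset="dementia_and_adl3"),
            }
        )
    return pd.DataFrame(rows)


def _cell_value(older_year, sex, age_group, subset, kind, older_t0=None, horizon=None):
    v = _aggregate_array(older_year, sex, age_group, subset)
    if kind == "count":
        return v
    v0 = _aggregate_array(older_t0, sex, age_group, subset)
    if kind == "relative":
        return relative_change(v0, v)
    if kind == "annual":
        return annual_relative_change(v0, v, horizon)
    raise ValueError(kind)


def _fraction_cell(older_year, sex):
    return fraction_of(
        _aggregate_array(older_year, sex, "all", "impaired"),
        _aggregate_array(older_year, sex, "all", "any"),
    )


_ROUND = {"count": 3, "annual": 2, "relative": 1, "fraction": 2}


def make_tables(
    point: ProjectionResult,
    replicate_older: np.ndarray | None = None,
    t0: int = 2015,
    t1: int = 2060,
) -> dict[str, pd.DataFrame]:
    """Render the four summary tables and the care-needs series.

    ``replicate_older`` is an optional (R, n_years, 2, 36, 4, 3) stack of
    bootstrap-replicate stocks aligned with ``point.years``; when given,
    each cell is the string "point (lo-hi)" with 95% percentile bounds,
    otherwise cells are plain floats.  Counts are millions rounded (half
    to even) to 3 d.p.; annual changes to 2 d.p.; total changes to 1 d.p.
    """
    horizon = t1 - t0
    i0, i1 = point._index(t0), point._index(t1)
    if replicate_older is not None and replicate_older.shape[1:] != point.older.shape:
        raise ValueError("replicate stack does not match the point projection")

    def cell(fn, kind):
        v = np.round(fn(point.older[i0], point.older[i1]), _ROUND[kind])
        if replicate_older is None:
            return v
        vals = np.array(
            [fn(rep[i0], rep[i1]) for rep in replicate_older]
        )
        lo, hi = np.quantile(vals, [0.025, 0.975])
        d = _ROUND[kind]
        return f"{v:.{d}f} ({lo:.{d}f}-{hi:.{d}f})"

    def block(rows):
        # rows: list of (label, subset, sex, age_group) -> standard 4 columns
        recs = []
        for label, subset, sex, age_group in rows:
            if subset == "fraction":
                recs.append(
                    {
                        "row": label,
                        f"y{t0}": cell(lambda a, b: _fraction_cell(a, sex), "fraction"),
                        f"y{t1}": cell(lambda a, b: _fraction_cell(b, sex), "fraction"),
                        "annual_change_pct": cell(
                            lambda a, b: annual_relative_change(
                                _fraction_cell(a, sex), _fraction_cell(b, sex), horizon
                            ),
                            "annual",
                        ),
                        "relative_change_pct": cell(
                            lambda a, b: relative_change(
                                _fraction_cell(a, sex), _fraction_cell(b, sex)
                            ),
                            "relative",
                        ),
                    }
                )
                continue
            args = (sex, age_group, subset)
            recs.append(
                {
                    "row": label,
                    f"y{t0}": cell(lambda a, b: _aggregate_array(a, *args), "count"),
                    f"y{t1}": cell(lambda a, b: _aggregate_array(b, *args), "count"),
                    "annual_change_pct": cell(
                        lambda a, b: annual_relative_change(
                            _aggregate_array(a, *args), _aggregate_array(b, *args), horizon
                        ),
                        "annual",
                    ),
                    "relative_change_pct": cell(
                        lambda a, b: relative_change(
                            _aggregate_array(a, *args), _aggregate_array(b, *args)
                        ),
                        "relative",
                    ),
                }
            )
        return pd.DataFrame(recs)

    tables = {}
    rows1 = []
    for sex in ("all", "female", "male"):
        rows1 += [
            (f"{sex}: total older adult", "any", sex, "all"),
            (f"{sex}: without impairment", "NONE", sex, "all"),
            (f"{sex}: with impairment", "impaired", sex, "all"),
            (f"{sex}: fraction with impairment (%)", "fraction", sex, "all"),
        ]
    tables["table1"] = block(rows1)

    rows2 = [
        (f"{sex}: {ag}", "impaired", sex, ag)
        for sex in ("all", "female", "male")
        for ag in ("65-74", "75-84", "85+")
    ]
    tables["table2"] = block(rows2)

    rows3 = [
        (f"{sex}: {cls}", cls, sex, "all")
        for sex in ("all", "female", "male")
        for cls in ("ADL_ONLY", "CI_ONLY", "CI_AND_ADL")
    ]
    tables["table3"] = block(rows3)

    rows4 = [
        (f"{ag}: {cls}", cls, "all", ag)
        for ag in ("65-74", "75-84", "85+")
        for cls in ("ADL_ONLY", "CI_ONLY", "CI_AND_ADL")
    ]
    tables["table4"] = block(rows4)

    care = care_needs_series(point)
    if replicate_older is not None:
        # attach percentile bounds to the total care-needs column
        totals = np.array(
            [
                [
                    _aggregate_array(rep[y], "all", "all", "care_needs")
                    for y in range(rep.shape[0])
                ]
                for rep in replicate_older
            ]
        )
        care["care_needs_lo"] = np.quantile(totals, 0.025, axis=0)
        care["care_needs_hi"] = np.quantile(totals, 0.975, axis=0)
    tables["care_needs"] = care
    return tables
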