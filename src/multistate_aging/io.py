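"""CSV / YAML schemas shared by the library and the command line.

All tabular artefacts are plain CSV: survey records, tidy coefficient and
rate tables, demographic inputs (population.csv, fertility.csv,
lifetable.csv, migration.csv), projection stocks and flows.  Configuration
(the assumption schedule) round-trips through YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .estimation import (
    COGNITIVE,
    FUNCTIONAL,
    TransitionModelCoefficients,
    TransitionRateTable,
    validate_survey,
)
from .projection import AssumptionSchedule, DemographicInputs, ProjectionResult
from .states import CompositeState

__all__ = [
    "read_survey",
    "write_survey",
    "write_coefficients",
    "read_coefficients",
    "write_rate_table",
    "read_rate_table",
    "write_demographics",
    "read_demographics",
    "write_projection",
    "read_schedule",
    "write_schedule",
]


def read_survey(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"respondent_id": str}, keep_default_na=False)
    df["age_w1"] = df["age_w1"].astype(int)
    df["weight"] = df["weight"].astype(float)
    df["dead_w2"] = df["dead_w2"].astype(int)
    return validate_survey(df)


def write_survey(survey: pd.DataFrame, path: str | Path) -> None:
    survey.to_csv(path, index=False)


def write_coefficients(
    cog: TransitionModelCoefficients, fun: TransitionModelCoefficients, path: str | Path
) -> None:
    """Natural-scale coefficients of both processes as one tidy CSV."""
    pd.concat([cog.natural_frame(), fun.natural_frame()], ignore_index=True).to_csv(
        path, index=False
    )


def read_coefficients(
    path: str | Path,
) -> tuple[TransitionModelCoefficients, TransitionModelCoefficients]:
    frame = pd.read_csv(path)
    return (
        TransitionModelCoefficients.from_natural_frame(frame, COGNITIVE),
        TransitionModelCoefficients.from_natural_frame(frame, FUNCTIONAL),
    )


def write_rate_table(table: TransitionRateTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False)


def read_rate_table(path: str | Path) -> TransitionRateTable:
    return TransitionRateTable.from_frame(pd.read_csv(path, keep_default_na=False))


def write_demographics(inputs: DemographicInputs, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sexlab = ("male", "female")
    pop = [
        {"age": a, "sex": sexlab[s], "count": inputs.initial_population[s, a]}
        for s in (0, 1)
        for a in range(101)
    ]
    pd.DataFrame(pop).to_csv(out / "population.csv", index=False)
    fert = [
        {"year": y, "age": 15 + i, "rate": r}
        for y, rates in sorted(inputs.fertility.items())
        for i, r in enumerate(rates)
    ]
    pd.DataFrame(fert).to_csv(out / "fertility.csv", index=False)
    lt = [
        {"age": a, "sex": sexlab[s], "qx": inputs.life_table[s, a]}
        for s in (0, 1)
        for a in range(65)
    ]
    pd.DataFrame(lt).to_csv(out / "lifetable.csv", index=False)
    mig = [
        {"year": y, "age": a, "sex": sexlab[s], "net": m[s, a]}
        for y, m in sorted(inputs.migration.items())
        for s in (0, 1)
        for a in range(65)
    ]
    pd.DataFrame(mig, columns=["year", "age", "sex", "net"]).to_csv(
        out / "migration.csv", index=False
    )


def read_demographics(in_dir: str | Path, sex_ratio_at_birth: float = 1.05) -> DemographicInputs:
    d = Path(in_dir)
    sex_idx = {"male": 0, "female": 1}
    pop = np.zeros((2, 101))
    for row in pd.read_csv(d / "population.csv").itertuples(index=False):
        pop[sex_idx[row.sex], int(row.age)] = row.count
    fertility: dict[int, np.ndarray] = {}
    for row in pd.read_csv(d / "fertility.csv").itertuples(index=False):
        fertility.setdefault(int(row.year), np.zeros(35))[int(row.age) - 15] = row.rate
    lt = np.zeros((2, 65))
    for row in pd.read_csv(d / "lifetable.csv").itertuples(index=False):
        lt[sex_idx[row.sex], int(row.age)] = row.qx
    migration: dict[int, np.ndarray] = {}
    mig_path = d / "migration.csv"
    if mig_path.exists():
        mig = pd.read_csv(mig_path)
        for row in mig.itertuples(index=False):
            migration.setdefault(int(row.year), np.zeros((2, 65)))[
                sex_idx[row.sex], int(row.age)
            ] = row.net
    inputs = DemographicInputs(
        initial_population=pop,
        fertility=fertility,
        life_table=lt,
        migration=migration,
        sex_ratio_at_birth=sex_ratio_at_birth,
    )
    inputs.validate()
    return inputs


def write_projection(result: ProjectionResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.older_frame().to_csv(out / "projection.csv", index=False)
    result.flows.to_csv(out / "flows.csv", index=False)


def read_schedule(path: str | Path | None) -> AssumptionSchedule:
    if path is None:
        return AssumptionSchedule()
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    allowed = set(AssumptionSchedule.__dataclass_fields__)
    unknown = set(cfg) - allowed
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    return AssumptionSchedule(**cfg)


def write_schedule(schedule: AssumptionSchedule, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(schedule.__dict__, fh)
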