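"""Core record types, intake bookkeeping, and standardization.

The geometric framework for nutrition tracks every individual's cumulative
intake of protein (P) and carbohydrate (C) in mg of dry mass, together with
the life-history traits measured on it (life span in days, daily and lifetime
reproductive effort).  All downstream stages — response-surface fits,
between-group comparisons, the pedigree animal model — consume the tabular
containers defined here.

Tables are plain :class:`pandas.DataFrame` objects with a documented column
contract (see :data:`INTAKE_COLUMNS`); small frozen dataclasses carry the
per-diet and per-individual metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: canonical intake-table columns; trait columns are optional
INTAKE_COLUMNS = (
    "individual_id",
    "sex",
    "design_cell",
    "p_intake",
    "c_intake",
)

#: trait columns recognised in delimited files (file header -> internal name)
TRAIT_COLUMNS = {"lifespan_d": "lifespan", "dre": "dre", "lre": "lre"}

SEXES = ("male", "female")


@dataclass(frozen=True)
class DietComposition:
    """A single artificial diet: proportions of dry mass that are P and C.

    An animal confined to one diet can only move along that diet's
    "nutritional rail" — the line in (P, C) intake space with slope
    ``c_frac / p_frac``.
    """

    diet_id: str
    p_frac: float
    c_frac: float

    def __post_init__(self) -> None:
        if self.p_frac < 0 or self.c_frac < 0:
            raise ValueError(
                f"diet {self.diet_id!r}: nutrient fractions must be >= 0 "
                f"(got p_frac={self.p_frac}, c_frac={self.c_frac})"
            )
        if self.p_frac + self.c_frac > 1 + 1e-12:
            raise ValueError(
                f"diet {self.diet_id!r}: p_frac + c_frac = "
                f"{self.p_frac + self.c_frac:.4f} exceeds 1"
            )

    @property
    def pc_ratio(self) -> float:
        """P:C ratio expressed as P per unit C."""
        return self.p_frac / self.c_frac


@dataclass(frozen=True)
class PedigreeEntry:
    """One pedigree row; unknown parents are ``None``."""

    individual_id: str
    sire_id: str | None
    dam_id: str | None
    sex: str


def convert_consumption(
    dry_mass_consumed: float, diet: DietComposition, record: str | None = None
) -> tuple[float, float]:
    """Convert consumed dry diet mass (mg) into ingested P and C (mg).

    Intake is the product of the mass eaten and the diet's nutrient
    fractions, so the map is linear in mass.
    """
    if dry_mass_consumed < 0:
        where = f" in record {record!r}" if record else ""
        raise ValueError(
            f"negative consumed mass {dry_mass_consumed} mg{where} "
            f"(diet {diet.diet_id!r})"
        )
    return dry_mass_consumed * diet.p_frac, dry_mass_consumed * diet.c_frac


# ---------------------------------------------------------------------------
# standardization


@dataclass
class StandardizedTable:
    """An intake table on the z-scale plus the scaling needed to undo it.

    ``scaling`` maps ``(group, column) -> (mean, sd)``.  ``group_by`` is the
    column used to define standardization groups ("" when pooled).
    """

    data: pd.DataFrame
    scaling: dict[tuple[str, str], tuple[float, float]]
    group_by: str | None

    def back_transform(self) -> pd.DataFrame:
        """Undo the z-transformation using the stored (mean, sd) factors."""
        out = self.data.copy()
        for (group, col), (mu, sd) in self.scaling.items():
            if self.group_by is None:
                mask = slice(None)
            else:
                mask = out[self.group_by] == group
            out.loc[mask, col] = out.loc[mask, col] * sd + mu
        return out


def z_standardize(
    table: pd.DataFrame,
    columns: Sequence[str] | None = None,
    group_by: str | None = "sex",
) -> StandardizedTable:
    """Z-transform intake and trait columns to mean 0, SD 1 within groups.

    Parameters
    ----------
    table:
        Intake table following the :data:`INTAKE_COLUMNS` contract.
    columns:
        Columns to standardize.  Defaults to ``p_intake``, ``c_intake`` and
        any recognised trait columns present.
    group_by:
        Column defining the standardization groups (default per sex, which is
        how single-group response surfaces are fitted); ``None`` pools all
        rows.

    The SD uses the n-1 (sample) denominator.  Missing trait values are
    ignored when computing moments and stay missing afterwards.
    """
    if columns is None:
        columns = [c for c in ("p_intake", "c_intake", "lifespan", "dre", "lre")
                   if c in table.columns]
    out = table.copy()
    scaling: dict[tuple[str, str], tuple[float, float]] = {}
    if group_by is None:
        groups: Iterable[tuple[str, pd.DataFrame]] = [("", out)]
    else:
        groups = out.groupby(group_by, observed=True, sort=True)
    for gname, gdf in groups:
        gname = str(gname)
        for col in columns:
            vals = gdf[col].to_numpy(dtype=float)
            finite = vals[np.isfinite(vals)]
            if len(np.unique(finite)) < 2:
                raise ValueError(
                    f"column {col!r} in group {gname!r} has fewer than two "
                    "distinct finite values; cannot z-standardize"
                )
            mu = float(finite.mean())
            sd = float(finite.std(ddof=1))
            if sd == 0:
                raise ValueError(
                    f"column {col!r} in group {gname!r} has zero variance"
                )
            idx = gdf.index
            out.loc[idx, col] = (vals - mu) / sd
            scaling[(gname, col)] = (mu, sd)
    return StandardizedTable(data=out, scaling=scaling, group_by=group_by)


# ---------------------------------------------------------------------------
# i/o


def validate_intake_table(table: pd.DataFrame) -> list[str]:
    """Row-level diagnostics for an intake table; returns human messages."""
    findings: list[str] = []
    for col in INTAKE_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"intake table is missing required column {col!r}")
    bad_sex = ~table["sex"].isin(SEXES)
    for i in table.index[bad_sex]:
        findings.append(f"row {i}: unrecognised sex {table.loc[i, 'sex']!r}")
    for col in ("p_intake", "c_intake"):
        vals = pd.to_numeric(table[col], errors="coerce")
        for i in table.index[vals.isna()]:
            findings.append(f"row {i}: non-numeric {col}")
        for i in table.index[vals < 0]:
            findings.append(f"row {i}: negative {col} ({vals[i]})")
    return findings


def read_intake_table(path) -> pd.DataFrame:
    """Read a comma-separated intake table.

    Expected header: ``individual_id, sex, diet`` (or ``diet_pair``),
    ``p_intake_mg, c_intake_mg`` and optionally ``lifespan_d, dre, lre``.
    Rows with missing P or C intake are rejected; missing traits propagate
    as NaN.
    """
    raw = pd.read_csv(path)
    rename = {"p_intake_mg": "p_intake", "c_intake_mg": "c_intake"}
    for cand in ("diet", "diet_pair"):
        if cand in raw.columns:
            rename[cand] = "design_cell"
    rename.update({k: v for k, v in TRAIT_COLUMNS.items() if k in raw.columns})
    df = raw.rename(columns=rename)
    missing = df["p_intake"].isna() | df["c_intake"].isna()
    if missing.any():
        rows = ", ".join(str(i) for i in df.index[missing][:5])
        raise ValueError(f"rows with missing P or C intake rejected: {rows}")
    df["individual_id"] = df["individual_id"].astype(str)
    findings = validate_intake_table(df)
    neg = [f for f in findings if "negative" in f]
    if neg:
        raise ValueError("; ".join(neg))
    return df


def write_intake_table(table: pd.DataFrame, path) -> None:
    out = table.rename(
        columns={"p_intake": "p_intake_mg", "c_intake": "c_intake_mg",
                 "design_cell": "diet",
                 "lifespan": "lifespan_d"})
    out.to_csv(path, index=False)


def read_pedigree(path) -> list[PedigreeEntry]:
    """Read a comma-separated pedigree (columns id, sire, dam, sex).

    Unknown parents are coded as empty fields or ``0``.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    entries = []
    for _, row in df.iterrows():
        sire = row["sire"] if row["sire"] not in ("", "0") else None
        dam = row["dam"] if row["dam"] not in ("", "0") else None
        entries.append(PedigreeEntry(str(row["id"]), sire, dam, row["sex"]))
    check_pedigree(entries)
    return entries


def write_pedigree(entries: Sequence[PedigreeEntry], path) -> None:
    df = pd.DataFrame(
        {
            "id": [e.individual_id for e in entries],
            "sire": [e.sire_id or "0" for e in entries],
            "dam": [e.dam_id or "0" for e in entries],
            "sex": [e.sex for e in entries],
        }
    )
    df.to_csv(path, index=False)


def check_pedigree(entries: Sequence[PedigreeEntry]) -> list[PedigreeEntry]:
    """Validate and topologically sort a pedigree (founders first).

    Raises on cycles (an individual being its own ancestor) and on parent
    ids that do not resolve to a listed individual.
    """
    by_id = {e.individual_id: e for e in entries}
    if len(by_id) != len(entries):
        seen: set[str] = set()
        for e in entries:
            if e.individual_id in seen:
                raise ValueError(f"duplicate pedigree id {e.individual_id!r}")
            seen.add(e.individual_id)
    for e in entries:
        for parent in (e.sire_id, e.dam_id):
            if parent is not None and parent not in by_id:
                raise ValueError(
                    f"individual {e.individual_id!r} references unknown "
                    f"parent {parent!r}"
                )
    order: list[PedigreeEntry] = []
    state: dict[str, int] = {}  # 0 visiting, 1 done

    def visit(eid: str, chain: list[str]) -> None:
        st = state.get(eid)
        if st == 1:
            return
        if st == 0:
            cyc = " -> ".join(chain[chain.index(eid):] + [eid])
            raise ValueError(f"pedigree cycle detected: {cyc}")
        state[eid] = 0
        e = by_id[eid]
        for parent in (e.sire_id, e.dam_id):
            if parent is not None:
                visit(parent, chain + [eid])
        state[eid] = 1
        order.append(e)

    for e in entries:
        visit(e.individual_id, [])
    return order
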