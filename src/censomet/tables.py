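"""Core data containers and I/O for wide metabolite-abundance tables.

An abundance table is a samples x metabolites matrix of non-negative
peak areas in which a *missing* cell means the metabolite was below the
limit of quantification (BLQ) in that sample.  Missingness is a distinct
state carried as NaN internally and as an empty cell on disk — never as
zero, because a non-detected metabolite has an unknown (small) amount,
not a zero amount.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "SampleInfo",
    "read_abundance",
    "write_abundance",
    "read_sample_info",
    "write_sample_info",
    "read_annotation",
    "runday_normalize",
    "harmonize_cohorts",
]


class AbundanceTable:
    """Samples x metabolites matrix of non-negative amounts with explicit
    below-LOQ missingness.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by sample id, columns by metabolite id.  NaN marks a
        missing (below-LOQ) cell.  All present values must be >= 0.
    provenance : str
        Free-text label describing where the table came from.
    """

    def __init__(self, data: pd.DataFrame, provenance: str = ""):
        data = data.astype(float)
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if data.columns.has_duplicates:
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate metabolite ids: {dups}")
        if (data.to_numpy() < 0).any():
            raise ValueError("abundance values must be non-negative")
        self.data = data
        self.provenance = provenance

    # -- basic introspection -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.data.shape[1]

    def missing_mask(self) -> pd.DataFrame:
        """Boolean frame, True where a cell is below LOQ."""
        return self.data.isna()

    def n_missing(self) -> pd.Series:
        """Missing-cell count per metabolite."""
        return self.data.isna().sum(axis=0)

    # -- manipulation --------------------------------------------------------

    def select_metabolites(self, ids: Sequence[str]) -> "AbundanceTable":
        missing = [i for i in ids if i not in self.data.columns]
        if missing:
            raise KeyError(f"unknown metabolite ids: {missing[:5]}")
        return AbundanceTable(self.data[list(ids)], self.provenance)

    def select_samples(self, ids: Sequence[str]) -> "AbundanceTable":
        missing = [i for i in ids if i not in self.data.index]
        if missing:
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        return AbundanceTable(self.data.loc[list(ids)], self.provenance)

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        if not isinstance(other, AbundanceTable):
            return NotImplemented
        return self.data.equals(other.data)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"AbundanceTable({self.n_samples} samples x "
            f"{self.n_metabolites} metabolites, "
            f"{int(self.data.isna().sum().sum())} missing cells)"
        )


@dataclass(frozen=True)
class SampleInfo:
    """Per-sample metadata: study group, pairing and covariates.

    Groups: ``D`` (healthy sibling donor), ``Rs`` (transplant recipient
    without acute GvHD), ``Ra`` (recipient at acute GvHD onset).
    ``pair_id`` links a donor to their recipient.
    """

    sample_id: str
    subject_role: Literal["donor", "recipient"]
    group: Literal["D", "Rs", "Ra"]
    pair_id: str | None = None
    age: float = float("nan")
    sex: Literal["M", "F"] = "M"
    bmi: float = float("nan")
    runday: str = "day1"

    def __post_init__(self):
        if self.subject_role == "donor" and self.group != "D":
            raise ValueError(f"{self.sample_id}: donors must be group D")
        if self.subject_role == "recipient" and self.group not in ("Rs", "Ra"):
            raise ValueError(f"{self.sample_id}: recipients must be Rs or Ra")


def validate_pairing(info: Iterable[SampleInfo]) -> None:
    """Each pair id may appear in at most one donor and one recipient."""
    seen: dict[tuple[str, str], str] = {}
    for rec in info:
        if rec.pair_id is None:
            continue
        key = (rec.pair_id, rec.subject_role)
        if key in seen:
            raise ValueError(
                f"pair {rec.pair_id!r} has two {rec.subject_role}s: "
                f"{seen[key]}, {rec.sample_id}"
            )
        seen[key] = rec.sample_id


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_DIALECT_SEP = {"csv": ",", "tsv": "\t"}


def read_abundance(path: str | Path, dialect: Literal["csv", "tsv"] = "csv",
                   provenance: str | None = None) -> AbundanceTable:
    """Read a wide abundance table.

    Header row holds metabolite ids, first column holds sample ids, empty
    cells are below-LOQ.  Negative or non-numeric (non-empty) cells raise.
    """
    sep = _DIALECT_SEP[dialect]
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from None
    return AbundanceTable(df, provenance if provenance is not None else str(path))


def write_abundance(t: AbundanceTable, path: str | Path,
                    dialect: Literal["csv", "tsv"] = "csv") -> None:
    """Write a table; missing cells serialize as empty strings."""
    t.data.to_csv(path, sep=_DIALECT_SEP[dialect], na_rep="")


def read_sample_info(path: str | Path) -> list[SampleInfo]:
    df = pd.read_csv(path, dtype={"sample_id": str, "pair_id": str, "runday": str})
    out = []
    for row in df.itertuples(index=False):
        pair = getattr(row, "pair_id", None)
        if pair is not None and (pd.isna(pair) or pair == ""):
            pair = None
        out.append(SampleInfo(
            sample_id=str(row.sample_id),
            subject_role=row.subject_role,
            group=row.group,
            pair_id=pair,
            age=float(row.age),
            sex=row.sex,
            bmi=float(row.bmi),
            runday=str(row.runday),
        ))
    validate_pairing(out)
    return out


def write_sample_info(info: Sequence[SampleInfo], path: str | Path) -> None:
    pd.DataFrame([vars(s) for s in info]).to_csv(path, index=False)


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Metabolite annotations: sub/super pathway plus microbial and
    xenobiotic flags, indexed by metabolite id."""
    df = pd.read_csv(path, dtype={"metabolite_id": str}).set_index("metabolite_id")
    for col in ("super_pathway", "sub_pathway"):
        if col not in df.columns:
            raise ValueError(f"annotation file missing column {col!r}")
    for col in ("microbial", "xenobiotic"):
        df[col] = df[col].astype(bool)
    return df


# ---------------------------------------------------------------------------
# Run-day normalization and cohort harmonization
# ---------------------------------------------------------------------------

def runday_normalize(t: AbundanceTable, info: Sequence[SampleInfo]) -> AbundanceTable:
    """Scale each metabolite within each run-day block so the median of its
    *detected* values equals 1.00.

    Below-LOQ cells carry no magnitude, so medians are taken over detected
    values only and missing cells are left untouched.  A metabolite with no
    detected value in some block cannot be scaled there: it is left as-is in
    that block and a warning names it.
    """
    runday = {s.sample_id: s.runday for s in info}
    missing_meta = [sid for sid in t.sample_ids if sid not in runday]
    if missing_meta:
        raise ValueError(f"samples without run-day label: {missing_meta[:5]}")

    out = t.data.copy()
    flagged: list[tuple[str, str]] = []
    blocks = pd.Series({sid: runday[sid] for sid in t.sample_ids})
    for block, sample_idx in blocks.groupby(blocks).groups.items():
        sub = out.loc[sample_idx]
        med = sub.median(axis=0, skipna=True)  # detected values only
        all_missing = med.isna()
        if all_missing.any():
            flagged.extend((str(block), m) for m in med.index[all_missing])
            med = med.fillna(1.0)  # leave unscaled
        out.loc[sample_idx] = sub / med
    if flagged:
        warnings.warn(
            f"{len(flagged)} (block, metabolite) cells had no detected value "
            f"and were left unscaled, e.g. {flagged[:3]}",
            stacklevel=2,
        )
    return AbundanceTable(out, t.provenance)


def harmonize_cohorts(a: AbundanceTable, b: AbundanceTable
                      ) -> tuple[AbundanceTable, AbundanceTable, list[str]]:
    """Restrict two cohorts to their shared metabolites, in a common
    column order (order of appearance in the first table)."""
    shared = [m for m in a.metabolite_ids if m in set(b.metabolite_ids)]
    if not shared:
        raise ValueError("cohorts share no metabolite ids")
    return a.select_metabolites(shared), b.select_metabolites(shared), shared
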