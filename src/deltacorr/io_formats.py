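"""Readers and writers for the on-disk artifacts of a delta-corr analysis.

All tabular inputs are UTF-8 tab-separated files with a header row (GMT files
excepted, which follow the usual one-set-per-line convention). Gene and sample
identifiers are opaque, case-sensitive strings; matching between the mRNA and
protein layers is by exact string equality of sample ids. Missing abundance
values are encoded as empty cells or ``NA`` on disk and as NaN in memory.
"""

from __future__ import annotations

import math
import os
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CONDITIONS = ("tumor", "normal")

_NA_STRINGS = ["", "NA"]


class FormatError(ValueError):
    """A file violated the expected format; the message names the offender."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AbundanceMatrix:
    """One omics layer: genes x samples, log2 abundances, NaN = missing.

    Parameters
    ----------
    layer : str
        Either ``"mRNA"`` or ``"protein"``; fixed at construction.
    data : pandas.DataFrame
        Genes in rows (index), samples in columns, float values.
    """

    layer: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.layer not in ("mRNA", "protein"):
            raise ValueError(f"layer must be 'mRNA' or 'protein', got {self.layer!r}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dups}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def gene_values(self, gene: str) -> pd.Series:
        if gene not in self.data.index:
            raise KeyError(f"gene {gene!r} not present in {self.layer} matrix")
        return self.data.loc[gene]

    def n_missing(self) -> int:
        return int(self.data.isna().sum().sum())


@dataclass(frozen=True)
class CohortDesign:
    """Sample annotations: condition (tumor/normal), cohort, optional stage
    and patient id. Backed by a DataFrame indexed by sample_id."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"condition", "cohort"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"design is missing required columns: {sorted(missing)}")
        if self.table.index.duplicated().any():
            dups = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids in design: {dups}")
        bad = set(self.table["condition"]) - set(CONDITIONS)
        if bad:
            raise FormatError(
                f"illegal condition values {sorted(bad)}; allowed: {list(CONDITIONS)}"
            )

    @property
    def samples(self) -> list[str]:
        return list(self.table.index)

    def condition(self, sample: str) -> str:
        return self.table.loc[sample, "condition"]

    def samples_for(self, condition: str, cohort: str | None = None) -> list[str]:
        mask = self.table["condition"] == condition
        if cohort is not None:
            mask &= self.table["cohort"] == cohort
        return list(self.table.index[mask])

    def stage_of(self, sample: str) -> str | None:
        if "stage" not in self.table.columns:
            return None
        val = self.table.loc[sample, "stage"]
        return None if pd.isna(val) else str(val)

    @property
    def cohorts(self) -> list[str]:
        return sorted(self.table["cohort"].unique())


@dataclass(frozen=True)
class MutationTable:
    """Somatic mutation records (gene, sample_id, variant_class) with a
    derived binary status: mutated iff at least one retained record."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene", "sample_id", "variant_class"}
        missing = required - set(self.records.columns)
        if missing:
            raise FormatError(f"mutation table is missing columns: {sorted(missing)}")

    def status(self, gene: str, sample: str) -> bool:
        rec = self.records
        return bool(((rec["gene"] == gene) & (rec["sample_id"] == sample)).any())

    def mutated_samples(self, gene: str) -> set[str]:
        rec = self.records
        return set(rec.loc[rec["gene"] == gene, "sample_id"])

    def mutated_pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.records["gene"], self.records["sample_id"]))

    @property
    def genes(self) -> list[str]:
        return sorted(self.records["gene"].unique())


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (insertion-ordered) with an optional universe."""

    sets: dict[str, tuple[str, frozenset[str]]]  # id -> (description, members)
    universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        for set_id, (_, members) in self.sets.items():
            if not members:
                raise FormatError(f"gene set {set_id!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def members(self, set_id: str) -> frozenset[str]:
        return self.sets[set_id][1]

    def description(self, set_id: str) -> str:
        return self.sets[set_id][0]


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_abundance(path: str | os.PathLike, layer: str) -> AbundanceMatrix:
    """Read a genes-x-samples abundance TSV into an :class:`AbundanceMatrix`.

    First column holds gene symbols; remaining columns are sample ids.
    Empty cells and ``NA`` become NaN. Duplicate gene rows, duplicate sample
    columns, and non-numeric non-empty cells are rejected.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    raw = pd.read_csv(
        path, sep="\t", dtype=str, index_col=0, keep_default_na=False,
        na_values=_NA_STRINGS,
    )
    raw.index = raw.index.astype(str)
    if raw.index.duplicated().any():
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate gene rows: {dups}")
    if raw.columns.duplicated().any():
        dups = raw.columns[raw.columns.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate sample columns: {dups}")
    try:
        data = raw.astype(float)
    except ValueError:
        # locate the first offending cell to name it in the error
        for col in raw.columns:
            coerced = pd.to_numeric(raw[col], errors="coerce")
            bad = coerced.isna() & raw[col].notna()
            if bad.any():
                gene = raw.index[bad][0]
                raise FormatError(
                    f"{path}: non-numeric value {raw.loc[gene, col]!r} "
                    f"at gene {gene!r}, sample {col!r}"
                ) from None
        raise
    return AbundanceMatrix(layer=layer, data=data)


def read_design(path: str | os.PathLike) -> CohortDesign:
    """Read the sample annotation TSV (sample_id, condition, cohort,
    optional stage / patient_id)."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    table = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, na_values=_NA_STRINGS
    )
    required = {"sample_id", "condition", "cohort"}
    missing = required - set(table.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns: {sorted(missing)}")
    if table["sample_id"].duplicated().any():
        dups = table.loc[table["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"{path}: duplicate sample_id values: {dups}")
    table = table.set_index("sample_id")
    return CohortDesign(table=table)


def read_mutations(
    path: str | os.PathLike, keep_classes: Iterable[str] | None = None
) -> MutationTable:
    """Read a MAF-like mutation TSV (gene, sample_id, variant_class).

    When ``keep_classes`` is given only records whose variant_class is in the
    set are retained; by default every record counts.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    rec = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"gene", "sample_id", "variant_class"}
    missing = required - set(rec.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns: {sorted(missing)}")
    if keep_classes is not None:
        keep = set(keep_classes)
        rec = rec[rec["variant_class"].isin(keep)].reset_index(drop=True)
    return MutationTable(records=rec)


def read_gmt(path: str | os.PathLike) -> GeneSetCollection:
    """Read a standard GMT file: per line ``set_id<TAB>description<TAB>genes...``.

    Duplicate members within a set are collapsed; set order is preserved.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields "
                    f"(id, description, members...), got {len(fields)}"
                )
            set_id, desc = fields[0], fields[1]
            members = frozenset(g for g in fields[2:] if g)
            if not members:
                raise FormatError(f"{path}: line {lineno}: set {set_id!r} has no members")
            if set_id in sets:
                raise FormatError(f"{path}: line {lineno}: duplicate set id {set_id!r}")
            sets[set_id] = (desc, members)
    return GeneSetCollection(sets=sets)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_results(records: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a result table as TSV with deterministic column order and ``NA``
    for missing values, atomically (temp file + rename).

    Floats are written with ``repr`` precision so read-back reproduces the
    stored values exactly (including subnormals such as 1e-300).
    """
    _atomic_to_csv(records, path, index=False)


def read_results(path: str | os.PathLike) -> pd.DataFrame:
    """Read back a result TSV written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t", keep_default_na=False, na_values=_NA_STRINGS)


def write_abundance(matrix: AbundanceMatrix, path: str | os.PathLike) -> None:
    _atomic_to_csv(matrix.data, path, index=True, index_label="gene")


def write_design(design: CohortDesign, path: str | os.PathLike) -> None:
    _atomic_to_csv(design.table, path, index=True, index_label="sample_id")


def write_mutations(mutations: MutationTable, path: str | os.PathLike) -> None:
    _atomic_to_csv(mutations.records, path, index=False)


def _atomic_to_csv(df: pd.DataFrame, path: str | os.PathLike, **kwargs) -> None:
    directory = os.path.dirname(os.fspath(path)) or "."
    fd, tmp = tempfile.mkstemp(dir=directory, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="") as fh:
            df.to_csv(fh, sep="\t", na_rep="NA", **kwargs)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
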