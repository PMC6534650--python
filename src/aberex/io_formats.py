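"""Readers/writers for the plain-text formats the pipeline touches.

Conventions
-----------
* Expression matrices are tab-separated: first column gene identifier,
  header row of sample identifiers, values are normalized log-scale
  expression.  In memory they are pandas DataFrames (genes x samples).
* Phenotype tables are tab-separated with a header; the first column is the
  sample identifier.  Required column: ``diagnosis``.
* Gene sets use the GMT format (name, description, then member symbols).
* Candidate-gene lists are one symbol per line.

Gene identity is case-sensitive exact string match on symbols; no alias
mapping is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "GmtParseError",
    "read_gmt",
    "write_gmt",
    "restrict_to_background",
    "read_expression",
    "write_expression",
    "validate_expression",
    "read_phenotype",
    "write_phenotype",
    "read_gene_list",
    "write_gene_list",
]

DIAGNOSES = ("control", "AUT", "SCZ", "BPD")


class GmtParseError(ValueError):
    """Raised for malformed GMT content (carries the offending line number)."""


@dataclass(frozen=True)
class GeneSet:
    """A named gene set.

    ``total_count`` is the size of the set as originally read; after
    background restriction ``included_count`` holds the number of members
    found in the analyzed expression data, so a set can be reported as
    ``"34/79"`` (included/total).
    """

    name: str
    description: str
    members: frozenset
    total_count: int
    included_count: int | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")
        if self.included_count is not None and self.included_count > self.total_count:
            raise ValueError(
                f"gene set {self.name!r}: included_count {self.included_count} "
                f"> total_count {self.total_count}"
            )

    @property
    def label(self) -> str:
        """`included/total` as printed in results tables."""
        inc = len(self.members) if self.included_count is None else self.included_count
        return f"{inc}/{self.total_count}"


class GeneSetCollection:
    """An ordered collection of uniquely named :class:`GeneSet` objects."""

    def __init__(self, sets: Iterable[GeneSet]):
        self.sets: list[GeneSet] = list(sets)
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate gene set name(s): {', '.join(dupes)}")
        self._by_name: Mapping[str, GeneSet] = {s.name: s for s in self.sets}

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: one gene set per line, tab-separated
    ``name<TAB>description<TAB>gene1<TAB>gene2...``.

    Duplicate gene symbols within a line are deduplicated; the order of sets
    is preserved.  A line with fewer than 3 fields or a repeated set name is
    an error.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, description = fields[0], fields[1]
            genes = [g for g in fields[2:] if g]
            if not genes:
                raise GmtParseError(f"{path}: line {lineno}: set {name!r} has no genes")
            members = frozenset(genes)
            sets.append(GeneSet(name, description, members, total_count=len(members)))
    return GeneSetCollection(sets)


def write_gmt(coll: GeneSetCollection, path) -> None:
    """Write a collection back to GMT (members sorted for stable output)."""
    with open(path, "w") as fh:
        for s in coll:
            fh.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")


def restrict_to_background(
    coll: GeneSetCollection,
    background: Iterable[str],
    min_included: int = 2,
) -> GeneSetCollection:
    """Intersect every set with the analyzed-gene background.

    ``included_count`` becomes the intersection size while ``total_count``
    keeps the original set size, so results can be reported as
    ``included/total``.  Sets with fewer than ``min_included`` background
    genes are dropped.  Idempotent for a fixed background.
    """
    bg = frozenset(background)
    if not bg:
        raise ValueError("background is empty")
    if min_included < 2:
        raise ValueError("min_included must be >= 2")
    out = []
    for s in coll:
        kept = s.members & bg
        if len(kept) < min_included:
            continue
        out.append(replace(s, members=kept, included_count=len(kept)))
    return GeneSetCollection(out)


# ---------------------------------------------------------------------------
# Expression matrices and phenotype tables


def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Check the expression-matrix invariants: unique gene and sample
    identifiers and finite values."""
    if expr.index.has_duplicates:
        dupes = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene identifiers: {dupes[:5]}")
    if expr.columns.has_duplicates:
        dupes = expr.columns[expr.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample identifiers: {dupes[:5]}")
    values = expr.to_numpy()
    if not np.isfinite(values).all():
        bad = int((~np.isfinite(values)).sum())
        raise ValueError(f"expression matrix contains {bad} non-finite value(s)")
    return expr


def read_expression(path) -> pd.DataFrame:
    expr = pd.read_csv(path, sep="\t", index_col=0)
    expr.index = expr.index.astype(str)
    expr.columns = expr.columns.astype(str)
    return validate_expression(expr.astype(float))


def write_expression(expr: pd.DataFrame, path) -> None:
    validate_expression(expr)
    expr.to_csv(path, sep="\t", index_label="gene")


def read_phenotype(path, expression: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read a phenotype table (tab-separated, first column sample id).

    If ``expression`` is given, the sample ids must match its columns exactly
    and the table is reordered to the expression column order.
    """
    samples = pd.read_csv(path, sep="\t", index_col=0)
    samples.index = samples.index.astype(str)
    if samples.index.has_duplicates:
        raise ValueError("duplicate sample identifiers in phenotype table")
    if "diagnosis" not in samples.columns:
        raise ValueError("phenotype table lacks a 'diagnosis' column")
    if samples["diagnosis"].isna().any() or (samples["diagnosis"] == "").any():
        raise ValueError("phenotype table has empty diagnosis entries")
    unknown = set(samples["diagnosis"]) - set(DIAGNOSES)
    if unknown:
        raise ValueError(f"unknown diagnosis value(s): {sorted(unknown)}")
    if expression is not None:
        if set(samples.index) != set(expression.columns):
            raise ValueError("phenotype sample ids do not match expression columns")
        samples = samples.loc[expression.columns]
    return samples


def write_phenotype(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index_label="sample_id")


def read_gene_list(path) -> list[str]:
    """One gene symbol per line; blank lines skipped, order preserved,
    duplicates removed (first occurrence wins)."""
    seen: dict[str, None] = {}
    with open(path) as fh:
        for raw in fh:
            g = raw.strip()
            if g:
                seen.setdefault(g)
    return list(seen)


def write_gene_list(genes: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")
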