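"""Per-domain gene counts and multi-species repertoire tables.

Counting semantics: a domain's count is the number of distinct genes
with at least one retained hit of that domain — a gene with ten LRR
repeats contributes one to the LRR column.  Each domain is counted from
its own independent scan, so one gene may contribute to several columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import DomainHit


@dataclass
class RepertoireTable:
    """Species x domain gene-count matrix with provenance."""

    frame: pd.DataFrame  # index: species, columns: domains, values: int counts
    profile_set: str = ""
    alpha: float | None = None

    def __post_init__(self) -> None:
        if (self.frame.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="species")

    @classmethod
    def from_tsv(cls, path) -> "RepertoireTable":
        return cls(pd.read_csv(path, sep="\t", index_col="species"))


def count_domain_genes(
    hits: Iterable[DomainHit],
    domains: Sequence[str] | None = None,
    species: str = "",
) -> RepertoireTable:
    """One repertoire row: distinct-gene count per domain model.

    ``domains`` fixes the column set (zero-filled where absent); by
    default the columns are the models present in the hit table.
    """
    genes: dict[str, set[str]] = {}
    for h in hits:
        genes.setdefault(h.model, set()).add(h.protein_id)
    cols = list(domains) if domains is not None else sorted(genes)
    row = {d: len(genes.get(d, ())) for d in cols}
    frame = pd.DataFrame([row], index=[species], columns=cols).astype(int)
    return RepertoireTable(frame)


def cross_species_table(rows: Sequence[RepertoireTable]) -> RepertoireTable:
    """Merge per-species rows into one matrix.

    Domain columns are the union (first-seen order), missing entries are
    zero-filled, and row sums are preserved.  Duplicate species labels
    are an error.
    """
    if not rows:
        raise ValueError("need at least one repertoire row")
    species_seen: list[str] = []
    for r in rows:
        for sp in r.frame.index:
            if sp in species_seen:
                raise ValueError(f"duplicate species label {sp!r}")
            species_seen.append(sp)
    columns: list[str] = []
    for r in rows:
        for c in r.frame.columns:
            if c not in columns:
                columns.append(c)
    merged = pd.concat([r.frame for r in rows]).reindex(columns=columns).fillna(0).astype(int)
    return RepertoireTable(merged)


def split_species_table(table: RepertoireTable) -> list[RepertoireTable]:
    """Inverse of :func:`cross_species_table` (one row per species)."""
    return [RepertoireTable(table.frame.loc[[sp]]) for sp in table.frame.index]
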