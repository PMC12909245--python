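"""Readers and writers for the formats the pipeline touches.

Protein FASTA, GFF3 gene coordinates, and the pipeline's own tabular
artifacts (domain-hit tables).  All protein coordinates anywhere in the
package are 1-based inclusive residue numbers; genomic coordinates follow
the GFF3 convention (1-based, inclusive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: residues legal in a :class:`ProteinRecord` sequence
PROTEIN_ALPHABET = frozenset(AMINO_ACIDS + "X")

HIT_TABLE_COLUMNS = ["protein_id", "model", "ali_start", "ali_end", "bitscore", "significance"]


@dataclass(frozen=True)
class ProteinRecord:
    """One translated gene model.

    ``id`` must be unique within a proteome; ``sequence`` is an upper-case
    string over the 20 amino acids plus ``X`` (unknown residue), with no
    gap characters.
    """

    id: str
    sequence: str
    species: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(
                f"protein {self.id!r}: illegal residue(s) {sorted(bad)!r} "
                "(allowed: 20 amino acids plus X)"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneLocus:
    """Genomic placement of one gene (GFF3 convention, 1-based inclusive)."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chromosome:
            raise ValueError(f"locus {self.gene_id!r}: empty chromosome label")
        if self.start > self.end:
            raise ValueError(f"locus {self.gene_id!r}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"locus {self.gene_id!r}: strand must be + or -")


@dataclass(frozen=True)
class DomainHit:
    """One detected domain instance on one protein.

    ``ali_start``/``ali_end`` are 1-based inclusive residue coordinates,
    ``bitscore`` a log2-odds score against the background model, and
    ``significance`` the calibrated null exceedance probability of the
    score (smaller is more significant).
    """

    protein_id: str
    model: str
    ali_start: int
    ali_end: int
    bitscore: float
    significance: float = float("nan")

    def __post_init__(self) -> None:
        if self.ali_start > self.ali_end:
            raise ValueError(
                f"hit {self.model} on {self.protein_id}: "
                f"ali_start {self.ali_start} > ali_end {self.ali_end}"
            )

    @property
    def span(self) -> int:
        return self.ali_end - self.ali_start + 1


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, species: str = "") -> list[ProteinRecord]:
    """Read a protein FASTA file into :class:`ProteinRecord` objects.

    The id is the first whitespace-delimited token of the header.  A
    trailing ``*`` (stop codon) is stripped; an internal ``*`` is an error.
    Duplicate ids raise; an empty file returns an empty list with a warning.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if "*" in seq:
            raise ValueError(f"record {header!r}: internal stop character '*'")
        if header in seen:
            raise ValueError(f"duplicate FASTA id {header!r} in {path}")
        seen.add(header)
        records.append(ProteinRecord(id=header, sequence=seq, species=species))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if line[1:].split() else ""
                chunks = []
            else:
                if header is None:
                    raise ValueError(f"{path}: sequence data before first FASTA header")
                chunks.append(line)
        flush()
    if not records:
        warnings.warn(f"{path}: no FASTA records found", stacklevel=2)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width``."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(
    path: str | Path,
    feature_type: str = "gene",
    id_attribute: str = "ID",
) -> list[GeneLocus]:
    """Read gene loci from a GFF3 file.

    Only lines whose third column equals ``feature_type`` are kept; the
    gene id is taken from ``id_attribute`` in column 9.  Features missing
    the attribute are skipped with a warning; ``start > end`` is an error
    reporting the offending line number.
    """
    path = Path(path)
    loci: list[GeneLocus] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 tab-separated columns")
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
            if ftype != feature_type:
                continue
            start, end = int(start_s), int(end_s)
            if start > end:
                raise ValueError(f"{path}:{lineno}: start {start} > end {end}")
            attr_map = _parse_gff3_attributes(attrs)
            if id_attribute not in attr_map:
                warnings.warn(
                    f"{path}:{lineno}: feature lacks attribute {id_attribute!r}; skipped",
                    stacklevel=2,
                )
                continue
            loci.append(
                GeneLocus(
                    gene_id=attr_map[id_attribute],
                    chromosome=seqid,
                    start=start,
                    end=end,
                    strand=strand if strand in ("+", "-") else "+",
                )
            )
    return loci


def _parse_gff3_attributes(attrs: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in attrs.split(";"):
        part = part.strip()
        if not part or "=" not in part:
            continue
        key, value = part.split("=", 1)
        out[key] = value
    return out


def write_gff3(
    loci: Iterable[GeneLocus],
    path: str | Path,
    feature_type: str = "gene",
    source: str = "nlrkit",
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for loc in loci:
            fh.write(
                "\t".join(
                    [
                        loc.chromosome,
                        source,
                        feature_type,
                        str(loc.start),
                        str(loc.end),
                        ".",
                        loc.strand,
                        ".",
                        f"ID={loc.gene_id}",
                    ]
                )
                + "\n"
            )


def link_proteins_to_loci(
    protein_ids: Sequence[str],
    loci: Sequence[GeneLocus],
    suffix_strip: str = "",
) -> dict[str, GeneLocus]:
    """Join protein ids to gene loci by exact string match.

    ``suffix_strip`` removes a configurable transcript suffix (e.g. ``.t1``)
    from the protein id before matching, since gene-model naming schemes
    vary between annotation pipelines.
    """
    by_id = {loc.gene_id: loc for loc in loci}
    out: dict[str, GeneLocus] = {}
    for pid in protein_ids:
        key = pid
        if suffix_strip and key.endswith(suffix_strip):
            key = key[: -len(suffix_strip)]
        if key in by_id:
            out[pid] = by_id[key]
    return out


# ---------------------------------------------------------------------------
# Domain-hit tables


def write_hit_table(hits: Iterable[DomainHit], path: str | Path) -> None:
    """Serialize hits to TSV (coordinates 1-based inclusive). Lossless."""
    df = pd.DataFrame(
        [
            (h.protein_id, h.model, h.ali_start, h.ali_end, h.bitscore, h.significance)
            for h in hits
        ],
        columns=HIT_TABLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_hit_table(path: str | Path) -> list[DomainHit]:
    """Read a TSV hit table written by :func:`write_hit_table`."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "model": str})
    missing = [c for c in HIT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    hits = []
    for rownum, row in enumerate(df.itertuples(index=False), start=2):
        try:
            hits.append(
                DomainHit(
                    protein_id=str(row.protein_id),
                    model=str(row.model),
                    ali_start=int(row.ali_start),
                    ali_end=int(row.ali_end),
                    bitscore=float(row.bitscore),
                    significance=float(row.significance),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: malformed row {rownum}: {exc}") from exc
    return hits


def hits_to_frame(hits: Iterable[DomainHit]) -> pd.DataFrame:
    """Hit list as a DataFrame with the canonical column order."""
    return pd.DataFrame(
        [
            (h.protein_id, h.model, h.ali_start, h.ali_end, h.bitscore, h.significance)
            for h in hits
        ],
        columns=HIT_TABLE_COLUMNS,
    )
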