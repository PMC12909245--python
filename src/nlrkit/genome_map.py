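"""Chromosomal placement of NLR genes, cluster and duplicate detection.

Places classified genes on chromosomes, finds same-category tandem
clusters (runs of genes whose consecutive gaps stay below a configurable
distance), and detects near-identical gene pairs — the signature of
recent tandem duplication — by global protein alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

from .architecture import BONA_FIDE, NLRCategory, NLRRecord
from .io_formats import GeneLocus

__all__ = [
    "LocatedNLR",
    "GeneCluster",
    "DuplicatePair",
    "assign_loci",
    "detect_clusters",
    "pairwise_identity",
    "find_near_duplicates",
    "export_ideogram",
    "read_ideogram_marks",
]


@dataclass(frozen=True)
class LocatedNLR:
    record: NLRRecord
    locus: GeneLocus

    @property
    def gene_id(self) -> str:
        return self.record.gene_id

    @property
    def category(self) -> NLRCategory:
        return self.record.category


@dataclass(frozen=True)
class GeneCluster:
    chromosome: str
    category: NLRCategory
    genes: tuple[str, ...]  # ordered by start coordinate
    start: int
    end: int


@dataclass(frozen=True)
class DuplicatePair:
    gene_a: str
    gene_b: str
    identity: float  # percent, 0-100, global alignment
    same_chromosome: bool
    genomic_gap: int | None  # bp between the two gene spans; None if different chromosomes


def assign_loci(
    records: Sequence[NLRRecord], loci: Sequence[GeneLocus]
) -> tuple[list[LocatedNLR], list[NLRRecord]]:
    """Inner-join records to loci on gene id; unmatched records returned
    separately.  Order-independent: output sorted by (chromosome, start)."""
    by_id = {loc.gene_id: loc for loc in loci}
    located = [
        LocatedNLR(rec, by_id[rec.gene_id]) for rec in records if rec.gene_id in by_id
    ]
    unplaced = [rec for rec in records if rec.gene_id not in by_id]
    located.sort(key=lambda l: (l.locus.chromosome, l.locus.start, l.gene_id))
    unplaced.sort(key=lambda r: r.gene_id)
    return located, unplaced


def detect_clusters(
    located: Sequence[LocatedNLR],
    max_gap_bp: int = 100_000,
    min_size: int = 2,
    categories: frozenset[NLRCategory] = BONA_FIDE,
) -> list[GeneCluster]:
    """Maximal same-chromosome, same-category runs of nearby genes.

    Genes of each (chromosome, category) group are sorted by start; a
    run extends while the gap between consecutive gene spans
    (``next.start - prev.end - 1``, floored at 0) is <= ``max_gap_bp``.
    Runs shorter than ``min_size`` are discarded.  Output is independent
    of input ordering.
    """
    groups: dict[tuple[str, NLRCategory], list[LocatedNLR]] = {}
    for item in located:
        if item.category in categories:
            groups.setdefault((item.locus.chromosome, item.category), []).append(item)
    clusters: list[GeneCluster] = []
    for (chrom, cat), members in sorted(groups.items(), key=lambda kv: (kv[0][0], kv[0][1].value)):
        members.sort(key=lambda l: (l.locus.start, l.locus.end, l.gene_id))
        run: list[LocatedNLR] = []
        for item in members:
            if run and max(0, item.locus.start - run[-1].locus.end - 1) > max_gap_bp:
                if len(run) >= min_size:
                    clusters.append(_make_cluster(chrom, cat, run))
                run = []
            run.append(item)
        if len(run) >= min_size:
            clusters.append(_make_cluster(chrom, cat, run))
    return clusters


def _make_cluster(chrom: str, cat: NLRCategory, run: list[LocatedNLR]) -> GeneCluster:
    return GeneCluster(
        chromosome=chrom,
        category=cat,
        genes=tuple(l.gene_id for l in run),
        start=min(l.locus.start for l in run),
        end=max(l.locus.end for l in run),
    )


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner(
        mode="global",
        substitution_matrix=substitution_matrices.load("BLOSUM62"),
        open_gap_score=-11.0,
        extend_gap_score=-1.0,
    )
    return aligner


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity from a Needleman-Wunsch global alignment.

    BLOSUM62 with affine gaps (open -11, extend -1); identity = identical
    columns / total alignment columns (gap columns included in the
    denominator) x 100, reported to 0.1%.  Symmetric: co-optimal
    alignments are disambiguated by aligning the lexicographically
    smaller sequence first.
    """
    if not seq_a or not seq_b:
        raise ValueError("pairwise_identity requires two non-empty sequences")
    if seq_b < seq_a:
        seq_a, seq_b = seq_b, seq_a
    aligner = _make_aligner()
    aln = aligner.align(seq_a, seq_b)[0]
    counts = aln.counts()
    return round(100.0 * counts.identities / aln.length, 1)


def find_near_duplicates(
    located: Sequence[LocatedNLR],
    sequences: Mapping[str, str],
    identity_threshold: float = 90.0,
    same_category: bool = True,
) -> list[DuplicatePair]:
    """All gene pairs at or above the identity threshold.

    Each pair is annotated with chromosome co-location and the genomic
    gap between the gene spans.  With ``same_category`` only pairs in the
    same NLR category are compared (near-identical tandem copies are
    expected within a category).
    """
    pairs: list[DuplicatePair] = []
    for a, b in combinations(sorted(located, key=lambda l: l.gene_id), 2):
        if same_category and a.category != b.category:
            continue
        if a.gene_id not in sequences or b.gene_id not in sequences:
            raise KeyError(f"no sequence for {a.gene_id if a.gene_id not in sequences else b.gene_id}")
        ident = pairwise_identity(sequences[a.gene_id], sequences[b.gene_id])
        if ident >= identity_threshold:
            same_chrom = a.locus.chromosome == b.locus.chromosome
            gap = None
            if same_chrom:
                gap = max(
                    0,
                    max(a.locus.start, b.locus.start) - min(a.locus.end, b.locus.end) - 1,
                )
            pairs.append(
                DuplicatePair(
                    gene_a=a.gene_id,
                    gene_b=b.gene_id,
                    identity=ident,
                    same_chromosome=same_chrom,
                    genomic_gap=gap,
                )
            )
    return pairs


def export_ideogram(
    located: Sequence[LocatedNLR],
    chromosome_lengths: Mapping[str, int],
    karyotype_path: str | Path,
    marks_path: str | Path,
) -> None:
    """Write ideogram-ready karyotype and marks tables (TSV).

    The karyotype table lists every chromosome with its length; the marks
    table one row per located gene with category and coordinates — the
    layout chromosome-ideogram plotters consume.
    """
    for item in located:
        chrom = item.locus.chromosome
        if chrom not in chromosome_lengths:
            raise ValueError(f"gene {item.gene_id}: unknown chromosome {chrom!r}")
        if item.locus.end > chromosome_lengths[chrom]:
            raise ValueError(
                f"gene {item.gene_id}: end {item.locus.end} beyond "
                f"{chrom} length {chromosome_lengths[chrom]}"
            )
    kary = pd.DataFrame(
        sorted(chromosome_lengths.items()), columns=["chromosome", "length"]
    )
    kary.to_csv(karyotype_path, sep="\t", index=False)
    marks = pd.DataFrame(
        [
            {
                "gene_id": l.gene_id,
                "category": l.category.value,
                "chromosome": l.locus.chromosome,
                "start": l.locus.start,
                "end": l.locus.end,
            }
            for l in located
        ],
        columns=["gene_id", "category", "chromosome", "start", "end"],
    )
    marks.to_csv(marks_path, sep="\t", index=False)


def read_ideogram_marks(marks_path: str | Path) -> pd.DataFrame:
    return pd.read_csv(marks_path, sep="\t")
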