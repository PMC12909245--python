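"""Domain-architecture resolution and NLR classification.

NOD-like receptors (NLRs) are defined by a NACHT nucleotide-binding
domain; *bona fide* NLRs additionally carry C-terminal leucine-rich
repeats (LRRs).  The grammar implemented here assigns each protein one
of six categories:

* ``NLRC``  — bona fide, CARD N-terminal of the NACHT
* ``NLRD``  — bona fide, DEATH N-terminal of the NACHT (no CARD)
* ``NLRX``  — bona fide, neither CARD nor DEATH N-terminal (other
  N-terminal domains are allowed and recorded)
* ``NACHT_OTHER`` — NACHT plus other recognized domains but no
  C-terminal LRR (e.g. NACHT-WD40, NACHT-TPR, sushi-NACHT)
* ``NACHT_ONLY``  — NACHT hit(s) and nothing else
* ``NONE``  — no NACHT hit

CARD takes precedence over DEATH when both occur N-terminally (the
categories are mutually exclusive; the tiebreak is recorded in a flag).
Classification is relative to the most N-terminal NACHT hit.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import DomainHit

__all__ = [
    "NLRCategory",
    "DomainAnnotation",
    "NLRRecord",
    "TokenMap",
    "DEFAULT_TOKEN_MAP",
    "BONA_FIDE",
    "resolve_overlaps",
    "architecture_string",
    "classify_nlr",
    "classify_protein",
    "classify_hit_table",
    "bin_lrr_counts",
    "cooccurrence",
]


class NLRCategory(str, Enum):
    NLRC = "NLRC"
    NLRD = "NLRD"
    NLRX = "NLRX"
    NACHT_ONLY = "NACHT_ONLY"
    NACHT_OTHER = "NACHT_OTHER"
    NONE = "NONE"


BONA_FIDE = frozenset({NLRCategory.NLRC, NLRCategory.NLRD, NLRCategory.NLRX})


class TokenMap:
    """Maps profile/model names to grammar tokens.

    Several LRR-family profiles (LRR_1 ... LRR_6 equivalents) collapse to
    a single ``LRR`` token for the grammar while the hit table keeps the
    original model names.  Unmapped models pass through unchanged as
    their own token (e.g. WD40, TPR, sushi).
    """

    def __init__(self, roles: Mapping[str, str] | None = None):
        self._roles = dict(roles or {})

    def token(self, model: str) -> str:
        return self._roles.get(model, model)

    def models_for(self, token: str) -> list[str]:
        out = [m for m, t in self._roles.items() if t == token]
        return out or [token]


DEFAULT_TOKEN_MAP = TokenMap(
    {f"LRR_{i}": "LRR" for i in (1, 2, 3, 4, 6)} | {"LRR": "LRR"}
)


@dataclass(frozen=True)
class DomainAnnotation:
    """Overlap-resolved, start-ordered hits of one protein."""

    protein_id: str
    hits: tuple[DomainHit, ...]
    overlap_flags: tuple[bool, ...]  # True where the kept hit overlaps another kept hit

    def __post_init__(self) -> None:
        starts = [h.ali_start for h in self.hits]
        if starts != sorted(starts):
            raise ValueError("annotation hits must be sorted by ali_start")


@dataclass
class NLRRecord:
    """One gene's resolved architecture and NLR category."""

    gene_id: str
    category: NLRCategory
    lrr_count: int
    architecture: tuple[str, ...]
    species: str = ""
    flags: tuple[str, ...] = ()


def _overlap_len(a: DomainHit, b: DomainHit) -> int:
    return max(0, min(a.ali_end, b.ali_end) - max(a.ali_start, b.ali_start) + 1)


def _compatible(a: DomainHit, b: DomainHit, max_overlap_frac: float) -> bool:
    shorter = min(a.span, b.span)
    return _overlap_len(a, b) <= max_overlap_frac * shorter


def resolve_overlaps(
    hits: Sequence[DomainHit], max_overlap_frac: float = 0.5
) -> DomainAnnotation:
    """Greedy overlap resolution of one protein's hits.

    Candidates are taken in order of descending bitscore (ties: earlier
    start, then earlier end, then model name); a candidate whose overlap
    with any already-accepted hit exceeds ``max_overlap_frac`` of the
    shorter span is dropped.  Smaller overlaps are kept but flagged,
    mirroring the keep-if-visible-or-overlapping convention of manual
    domain-architecture curation.
    """
    ids = {h.protein_id for h in hits}
    if len(ids) > 1:
        raise ValueError(f"hits from multiple proteins: {sorted(ids)}")
    order = sorted(hits, key=lambda h: (-h.bitscore, h.ali_start, h.ali_end, h.model))
    kept: list[DomainHit] = []
    for cand in order:
        if all(_compatible(cand, acc, max_overlap_frac) for acc in kept):
            kept.append(cand)
    kept.sort(key=lambda h: (h.ali_start, h.ali_end, h.model))
    flags = tuple(
        any(_overlap_len(h, other) > 0 for other in kept if other is not h) for h in kept
    )
    pid = next(iter(ids)) if ids else ""
    return DomainAnnotation(protein_id=pid, hits=tuple(kept), overlap_flags=flags)


def architecture_string(
    annotation: DomainAnnotation, token_map: TokenMap = DEFAULT_TOKEN_MAP
) -> list[str]:
    """N-to-C ordered grammar tokens, repeats preserved."""
    return [token_map.token(h.model) for h in annotation.hits]


def classify_nlr(tokens: Sequence[str]) -> tuple[NLRCategory, int]:
    """Classify an ordered token list; returns (category, lrr_count).

    Rules, applied in order relative to the most N-terminal NACHT token:

    1. no NACHT -> NONE
    2. >= 1 LRR C-terminal of the NACHT -> bona fide: CARD N-terminal
       -> NLRC; else DEATH N-terminal -> NLRD; else -> NLRX
    3. NACHT with other recognized domains but no C-terminal LRR
       -> NACHT_OTHER
    4. NACHT and nothing else -> NACHT_ONLY

    ``lrr_count`` is the number of LRR tokens C-terminal of the NACHT.
    Total and deterministic for every token sequence.
    """
    tokens = list(tokens)
    if "NACHT" not in tokens:
        return NLRCategory.NONE, 0
    nacht = tokens.index("NACHT")
    lrr_count = sum(1 for t in tokens[nacht + 1 :] if t == "LRR")
    if lrr_count >= 1:
        n_term = tokens[:nacht]
        if "CARD" in n_term:
            return NLRCategory.NLRC, lrr_count
        if "DEATH" in n_term:
            return NLRCategory.NLRD, lrr_count
        return NLRCategory.NLRX, lrr_count
    if any(t != "NACHT" for t in tokens):
        return NLRCategory.NACHT_OTHER, 0
    return NLRCategory.NACHT_ONLY, 0


def classify_protein(
    hits: Sequence[DomainHit],
    max_overlap_frac: float = 0.5,
    token_map: TokenMap = DEFAULT_TOKEN_MAP,
    species: str = "",
) -> NLRRecord:
    """Resolve overlaps, build the token string, and classify one protein."""
    ann = resolve_overlaps(hits, max_overlap_frac)
    tokens = architecture_string(ann, token_map)
    category, lrr_count = classify_nlr(tokens)
    flags: list[str] = []
    if any(ann.overlap_flags):
        flags.append("overlapping_domains")
    if tokens.count("NACHT") > 1:
        flags.append("multiple_nacht")
    if category is NLRCategory.NLRC and "DEATH" in tokens[: tokens.index("NACHT")]:
        flags.append("card_precedence_over_death")
    return NLRRecord(
        gene_id=ann.protein_id,
        category=category,
        lrr_count=lrr_count,
        architecture=tuple(tokens),
        species=species,
        flags=tuple(flags),
    )


def classify_hit_table(
    hits: Iterable[DomainHit],
    max_overlap_frac: float = 0.5,
    token_map: TokenMap = DEFAULT_TOKEN_MAP,
    species: str = "",
) -> list[NLRRecord]:
    """Classify every protein appearing in a hit table."""
    by_protein: dict[str, list[DomainHit]] = defaultdict(list)
    for h in hits:
        by_protein[h.protein_id].append(h)
    return [
        classify_protein(by_protein[pid], max_overlap_frac, token_map, species)
        for pid in sorted(by_protein)
    ]


DEFAULT_LRR_BINS: tuple[tuple[int, int], ...] = ((2, 4), (7, 22), (15, 30))


def bin_lrr_counts(
    records: Iterable[NLRRecord],
    bin_edges: Sequence[tuple[int, int]] = DEFAULT_LRR_BINS,
) -> dict[NLRCategory, dict[str, list[str]]]:
    """Bin records by LRR-repeat count, per category.

    Default bins (2-4, 7-22, 15-30 repeats) follow the repeat-count
    clusters observed among sponge NLRX genes; bins may overlap, and a
    record falls in every bin containing its count.  Records outside all
    bins land in ``"unbinned"``.
    """
    out: dict[NLRCategory, dict[str, list[str]]] = {}
    labels = [f"{lo}-{hi}" for lo, hi in bin_edges]
    for rec in records:
        cat = out.setdefault(rec.category, {lab: [] for lab in labels + ["unbinned"]})
        placed = False
        for (lo, hi), lab in zip(bin_edges, labels):
            if lo <= rec.lrr_count <= hi:
                cat[lab].append(rec.gene_id)
                placed = True
        if not placed:
            cat["unbinned"].append(rec.gene_id)
    return out


def cooccurrence(
    hits: Iterable[DomainHit], domain_a: str, domain_b: str
) -> set[str]:
    """Gene ids with at least one retained hit of each of two domains."""
    seen: dict[str, set[str]] = defaultdict(set)
    models = set()
    for h in hits:
        models.add(h.model)
        seen[h.model].add(h.protein_id)
    for d in (domain_a, domain_b):
        if d not in models:
            raise ValueError(f"unknown domain name {d!r}; models present: {sorted(models)}")
    return seen[domain_a] & seen[domain_b]


def records_to_frame(records: Iterable[NLRRecord]) -> pd.DataFrame:
    """Classified records as the canonical TSV layout."""
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "species": r.species,
                "category": r.category.value,
                "lrr_count": r.lrr_count,
                "architecture": "-".join(r.architecture),
                "flags": ",".join(r.flags),
            }
            for r in records
        ],
        columns=["gene_id", "species", "category", "lrr_count", "architecture", "flags"],
    )
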