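"""Synthetic proteomes, genome layouts, and evolved alignments with
machine-readable ground truth.

The generator emulates the statistical structure the annotation pipeline
assumes: multi-domain proteins built by concatenating domain instances
sampled from profile HMMs (e.g. CARD-NACHT-LRRxN architectures) joined
by background-composition linkers, plus i.i.d. background decoys;
chromosome layouts with plantable same-category gene clusters;
near-identical duplicate pairs; and ungapped alignments evolved down a
known tree.  Every artifact is reproducible byte-for-byte from
(config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from skbio import TreeNode

from .architecture import NLRCategory, classify_nlr
from .io_formats import AMINO_ACIDS, GeneLocus, ProteinRecord
from .profile_hmm import (
    MultipleAlignment,
    ProfileHMM,
    build_profile,
    uniform_background,
)

__all__ = [
    "PlantSpec",
    "TruthEntry",
    "SyntheticTruth",
    "ClusterSpec",
    "DomainLibrary",
    "default_domain_library",
    "sample_from_profile",
    "generate_proteome",
    "generate_genome_layout",
    "mutate_pair",
    "evolve_alignment",
    "random_additive_tree",
    "tree_distances",
    "species_duplication_scenario",
]


# ---------------------------------------------------------------------------
# Domain library


#: realistic-order lengths for the emulated domain families (residues)
DEFAULT_DOMAIN_LENGTHS: dict[str, int] = {
    "NACHT": 60,
    "CARD": 45,
    "DEATH": 45,
    "LRR": 24,
    "WD40": 40,
    "TPR": 34,
    "TIR": 45,
    "TIR2": 45,
    "Ig": 40,
    "sushi": 35,
}


def make_domain_msa(
    name: str,
    length: int,
    n_rows: int = 10,
    divergence: float = 0.10,
    gap_prob: float = 0.02,
    seed: int = 0,
    alphabet: str = AMINO_ACIDS,
) -> MultipleAlignment:
    """Seed alignment for one emulated domain family.

    A random consensus is diverged into ``n_rows`` members by i.i.d.
    substitutions at rate ``divergence`` and sparse deletions at
    ``gap_prob`` — a desk-scale stand-in for a curated family alignment.
    """
    rng = np.random.default_rng(seed)
    letters = list(alphabet)
    consensus = "".join(rng.choice(letters, size=length))
    rows = []
    for _ in range(n_rows):
        chars = []
        for c in consensus:
            if rng.random() < gap_prob:
                chars.append("-")
            elif rng.random() < divergence:
                chars.append(_other_residue(c, rng, alphabet))
            else:
                chars.append(c)
        rows.append("".join(chars))
    ids = tuple(f"{name}_seed{i}" for i in range(n_rows))
    return MultipleAlignment(ids, tuple(rows))


def _other_residue(c: str, rng: np.random.Generator, alphabet: str = AMINO_ACIDS) -> str:
    choices = [a for a in alphabet if a != c]
    return choices[int(rng.integers(len(choices)))]


@dataclass
class DomainLibrary:
    """Seed alignments and built profiles for a set of domain families."""

    msas: dict[str, MultipleAlignment]
    profiles: dict[str, ProfileHMM]

    def profile(self, name: str) -> ProfileHMM:
        return self.profiles[name]

    @property
    def names(self) -> list[str]:
        return sorted(self.profiles)


def default_domain_library(
    seed: int = 0,
    domains: Sequence[str] | None = None,
    lengths: Mapping[str, int] | None = None,
) -> DomainLibrary:
    """Build the default emulated domain set (profiles + seed MSAs)."""
    lengths = dict(DEFAULT_DOMAIN_LENGTHS) | dict(lengths or {})
    names = list(domains) if domains is not None else list(lengths)
    msas: dict[str, MultipleAlignment] = {}
    profiles: dict[str, ProfileHMM] = {}
    for i, name in enumerate(names):
        msa = make_domain_msa(name, lengths[name], seed=seed * 10007 + i)
        msas[name] = msa
        # light transition smoothing: 10 seed rows would otherwise imply
        # implausibly indel-prone domains, especially for short repeats
        profiles[name] = build_profile(msa, name=name, transition_pseudocount=0.2)
    return DomainLibrary(msas=msas, profiles=profiles)


# ---------------------------------------------------------------------------
# Profile sampling


def sample_from_profile(profile: ProfileHMM, seed: int | np.random.Generator = 0) -> str:
    """Sample one domain instance by a stochastic walk through the model.

    Starts at the first match state and follows the match/insert/delete
    transition probabilities to the last; emissions come from the
    per-state distributions.  Deterministic given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    letters = list(profile.alphabet)
    out: list[str] = []
    L = profile.L
    state, k = "M", 0
    while True:
        if state == "M":
            out.append(letters[int(rng.choice(profile.K, p=profile.match_emissions[k]))])
            if k == L - 1:
                break
            move = rng.choice(3, p=[profile.t_mm[k], profile.t_mi[k], profile.t_md[k]])
            if move == 0:
                state, k = "M", k + 1
            elif move == 1:
                state = "I"
            else:
                state, k = "D", k + 1
        elif state == "I":
            out.append(letters[int(rng.choice(profile.K, p=profile.insert_emissions))])
            move = rng.choice(2, p=[profile.t_im[k], profile.t_ii[k]])
            if move == 0:
                state, k = "M", k + 1
        else:  # D
            if k == L - 1:
                break
            move = rng.choice(2, p=[profile.t_dm[k], profile.t_dd[k]])
            state, k = ("M", k + 1) if move == 0 else ("D", k + 1)
    return "".join(out)


# ---------------------------------------------------------------------------
# Proteome generation


@dataclass(frozen=True)
class PlantSpec:
    """Recipe for a batch of planted multi-domain proteins."""

    architecture: tuple[str, ...]  # e.g. ("CARD", "NACHT", "LRR", "LRR")
    copies: int = 1
    linker_length: tuple[int, int] = (5, 25)  # uniform, residues
    noise: float = 0.0  # per-residue substitution prob on domain residues

    def __post_init__(self) -> None:
        if self.copies < 0:
            raise ValueError("copies must be >= 0")
        if not (0.0 <= self.noise < 1.0):
            raise ValueError("noise must be in [0, 1)")


@dataclass(frozen=True)
class TruthEntry:
    """Ground truth for one generated protein."""

    protein_id: str
    domains: tuple[tuple[str, int, int], ...]  # (name, start, end) 1-based inclusive
    tokens: tuple[str, ...]
    category: NLRCategory
    lrr_count: int
    length: int
    species: str = ""


@dataclass
class SyntheticTruth:
    entries: list[TruthEntry]

    def by_id(self) -> dict[str, TruthEntry]:
        return {e.protein_id: e for e in self.entries}

    def categorized(self) -> list[TruthEntry]:
        return [e for e in self.entries if e.category is not NLRCategory.NONE]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "protein_id": e.protein_id,
                    "category": e.category.value,
                    "lrr_count": e.lrr_count,
                    "tokens": "-".join(e.tokens),
                    "domains": ";".join(f"{n}:{s}-{t}" for n, s, t in e.domains),
                    "length": e.length,
                    "species": e.species,
                }
                for e in self.entries
            ]
        )


def generate_proteome(
    plant_specs: Sequence[PlantSpec],
    n_decoys: int = 0,
    library: DomainLibrary | None = None,
    background: np.ndarray | None = None,
    seed: int = 0,
    species: str = "synthetic",
) -> tuple[list[ProteinRecord], SyntheticTruth]:
    """Emit planted multi-domain proteins plus background decoys.

    Plants concatenate profile-sampled domain instances with uniform
    linkers; ``noise`` applies i.i.d. substitutions to domain residues
    only (linkers are background already).  Decoys are i.i.d. background
    sequences length-matched to the plants.  The truth table records
    every planted span and the category implied by the planted tokens.
    """
    if not plant_specs and n_decoys == 0:
        return [], SyntheticTruth(entries=[])
    rng = np.random.default_rng(seed)
    library = library or default_domain_library(seed=0)
    bg = uniform_background() if background is None else background
    letters = list(AMINO_ACIDS)

    records: list[ProteinRecord] = []
    entries: list[TruthEntry] = []
    plant_lengths: list[int] = []
    counter = 0
    for spec in plant_specs:
        for _ in range(spec.copies):
            counter += 1
            pid = f"plant_{counter:04d}"
            parts: list[str] = []
            spans: list[tuple[str, int, int]] = []
            pos = 0

            def linker() -> None:
                nonlocal pos
                lo, hi = spec.linker_length
                ln = int(rng.integers(lo, hi + 1))
                parts.append("".join(rng.choice(letters, size=ln, p=bg)))
                pos += ln

            linker()
            for token in spec.architecture:
                dom = sample_from_profile(library.profile(token), rng)
                if spec.noise > 0:
                    dom = "".join(
                        _other_residue(c, rng) if rng.random() < spec.noise else c
                        for c in dom
                    )
                spans.append((token, pos + 1, pos + len(dom)))
                parts.append(dom)
                pos += len(dom)
                linker()
            seq = "".join(parts)
            category, lrr_count = classify_nlr(spec.architecture)
            records.append(ProteinRecord(id=pid, sequence=seq, species=species))
            entries.append(
                TruthEntry(
                    protein_id=pid,
                    domains=tuple(spans),
                    tokens=spec.architecture,
                    category=category,
                    lrr_count=lrr_count,
                    length=len(seq),
                    species=species,
                )
            )
            plant_lengths.append(len(seq))

    for d in range(n_decoys):
        if plant_lengths:
            ln = int(rng.choice(plant_lengths))
        else:
            ln = int(rng.integers(150, 600))
        seq = "".join(rng.choice(letters, size=ln, p=bg))
        pid = f"decoy_{d + 1:04d}"
        records.append(ProteinRecord(id=pid, sequence=seq, species=species))
        entries.append(
            TruthEntry(
                protein_id=pid,
                domains=(),
                tokens=(),
                category=NLRCategory.NONE,
                lrr_count=0,
                length=ln,
                species=species,
            )
        )
    return records, SyntheticTruth(entries=entries)


# ---------------------------------------------------------------------------
# Genome layout


@dataclass(frozen=True)
class ClusterSpec:
    """Plant ``n_genes`` same-category genes within ``window_bp`` on one
    chromosome, to create a recoverable tandem cluster."""

    category: NLRCategory
    n_genes: int
    window_bp: int
    chromosome: str = "c1"
    window_start: int = 1


def generate_genome_layout(
    truth: SyntheticTruth,
    n_chromosomes: int = 15,
    chromosome_length: int = 5_000_000,
    cluster_specs: Sequence[ClusterSpec] = (),
    seed: int = 0,
) -> list[GeneLocus]:
    """Assign every truth protein a gene locus on chromosomes c1..cN.

    Cluster specs pin chosen same-category genes inside a stated window
    (consecutive, non-overlapping placements); all remaining genes are
    placed uniformly.  Gene span is 3 bp per residue (no introns).
    """
    if not truth.entries:
        raise ValueError("truth table is empty")
    rng = np.random.default_rng(seed)
    chroms = [f"c{i + 1}" for i in range(n_chromosomes)]
    loci: list[GeneLocus] = []
    placed: set[str] = set()

    for cs in cluster_specs:
        pool = [
            e
            for e in truth.entries
            if e.category == cs.category and e.protein_id not in placed
        ]
        if len(pool) < cs.n_genes:
            raise ValueError(
                f"cluster spec wants {cs.n_genes} {cs.category.value} genes; "
                f"only {len(pool)} available"
            )
        chosen = pool[: cs.n_genes]
        total_span = sum(3 * e.length for e in chosen)
        if total_span > cs.window_bp:
            raise ValueError(
                f"window {cs.window_bp} bp smaller than the {total_span} bp "
                "needed by the chosen gene spans"
            )
        slack = cs.window_bp - total_span
        gaps = rng.multinomial(slack, np.full(cs.n_genes, 1.0 / cs.n_genes))
        pos = cs.window_start
        for e, gap in zip(chosen, gaps):
            start = pos + int(gap)
            end = start + 3 * e.length - 1
            loci.append(GeneLocus(e.protein_id, cs.chromosome, start, end, "+"))
            pos = end + 1
            placed.add(e.protein_id)

    for e in truth.entries:
        if e.protein_id in placed:
            continue
        span = 3 * e.length
        chrom = chroms[int(rng.integers(n_chromosomes))]
        start = int(rng.integers(1, max(2, chromosome_length - span)))
        strand = "+" if rng.random() < 0.5 else "-"
        loci.append(GeneLocus(e.protein_id, chrom, start, start + span - 1, strand))
    return loci


# ---------------------------------------------------------------------------
# Near-duplicate pairs


def mutate_pair(sequence: str, target_identity: float, seed: int = 0) -> str:
    """Mutate a copy of ``sequence`` toward a target percent identity.

    Substitutes Binomial(L, 1 - target/100) positions, chosen without
    replacement, each to a uniformly random different residue — the
    generative model for near-identical tandem gene duplicates.
    """
    if not (0.0 < target_identity <= 100.0):
        raise ValueError("target_identity must be in (0, 100]")
    rng = np.random.default_rng(seed)
    L = len(sequence)
    n_mut = int(rng.binomial(L, 1.0 - target_identity / 100.0))
    if n_mut == 0:
        return sequence
    positions = rng.choice(L, size=n_mut, replace=False)
    chars = list(sequence)
    for p in positions:
        chars[p] = _other_residue(chars[p], rng)
    return "".join(chars)


# ---------------------------------------------------------------------------
# Alignment evolution and tree scenarios


def random_additive_tree(
    n_leaves: int,
    seed: int = 0,
    min_branch: float = 0.05,
    max_branch: float = 1.0,
) -> TreeNode:
    """Random unrooted binary tree with positive branch lengths.

    Built by sequential random attachment; leaf names t1..tN.  Path
    lengths between leaves form an additive distance matrix that
    neighbor joining must recover exactly.
    """
    if n_leaves < 4:
        raise ValueError("need >= 4 leaves for an interesting unrooted tree")
    rng = np.random.default_rng(seed)

    def bl() -> float:
        return float(rng.uniform(min_branch, max_branch))

    leaves = [TreeNode(name=f"t{i + 1}", length=bl()) for i in range(3)]
    root = TreeNode()
    root.extend(leaves)
    edges = list(leaves)
    for i in range(3, n_leaves):
        edge = edges[int(rng.integers(len(edges)))]
        parent = edge.parent
        split = TreeNode(length=float(rng.uniform(0.0, 1.0)) * edge.length)
        rest = edge.length - split.length
        # guard against zero-length internal edges, which make the
        # topology unidentifiable
        split.length = max(split.length, min_branch / 2)
        parent.remove(edge)
        parent.append(split)
        edge.length = max(rest, min_branch / 2)
        new_leaf = TreeNode(name=f"t{i + 1}", length=bl())
        split.extend([edge, new_leaf])
        edges.extend([split, edge, new_leaf])
    return root


def tree_distances(tree: TreeNode) -> tuple[list[str], np.ndarray]:
    """Leaf labels and the additive path-length matrix of a tree."""
    dm = tree.tip_tip_distances()
    return list(dm.ids), dm.data.copy()


def _as_tree(tree_spec: TreeNode | str) -> TreeNode:
    if isinstance(tree_spec, TreeNode):
        return tree_spec
    import io as _io

    return TreeNode.read(_io.StringIO(tree_spec), format="newick")


def evolve_alignment(
    tree_spec: TreeNode | str,
    n_columns: int = 500,
    subst_prob: float = 0.05,
    seed: int = 0,
    use_branch_lengths: bool = False,
) -> tuple[MultipleAlignment, TreeNode]:
    """Evolve an ungapped alignment down a tree.

    The root sequence is i.i.d. background; along every branch each
    column substitutes with probability ``subst_prob`` (to a uniformly
    random different residue).  With ``use_branch_lengths`` the branch
    length itself is the per-column substitution probability.  No
    indels.  Returns the leaf alignment and the generating tree.
    """
    tree = _as_tree(tree_spec)
    n_branches = sum(1 for n in tree.traverse() if n.parent is not None)
    if n_branches < 3:
        raise ValueError("tree must have >= 3 branches")
    rng = np.random.default_rng(seed)
    letters = list(AMINO_ACIDS)
    root_seq = "".join(rng.choice(letters, size=n_columns))
    seqs: dict[int, str] = {id(tree): root_seq}
    ids: list[str] = []
    rows: list[str] = []
    for node in tree.preorder():
        if node.parent is None:
            continue
        parent_seq = seqs[id(node.parent)]
        p = float(node.length) if use_branch_lengths else subst_prob
        child = "".join(
            _other_residue(c, rng) if rng.random() < p else c for c in parent_seq
        )
        seqs[id(node)] = child
        if node.is_tip():
            ids.append(node.name)
            rows.append(child)
    return MultipleAlignment(tuple(ids), tuple(rows)), tree


def species_duplication_scenario(
    n_species: int = 4,
    genes_per_species: int = 4,
    n_columns: int = 400,
    between_subst: float = 0.12,
    within_subst: float = 0.02,
    seed: int = 0,
) -> tuple[MultipleAlignment, dict[str, str], dict[str, str]]:
    """Alignment evolved under species-level gene duplication.

    Each species carries a clade of recently duplicated gene copies
    (low within-species divergence) while species are well separated
    (high between-species divergence); NLR categories are assigned
    cycling across copies, so they do not follow the tree.  Returns the
    alignment plus per-leaf species and category attribute maps — a
    scenario where genes must group by species, not category.
    """
    categories = ["NLRC", "NLRD", "NLRX"]
    root = TreeNode()
    species_attrs: dict[str, str] = {}
    category_attrs: dict[str, str] = {}
    for s in range(n_species):
        clade = TreeNode(length=between_subst)
        for g in range(genes_per_species):
            name = f"sp{s + 1}_g{g + 1}"
            clade.append(TreeNode(name=name, length=within_subst))
            species_attrs[name] = f"sp{s + 1}"
            category_attrs[name] = categories[g % len(categories)]
        root.append(clade)
    msa, _ = evolve_alignment(
        root, n_columns=n_columns, seed=seed, use_branch_lengths=True
    )
    return msa, species_attrs, category_attrs
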