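"""NACHT-domain phylogenetics: alignment, distances, neighbor joining,
bootstrap support, and a species-vs-category grouping statistic.

Trees are distance-based: pairwise divergences (p-distance or its
Poisson correction) feed canonical Saitou-Nei neighbor joining, and node
support comes from column-bootstrap replicates.  Trees are unrooted;
re-rooting on an outgroup is a display-time operation only.
"""

from __future__ import annotations

import io
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from skbio import DistanceMatrix, TreeNode

from Bio.Align import substitution_matrices

from .profile_hmm import MultipleAlignment

__all__ = [
    "align_domains",
    "distance_matrix",
    "neighbor_joining",
    "bootstrap_support",
    "grouping_statistic",
    "tree_to_newick",
    "tree_from_newick",
    "canonical_order",
    "bipartitions",
    "write_phylip",
]

_BLOSUM = substitution_matrices.load("BLOSUM62")
_GAP_SCORE = -4.0


# ---------------------------------------------------------------------------
# Progressive multiple alignment


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    if not ka or not kb:
        return 1.0
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


def _column_score(col_a: Sequence[str], col_b: Sequence[str]) -> float:
    """Mean sum-of-pairs score of pairing two profile columns.

    Residue pairs score BLOSUM62, residue-vs-gap pairs the gap penalty,
    gap-gap pairs zero — the same convention the final alignment is
    judged by, so profile merges optimize a consistent objective.
    """
    total, pairs = 0.0, 0
    for x in col_a:
        for y in col_b:
            pairs += 1
            if x != "-" and y != "-":
                total += _BLOSUM[x][y]
            elif x != y:
                total += _GAP_SCORE
    return total / pairs if pairs else 0.0


def _gap_cost(col: Sequence[str]) -> float:
    """Mean cost of aligning a profile column against all-gap."""
    occ = sum(1 for x in col if x != "-") / len(col)
    return _GAP_SCORE * occ


def _merge_profiles(rows_a: list[str], rows_b: list[str]) -> tuple[list[str], list[str]]:
    """Profile-profile Needleman-Wunsch with linear gaps.

    Deterministic tie rule: diagonal preferred over up (gap in B) over
    left (gap in A).  Returns the two row sets padded to equal length.
    """
    la, lb = len(rows_a[0]), len(rows_b[0])
    cols_a = ["".join(r[i] for r in rows_a) for i in range(la)]
    cols_b = ["".join(r[j] for r in rows_b) for j in range(lb)]
    gap_a = [_gap_cost(c) for c in cols_a]
    gap_b = [_gap_cost(c) for c in cols_b]
    S = np.zeros((la + 1, lb + 1))
    P = np.zeros((la + 1, lb + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    for i in range(1, la + 1):
        S[i, 0] = S[i - 1, 0] + gap_a[i - 1]
        P[i, 0] = 1
    for j in range(1, lb + 1):
        S[0, j] = S[0, j - 1] + gap_b[j - 1]
        P[0, j] = 2
    for i in range(1, la + 1):
        ca = cols_a[i - 1]
        for j in range(1, lb + 1):
            diag = S[i - 1, j - 1] + _column_score(ca, cols_b[j - 1])
            up = S[i - 1, j] + gap_a[i - 1]
            left = S[i, j - 1] + gap_b[j - 1]
            if diag >= up and diag >= left:
                S[i, j], P[i, j] = diag, 0
            elif up >= left:
                S[i, j], P[i, j] = up, 1
            else:
                S[i, j], P[i, j] = left, 2
    # traceback
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    i, j = la, lb
    while i > 0 or j > 0:
        move = P[i, j]
        if move == 0:
            for r, row in zip(out_a, rows_a):
                r.append(row[i - 1])
            for r, row in zip(out_b, rows_b):
                r.append(row[j - 1])
            i, j = i - 1, j - 1
        elif move == 1:
            for r, row in zip(out_a, rows_a):
                r.append(row[i - 1])
            for r in out_b:
                r.append("-")
            i -= 1
        else:
            for r in out_a:
                r.append("-")
            for r, row in zip(out_b, rows_b):
                r.append(row[j - 1])
            j -= 1
    return ["".join(reversed(r)) for r in out_a], ["".join(reversed(r)) for r in out_b]


def align_domains(sequences: Mapping[str, str] | Sequence[tuple[str, str]]) -> MultipleAlignment:
    """Progressive multiple alignment of domain sequences.

    Guide tree: UPGMA (average linkage) on 3-mer set distances;
    merges: profile-profile Needleman-Wunsch with mean-BLOSUM62 column
    scores and linear gap penalty.  Deterministic given input order.
    """
    items = list(sequences.items()) if isinstance(sequences, Mapping) else list(sequences)
    if len(items) < 2:
        raise ValueError("alignment needs >= 2 sequences")
    names = [n for n, _ in items]
    seqs = [s for _, s in items]
    if len(items) == 2:
        a, b = _merge_profiles([seqs[0]], [seqs[1]])
        return MultipleAlignment(tuple(names), (a[0], b[0]))

    n = len(items)
    cond = []
    for i in range(n):
        for j in range(i + 1, n):
            cond.append(_kmer_distance(seqs[i], seqs[j]))
    Z = linkage(np.array(cond), method="average")

    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([names[i]], [seqs[i]]) for i in range(n)
    }
    for step, (a_id, b_id, _dist, _size) in enumerate(Z):
        na, ra = clusters.pop(int(a_id))
        nb, rb = clusters.pop(int(b_id))
        ra2, rb2 = _merge_profiles(ra, rb)
        clusters[n + step] = (na + nb, ra2 + rb2)
    (final_names, final_rows), = clusters.values()
    order = {name: i for i, name in enumerate(final_names)}
    rows_by_input = tuple(final_rows[order[name]] for name in names)
    return MultipleAlignment(tuple(names), rows_by_input)


# ---------------------------------------------------------------------------
# Distances


def distance_matrix(msa: MultipleAlignment, model: str = "p") -> DistanceMatrix:
    """Pairwise divergences over mutually ungapped columns.

    ``model="p"``: proportion of differing comparable columns;
    ``model="poisson"``: d = -ln(1 - p), the Poisson multiple-hit
    correction.  A pair with zero comparable columns is an error; a
    saturated pair (p = 1, where the correction diverges) is capped at
    p = 1 - 0.5/comparable so that bootstrap replicates of highly
    diverged pairs remain usable.
    """
    if model not in ("p", "poisson"):
        raise ValueError(f"unknown distance model {model!r}")
    n = msa.n_rows
    mat = np.zeros((n, n))
    rows = msa.rows
    for i in range(n):
        for j in range(i + 1, n):
            comparable = diffs = 0
            for a, b in zip(rows[i], rows[j]):
                if a != "-" and b != "-":
                    comparable += 1
                    if a != b:
                        diffs += 1
            if comparable == 0:
                raise ValueError(
                    f"rows {msa.ids[i]!r} and {msa.ids[j]!r} share no ungapped columns"
                )
            p = diffs / comparable
            if model == "poisson":
                p = min(p, 1.0 - 0.5 / comparable)
                d = -math.log1p(-p)
            else:
                d = p
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, list(msa.ids))


# ---------------------------------------------------------------------------
# Neighbor joining


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Canonical Saitou-Nei neighbor joining.

    Q-criterion agglomeration; ties resolve to the lexicographically
    smallest (label, label) pair, so the result is deterministic.  A
    negative branch length is clamped to 0 and its deficit moved to the
    sibling branch (total preserved).  Returns an unrooted tree as a
    trifurcating-root :class:`skbio.TreeNode`.
    """
    labels = list(dm.ids)
    if len(labels) < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    D = dm.data.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in labels]
    # smallest leaf name under each working node, for the deterministic tie-break
    reps = [lab for lab in labels]

    while len(nodes) > 3:
        m = len(nodes)
        row_sums = D.sum(axis=1)
        Q = (m - 2) * D - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cands = np.argwhere(Q <= qmin + 1e-10 * max(1.0, abs(qmin)))
        best = min(
            (tuple(sorted((reps[i], reps[j]))), i, j)
            for i, j in cands
            if i < j
        )
        _, i, j = best
        li = 0.5 * D[i, j] + (row_sums[i] - row_sums[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        li, lj = _clamp_pair(li, lj)
        new = TreeNode()
        a, b = nodes[i], nodes[j]
        a.length, b.length = float(li), float(lj)
        new.extend([a, b])
        dist_new = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = dist_new[keep]
        D2[:-1, -1] = dist_new[keep]
        D2[-1, -1] = 0.0
        D = D2
        new_rep = min(reps[i], reps[j])
        nodes = [nodes[k] for k in keep] + [new]
        reps = [reps[k] for k in keep] + [new_rep]

    # closed-form star resolution of the last three nodes
    (a, b, c) = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    la, lb = _clamp_pair(la, lb)
    lc = max(0.0, lc)
    root = TreeNode()
    a.length, b.length, c.length = float(la), float(lb), float(lc)
    root.extend([a, b, c])
    return root


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0.0:
        lj += li
        li = 0.0
    if lj < 0.0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


# ---------------------------------------------------------------------------
# Newick round trip and bipartitions


def canonical_order(tree: TreeNode) -> TreeNode:
    """Sort children by their smallest descendant tip name, in place."""
    for node in tree.postorder():
        if not node.is_tip():
            node._smallest = min(
                (getattr(c, "_smallest", c.name or "") for c in node.children), default=""
            )
        else:
            node._smallest = node.name or ""
    for node in tree.preorder():
        if not node.is_tip():
            node.children.sort(key=lambda c: c._smallest)
    for node in tree.traverse():
        if hasattr(node, "_smallest"):
            del node._smallest
    return tree


def tree_to_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def tree_from_newick(newick: str) -> TreeNode:
    return TreeNode.read(io.StringIO(newick), format="newick")


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions as canonical tip-name sets.

    Each internal edge splits the tips in two; the side not containing
    the lexicographically smallest tip is the canonical representative.
    """
    tips = sorted(t.name for t in tree.tips())
    ref = tips[0]
    all_tips = set(tips)
    out: set[frozenset[str]] = set()
    for node in tree.non_tips():
        if node.parent is None:
            continue
        side = {t.name for t in node.tips()}
        if len(side) < 2 or len(side) > len(all_tips) - 2:
            continue
        if ref in side:
            side = all_tips - side
        out.add(frozenset(side))
    return out


# ---------------------------------------------------------------------------
# Bootstrap


def bootstrap_support(
    msa: MultipleAlignment,
    n_replicates: int = 100,
    seed: int = 0,
    model: str = "poisson",
) -> TreeNode:
    """Point-estimate NJ tree with column-bootstrap support values.

    Columns are resampled with replacement ``n_replicates`` times; the
    support of each internal edge of the point tree is the percentage of
    replicate trees containing the same bipartition, stored as the
    internal node name (0-100).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    point = neighbor_joining(distance_matrix(msa, model))
    canonical_order(point)
    target = {bp: 0 for bp in bipartitions(point)}
    rng = np.random.default_rng(seed)
    ncol = msa.length
    for _ in range(n_replicates):
        cols = rng.integers(0, ncol, size=ncol)
        rows = tuple("".join(row[c] for c in cols) for row in msa.rows)
        rep_msa = MultipleAlignment(msa.ids, rows)
        rep_tree = neighbor_joining(distance_matrix(rep_msa, model))
        rep_bps = bipartitions(rep_tree)
        for bp in target:
            if bp in rep_bps:
                target[bp] += 1
    tips_all = {t.name for t in point.tips()}
    ref = min(tips_all)
    for node in point.non_tips():
        if node.parent is None:
            continue
        side = {t.name for t in node.tips()}
        if len(side) < 2 or len(side) > len(tips_all) - 2:
            continue
        if ref in side:
            side = tips_all - side
        count = target.get(frozenset(side), 0)
        node.name = f"{100.0 * count / n_replicates:g}"
    return point


# ---------------------------------------------------------------------------
# Grouping statistic


def grouping_statistic(
    tree: TreeNode, attributes: Mapping[str, str]
) -> float:
    """Fraction of leaves whose nearest leaf shares the given attribute.

    Distance is path length along the tree.  Ties are broken toward
    non-matching (conservative): if any equally-nearest leaf carries a
    different attribute value, the leaf does not count as matching.
    """
    tips = [t.name for t in tree.tips()]
    missing = [t for t in tips if t not in attributes]
    if missing:
        raise ValueError(f"attribute missing for leaves: {missing[:5]}")
    if len(tips) < 2:
        raise ValueError("need >= 2 leaves")
    dm = tree.tip_tip_distances()
    matched = 0
    for leaf in tips:
        d = np.array([dm[leaf, other] for other in tips if other != leaf])
        others = [other for other in tips if other != leaf]
        dmin = d.min()
        nearest = [o for o, dist in zip(others, d) if dist <= dmin + 1e-12]
        if all(attributes[o] == attributes[leaf] for o in nearest):
            matched += 1
    return matched / len(tips)


def write_phylip(msa: MultipleAlignment, path) -> None:
    """Relaxed PHYLIP export (for external ML tools)."""
    with open(path, "w") as fh:
        fh.write(f" {msa.n_rows} {msa.length}\n")
        for name, row in zip(msa.ids, msa.rows):
            fh.write(f"{name}  {row}\n")
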