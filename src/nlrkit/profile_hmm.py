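"""Profile hidden Markov models of protein domains.

Builds a position-specific model from a curated multiple alignment of a
conserved domain (match / insert / delete states, plan7-style transition
topology), scans proteomes for local domain instances with Viterbi and
forward scoring in bits (log2-odds against an i.i.d. background model),
and calibrates significance thresholds on shuffled-composition decoys via
a Gumbel fit.

The local-alignment model uses uniform entry over match states and a
per-state exit probability ``1/(L-k)`` (0-indexed state ``k``) so that the
exit point is uniform given the entry point and every outgoing
distribution remains a proper probability distribution.  Flanking
residues outside the local alignment emit at background frequency and
contribute zero bits.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io_formats import AMINO_ACIDS, DomainHit, ProteinRecord

__all__ = [
    "MultipleAlignment",
    "ProfileHMM",
    "GumbelNull",
    "read_alignment_fasta",
    "write_alignment_fasta",
    "build_profile",
    "select_conserved_block",
    "viterbi_local",
    "forward_local",
    "calibrate_null",
    "scan_proteome",
    "extract_domain_region",
]

NEG = -np.inf
_EULER_GAMMA = 0.5772156649015329


@dataclass(frozen=True)
class MultipleAlignment:
    """A gapped multiple sequence alignment ('-' gaps, 20 aa + X)."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("alignment needs >= 2 rows")
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in number")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)

    def gap_fraction(self, j: int) -> float:
        col = self.column(j)
        return col.count("-") / len(col)

    def occupancy(self, j: int) -> float:
        return 1.0 - self.gap_fraction(j)

    def slice_columns(self, start: int, stop: int) -> "MultipleAlignment":
        """Sub-alignment of columns [start, stop) (0-based half-open)."""
        return MultipleAlignment(self.ids, tuple(r[start:stop] for r in self.rows))


def read_alignment_fasta(path: str | Path) -> MultipleAlignment:
    """Read an aligned FASTA file (rows may contain '-' gaps)."""
    ids: list[str] = []
    rows: list[str] = []
    header = None
    chunks: list[str] = []

    def flush() -> None:
        if header is not None:
            ids.append(header)
            rows.append("".join(chunks).upper())

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
        flush()
    return MultipleAlignment(tuple(ids), tuple(rows))


def write_alignment_fasta(msa: MultipleAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, row in zip(msa.ids, msa.rows):
            fh.write(f">{name}\n{row}\n")


# ---------------------------------------------------------------------------
# Model


@dataclass
class GumbelNull:
    """Moment-fitted Gumbel null distribution of local bit scores."""

    location: float
    scale: float
    alpha: float
    threshold_bits: float

    def significance(self, score: float) -> float:
        """Null exceedance probability P(S >= score) under the fit."""
        if self.scale <= 0:
            return 0.0 if score > self.location else 1.0
        z = (score - self.location) / self.scale
        # 1 - exp(-exp(-z)), numerically stable in both tails
        return float(-math.expm1(-math.exp(-min(z, 700.0))))

    def threshold_for(self, alpha: float) -> float:
        if alpha >= 1.0:
            return -math.inf
        return self.location - self.scale * math.log(-math.log1p(-alpha))


@dataclass
class ProfileHMM:
    """Profile HMM over ``alphabet`` with ``L`` match states.

    Transition arrays are indexed by the 0-based source match state:
    ``t_mm/t_mi/t_md`` from M_k (k = 0..L-2), ``t_im/t_ii`` from the
    insert state I_k sitting between M_k and M_k+1, and ``t_dm/t_dd``
    from D_k.  ``entry[k]`` is the probability of beginning the local
    alignment at M_k; ``exit_[k]`` the probability of ending it after M_k.
    """

    name: str
    alphabet: str
    match_emissions: np.ndarray  # (L, K)
    insert_emissions: np.ndarray  # (K,)
    background: np.ndarray  # (K,)
    t_mm: np.ndarray
    t_mi: np.ndarray
    t_md: np.ndarray
    t_im: np.ndarray
    t_ii: np.ndarray
    t_dm: np.ndarray
    t_dd: np.ndarray
    entry: np.ndarray
    exit_: np.ndarray
    null: GumbelNull | None = None
    _scoring_cache: dict | None = field(default=None, repr=False, compare=False)

    @property
    def L(self) -> int:
        return self.match_emissions.shape[0]

    @property
    def K(self) -> int:
        return len(self.alphabet)

    def validate(self, atol: float = 1e-9) -> None:
        L = self.L
        if L < 2:
            raise ValueError("profile needs L >= 2 match states")
        def _check(name: str, dist: np.ndarray) -> None:
            if np.any(dist <= 0):
                raise ValueError(f"{self.name}: {name} has non-positive probabilities")
            if abs(float(dist.sum()) - 1.0) > atol:
                raise ValueError(f"{self.name}: {name} sums to {dist.sum()}, not 1")
        for k in range(L):
            _check(f"match emission {k}", self.match_emissions[k])
        _check("insert emission", self.insert_emissions)
        _check("background", self.background)
        _check("entry", self.entry)
        for k in range(L - 1):
            _check(f"M{k} transitions", np.array([self.t_mm[k], self.t_mi[k], self.t_md[k]]))
            _check(f"I{k} transitions", np.array([self.t_im[k], self.t_ii[k]]))
            _check(f"D{k} transitions", np.array([self.t_dm[k], self.t_dd[k]]))
        if np.any(self.exit_ <= 0) or np.any(self.exit_ > 1):
            raise ValueError(f"{self.name}: exit probabilities outside (0, 1]")
        if abs(float(self.exit_[-1]) - 1.0) > atol:
            raise ValueError(f"{self.name}: exit from last match state must be 1")

    def consensus(self) -> str:
        """Most probable residue per match state."""
        idx = np.argmax(self.match_emissions, axis=1)
        return "".join(self.alphabet[i] for i in idx)

    # -- scoring tables -----------------------------------------------------

    def scoring(self) -> dict:
        """Cached log2 scoring arrays for the DP routines."""
        if self._scoring_cache is None:
            with np.errstate(divide="ignore"):
                keep = 1.0 - self.exit_  # continue probability from M_k
                cache = {
                    "lod_m": np.log2(self.match_emissions / self.background),
                    "lod_i": np.log2(self.insert_emissions / self.background),
                    "a_mm": np.log2(keep[:-1] * self.t_mm),
                    "a_mi": np.log2(keep[:-1] * self.t_mi),
                    "a_md": np.log2(keep[:-1] * self.t_md),
                    "a_im": np.log2(self.t_im),
                    "a_ii": np.log2(self.t_ii),
                    "a_dm": np.log2(self.t_dm),
                    "a_dd": np.log2(self.t_dd),
                    "entry_log": np.log2(self.entry),
                    "exit_log": np.log2(self.exit_),
                    "index": {c: i for i, c in enumerate(self.alphabet)},
                }
            self._scoring_cache = cache
        return self._scoring_cache

    def encode(self, sequence: str) -> np.ndarray:
        """Encode residues as alphabet indices; X (unknown) becomes -1."""
        index = self.scoring()["index"]
        out = np.empty(len(sequence), dtype=np.int64)
        for i, c in enumerate(sequence):
            if c in index:
                out[i] = index[c]
            elif c == "X":
                out[i] = -1
            else:
                raise ValueError(f"residue {c!r} not in profile alphabet")
        return out

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "format": "nlrkit-profile-hmm-v1",
            "name": self.name,
            "alphabet": self.alphabet,
            "match_emissions": self.match_emissions.tolist(),
            "insert_emissions": self.insert_emissions.tolist(),
            "background": self.background.tolist(),
            "transitions": {
                t: getattr(self, t).tolist()
                for t in ("t_mm", "t_mi", "t_md", "t_im", "t_ii", "t_dm", "t_dd")
            },
            "entry": self.entry.tolist(),
            "exit": self.exit_.tolist(),
            "null": None
            if self.null is None
            else {
                "location": self.null.location,
                "scale": self.null.scale,
                "alpha": self.null.alpha,
                "threshold_bits": self.null.threshold_bits,
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ProfileHMM":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "nlrkit-profile-hmm-v1":
            raise ValueError(f"{path}: not a nlrkit profile file")
        tr = payload["transitions"]
        null = payload.get("null")
        prof = cls(
            name=payload["name"],
            alphabet=payload["alphabet"],
            match_emissions=np.array(payload["match_emissions"], dtype=float),
            insert_emissions=np.array(payload["insert_emissions"], dtype=float),
            background=np.array(payload["background"], dtype=float),
            t_mm=np.array(tr["t_mm"], dtype=float),
            t_mi=np.array(tr["t_mi"], dtype=float),
            t_md=np.array(tr["t_md"], dtype=float),
            t_im=np.array(tr["t_im"], dtype=float),
            t_ii=np.array(tr["t_ii"], dtype=float),
            t_dm=np.array(tr["t_dm"], dtype=float),
            t_dd=np.array(tr["t_dd"], dtype=float),
            entry=np.array(payload["entry"], dtype=float),
            exit_=np.array(payload["exit"], dtype=float),
            null=None
            if null is None
            else GumbelNull(null["location"], null["scale"], null["alpha"], null["threshold_bits"]),
        )
        prof.validate()
        return prof


# ---------------------------------------------------------------------------
# Construction


def select_conserved_block(
    msa: MultipleAlignment, min_occupancy: float = 0.5, min_run: int = 10
) -> MultipleAlignment:
    """Longest contiguous run of well-occupied columns.

    Returns the sub-alignment over the longest run of >= ``min_run``
    consecutive columns each with non-gap fraction >= ``min_occupancy``:
    an objective stand-in for manually trimming an alignment down to the
    block that is well aligned across all members.  Leftmost run wins ties.
    """
    good = [msa.occupancy(j) >= min_occupancy for j in range(msa.length)]
    best_start, best_len = 0, 0
    run_start = None
    for j, ok in enumerate(good + [False]):
        if ok and run_start is None:
            run_start = j
        elif not ok and run_start is not None:
            run_len = j - run_start
            if run_len > best_len:
                best_start, best_len = run_start, run_len
            run_start = None
    if best_len < min_run:
        raise ValueError(
            f"no run of >= {min_run} columns with occupancy >= {min_occupancy}; "
            "lower min_occupancy or min_run"
        )
    return msa.slice_columns(best_start, best_start + best_len)


def uniform_background(alphabet: str = AMINO_ACIDS) -> np.ndarray:
    return np.full(len(alphabet), 1.0 / len(alphabet))


def build_profile(
    msa: MultipleAlignment,
    name: str = "profile",
    gap_fraction_threshold: float = 0.5,
    pseudocount_weight: float = 1.0,
    transition_pseudocount: float = 1.0,
    background: np.ndarray | None = None,
    alphabet: str = AMINO_ACIDS,
) -> ProfileHMM:
    """Estimate a profile HMM from a multiple alignment.

    Columns with gap fraction <= ``gap_fraction_threshold`` become match
    states.  Match emissions are residue counts (uniform sequence weights)
    smoothed with ``pseudocount_weight`` x background per column;
    transitions are counted from each row's implied state path with
    Laplace smoothing of ``transition_pseudocount`` per move (with few
    seed sequences a smaller value keeps the match chain tight).
    Entry/exit follow the uniform local model described in the module
    docstring.
    """
    if not (0.0 < gap_fraction_threshold < 1.0):
        raise ValueError("gap_fraction_threshold must be in (0, 1)")
    K = len(alphabet)
    bg = uniform_background(alphabet) if background is None else np.asarray(background, float)
    idx = {c: i for i, c in enumerate(alphabet)}

    match_cols = [
        j for j in range(msa.length) if msa.gap_fraction(j) <= gap_fraction_threshold
    ]
    L = len(match_cols)
    if L < 2:
        raise ValueError(
            f"alignment yields only {L} match state(s) at gap threshold "
            f"{gap_fraction_threshold}; need >= 2"
        )
    col_rank = {j: k for k, j in enumerate(match_cols)}
    match_set = set(match_cols)

    # emission counts (X treated as uninformative and skipped)
    em = np.zeros((L, K))
    for row in msa.rows:
        for j in match_cols:
            c = row[j]
            if c in idx:
                em[col_rank[j], idx[c]] += 1.0
    em += pseudocount_weight * bg
    em /= em.sum(axis=1, keepdims=True)

    # transition counts from per-row state paths; leading/trailing deletes
    # are trimmed (local model: rows enter at their first occupied match
    # column and leave at their last)
    if transition_pseudocount <= 0:
        raise ValueError("transition_pseudocount must be > 0")
    c_m = np.full((L - 1, 3), transition_pseudocount)  # M_k -> M/I/D
    c_i = np.full((L - 1, 2), transition_pseudocount)  # I_k -> M/I
    c_d = np.full((L - 1, 2), transition_pseudocount)  # D_k -> M/D
    for row in msa.rows:
        path: list[tuple[str, int]] = []
        last_k = -1
        for j in range(msa.length):
            c = row[j]
            if j in match_set:
                k = col_rank[j]
                path.append(("M" if c != "-" else "D", k))
                last_k = k
            elif c != "-":
                path.append(("I", last_k))
        # trim flanking deletes and flanking inserts (outside local span)
        first = next((i for i, (s, _) in enumerate(path) if s == "M"), None)
        if first is None:
            continue
        last = max(i for i, (s, _) in enumerate(path) if s == "M")
        for (s1, k1), (s2, _k2) in zip(path[first:last], path[first + 1 : last + 1]):
            if k1 < 0:
                continue
            col = {"M": 0, "I": 1, "D": 2}[s2] if s1 == "M" else {"M": 0, "I": 1, "D": 1}[s2]
            if s1 == "M" and k1 < L - 1:
                c_m[k1, col] += 1.0
            elif s1 == "I" and 0 <= k1 < L - 1:
                c_i[k1, 0 if s2 == "M" else 1] += 1.0
            elif s1 == "D" and k1 < L - 1:
                c_d[k1, 0 if s2 == "M" else 1] += 1.0

    t_m = c_m / c_m.sum(axis=1, keepdims=True)
    t_i = c_i / c_i.sum(axis=1, keepdims=True)
    t_d = c_d / c_d.sum(axis=1, keepdims=True)

    exit_ = 1.0 / (L - np.arange(L, dtype=float))  # uniform exit point
    prof = ProfileHMM(
        name=name,
        alphabet=alphabet,
        match_emissions=em,
        insert_emissions=bg.copy(),
        background=bg,
        t_mm=t_m[:, 0],
        t_mi=t_m[:, 1],
        t_md=t_m[:, 2],
        t_im=t_i[:, 0],
        t_ii=t_i[:, 1],
        t_dm=t_d[:, 0],
        t_dd=t_d[:, 1],
        entry=np.full(L, 1.0 / L),
        exit_=exit_,
    )
    prof.validate()
    return prof


# ---------------------------------------------------------------------------
# Scoring


@dataclass(frozen=True)
class LocalHit:
    """Best local alignment of a profile to one sequence."""

    ali_start: int  # 1-based inclusive
    ali_end: int
    bitscore: float
    path: tuple[tuple[str, int], ...]  # (state, 0-based match index) per step

    @property
    def found(self) -> bool:
        return math.isfinite(self.bitscore)


_NO_HIT = LocalHit(0, 0, NEG, ())


def _lod_column(lod_m: np.ndarray, xi: int) -> np.ndarray:
    if xi < 0:  # X: background ratio 1 in every state
        return np.zeros(lod_m.shape[0])
    return lod_m[:, xi]


def viterbi_local(profile: ProfileHMM, sequence: str) -> LocalHit:
    """Maximum-scoring local alignment of ``profile`` to ``sequence``.

    Returns 1-based inclusive coordinates of the aligned span, the score
    in bits, and the match/insert/delete state path.  Deterministic: ties
    resolve toward earlier start, match over insert over delete.
    """
    n = len(sequence)
    if n == 0:
        return _NO_HIT
    sc = profile.scoring()
    L = profile.L
    x = profile.encode(sequence)

    VM = np.full((n + 1, L), NEG)
    VI = np.full((n + 1, L), NEG)
    VD = np.full((n + 1, L), NEG)
    # pointers: M: 0=start 1=M 2=I 3=D ; I: 0=M 1=I ; D: 0=M 1=D
    pM = np.zeros((n + 1, L), dtype=np.int8)
    pI = np.zeros((n + 1, L), dtype=np.int8)
    pD = np.zeros((n + 1, L), dtype=np.int8)

    a_mm, a_mi, a_md = sc["a_mm"], sc["a_mi"], sc["a_md"]
    a_im, a_ii = sc["a_im"], sc["a_ii"]
    a_dm, a_dd = sc["a_dm"], sc["a_dd"]
    entry_log, exit_log, lod_m, lod_i = sc["entry_log"], sc["exit_log"], sc["lod_m"], sc["lod_i"]

    # per-position emission log-odds, X rows all-zero
    E = np.zeros((n, L))
    known = x >= 0
    E[known] = lod_m[:, x[known]].T
    EI = np.zeros(n)
    EI[known] = lod_i[x[known]]

    # delete-chain prefix sums: U[k] = sum of a_dd[0:k-1] entering D_k.
    # The prefix-sum shortcut needs finite a_dd (guaranteed after
    # pseudocounts); hand-built profiles with zero-probability D->D
    # transitions take the explicit per-state loop instead.
    dd_finite = bool(np.all(np.isfinite(a_dd)))
    U = np.zeros(L)
    if dd_finite:
        U[2:] = np.cumsum(a_dd[1 : L - 1])

    cand = np.empty((4, L))
    for i in range(1, n + 1):
        e, ei = E[i - 1], EI[i - 1]
        cand[0] = entry_log
        cand[1, 0] = cand[2, 0] = cand[3, 0] = NEG
        cand[1, 1:] = VM[i - 1, :-1] + a_mm
        cand[2, 1:] = VI[i - 1, :-1] + a_im
        cand[3, 1:] = VD[i - 1, :-1] + a_dm
        pM[i] = np.argmax(cand, axis=0)
        VM[i] = e + np.max(cand, axis=0)

        cm = np.full(L, NEG)
        ci = np.full(L, NEG)
        cm[: L - 1] = VM[i - 1, : L - 1] + a_mi
        ci[: L - 1] = VI[i - 1, : L - 1] + a_ii
        pI[i] = (ci > cm).astype(np.int8)
        VI[i] = ei + np.maximum(cm, ci)

        # VD[i,k] = max_{j<k} VM[i,j] + a_md[j] + sum(a_dd[j+1:k]); vectorized
        # via prefix sums of a_dd and a running maximum
        if dd_finite:
            B = VM[i, : L - 1] + a_md - U[1:]
            VD[i, 1:] = np.maximum.accumulate(B) + U[1:]
            from_m = VM[i, : L - 1] + a_md
            from_d = np.full(L - 1, NEG)
            from_d[1:] = VD[i, 1 : L - 1] + a_dd[1:]
            pD[i, 1:] = (from_d > from_m).astype(np.int8)
        else:
            for k in range(1, L):
                from_m = VM[i, k - 1] + a_md[k - 1]
                from_d = VD[i, k - 1] + a_dd[k - 1] if k >= 2 else NEG
                if from_d > from_m:
                    VD[i, k], pD[i, k] = from_d, 1
                else:
                    VD[i, k], pD[i, k] = from_m, 0

    end_scores = VM[1:] + exit_log[None, :]
    flat = int(np.argmax(end_scores))
    best = float(end_scores.flat[flat])
    if not math.isfinite(best):
        return _NO_HIT
    i_best, k_best = flat // L + 1, flat % L

    # traceback
    path: list[tuple[str, int]] = []
    state, i, k = "M", i_best, k_best
    start_i = i_best
    while True:
        path.append((state, k))
        if state == "M":
            choice = pM[i, k]
            if choice == 0:
                start_i = i
                break
            state = {1: "M", 2: "I", 3: "D"}[int(choice)]
            i, k = i - 1, k - 1
        elif state == "I":
            state = "I" if pI[i, k] else "M"
            i = i - 1
        else:  # D
            state = "D" if pD[i, k] else "M"
            k = k - 1
    path.reverse()
    return LocalHit(ali_start=start_i, ali_end=i_best, bitscore=best, path=tuple(path))


def forward_local(profile: ProfileHMM, sequence: str) -> float:
    """Total local bit score: log2-sum over all local alignments.

    Always >= the Viterbi score; equals it when exactly one path has
    non-zero probability.
    """
    n = len(sequence)
    if n == 0:
        return NEG
    sc = profile.scoring()
    L = profile.L
    x = profile.encode(sequence)

    FM = np.full((n + 1, L), NEG)
    FI = np.full((n + 1, L), NEG)
    FD = np.full((n + 1, L), NEG)
    a_mm, a_mi, a_md = sc["a_mm"], sc["a_mi"], sc["a_md"]
    a_im, a_ii = sc["a_im"], sc["a_ii"]
    a_dm, a_dd = sc["a_dm"], sc["a_dd"]
    entry_log, exit_log, lod_m, lod_i = sc["entry_log"], sc["exit_log"], sc["lod_m"], sc["lod_i"]

    with np.errstate(invalid="ignore"):
        for i in range(1, n + 1):
            xi = x[i - 1]
            e = _lod_column(lod_m, xi)
            ei = 0.0 if xi < 0 else float(lod_i[xi])
            acc = entry_log.copy()
            acc[1:] = np.logaddexp2(acc[1:], FM[i - 1, :-1] + a_mm)
            acc[1:] = np.logaddexp2(acc[1:], FI[i - 1, :-1] + a_im)
            acc[1:] = np.logaddexp2(acc[1:], FD[i - 1, :-1] + a_dm)
            FM[i] = e + acc

            acc_i = np.full(L, NEG)
            acc_i[: L - 1] = np.logaddexp2(
                FM[i - 1, : L - 1] + a_mi, FI[i - 1, : L - 1] + a_ii
            )
            FI[i] = ei + acc_i

            for k in range(1, L):
                if k - 1 < L - 1:
                    FD[i, k] = np.logaddexp2(
                        FM[i, k - 1] + a_md[k - 1], FD[i, k - 1] + a_dd[k - 1]
                    )

        total = NEG
        ends = FM[1:] + exit_log[None, :]
        finite = ends[np.isfinite(ends)]
        if finite.size:
            m = float(finite.max())
            total = m + math.log2(float(np.sum(np.exp2(finite - m))))
    return total


# ---------------------------------------------------------------------------
# Calibration and scanning


def _sample_lengths(length_dist, n: int, rng: np.random.Generator) -> np.ndarray:
    if isinstance(length_dist, int):
        return np.full(n, length_dist, dtype=int)
    if isinstance(length_dist, tuple) and len(length_dist) == 2:
        lo, hi = length_dist
        return rng.integers(lo, hi + 1, size=n)
    pool = np.asarray(list(length_dist), dtype=int)
    return rng.choice(pool, size=n, replace=True)


def random_background_sequence(
    length: int, rng: np.random.Generator, alphabet: str = AMINO_ACIDS,
    background: np.ndarray | None = None,
) -> str:
    p = uniform_background(alphabet) if background is None else background
    chars = rng.choice(list(alphabet), size=length, p=p)
    return "".join(chars)


def calibrate_null(
    profile: ProfileHMM,
    length_dist,
    n_shuffles: int = 500,
    seed: int = 0,
    alpha: float = 1e-3,
) -> float:
    """Calibrate the profile's significance threshold on random decoys.

    Scores ``n_shuffles`` background-composition sequences (lengths drawn
    from ``length_dist``: an int, a (min, max) tuple, or a pool of
    lengths), fits a Gumbel by the method of moments, and stores the fit
    on ``profile.null``.  Returns the bit score whose fitted tail
    probability equals ``alpha``.
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100 for a stable fit")
    rng = np.random.default_rng(seed)
    lengths = _sample_lengths(length_dist, n_shuffles, rng)
    scores = np.empty(n_shuffles)
    for i, ln in enumerate(lengths):
        seq = random_background_sequence(int(ln), rng, profile.alphabet, profile.background)
        scores[i] = viterbi_local(profile, seq).bitscore

    sd = float(np.std(scores, ddof=1))
    if sd < 1e-9:
        warnings.warn(
            f"{profile.name}: degenerate null score variance; "
            "falling back to max(null) + 1 bit",
            stacklevel=2,
        )
        thr = float(np.max(scores)) + 1.0
        profile.null = GumbelNull(float(np.mean(scores)), 0.0, alpha, thr)
        return thr

    scale = sd * math.sqrt(6.0) / math.pi
    loc = float(np.mean(scores)) - _EULER_GAMMA * scale
    null = GumbelNull(loc, scale, alpha, 0.0)
    null.threshold_bits = null.threshold_for(alpha)
    profile.null = null
    return null.threshold_bits


def _segments(n: int, masked: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Maximal unmasked 1-based inclusive segments of a length-n sequence."""
    segs = []
    pos = 1
    for s, e in sorted(masked):
        if pos <= s - 1:
            segs.append((pos, s - 1))
        pos = max(pos, e + 1)
    if pos <= n:
        segs.append((pos, n))
    return segs


def scan_protein(
    profile: ProfileHMM, protein: ProteinRecord, threshold_bits: float
) -> list[DomainHit]:
    """Iteratively report non-overlapping significant hits of one profile.

    Finds the best local hit, masks its span, and repeats on the unmasked
    remainder until the best score drops below threshold — supporting
    multi-copy domains such as tandem LRR repeats.
    """
    if profile.null is None:
        raise ValueError(f"profile {profile.name} is not calibrated; run calibrate_null first")
    hits: list[DomainHit] = []
    masked: list[tuple[int, int]] = []
    n = len(protein.sequence)
    while True:
        best: LocalHit | None = None
        best_seg = None
        for s, e in _segments(n, masked):
            sub = protein.sequence[s - 1 : e]
            if len(sub) == 0:
                continue
            hit = viterbi_local(profile, sub)
            if hit.found and (best is None or hit.bitscore > best.bitscore):
                best, best_seg = hit, (s, e)
        if best is None or best.bitscore < threshold_bits:
            break
        off = best_seg[0] - 1
        start, end = best.ali_start + off, best.ali_end + off
        hits.append(
            DomainHit(
                protein_id=protein.id,
                model=profile.name,
                ali_start=start,
                ali_end=end,
                bitscore=round(best.bitscore, 6),
                significance=profile.null.significance(best.bitscore),
            )
        )
        masked.append((start, end))
    hits.sort(key=lambda h: (h.ali_start, h.ali_end))
    return hits


def scan_proteome(
    profiles: Sequence[ProfileHMM],
    proteome: Sequence[ProteinRecord],
    alpha: float | None = None,
) -> list[DomainHit]:
    """Scan every protein with every calibrated profile.

    Each profile is searched independently (hits of different profiles may
    overlap; overlap resolution is a downstream, per-protein step).
    ``alpha`` overrides the calibration-time significance level using the
    stored Gumbel fit.  Deterministic and permutation-equivariant in the
    proteome order.
    """
    all_hits: list[DomainHit] = []
    for protein in proteome:
        for profile in profiles:
            if profile.null is None:
                raise ValueError(f"profile {profile.name} is not calibrated")
            thr = (
                profile.null.threshold_bits
                if alpha is None
                else profile.null.threshold_for(alpha)
            )
            all_hits.extend(scan_protein(profile, protein, thr))
    return all_hits


def extract_domain_region(protein: ProteinRecord, hit: DomainHit, flank: int = 0) -> str:
    """Subsequence [ali_start - flank, ali_end + flank], clipped to bounds."""
    if hit.ali_start < 1 or hit.ali_end > len(protein.sequence):
        raise ValueError(f"hit {hit.model}@{hit.ali_start}-{hit.ali_end} outside {protein.id}")
    s = max(1, hit.ali_start - flank)
    e = min(len(protein.sequence), hit.ali_end + flank)
    return protein.sequence[s - 1 : e]
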