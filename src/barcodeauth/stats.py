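"""Barcode-library statistics: haplotypes, variable sites, Kimura 2-parameter
distances and barcode-gap assessment.

The K2P distance distinguishes transitions (A<->G, C<->T; proportion P) from
transversions (proportion Q) and corrects for multiple hits:

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

Sites where either sequence carries a gap or an ambiguity code are excluded
from the comparable-site count.  Saturated pairs (log/sqrt argument <= 0) and
pairs with no comparable sites are returned as NaN markers, never exceptions,
so a whole-matrix build always completes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from scipy.cluster.hierarchy import linkage

from .seqio import Alignment, SampleTable, SequenceRecord

log = logging.getLogger(__name__)

__all__ = [
    "SitePairCounts",
    "DistanceMatrix",
    "HaplotypeSet",
    "DistanceSummary",
    "GapReport",
    "ALL_OTHERS",
    "k2p_distance",
    "distance_matrix",
    "collapse_haplotypes",
    "variable_sites",
    "species_summary",
    "barcode_gap",
    "align_library",
]

# Integer encoding: A=0 G=1 C=2 T=3 so that a substitution is a transition
# iff code//2 is equal (purine pair vs pyrimidine pair).  Anything else
# (gap, ambiguity) encodes as -1 and is excluded pairwise.
_CODE = {"A": 0, "G": 1, "C": 2, "T": 3}


def encode(residues: str) -> np.ndarray:
    return np.fromiter((_CODE.get(c, -1) for c in residues), dtype=np.int8, count=len(residues))


@dataclass(frozen=True)
class SitePairCounts:
    """Comparable sites and the transition/transversion tallies of one pair."""

    n: int
    s: int
    v: int

    @property
    def P(self) -> float:
        return self.s / self.n if self.n else float("nan")

    @property
    def Q(self) -> float:
        return self.v / self.n if self.n else float("nan")


def _k2p_from_counts(n: int, s: int, v: int) -> float:
    if n == 0:
        return float("nan")
    P, Q = s / n, v / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return float("nan")  # saturated
    return -0.5 * math.log(w1 * math.sqrt(w2))


def k2p_distance(a: str, b: str) -> tuple[float, SitePairCounts]:
    """K2P distance between two equal-length aligned sequences.

    Returns ``(d, counts)``; ``d`` is NaN when no comparable sites remain or
    the correction saturates.
    """
    if len(a) != len(b):
        raise ValueError("sequences must have equal aligned length")
    ca, cb = encode(a.upper()), encode(b.upper())
    valid = (ca >= 0) & (cb >= 0)
    n = int(valid.sum())
    diff = valid & (ca != cb)
    ts = int((diff & ((ca >> 1) == (cb >> 1))).sum())
    tv = int(diff.sum()) - ts
    d = _k2p_from_counts(n, ts, tv)
    if math.isnan(d) and n:
        log.debug("K2P saturated: n=%d s=%d v=%d", n, ts, tv)
    return d, SitePairCounts(n, ts, tv)


class DistanceMatrix:
    """Symmetric pairwise distance matrix with NaN for undefined entries."""

    def __init__(self, labels: Sequence[str], values: np.ndarray,
                 counts: np.ndarray | None = None):
        labels = list(labels)
        values = np.asarray(values, dtype=float)
        if values.shape != (len(labels), len(labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(values, values.T, equal_nan=True):
            raise ValueError("matrix not symmetric")
        self.labels = labels
        self.values = values
        self.counts = counts  # optional (n,3) per-pair n/s/v array, same index order
        self._index = {l: i for i, l in enumerate(labels)}

    def get(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    @property
    def n_undefined(self) -> int:
        iu = np.triu_indices(len(self.labels), k=1)
        return int(np.isnan(self.values[iu]).sum())

    def is_fully_defined(self) -> bool:
        return self.n_undefined == 0

    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                if math.isnan(self.values[i, j]):
                    out.append((self.labels[i], self.labels[j]))
        return out

    def submatrix(self, labels: Iterable[str]) -> "DistanceMatrix":
        idx = [self._index[l] for l in labels]
        return DistanceMatrix([self.labels[i] for i in idx], self.values[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for i, lab in enumerate(self.labels):
                row = " ".join(f"{v:.6f}" if np.isfinite(v) else "NA" for v in self.values[i])
                fh.write(f"{lab}  {row}\n")

    def to_long_tsv(self, path: str | Path) -> None:
        rows = []
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                rec = {"id_a": self.labels[i], "id_b": self.labels[j],
                       "d": self.values[i, j]}
                if self.counts is not None:
                    rec.update(zip(("n", "s", "v"), self.counts[i, j]))
                rows.append(rec)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _pairwise_counts(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized n/s/v counts over all pairs of encoded rows (m x L int8)."""
    a = mat[:, None, :]
    b = mat[None, :, :]
    valid = (a >= 0) & (b >= 0)
    diff = valid & (a != b)
    ts = diff & ((a >> 1) == (b >> 1))
    return valid.sum(axis=2), ts.sum(axis=2), diff.sum(axis=2) - ts.sum(axis=2)


def distance_matrix(alignment: Alignment, *, deletion: str = "pairwise") -> DistanceMatrix:
    """All-pairs K2P matrix.

    ``deletion`` selects the gap/ambiguity policy: ``"pairwise"`` (each pair
    uses its own comparable-site set, MEGA's default) or ``"complete"`` (any
    column with a gap or ambiguity in any sequence is dropped for all pairs).
    """
    if len(alignment) < 2:
        raise ValueError("need at least 2 records")
    if deletion not in ("pairwise", "complete"):
        raise ValueError("deletion must be 'pairwise' or 'complete'")
    mat = np.stack([encode(r.residues) for r in alignment.records])
    if deletion == "complete":
        mat = mat[:, (mat >= 0).all(axis=0)]
    n, s, v = _pairwise_counts(mat)
    m = len(alignment)
    values = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            values[i, j] = values[j, i] = _k2p_from_counts(int(n[i, j]), int(s[i, j]), int(v[i, j]))
    counts = np.stack([n, s, v], axis=-1)
    return DistanceMatrix(alignment.ids(), values, counts=counts)


@dataclass
class HaplotypeSet:
    """Distinct aligned sequences and their member samples, H1, H2, ..."""

    haplotypes: list[tuple[str, str, list[str]]]  # (haplotype_id, residues, member ids)

    def __len__(self) -> int:
        return len(self.haplotypes)

    def largest(self) -> tuple[str, str, list[str]]:
        return self.haplotypes[0]

    def representative_ids(self) -> list[str]:
        return [members[0] for _, _, members in self.haplotypes]


def collapse_haplotypes(alignment: Alignment, members: Iterable[str] | None = None) -> HaplotypeSet:
    """Group samples by exact aligned-residue equality (gap columns included).

    Haplotypes are ordered by descending member count, ties by first occurrence;
    ids are H1, H2, ...
    """
    ids = list(members) if members is not None else alignment.ids()
    if not ids:
        raise ValueError("member subset must be non-empty")
    sub = alignment.subset(ids)
    classes: dict[str, list[str]] = {}
    for rec in sub.records:
        classes.setdefault(rec.residues, []).append(rec.id)
    order = sorted(classes.items(), key=lambda kv: (-len(kv[1]),
                                                    min(sub.ids().index(i) for i in kv[1])))
    return HaplotypeSet([(f"H{k+1}", seq, mem) for k, (seq, mem) in enumerate(order)])


def variable_sites(alignment: Alignment, members: Iterable[str] | None = None) -> list[int]:
    """1-based columns with >=2 distinct states among ``members``.

    The gap is a state; each ambiguity code is its own state.
    """
    ids = list(members) if members is not None else alignment.ids()
    if len(ids) < 2:
        raise ValueError("need at least 2 members")
    sub = alignment.subset(ids)
    out = []
    for pos in range(1, sub.length + 1):
        if len(set(sub.column(pos))) > 1:
            out.append(pos)
    return out


@dataclass
class DistanceSummary:
    """Aggregate of a set of pairwise distances."""

    min: float
    max: float
    mean: float
    n_pairs: int
    n_undefined: int = 0


ALL_OTHERS = "__all_others__"


def _collect(matrix: DistanceMatrix, pairs: list[tuple[str, str]]) -> DistanceSummary:
    vals = [matrix.get(a, b) for a, b in pairs]
    defined = [v for v in vals if not math.isnan(v)]
    und = len(vals) - len(defined)
    if not defined:
        return DistanceSummary(float("nan"), float("nan"), float("nan"), 0, und)
    return DistanceSummary(min(defined), max(defined),
                           sum(defined) / len(defined), len(defined), und)


def species_summary(matrix: DistanceMatrix, table: SampleTable, species_a: str,
                    species_b: str | set[str] | frozenset[str] = ALL_OTHERS) -> DistanceSummary:
    """Intra- or inter-specific distance summary.

    ``species_b`` may be the same label as ``species_a`` (intraspecific, over
    unordered within-species pairs), an explicit label or label set, or
    ``ALL_OTHERS`` for every other species in the table.
    """
    a_ids = [i for i in table.members(species_a) if i in set(matrix.labels)]
    if not a_ids:
        raise ValueError(f"species {species_a!r} absent from matrix/table")
    if isinstance(species_b, str) and species_b == species_a:
        pairs = [(a_ids[i], a_ids[j]) for i in range(len(a_ids)) for j in range(i + 1, len(a_ids))]
        return _collect(matrix, pairs)
    if isinstance(species_b, str) and species_b == ALL_OTHERS:
        labels_b = set(table.species_labels()) - {species_a}
    elif isinstance(species_b, str):
        labels_b = {species_b}
    else:
        labels_b = set(species_b)
    b_ids = [i for i in table.members(labels_b) if i in set(matrix.labels)]
    if not b_ids:
        raise ValueError(f"comparison scope {labels_b} absent from matrix/table")
    pairs = [(a, b) for a in a_ids for b in b_ids]
    return _collect(matrix, pairs)


@dataclass
class GapReport:
    """Barcode-gap assessment for one target species against a scope."""

    max_intra: float
    min_inter: float
    gap_present: bool
    scope: str


def barcode_gap(matrix: DistanceMatrix, table: SampleTable, target: str,
                scope: str = "all") -> GapReport:
    """Compare the target's maximum intraspecific distance with the minimum
    interspecific distance to species in ``scope`` (a group name:
    ``congener``/``adulterant``, or ``all`` other species)."""
    if len(table.members(target)) < 2:
        raise ValueError(f"target {target!r} needs >=2 samples for an intraspecific maximum")
    intra = species_summary(matrix, table, target, target)
    if scope in ("congener", "adulterant"):
        species_b = set(table.species_in_group(scope)) - {target}
    elif scope == "all":
        species_b = set(table.species_labels()) - {target}
    else:
        species_b = {scope}
    if not species_b:
        raise ValueError(f"empty comparison scope {scope!r}")
    inter = species_summary(matrix, table, target, frozenset(species_b))
    return GapReport(max_intra=intra.max, min_inter=inter.min,
                     gap_present=bool(inter.min > intra.max), scope=scope)


# ---------------------------------------------------------------------------
# Progressive multiple alignment (guide distances -> UPGMA -> profile merges)
# ---------------------------------------------------------------------------

_MATCH, _MISMATCH, _GAP_OPEN, _GAP_EXT = 1.0, -1.0, -5.0, -1.0
_NEG = -1e30


def _guide_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = _MATCH
    a.mismatch_score = _MISMATCH
    a.open_gap_score = _GAP_OPEN
    a.extend_gap_score = _GAP_EXT
    return a


def _profile(cols: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Frequency matrix (L x 4 over A,G,C,T) and per-column weights; gaps and
    ambiguity codes carry zero weight."""
    L = len(cols[0]) if cols else 0
    seqs = np.stack([encode(s) for s in cols]) if cols else np.zeros((0, 0), dtype=np.int8)
    F = np.zeros((seqs.shape[1], 4))
    for b in range(4):
        F[:, b] = (seqs == b).sum(axis=0)
    w = F.sum(axis=1)
    return F, w


def _profile_align(rows_a: list[str], rows_b: list[str]) -> tuple[list[str], list[str]]:
    """Gotoh profile-profile alignment with sum-of-pairs column scores.

    Ties are broken with a fixed preference (match, then gap-in-B, then
    gap-in-A), which places gaps deterministically and as far left as the
    recurrence allows.
    """
    FA, wA = _profile(rows_a)
    FB, wB = _profile(rows_b)
    la, lb = FA.shape[0], FB.shape[0]
    # score of aligning column i of A with column j of B
    dot = FA @ FB.T
    ww = np.outer(wA, wB)
    with np.errstate(divide="ignore", invalid="ignore"):
        S = np.where(ww > 0, (2.0 * dot - ww) / np.where(ww > 0, ww, 1.0), 0.0)

    M = np.full((la + 1, lb + 1), _NEG)
    X = np.full((la + 1, lb + 1), _NEG)  # gap in B (consume A)
    Y = np.full((la + 1, lb + 1), _NEG)  # gap in A (consume B)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = _GAP_OPEN + _GAP_EXT * (i - 1)
    for j in range(1, lb + 1):
        Y[0, j] = _GAP_OPEN + _GAP_EXT * (j - 1)
    for i in range(1, la + 1):
        Mi1, Xi1, Yi1 = M[i - 1], X[i - 1], Y[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Si = S[i - 1]
        for j in range(1, lb + 1):
            best = max(Mi1[j - 1], Xi1[j - 1], Yi1[j - 1])
            Mi[j] = best + Si[j - 1]
            Xi[j] = max(Mi1[j] + _GAP_OPEN, Xi1[j] + _GAP_EXT, Yi1[j] + _GAP_OPEN)
            Yi[j] = max(Mi[j - 1] + _GAP_OPEN, Yi[j - 1] + _GAP_EXT, Xi[j - 1] + _GAP_OPEN)
    # traceback
    i, j = la, lb
    state = max((M[i, j], "M"), (X[i, j], "X"), (Y[i, j], "Y"),
                key=lambda t: (t[0], t[1] == "M", t[1] == "X"))[1]
    ops: list[str] = []
    while i > 0 or j > 0:
        if i == 0:
            ops.append("Y"); j -= 1; continue
        if j == 0:
            ops.append("X"); i -= 1; continue
        if state == "M":
            prev = max((M[i - 1, j - 1], "M"), (X[i - 1, j - 1], "X"), (Y[i - 1, j - 1], "Y"),
                       key=lambda t: (t[0], t[1] == "M", t[1] == "X"))[1]
            ops.append("M"); i -= 1; j -= 1; state = prev
        elif state == "X":
            cand = [(M[i - 1, j] + _GAP_OPEN, "M"), (X[i - 1, j] + _GAP_EXT, "X"),
                    (Y[i - 1, j] + _GAP_OPEN, "Y")]
            prev = max(cand, key=lambda t: (t[0], t[1] == "M", t[1] == "X"))[1]
            ops.append("X"); i -= 1; state = prev
        else:
            cand = [(M[i, j - 1] + _GAP_OPEN, "M"), (Y[i, j - 1] + _GAP_EXT, "Y"),
                    (X[i, j - 1] + _GAP_OPEN, "X")]
            prev = max(cand, key=lambda t: (t[0], t[1] == "M", t[1] == "Y"))[1]
            ops.append("Y"); j -= 1; state = prev
    ops.reverse()
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op in ("M", "X"):
            for k, s in enumerate(rows_a):
                out_a[k] += s[ia]
            ia += 1
        else:
            for k in range(len(rows_a)):
                out_a[k] += "-"
        if op in ("M", "Y"):
            for k, s in enumerate(rows_b):
                out_b[k] += s[ib]
            ib += 1
        else:
            for k in range(len(rows_b)):
                out_b[k] += "-"
    return out_a, out_b


def align_library(records: Sequence[SequenceRecord]) -> Alignment:
    """Progressive multiple alignment of ungapped records.

    Pairwise Needleman-Wunsch alignments (match +1, mismatch -1, gap open -5,
    gap extend -1) provide guide distances; a UPGMA guide tree orders the
    profile-profile merges, which use the same scores.  Deterministic for a
    fixed input order.
    """
    records = list(records)
    if any("-" in r.residues for r in records):
        raise ValueError("align_library expects ungapped input")
    if len(records) == 1:
        log.warning("align_library called with a single record; returned unchanged")
        return Alignment(records)
    m = len(records)
    aligner = _guide_aligner()
    dist = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            aln = aligner.align(records[i].residues, records[j].residues)[0]
            sa, sb = str(aln[0]), str(aln[1])
            ident = sum(x == y for x, y in zip(sa, sb))
            dist[i, j] = dist[j, i] = 1.0 - ident / len(sa)
    condensed = dist[np.triu_indices(m, k=1)]
    Z = linkage(condensed, method="average")
    # progressive merges following the UPGMA join order
    clusters: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [records[i].residues]) for i in range(m)
    }
    nxt = m
    for a, b, _, _ in Z:
        ia, ib = int(a), int(b)
        idx_a, rows_a = clusters.pop(ia)
        idx_b, rows_b = clusters.pop(ib)
        new_a, new_b = _profile_align(rows_a, rows_b)
        clusters[nxt] = (idx_a + idx_b, new_a + new_b)
        nxt += 1
    order, rows = clusters.popitem()[1]
    by_input = sorted(zip(order, rows))
    return Alignment(
        [
            SequenceRecord(records[i].id, row, species=records[i].species, group=records[i].group)
            for i, row in by_input
        ]
    )


def map_query_to_alignment(alignment: Alignment, query: str,
                           ref_id: str | None = None) -> str:
    """Thread an ungapped query into the alignment's column frame.

    The query is pairwise-aligned (same scores as the library aligner) to its
    best-matching reference row (or to ``ref_id`` when given); reference
    columns absorb the query bases and query insertions relative to that
    reference are dropped, so the result has exactly ``alignment.length``
    characters.
    """
    aligner = _guide_aligner()
    if ref_id is not None:
        best_rec = alignment.get(ref_id)
    else:
        best_rec, best_score = None, -math.inf
        for rec in alignment.records:
            score = aligner.score(rec.residues.replace("-", ""), query)
            if score > best_score:
                best_rec, best_score = rec, score
    assert best_rec is not None
    ref_ungapped = best_rec.residues.replace("-", "")
    aln = aligner.align(ref_ungapped, query)[0]
    ra, qa = str(aln[0]), str(aln[1])
    # query base aligned to each ungapped-reference position ('-' where deleted)
    per_ref: list[str] = []
    for x, y in zip(ra, qa):
        if x != "-":
            per_ref.append(y if y != "-" else "-")
    out = []
    k = 0
    for ch in best_rec.residues:
        if ch == "-":
            out.append("-")
        else:
            out.append(per_ref[k])
            k += 1
    return "".join(out)
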