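"""Neighbor-joining trees with bootstrap support.

The agglomeration uses the Studier-Keppler form of the Saitou-Nei criterion,

    Q(i, j) = (r - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k),

joining the pair minimizing Q at each step; ties are broken toward the
smallest (i, j) index pair in the current label order.  Branch lengths follow
the standard NJ formulas, with negative estimates clamped to zero (the clamped
deficit is logged).  Trees are unrooted, serialized with a trifurcating root.

Bootstrap supports are mapped onto the full-data topology: each replicate
resamples alignment columns with replacement, rebuilds the K2P matrix and NJ
tree, and each internal edge's support is the percentage of replicates whose
tree contains the same bipartition.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable

import numpy as np

from .seqio import Alignment, SampleTable, SequenceRecord
from .stats import DistanceMatrix, distance_matrix

log = logging.getLogger(__name__)

__all__ = [
    "Node",
    "neighbor_joining",
    "bootstrap_support",
    "to_newick",
    "parse_newick",
    "bipartitions",
    "monophyly_check",
    "render_ascii",
]


class Node:
    """Tree node: leaves carry ``name``; internal nodes may carry ``support``
    (integer percent) after bootstrapping.  ``length`` is the branch to the
    parent (None at the root)."""

    __slots__ = ("name", "length", "children", "support")

    def __init__(self, name: str | None = None, length: float | None = None,
                 children: list["Node"] | None = None):
        self.name = name
        self.length = length
        self.children = children or []
        self.support: int | None = None

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf():
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]

    def walk(self) -> Iterable["Node"]:
        yield self
        for c in self.children:
            yield from c.walk()


def neighbor_joining(matrix: DistanceMatrix) -> Node:
    """Build an unrooted NJ tree (trifurcating root) from a fully defined matrix."""
    if len(matrix.labels) < 3:
        raise ValueError("need at least 3 labels")
    if not matrix.is_fully_defined():
        raise ValueError(f"matrix has undefined entries: {matrix.undefined_pairs()}")
    labels = list(matrix.labels)
    D = matrix.values.copy()
    nodes: list[Node] = [Node(name=l) for l in labels]
    clamped = 0.0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += -x
            return 0.0
        return x

    while len(nodes) > 3:
        r = len(nodes)
        R = D.sum(axis=1)
        Q = (r - 2) * D - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        # argmin in row-major order = smallest (i, j) on ties
        i, j = np.unravel_index(int(np.argmin(Q)), Q.shape)
        if i > j:
            i, j = j, i
        dij = D[i, j]
        li = 0.5 * dij + (R[i] - R[j]) / (2.0 * (r - 2))
        lj = dij - li
        li, lj = clamp(li), clamp(lj)
        new = Node(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = li, lj
        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(r) if k not in (i, j)]
        D2 = np.empty((r - 1, r - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dnew[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[k] for k in keep] + [new]
    # final three nodes join at the trifurcating root
    a, b, c = nodes
    da_b, da_c, db_c = D[0, 1], D[0, 2], D[1, 2]
    a.length = clamp(0.5 * (da_b + da_c - db_c))
    b.length = clamp(0.5 * (da_b + db_c - da_c))
    c.length = clamp(0.5 * (da_c + db_c - da_b))
    if clamped > 0:
        log.info("clamped %.6g of negative branch length to 0", clamped)
    return Node(children=[a, b, c])


def bipartitions(tree: Node, *, trivial: bool = False) -> set[frozenset[str]]:
    """Splits induced by the tree's edges, canonicalized as the side that does
    not contain the lexicographically smallest leaf."""
    all_leaves = frozenset(tree.leaf_names())
    ref = min(all_leaves)
    out: set[frozenset[str]] = set()
    for node in tree.walk():
        if node is tree:
            continue
        side = frozenset(node.leaf_names())
        if ref in side:
            side = all_leaves - side
        if not trivial and (len(side) < 2 or len(side) > len(all_leaves) - 2):
            continue
        if side:
            out.add(side)
    return out


def _resample(alignment: Alignment, rng: np.random.Generator) -> Alignment:
    cols = rng.integers(0, alignment.length, size=alignment.length)
    return Alignment(
        [
            SequenceRecord(r.id, "".join(r.residues[c] for c in cols),
                           species=r.species, group=r.group)
            for r in alignment.records
        ]
    )


def bootstrap_support(alignment: Alignment, n_reps: int = 1000, seed: int = 1,
                      *, deletion: str = "pairwise", max_redraw_factor: int = 100) -> Node:
    """Reference NJ tree with bootstrap supports on its internal edges.

    Replicates whose resampled K2P matrix has undefined entries are discarded
    and redrawn (count logged) so that ``n_reps`` effective replicates are
    always aggregated.  Deterministic for a fixed seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    full = distance_matrix(alignment, deletion=deletion)
    if not full.is_fully_defined():
        raise ValueError("full-data distance matrix has undefined entries")
    ref_tree = neighbor_joining(full)
    ref_splits = bipartitions(ref_tree)
    counts = {s: 0 for s in ref_splits}
    rng = np.random.default_rng(seed)
    done = redraws = 0
    while done < n_reps:
        if redraws > max_redraw_factor * n_reps:
            raise RuntimeError("too many bootstrap replicates with undefined distances")
        rep = _resample(alignment, rng)
        dm = distance_matrix(rep, deletion=deletion)
        if not dm.is_fully_defined():
            redraws += 1
            continue
        rep_splits = bipartitions(neighbor_joining(dm))
        for s in ref_splits & rep_splits:
            counts[s] += 1
        done += 1
    if redraws:
        log.info("redrew %d bootstrap replicates with undefined distances", redraws)
    all_leaves = frozenset(ref_tree.leaf_names())
    ref = min(all_leaves)
    for node in ref_tree.walk():
        if node is ref_tree or node.is_leaf():
            continue
        side = frozenset(node.leaf_names())
        if ref in side:
            side = all_leaves - side
        if side in counts:
            node.support = int(round(100.0 * counts[side] / n_reps))
    return ref_tree


def _fmt_len(x: float | None) -> str:
    return "" if x is None else f":{x:.6g}"


def _newick(node: Node) -> str:
    if node.is_leaf():
        return f"{node.name}{_fmt_len(node.length)}"
    inner = ",".join(_newick(c) for c in node.children)
    label = "" if node.support is None else str(node.support)
    return f"({inner}){label}{_fmt_len(node.length)}"


def to_newick(tree: Node) -> str:
    """Newick string with branch lengths (6 s.f.) and integer supports as
    internal-node labels."""
    return _newick(tree) + ";"


def parse_newick(text: str) -> Node:
    """Minimal Newick reader (labels, branch lengths, integer internal labels)."""
    s = text.strip()
    if not s.endswith(";"):
        raise ValueError("newick must end with ';'")
    s = s[:-1]
    pos = 0

    def parse_node() -> Node:
        nonlocal pos
        node = Node()
        if s[pos] == "(":
            pos += 1
            node.children.append(parse_node())
            while s[pos] == ",":
                pos += 1
                node.children.append(parse_node())
            if s[pos] != ")":
                raise ValueError(f"expected ')' at {pos}")
            pos += 1
        # label
        start = pos
        while pos < len(s) and s[pos] not in ",():;":
            pos += 1
        label = s[start:pos]
        if label:
            if node.children:
                node.support = int(label)
            else:
                node.name = label
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",()":
                pos += 1
            node.length = float(s[start:pos])
        return node

    root = parse_node()
    if pos != len(s):
        raise ValueError("trailing characters in newick")
    return root


def monophyly_check(tree: Node, table: SampleTable, species: str | Iterable[str]) -> bool:
    """True iff some edge of the unrooted tree separates exactly the species'
    leaves from everything else (singletons and the full leaf set are trivially
    monophyletic)."""
    wanted = set(table.members(species))
    leaves = set(tree.leaf_names())
    present = wanted & leaves
    if not present:
        raise ValueError(f"species {species!r} has no leaves in the tree")
    if len(present) in (1, len(leaves)):
        return True
    all_leaves = frozenset(leaves)
    ref = min(all_leaves)
    target = frozenset(present)
    if ref in target:
        target = all_leaves - target
    return target in bipartitions(tree, trivial=True)


def render_ascii(tree: Node, width: int = 60) -> str:
    """Small indented text rendering for logs and smoke tests."""
    lines: list[str] = []

    def rec(node: Node, depth: int) -> None:
        tag = node.name or ""
        if node.support is not None:
            tag += f" [{node.support}]"
        if node.length is not None:
            tag += f" ({node.length:.4g})"
        lines.append("  " * depth + "+-" + (tag or "*"))
        for c in node.children:
            rec(c, depth + 1)

    rec(tree, 0)
    return "\n".join(lines)
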