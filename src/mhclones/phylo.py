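"""Kimura 2-parameter distances, neighbor-joining and bootstrap support.

The distance model separates transition (``p``) and transversion (``q``)
proportions:

    d = -(1/2) ln(1 - 2p - q) - (1/4) ln(1 - 2q)

Trees are built by neighbor joining on the Q-criterion with a deterministic
tie-break (lowest index pair) and the standard fix for negative branch
lengths (clamp to zero, transfer the deficit to the sister branch).
Bootstrap support is the percentage of column-resampled replicates whose NJ
tree contains each internal bipartition; branches at or below the collapse
threshold (default 50%) are collapsed to polytomies.

Trees are dendropy objects throughout, so Newick round-trips and leaf
bookkeeping follow dendropy semantics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import dendropy
import numpy as np

from .diversity import NUCLEOTIDES, SiteAlignment

logger = logging.getLogger(__name__)

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


class SaturationError(ValueError):
    """The K2P logarithms are undefined: the pair is too divergent."""


@dataclass(frozen=True)
class PairwiseDistance:
    p: float  # transition proportion
    q: float  # transversion proportion
    d: float  # K2P distance

    def __post_init__(self) -> None:
        if self.p < 0 or self.q < 0 or self.p + self.q > 1:
            raise ValueError("invalid transition/transversion proportions")


@dataclass(frozen=True)
class DistanceMatrix:
    taxa: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")


def k2p_distance(
    seq_a: str,
    seq_b: str,
    mask: np.ndarray | None = None,
    names: tuple[str, str] = ("seqA", "seqB"),
) -> PairwiseDistance:
    """K2P distance between two equal-length sequences.

    Sites where either sequence carries a non-ACGT symbol are removed
    (pairwise deletion); ``mask`` optionally restricts the comparison to a
    boolean site selection first.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(f"sequences {names[0]} and {names[1]} have different lengths")
    a = np.frombuffer(seq_a.upper().encode(), dtype="S1").astype("U1")
    b = np.frombuffer(seq_b.upper().encode(), dtype="S1").astype("U1")
    if mask is not None:
        a, b = a[mask], b[mask]
    valid = np.isin(a, NUCLEOTIDES) & np.isin(b, NUCLEOTIDES)
    a, b = a[valid], b[valid]
    n = a.size
    if n == 0:
        raise ValueError(f"no comparable sites between {names[0]} and {names[1]}")
    diff = a != b
    transitions = 0
    for x, y in zip(a[diff], b[diff]):
        if (x in _PURINES) == (y in _PURINES):
            transitions += 1
    p = transitions / n
    q = (int(diff.sum()) - transitions) / n
    w1, w2 = 1.0 - 2.0 * p - q, 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"K2P distance undefined for pair ({names[0]}, {names[1]}): "
            f"p={p:.3f}, q={q:.3f} (saturated)"
        )
    d = max(-0.5 * math.log(w1) - 0.25 * math.log(w2), 0.0)
    return PairwiseDistance(p, q, d)


def _encode(mat: np.ndarray) -> np.ndarray:
    """A,G -> 0,1 (purines); C,T -> 2,3 (pyrimidines); other -> -1."""
    codes = np.full(mat.shape, -1, dtype=np.int8)
    for code, nt in enumerate("AGCT"):
        codes[mat == nt] = code
    return codes


def k2p_matrix(aln: SiteAlignment, columns: np.ndarray | None = None) -> DistanceMatrix:
    """All-pairs K2P distance matrix for an alignment.

    ``columns`` optionally selects 0-based column indices (used for
    bootstrap resampling; repeats allowed).  Pairwise deletion of sites with
    non-ACGT symbols, as in :func:`k2p_distance`.
    """
    codes = _encode(aln.matrix if columns is None else aln.matrix[:, columns])
    n = aln.n
    values = np.zeros((n, n))
    for i in range(n - 1):
        ci = codes[i]
        for j in range(i + 1, n):
            cj = codes[j]
            valid = (ci >= 0) & (cj >= 0)
            m = int(valid.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable sites between {aln.names[i]} and {aln.names[j]}"
                )
            diff = valid & (ci != cj)
            ts = int((diff & ((ci >> 1) == (cj >> 1))).sum())
            p = ts / m
            q = (int(diff.sum()) - ts) / m
            w1, w2 = 1.0 - 2.0 * p - q, 1.0 - 2.0 * q
            if w1 <= 0 or w2 <= 0:
                raise SaturationError(
                    f"K2P distance undefined for pair ({aln.names[i]}, {aln.names[j]})"
                )
            d = max(-0.5 * math.log(w1) - 0.25 * math.log(w2), 0.0)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(tuple(aln.names), values)


def _nj_nodes(dm: DistanceMatrix, tns: dendropy.TaxonNamespace) -> dendropy.Node:
    """Neighbor joining; returns the central (unrooted) node."""
    n = len(dm.taxa)
    nodes: list[dendropy.Node] = []
    for name in dm.taxa:
        nd = dendropy.Node()
        nd.taxon = tns.get_taxon(name) or tns.new_taxon(name)
        nodes.append(nd)
    d = dm.values.astype(float).copy()
    active = list(range(n))

    def _clamped(child_lengths: list[float]) -> list[float]:
        # negative branch: set to 0, move the deficit to the sister branch
        out = list(child_lengths)
        for i, v in enumerate(out):
            if v < 0:
                out[1 - i] += v
                out[i] = 0.0
        return [max(v, 0.0) for v in out]

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # deterministic tie-break: first minimal (i, j) in row-major order
        flat = int(np.argmin(q))
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        vi = 0.5 * sub[ai, aj] + (r[ai] - r[aj]) / (2.0 * (m - 2))
        vj = sub[ai, aj] - vi
        vi, vj = _clamped([vi, vj])
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = vi
        nodes[j].edge.length = vj
        # distances from the new node to the remaining ones
        new_row = np.zeros(d.shape[0] + 1)
        for ak in active:
            if ak in (i, j):
                continue
            new_row[ak] = 0.5 * (d[i, ak] + d[j, ak] - d[i, j])
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, : new_row.size - 1] = new_row[:-1]
        d[: new_row.size - 1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [d.shape[0] - 1]

    center = dendropy.Node()
    if len(active) == 3:
        i, j, k = active
        vi = 0.5 * (d[i, j] + d[i, k] - d[j, k])
        vj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
        vk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        for idx, v in zip((i, j, k), (vi, vj, vk)):
            center.add_child(nodes[idx])
            nodes[idx].edge.length = max(v, 0.0)
    elif len(active) == 2:
        i, j = active
        center.add_child(nodes[i])
        center.add_child(nodes[j])
        nodes[i].edge.length = d[i, j] / 2.0
        nodes[j].edge.length = d[i, j] / 2.0
    else:
        center = nodes[active[0]]
    return center


def build_nj(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree (unrooted) from a distance matrix."""
    if len(dm.taxa) < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    tns = dendropy.TaxonNamespace()
    center = _nj_nodes(dm, tns)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=center)
    tree.is_rooted = False
    return tree


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions as leaf-name sets on the side away from a
    fixed reference taxon (the lexicographically first leaf)."""
    leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = leaves[0]
    all_leaves = frozenset(leaves)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = all_leaves - side
        if 1 < len(side) < len(all_leaves) - 1:
            out.add(side)
    return out


def bootstrap_support(
    aln: SiteAlignment,
    n_reps: int = 1000,
    seed: int | None = None,
    collapse_threshold: float = 50.0,
) -> dendropy.Tree:
    """NJ tree with bootstrap supports; branches <= threshold collapsed.

    Columns are resampled with replacement per replicate; replicates whose
    K2P matrix saturates are dropped (counted in a warning).  Supports are
    percentages of retained replicates and are stored as internal node
    labels.  ``n_reps=0`` returns the plain NJ tree.
    """
    tree = build_nj(k2p_matrix(aln))
    if n_reps == 0:
        return tree
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {}
    dropped = 0
    for _ in range(n_reps):
        cols = rng.integers(0, aln.length, size=aln.length)
        try:
            rep_tree = build_nj(k2p_matrix(aln, columns=cols))
        except (SaturationError, ValueError):
            dropped += 1
            continue
        for bp in bipartitions(rep_tree):
            counts[bp] = counts.get(bp, 0) + 1
    kept = n_reps - dropped
    if dropped:
        logger.warning("%d of %d bootstrap replicates dropped (saturated distances)", dropped, n_reps)
    if kept == 0:
        raise SaturationError("all bootstrap replicates saturated")
    leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = leaves[0]
    all_leaves = frozenset(leaves)
    to_collapse = []
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = all_leaves - side
        if not (1 < len(side) < len(all_leaves) - 1):
            continue
        support = 100.0 * counts.get(side, 0) / kept
        node.label = f"{support:.0f}"
        if support <= collapse_threshold:
            to_collapse.append(node.edge)
    for edge in to_collapse:
        edge.head_node.label = None
        edge.collapse()
    return tree


def write_newick(tree: dendropy.Tree, with_supports: bool = True) -> str:
    """Newick string; internal node labels carry bootstrap supports."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        suppress_internal_node_labels=not with_supports,
    ).strip() + "\n"


def read_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")
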