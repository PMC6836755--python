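"""Polymorphism statistics on site partitions of a gap-free alignment.

The unit of analysis is an equal-length nucleotide alignment of MHC class I
exon 2+3 alleles (546 nt by convention, codons 1-182).  Statistics are the
DnaSP-style quintet per site class:

* ``Ns`` -- number of sites analysed,
* ``S``  -- segregating (polymorphic) sites: columns with >= 2 nucleotides,
* ``N``  -- number of mutations (eta): sum over columns of (distinct - 1),
* ``K``  -- mean number of pairwise nucleotide differences,
* ``Pi`` -- nucleotide diversity per site, ``Pi = K / Ns``.

Partitions are defined at codon (residue) resolution so that functional
residue classes (peptide-binding and TCR-binding sites) map to nucleotide
triplets; complementary partitions are additive in S, N and K.

Per-site variability uses the second-most-common-residue index: the
frequency ``f2`` of the second most frequent symbol in a column, with
``f2 > 0.05`` classifying a site as highly polymorphic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

NUCLEOTIDES = ("A", "C", "G", "T")

DEFAULT_LENGTH = 546
#: last 1-based site of exon 2 (exon 2 = sites 1..270, exon 3 = 271..546)
DEFAULT_EXON_BOUNDARY = 270
#: amino-acid analyses cover residues 2..182 of the mature protein
DEFAULT_RESIDUE_RANGE = (2, 182)


@dataclass(frozen=True)
class SiteAlignment:
    """Equal-length, nominally gap-free nucleotide alignment.

    Sites are 1-based; codon ``i`` spans sites ``3i-2 .. 3i``; the exon
    boundary marks the last site of exon 2.
    """

    names: tuple[str, ...]
    matrix: np.ndarray  # (n, L) array of single characters
    exon_boundary: int = DEFAULT_EXON_BOUNDARY

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2:
            raise ValueError("alignment matrix must be 2-D")
        if len(self.names) != self.matrix.shape[0]:
            raise ValueError("number of names does not match number of rows")
        if len(set(self.names)) != len(self.names):
            raise ValueError("sequence names must be unique")

    @classmethod
    def from_sequences(
        cls,
        names: Sequence[str],
        seqs: Sequence[str],
        exon_boundary: int = DEFAULT_EXON_BOUNDARY,
    ) -> "SiteAlignment":
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            raise ValueError(f"sequences have mixed lengths: {sorted(lengths)}")
        mat = np.array([list(s.upper()) for s in seqs], dtype="U1")
        return cls(tuple(names), mat, exon_boundary)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def sequence(self, name: str) -> str:
        return "".join(self.matrix[self.names.index(name)])

    def codon_of_site(self, site: int) -> int:
        """1-based codon index containing 1-based site."""
        return (site + 2) // 3

    def subset(self, names: Iterable[str]) -> "SiteAlignment":
        names = list(names)
        idx = [self.names.index(nm) for nm in names]
        return SiteAlignment(tuple(names), self.matrix[idx], self.exon_boundary)


@dataclass(frozen=True)
class SitePartition:
    """A class of codon positions and the nucleotide sites they span."""

    label: str
    residues: frozenset[int] = field(default_factory=frozenset)

    @classmethod
    def from_residues(cls, label: str, residues: Iterable[int]) -> "SitePartition":
        return cls(label, frozenset(int(r) for r in residues))

    @classmethod
    def full(cls, length: int = DEFAULT_LENGTH, label: str = "All") -> "SitePartition":
        if length % 3:
            raise ValueError("alignment length must be divisible by 3")
        return cls(label, frozenset(range(1, length // 3 + 1)))

    def complement(self, length: int = DEFAULT_LENGTH, label: str | None = None) -> "SitePartition":
        all_codons = set(range(1, length // 3 + 1))
        return SitePartition(label or f"Non-{self.label}", frozenset(all_codons - self.residues))

    @property
    def nt_sites(self) -> np.ndarray:
        """Sorted 1-based nucleotide site indices (3 per codon)."""
        sites = sorted(s for r in self.residues for s in (3 * r - 2, 3 * r - 1, 3 * r))
        return np.asarray(sites, dtype=int)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class DiversitySummary:
    """One row of the per-partition polymorphism table."""

    label: str
    ns: int
    s: int
    n_mutations: int
    pi: float
    k: float
    excluded_sites: int = 0

    def __post_init__(self) -> None:
        if self.s > self.n_mutations:
            raise ValueError("S cannot exceed the number of mutations")
        if min(self.ns, self.s, self.n_mutations) < 0 or min(self.pi, self.k) < 0:
            raise ValueError("polymorphism statistics must be non-negative")
        if self.ns and abs(self.pi - self.k / self.ns) > 1e-12:
            raise ValueError("Pi must equal K / Ns")


def _column_view(aln: SiteAlignment, partition: SitePartition | None) -> tuple[np.ndarray, int]:
    """Columns of the partition with non-ACGT columns removed (complete deletion).

    Returns (sub-matrix of valid columns, number of excluded columns).
    """
    if partition is None:
        partition = SitePartition.full(aln.length)
    sites = partition.nt_sites
    if sites.size and sites.max() > aln.length:
        raise ValueError("partition refers to sites beyond the alignment length")
    cols = aln.matrix[:, sites - 1] if sites.size else aln.matrix[:, :0]
    valid = np.isin(cols, NUCLEOTIDES).all(axis=0)
    n_excluded = int((~valid).sum())
    if n_excluded:
        logger.warning("%d column(s) with non-ACGT symbols excluded from statistics", n_excluded)
    return cols[:, valid], n_excluded


def segregating_sites(
    aln: SiteAlignment, partition: SitePartition | None = None
) -> tuple[int, int, int]:
    """(Ns, S, N) for the partition: sites analysed, segregating sites, mutations."""
    if partition is not None and len(partition) == 0:
        logger.warning("empty partition: returning (0, 0, 0)")
        return 0, 0, 0
    cols, _ = _column_view(aln, partition)
    ns = cols.shape[1]
    distinct = np.array([len(set(cols[:, j])) for j in range(ns)], dtype=int)
    s = int((distinct >= 2).sum())
    n_mut = int((distinct - 1).sum())
    return ns, s, n_mut


def pairwise_diffs(
    aln: SiteAlignment, partition: SitePartition | None = None
) -> tuple[float, float]:
    """(K, Pi): mean pairwise differences within the partition and per-site diversity."""
    if aln.n < 2:
        raise ValueError("pairwise differences require at least 2 sequences")
    cols, _ = _column_view(aln, partition)
    n, ns = cols.shape
    if ns == 0:
        return 0.0, 0.0
    total = 0
    for i in range(n - 1):
        total += int((cols[i + 1 :] != cols[i]).sum())
    k = 2.0 * total / (n * (n - 1))
    return k, k / ns


def diversity_summary(
    aln: SiteAlignment, partition: SitePartition | None = None
) -> DiversitySummary:
    label = partition.label if partition is not None else "All"
    ns, s, n_mut = segregating_sites(aln, partition)
    if aln.n >= 2 and ns:
        k, pi = pairwise_diffs(aln, partition)
    else:
        k = pi = 0.0
    _, excluded = _column_view(aln, partition) if (partition is None or len(partition)) else (None, 0)
    return DiversitySummary(label, ns, s, n_mut, pi, k, excluded)


def diversity_table(
    aln: SiteAlignment, functional: SitePartition, labels: tuple[str, str, str] = ("All", "PBS or TBS", "Non-PBS or TBS")
) -> pd.DataFrame:
    """Per-partition polymorphism table (all sites / functional / non-functional).

    The complementary rows are checked for additivity in S, N and K; a
    violation indicates inconsistent partitions and aborts.
    """
    full = SitePartition.full(aln.length, labels[0])
    func = SitePartition(labels[1], functional.residues)
    rest = func.complement(aln.length, labels[2])
    rows = [diversity_summary(aln, p) for p in (full, func, rest)]
    a, f, c = rows
    if a.s != f.s + c.s or a.n_mutations != f.n_mutations + c.n_mutations:
        raise AssertionError("partition additivity violated for S or N")
    if abs(a.k - (f.k + c.k)) > 1e-9:
        raise AssertionError("partition additivity violated for K")
    return pd.DataFrame(
        [
            {"partition": r.label, "Ns": r.ns, "S": r.s, "N": r.n_mutations, "Pi": r.pi, "K": r.k}
            for r in rows
        ]
    )


@dataclass(frozen=True)
class VariabilityProfile:
    """Second-most-common-residue index per alignment column.

    ``f2`` is the count of the second most frequent symbol divided by the
    number of sequences; a tie at the top counts the shared maximum.
    Classification: ``highly_polymorphic`` (f2 > threshold),
    ``rare_variation`` (0 < f2 <= threshold), ``invariant`` (f2 = 0).
    """

    positions: np.ndarray  # 1-based indices in the analysed coordinate system
    f2: np.ndarray
    classification: tuple[str, ...]
    threshold: float = 0.05

    @property
    def n_highly_polymorphic(self) -> int:
        return self.classification.count("highly_polymorphic")

    @property
    def n_rare_variation(self) -> int:
        return self.classification.count("rare_variation")

    @property
    def n_variable(self) -> int:
        return self.n_highly_polymorphic + self.n_rare_variation

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position": self.positions, "f2": self.f2, "class": self.classification}
        )


def variability_profile(
    matrix: np.ndarray,
    threshold: float = 0.05,
    positions: Sequence[int] | None = None,
) -> VariabilityProfile:
    """Per-column f2 index for a character matrix (nucleotide or amino acid)."""
    if matrix.size == 0:
        return VariabilityProfile(np.array([], dtype=int), np.array([]), ())
    n, length = matrix.shape
    f2 = np.empty(length)
    for j in range(length):
        _, counts = np.unique(matrix[:, j], return_counts=True)
        counts = np.sort(counts)[::-1]
        if counts.size == 1:
            f2[j] = 0.0
        elif counts[0] == counts[1]:
            # tie at the top: the second-most common is as frequent as the most
            f2[j] = counts[0] / n
        else:
            f2[j] = counts[1] / n
    cls = tuple(
        "invariant" if v == 0 else ("highly_polymorphic" if v > threshold else "rare_variation")
        for v in f2
    )
    pos = np.asarray(positions, dtype=int) if positions is not None else np.arange(1, length + 1)
    return VariabilityProfile(pos, f2, cls, threshold)


def translate_alignment(
    aln: SiteAlignment,
    frame: int = 0,
    residue_start: int = 1,
    residue_range: tuple[int, int] | None = DEFAULT_RESIDUE_RANGE,
) -> tuple[tuple[str, ...], np.ndarray, np.ndarray]:
    """Translate a nucleotide alignment to amino acids.

    Codons are numbered from ``residue_start`` and the result restricted to
    ``residue_range`` (inclusive).  Sequences with an internal stop codon are
    excluded from amino-acid statistics and logged.

    Returns (names kept, amino-acid matrix, 1-based residue indices).
    """
    if aln.length - frame < 3:
        raise ValueError("alignment too short to translate in this frame")
    usable = (aln.length - frame) // 3 * 3
    kept_names: list[str] = []
    rows: list[list[str]] = []
    for name, row in zip(aln.names, aln.matrix):
        nt = "".join(row[frame : frame + usable])
        aa = str(Seq(nt).translate())
        if "*" in aa:
            logger.warning("stop codon in %s: excluded from amino-acid statistics", name)
            continue
        kept_names.append(name)
        rows.append(list(aa))
    if not rows:
        return (), np.empty((0, 0), dtype="U1"), np.array([], dtype=int)
    mat = np.array(rows, dtype="U1")
    residues = np.arange(residue_start, residue_start + mat.shape[1])
    if residue_range is not None:
        lo, hi = residue_range
        keep = (residues >= lo) & (residues <= hi)
        mat = mat[:, keep]
        residues = residues[keep]
    return tuple(kept_names), mat, residues
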