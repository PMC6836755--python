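"""Allele calling from clone libraries.

Identical clone sequences are grouped per locus, and a candidate sequence
is promoted to a named allele only under the evidence rule used for
Sanger-sequenced cDNA clone studies: at least three identical clones,
observed either in at least two animals or in at least two independent PCR
batches of a single animal.  This guards against polymerase errors (which
do not recur identically) and single-reaction chimeras.

Validated alleles carry their supporting-clone provenance, carrier sets and
cohort distribution frequencies (carriers / cohort size).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace

import pandas as pd
from Bio.Seq import Seq

from .cohort import CloneRecord, Locus

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CandidateGroup:
    seq: str
    locus: Locus
    #: (clone_id, animal, pcr_batch) for every supporting clone
    clones: tuple[tuple[str, str, str], ...]

    @property
    def n_clones(self) -> int:
        return len(self.clones)

    @property
    def animals(self) -> set[str]:
        return {animal for _, animal, _ in self.clones}

    @property
    def batches_by_animal(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = defaultdict(set)
        for _, animal, batch in self.clones:
            out[animal].add(batch)
        return dict(out)


@dataclass(frozen=True)
class ValidatedAllele:
    name: str
    seq: str
    locus: Locus
    n_clones: int
    carriers: frozenset[str]
    n_batches_per_animal: tuple[tuple[str, int], ...]
    distribution_frequency: float | None = None

    @property
    def n_animals(self) -> int:
        return len(self.carriers)


@dataclass(frozen=True)
class GroupingResult:
    groups: tuple[CandidateGroup, ...]
    #: clones excluded from grouping (ambiguity codes), with reasons
    excluded: tuple[tuple[str, str], ...] = ()


def group_identical(
    clones: list[CloneRecord] | tuple[CloneRecord, ...],
    trim: tuple[int, int] | None = None,
    exclude_ambiguous: bool = True,
) -> GroupingResult:
    """Group clones by exact sequence identity, per locus.

    ``trim`` is an optional 1-based inclusive coordinate pair applied to
    every clone before grouping (removing primer-derived flanks).  Clones
    whose sequence carries non-ACGT symbols are ineligible for grouping and
    are returned in ``excluded``; identity-based validation demands
    unambiguous reads.  Mixed trimmed lengths raise.
    """
    buckets: dict[tuple[Locus, str], list[tuple[str, str, str]]] = defaultdict(list)
    excluded: list[tuple[str, str]] = []
    lengths: set[int] = set()
    for clone in clones:
        if clone.animal is None or not clone.pcr_batch:
            raise ValueError(f"clone {clone.clone_id} lacks provenance (animal/batch)")
        seq = clone.seq.upper()
        if trim is not None:
            lo, hi = trim
            seq = seq[lo - 1 : hi]
        lengths.add(len(seq))
        if exclude_ambiguous and set(seq) - set("ACGT"):
            logger.warning("clone %s contains ambiguity codes: excluded from grouping", clone.clone_id)
            excluded.append((clone.clone_id, "ambiguity codes"))
            continue
        buckets[(clone.locus, seq)].append((clone.clone_id, clone.animal, clone.pcr_batch))
    if len(lengths) > 1:
        raise ValueError(
            f"clones have mixed lengths {sorted(lengths)}; configure trimming coordinates"
        )
    groups = tuple(
        CandidateGroup(seq, locus, tuple(members))
        for (locus, seq), members in sorted(
            buckets.items(), key=lambda kv: (kv[0][0].value, -len(kv[1]), kv[0][1])
        )
    )
    return GroupingResult(groups, tuple(excluded))


def validate_candidates(
    groups: tuple[CandidateGroup, ...] | list[CandidateGroup],
    min_clones: int = 3,
    min_animals: int = 2,
    min_batches: int = 2,
    name_prefix: str = "allele",
) -> tuple[tuple[ValidatedAllele, ...], tuple[tuple[CandidateGroup, str], ...]]:
    """Apply the evidence rule; returns (validated, rejected-with-reason).

    A group is validated iff it has >= ``min_clones`` identical clones AND
    (>= ``min_animals`` distinct animals OR >= ``min_batches`` distinct PCR
    batches within one animal).  Names are assigned per locus in order of
    decreasing clone support.
    """
    validated: list[ValidatedAllele] = []
    rejected: list[tuple[CandidateGroup, str]] = []
    per_locus_counter: dict[Locus, int] = defaultdict(int)
    ordered = sorted(groups, key=lambda g: (g.locus.value, -g.n_clones, g.seq))
    for group in ordered:
        if group.n_clones < min_clones:
            rejected.append((group, f"only {group.n_clones} identical clone(s) (< {min_clones})"))
            continue
        batches = group.batches_by_animal
        multi_batch = any(len(bs) >= min_batches for bs in batches.values())
        if len(group.animals) < min_animals and not multi_batch:
            rejected.append(
                (group, "insufficient provenance: one animal, one PCR batch")
            )
            continue
        per_locus_counter[group.locus] += 1
        name = f"{name_prefix}-{group.locus.value}*{per_locus_counter[group.locus]:03d}"
        validated.append(
            ValidatedAllele(
                name=name,
                seq=group.seq,
                locus=group.locus,
                n_clones=group.n_clones,
                carriers=frozenset(group.animals),
                n_batches_per_animal=tuple(sorted((a, len(b)) for a, b in batches.items())),
            )
        )
    return tuple(validated), tuple(rejected)


@dataclass(frozen=True)
class CohortSummary:
    cohort_size: int
    #: DataFrame: animal, locus, n_alleles
    per_animal: pd.DataFrame = field(repr=False)
    #: DataFrame: allele, locus, n_clones, n_animals, distribution_frequency, pct
    frequency_table: pd.DataFrame = field(repr=False)
    mean_genes_per_animal: float = 0.0


def summarize_cohort(
    validated: tuple[ValidatedAllele, ...],
    animals: tuple[str, ...] | list[str],
) -> tuple[tuple[ValidatedAllele, ...], CohortSummary]:
    """Cohort distribution frequencies and per-animal allele counts.

    The frequency denominator is the full cohort size, and the mean number
    of expressed genes per animal is total (animal, allele) incidences over
    the cohort size.  Returns the alleles with frequencies filled in, plus
    the summary.
    """
    if not animals:
        raise ValueError("cohort size must be positive")
    cohort = len(animals)
    with_freq = tuple(
        replace(v, distribution_frequency=v.n_animals / cohort) for v in validated
    )
    rows = []
    for v in with_freq:
        rows.append(
            {
                "allele": v.name,
                "locus": v.locus.value,
                "n_clones": v.n_clones,
                "n_animals": v.n_animals,
                "distribution_frequency": v.distribution_frequency,
                "pct": round(100.0 * v.distribution_frequency, 1),
            }
        )
    freq = pd.DataFrame(rows, columns=["allele", "locus", "n_clones", "n_animals", "distribution_frequency", "pct"])
    counts = []
    total_incidences = 0
    for animal in animals:
        for locus in Locus:
            k = sum(1 for v in with_freq if v.locus is locus and animal in v.carriers)
            counts.append({"animal": animal, "locus": locus.value, "n_alleles": k})
            total_incidences += k
    per_animal = pd.DataFrame(counts, columns=["animal", "locus", "n_alleles"])
    summary = CohortSummary(
        cohort_size=cohort,
        per_animal=per_animal,
        frequency_table=freq,
        mean_genes_per_animal=total_incidences / cohort,
    )
    return with_freq, summary


@dataclass(frozen=True)
class ProteinGroup:
    aa_seq: str
    alleles: tuple[str, ...]
    carriers: frozenset[str]


def collapse_by_protein(
    validated: tuple[ValidatedAllele, ...],
    frame: int = 0,
) -> tuple[tuple[ProteinGroup, ...], tuple[str, ...]]:
    """Merge alleles whose deduced amino-acid sequences are identical.

    Alleles differing only by synonymous substitutions collapse to one
    group whose carrier set is the union.  Alleles with an in-frame stop
    codon are flagged, excluded and logged; returns (groups, flagged).
    """
    buckets: dict[tuple[Locus, str], list[ValidatedAllele]] = defaultdict(list)
    flagged: list[str] = []
    for v in validated:
        nt = v.seq[frame:]
        nt = nt[: len(nt) // 3 * 3]
        aa = str(Seq(nt).translate())
        if "*" in aa:
            logger.warning("allele %s has an in-frame stop codon: excluded from protein grouping", v.name)
            flagged.append(v.name)
            continue
        buckets[(v.locus, aa)].append(v)
    groups = tuple(
        ProteinGroup(
            aa_seq=aa,
            alleles=tuple(sorted(v.name for v in members)),
            carriers=frozenset().union(*(v.carriers for v in members)),
        )
        for (locus, aa), members in sorted(buckets.items(), key=lambda kv: (kv[0][0].value, kv[0][1]))
    )
    return groups, tuple(flagged)
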