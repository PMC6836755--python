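"""Synthetic cohort generator with known ground truth.

Emulates an MHC class I cDNA cloning study: a pool of distinct exon 2+3
alleles per locus (polymorphism concentrated at functional codons), a
cohort of animals each carrying a small, variable number of alleles per
locus (1-5 at locus A, 2-7 at locus B by default, some alleles shared
widely across animals), and per-animal clone libraries with per-base
substitution errors and PCR crossover chimeras.  Every emitted clone's
origin (source allele, error overlay, chimera parents and breakpoint) is
recorded in a truth table, so downstream allele calling and recombination
detection can be validated against it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_LENGTH = 546
NUCLEOTIDES = np.array(list("ACGT"), dtype="U1")


class Locus(str, Enum):
    A = "A"
    B = "B"


@dataclass(frozen=True)
class FunctionalSites:
    """PBS/TBS residue positions (1-based codon indices)."""

    pbs: frozenset[int]
    tbs: frozenset[int]

    @property
    def union(self) -> frozenset[int]:
        return self.pbs | self.tbs

    @property
    def shared(self) -> frozenset[int]:
        return self.pbs & self.tbs


def load_functional_sites(path: str | Path | None = None) -> FunctionalSites:
    """Load a PBS/TBS residue configuration (JSON with "pbs"/"tbs" lists).

    Without a path, loads the packaged synthetic default: 36 PBS + 26 TBS
    placeholder positions (8 shared, 54 distinct) within residues 2-182.
    """
    if path is None:
        text = (
            resources.files("mhclones.data")
            .joinpath("functional_sites_synthetic.json")
            .read_text()
        )
    else:
        text = Path(path).read_text()
    cfg = json.loads(text)
    return FunctionalSites(frozenset(cfg["pbs"]), frozenset(cfg["tbs"]))


@dataclass(frozen=True)
class AlleleSequence:
    name: str
    locus: Locus
    seq: str

    def __post_init__(self) -> None:
        if set(self.seq) - set("ACGT"):
            raise ValueError(f"allele {self.name} contains non-ACGT symbols")


@dataclass(frozen=True)
class CohortGenotype:
    animals: tuple[str, ...]
    #: animal -> locus -> tuple of allele names
    assignment: Mapping[str, Mapping[Locus, tuple[str, ...]]]

    def carriers(self, allele: str) -> set[str]:
        return {
            a
            for a, by_locus in self.assignment.items()
            for names in by_locus.values()
            if allele in names
        }


@dataclass(frozen=True)
class CloneRecord:
    clone_id: str
    animal: str
    locus: Locus
    pcr_batch: str
    seq: str

    def __post_init__(self) -> None:
        if not self.pcr_batch:
            raise ValueError(f"clone {self.clone_id} has an empty PCR batch")


@dataclass(frozen=True)
class CloneOrigin:
    origin_type: str  # "exact" | "error" | "chimera" | "chimera+error"
    source_allele: str
    parent2: str | None = None
    breakpoint: int | None = None  # last 1-based site taken from source_allele
    n_errors: int = 0


@dataclass(frozen=True)
class SyntheticTruth:
    true_alleles: tuple[AlleleSequence, ...]
    genotypes: CohortGenotype
    clone_origin: Mapping[str, CloneOrigin]
    rng_seed: int | None = None

    def allele(self, name: str) -> AlleleSequence:
        return next(a for a in self.true_alleles if a.name == name)

    def expected_sequence(self, clone_id: str) -> str:
        """Clone sequence before the error overlay (chimeras reconstructed)."""
        origin = self.clone_origin[clone_id]
        src = self.allele(origin.source_allele).seq
        if origin.parent2 is None:
            return src
        p2 = self.allele(origin.parent2).seq
        return src[: origin.breakpoint] + p2[origin.breakpoint :]


_STOP_CODONS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = np.array(
    [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
     if a + b + c not in _STOP_CODONS]
)


def _random_coding(rng: np.random.Generator, length: int) -> np.ndarray:
    """Random in-frame stop-free nucleotide sequence (array of 1-chars)."""
    codons = rng.choice(_SENSE_CODONS, size=length // 3)
    return np.array(list("".join(codons)), dtype="U1")


def _revert_stop_codons(seq: np.ndarray, ancestor: np.ndarray) -> None:
    """Revert codons that substitutions turned into stops (alleles are expressed)."""
    for i in range(0, seq.size - 2, 3):
        if "".join(seq[i : i + 3]) in _STOP_CODONS:
            seq[i : i + 3] = ancestor[i : i + 3]


def _functional_nt_mask(length: int, residues: Iterable[int]) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for r in residues:
        if 3 * r <= length:
            mask[3 * r - 3 : 3 * r] = True
    return mask


def generate_allele_pool(
    n_alleles: int,
    length: int = DEFAULT_LENGTH,
    functional_residues: Iterable[int] | None = None,
    hotspot_rate: float = 0.085,
    background_rate: float = 0.018,
    seed: int | None = None,
    locus: Locus = Locus.A,
    name_prefix: str | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[AlleleSequence, ...]:
    """Pool of distinct alleles diverged from a common ancestral sequence.

    Each allele substitutes the ancestor independently per site, at
    ``hotspot_rate`` inside functional codons and ``background_rate``
    elsewhere, so polymorphism concentrates at functional positions.
    """
    if n_alleles < 2:
        raise ValueError("an allele pool needs at least 2 alleles")
    if length % 3:
        raise ValueError("alignment length must be divisible by 3")
    if hotspot_rate < background_rate:
        raise ValueError("hotspot_rate must be >= background_rate")
    if hotspot_rate == 0 and background_rate == 0:
        raise ValueError("cannot create distinct alleles with zero substitution rates")
    if functional_residues is None:
        functional_residues = load_functional_sites().union
    rng = rng if rng is not None else np.random.default_rng(seed)
    locus = Locus(locus)
    prefix = name_prefix or f"{locus.value}"
    ancestor = _random_coding(rng, length)
    rates = np.where(_functional_nt_mask(length, functional_residues), hotspot_rate, background_rate)
    pool: list[AlleleSequence] = []
    seen: set[str] = set()
    attempts = 0
    while len(pool) < n_alleles:
        attempts += 1
        if attempts > 50 * n_alleles:
            raise RuntimeError("could not generate enough distinct alleles; raise the rates")
        seq = ancestor.copy()
        hit = rng.random(length) < rates
        # substitute with one of the 3 alternative nucleotides, uniformly
        shift = rng.integers(1, 4, size=int(hit.sum()))
        idx = np.searchsorted(NUCLEOTIDES, seq[hit])
        seq[hit] = NUCLEOTIDES[(idx + shift) % 4]
        _revert_stop_codons(seq, ancestor)
        s = "".join(seq)
        if s in seen:
            continue
        seen.add(s)
        pool.append(AlleleSequence(f"{prefix}*{len(pool) + 1:03d}", locus, s))
    return tuple(pool)


def assign_genotypes(
    pool: Sequence[AlleleSequence],
    n_animals: int = 30,
    a_range: tuple[int, int] = (1, 5),
    b_range: tuple[int, int] = (2, 7),
    sharing_skew: float = 2.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> CohortGenotype:
    """Assign each animal a per-locus allele set drawn from skewed weights.

    Allele carriage weights come from a Dirichlet whose concentration
    shrinks as ``sharing_skew`` grows; with positive skew a minority of
    alleles are carried by many animals (cohort frequency above 10%).
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    ranges = {Locus.A: a_range, Locus.B: b_range}
    by_locus = {loc: [a for a in pool if a.locus is loc] for loc in Locus}
    weights: dict[Locus, np.ndarray] = {}
    for loc, (lo, hi) in ranges.items():
        alleles = by_locus[loc]
        if not alleles:
            raise ValueError(f"allele pool has no locus-{loc.value} alleles")
        if len(alleles) < hi:
            raise ValueError(
                f"locus {loc.value}: pool of {len(alleles)} cannot satisfy up to {hi} alleles per animal"
            )
        conc = 1.0 / (1.0 + sharing_skew)
        weights[loc] = rng.dirichlet(np.full(len(alleles), conc))
    animals = tuple(f"M{i + 1:02d}" for i in range(n_animals))
    assignment: dict[str, dict[Locus, tuple[str, ...]]] = {}
    for animal in animals:
        per_locus: dict[Locus, tuple[str, ...]] = {}
        for loc, (lo, hi) in ranges.items():
            k = int(rng.integers(lo, hi + 1))
            names = [a.name for a in by_locus[loc]]
            chosen = rng.choice(names, size=k, replace=False, p=weights[loc])
            per_locus[loc] = tuple(sorted(chosen))
        assignment[animal] = per_locus
    return CohortGenotype(animals, assignment)


def generate_clone_library(
    genotypes: CohortGenotype,
    pool: Sequence[AlleleSequence],
    clones_per_locus: int = 30,
    error_rate: float = 1e-4,
    chimera_rate: float = 0.02,
    n_batches: int = 2,
    breakpoint_margin: int = 30,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[tuple[CloneRecord, ...], SyntheticTruth]:
    """Per-animal clone libraries with substitution errors and PCR chimeras.

    Each clone derives from one of its animal's alleles at that locus
    (uniformly), lands in one of ``n_batches`` PCR batches (uniformly), and
    with probability ``chimera_rate`` is a crossover between two distinct
    co-amplified alleles with a breakpoint uniform over the interior
    ``[margin, L - margin]``.  Substitution errors are applied last at
    ``error_rate`` per base.  Errors are substitutions only: the study's
    exon alignments are gap-free.
    """
    for rate, label in ((error_rate, "error_rate"), (chimera_rate, "chimera_rate")):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{label} must lie in [0, 1]")
    if clones_per_locus == 0:
        logger.warning("clones_per_locus=0: emitting an empty clone library")
        return (), SyntheticTruth(tuple(pool), genotypes, {}, seed)
    rng = rng if rng is not None else np.random.default_rng(seed)
    seq_of = {a.name: a.seq for a in pool}
    records: list[CloneRecord] = []
    origins: dict[str, CloneOrigin] = {}
    for animal in genotypes.animals:
        for locus in Locus:
            carried = genotypes.assignment[animal].get(locus, ())
            if not carried:
                continue
            length = len(seq_of[carried[0]])
            for i in range(clones_per_locus):
                clone_id = f"{animal}_{locus.value}_{i + 1:03d}"
                batch = f"PCR{int(rng.integers(1, n_batches + 1))}"
                source = str(rng.choice(list(carried)))
                parent2 = None
                breakpoint = None
                seq = np.array(list(seq_of[source]), dtype="U1")
                if len(carried) >= 2 and rng.random() < chimera_rate:
                    parent2 = str(rng.choice([c for c in carried if c != source]))
                    breakpoint = int(rng.integers(breakpoint_margin, length - breakpoint_margin + 1))
                    p2 = np.array(list(seq_of[parent2]), dtype="U1")
                    chimeric = seq.copy()
                    chimeric[breakpoint:] = p2[breakpoint:]
                    if "".join(chimeric) in (seq_of[source], seq_of[parent2]):
                        # parents identical over one flank: the product is not
                        # a detectable chimera, record it as a plain clone
                        parent2 = None
                        breakpoint = None
                    else:
                        seq = chimeric
                err = rng.random(length) < error_rate
                n_err = int(err.sum())
                if n_err:
                    shift = rng.integers(1, 4, size=n_err)
                    idx = np.searchsorted(NUCLEOTIDES, seq[err])
                    seq[err] = NUCLEOTIDES[(idx + shift) % 4]
                if parent2 is not None:
                    origin_type = "chimera+error" if n_err else "chimera"
                elif n_err:
                    origin_type = "error"
                else:
                    origin_type = "exact"
                records.append(CloneRecord(clone_id, animal, locus, batch, "".join(seq)))
                origins[clone_id] = CloneOrigin(origin_type, source, parent2, breakpoint, n_err)
    truth = SyntheticTruth(tuple(pool), genotypes, origins, seed)
    return tuple(records), truth


@dataclass(frozen=True)
class CohortSimulation:
    """Everything one simulated study produces."""

    pool: tuple[AlleleSequence, ...]
    genotypes: CohortGenotype
    clones: tuple[CloneRecord, ...]
    truth: SyntheticTruth


def simulate_cohort(
    n_alleles_a: int = 40,
    n_alleles_b: int = 60,
    length: int = DEFAULT_LENGTH,
    n_animals: int = 30,
    a_range: tuple[int, int] = (1, 5),
    b_range: tuple[int, int] = (2, 7),
    sharing_skew: float = 2.0,
    clones_per_locus: int = 30,
    error_rate: float = 1e-4,
    chimera_rate: float = 0.02,
    n_batches: int = 2,
    hotspot_rate: float = 0.085,
    background_rate: float = 0.018,
    functional_residues: Iterable[int] | None = None,
    seed: int | None = None,
) -> CohortSimulation:
    """One-call cohort simulation with deterministic per-stage sub-streams."""
    ss = np.random.SeedSequence(seed)
    s_pool_a, s_pool_b, s_geno, s_lib = ss.spawn(4)
    if functional_residues is None:
        functional_residues = load_functional_sites().union
    pool_a = generate_allele_pool(
        n_alleles_a, length, functional_residues, hotspot_rate, background_rate,
        locus=Locus.A, rng=np.random.default_rng(s_pool_a),
    )
    pool_b = generate_allele_pool(
        n_alleles_b, length, functional_residues, hotspot_rate, background_rate,
        locus=Locus.B, rng=np.random.default_rng(s_pool_b),
    )
    pool = pool_a + pool_b
    genotypes = assign_genotypes(
        pool, n_animals, a_range, b_range, sharing_skew, rng=np.random.default_rng(s_geno)
    )
    clones, truth = generate_clone_library(
        genotypes, pool, clones_per_locus, error_rate, chimera_rate, n_batches,
        rng=np.random.default_rng(s_lib), seed=seed,
    )
    return CohortSimulation(pool, genotypes, clones, truth)
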