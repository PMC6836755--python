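"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from mhclones import cohort
from mhclones.diversity import SiteAlignment

ALPHABET = "ACGT"


def mutate(seq: str, positions, rng: np.random.Generator) -> str:
    """Substitute the given 0-based positions with a random other nucleotide."""
    out = list(seq)
    for pos in positions:
        out[pos] = ALPHABET[(ALPHABET.index(out[pos]) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(ALPHABET), size=length))


def diverged_pair(rng: np.random.Generator, length: int, n_diffs: int) -> tuple[str, str]:
    """Two sequences differing at exactly n_diffs random positions."""
    a = random_seq(rng, length)
    pos = rng.choice(length, size=n_diffs, replace=False)
    return a, mutate(a, pos, rng)


# ---------------------------------------------------------------- oracles


def naive_diversity(rows: list[str], site_idx: list[int] | None = None):
    """Brute-force (Ns, S, N, K, Pi) by enumerating columns and pairs."""
    length = len(rows[0])
    sites = site_idx if site_idx is not None else list(range(length))
    s = n_mut = 0
    for j in sites:
        symbols = {r[j] for r in rows}
        if len(symbols) >= 2:
            s += 1
        n_mut += len(symbols) - 1
    total = 0
    n_pairs = 0
    for a, b in itertools.combinations(rows, 2):
        total += sum(1 for j in sites if a[j] != b[j])
        n_pairs += 1
    k = total / n_pairs if n_pairs else 0.0
    ns = len(sites)
    return ns, s, n_mut, k, (k / ns if ns else 0.0)


def naive_group_sizes(seqs: list[str]) -> list[int]:
    """Multiset of identical-sequence group sizes by O(n^2) comparison."""
    remaining = list(range(len(seqs)))
    sizes = []
    while remaining:
        first = remaining.pop(0)
        members = [first]
        still = []
        for j in remaining:
            if seqs[j] == seqs[first]:
                members.append(j)
            else:
                still.append(j)
        remaining = still
        sizes.append(len(members))
    return sorted(sizes)


# ---------------------------------------------------------------- fixtures


@pytest.fixture
def toy_aln() -> SiteAlignment:
    return SiteAlignment.from_sequences(
        ["s1", "s2", "s3"], ["AAATTT", "AAGTTT", "AAGTTC"], exon_boundary=3
    )


@pytest.fixture(scope="session")
def small_sim() -> cohort.CohortSimulation:
    """A small but fully featured simulated cohort."""
    return cohort.simulate_cohort(
        n_alleles_a=12, n_alleles_b=16, n_animals=10, clones_per_locus=12, seed=7
    )
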