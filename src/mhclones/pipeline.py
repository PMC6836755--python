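"""End-to-end pipeline: simulate (or ingest) -> call alleles -> diversity ->
phylogeny -> recombination -> report.

Every stage writes standard-format artifacts (FASTA, TSV, Newick, JSON) to
the output directory, and the machine-readable run summary echoes the full
configuration and seed so every number is regenerable.  Report-time
consistency checks (partition additivity of the diversity table) abort on
violation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import calling, cohort, diversity, io, phylo, recomb

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of a run; defaults mirror the emulated study design."""

    # simulation (used unless clones_fasta is given)
    clones_fasta: str | None = None
    n_alleles_a: int = 40
    n_alleles_b: int = 60
    length: int = 546
    n_animals: int = 30
    a_range: tuple[int, int] = (1, 5)
    b_range: tuple[int, int] = (2, 7)
    sharing_skew: float = 2.0
    clones_per_locus: int = 30
    error_rate: float = 1e-4
    chimera_rate: float = 0.02
    n_batches: int = 2
    hotspot_rate: float = 0.085
    background_rate: float = 0.018
    # allele calling
    trim: tuple[int, int] | None = None
    min_clones: int = 3
    min_animals: int = 2
    min_batches: int = 2
    # diversity
    functional_sites_file: str | None = None
    exon_boundary: int = 270
    variability_threshold: float = 0.05
    residue_range: tuple[int, int] = (2, 182)
    # phylogeny
    bootstrap_reps: int = 1000
    collapse_threshold: float = 50.0
    # recombination
    scan_window: int = 200
    scan_step: int = 10
    scan_confidence: float = 0.99
    #: informative sites per MaxChi flank; None = classic whole-segment form
    maxchi_flank: int | None = None
    maxchi_perms: int = 2000
    alpha: float = 0.05
    # global
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_clones", "min_animals", "min_batches", "bootstrap_reps",
                     "scan_window", "scan_step", "maxchi_perms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("a_range", "b_range", "trim", "residue_range"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


@dataclass
class RunReport:
    out_dir: Path
    validated: tuple[calling.ValidatedAllele, ...]
    summary: calling.CohortSummary
    diversity_tables: dict[str, pd.DataFrame]
    variability: dict[str, dict[str, int]]
    trees: dict[str, str] = field(default_factory=dict)  # locus -> newick
    recomb_calls: pd.DataFrame | None = None
    run_summary: dict[str, Any] = field(default_factory=dict)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # annotate with the stage name
                raise StageError(name, exc) from exc
            logger.info("stage %-12s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


@_stage("simulate")
def _simulate(cfg: PipelineConfig, out_dir: Path, functional) -> cohort.CohortSimulation:
    sim = cohort.simulate_cohort(
        n_alleles_a=cfg.n_alleles_a, n_alleles_b=cfg.n_alleles_b, length=cfg.length,
        n_animals=cfg.n_animals, a_range=cfg.a_range, b_range=cfg.b_range,
        sharing_skew=cfg.sharing_skew, clones_per_locus=cfg.clones_per_locus,
        error_rate=cfg.error_rate, chimera_rate=cfg.chimera_rate,
        n_batches=cfg.n_batches, hotspot_rate=cfg.hotspot_rate,
        background_rate=cfg.background_rate, functional_residues=functional.union,
        seed=cfg.seed,
    )
    io.write_clone_fasta(sim.clones, out_dir / "clones.fasta")
    io.write_truth_tsv(sim.truth, out_dir / "truth.tsv")
    io.write_pool_fasta(sim.pool, out_dir / "true_alleles.fasta")
    return sim


@_stage("call-alleles")
def _call(cfg: PipelineConfig, clones, animals, out_dir: Path):
    grouping = calling.group_identical(clones, trim=cfg.trim)
    validated, rejected = calling.validate_candidates(
        grouping.groups, cfg.min_clones, cfg.min_animals, cfg.min_batches
    )
    validated, summary = calling.summarize_cohort(validated, animals)
    io.write_allele_fasta(validated, out_dir / "alleles.fasta")
    summary.frequency_table.to_csv(out_dir / "alleles.tsv", sep="\t", index=False)
    summary.per_animal.to_csv(out_dir / "per_animal_counts.tsv", sep="\t", index=False)
    return grouping, validated, rejected, summary


@_stage("diversity")
def _diversity(cfg: PipelineConfig, validated, functional, out_dir: Path):
    partition = diversity.SitePartition.from_residues("PBS or TBS", functional.union)
    tables: dict[str, pd.DataFrame] = {}
    variability: dict[str, dict[str, int]] = {}
    for locus in cohort.Locus:
        seqs = [v for v in validated if v.locus is locus]
        if len(seqs) < 2:
            continue
        aln = diversity.SiteAlignment.from_sequences(
            [v.name for v in seqs], [v.seq for v in seqs], cfg.exon_boundary
        )
        table = diversity.diversity_table(aln, partition)
        table.to_csv(out_dir / f"diversity_{locus.value}.tsv", sep="\t", index=False,
                     float_format="%.3f")
        tables[locus.value] = table
        prof_nt = diversity.variability_profile(aln.matrix, cfg.variability_threshold)
        prof_nt.to_frame().to_csv(out_dir / f"variability_nt_{locus.value}.tsv", sep="\t", index=False)
        names, aa, residues = diversity.translate_alignment(aln, residue_range=cfg.residue_range)
        counts = {
            "nt_highly_polymorphic": prof_nt.n_highly_polymorphic,
            "nt_rare_variation": prof_nt.n_rare_variation,
        }
        if len(names) >= 2:
            prof_aa = diversity.variability_profile(aa, cfg.variability_threshold, positions=residues)
            prof_aa.to_frame().to_csv(out_dir / f"variability_aa_{locus.value}.tsv", sep="\t", index=False)
            counts["aa_highly_polymorphic"] = prof_aa.n_highly_polymorphic
            counts["aa_rare_variation"] = prof_aa.n_rare_variation
        variability[locus.value] = counts
    return tables, variability


@_stage("phylo")
def _phylo(cfg: PipelineConfig, validated, out_dir: Path, seed: int):
    trees: dict[str, str] = {}
    for locus in cohort.Locus:
        seqs = [v for v in validated if v.locus is locus]
        if len(seqs) < 4:
            continue
        aln = diversity.SiteAlignment.from_sequences(
            [v.name for v in seqs], [v.seq for v in seqs], cfg.exon_boundary
        )
        tree = phylo.bootstrap_support(
            aln, n_reps=cfg.bootstrap_reps, seed=seed + {"A": 0, "B": 1}[locus.value],
            collapse_threshold=cfg.collapse_threshold,
        )
        newick = phylo.write_newick(tree)
        (out_dir / f"tree_{locus.value}.nwk").write_text(newick)
        trees[locus.value] = newick
    return trees


def _hamming(a: str, b: str, lo: int, hi: int) -> int:
    return sum(1 for x, y in zip(a[lo:hi], b[lo:hi]) if x != y)


@_stage("recomb")
def _recomb(cfg: PipelineConfig, validated, out_dir: Path, seed: int):
    """Scan each validated allele as a potential crossover product.

    Candidate parents are the query's nearest neighbours on each side of
    the exon boundary; a triplet is tested only when they differ.  MaxChi
    p-values are Bonferroni-corrected for the number of triplets scanned.
    """
    rows = []
    tested = []
    for locus in cohort.Locus:
        seqs = {v.name: v.seq for v in validated if v.locus is locus}
        if len(seqs) < 3:
            continue
        for query, qseq in seqs.items():
            others = {n: s for n, s in seqs.items() if n != query}
            left = min(others, key=lambda n: (_hamming(qseq, others[n], 0, cfg.exon_boundary), n))
            right = min(others, key=lambda n: (_hamming(qseq, others[n], cfg.exon_boundary, len(qseq)), n))
            if left == right:
                continue
            tested.append((locus, query, left, right, others))
    n_tests = len(tested)
    for i, (locus, query, left, right, others) in enumerate(tested):
        qseq = {v.name: v.seq for v in validated}[query]
        result = recomb.maxchi_test(
            query, qseq, left, others[left], right, others[right],
            flank=cfg.maxchi_flank, n_perms=cfg.maxchi_perms, seed=seed + i,
        )
        if result.skipped:
            continue
        p_adj = min(1.0, result.p_value * n_tests)
        significant = p_adj < cfg.alpha
        row = {
            "locus": locus.value, "query": query, "parent_left": left,
            "parent_right": right, "max_chi2": result.max_chi2,
            "breakpoint_lo": result.breakpoint_interval[0],
            "breakpoint_hi": result.breakpoint_interval[1],
            "p_value": result.p_value, "p_bonferroni": p_adj,
            "significant": significant,
        }
        if significant:
            scan = recomb.window_scan(
                query, qseq, {left: others[left], right: others[right]},
                window=min(cfg.scan_window, len(qseq)), step=cfg.scan_step,
                confidence=cfg.scan_confidence,
            )
            if scan.switches:
                row["scan_switch_lo"] = scan.switches[0].interval[0]
                row["scan_switch_hi"] = scan.switches[0].interval[1]
        rows.append(row)
    calls = pd.DataFrame(rows)
    calls.to_csv(out_dir / "recomb_calls.tsv", sep="\t", index=False)
    return calls


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> RunReport:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    functional = cohort.load_functional_sites(config.functional_sites_file)
    try:
        if config.clones_fasta:
            clones, _ = io.read_clone_fasta(config.clones_fasta)
            animals = tuple(sorted({c.animal for c in clones}))
        else:
            sim = _simulate(config, out_dir, functional)
            clones, animals = sim.clones, sim.genotypes.animals
        _, validated, rejected, summary = _call(config, clones, animals, out_dir)
        tables, variability = _diversity(config, validated, functional, out_dir)
        trees = _phylo(config, validated, out_dir, config.seed + 1000)
        calls = _recomb(config, validated, out_dir, config.seed + 2000)
    except StageError as exc:
        (out_dir / "FAILED").write_text(str(exc) + "\n")
        raise
    run_summary = {
        "config": config.to_dict(),
        "seed": config.seed,
        "n_clones": len(clones),
        "cohort_size": summary.cohort_size,
        "n_validated": {
            loc.value: sum(1 for v in validated if v.locus is loc) for loc in cohort.Locus
        },
        "n_rejected_groups": len(rejected),
        "mean_genes_per_animal": summary.mean_genes_per_animal,
        "diversity": {k: v.to_dict(orient="records") for k, v in tables.items()},
        "variability": variability,
        "n_recomb_significant": int(calls["significant"].sum()) if len(calls) else 0,
    }
    (out_dir / "run_summary.json").write_text(json.dumps(run_summary, indent=2, sort_keys=True) + "\n")
    return RunReport(out_dir, validated, summary, tables, variability, trees, calls, run_summary)
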