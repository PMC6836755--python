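# Methods

This note documents the models and procedures implemented in `mhclones`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic data does and does not establish about real cohorts.

## The study design being emulated

The pipeline targets Sanger-era clone-library genotyping of duplicated MHC
class I loci: a cohort of ~30 animals, RT-PCR of the exon 2+3 region
(546 nt, codons 1–182 of the mature protein; exon 2 = sites 1–270, exon 3 =
sites 271–546), ~30 sequenced clones per animal per locus from two
independent PCRs, and allele naming from recurring identical clones.
Haplotypes carry variable numbers of duplicated genes, so an animal
expresses 1–5 locus-A and 2–7 locus-B alleles; a minority of alleles are
shared widely across the cohort.

## Allele validation

A candidate sequence (an exact-identity clone group within one locus) is
validated iff

* it is supported by ≥ `min_clones` (default 3) identical clones, **and**
* those clones come from ≥ `min_animals` (default 2) animals, **or** from
  ≥ `min_batches` (default 2) independent PCR batches of a single animal.

Rationale: polymerase substitution errors (~1e-4/bp) are essentially never
reproduced identically in three clones, and PCR-generated chimeras do not
recur across independent reactions.  Identity is exact string equality on
the trimmed exon 2+3 region (primer-derived flanks can be removed with the
`trim` coordinates; the primers sit in exons 1 and 4).  Clones containing
ambiguity codes are ineligible for grouping and are logged — validation
demands unambiguous identical reads.  Distribution frequencies use the
full cohort size as denominator, not the number of animals with data at
that locus.

## Polymorphism statistics

For an equal-length, gap-free alignment of n alleles and a site partition
(a set of codons, 3 nt sites per codon):

* `S` — columns with ≥ 2 distinct nucleotides;
* `N` (η) — Σ over columns of (distinct nucleotides − 1);
* `K` — (2 / n(n−1)) Σ_{i<j} d_ij, d_ij the count of mismatching sites
  within the partition;
* `π` — K / Ns.

Columns containing any non-ACGT symbol are excluded from all nucleotide
statistics (complete deletion, DnaSP-style) and counted.  S, N and K are
additive over complementary partitions and π = K/Ns is enforced as a
report-time invariant (the pipeline aborts on violation).

The functional partition is the union of peptide-binding (PBS) and
TCR-binding (TBS) residues: 36 + 26 positions with 8 shared, 54 distinct
codons = 162 nt sites, leaving 128 codons = 384 sites.  The packaged
default (`data/functional_sites_synthetic.json`) is a synthetic stand-in
with this exact class structure, concentrated along the groove-forming
regions of α1/α2; studies should supply their own PBS/TBS list via
`functional_sites_file`.  The 546 nt / 181 residue bookkeeping: codons are
numbered 1–182 and amino-acid analyses default to residues 2–182
(`residue_range`), since the mature-protein numbering starts at residue 2.

Site variability uses the frequency f₂ of the second-most common symbol
per column.  `f₂ > 0.05` (strict inequality, configurable) classifies a
site as highly polymorphic, `0 < f₂ ≤ 0.05` as rare variation, `f₂ = 0` as
invariant.  A tie at the top counts the shared maximum, so f₂ ≤ 0.5
always, and f₂ > 0 exactly at segregating columns.

## Phylogenetics

Pairwise distances use the Kimura 2-parameter model,
d = −½ ln(1−2P−Q) − ¼ ln(1−2Q) with P/Q the transition/transversion
proportions; sites with a non-ACGT symbol in either sequence are dropped
per pair (pairwise deletion — preserves data in clone-derived alignments).
Saturated pairs (1−2P−Q ≤ 0 or 1−2Q ≤ 0) raise a named error.

Neighbor joining follows the standard Q-criterion agglomeration with two
determinism/robustness choices: ties in the Q matrix resolve to the lowest
index pair, and a negative branch length is set to zero with the deficit
transferred to its sister branch.  On additive matrices the algorithm
recovers topology and branch lengths exactly (tested for n = 4–8).

Bootstrap support resamples alignment columns with replacement, rebuilds
the NJ tree per replicate (default 1,000), and scores each internal
bipartition by the percentage of retained replicates containing it;
replicates with saturated distances are dropped and counted.  Branches at
or below the collapse threshold (default 50%) become polytomies.  Trees
are dendropy objects; Newick output carries supports as internal node
labels and round-trips.

## Crossover detection

Three views of a putative recombinant ("query") against candidate parents:

* **Exon fingerprint** — per-parent mismatch counts split at the exon 2/3
  boundary, with a 5′/3′ annotation when all of an exon's mismatches fall
  in one half.  This is the pattern that exposes a crossover by eye
  (near-identity to one parent in one exon, to the other parent in the
  other).
* **Window scan** — per-window (default 200 nt, step 10, final window
  clipped to the 3′ end) identity to each parent.  A window's best-parent
  call is *confident* when, among window sites where the top two parents
  disagree, the query's matches reject a 50:50 split by an exact two-sided
  binomial test at the configured confidence (default 99%).  A switch is
  reported between maximal same-best-parent segments that each contain
  ≥ 2 consecutive confident windows; the breakpoint is the interval
  between the flanking confident window centers.  The exact-binomial
  formulation reproduces the decision logic of RIP-style confident
  best-parent assignment with a published, testable statistic.
* **MaxChi triplet test** — informative sites are positions where the two
  parents differ and the query matches exactly one.  For each cut of the
  informative-site vector a 2×2 table (left/right × matches-A/B) gives a
  chi-square; the maximum over cuts is the statistic.  `flank=k` compares
  fixed windows of k informative sites per side (RDP-style); `flank=None`
  (the pipeline default) compares whole left/right segments — the classic
  form, which keeps every cut admissible when parents are only ~5%
  divergent (28 informative sites leave a single admissible cut at
  flank 20).  Significance is by permutation of the site order with the
  add-one estimator p = (1 + #{perm ≥ obs}) / (n_perms + 1); breakpoints
  are reported as the interval between the informative sites flanking the
  best cut, since the exact position between them is unidentifiable.

The pipeline scans each validated allele as a query with its nearest
neighbor on each side of the exon boundary as candidate parents (testing
only when they differ), and Bonferroni-corrects MaxChi p-values for the
number of triplets scanned (α default 0.05).  The full multi-method
recombination-suite approach (GENECONV, Bootscan, SiScan, 3Seq, ...) is
out of scope; the fingerprint + scan + MaxChi combination covers crossover
products between co-amplified alleles, the dominant artifact/mechanism in
clone libraries.

## Synthetic cohort generator

The generator is the package's ground-truth instrument; its defaults
encode the emulated study design:

| parameter | default | why |
|---|---|---|
| animals | 30 | cohort size of the emulated design |
| allele pool | 40 A + 60 B | scale of a cohort-level allele catalogue |
| alleles/animal | 1–5 (A), 2–7 (B), uniform | observed per-animal gene counts |
| clones/animal/locus | 30 (fixed, not Poisson) | "about 30 clones" per reaction |
| PCR batches | 2 | two independent PCRs per animal |
| error rate | 1e-4 /bp | Taq-class substitution error; indels excluded because the exon alignments are gap-free |
| chimera rate | 0.02 /clone | typical PCR chimera incidence for co-amplified templates |
| breakpoint | uniform on [30, L−30] | both flanks must be detectable by a window scan |
| hotspot / background substitution | 0.085 / 0.018 per site | gives expected pairwise diversity π ≈ 2r − (4/3)r² of ~0.16 at functional and ~0.035 at background sites, the magnitudes seen in real class I cohorts |
| sharing skew | 2.0 (Dirichlet concentration 1/(1+skew)) | a minority of alleles reach cohort frequencies > 10% |

Alleles descend independently from a random stop-free ancestor; any codon
that a substitution turns into a stop is reverted (alleles are expressed
transcripts).  A "chimera" whose crossover product equals one of its
parents (no differing sites on one flank) is recorded as a plain clone of
that parent — it is not a detectable chimera.  All randomness flows from
one seed through deterministically spawned per-stage substreams, so a
config + seed fixes every output byte.

What the generator does **not** emulate: haplotype block structure across
loci, intron sequences, expression-level variation among alleles,
alignment uncertainty (clones are generated pre-aligned and gap-free), and
sequence-context-dependent error or chimera hotspots.  Passing tests
therefore establish the correctness of the statistics and the decision
rules under the stated noise model, not robustness to misalignment or
context-dependent artifacts.

## Numerical and scale choices

* Diversity statistics are exact integer/rational computations; K and π
  match a naive pair/column enumeration to 1e-12.
* Bootstrap supports are percentages of retained replicates; with 1,000
  replicates the Monte Carlo standard error of a 50% support is ~1.6
  points.
* Permutation p-values use the add-one estimator and are therefore
  conservative, never zero; pipeline-level MaxChi uses 2,000 permutations
  so the Bonferroni-adjusted floor stays below α for the tens of triplets
  a cohort produces.
* Test-suite problem sizes (e.g. 10×60 alignments for oracle equivalence,
  100 planted chimeras, 200 null replicates, brute-force grouping on a
  ~1,000-clone cohort) are chosen so the whole suite runs in well under a
  minute while keeping Monte Carlo margins far from the asserted
  thresholds.
* Degenerate inputs: empty partitions return zeros with a warning;
  `clones_per_locus=0` yields an empty library with a warning; single
  sequences cannot produce pairwise statistics (error); alignments with
  mixed lengths require explicit trimming coordinates.

## Replaying published numbers

The diversity table and variability counts reproduce a published
67-sequence locus-A alignment (S=157, N=218, π=0.073/0.162/0.035,
K=39.886/26.316/13.570, 97 nt / 48 aa highly polymorphic sites) when the
deposited sequences and the study's PBS/TBS residue list are supplied
under `tests/data/deposited/`; the corresponding tests state exactly which
files are needed.  Those third-party records are not redistributable with
the package, so the tests report the missing inputs when run without them.
The same applies to the published crossover triplet (exon fingerprint
24/4/2 and a best-parent switch at the exon 2/3 boundary).

## Known limitations

* Exact-identity grouping cannot merge clones differing by sequencing
  ambiguities; such clones are excluded rather than wildcard-matched.
* The window scan needs flanking signal: breakpoints within ~half a window
  of either end of the alignment are localized by MaxChi only.
* MaxChi assumes exactly two candidate parents; three-parent mosaics are
  reported as the best two-parent approximation.
* NJ is a distance method; for deep or saturated divergences the K2P
  correction fails loudly (saturation errors) rather than degrading
  silently.
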