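# Methods

`gak` reimplements, as one tested pipeline, the genome-architecture
analyses used in comparative studies of filamentous ascomycetes:
microsatellite (SSR) scanning with per-Mb statistics, telomere
end-calling, flanking-intergenic-region (FIR) "two-speed genome"
compartment analysis with effector/CAZyme enrichment, and the small
normalization and consistency statistics that accompany published
comparative tables. This note records the models, conventions and
numerical choices behind each stage.

## Coordinates and formats

All coordinates are 0-based half-open internally; GFF3's 1-based
inclusive convention is converted exactly once, at the file boundary, so
`length = end − start` holds for every record and FIR arithmetic never
carries an off-by-one. Lowercase (soft-masked) FASTA bases are uppercased
and not treated specially; characters outside `{A,C,G,T,N}` map to `N`
with a logged count. The GFF3 reader keeps a single feature type
(default `gene`, configurable), since published FIR analyses do not state
whether gene or mRNA records were used.

## SSR detection

An SSR locus is a **maximal perfect tandem run**: an interval where
`s[i] == s[i + p]` holds for a period `p` in 2–10 bp, spanning at least 5
complete units. The scanner computes the period-`p` match vector with
numpy and segments it into runs; a run's span automatically includes
leading/trailing partial units, while `units = floor(span / p)` counts
complete units only. Conventions, all deliberately explicit because
detection tools differ in them:

* **Perfect repeats only** — no mismatches or indels.
* **Period minimality** — a run whose motif is itself periodic (e.g.
  `ATAT` at p=4, or `AA` at p=2) is reported only at its fundamental
  period; mononucleotide runs are excluded by the 2 bp minimum.
* **Strand symmetry by canonicalization** — motifs are normalized to the
  lexicographic minimum over all rotations of the motif and of its
  reverse complement (TG/GT/CA/AC → AC), so each genomic locus is
  reported exactly once, on forward-strand coordinates, rather than
  scanning both strands and double counting.
* **Overlap resolution** — candidate runs of different periods that
  overlap are resolved greedily: longest span wins, ties go to the
  smaller period, remaining ties to the leftmost start.
* **N handling** — runs are split at `N`; loci never contain `N`.
* Adjacent loci of different motifs (compound SSRs) stay separate; the
  assembly-level report gives both this raw count and the merged
  (union-interval) count, because external tools differ in exactly this
  convention and genome-wide totals are sensitive to it.

Statistics follow the standard definitions: density = SSR bases per Mb,
coverage = percent of genome covered (computed on the union of spans),
frequency = loci per Mb; motif spectra count canonical motifs per period
with per-Mb normalization, optionally over the fixed universe of
canonical minimal motifs (4 dimers, 10 trimers, 33 tetramers) so that
absent motifs appear as explicit zeros in cross-genome heatmaps.

The scanner is validated for exact equality against an independent
brute-force oracle (regex lookahead at every position, followed by the
same minimality/overlap rules) on a thousand random sequences, including
AT-rich and N-containing compositions.

## Telomere calling

A scaffold end is telomeric when ≥ `min_copies` (default 5) consecutive
copies of the telomere unit occur within a terminal window (default
200 bp). The unit (default `TTAGGG`, the common fungal repeat) is read on
the G-rich strand: forward copies at the 3′ end, reverse-complement
copies (`CCCTAA`) at the 5′ end. Runs must be strictly consecutive — a
single interrupting base ends a run — which is the simplest defensible
contract and is declared rather than inherited from any external script.
Copy counts are the longest run in the window, so reverse-complementing
a scaffold swaps the 5′/3′ calls exactly (a tested invariant). Scaffolds
are summarized as complete (both ends), one-end, or none.

## FIRs and two-speed compartments

For start-sorted consecutive genes a, b on a scaffold the gap is
`max(0, b.start − a.end)` (0 for overlapping or nested spans). Each
gene's left/right gaps map to its 5′/3′ FIR according to its own strand,
so for `+`-strand neighbors `a.fir3 == b.fir5` exactly. Scaffold-terminal
genes get the distance to the scaffold end on the geneless side and a
boundary flag; boundary genes are excluded from densities, summaries and
classification by default because a scaffold break truncates the true
intergenic distance.

The joint (fir5, fir3) distribution is binned on log10-spaced edges
(default 30 bins over 1–100,000 bp, +1 pseudo-count so 0-bp FIRs land in
the first bin, out-of-range values clamped), which renders the bipartite
architecture as two modes. The compartment classifier formalizes the
visual "two-speed" call: a gene is **sparse** iff both FIRs are at or
above a threshold, either a fixed bp value or a quantile of the pooled
non-boundary FIR values (default q75). With gene-dense regions holding
most genes, the pooled 75th percentile falls just above the dense-gap
distribution (~420 bp under the default synthetic conditions), separating
the compartments cleanly.

Category enrichment in the sparse compartment uses a 2×2 Fisher exact
test per category (effector, CAZyme) with BH correction across the
tested categories at α = 0.05. Odds ratios are sample ORs with a 0.5
Haldane correction applied only when a cell is zero. A gene labelled
both effector and CAZyme is treated as effector (the rarer class) in
summaries and plots, while remaining countable in both raw category
tallies.

## Statistical primitives

`fisher_exact_2x2` computes the two-sided p by the probability-mass rule:
it sums hypergeometric probabilities of all tables sharing the observed
margins whose probability does not exceed the observed table's. Weights
are exact integers (`C(r1,k)·C(r2,c1−k)`), so tie comparison is exact and
needs no floating-point slack; the result is validated against a
rational-arithmetic enumeration oracle for every table with n ≤ 30 and
against `scipy.stats.fisher_exact`. Under hypergeometric null sampling
the empirical type-I error at 0.05 stays within three binomial standard
errors of nominal (the test is conservative, as expected for a discrete
exact test).

`bh_correct` wraps the statsmodels `fdr_bh` step-up procedure and is
property-tested against the textbook formula
`q_(i) = min_{j≥i} (m·p_(j)/j)`. Percent outputs of the table checks
(coding fraction, singleton percentage) round half-up to 2 decimals to
match published table formatting; `normalize_per_10k` and
`enzyme_activity` (U = µmol product · min⁻¹ · ml⁻¹) are direct
definitions.

## Synthetic assemblies

The simulator generates the study conditions every stage is tested
against; its defaults are fixed and are not tuned per test:

* **Layout** — 5 scaffolds × 100 genes, alternating dense blocks of 40
  genes and sparse blocks of 10. Sparse regions hold fewer genes because
  gene-sparse regions are by definition gene-poor; an equal gene split
  would place the pooled q75 threshold inside the sparse-gap distribution
  and make "both FIRs above threshold" fail for most genuinely sparse
  genes, defeating the classifier that the data are meant to exercise.
* **Gaps** — each gene's preceding gap is drawn from its block's
  distribution: LogNormal(ln 200, 0.5) in dense blocks, LogNormal(ln
  5000, 0.5) in sparse blocks (≥1 bp after rounding). The last gene of a
  sparse block is followed by a dense-block gap, so a handful of
  block-edge genes are intrinsically ambiguous; classification accuracy
  ~98–99% rather than 100% reflects that structure, not noise.
* **Genes** — lengths Normal(1500, 300) clipped at 300 bp (matching the
  ~1.5 kb mean gene length of the studied fungal annotations), strands
  uniform, bodies plain background sequence (no codon model: no analysis
  under test reads gene content).
* **Labels** — each gene is labelled effector with probability 0.75 in
  the sparse compartment vs 0.05 in the dense one, and CAZyme with
  probability 0.10 in both (CAZymes are not strongly compartmentalized),
  effector taking precedence. This plants a strong, recoverable effector
  enrichment and a null-like CAZyme pattern.
* **Background** — i.i.d. bases at GC 0.52 (typical of these genomes);
  no transposable-element or RIP model, which is the main respect in
  which the synthetic data are easier than real genomes: passing tests
  demonstrate correctness of the measurements, not robustness to
  repeat-driven assembly artifacts.
* **Planted SSRs** — default 10×(AT)₈, 6×(AAG)₆, 4×(ACGT)₅ arrays placed
  in randomly chosen intergenic gaps (one per gap, never overlapping
  genes or each other), framed by guard bases chosen so the array cannot
  be extended by even one base; recovery is therefore expected to be
  exact, and the scanner's 100% planted recall is a meaningful check.
  Background sequence also yields spontaneous SSRs (~10–25 loci per Mb,
  almost all dimers), counted separately as the precision denominator.
* **Telomeres** — (CCCTAA)₁₀ / (TTAGGG)₁₀ written at configured termini;
  the default plan gives one complete scaffold, three one-end scaffolds
  and one bare scaffold, mirroring the typical draft-assembly picture.
* **Determinism** — all randomness flows from one seeded generator;
  identical config (including seed) gives byte-identical files.

A genome this size (~1.35 Mb, 500 genes) keeps a full simulate–scan–
classify–test cycle under a second, so the replicate analyses (100 seeds
for enrichment significance and effect direction) run in seconds; these
sizes are the package's chosen test conditions and are recorded here so
full-scale runs are not confused with them.

## Known limitations

* SSR counts on real assemblies are convention-sensitive (compound-repeat
  handling, strand double-counting, partial units); comparisons against
  external tools should use the raw/merged pair the assembly report emits
  rather than a single number.
* The telomere caller ignores interstitial telomeric repeats and degraded
  (mismatch-containing) arrays.
* The compartment classifier is a thresholding rule on FIRs only; it does
  not use repeat density or synteny, and on one-speed genomes the q75
  threshold still splits genes into nominal compartments — the
  enrichment test, not the split itself, carries the architectural
  signal.
* Transposable-element annotation and RIP indices are out of scope.
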