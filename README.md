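# gak — genome architecture kit

A tested pipeline for the genome-architecture analyses used in
comparative genomics of filamentous fungi (endophytes and plant
pathogens of the *Apiospora* / *Arthrinium* / *Nigrospora* group and
similar ascomycetes):

* **SSR scanning** — detection of maximal perfect tandem repeats
  (microsatellites; motifs 2–10 bp, ≥ 5 units) with canonical-motif
  normalization under strand/rotation equivalence, per-Mb density,
  genome coverage, frequency, and dimer/trimer/tetramer motif spectra
  for cross-genome heatmaps.
* **Telomere end-calling** — consecutive `TTAGGG`/`CCCTAA` arrays at
  scaffold termini, summarized as complete / one-end / bare scaffolds.
* **Two-speed genome analysis** — per-gene 5′/3′ flanking intergenic
  regions (FIRs) from GFF3, log-binned 2-D FIR densities, dense/sparse
  compartment classification, and Fisher-exact (BH-corrected) tests of
  effector/CAZyme enrichment in the gene-sparse compartment.
* **Comparative table statistics** — exact 2×2 Fisher test, BH
  correction, per-10,000-gene normalization, coding fraction, enzyme
  activity units, and ortholog-cluster table consistency checks.
* **Synthetic assemblies** — a deterministic simulator that plants a
  bipartite gene layout, category labels, tandem-repeat arrays and
  telomeres with full ground truth, so every stage is testable without
  downloads.

## Core definitions

For a motif of period *p* repeated in a maximal run of span *s*,
`units = ⌊s/p⌋` and the canonical motif is
`min over rotations of {motif, revcomp(motif)}`. Per-genome SSR
statistics on a genome of length *G* (bp):

    density  = covered_bases / (G/10^6)      [bp per Mb]
    coverage = covered_bases / G × 100       [%]
    frequency = n_loci / (G/10^6)            [loci per Mb]

A gene with flanking intergenic distances (fir5, fir3) is **sparse** iff
`fir5 ≥ t` and `fir3 ≥ t`, with *t* a fixed value or a quantile (default
q75) of the pooled FIR values; enrichment of a gene category in the
sparse compartment is tested on the 2×2 table
[[category∩sparse, category∩dense], [other∩sparse, other∩dense]] with the
two-sided Fisher exact test (probability-mass rule) and
Benjamini–Hochberg correction across categories.

## Worked example

```sh
gak simulate --seed 1 --out-dir demo
gak run-all --fasta demo/synthetic.fasta --gff3 demo/synthetic.gff3 \
    --labels demo/synthetic.labels.tsv --out-dir demo/report
```

The same steps via the analysis drivers (which also compare every call
against the simulator's planted truth):

```sh
python analysis/01_simulate_assemblies.py --seed 1
python analysis/02_scan_ssrs.py
python analysis/03_call_telomeres.py
python analysis/04_fir_compartments.py
python analysis/05_printed_tables.py
```

which prints, among other lines:

```
genomeA: 5 scaffolds, 1,350,449 bp, 500 genes, 20 planted SSRs -> results/synthetic
genomeA: 38 loci, 0.0582% coverage, planted recall 100%
genomeA: {'complete': 1, 'one_end': 3, 'none': 1} | recall 100%, precision 100%
genomeA: q75 threshold 424 bp, classification accuracy 98.4%; effector sparse enrichment OR=45.3, q=1.03e-42
Apiospora malaysiana         coding  42.14%  [OK]
cluster totals: 98,439 proteins, 3,439 singleton clusters (3.49%)
```

Reading: the simulated genome carries 20 planted tandem-repeat arrays,
all recovered at their exact spans (the other observed loci are
spontaneous background repeats); telomere calls match the planted plan on
every scaffold end; the q75 FIR threshold lands at 424 bp, recovering
98.4% of planted compartments, and the planted effector bias toward the
sparse compartment is detected with odds ratio ≈ 45 at q ≪ 0.05. The
table checks recompute the published comparative-table columns (coding
percentage per organism and ortholog-cluster totals) from their printed
cells. `analysis/06_fullscale_ssr.py` runs the identical SSR pipeline on
any locally available assembly FASTA (e.g. GCA_006508115.1) and reports
raw and merged counts next to the published species values.

## Layout

    src/gak/        library: io_formats, ssr, telomeres, fir, stats,
                    simulate, report, cli (+ packaged table data)
    analysis/       numbered narrative drivers writing results/
    tests/          pytest suite with brute-force oracles
    scripts/        acceptance.py
    docs/methods.md model conventions, simulator design, limitations
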