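import dataclasses

import numpy as np
import pytest

from gak.fir import (FIRRecord, bin_fir_density, category_fir_summary,
                     classify_compartments, compartment_enrichment, compute_firs)
from gak.io_formats import CategoryLabel, GeneModel


def genes_on_scaffold():
    return [GeneModel("g1", "s", 100, 200, "+"),
            GeneModel("g2", "s", 500, 700, "+"),
            GeneModel("g3", "s", 1500, 1600, "-")]


class TestComputeFirs:
    def test_worked_example_with_strands_and_boundaries(self):
        firs = {f.gene_id: f for f in compute_firs(genes_on_scaffold(), {"s": 2000})}
        assert (firs["g1"].fir5, firs["g1"].fir3) == (100, 300)
        assert firs["g1"].boundary5 and not firs["g1"].boundary3
        assert (firs["g2"].fir5, firs["g2"].fir3) == (300, 800)
        assert not firs["g2"].is_boundary
        # minus strand: the scaffold-end side is its 5'
        assert (firs["g3"].fir5, firs["g3"].fir3) == (400, 800)
        assert firs["g3"].boundary5 and not firs["g3"].boundary3

    def test_overlapping_genes_clip_to_zero(self):
        genes = [GeneModel("a", "s", 100, 300, "+"), GeneModel("b", "s", 250, 400, "+")]
        firs = {f.gene_id: f for f in compute_firs(genes, {"s": 1000})}
        assert firs["a"].fir3 == 0 and firs["b"].fir5 == 0

    def test_single_gene_both_boundaries(self):
        (f,) = compute_firs([GeneModel("g", "s", 300, 400, "+")], {"s": 1000})
        assert (f.fir5, f.fir3) == (300, 600)
        assert f.boundary5 and f.boundary3

    def test_gene_past_scaffold_end_rejected(self):
        with pytest.raises(ValueError):
            compute_firs([GeneModel("g", "s", 0, 100, "+")], {"s": 50})

    def test_adjacency_consistency_plus_strand(self, default_sim):
        lengths = {r.scaffold_id: r.length for r in default_sim.records}
        firs = {f.gene_id: f for f in compute_firs(default_sim.genes, lengths)}
        by_scaffold = {}
        for g in default_sim.genes:
            by_scaffold.setdefault(g.scaffold_id, []).append(g)
        for scaffold_genes in by_scaffold.values():
            ordered = sorted(scaffold_genes, key=lambda g: g.start)
            for a, b in zip(ordered, ordered[1:]):
                gap = max(0, b.start - a.end)
                a_out = firs[a.gene_id].fir3 if a.strand == "+" else firs[a.gene_id].fir5
                b_in = firs[b.gene_id].fir5 if b.strand == "+" else firs[b.gene_id].fir3
                assert a_out == gap and b_in == gap

    def test_translation_invariance(self):
        genes = genes_on_scaffold()
        shifted = [dataclasses.replace(g, start=g.start + 123, end=g.end + 123)
                   for g in genes]
        base = compute_firs(genes, {"s": 2000})
        moved = compute_firs(shifted, {"s": 2123})
        # interior gaps unchanged; only boundary distances move
        for f0, f1 in zip(base, moved):
            if not f0.boundary5:
                assert f0.fir5 == f1.fir5
            if not f0.boundary3:
                assert f0.fir3 == f1.fir3


class TestBinFirDensity:
    def test_conservation(self):
        firs = [FIRRecord(f"g{i}", 10 * i, 20 * i, False, False) for i in range(1, 4)]
        density = bin_fir_density(firs)
        assert density.matrix.sum() == density.n_genes == 3

    def test_equal_firs_sit_on_diagonal(self):
        firs = [FIRRecord(f"g{i}", v, v, False, False)
                for i, v in enumerate([0, 10, 100, 5000, 10**7])]
        density = bin_fir_density(firs)
        assert np.all(density.matrix == np.diag(np.diag(density.matrix)))
        assert density.matrix.sum() == 5  # zero and out-of-range values clamped

    def test_boundary_genes_excluded(self):
        firs = [FIRRecord("g1", 5, 5, False, False),
                FIRRecord("g2", 5, 5, True, False)]
        assert bin_fir_density(firs).n_genes == 1

    def test_two_compartment_genome_is_bimodal(self, default_sim):
        lengths = {r.scaffold_id: r.length for r in default_sim.records}
        firs = compute_firs(default_sim.genes, lengths)
        density = bin_fir_density(firs)
        marginal = density.matrix.sum(axis=1).astype(float)
        edges = density.bin_edges
        centers = np.sqrt(edges[:-1] * edges[1:])
        dense_mass = marginal[(centers > 50) & (centers < 1000)].sum()
        sparse_mass = marginal[(centers > 1500) & (centers < 30000)].sum()
        trough = marginal[(centers >= 1000) & (centers <= 1500)].sum()
        assert dense_mass > 10 * max(trough, 1)
        assert sparse_mass > 5 * max(trough, 1)

    def test_n_bins_validation(self):
        with pytest.raises(ValueError):
            bin_fir_density([], n_bins=1)


class TestClassifyCompartments:
    def test_fixed_threshold(self):
        firs = [FIRRecord("sparse", 2000, 3000, False, False),
                FIRRecord("dense", 100, 50, False, False),
                FIRRecord("mixed", 2000, 50, False, False)]
        calls = {c.gene_id: c.compartment for c in classify_compartments(firs, 1500)}
        assert calls == {"sparse": "sparse", "dense": "dense", "mixed": "dense"}

    def test_all_boundary_rejected(self):
        with pytest.raises(ValueError):
            classify_compartments([FIRRecord("g", 1, 1, True, True)])

    def test_planted_compartment_recovery_at_q75(self, default_sim, default_analysis):
        truth = {g["gene_id"]: g["compartment"] for g in default_sim.truth["genes"]}
        calls = default_analysis["compartments"]
        acc = np.mean([truth[c.gene_id] == c.compartment for c in calls])
        assert acc >= 0.90


class TestCategorySummaryAndEnrichment:
    def test_planted_effectors_have_longer_firs(self, default_sim, default_analysis):
        summary = default_analysis["category_summary"].set_index("category")
        assert summary.loc["effector", "mean_fir5"] > summary.loc["core", "mean_fir5"]
        assert summary.loc["effector", "mean_fir3"] > summary.loc["core", "mean_fir3"]

    def test_single_category_row_counts(self):
        firs = [FIRRecord(f"g{i}", 10, 10, False, False) for i in range(5)]
        summary = category_fir_summary(firs, []).set_index("category")
        assert summary.loc["core", "n"] == 5
        assert summary.loc["effector", "n"] == 0
        assert np.isnan(summary.loc["effector", "mean_fir5"])

    def test_dual_labelled_gene_summarized_as_effector(self):
        firs = [FIRRecord("g1", 10, 10, False, False),
                FIRRecord("g2", 9000, 9000, False, False)]
        labels = [CategoryLabel("g2", "cazyme"), CategoryLabel("g2", "effector")]
        summary = category_fir_summary(firs, labels).set_index("category")
        assert summary.loc["effector", "n"] == 1
        assert summary.loc["cazyme", "n"] == 0

    def test_enrichment_odds_ratio_arithmetic(self, default_sim):
        # table [[30,10],[190,770]]: OR = (30*770)/(10*190)
        from gak.stats import fisher_exact_2x2
        result = fisher_exact_2x2(30, 10, 190, 770)
        assert result["odds_ratio"] == pytest.approx(30 * 770 / (10 * 190))
        assert result["odds_ratio"] == pytest.approx(12.158, abs=1e-3)

    def test_independence_gives_or_one(self):
        from gak.fir import CompartmentCall
        calls = ([CompartmentCall(f"s{i}", "sparse", 1) for i in range(40)]
                 + [CompartmentCall(f"d{i}", "dense", 1) for i in range(160)])
        # 25% of each compartment labelled: proportions equal
        labels = ([CategoryLabel(f"s{i}", "effector") for i in range(10)]
                  + [CategoryLabel(f"d{i}", "effector") for i in range(40)])
        df = compartment_enrichment(calls, labels, categories=("effector",))
        assert df.loc[0, "odds_ratio"] == pytest.approx(1.0)
        assert df.loc[0, "p_value"] == pytest.approx(1.0)

    def test_degenerate_margin_rejected(self):
        from gak.fir import CompartmentCall
        calls = [CompartmentCall("g1", "dense", 1), CompartmentCall("g2", "dense", 1)]
        with pytest.raises(ValueError):
            compartment_enrichment(calls, [CategoryLabel("g1", "effector")])

    def test_planted_enrichment_detected(self, default_analysis):
        enrichment = default_analysis["enrichment"].set_index("category")
        assert enrichment.loc["effector", "odds_ratio"] > 1
        assert enrichment.loc["effector", "q_value"] < 0.01
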