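from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gak.io_formats import GenomeRecord
from gak.ssr import (canonical_motif, find_ssrs, merged_bases, motif_spectrum,
                     reverse_complement, scan_assembly, ssr_proportion_by_class,
                     ssr_statistics)

from helpers_oracle import oracle_canonical, oracle_find_ssrs

motifs = st.text(alphabet="ACGT", min_size=1, max_size=10)


class TestCanonicalMotif:
    @pytest.mark.parametrize("motif,expected", [
        ("TG", "AC"), ("GT", "AC"), ("CA", "AC"), ("AC", "AC"),
        ("TA", "AT"), ("AT", "AT"), ("GC", "CG"),
        ("TTA", "AAT"), ("GGA", "AGG"),
    ])
    def test_known_classes(self, motif, expected):
        assert canonical_motif(motif) == expected

    def test_rejects_non_acgt(self):
        with pytest.raises(ValueError):
            canonical_motif("ANT")

    @given(motifs)
    @settings(deadline=None)
    def test_idempotent_and_matches_enumeration(self, motif):
        canon = canonical_motif(motif)
        assert canon == oracle_canonical(motif)
        assert canonical_motif(canon) == canon

    @given(motifs)
    @settings(deadline=None)
    def test_invariant_under_rotation_and_revcomp(self, motif):
        canon = canonical_motif(motif)
        rotated = motif[3 % len(motif):] + motif[: 3 % len(motif)]
        assert canonical_motif(rotated) == canon
        assert canonical_motif(reverse_complement(motif)) == canon


class TestFindSsrs:
    def test_simple_dimer_run(self):
        loci = find_ssrs(GenomeRecord("s", "ATATATATAT"))
        assert len(loci) == 1
        L = loci[0]
        assert (L.start, L.end, L.period, L.motif, L.units) == (0, 10, 2, "AT", 5)

    def test_mononucleotide_run_excluded_by_period_minimality(self):
        assert find_ssrs(GenomeRecord("s", "AAAAAAAAAA")) == []

    def test_below_unit_threshold(self):
        assert find_ssrs(GenomeRecord("s", "ACGACGACGACG")) == []

    def test_partial_trailing_unit_extends_span_not_units(self):
        # 5 full AGC units plus a partial "AG"
        loci = find_ssrs(GenomeRecord("s", "T" + "AGC" * 5 + "AG" + "TTT"))
        (L,) = loci
        assert (L.start, L.end, L.units) == (1, 1 + 17, 5)

    def test_runs_split_at_n(self):
        seq = "AT" * 5 + "N" + "AT" * 5
        loci = find_ssrs(GenomeRecord("s", seq))
        assert [(L.start, L.end) for L in loci] == [(0, 10), (11, 21)]

    def test_empty_sequence(self):
        assert find_ssrs(GenomeRecord("s", "")) == []

    def test_parameter_validation(self):
        rec = GenomeRecord("s", "ACGT")
        with pytest.raises(ValueError):
            find_ssrs(rec, min_len=0)
        with pytest.raises(ValueError):
            find_ssrs(rec, min_repeats=1)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_oracle_on_random_sequences(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(200, 8000))
        # AT-rich alphabet raises the tandem-repeat rate
        seq = "".join(rng.choice(list("ACGTATN"), size=n))
        got = [(L.start, L.end, L.period, L.canonical, L.units)
               for L in find_ssrs(GenomeRecord("s", seq))]
        assert got == oracle_find_ssrs(seq)

    @pytest.mark.parametrize("seed", range(6))
    def test_strand_invariance(self, seed):
        rng = np.random.default_rng(100 + seed)
        seq = "".join(rng.choice(list("ACGTAT"), size=4000))
        fwd = find_ssrs(GenomeRecord("s", seq))
        rev = find_ssrs(GenomeRecord("s", reverse_complement(seq)))
        n = len(seq)
        assert Counter((L.canonical, L.span) for L in fwd) == \
            Counter((L.canonical, L.span) for L in rev)
        assert sorted((n - L.end, n - L.start) for L in fwd) == \
            sorted((L.start, L.end) for L in rev)

    def test_planted_loci_recovered_exactly(self, default_sim, default_analysis):
        observed = {(L.scaffold_id, L.start, L.end, L.canonical)
                    for L in default_analysis["loci"]}
        for t in default_sim.truth["ssrs"]:
            assert (t["scaffold"], t["start"], t["end"], t["canonical"]) in observed


class TestSsrStatistics:
    def test_direct_arithmetic(self):
        loci = [type("L", (), {"scaffold_id": "s", "start": 0, "end": 2900})()]
        stats = ssr_statistics(loci, 1_000_000)
        assert stats.coverage_percent == pytest.approx(0.29)
        assert stats.density_per_mb == pytest.approx(2900.0)
        assert stats.frequency_per_mb == pytest.approx(1.0)

    def test_no_loci_all_zero(self):
        stats = ssr_statistics([], 1000)
        assert (stats.total_count, stats.bases_covered) == (0, 0)
        assert stats.coverage_percent == 0.0

    def test_invalid_genome_length(self):
        with pytest.raises(ValueError):
            ssr_statistics([], 0)

    def test_merged_bases_unions_overlaps(self):
        loci = [type("L", (), {"scaffold_id": "s", "start": 0, "end": 10})(),
                type("L", (), {"scaffold_id": "s", "start": 5, "end": 15})(),
                type("L", (), {"scaffold_id": "t", "start": 0, "end": 4})()]
        assert merged_bases(loci) == 19


class TestMotifSpectrum:
    def test_per_mb_arithmetic(self, ):
        loci = find_ssrs(GenomeRecord("s", ("AT" * 5 + "GGCCC") * 5))
        at_loci = [L for L in loci if L.canonical == "AT"]
        spectra = motif_spectrum(at_loci, 500_000, k_values=(2,))
        count, per_mb = spectra[0].rows["AT"]
        assert (count, per_mb) == (5, 10.0)

    def test_full_universe_includes_absent_motifs(self):
        spectra = motif_spectrum([], 1_000_000, k_values=(2,), full_universe=True)
        assert set(spectra[0].rows) == {"AC", "AG", "AT", "CG"}
        assert spectra[0].rows["AC"] == (0, 0.0)

    def test_counts_partition_by_period(self, default_analysis):
        loci = default_analysis["loci"]
        ks = sorted({L.period for L in loci})
        spectra = motif_spectrum(loci, 1, k_values=ks)
        assert sum(s.total_count for s in spectra) == len(loci)
        for spec in spectra:
            assert spec.total_count == sum(1 for L in loci if L.period == spec.k)

    def test_proportions(self):
        mk = lambda k, n: [type("L", (), {"period": k})() for _ in range(n)]
        loci = mk(2, 46) + mk(3, 30) + mk(4, 16) + mk(5, 8)
        props = ssr_proportion_by_class(loci)
        assert props == {2: 46.0, 3: 30.0, 4: 16.0, 5: 8.0}
        assert props[2] + props[3] + props[4] == pytest.approx(92.0)
        assert ssr_proportion_by_class([]) == {}


def test_scan_assembly_deterministic_order(default_sim):
    loci = scan_assembly(default_sim.records)
    assert loci == sorted(loci, key=lambda L: (L.scaffold_id, L.start))
    assert loci == scan_assembly(default_sim.records)
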