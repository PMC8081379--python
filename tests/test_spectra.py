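"""Spectrum classification, strand bias and rate normalization."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from platmut import spectra
from platmut.channels import (
    BASES,
    CHANNEL_LABELS,
    N_CHANNELS,
    channel_index,
    classify_snv,
    revcomp,
)
from platmut.synthetic_data import Gene


class TestClassifySNV:
    def test_pyrimidine_context_is_kept(self):
        assert CHANNEL_LABELS[classify_snv("ACG", "C", "T")] == "A[C>T]G"

    def test_purine_context_is_reverse_complemented(self):
        assert CHANNEL_LABELS[classify_snv("TGA", "G", "A")] == "T[C>T]A"

    def test_bijection_over_all_substitutions(self):
        """All 192 (context, alt) pairs map onto the 96 channels exactly twice,
        and each channel is hit once from the pyrimidine and once from the
        purine representation."""
        hits = {i: [] for i in range(N_CHANNELS)}
        for five, mid, three in itertools.product(BASES, repeat=3):
            for alt in BASES:
                if alt == mid:
                    continue
                ch = classify_snv(five + mid + three, mid, alt)
                hits[ch].append((five + mid + three, alt))
        assert all(len(v) == 2 for v in hits.values())
        for ch, pair in hits.items():
            (ctx_a, alt_a), (ctx_b, alt_b) = pair
            assert ctx_b == revcomp(ctx_a) and alt_b == revcomp(alt_a) or \
                   ctx_a == revcomp(ctx_b) and alt_a == revcomp(alt_b)

    def test_rejects_ambiguous_bases_and_mismatches(self):
        with pytest.raises(ValueError):
            classify_snv("ANG", "N", "T")
        with pytest.raises(ValueError):
            classify_snv("ACG", "T", "A")
        with pytest.raises(ValueError):
            classify_snv("ACG", "C", "C")


def _calls(rows):
    return pd.DataFrame(rows, columns=["sample", "contig", "pos", "ref", "alt",
                                       "type", "score", "vaf", "context"])


class TestBuildSpectrum:
    def test_single_snv_fills_one_channel(self):
        calls = _calls([("s1", "chr1", 10, "C", "T", "SNV", 5.0, 0.5, "ACG")])
        vec = spectra.build_spectrum(calls, ["s1"])
        assert vec.sum() == 1
        assert vec[channel_index("A[C>T]G")] == 1

    def test_averaging_identical_samples_is_idempotent(self):
        calls = _calls([
            ("s1", "chr1", 10, "C", "T", "SNV", 5.0, 0.5, "ACG"),
            ("s2", "chr1", 20, "C", "T", "SNV", 5.0, 0.5, "ACG"),
        ])
        mean = spectra.build_spectrum(calls, ["s1", "s2"], mode="mean")
        single = spectra.build_spectrum(calls, ["s1"])
        assert np.allclose(mean, single)

    def test_empty_sample_subset_rejected(self):
        with pytest.raises(ValueError):
            spectra.build_spectrum(_calls([]), [])

    def test_channel_conservation_with_drops(self):
        calls = _calls([
            ("s1", "chr1", 1, "C", "T", "SNV", 5.0, 0.5, ""),     # edge, dropped
            ("s1", "chr1", 10, "C", "A", "SNV", 5.0, 0.5, "TCC"),
            ("s1", "chr1", 30, "T", "A", "SNV", 5.0, 0.5, "CTA"),
        ])
        assert spectra.build_spectrum(calls, ["s1"]).sum() == 2


class TestStrandComplementInvariance:
    def test_spectrum_unchanged_under_reference_reverse_complement(self, small_reference, small_cohort):
        """Relabeling every SNV to the opposite strand (and flipping gene
        strands) leaves the pyrimidine-centred spectrum and strand-bias
        table unchanged."""
        _, truth, _ = small_cohort
        snvs = truth[truth["type"] == "SNV"].head(300)
        calls = _calls([
            (r.clone, r.contig, r.pos, r.ref, r.alt, "SNV", 5.0, 0.5,
             small_reference.context(r.contig, r.pos - 1))
            for r in snvs.itertuples(index=False)
        ])
        flipped = calls.copy()
        flipped["ref"] = [revcomp(b) for b in calls["ref"]]
        flipped["alt"] = [revcomp(b) for b in calls["alt"]]
        flipped["context"] = [revcomp(c) for c in calls["context"]]
        samples = sorted(calls["sample"].unique())
        np.testing.assert_array_equal(
            spectra.build_spectrum(calls, samples),
            spectra.build_spectrum(flipped, samples))
        genes = small_reference.genes
        genes_flipped = [Gene(g.contig, g.start, g.end,
                              "+" if g.strand == "-" else "-") for g in genes]
        a = spectra.strand_bias(calls, genes)
        b = spectra.strand_bias(flipped, genes_flipped)
        pd.testing.assert_frame_equal(a, b)


class TestDBS:
    def test_adjacent_pair_merges_to_doublet(self):
        calls = _calls([
            ("s1", "chr1", 100, "C", "A", "SNV", 5.0, 0.5, "ACC"),
            ("s1", "chr1", 101, "C", "A", "SNV", 5.0, 0.5, "CCG"),
        ])
        dbs, multi = spectra.classify_dbs(calls)
        assert dbs.to_dict() == {"CC>AA": 1}
        assert len(multi) == 0

    def test_no_adjacent_pairs_gives_empty_spectrum(self):
        calls = _calls([
            ("s1", "chr1", 100, "C", "A", "SNV", 5.0, 0.5, "ACC"),
            ("s1", "chr1", 200, "C", "A", "SNV", 5.0, 0.5, "ACC"),
        ])
        dbs, _ = spectra.classify_dbs(calls)
        assert len(dbs) == 0

    def test_triple_run_excluded_and_logged(self):
        calls = _calls([
            ("s1", "chr1", p, "C", "A", "SNV", 5.0, 0.5, "ACC")
            for p in (100, 101, 102)
        ])
        dbs, multi = spectra.classify_dbs(calls)
        assert len(dbs) == 0
        assert multi.iloc[0]["length"] == 3

    def test_strand_normalization_of_reference_doublet(self):
        # GG>TT reverse-complements to CC>AA
        calls = _calls([
            ("s1", "chr1", 100, "G", "T", "SNV", 5.0, 0.5, "AGG"),
            ("s1", "chr1", 101, "G", "T", "SNV", 5.0, 0.5, "GGA"),
        ])
        dbs, _ = spectra.classify_dbs(calls)
        assert dbs.to_dict() == {"CC>AA": 1}

    def test_expected_collision_rate_of_random_positions(self):
        """Adjacent pairs among n uniform sites follow the collision-count
        expectation n^2 * 2 / (2L) within 3 sigma (Poisson oracle)."""
        rng = np.random.default_rng(5)
        L, n = 200_000, 2000
        pos = rng.choice(np.arange(2, L), size=n, replace=False)
        calls = _calls([
            ("s1", "chr1", int(p), "C", "A", "SNV", 5.0, 0.5, "ACC") for p in pos
        ])
        dbs, multi = spectra.classify_dbs(calls)
        observed = int(dbs.sum()) + int((multi["length"] - 1).sum() if len(multi) else 0)
        expected = n * (n - 1) / L  # n(n-1)/2 pairs x 2 adjacent offsets / L
        assert abs(observed - expected) <= 3 * np.sqrt(expected)


class TestIndelClasses:
    def test_one_bp_deletion_in_homopolymer(self):
        seq = "GGAAAAAGG"
        assert spectra.classify_indel("GA", "G", "DEL", seq, 3) == ("DEL", "1", "5+")

    def test_insertion_in_non_repeat_context(self):
        seq = "GACGTACG"
        assert spectra.classify_indel("C", "CTTA", "INS", seq, 3) == ("INS", "2-4", "0-1")

    def test_class_invariant_under_reverse_complement(self):
        seq = "GGCAAAACTT"
        rc = revcomp(seq)
        # delete the first A of the A4 run; on the rc strand that is a T of T4
        fwd = spectra.classify_indel("CA", "C", "DEL", seq, 4)
        pos_rc = len(seq) - 1 - 4
        rev = spectra.classify_indel("GT", "G", "DEL", rc, pos_rc)
        assert fwd == rev == ("DEL", "1", "2-4")


class TestStrandBias:
    def test_symmetric_counts_give_p_one(self):
        genes = [Gene("chr1", 0, 10_000, "+")]
        rows = []
        for i in range(10):
            rows.append(("s1", "chr1", 100 + 3 * i, "C", "A", "SNV", 5.0, 0.5, "ACA"))
        for i in range(10):
            rows.append(("s1", "chr1", 500 + 3 * i, "G", "T", "SNV", 5.0, 0.5, "AGA"))
        table = spectra.strand_bias(_calls(rows), genes)
        row = table[table["class"] == "C>A"].iloc[0]
        assert row["transcribed"] == 10 and row["untranscribed"] == 10
        assert row["ratio"] == 1.0 and row["p_value"] == 1.0

    def test_binomial_tail_oracle_30_vs_10(self):
        """p for a 30/10 split equals the two-sided Binomial(40, 1/2) tail
        summed directly from binomial pmf terms."""
        from math import comb

        genes = [Gene("chr1", 0, 100_000, "+")]
        rows = []
        # gene on '+': pyrimidine ref on '+' strand -> untranscribed;
        # purine ref (pyr on '-') -> transcribed
        for i in range(30):
            rows.append(("s1", "chr1", 100 + 3 * i, "G", "T", "SNV", 5.0, 0.5, "AGA"))
        for i in range(10):
            rows.append(("s1", "chr1", 1000 + 3 * i, "C", "A", "SNV", 5.0, 0.5, "ACA"))
        table = spectra.strand_bias(_calls(rows), genes)
        row = table[table["class"] == "C>A"].iloc[0]
        oracle = sum(comb(40, k) for k in range(40 + 1) if abs(k - 20) >= 10) / 2 ** 40
        assert row["transcribed"] == 30
        assert row["p_value"] == pytest.approx(oracle, rel=1e-12)

    def test_intergenic_snvs_excluded(self):
        genes = [Gene("chr1", 5000, 6000, "+")]
        calls = _calls([("s1", "chr1", 100, "C", "A", "SNV", 5.0, 0.5, "ACA")])
        assert len(spectra.strand_bias(calls, genes)) == 0


class TestMutationRate:
    def test_spontaneous_rate_worked_example(self):
        """169 substitutions / 50 days / 16-h cycle / 3 Gb -> 0.75 per Gb
        per cycle at two decimals."""
        res = spectra.mutation_rate(169, 50, 16, 3.0)
        assert round(res.rate_per_gb_per_cycle, 2) == 0.75

    def test_zero_mutations_zero_rate(self):
        assert spectra.mutation_rate(0, 50, 16, 3.0).rate_per_gb_per_cycle == 0.0

    def test_exact_cycle_arithmetic(self):
        # 50 days x 24 h / 16 h = 75 cycles; 75 mutations on 1 Gb -> rate 1
        assert spectra.mutation_rate(75, 50, 16, 1.0).rate_per_gb_per_cycle == pytest.approx(1.0)

    def test_rejects_nonpositive_denominators(self):
        with pytest.raises(ValueError):
            spectra.mutation_rate(10, 0, 16, 3.0)
        with pytest.raises(ValueError):
            spectra.mutation_rate(10, 50, 16, -1.0)

    @given(st.integers(0, 10_000), st.floats(1, 100), st.floats(1, 100),
           st.floats(0.1, 10))
    def test_rate_linearity(self, n, days, cycle, gb):
        base = spectra.mutation_rate(n, days, cycle, gb).rate_per_gb_per_cycle
        doubled = spectra.mutation_rate(2 * n, days, cycle, gb).rate_per_gb_per_cycle
        halved_genome = spectra.mutation_rate(n, days, cycle, 2 * gb).rate_per_gb_per_cycle
        assert doubled == pytest.approx(2 * base)
        assert halved_genome == pytest.approx(base / 2)
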