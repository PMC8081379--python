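"""Unique-mutation detection, Fisher scoring and FP calibration."""

import math
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from platmut import synthetic_data as sd
from platmut import variant_calling as vc


def make_site(ref_base, per_sample, pos=100):
    """per_sample: list of dicts with cov and base counts / supports."""
    samples = tuple(f"s{i+1}" for i in range(len(per_sample)))
    cov = np.array([d["cov"] for d in per_sample])
    bases = np.array([[d.get(b, 0) for b in "ACGT"] for d in per_sample])
    ins = np.array([d.get("ins", 0) for d in per_sample])
    dele = np.array([d.get("del", 0) for d in per_sample])
    return vc.SiteCounts("chr1", pos, ref_base, samples, cov, bases, ins, dele)


def exact_fisher_tail(alt_m, ref_m, alt_o, ref_o):
    """Exact one-sided hypergeometric tail P(X >= alt_m) via integer
    enumeration; independent of scipy."""
    M = alt_m + ref_m + alt_o + ref_o
    n_alt = alt_m + alt_o
    N_row = alt_m + ref_m
    denom = comb(M, n_alt)
    num = sum(comb(N_row, k) * comb(M - N_row, n_alt - k)
              for k in range(alt_m, min(n_alt, N_row) + 1))
    return Fraction(num, denom)


class TestDetectCandidates:
    def test_clear_het_against_clean_cohort(self):
        site = make_site("A", [{"cov": 30, "A": 15, "C": 15}]
                         + [{"cov": 30, "A": 30}] * 4)
        cand = vc.detect_candidates(site)
        assert cand is not None
        assert (cand.sample, cand.alt, cand.type) == ("s1", "C", "SNV")
        assert (cand.alt_count, cand.ref_count) == (15, 15)

    def test_shared_variant_is_not_unique(self):
        site = make_site("A", [{"cov": 30, "A": 15, "C": 15}] * 2
                         + [{"cov": 30, "A": 30}] * 3)
        assert vc.detect_candidates(site) is None

    def test_noisy_other_sample_blocks_candidate(self):
        # other sample ref freq 27/30 = 0.9 < 0.93
        site = make_site("A", [{"cov": 30, "A": 15, "C": 15},
                               {"cov": 30, "A": 27, "C": 3},
                               {"cov": 30, "A": 30}])
        assert vc.detect_candidates(site) is None

    def test_zero_coverage_sample_skips_site(self):
        site = make_site("A", [{"cov": 30, "A": 15, "C": 15}, {"cov": 0}])
        assert vc.detect_candidates(site) is None

    def test_indel_candidate(self):
        site = make_site("A", [{"cov": 30, "A": 16, "del": 14}]
                         + [{"cov": 30, "A": 30}] * 3)
        cand = vc.detect_candidates(site)
        assert cand.type == "DEL" and cand.sample == "s1"


class TestFisherScore:
    def test_het_vs_clean_matches_enumeration(self):
        """(15,15) vs (0,30): score equals -log10 of the exact
        hypergeometric tail of the 2x2 table with margins (30,30;15,45)."""
        expected = -math.log10(float(exact_fisher_tail(15, 15, 0, 30)))
        assert vc.fisher_score(15, 15, 0, 30) == pytest.approx(expected, abs=1e-9)

    def test_identical_tables_score_below_p_half_bound(self):
        # symmetric tables: tail >= 0.5, so score < log10(2) + eps
        assert vc.fisher_score(15, 15, 15, 15) < 0.31

    def test_score_monotone_in_other_alt_count(self):
        scores = [vc.fisher_score(15, 15, a, 30 - a) for a in range(0, 16)]
        assert all(x >= y - 1e-12 for x, y in zip(scores, scores[1:]))

    def test_score_candidate_uses_noisiest_comparison_sample(self):
        site = make_site("A", [{"cov": 30, "A": 15, "C": 15},
                               {"cov": 30, "A": 30},
                               {"cov": 30, "A": 28, "C": 2}])
        cand = vc.detect_candidates(
            site, vc.CallerParams(min_other_ref_freq=0.9))
        score = vc.score_candidate(site, cand)
        expected = -math.log10(float(exact_fisher_tail(15, 15, 2, 28)))
        assert score == pytest.approx(expected, abs=1e-9)

    @given(st.integers(0, 15), st.integers(0, 15), st.integers(0, 15),
           st.integers(0, 15))
    def test_matches_exact_enumeration_for_small_tables(self, a, b, c, d):
        p = float(exact_fisher_tail(a, b, c, d))
        expected = -math.log10(max(p, 1e-300))
        assert vc.fisher_score(a, b, c, d) == pytest.approx(expected, abs=1e-9)


class TestCalibration:
    def _calls(self, per_clone_scores, mtype="SNV"):
        rows = []
        for clone, scores in per_clone_scores.items():
            for s in scores:
                rows.append({"sample": clone, "contig": "chr1", "pos": 1,
                             "ref": "A", "alt": "C", "type": mtype,
                             "score": s, "vaf": 0.5})
        return pd.DataFrame(rows)

    def test_sweep_example_leaves_five_snvs(self):
        """Scores {1.2,2.0,3.5,4.0,4.1,4.2,9.9}: with inclusive >= the
        smallest threshold leaving <=5 calls is 3.5 (exhaustive sweep)."""
        scores = [1.2, 2.0, 3.5, 4.0, 4.1, 4.2, 9.9]
        calls = self._calls({"c1": scores})
        cal = vc.calibrate_threshold(calls, ["c1"])
        assert cal.snv_threshold == 3.5
        # exhaustive oracle over observed scores
        oracle = min(t for t in [0.0] + scores
                     if sum(s >= t for s in scores) <= 5)
        assert cal.snv_threshold == oracle

    def test_no_control_calls_gives_zero_thresholds(self):
        cal = vc.calibrate_threshold(self._calls({}), ["c1"])
        assert (cal.snv_threshold, cal.ins_threshold, cal.del_threshold) == (0, 0, 0)

    def test_all_equal_scores(self):
        # count within bound: threshold equals the score's minimum... the
        # sweep picks 0.0 since 5 calls already satisfy the bound
        cal = vc.calibrate_threshold(self._calls({"c1": [2.0] * 5}), ["c1"])
        assert cal.snv_threshold == 0.0
        # over the bound with all-equal scores: just above the score
        cal = vc.calibrate_threshold(self._calls({"c1": [2.0] * 7}), ["c1"])
        assert cal.snv_threshold == np.nextafter(2.0, np.inf)

    def test_threshold_is_minimal(self):
        rng = np.random.default_rng(0)
        scores = list(np.round(rng.uniform(0, 10, 40), 3))
        calls = self._calls({"c1": scores, "c2": scores[:20]})
        cal = vc.calibrate_threshold(calls, ["c1", "c2"])
        t = cal.snv_threshold
        for clone_scores in (scores, scores[:20]):
            assert sum(s >= t for s in clone_scores) <= 5
        # any smaller observed score violates some bound
        smaller = [s for s in set(scores) if s < t]
        for cand in smaller:
            assert any(sum(s >= cand for s in cs) > 5
                       for cs in (scores, scores[:20]))

    def test_indel_bounds_are_one(self):
        calls = pd.concat([
            self._calls({"c1": [1.0, 2.0, 3.0]}, "INS"),
            self._calls({"c1": [1.0, 2.0]}, "DEL"),
        ])
        cal = vc.calibrate_threshold(calls, ["c1"])
        # bound is <=1 surviving call per type
        assert cal.ins_threshold == 3.0
        assert cal.del_threshold == 2.0

    def test_empty_control_set_rejected(self):
        with pytest.raises(ValueError):
            vc.calibrate_threshold(self._calls({}), [])


class TestCallMutations:
    def test_zero_error_run_has_perfect_precision_and_high_sensitivity(
            self, small_reference, default_signatures):
        """With no sequencing noise every call is a planted mutation and
        >=99% of planted het SNVs are recovered."""
        from platmut.group_stats import TreatmentGroup

        direct, bg = default_signatures
        design = sd.ExperimentDesign(
            groups=[TreatmentGroup("drug", "IC50", "synthetic", ("a", "b", "c"))],
            mutations_per_clone={"drug_IC50": (400, 0.5)},
            seq_error_rate=0.0, seed=21)
        truth = sd.plant_mutations(small_reference, design, direct, bg)
        counts = sd.emit_counts(small_reference, truth, design, noise_sites=4000)
        raw = vc.detect_and_score(counts)
        cal = vc.CalibrationResult(0.0, 0.0, 0.0)
        calls = vc.call_mutations(counts, vc.CallerParams(), cal, small_reference)
        truth_keys = set(zip(truth["clone"], truth["contig"], truth["pos"]))
        call_keys = set(zip(calls["sample"], calls["contig"], calls["pos"]))
        assert call_keys <= truth_keys  # precision 1.0
        snv_truth = truth[truth["type"] == "SNV"]
        snv_keys = set(zip(snv_truth["clone"], snv_truth["contig"], snv_truth["pos"]))
        snv_calls = calls[calls["type"] == "SNV"]
        found = set(zip(snv_calls["sample"], snv_calls["contig"], snv_calls["pos"]))
        assert len(found & snv_keys) / len(snv_keys) >= 0.99

    def test_sensitivity_with_noise(self, small_cohort):
        """Planted het SNVs at 30x and 1e-3 error: sensitivity >= 0.95."""
        design, truth, counts = small_cohort
        raw = vc.detect_and_score(counts)
        cal = vc.calibrate_threshold(raw, ["ctrl_1", "ctrl_2"])
        calls = vc.call_mutations(counts, vc.CallerParams(), cal)
        snv_truth = truth[truth["type"] == "SNV"]
        truth_keys = set(zip(snv_truth["clone"], snv_truth["contig"], snv_truth["pos"]))
        snvs = calls[calls["type"] == "SNV"]
        found = set(zip(snvs["sample"], snvs["contig"], snvs["pos"]))
        assert len(found & truth_keys) / len(truth_keys) >= 0.95

    def test_vectorized_matches_per_site_logic(self, small_cohort):
        """detect_and_score agrees with detect_candidates/score_candidate
        applied site by site."""
        _, _, counts = small_cohort
        sub = counts.head(400)
        raw = vc.detect_and_score(sub)
        samples, cov, bases, ins, dele, ref_idx = vc._counts_arrays(sub)
        expected = []
        for i in range(len(sub)):
            site = vc.SiteCounts(sub["contig"].iloc[i], int(sub["pos"].iloc[i]),
                                 sub["ref_base"].iloc[i], tuple(samples),
                                 cov[i], bases[i], ins[i], dele[i])
            cand = vc.detect_candidates(site)
            if cand:
                expected.append((cand.sample, site.contig, site.pos, cand.type,
                                 round(vc.score_candidate(site, cand), 9)))
        got = [(r.sample, r.contig, r.pos, r.type, round(r.score, 9))
               for r in raw.itertuples(index=False)]
        assert sorted(got) == sorted(expected)

    def test_shared_ancestral_variant_never_called(self):
        rows = {"contig": ["chr1"], "pos": [50], "ref_base": ["A"]}
        for s in ("a", "b", "c"):
            rows.update({f"{s}.cov": [30], f"{s}.A": [15], f"{s}.C": [15],
                         f"{s}.G": [0], f"{s}.T": [0],
                         f"{s}.ins_support": [0], f"{s}.del_support": [0]})
        counts = pd.DataFrame(rows)
        assert len(vc.detect_and_score(counts)) == 0

    def test_deterministic_call_set(self, small_cohort):
        _, _, counts = small_cohort
        a = vc.detect_and_score(counts.head(2000))
        b = vc.detect_and_score(counts.head(2000))
        pd.testing.assert_frame_equal(a, b)
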