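"""Validation-engine tests: titration mechanics, scoring, concordance."""

import numpy as np
import pytest

from oncopanel.calling import CallerConfig, SitePileup, VariantCall, FilterStatus
from oncopanel.synthetic import build_reference_standard, make_snv_panel, simulate_pileups
from oncopanel.validation import (
    ConcordanceResult,
    TitrationPlan,
    classify_calls,
    downsample_pileups,
    maf_concordance,
    maf_stratum,
    method_concordance,
    pooled_sensitivity,
    replicate_count,
    reproducibility,
    run_titration,
)


def _call(chrom, pos, ref, alt, depth=1000, alt_count=100):
    return VariantCall(chrom, pos, ref, alt, depth, alt_count, FilterStatus.PASS)


class TestReplicateCount:
    @pytest.mark.parametrize("depth,expected", [(300, 10), (500, 10), (550, 3), (700, 3), (1000, 3)])
    def test_ten_low_three_high(self, depth, expected):
        assert replicate_count(depth) == expected

    def test_off_grid_depth_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            replicate_count(475)


class TestMafStratum:
    @pytest.mark.parametrize(
        "maf,stratum",
        [(0.01, "lt5"), (0.0499, "lt5"), (0.05, "5to10"), (0.0999, "5to10"),
         (0.10, "ge10"), (0.70, "ge10")],
    )
    def test_half_open_boundaries(self, maf, stratum):
        assert maf_stratum(maf) == stratum


class TestDownsample:
    def test_target_equal_to_current_is_identity(self):
        pileups = [
            SitePileup("chr1", 10 + i, "A", {"A": 700, "G": 300}) for i in range(5)
        ]
        thin = downsample_pileups(pileups, 1000, seed=1)  # retention prob 1
        assert [p.allele_counts for p in thin] == [p.allele_counts for p in pileups]

    def test_halving_is_unbiased(self, deep_pileups):
        current = np.median([p.depth for p in deep_pileups])
        depths, fracs = [], []
        for seed in range(50):
            thin = downsample_pileups(deep_pileups, int(current) // 2, seed=seed)
            depths.append(np.median([p.depth for p in thin]))
            for orig, t in zip(deep_pileups, thin):
                for allele, c0 in orig.allele_counts.items():
                    if allele != orig.ref and c0 >= 50 and t.depth:
                        fracs.append(
                            (t.allele_counts.get(allele, 0) / t.depth)
                            / (c0 / orig.depth)
                        )
        assert np.mean(depths) == pytest.approx(current / 2, rel=0.05)
        assert np.mean(fracs) == pytest.approx(1.0, abs=0.03)  # alt fraction unbiased

    def test_deterministic(self, deep_pileups):
        a = downsample_pileups(deep_pileups, 300, seed=7)
        b = downsample_pileups(deep_pileups, 300, seed=7)
        assert [p.allele_counts for p in a] == [p.allele_counts for p in b]

    def test_target_above_current_rejected(self, deep_pileups):
        with pytest.raises(ValueError, match="exceeds"):
            downsample_pileups(deep_pileups, 10_000, seed=0)


class TestClassifyCalls:
    def test_perfect_calls(self, small_truth):
        calls = [_call(*v.key) for v in small_truth.variants]
        tp, fp, fn = classify_calls(calls, small_truth)
        assert len(tp) == len(small_truth) and not fp and not fn

    def test_wrong_alt_is_fp_and_leaves_fn(self, small_truth):
        v = small_truth.variants[0]
        wrong_alt = next(b for b in "ACGT" if b not in (v.ref, v.alt))
        calls = [_call(v.chrom, v.pos, v.ref, wrong_alt)]
        tp, fp, fn = classify_calls(calls, small_truth)
        assert not tp and len(fp) == 1
        assert v in fn

    def test_ppv_numerator_counts(self, small_truth):
        # 51 calls all matching truth variants -> PPV 51/51
        calls = [
            _call(v.chrom, v.pos, v.ref, v.alt)
            for v in list(small_truth.variants) * 10
        ][:51]
        tp, fp, _ = classify_calls(calls, small_truth)
        assert (len(tp), len(fp)) == (51, 0)

    def test_partition_is_conservative(self, small_truth):
        calls = [_call(*v.key) for v in small_truth.variants[:3]]
        tp, fp, fn = classify_calls(calls, small_truth)
        assert len(tp) + len(fn) == len(small_truth)


class TestRunTitration:
    def test_high_maf_full_sensitivity_without_noise(self):
        panel = make_snv_panel(10, seed=21)
        spec = [((t.chrom, t.pos, t.ref_base, "C" if t.ref_base != "C" else "G"), 0.25)
                for t in panel]
        truth = build_reference_standard(spec, "hi", panel=panel)
        pileups = simulate_pileups(truth, panel, 1000, error_rate=0.0, seed=2)
        plan = TitrationPlan(depth_grid=(1000,), reps_high=3)
        cells = run_titration(pileups, truth, plan, seed=4)
        ge10 = [c for c in cells if c.maf_stratum == "ge10"]
        assert ge10 and all(c.sensitivity == 1.0 for c in ge10)

    def test_limit_depth_saturates_above_threshold_strata(self):
        # at very deep coverage with zero error every variant strictly above
        # the 5% cut-off is found (a variant AT the cut-off is detected with
        # probability ~1/2 regardless of depth: its observed MAF straddles it)
        panel = make_snv_panel(8, seed=22)
        mafs = [0.06, 0.07, 0.08, 0.10, 0.20, 0.35, 0.5, 0.7]
        spec = [((t.chrom, t.pos, t.ref_base, "A" if t.ref_base != "A" else "T"), m)
                for t, m in zip(panel, mafs)]
        truth = build_reference_standard(spec, "deep", panel=panel)
        pileups = simulate_pileups(truth, panel, 100_000, error_rate=0.0, seed=3)
        plan = TitrationPlan(depth_grid=(100_000,))
        cells = run_titration(pileups, truth, plan, seed=5)
        assert pooled_sensitivity(cells, strata=("5to10", "ge10")) == 1.0

    def test_trial_accounting(self, deep_pileups, small_truth, panel_contexts):
        plan = TitrationPlan(depth_grid=(200, 800))
        cells = run_titration(deep_pileups, small_truth, plan, seed=6,
                              contexts=panel_contexts)
        for c in cells:
            assert c.n_detected <= c.n_trials
            reps = 10 if c.depth_target <= 500 else 3
            n_in_stratum = sum(
                1 for v in small_truth.variants
                if maf_stratum(v.expected_maf) == c.maf_stratum
            )
            assert c.n_trials == n_in_stratum * reps


class TestMafConcordance:
    def test_perfect_agreement(self):
        pairs = [(0.05, 0.05), (0.2, 0.2), (0.5, 0.5)]
        r, slope, intercept = maf_concordance(pairs)
        assert (r, slope, intercept) == pytest.approx((1.0, 1.0, 0.0))

    def test_proportional_bias_detected(self):
        pairs = [(0.1, 0.2), (0.2, 0.4), (0.3, 0.6)]
        r, slope, _ = maf_concordance(pairs)
        assert r == pytest.approx(1.0) and slope == pytest.approx(2.0)

    def test_binomial_sampling_keeps_high_correlation(self):
        rng = np.random.default_rng(8)
        expected = np.linspace(0.05, 0.70, 30)
        observed = rng.binomial(1000, expected) / 1000
        r, slope, _ = maf_concordance(list(zip(expected, observed)))
        assert r >= 0.99
        assert slope == pytest.approx(1.0, abs=0.05)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            maf_concordance([(0.1, 0.1), (0.1, 0.2), (0.1, 0.3)])
        with pytest.raises(ValueError):
            maf_concordance([(0.1, 0.1)])


class TestMethodConcordance:
    def test_identical_sets(self):
        calls = [_call("chr7", 100, "A", "G")]
        assert method_concordance(calls, calls).concordance == 1.0

    def test_disjoint_sets(self):
        a = [_call("chr7", 100, "A", "G")]
        b = [_call("chr7", 200, "C", "T")]
        assert method_concordance(a, b).concordance == 0.0

    def test_symmetric(self):
        a = [_call("chr7", 100, "A", "G"), _call("chr7", 300, "C", "T")]
        b = [_call("chr7", 100, "A", "G")]
        ab, ba = method_concordance(a, b), method_concordance(b, a)
        assert ab.concordance == ba.concordance
        assert (ab.only_a, ab.only_b) == (ba.only_b, ba.only_a)

    def test_restriction_to_tested_sites(self):
        a = [_call("chr7", 100, "A", "G"), _call("chr9", 1, "A", "C")]
        b = [_call("chr7", 100, "A", "G")]
        res = method_concordance(a, b, tested_sites=[("chr7", 100)])
        assert res.concordance == 1.0


class TestReproducibility:
    def _expected(self):
        spec = [
            (("chr12", 25398284, "C", "A"), 0.2),   # KRAS G12V-like
            (("chr12", 25398284, "C", "T"), 0.2),   # KRAS G12D-like
            (("chr17", 7577538, "C", "T"), 0.2),    # TP53 R248W-like
            (("chr17", 7577100, "CT", "C"), 0.2),   # TP53 frameshift-like
            (("chr7", 55259515, "T", "G"), 0.2),    # EGFR L858R-like
        ]
        return build_reference_standard(spec, "repro")

    def test_24_of_25_detections_gives_96_percent(self):
        expected = self._expected()
        full = [_call(*v.key) for v in expected.variants]
        reps = [("run1", full), ("run1", full), ("run1", full),
                ("run2", full), ("run3", full[:-1])]  # one miss: 24/25
        overall, inter, intra = reproducibility(reps, expected)
        assert overall == pytest.approx(0.96)

    def test_all_detected(self):
        expected = self._expected()
        full = [_call(*v.key) for v in expected.variants]
        overall, inter, intra = reproducibility(
            [("r1", full), ("r1", full), ("r2", full)], expected
        )
        assert (overall, inter, intra) == (1.0, 1.0, 1.0)

    def test_one_empty_replicate(self):
        expected = self._expected()
        full = [_call(*v.key) for v in expected.variants]
        reps = [("r1", full), ("r2", full), ("r3", full), ("r4", full), ("r5", [])]
        overall, _, _ = reproducibility(reps, expected)
        assert overall == pytest.approx(0.80)

    def test_empty_expected_rejected(self):
        empty = build_reference_standard([], "none")
        with pytest.raises(ValueError):
            reproducibility([("r1", []), ("r2", [])], empty)
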