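"""Generator tests: dilution arithmetic, sampling models, determinism."""

import numpy as np
import pytest

from oncopanel.synthetic import (
    CohortSimParams,
    build_reference_standard,
    default_cohort_params,
    make_snv_panel,
    mix_standards,
    simulate_cohort,
    simulate_pileups,
)


def _snv_spec(panel, mafs):
    spec = []
    for target, maf in zip(panel, mafs):
        alt = next(b for b in "ACGT" if b != target.ref_base)
        spec.append(((target.chrom, target.pos, target.ref_base, alt), maf))
    return spec


class TestBuildReferenceStandard:
    def test_multiplex_standard_size(self):
        # a 54-SNV multiplex with MAFs spanning 1-70%, like a mixed set of
        # commercial reference standards
        panel = make_snv_panel(54, seed=3)
        mafs = np.linspace(0.01, 0.70, 54)
        truth = build_reference_standard(_snv_spec(panel, mafs), "HD-like", panel=panel)
        assert len(truth) == 54
        assert {v.variant_class for v in truth.variants} == {"SNV"}

    def test_empty_spec_is_valid(self):
        assert len(build_reference_standard([], "empty")) == 0

    def test_duplicate_variant_rejected(self):
        spec = [(("chr1", 10, "A", "G"), 0.1), (("chr1", 10, "A", "G"), 0.2)]
        with pytest.raises(ValueError, match="duplicate"):
            build_reference_standard(spec, "dup")

    @pytest.mark.parametrize("maf", [0.0, 1.2, -0.1])
    def test_maf_outside_unit_interval_rejected(self, maf):
        with pytest.raises(ValueError):
            build_reference_standard([(("chr1", 10, "A", "G"), maf)], "bad")


class TestMixStandards:
    def test_one_to_one_dilution(self):
        a = build_reference_standard([(("chr1", 10, "A", "G"), 0.10)], "a")
        b = build_reference_standard([(("chr1", 99, "C", "T"), 0.30)], "b")
        mixed = mix_standards(a, b)
        by_key = mixed.by_key()
        assert by_key[("chr1", 10, "A", "G")].expected_maf == pytest.approx(0.05)
        assert by_key[("chr1", 99, "C", "T")].expected_maf == pytest.approx(0.15)

    def test_shared_variant_identity(self):
        a = build_reference_standard([(("chr1", 10, "A", "G"), 0.10)], "a")
        b = build_reference_standard([(("chr1", 10, "A", "G"), 0.10)], "b")
        assert mix_standards(a, b).variants[0].expected_maf == pytest.approx(0.10)

    def test_wildtype_mix_halves_all_mafs_exactly(self):
        # arithmetic oracle over every variant: 1:1 with wild type halves MAF
        panel = make_snv_panel(20, seed=4)
        mafs = np.linspace(0.05, 0.65, 20)
        std = build_reference_standard(_snv_spec(panel, mafs), "std", panel=panel)
        wt = build_reference_standard([], "wt")
        mixed = mix_standards(std, wt)
        assert len(mixed) == len(std)
        for v in std.variants:
            assert mixed.by_key()[v.key].expected_maf == v.expected_maf * 0.5

    def test_uneven_ratio_weighted_average(self):
        a = build_reference_standard([(("chr1", 10, "A", "G"), 0.40)], "a")
        b = build_reference_standard([(("chr1", 10, "A", "G"), 0.10)], "b")
        mixed = mix_standards(a, b, ratio=(0.25, 0.75))
        assert mixed.variants[0].expected_maf == pytest.approx(0.175)

    def test_ratio_must_sum_to_one(self):
        a = build_reference_standard([], "a")
        with pytest.raises(ValueError):
            mix_standards(a, a, ratio=(0.5, 0.6))


class TestSimulatePileups:
    def test_counts_conserve_depth(self, small_panel, small_truth):
        pileups = simulate_pileups(small_truth, small_panel, 800, seed=1)
        for p in pileups:
            assert sum(p.allele_counts.values()) == p.depth

    def test_alt_counts_match_binomial_mean(self):
        # one 50% variant at 1000x, no error: mean alt count over many
        # replicate simulations approaches Binomial(1000, 0.5) / depth ratio
        panel = make_snv_panel(1, seed=6)
        truth = build_reference_standard(_snv_spec(panel, [0.5]), "s", panel=panel)
        fractions = []
        for rep in range(200):
            (p,) = simulate_pileups(truth, panel, 1000, error_rate=0.0, seed=rep)
            alt = next(c for a, c in p.allele_counts.items() if a != p.ref and c)
            fractions.append(alt / p.depth)
        # SE of the mean fraction ~ sqrt(0.25/1000)/sqrt(200) ~ 0.0011
        assert np.mean(fractions) == pytest.approx(0.5, abs=0.005)

    def test_no_error_no_truth_gives_pure_reference(self, small_panel):
        truth = build_reference_standard([], "wt")
        pileups = simulate_pileups(truth, small_panel, 500, error_rate=0.0, seed=2)
        for p in pileups:
            assert p.allele_counts == {p.ref: p.depth}

    def test_deterministic_under_seed(self, small_panel, small_truth):
        a = simulate_pileups(small_truth, small_panel, 600, seed=42)
        b = simulate_pileups(small_truth, small_panel, 600, seed=42)
        assert [(p.pos, p.allele_counts) for p in a] == [
            (p.pos, p.allele_counts) for p in b
        ]

    def test_orphan_truth_variant_rejected(self, small_panel):
        orphan = build_reference_standard([(("chrZ", 1, "A", "G"), 0.2)], "orphan")
        with pytest.raises(ValueError, match="outside the panel"):
            simulate_pileups(orphan, small_panel, 100, seed=0)

    def test_indel_truth_alleles_round_trip(self):
        panel = make_snv_panel(2, seed=9)
        t0 = panel[0]
        ins = ((t0.chrom, t0.pos, t0.ref_base, t0.ref_base + "TGA"), 0.3)
        truth = build_reference_standard([ins], "indels")  # spelling kept on-site
        pileups = simulate_pileups(truth, panel, 1000, error_rate=0.0, seed=3)
        keys = set(pileups[0].allele_counts)
        assert "ins:TGA" in keys


class TestSimulateCohort:
    def test_zero_patients_yields_empty_outputs(self):
        params = CohortSimParams(n_patients=0, gene_baseline_rates={"EGFR": 0.4})
        variants, records = simulate_cohort(params)
        assert variants == [] and records == []

    def test_deterministic_under_seed(self):
        params = default_cohort_params(n_patients=60, seed=9)
        assert simulate_cohort(params) == simulate_cohort(params)

    def test_baseline_rate_recovered_without_effects(self):
        # law-of-large-numbers check: with all odds multipliers at 1 the
        # observed per-sample mutation rate matches the programmed baseline
        params = CohortSimParams(
            n_patients=10_000, gene_baseline_rates={"EGFR": 0.42}, seed=17
        )
        variants, records = simulate_cohort(params)
        rate = len({v.sample_id for v in variants}) / len(records)
        se = np.sqrt(0.42 * 0.58 / 10_000)
        assert abs(rate - 0.42) < 3 * se

    def test_unknown_gene_in_effects_rejected(self):
        with pytest.raises(ValueError, match="unknown gene"):
            CohortSimParams(
                n_patients=10,
                gene_baseline_rates={"EGFR": 0.4},
                covariate_effects={("NOPE", "gender", "female"): 2.0},
            )

    def test_unknown_characteristic_rejected(self):
        with pytest.raises(ValueError, match="unknown characteristic"):
            CohortSimParams(
                n_patients=10,
                gene_baseline_rates={"EGFR": 0.4},
                covariate_effects={("EGFR", "shoe_size", "42"): 2.0},
            )

    def test_multi_hit_allows_more_variants_than_carriers(self):
        params = default_cohort_params(n_patients=800, seed=23)
        variants, _ = simulate_cohort(params)
        egfr = [v for v in variants if v.gene == "EGFR"]
        carriers = {v.sample_id for v in egfr}
        assert len(egfr) > len(carriers)  # Poisson multi-hit occurs at n=800

    def test_na_rates_respected(self):
        params = default_cohort_params(n_patients=4000, seed=31)
        _, records = simulate_cohort(params)
        na_rate = sum(1 for r in records if r.smoking is None) / len(records)
        assert na_rate == pytest.approx(327 / 422, abs=0.03)
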