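"""Burden association machinery: collapsing, logistic fits against the 2×2
cross-product oracle, Fisher exact against hypergeometric enumeration,
subtype and heterogeneity analyses, and the single-variant screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom, kstest

from geneburden.association import (
    collapse_carriers,
    fisher_burden,
    fit_burden_logistic,
    heterogeneity_pdiff,
    run_association_suite,
    single_variant_screen,
    subtype_association,
)
from geneburden.qualify import build_variant_sets, QualificationParams


def two_by_two(ncc, ncn, n_cases, n_controls):
    carrier = np.concatenate(
        [np.ones(ncc), np.zeros(n_cases - ncc), np.ones(ncn), np.zeros(n_controls - ncn)]
    )
    status = np.concatenate([np.ones(n_cases), np.zeros(n_controls)])
    return carrier, status


def cross_product(ncc, ncn, n_cases, n_controls):
    return (ncc * (n_controls - ncn)) / ((n_cases - ncc) * ncn)


def fisher_enumeration(a, b, c, d):
    """Independent oracle: two-sided Fisher p by exhaustive hypergeometric
    enumeration (sum of point probabilities <= the observed one)."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    rv = hypergeom(n, row1, col1)
    lo, hi = max(0, col1 - (c + d)), min(row1, col1)
    p_obs = rv.pmf(a)
    return sum(rv.pmf(x) for x in range(lo, hi + 1) if rv.pmf(x) <= p_obs * (1 + 1e-7))


class TestCollapse:
    def test_indicator_semantics(self, small_cohort, qual_params):
        c = small_cohort
        sets = build_variant_sets(c.variants, c.transcripts, qual_params)
        carriers = collapse_carriers(c.genotypes, c.variant_index, sets)
        gene = "GENE_RISK"
        lof_idx = [c.variant_index[k] for k in sets[gene].lof]
        expect = (c.genotypes[:, lof_idx] > 0).any(axis=1)
        assert (carriers[f"{gene}:lof"].to_numpy() == expect.astype(int)).all()
        # combined row = elementwise OR of the class rows
        comb = carriers[f"{gene}:combined"]
        assert (
            comb == (carriers[f"{gene}:lof"] | carriers[f"{gene}:missense"])
        ).all()
        # indicator, not a count: never exceeds 1
        assert comb.max() <= 1

    def test_idempotent(self, small_cohort, qual_params):
        c = small_cohort
        sets = build_variant_sets(c.variants, c.transcripts, qual_params)
        a = collapse_carriers(c.genotypes, c.variant_index, sets)
        b = collapse_carriers(c.genotypes, c.variant_index, sets)
        pd.testing.assert_frame_equal(a, b)


class TestLogisticFit:
    def test_single_stratum_equals_cross_product(self):
        carrier, status = two_by_two(111, 32, 6211, 6019)
        res = fit_burden_logistic(carrier, status)
        assert res.or_estimate == pytest.approx(
            cross_product(111, 32, 6211, 6019), rel=1e-6
        )
        assert res.ci_low < res.or_estimate < res.ci_high

    @given(
        ncc=st.integers(2, 40), ncn=st.integers(2, 40),
        n_cases=st.integers(100, 800), n_controls=st.integers(100, 800),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_cross_product_identity_property(self, ncc, ncn, n_cases, n_controls):
        carrier, status = two_by_two(ncc, ncn, n_cases, n_controls)
        res = fit_burden_logistic(carrier, status)
        assert res.or_estimate == pytest.approx(
            cross_product(ncc, ncn, n_cases, n_controls), rel=1e-6
        )

    def test_null_effect(self):
        carrier, status = two_by_two(50, 50, 5000, 5000)
        res = fit_burden_logistic(carrier, status)
        assert res.or_estimate == pytest.approx(1.0, abs=1e-6)
        assert res.p_value > 0.9

    def test_separation_convention(self):
        # zero carrier controls: diverged positive coefficient
        carrier, status = two_by_two(4, 0, 6211, 6019)
        res = fit_burden_logistic(carrier, status)
        assert res.separation_flag
        assert res.or_estimate == np.inf
        assert res.ci_low == 0.0 and res.ci_high == np.inf
        assert res.p_value > 0.9
        # zero carrier cases: diverged negative
        carrier, status = two_by_two(0, 4, 6211, 6019)
        res = fit_burden_logistic(carrier, status)
        assert res.separation_flag and res.or_estimate == 0.0

    def test_degenerate_inputs_flagged(self):
        carrier, status = two_by_two(0, 0, 100, 100)
        assert fit_burden_logistic(carrier, status).degenerate
        res = fit_burden_logistic(np.ones(10), np.ones(10))
        assert res.degenerate

    def test_adding_noncarriers_keeps_separation_flag(self):
        carrier, status = two_by_two(4, 0, 100, 100)
        res = fit_burden_logistic(carrier, status)
        assert res.separation_flag
        carrier2 = np.concatenate([carrier, [0, 0]])
        status2 = np.concatenate([status, [1, 0]])
        assert fit_burden_logistic(carrier2, status2).separation_flag

    def test_wald_p_invariant_under_stratum_relabeling(self):
        rng = np.random.default_rng(8)
        n = 2000
        carrier = (rng.random(n) < 0.02).astype(int)
        status = (rng.random(n) < 0.5).astype(int)
        study = rng.choice(["u", "v", "w"], n)
        p1 = fit_burden_logistic(carrier, status, study).p_value
        relabel = {"u": "z9", "v": "a0", "w": "m5"}
        study2 = np.array([relabel[s] for s in study], dtype=object)
        p2 = fit_burden_logistic(carrier, status, study2).p_value
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_adjustment_shifts_or_under_confounding(self):
        # stratum with high baseline carrier odds and high case fraction
        rng = np.random.default_rng(12)
        n_a, n_b = 3000, 3000
        study = np.array(["A"] * n_a + ["B"] * n_b, dtype=object)
        status = np.concatenate(
            [(rng.random(n_a) < 0.7), (rng.random(n_b) < 0.3)]
        ).astype(int)
        p_carrier = np.where(study == "A", 0.04, 0.005)
        carrier = (rng.random(n_a + n_b) < p_carrier).astype(int)
        crude = fit_burden_logistic(carrier, status).or_estimate
        adjusted = fit_burden_logistic(carrier, status, study).or_estimate
        # positive confounding: the crude OR sits well above the adjusted
        # (within-stratum null) estimate
        assert crude > 1.2 * adjusted


class TestFisher:
    def test_symmetric_table(self):
        or_, p = fisher_burden(2, 4, 2, 4)
        assert or_ == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_crude_cross_product(self):
        or_, _ = fisher_burden(11, 6211, 1, 6019)
        assert or_ == pytest.approx((11 * 6018) / (6200 * 1), rel=1e-9)

    def test_zero_cell_coding(self):
        assert fisher_burden(3, 10, 0, 10)[0] == np.inf
        assert fisher_burden(0, 10, 3, 10)[0] == 0.0

    def test_matches_enumeration_for_small_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(60):
            n_cases = int(rng.integers(2, 31))
            n_controls = int(rng.integers(2, 31))
            a = int(rng.integers(0, n_cases + 1))
            c = int(rng.integers(0, n_controls + 1))
            _, p = fisher_burden(a, n_cases, c, n_controls)
            expect = fisher_enumeration(a, n_cases - a, c, n_controls - c)
            assert p == pytest.approx(expect, rel=1e-6), (a, n_cases, c, n_controls)

    def test_counts_exceeding_groups_rejected(self):
        with pytest.raises(ValueError):
            fisher_burden(5, 4, 0, 10)


def make_samples(n_cases, n_controls, er_neg=0, er_pos=0, seed=0):
    rng = np.random.default_rng(seed)
    er = ["neg"] * er_neg + ["pos"] * er_pos + ["unknown"] * (n_cases - er_neg - er_pos)
    return pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(n_cases + n_controls)],
            "status": ["case"] * n_cases + ["control"] * n_controls,
            "er_status": er + ["unknown"] * n_controls,
            "study": rng.choice(["A", "B"], n_cases + n_controls),
        }
    )


class TestSubtype:
    def test_restricted_crude_or_matches_oracle(self):
        # ER- cases 16/808 carriers vs controls 31/6019, single stratum
        samples = make_samples(6211, 6019, er_neg=808, er_pos=2764)
        samples["study"] = "A"
        carrier = np.zeros(len(samples), dtype=int)
        carrier[:16] = 1          # first 16 cases are ER- carriers
        carrier[6211:6211 + 31] = 1
        res = subtype_association(carrier, samples, "er_neg")
        assert res.n_cases == 808 and res.n_controls == 6019
        assert res.or_estimate == pytest.approx(
            (16 * 5988) / (792 * 31), rel=1e-6
        )

    def test_zero_carrier_subtype_flagged(self):
        samples = make_samples(100, 100, er_neg=30, er_pos=50)
        carrier = np.zeros(200, dtype=int)
        carrier[150:155] = 1  # control carriers only
        res = subtype_association(carrier, samples, "er_neg")
        assert res.separation_flag and res.or_estimate == 0.0

    def test_subtypes_partition_typed_cases(self):
        samples = make_samples(200, 100, er_neg=60, er_pos=90)
        carrier = np.zeros(300, dtype=int)
        carrier[:5] = 1
        neg = subtype_association(carrier, samples, "er_neg")
        pos = subtype_association(carrier, samples, "er_pos")
        assert neg.n_cases + pos.n_cases == 150  # typed cases only
        assert neg.n_cases + pos.n_cases < 200

    def test_no_labeled_cases_returns_none(self):
        samples = make_samples(50, 50)
        assert subtype_association(np.zeros(100), samples, "er_neg") is None


class TestHeterogeneity:
    def test_identical_frequency_null(self):
        samples = make_samples(400, 10, er_neg=100, er_pos=300)
        carrier = np.zeros(410, dtype=int)
        carrier[:10] = 1            # 10% of ER- cases
        carrier[100:130] = 1        # 10% of ER+ cases
        res = heterogeneity_pdiff(carrier, samples)
        assert res.p_diff >= 0.9

    def test_concentrated_carriers_agree_with_fisher(self):
        # all carriers in one subtype separates the case-only logistic, so
        # the default method must fall back to the exact test
        samples = make_samples(600, 10, er_neg=200, er_pos=400)
        carrier = np.zeros(610, dtype=int)
        carrier[:12] = 1  # all carriers ER-
        logit = heterogeneity_pdiff(carrier, samples, method="logistic")
        fisher = heterogeneity_pdiff(carrier, samples, method="fisher")
        assert fisher.method == "fisher"
        assert logit.method == "case_only_fisher_fallback"
        assert logit.p_diff <= 2 * fisher.p_diff
        assert fisher.p_diff <= 2 * max(logit.p_diff, 1e-12)

    def test_near_concentrated_wald_tracks_fisher(self):
        # unbalanced but unseparated: Wald and exact p within a factor of 2
        samples = make_samples(600, 10, er_neg=200, er_pos=400)
        carrier = np.zeros(610, dtype=int)
        carrier[:10] = 1        # 10 ER- carriers
        carrier[200:206] = 1    # 6 ER+ carriers
        logit = heterogeneity_pdiff(carrier, samples, method="logistic")
        fisher = heterogeneity_pdiff(carrier, samples, method="fisher")
        assert logit.method == "case_only_logistic"
        assert logit.p_diff <= 2 * fisher.p_diff
        assert fisher.p_diff <= 2 * logit.p_diff

    def test_no_typed_carriers_is_no_data(self):
        samples = make_samples(100, 10, er_neg=30, er_pos=40)
        res = heterogeneity_pdiff(np.zeros(110, dtype=int), samples)
        assert res.p_diff is None

    def test_permutation_null_is_uniform(self):
        rng = np.random.default_rng(42)
        n_neg, n_pos = 400, 800
        samples = make_samples(n_neg + n_pos, 5, er_neg=n_neg, er_pos=n_pos, seed=1)
        base_carrier = (rng.random(n_neg + n_pos + 5) < 0.08).astype(int)
        er_case = samples["er_status"].to_numpy()[: n_neg + n_pos].copy()
        pvals = []
        for _ in range(1000):
            perm = samples.copy()
            perm.loc[: n_neg + n_pos - 1, "er_status"] = rng.permutation(er_case)
            pvals.append(heterogeneity_pdiff(base_carrier, perm).p_diff)
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestSingleVariantScreen:
    def _cohort(self, case_carriers, control_carriers):
        from geneburden.qualify import Consequence, Variant

        n_cases, n_controls = 50, 50
        samples = make_samples(n_cases, n_controls)
        v = Variant(chrom="1", pos=100, ref="G", alt="A", gene_id="G1",
                    consequence=Consequence.STOP_GAINED, maf=1e-3)
        geno = np.zeros((100, 1), dtype=np.int8)
        geno[:case_carriers, 0] = 1
        geno[n_cases:n_cases + control_carriers, 0] = 1
        return [v], geno, samples

    def test_inclusion_rule(self):
        tab = single_variant_screen(*self._cohort(2, 1))
        assert len(tab) == 1

    def test_case_minimum_excludes(self):
        tab = single_variant_screen(*self._cohort(1, 2))
        assert len(tab) == 0

    def test_case_only_carriers_flagged(self):
        tab = single_variant_screen(*self._cohort(3, 0))
        assert len(tab) == 1
        assert bool(tab["separation_flag"].iloc[0])


class TestSuite:
    def test_row_cartesian_count(self, small_cohort, qual_params):
        c = small_cohort
        sets = build_variant_sets(c.variants, c.transcripts, qual_params)
        suite = run_association_suite(c.samples, c.variants, c.genotypes, sets)
        # 2 genes x 3 classes x 3 subgroups
        assert len(suite.gene_results) == 18
        assert len(suite.heterogeneity) == 6

    def test_combined_carriers_bound_classes(self, small_cohort, qual_params):
        c = small_cohort
        sets = build_variant_sets(c.variants, c.transcripts, qual_params)
        suite = run_association_suite(c.samples, c.variants, c.genotypes, sets)
        overall = suite.gene_results.query("subgroup == 'overall'")
        for gene, grp in overall.groupby("gene_id"):
            counts = grp.set_index("variant_class")["n_carrier_cases"]
            assert counts["combined"] >= max(counts["lof"], counts["missense"])

    def test_deterministic(self, small_cohort, qual_params):
        c = small_cohort
        sets = build_variant_sets(c.variants, c.transcripts, qual_params)
        a = run_association_suite(c.samples, c.variants, c.genotypes, sets)
        b = run_association_suite(c.samples, c.variants, c.genotypes, sets)
        pd.testing.assert_frame_equal(a.gene_results, b.gene_results)

    def test_class_restriction_option(self, small_cohort, qual_params):
        c = small_cohort
        sets = build_variant_sets(c.variants, c.transcripts, qual_params)
        suite = run_association_suite(
            c.samples, c.variants, c.genotypes, sets, classes=("lof",)
        )
        assert set(suite.gene_results["variant_class"]) == {"lof"}

    def test_per_study_fisher_rows(self, small_cohort, qual_params):
        c = small_cohort
        sets = build_variant_sets(c.variants, c.transcripts, qual_params)
        suite = run_association_suite(
            c.samples, c.variants, c.genotypes, sets, per_study=True,
            classes=("lof",),
        )
        assert suite.per_study is not None
        assert (suite.per_study["method"] == "fisher").all()
        n_studies = c.samples["study"].nunique()
        assert len(suite.per_study) == 2 * n_studies
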