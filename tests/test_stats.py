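"""Statistical tests: exactness, calibration and the comparison battery."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from cpgnet import (
    AnnotationTable,
    UsageError,
    bh_adjust,
    chi2_2x2,
    hypergeom_enrichment,
    ks_two_sample,
    run_comparisons,
    wilcoxon_rank_sum,
)
from cpgnet.model import ClassificationTable

from oracles import hypergeom_oracle, wilcoxon_exact_oracle


class TestWilcoxon:
    def test_identical_samples_p_one(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_exact_small_sample(self):
        _, p = wilcoxon_rank_sum([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3)

    def test_empty_sample_rejected(self):
        with pytest.raises(UsageError):
            wilcoxon_rank_sum([], [1.0])

    @pytest.mark.parametrize(
        "n1,n2", [(n1, n2) for n1 in range(1, 6) for n2 in range(1, 6) if n1 + n2 <= 10]
    )
    def test_exact_matches_full_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        x = list(rng.permutation(n1 + n2)[:n1] + 0.0)
        y = [float(v) for v in range(100, 100 + n2)]
        # tie-free by construction except possible x/y overlap; shift y
        _, p = wilcoxon_rank_sum(x, y)
        assert p == pytest.approx(wilcoxon_exact_oracle(x, y), abs=1e-12)

    def test_large_shift_detected_by_both_tests(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 60)
        y = rng.normal(3, 1, 60)
        _, p_w = wilcoxon_rank_sum(x, y)
        _, p_k = ks_two_sample(x, y)
        assert p_w < 1e-3 and p_k < 1e-3


class TestKs:
    def test_identical_statistic_zero(self):
        stat, _ = ks_two_sample([1.0, 2.0], [1.0, 2.0])
        assert stat == 0.0

    def test_disjoint_statistic_one(self):
        stat, _ = ks_two_sample([0.0], [1.0])
        assert stat == 1.0


class TestChi2:
    def test_matches_closed_form_and_scipy(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            table = rng.integers(1, 200, size=(2, 2))
            stat, p = chi2_2x2(table)
            ref = sps.chi2_contingency(table, correction=False)
            assert stat == pytest.approx(ref.statistic, abs=1e-9)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)
            stat_y, p_y = chi2_2x2(table, yates=True)
            ref_y = sps.chi2_contingency(table, correction=True)
            assert stat_y == pytest.approx(ref_y.statistic, abs=1e-9)

    def test_proportional_rows_statistic_zero(self):
        stat, p = chi2_2x2([[7, 13], [7, 13]])
        assert stat == 0.0 and p == 1.0
        assert chi2_2x2([[5, 5], [5, 5]])[0] == 0.0

    def test_zero_margin_rejected(self):
        with pytest.raises(UsageError):
            chi2_2x2([[0, 0], [3, 4]])


class TestHypergeom:
    def annotation(self, hits):
        return AnnotationTable(
            feature_type="GO_MF",
            features={p: frozenset({"f"}) for p in hits},
        )

    def test_target_equals_background_p_one(self):
        background = {f"P{i}" for i in range(10)}
        results = hypergeom_enrichment(
            background, background, self.annotation(list(background)[:5])
        )
        assert all(r.p_value == pytest.approx(1.0) for r in results)

    def test_closed_form_urn(self):
        background = [f"P{i}" for i in range(10)]
        hits = background[:5]
        target = hits[:4]
        (result,) = hypergeom_enrichment(
            target, background, self.annotation(hits)
        )
        assert result.p_value == pytest.approx(5 / 210, abs=1e-12)

    def test_target_outside_background_rejected(self):
        with pytest.raises(UsageError):
            hypergeom_enrichment({"X"}, {"A"}, self.annotation(["A"]))

    def test_matches_enumeration_small_universe(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            n_bg = int(rng.integers(4, 16))
            background = [f"P{i}" for i in range(n_bg)]
            hits = list(
                rng.choice(background, size=int(rng.integers(1, n_bg + 1)), replace=False)
            )
            target = list(
                rng.choice(background, size=int(rng.integers(1, n_bg + 1)), replace=False)
            )
            (result,) = hypergeom_enrichment(
                target, background, self.annotation(hits)
            )
            expected = hypergeom_oracle(
                n_bg, len(hits), len(target), int(result.statistic)
            )
            assert result.p_value == pytest.approx(expected, abs=1e-12)


class TestBH:
    def test_hand_worked_example(self):
        adjusted = bh_adjust([0.01, 0.02, 0.03])
        assert list(adjusted) == pytest.approx([0.03, 0.03, 0.03])

    def test_monotone_after_sorting(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=20)
        adjusted = bh_adjust(p)
        assert (adjusted >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adjusted[order]) >= -1e-12).all()


class TestBattery:
    def test_planted_degree_shift_detected(self, pipeline_result):
        report = pipeline_result.comparisons
        row = report[
            (report["comparison"] == "degree: CP vs PP")
            & (report["test"] == "WILCOXON")
        ]
        assert float(row["p_value"].iloc[0]) < 0.05

    def test_planted_flag_contrasts_present(self, pipeline_result):
        report = pipeline_result.comparisons
        assert (report["test"] == "CHI2").sum() >= 6
        assert (report["test"] == "HYPERGEOM").sum() >= 1

    def test_empty_classification_rejected(self, pipeline_result):
        empty = ClassificationTable(
            group_label={},
            protein_label={},
            crosstalk=frozenset(),
            flow_critical=frozenset(),
        )
        with pytest.raises(UsageError):
            run_comparisons(
                pipeline_result.centralities,
                pipeline_result.group_sd,
                pipeline_result.specificity,
                {},
                empty,
            )

    def test_stars_follow_thresholds(self, pipeline_result):
        report = pipeline_result.comparisons
        for row in report.itertuples(index=False):
            p = row.adjusted_p if row.adjusted_p != "" else row.p_value
            p = float(p)
            expected = (
                "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""
            )
            assert row.star == expected
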