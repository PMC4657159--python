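"""Liability-threshold machinery and the end-to-end per-variant pipeline."""

import math

import pytest
from scipy.stats import norm

from polyherit.frequencies import PolymorphismRecord
from polyherit.liability import (
    combined_heritability,
    falconer_h2_first_degree,
    liability_stats,
    mean_liability_of_affected,
    polymorphism_heritability,
    upper_tail_threshold,
    variants_needed,
)

TRIAL_PREVALENCES = (0.006, 0.01, 0.015, 0.023, 0.085, 0.1, 0.14, 0.2)


def record(p, OR, P, **kwargs):
    return PolymorphismRecord("test", "test", P, OR, pop_freq=p, **kwargs)


class TestThreshold:
    @pytest.mark.parametrize("K, expected, tol", [
        (0.01, 2.32635, 5e-5),
        (0.5, 0.0, 1e-12),
        (0.011911, 2.25998, 5e-5),
    ])
    def test_values(self, K, expected, tol):
        assert upper_tail_threshold(K) == pytest.approx(expected, abs=tol)

    def test_domain(self):
        for K in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                upper_tail_threshold(K)


class TestMeanLiability:
    def test_one_percent_prevalence(self):
        assert mean_liability_of_affected(0.01) == pytest.approx(2.6652,
                                                                 abs=5e-4)

    def test_half_population(self):
        assert mean_liability_of_affected(0.5) == pytest.approx(
            math.sqrt(2.0 / math.pi), abs=1e-12)

    @pytest.mark.parametrize("K", TRIAL_PREVALENCES)
    def test_exceeds_threshold_and_self_consistent(self, K):
        stats = liability_stats(K)
        assert stats.mean_affected > stats.threshold
        assert stats.mean_affected == pytest.approx(
            float(norm.pdf(stats.threshold)) / K, abs=1e-14)


class TestFalconer:
    def test_worked_example(self):
        assert falconer_h2_first_degree(0.01, 0.011911) == pytest.approx(
            0.0498, abs=0.0005)

    def test_no_excess_recurrence(self):
        assert falconer_h2_first_degree(0.01, 0.01) == 0.0

    def test_negative_estimate_warns_not_clamps(self):
        with pytest.warns(UserWarning, match="negative"):
            h2 = falconer_h2_first_degree(0.02, 0.015)
        assert h2 < 0.0


class TestPipeline:
    @pytest.mark.parametrize("p, OR, P, expected, tol", [
        (0.000039, math.inf, 0.01, 0.0498, 0.0005),   # 16p11.2 dup
        (0.022, 14.8, 0.10, 0.1594, 0.001),           # 4p16.3 del
    ])
    def test_anchor_variants(self, p, OR, P, expected, tol):
        est = polymorphism_heritability(record(p, OR, P))
        assert est.h_p2 == pytest.approx(expected, abs=tol)

    def test_intermediates_consistent(self):
        est = polymorphism_heritability(record(0.000039, math.inf, 0.01))
        assert est.threshold_P == pytest.approx(2.32635, abs=5e-5)
        assert est.threshold_Q == pytest.approx(2.25998, abs=5e-5)
        assert est.mean_affected_P == pytest.approx(2.6652, abs=5e-4)
        assert est.h_p2 == pytest.approx(
            2.0 * (est.threshold_P - est.threshold_Q) / est.mean_affected_P,
            abs=1e-12)
        assert est.solved_freqs.u == 0.0039

    def test_or_one_gives_zero(self):
        est = polymorphism_heritability(record(0.1, 1.0, 0.05))
        assert est.h_p2 == 0.0

    def test_protective_allele_oriented_equals_preflipped(self):
        protective = polymorphism_heritability(record(0.063, 0.55, 0.015))
        preflipped = polymorphism_heritability(
            record(1.0 - 0.063, 1.0 / 0.55, 0.015))
        assert protective.flipped and not preflipped.flipped
        assert protective.h_p2 == pytest.approx(preflipped.h_p2, abs=1e-12)

    def test_monotone_in_odds_ratio(self):
        values = [polymorphism_heritability(record(0.01, OR, 0.05)).h_p2
                  for OR in (1.0, 1.5, 3.0, 10.0, 100.0)]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_sibling_request_carries_caveat(self):
        est = polymorphism_heritability(
            record(0.000039, math.inf, 0.01, relative="sibling"))
        assert any("de novo" in note for note in est.warnings)


class TestCombined:
    FREQS = (3.9e-05, 3.5e-05, 1.6e-05, 1.2e-05)   # four CNVs, one disease

    def records(self):
        return [record(p, math.inf, 0.01) for p in self.FREQS]

    def test_single_record_equals_pipeline(self):
        single = polymorphism_heritability(self.records()[0])
        assert combined_heritability(0.01, self.records()[:1]) == \
            pytest.approx(single.h_p2, abs=1e-12)

    def test_empty_list(self):
        assert combined_heritability(0.01, []) == 0.0

    def test_four_cnvs_bounded_by_singles(self):
        singles = [polymorphism_heritability(r).h_p2 for r in self.records()]
        combined = combined_heritability(0.01, self.records())
        assert max(singles) < combined < sum(singles)
        # regression pin; consistent with "about 15%" of a twin-study
        # schizophrenia heritability of ~0.8
        assert combined == pytest.approx(0.1172, abs=0.005)

    def test_mismatched_prevalence_rejected(self):
        with pytest.raises(ValueError, match="prevalence"):
            combined_heritability(0.02, self.records())


class TestVariantsNeeded:
    def naive(self, P, target, u, p, model):
        from polyherit.recurrence import attributable_excess
        excess = attributable_excess(P, u, p, model, "offspring")
        n = 0
        while True:
            n += 1
            if falconer_h2_first_degree(P, P + n * excess) >= target:
                return n

    def test_single_large_variant(self):
        # one 16p11.2-dup-sized variant already explains 0.0498
        assert variants_needed(0.01, 0.04, 0.0039, 3.9e-05, "AD") == 1

    @pytest.mark.parametrize("target", [0.05, 0.1, 0.4])
    def test_matches_naive_increment_loop(self, target):
        got = variants_needed(0.01, target, 0.0039, 3.9e-05, "AD")
        assert got == self.naive(0.01, target, 0.0039, 3.9e-05, "AD")

    def test_nonincreasing_in_effect_size(self):
        ns = [variants_needed(0.01, 0.4, p / 0.01, p, "AD")
              for p in (1e-05, 2e-05, 4e-05, 8e-05)]
        assert all(b <= a for a, b in zip(ns, ns[1:]))

    def test_null_variant_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            variants_needed(0.01, 0.4, 0.1, 0.1, "AD")
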