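"""Percent agreement, Bland–Altman, coincidence matrix, private variants."""

import math
import random

import pytest

from lbconcord import (Analyte, COMBINED, ContractError, PatientCohort,
                       analyte_private_variants, bland_altman,
                       coincidence_matrix, make_key, match_sets,
                       percent_concordance)
from lbconcord.dedup import KeyKind, VariantKey
from lbconcord.simulate import SyntheticConfig, generate_cohort

from conftest import make_variant


def _cohort_from_positions(spec):
    """Build a cohort from {pid: {analyte: [pos, ...]}} position lists."""
    cohort = PatientCohort()
    for pid, slots in spec.items():
        for analyte, positions in slots.items():
            cohort.add_variants(pid, analyte, [
                make_variant(patient_id=pid, analyte=analyte, pos=p)
                for p in positions])
    return cohort


class TestMatchSets:
    def _keys(self, positions):
        return {make_key(make_variant(pos=p)) for p in positions}

    def test_intersection(self):
        assert match_sets(self._keys([1, 2, 3]), self._keys([2, 3, 9])) == \
            self._keys([2, 3])

    def test_identical_and_disjoint(self):
        keys = self._keys([1, 2])
        assert match_sets(keys, keys) == keys
        assert match_sets(keys, self._keys([7, 8])) == set()

    def test_mixed_key_kinds_rejected(self):
        snv = {make_key(make_variant())}
        indel = {VariantKey(KeyKind.INDEL, ("1:5", "-", "ENST1"))}
        with pytest.raises(ContractError):
            match_sets(snv, indel)


class TestPercentConcordance:
    def test_identical_analyte_scores_100_everywhere(self):
        spec = {f"p{i}": {"tumor": [1, 2, 3], "ev": [1, 2, 3]}
                for i in range(1, 4)}
        result = percent_concordance(_cohort_from_positions(spec), "ev")
        assert all(p.percent == 100.0 for p in result.per_patient)
        assert result.mean_percent == 100.0

    def test_patient_without_tumor_excluded_not_scored(self):
        spec = {"p1": {"tumor": [1, 2], "ev": [1]},
                "p2": {"ev": [5, 6]}}
        result = percent_concordance(_cohort_from_positions(spec), "ev")
        assert [p.patient_id for p in result.per_patient] == ["p1"]
        assert "p2" in result.excluded
        assert result.mean_percent == pytest.approx(50.0)

    def test_combined_analyte_uses_union(self):
        spec = {"p1": {"tumor": [1, 2], "ev": [1], "cf": [2]}}
        cohort = _cohort_from_positions(spec)
        assert percent_concordance(cohort, "ev").mean_percent == 50.0
        assert percent_concordance(cohort, "cf").mean_percent == 50.0
        assert percent_concordance(cohort, COMBINED).mean_percent == 100.0

    def test_combined_never_below_single_analytes(self):
        cohort, _ = generate_cohort(SyntheticConfig(seed=5))
        ev = percent_concordance(cohort, "ev")
        cf = percent_concordance(cohort, "cf")
        both = percent_concordance(cohort, COMBINED)
        per_ev = {p.patient_id: p.percent for p in ev.per_patient}
        per_cf = {p.patient_id: p.percent for p in cf.per_patient}
        for p in both.per_patient:
            assert p.percent >= max(per_ev[p.patient_id],
                                    per_cf[p.patient_id]) - 1e-12
        assert both.mean_percent >= max(ev.mean_percent, cf.mean_percent)


class TestBlandAltman:
    def test_worked_example(self):
        # analyte counts below tumor counts: (8,10), (15,20), (28,30)
        result = bland_altman([(8, 10), (15, 20), (28, 30)])
        assert result.bias == pytest.approx(-3.0)
        assert result.sd == pytest.approx(math.sqrt(3.0), abs=1e-12)
        assert result.loa_low == pytest.approx(-3.0 - 1.96 * math.sqrt(3.0))
        assert result.loa_high == pytest.approx(-3.0 + 1.96 * math.sqrt(3.0))
        assert result.n_outside == 0

    def test_equal_pairs_collapse_limits(self):
        result = bland_altman([(5, 5), (7, 7), (9, 9)])
        assert result.bias == 0.0 and result.sd == 0.0
        assert (result.loa_low, result.loa_high) == (0.0, 0.0)

    def test_under_detection_gives_negative_bias(self):
        result = bland_altman([(80, 100), (90, 120), (70, 95), (60, 90)])
        assert result.bias < 0

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([(1, 1), (2, 2)])

    def test_matches_direct_recomputation_and_reordering(self):
        rng = random.Random(13)
        pairs = [(rng.randint(0, 200), rng.randint(0, 200))
                 for _ in range(25)]
        result = bland_altman(pairs)
        diffs = [a - t for a, t in pairs]
        n = len(diffs)
        bias = sum(diffs) / n
        sd = math.sqrt(sum((d - bias) ** 2 for d in diffs) / (n - 1))
        assert abs(result.bias - bias) < 1e-9
        assert abs(result.sd - sd) < 1e-9
        assert abs(result.loa_low - (bias - 1.96 * sd)) < 1e-9
        assert abs(result.loa_high - (bias + 1.96 * sd)) < 1e-9
        shuffled = pairs[:]
        rng.shuffle(shuffled)
        assert bland_altman(shuffled) == result


class TestCoincidenceMatrix:
    def test_union_column_forced_to_100(self):
        spec = {"p1": {"tumor": [1, 2], "ev": [1], "cf": [2]}}
        result = coincidence_matrix(_cohort_from_positions(spec))
        assert result.mean_percent["ev"] == 50.0
        assert result.mean_percent["cf"] == 50.0
        assert result.mean_percent[COMBINED] == 100.0
        assert result.n_variants == 2
        assert result.matrix.shape == (2, 3)

    def test_union_mean_dominates_singles(self):
        cohort, _ = generate_cohort(SyntheticConfig(seed=21))
        result = coincidence_matrix(cohort)
        assert result.mean_percent[COMBINED] >= \
            max(result.mean_percent["ev"], result.mean_percent["cf"])

    def test_independent_detection_union_rate(self):
        # ev 0.69, cf 0.67 independent: union detection 1 - 0.31*0.33
        config = SyntheticConfig(n_patients=100,
                                 tumor_variants_per_patient=20,
                                 ev_sensitivity=0.69, cf_sensitivity=0.67,
                                 private_rate_ev=0.0, private_rate_cf=0.0,
                                 seed=2026)
        cohort, _ = generate_cohort(config)
        result = coincidence_matrix(cohort, key_kind=None)
        expected = 100.0 * (1.0 - 0.31 * 0.33)
        assert result.mean_percent[COMBINED] == pytest.approx(expected, abs=2.0)


class TestPrivateVariants:
    def test_set_difference_per_patient(self):
        spec = {"p1": {"tumor": [1, 2], "ev": [1, 9], "cf": [1]},
                "p2": {"tumor": [5], "ev": [5], "cf": [5, 6, 7]}}
        cohort = _cohort_from_positions(spec)
        ev_private = analyte_private_variants(cohort, "ev")
        cf_private = analyte_private_variants(cohort, "cf")
        assert list(ev_private) == ["p1"] and len(ev_private["p1"]) == 1
        assert list(cf_private) == ["p2"] and len(cf_private["p2"]) == 2

    def test_analyte_subset_of_tumor_is_empty(self):
        spec = {"p1": {"tumor": [1, 2, 3], "ev": [1, 2]}}
        assert analyte_private_variants(_cohort_from_positions(spec),
                                        "ev") == {}


class TestParameterRecovery:
    @pytest.mark.parametrize("sensitivity,seed", [
        (0.5, 101), (0.7, 102), (0.9, 103)])
    def test_mean_concordance_recovers_sensitivity(self, sensitivity, seed):
        config = SyntheticConfig(
            n_patients=50, tumor_variants_per_patient=20,
            ev_sensitivity=sensitivity, cf_sensitivity=sensitivity,
            private_rate_ev=0.0, private_rate_cf=0.0, seed=seed)
        cohort, _ = generate_cohort(config)
        result = percent_concordance(cohort, "ev")
        assert result.mean_percent == pytest.approx(100.0 * sensitivity,
                                                    abs=3.0)
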