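import itertools

import pytest

from potencyclm.curation import Compound
from potencyclm.evaluation import (
    AC_CCR_SC,
    CATEGORIES,
    CCR_SC,
    assess_generation,
    assess_predictions,
    build_test_system,
    categorize,
    category_counts,
    diversity_stats,
    kcc_reproduction_stats,
    potency_gain_distribution,
)
from potencyclm.pairing import AnaloguePair


def cpd(smiles, pki, class_id="X"):
    return Compound(smiles=smiles, class_id=class_id, pki=pki)


def pair(sa, pa, sb, pb, core="core"):
    return AnaloguePair(cpd_a=cpd(sa, pa), cpd_b=cpd(sb, pb), core=core)


# toluene analogues: same CCR core, real molecules for core matching
TOL_F = "Cc1ccc(F)cc1"
TOL_CL = "Cc1ccc(Cl)cc1"
TOL_BR = "Cc1ccc(Br)cc1"
TOL_N = "Cc1ccc(N)cc1"
UNRELATED = "C1CCNCC1"


@pytest.fixture()
def system():
    # CCR pair: Δ = 1.9; AC-CCR pairs: Δ ≥ 2
    pairs = [
        pair(TOL_F, 5.2, TOL_CL, 7.1),            # CCR-SC TOL_F, KCC TOL_CL
        pair(TOL_F, 5.2, TOL_BR, 7.9),            # AC: TOL_F also AC-CCR-SC
        pair(TOL_N, 5.0, TOL_BR, 7.9),            # AC: TOL_N an AC-CCR-SC
    ]
    return build_test_system(pairs)


class TestBuildTestSystem:
    def test_threshold_split(self):
        system = build_test_system([pair(TOL_F, 5.2, TOL_CL, 7.1)])
        assert system.sources == {TOL_F: {CCR_SC}}
        assert system.kccs == {TOL_CL}

    def test_boundary_pki_six_is_source(self):
        system = build_test_system([pair(TOL_F, 6.0, TOL_CL, 8.1)])
        assert TOL_F in system.sources
        assert TOL_F not in system.kccs

    def test_overlapping_compound_keeps_both_labels(self, system):
        assert system.source_labels(TOL_F) == {CCR_SC, AC_CCR_SC}
        # pooled once in the unique compound sets
        assert TOL_F in system.ccr_compounds and TOL_F in system.ac_compounds


class TestAssessGeneration:
    def test_counts_invalid_fraction(self):
        valid, frac = assess_generation(["CCO", "C(C", "c1ccccc1"])
        assert len(valid) == 2
        assert frac == pytest.approx(1 / 3)

    def test_all_valid(self):
        _, frac = assess_generation(["CCO", "CCN"])
        assert frac == 0.0

    def test_duplicates_retained(self):
        valid, _ = assess_generation(["CCO", "OCC", "CCO"])
        assert valid == ["CCO", "CCO", "CCO"]

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            assess_generation([])


class TestCategorize:
    def test_known_ccr_same_core_is_1_1(self, system):
        assert categorize(CCR_SC, TOL_CL, system, TOL_F) == "1.1"

    def test_novel_different_core_is_2_6(self, system):
        assert categorize(AC_CCR_SC, UNRELATED, system, TOL_N) == "2.6"

    def test_known_ac_compound_from_ccr_source_same_core(self, system):
        assert categorize(CCR_SC, TOL_BR, system, TOL_F) == "1.3"

    def test_all_twelve_categories_reachable(self, system):
        """Brute-force sweep of the 2×3×2 outcome space."""
        seen = set()
        # TOL_CL: known CCR cpd; TOL_BR: known AC cpd; toluene analogue novel;
        # UNRELATED: novel, different core
        novel_same_core = "Cc1ccc(O)cc1"
        for label in (CCR_SC, AC_CCR_SC):
            for generated in (TOL_CL, TOL_BR, novel_same_core, UNRELATED):
                seen.add(categorize(label, generated, system, TOL_F))
        # different-core variants of the known compounds
        for label in (CCR_SC, AC_CCR_SC):
            for generated in (TOL_CL, TOL_BR):
                seen.add(categorize(label, generated, system, UNRELATED))
        assert seen == set(CATEGORIES)

    def test_bad_label_rejected(self, system):
        with pytest.raises(ValueError):
            categorize("SC", TOL_CL, system, TOL_F)


class TestBookkeeping:
    def test_category_counts_sum_to_valid_predictions(self, system):
        samples = {
            TOL_F: [TOL_CL, TOL_BR, "C(C", "Cc1ccc(O)cc1"],
            TOL_N: [TOL_BR, TOL_BR, UNRELATED],
        }
        records = assess_predictions(system, samples)
        n_valid = sum(r.valid for r in records)
        assert n_valid == 6
        counts = category_counts(records, unique=False)
        assert sum(counts.values()) == n_valid
        assert all(r.category is None for r in records if not r.valid)

    def test_each_valid_prediction_gets_exactly_one_category(self, system):
        records = assess_predictions(system, {TOL_F: [TOL_CL, TOL_BR, UNRELATED]})
        for r in records:
            assert r.valid and r.category in CATEGORIES

    def test_kcc_match_implies_valid_and_potent(self, system):
        records = assess_predictions(system, {TOL_F: [TOL_CL, "xxx", UNRELATED]})
        for r in records:
            if r.kcc_match:
                assert r.valid and system.pki[r.canonical] > 6.0


class TestKccStats:
    def _trials(self, system, reproduced_counts):
        trials = []
        kccs = sorted(system.kccs)
        for n in reproduced_counts:
            samples = {TOL_F: kccs[:n] + [UNRELATED]}
            trials.append(assess_predictions(system, samples))
        return trials

    def test_mean_and_proportion(self, system):
        # 2 KCCs available; trials reproduce 1, 2, 1 of them
        stats = kcc_reproduction_stats(system, self._trials(system, [1, 2, 1]))
        assert stats["kccs_available"] == 2
        assert stats["reproduced_kccs_mean"] == pytest.approx(4 / 3)
        assert stats["reproduced_pct"] == pytest.approx(100 * (4 / 3) / 2)
        assert stats["non_kccs_mean"] == 1.0

    def test_single_trial_sd_zero(self, system):
        stats = kcc_reproduction_stats(system, self._trials(system, [2]))
        assert stats["reproduced_kccs_sd"] == 0.0

    def test_trial_order_invariant(self, system):
        a = kcc_reproduction_stats(system, self._trials(system, [1, 2]))
        b = kcc_reproduction_stats(system, self._trials(system, [2, 1]))
        assert a == b

    def test_no_kccs_raises(self):
        system = build_test_system([pair(TOL_F, 4.0, TOL_CL, 5.9)])
        with pytest.raises(ValueError):
            kcc_reproduction_stats(system, [[]])

    def test_no_trials_raises(self, system):
        with pytest.raises(ValueError):
            kcc_reproduction_stats(system, [])


class TestDiversity:
    def test_series_and_singletons(self):
        generated = [TOL_F, TOL_CL, TOL_BR, UNRELATED, "CCCCCCCCCC"]
        stats = diversity_stats(generated, original_cores=set(), max_sites=1)
        assert stats["n_series"] >= 1
        assert stats["n_singletons"] == 2

    def test_superset_reproduces_all_cores(self):
        from potencyclm.evaluation import _cores_of

        originals = [TOL_F, TOL_CL]
        cores = set()
        for s in originals:
            cores.update(_cores_of(s, 1))
        stats = diversity_stats(originals + [UNRELATED], cores, max_sites=1)
        assert stats["core_reproduction_pct"] == 100.0

    def test_empty_generated_set(self):
        stats = diversity_stats([], {"c"}, max_sites=1)
        assert stats == {"n_series": 0, "n_singletons": 0,
                         "core_reproduction_pct": 0.0}


class TestPotencyGains:
    def test_median_of_three(self):
        pairs = [(cpd("a", 5.0), cpd("b", 6.0)), (cpd("a", 5.0), cpd("c", 7.0)),
                 (cpd("a", 5.0), cpd("d", 8.0))]
        stats = potency_gain_distribution(pairs)
        assert stats["median"] == pytest.approx(2.0)
        assert stats["n"] == 3

    def test_ac_dominated_fixture_median_above_two(self):
        pairs = [(cpd("a", 4.0), cpd(f"k{i}", 6.0 + 0.5 * i)) for i in range(5)]
        stats = potency_gain_distribution(pairs)
        assert stats["median"] >= 2.0

    def test_single_pair_no_outliers(self):
        stats = potency_gain_distribution([(cpd("a", 5.0), cpd("b", 7.5))])
        assert stats["median"] == pytest.approx(2.5)
        assert stats["outliers"] == []

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            potency_gain_distribution([])
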