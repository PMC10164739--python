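import pytest
from hypothesis import given
from hypothesis import strategies as st

from potencyclm.analogues import AnalogueSeries
from potencyclm.curation import Compound
from potencyclm.pairing import (
    AC_CCR,
    CCR,
    AnaloguePair,
    classify_pair,
    curate_triples,
    enumerate_pairs,
    make_triples,
    orient_ac_triple,
    split_finetune_test,
)


def cpd(name, pki, class_id="X"):
    return Compound(smiles=name, class_id=class_id, pki=pki)


def series(core, *compounds):
    return AnalogueSeries(core=core, members=tuple((c, ("sub",)) for c in compounds))


def pair(pa, pb, core="core1", class_id="X", a="A", b="B"):
    return AnaloguePair(cpd_a=cpd(a, pa, class_id), cpd_b=cpd(b, pb, class_id), core=core)


class TestEnumeratePairs:
    def test_four_members_six_pairs(self):
        s = series("c", *(cpd(f"m{i}", 5 + i) for i in range(4)))
        assert len(enumerate_pairs([s])) == 6

    def test_disjoint_series_additive(self):
        s1 = series("c1", *(cpd(f"a{i}", 5) for i in range(3)))
        s2 = series("c2", *(cpd(f"b{i}", 5) for i in range(2)))
        assert len(enumerate_pairs([s1, s2])) == 4

    def test_shared_pair_deduplicated_to_larger_core(self):
        a, b = cpd("A", 5), cpd("B", 7)
        small = series("C[*:1]", a, b)
        large = series("c1ccc(C[*:1])cc1", a, b)
        pairs = enumerate_pairs([small, large])
        assert len(pairs) == 1
        assert pairs[0].core == "c1ccc(C[*:1])cc1"


class TestMakeTriples:
    def test_two_triples_per_pair_antisymmetric(self):
        triples = make_triples([pair(5.0, 7.5)])
        assert len(triples) == 2
        assert sorted(t.delta for t in triples) == [-2.5, 2.5]

    @given(st.integers(min_value=0, max_value=25))
    def test_output_size_always_doubles(self, n):
        pairs = [pair(5, 6, a=f"A{i}", b=f"B{i}") for i in range(n)]
        assert len(make_triples(pairs)) == 2 * n


class TestClassifyPair:
    @pytest.mark.parametrize("delta,label", [
        (2.0, AC_CCR), (-2.0, AC_CCR), (1.99, CCR), (-1.99, CCR), (0.0, CCR), (3.7, AC_CCR),
    ])
    def test_threshold_inclusive_at_hundredfold(self, delta, label):
        assert classify_pair(pair(5.0, 5.0 + delta)) == label

    @given(st.floats(min_value=-6, max_value=6, allow_nan=False))
    def test_symmetric_in_orientation(self, delta):
        assert classify_pair(pair(5.0, 5.0 + delta)) == classify_pair(pair(5.0 + delta, 5.0))


class TestOrientAcTriple:
    @pytest.mark.parametrize("pa,pb", [(5.0, 8.0), (8.0, 5.0)])
    def test_weak_to_potent_regardless_of_input_order(self, pa, pb):
        t = orient_ac_triple(pair(pa, pb))
        assert (t.source.pki, t.target.pki, t.delta) == (5.0, 8.0, 3.0)

    def test_ccr_pair_rejected(self):
        with pytest.raises(ValueError):
            orient_ac_triple(pair(5.0, 6.0))


class TestCurateTriples:
    def test_ambiguous_source_delta_across_classes_removed(self):
        p1 = pair(5.0, 6.0, class_id="X", a="S", b="T1")
        p2 = pair(5.0, 6.0, class_id="Y", a="S", b="T2")
        assert curate_triples([p1, p2]) == []

    def test_identical_potencies_in_two_classes_retained(self):
        p1 = pair(5.0, 6.0, class_id="X", a="S", b="T")
        p2 = pair(5.0, 6.0, class_id="Y", a="S", b="T")
        assert curate_triples([p1, p2]) == [p1, p2]

    def test_differing_potencies_for_same_pair_removed(self):
        p1 = pair(5.0, 6.0, class_id="X", a="S", b="T")
        p2 = pair(5.2, 6.3, class_id="Y", a="S", b="T")
        assert curate_triples([p1, p2]) == []

    def test_no_collisions_is_identity(self):
        pairs = [pair(5, 6, a="A", b="B"), pair(4, 7, a="C", b="D")]
        assert curate_triples(pairs) == pairs

    def test_globally_unique_source_delta_never_removed(self):
        # distinct deltas everywhere → nothing can be ambiguous
        pairs = [pair(5, 5 + 0.1 * i, a=f"A{i}", b=f"B{i}",
                      class_id="X" if i % 2 else "Y") for i in range(1, 8)]
        assert curate_triples(pairs) == pairs


class TestSplit:
    def _pairs(self, n_cores=5, per_core=2, potent=True):
        out = []
        for c in range(n_cores):
            for i in range(per_core):
                out.append(pair(5.0, 8.0 if potent else 6.0, core=f"core{c}",
                                a=f"A{c}_{i}", b=f"B{c}_{i}"))
        return out

    def test_core_disjoint_and_approximate_fraction(self):
        ac = self._pairs(5, 2)
        sp = split_finetune_test(ac, [], fraction=0.8, seed=1)
        ft_cores, test_cores = sp.core_sets()
        assert not ft_cores & test_cores
        assert len(sp.finetune) == 8 and len(sp.test) == 2

    def test_ccr_pair_with_finetune_core_omitted(self):
        ac = self._pairs(5, 2)
        sp0 = split_finetune_test(ac, [], fraction=0.8, seed=3)
        ft_cores, _ = sp0.core_sets()
        shadowed = pair(5.0, 6.0, core=next(iter(ft_cores)), a="C1", b="C2")
        free = pair(5.0, 6.0, core="elsewhere", a="C3", b="C4")
        sp = split_finetune_test(ac, [shadowed, free], fraction=0.8, seed=3)
        assert shadowed not in sp.test
        assert free in sp.test

    def test_same_seed_is_deterministic(self):
        ac = self._pairs(7, 3)
        a = split_finetune_test(ac, [], 0.8, seed=9)
        b = split_finetune_test(ac, [], 0.8, seed=9)
        assert a == b

    def test_single_core_class_warns_and_empties_test(self, caplog):
        ac = self._pairs(1, 4)
        with caplog.at_level("WARNING"):
            sp = split_finetune_test(ac, [], 0.8, seed=0)
        assert len(sp.finetune) == 4 and sp.test == ()
        assert any("test side" in m for m in caplog.messages)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            split_finetune_test(self._pairs(), [], fraction=1.0, seed=0)
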