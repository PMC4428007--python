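"""Maximum RAF and maximum pseudo-RAF detection."""

import numpy as np
import pytest

from rafkit import (
    CRS,
    Reaction,
    check_subset,
    horn_max_praf,
    make_cross_catalytic_cycle,
    make_linear_chain,
    max_praf,
    max_raf_basic,
    max_raf_modified,
)
from conftest import brute_force_maxraf, naive_max_praf, random_mixed_crs, small_polymer


def single_raf_crs():
    return CRS(
        reactions=[Reaction(id="r1", reactants=frozenset({"f1", "f2"}), products=frozenset({"x"}))],
        catalysis=[("f1", "r1")],
        food=["f1", "f2"],
    )


class TestMaxPraf:
    def test_cycle_full_set_is_max_praf(self):
        crs = make_cross_catalytic_cycle()
        assert max_praf(crs, crs.reactions) == frozenset(crs.reactions)

    def test_chain_has_no_praf(self):
        crs = make_linear_chain(6)
        assert max_praf(crs, crs.reactions) == frozenset()

    def test_equals_iterated_p_and_hornsat_on_random_systems(self, rng):
        for _ in range(50):
            crs = random_mixed_crs(rng)
            full = frozenset(crs.reactions)
            fixp = max_praf(crs, full)
            assert fixp == naive_max_praf(crs, full)
            assert fixp == horn_max_praf(crs)

    def test_union_of_prafs_is_a_praf(self, rng):
        # union-closure: pseudo-RAFs found on random sub-systems stay pseudo-RAFs
        for _ in range(20):
            crs = random_mixed_crs(rng)
            rids = sorted(crs.reactions)
            union = set()
            for _ in range(4):
                sub = [r for r in rids if rng.random() < 0.6]
                praf = max_praf(crs, sub)
                if praf:
                    assert check_subset(crs, praf).is_praf
                union |= praf
            if union:
                assert check_subset(crs, union).is_praf


class TestMaxRAF:
    @pytest.mark.parametrize("N", [2, 5, 10])
    def test_chain_call_counts(self, N):
        crs = make_linear_chain(N)
        basic = max_raf_basic(crs)
        mod = max_raf_modified(crs)
        assert basic.subset == mod.subset == frozenset()
        assert basic.closure_calls == N - 1
        assert mod.closure_calls == 1

    def test_single_food_catalysed_reaction_is_immediate_fixed_point(self):
        crs = single_raf_crs()
        for fn in (max_raf_basic, max_raf_modified):
            res = fn(crs)
            assert res.subset == frozenset({"r1"})
            assert res.closure_calls == 1

    def test_empty_reaction_set_returns_empty_without_closure(self):
        crs = CRS(molecules=["f"], food=["f"])
        res = max_raf_basic(crs)
        assert res.subset == frozenset() and res.closure_calls == 0

    def test_all_uncatalysed_makes_one_confirming_call(self):
        crs = CRS(
            reactions=[Reaction(id="r1", reactants=frozenset({"f"}), products=frozenset({"x"}))],
            food=["f"],
        )
        for fn in (max_raf_basic, max_raf_modified):
            res = fn(crs)
            assert res.subset == frozenset() and res.closure_calls == 1

    def test_matches_brute_force_on_small_random_systems(self, rng):
        found_nonempty = 0
        for _ in range(50):
            crs = random_mixed_crs(rng, n_mol=8, n_rxn=8)
            oracle = brute_force_maxraf(crs)
            basic = max_raf_basic(crs)
            mod = max_raf_modified(crs)
            assert basic.subset == oracle
            assert mod.subset == oracle
            found_nonempty += bool(oracle)
        assert found_nonempty >= 5  # the generator must exercise both outcomes

    def test_modified_equals_basic_and_never_needs_more_closures(self):
        for seed in range(12):
            crs = small_polymer(seed, n=7, p_cat=0.0009)
            basic = max_raf_basic(crs)
            mod = max_raf_modified(crs)
            assert basic.subset == mod.subset
            assert mod.closure_calls <= basic.closure_calls

    def test_detected_rafs_contain_every_raf_subset(self, rng):
        # maxRAF is the union of all RAFs: any verified RAF subset lies inside
        for _ in range(20):
            crs = random_mixed_crs(rng, n_mol=8, n_rxn=8)
            maxraf = max_raf_modified(crs).subset
            rids = sorted(crs.reactions)
            for _ in range(10):
                sub = frozenset(r for r in rids if rng.random() < 0.5)
                if sub and check_subset(crs, sub).is_raf:
                    assert sub <= maxraf

    def test_working_set_descends_via_map_f(self, rng):
        from rafkit import map_f

        for _ in range(10):
            crs = random_mixed_crs(rng)
            current = frozenset(crs.reactions)
            while True:
                nxt = map_f(crs, current)
                assert nxt <= current
                if nxt == current:
                    break
                current = nxt
                if not current:
                    break
            assert current == max_raf_basic(crs).subset


class TestCheckSubset:
    def test_cycle_is_praf_not_f_generated(self):
        crs = make_cross_catalytic_cycle()
        flags = check_subset(crs, crs.reactions)
        assert flags.is_praf and not flags.is_f_generated and not flags.is_raf

    def test_empty_subset_vacuously_true_but_flagged_empty(self):
        crs = make_linear_chain(3)
        flags = check_subset(crs, [])
        assert flags.is_praf and flags.is_f_generated and flags.is_raf
        assert flags.is_empty

    def test_maxraf_outputs_pass_the_raf_check(self, rng):
        seen = 0
        for _ in range(50):
            crs = random_mixed_crs(rng)
            res = max_raf_modified(crs)
            if res.subset:
                seen += 1
                flags = check_subset(crs, res.subset)
                assert flags.is_raf and flags.is_praf and flags.is_f_generated
        assert seen >= 5

    def test_every_raf_is_a_praf_and_f_generated_praf_is_raf(self, rng):
        for _ in range(30):
            crs = random_mixed_crs(rng)
            sub = frozenset(r for r in crs.reactions if rng.random() < 0.5)
            flags = check_subset(crs, sub)
            assert flags.is_raf == (flags.is_praf and flags.is_f_generated)
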