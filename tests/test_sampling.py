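"""irrRAF sampling, overlap statistics and the birthday bound."""

import math
from fractions import Fraction

import numpy as np
import pytest

from rafkit import (
    AbstractRAFFamily,
    FamilyMaxRAFProvider,
    birthday_test,
    exact_sampler_distribution,
    make_four_irrraf_family,
    make_pair_family,
    overlap_stats,
    sample_irrraf,
    sample_irrrafs,
)
from rafkit.sampling import CrsMaxRAFProvider, average_overlap_exact
from conftest import small_polymer
from rafkit import max_raf_modified


def two_disjoint_family(size_a=1, size_b=3):
    a = frozenset(f"a{i}" for i in range(size_a))
    b = frozenset(f"b{i}" for i in range(size_b))
    return AbstractRAFFamily(labels=tuple(sorted(a) + sorted(b)), irrrafs=(a, b))


class TestSampler:
    def test_irreducible_start_returned_unchanged(self):
        fam = two_disjoint_family(2, 3)
        prov = FamilyMaxRAFProvider(fam)
        a = fam.irrrafs[0]
        rng = np.random.default_rng(0)
        for _ in range(10):
            assert sample_irrraf(prov, a, rng) == a

    def test_non_raf_start_rejected(self):
        fam = two_disjoint_family(2, 3)
        prov = FamilyMaxRAFProvider(fam)
        with pytest.raises(ValueError, match="not an RAF"):
            sample_irrraf(prov, frozenset({"a0"}), np.random.default_rng(0))

    def test_four_family_samples_land_on_listed_irrrafs(self):
        fam = make_four_irrraf_family()
        prov = FamilyMaxRAFProvider(fam)
        sample = sample_irrrafs(prov, fam.all_labels(), 400, seed=5)
        assert set(sample.samples) <= set(fam.irrrafs)
        assert sample.distinct_count == 4

    def test_sampled_sets_are_irreducible_rafs(self):
        crs = small_polymer(1, n=6, p_cat=0.004)
        base = max_raf_modified(crs)
        assert base.subset, "fixture instance must contain an RAF"
        prov = CrsMaxRAFProvider(crs, within=base.subset)
        sample = sample_irrrafs(prov, base.subset, 10, seed=9)
        for s in sample.samples:
            assert prov.maxraf(s) == s  # an RAF
            for rid in s:  # removing any reaction destroys it
                assert not prov.maxraf(s - {rid})

    def test_trivial_sample_counts(self):
        fam = two_disjoint_family(2, 2)
        prov = FamilyMaxRAFProvider(fam)
        s1 = sample_irrrafs(prov, fam.irrrafs[0], 1, seed=0)
        assert s1.distinct_count == 1
        s100 = sample_irrrafs(prov, fam.irrrafs[0], 100, seed=0)
        assert s100.distinct_count == 1

    def test_smaller_of_two_disjoint_found_more_often(self):
        fam = two_disjoint_family(1, 3)
        dist = exact_sampler_distribution(fam)
        small = dist[fam.irrrafs[0]]
        assert small >= Fraction(1, 2)

    def test_empirical_frequencies_match_exact_enumeration(self):
        fam = two_disjoint_family(1, 3)
        dist = exact_sampler_distribution(fam)
        prov = FamilyMaxRAFProvider(fam)
        S = 4000
        sample = sample_irrrafs(prov, fam.all_labels(), S, seed=17)
        for irr, p in dist.items():
            freq = sum(s == irr for s in sample.samples) / S
            se = math.sqrt(float(p) * (1 - float(p)) / S)
            assert abs(freq - float(p)) < 4 * se


class TestExactDistribution:
    def test_four_family_printed_probabilities(self):
        fam = make_four_irrraf_family()
        dist = exact_sampler_distribution(fam)
        by_size = {}
        for s, p in dist.items():
            by_size.setdefault(len(s), set()).add(p)
        assert by_size[4] == {Fraction(58, 231)}  # Pr[A] = Pr[B] = 0.25108225…
        assert by_size[3] == {Fraction(115, 462)}  # Pr[C] = Pr[D] = 0.24891775…
        assert float(Fraction(58, 231)) == pytest.approx(0.25108225, abs=5e-9)

    def test_probabilities_sum_to_one(self):
        for fam in (make_four_irrraf_family(), make_pair_family(3), two_disjoint_family(2, 2)):
            dist = exact_sampler_distribution(fam)
            assert sum(dist.values()) == 1

    def test_equal_sized_disjoint_irrrafs_are_equiprobable(self):
        fam = two_disjoint_family(2, 2)
        dist = exact_sampler_distribution(fam)
        assert set(dist.values()) == {Fraction(1, 2)}


class TestOverlapStats:
    def test_identical_samples_give_full_overlap_and_coverage(self):
        s = frozenset({"r1", "r2"})
        st = overlap_stats([s, s, s])
        assert st.average_overlap == 1.0
        assert st.average_coverage == 1.0

    def test_disjoint_samples_give_zero(self):
        st = overlap_stats([frozenset({"a"}), frozenset({"b"}), frozenset({"c"})])
        assert st.average_overlap == 0.0
        assert st.average_coverage == 0.0

    def test_subset_asymmetry(self):
        ri = frozenset({"r1", "r2"})
        rj = frozenset({"r1", "r2", "r3", "r4"})
        st = overlap_stats([ri, rj])
        assert st.pairwise[0, 1] == 1.0  # R_i ⊆ R_j
        assert st.pairwise[1, 0] == 0.5

    def test_pair_family_full_enumeration_gives_closed_form(self):
        fam = make_pair_family(3)
        st = overlap_stats(list(fam.irrrafs))
        assert st.average_overlap == pytest.approx(3 / 7, abs=1e-12)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            overlap_stats([frozenset({"a"})])

    def test_share_proportion_identity_matches_pairwise_path(self, rng):
        # O_i via p_i(r) equals O_i via pairwise averages, exactly on rationals
        for _ in range(20):
            n = int(rng.integers(3, 8))
            subsets = []
            for _ in range(n):
                k = int(rng.integers(1, 6))
                subsets.append(frozenset(f"r{j}" for j in rng.choice(10, size=k, replace=False)))
            O_exact, C_exact = average_overlap_exact(subsets)
            st = overlap_stats(subsets)
            assert st.average_overlap == pytest.approx(float(O_exact), abs=1e-12)
            assert st.average_coverage == pytest.approx(float(C_exact), abs=1e-12)
            # Boole bound: C_i <= (S-1) O_i
            assert np.all(st.per_irrraf_coverage <= (n - 1) * st.per_irrraf_overlap + 1e-12)


class TestBirthdayTest:
    def test_thousand_distinct_asserts_hundred_thousand(self):
        bt = birthday_test(1000, 1000)
        assert bt.reject
        assert bt.asserted_lower_bound == 100_000
        assert bt.p_bound < 0.01

    def test_fifty_thousand_distinct_asserts_quarter_billion(self):
        bt = birthday_test(50_000, 50_000)
        assert bt.reject
        assert bt.asserted_lower_bound == 2.5e8

    def test_any_repeat_accepts_null(self):
        bt = birthday_test(1000, 999)
        assert not bt.reject
        assert bt.asserted_lower_bound is None

    def test_bound_below_one_percent_for_all_s_over_30(self):
        for S in (30, 100, 1000):
            bt = birthday_test(S, S)
            lam = S * (S - 1) / 2 / (S * S / 10)
            assert bt.lam == pytest.approx(lam)
            assert bt.p_bound == pytest.approx(math.exp(-lam))
            assert bt.p_bound < 0.01

    def test_small_s_warns_and_bad_distinct_rejected(self):
        with pytest.warns(UserWarning):
            birthday_test(10, 10)
        with pytest.raises(ValueError):
            birthday_test(10, 11)
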