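"""Binary polymer model generator and worked example networks."""

from fractions import Fraction

import numpy as np
import pytest

from rafkit import (
    PolymerParams,
    add_inhibition,
    generate_polymer_crs,
    make_four_irrraf_family,
    make_linear_chain,
    make_pair_family,
    max_raf_basic,
    max_raf_modified,
    pair_family_overlap,
)
from rafkit.io import format_crs
from rafkit.polymer import polymer_molecule_count, polymer_reaction_count
from rafkit.sampling import average_overlap_exact


class TestGenerator:
    def test_counts_for_n8(self):
        crs = generate_polymer_crs(PolymerParams(n=8, t=2, seed=0))
        assert len(crs.molecules) == 510
        assert len(crs.food) == 6
        assert len(crs.reactions) == 3076

    def test_counts_for_n2(self):
        crs = generate_polymer_crs(PolymerParams(n=2, t=1, seed=0))
        assert len(crs.reactions) == 4  # one cut each of 00, 01, 10, 11
        assert len(crs.food) == 2
        assert all(r.reversible for r in crs.reactions.values())

    @pytest.mark.parametrize("n", range(2, 13))
    def test_reaction_count_closed_form(self, n):
        # |R| = sum_{L=2..n} 2^L (L-1), via explicit cut-site enumeration
        explicit = sum((L - 1) * 2**L for L in range(2, n + 1))
        assert polymer_reaction_count(n) == explicit
        if n <= 7:
            crs = generate_polymer_crs(PolymerParams(n=n, t=1, seed=0))
            assert len(crs.reactions) == explicit
            assert len(crs.molecules) == polymer_molecule_count(n)

    def test_catalysis_matches_binomial_expectation(self):
        # E|C| = |X| * |R| * p; the mean over seeds must land within 3 SE
        p = 0.00041
        sizes = [
            len(generate_polymer_crs(PolymerParams(n=8, t=2, p_cat=p, seed=s)).catalysis)
            for s in range(60)
        ]
        expected = 510 * 3076 * p
        se = np.sqrt(expected) / np.sqrt(len(sizes))  # Poisson-scale SE
        assert abs(np.mean(sizes) - expected) < 3 * se

    def test_determinism_byte_identical_output(self):
        a = generate_polymer_crs(PolymerParams(n=6, t=2, p_cat=0.002, seed=7))
        b = generate_polymer_crs(PolymerParams(n=6, t=2, p_cat=0.002, seed=7))
        assert format_crs(a) == format_crs(b)
        c = generate_polymer_crs(PolymerParams(n=6, t=2, p_cat=0.002, seed=8))
        assert format_crs(a) != format_crs(c)

    def test_raf_probability_monotone_in_catalysis_level(self):
        fracs = []
        for p in (0.00030, 0.00041, 0.00060):
            hits = 0
            for s in range(40):
                crs = generate_polymer_crs(PolymerParams(n=8, t=2, p_cat=p, seed=s))
                hits += bool(max_raf_modified(crs).subset)
            fracs.append(hits / 40)
        assert fracs[0] <= fracs[1] <= fracs[2]
        assert fracs[0] < fracs[2]


class TestInhibition:
    def test_q_zero_gives_empty_inhibition_but_m_inhibitors(self):
        crs = generate_polymer_crs(PolymerParams(n=6, t=2, p_cat=0.002, m=5, q_inh=0.0, seed=3))
        assert not crs.inhibition
        assert len(crs.declared_inhibitors) == 5

    def test_inhibitors_never_in_food(self):
        for s in range(30):
            crs = generate_polymer_crs(
                PolymerParams(n=6, t=2, p_cat=0.002, m=8, q_inh=0.01, seed=s)
            )
            assert not (crs.declared_inhibitors & crs.food)
            assert not (crs.inhibitor_molecules & crs.food)

    def test_pair_count_matches_binomial_expectation(self):
        m, q = 10, 0.005
        counts = []
        for s in range(40):
            crs = generate_polymer_crs(PolymerParams(n=6, t=2, p_cat=0.002, m=m, q_inh=q, seed=s))
            counts.append(len(crs.inhibition))
        expected = m * 516 * q
        se = np.sqrt(expected) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_m_exceeding_non_food_rejected(self):
        crs = generate_polymer_crs(PolymerParams(n=2, t=1, seed=0))
        with pytest.raises(ValueError, match="exceeds"):
            add_inhibition(crs, m=10, q_inh=0.1, seed=0)

    def test_adding_inhibition_never_perturbs_catalysis(self):
        plain = generate_polymer_crs(PolymerParams(n=6, t=2, p_cat=0.002, seed=11))
        inhib = generate_polymer_crs(
            PolymerParams(n=6, t=2, p_cat=0.002, m=5, q_inh=0.01, seed=11)
        )
        assert plain.catalysis == inhib.catalysis


class TestLinearChain:
    @pytest.mark.parametrize("N", [2, 10])
    def test_basic_needs_n_minus_one_calls_modified_one(self, N):
        crs = make_linear_chain(N)
        basic = max_raf_basic(crs)
        mod = max_raf_modified(crs)
        assert basic.subset == frozenset() and basic.closure_calls == N - 1
        assert mod.subset == frozenset() and mod.closure_calls == 1

    def test_structure(self):
        crs = make_linear_chain(4)
        assert crs.food == frozenset({"x0"})
        assert len(crs.reactions) == 4
        # the final reaction is uncatalysed
        assert not crs.catalysts_of["r4"]
        assert crs.catalysts_of["r1"] == frozenset({"x2"})


class TestFamilies:
    def test_four_irrraf_family_shape(self):
        fam = make_four_irrraf_family()
        assert len(fam.labels) == 12
        assert len(fam.irrrafs) == 4
        C = next(s for s in fam.irrrafs if "r11" in s)
        D = next(s for s in fam.irrrafs if "r12" in s)
        assert C & D == frozenset({"r9", "r10"})
        assert sorted(len(c) for c in fam.classes) == [1, 1, 2, 4, 4]
        assert fam.maxraf(fam.labels) == frozenset(fam.labels)

    def test_pair_family_enumeration_matches_closed_form(self):
        fam = make_pair_family(3)
        assert len(fam.irrrafs) == 8
        O, C = average_overlap_exact(list(fam.irrrafs))
        exact, _ = pair_family_overlap(3)
        assert O == exact == Fraction(3, 7)

    @pytest.mark.parametrize("N,expect", [(3, Fraction(3, 7)), (10, Fraction(511, 1023))])
    def test_pair_family_overlap_values(self, N, expect):
        exact, approx = pair_family_overlap(N)
        assert exact == expect
        assert approx == pytest.approx(float(expect))
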