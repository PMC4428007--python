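"""Shared fixtures: small random reaction systems and brute-force oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from rafkit import CRS, PolymerParams, Reaction, generate_polymer_crs
from rafkit.raf import check_subset


def random_irreversible_crs(rng: np.random.Generator, n_mol=10, n_rxn=10, n_food=3) -> CRS:
    """A small random CRS with irreversible reactions and random catalysis."""
    mols = [f"m{i}" for i in range(n_mol)]
    rxns = []
    for i in range(n_rxn):
        rs = rng.choice(n_mol, size=int(rng.integers(1, 3)), replace=False)
        ps = rng.choice(n_mol, size=int(rng.integers(1, 3)), replace=False)
        rxns.append(
            Reaction(
                id=f"r{i:02d}",
                reactants=frozenset(mols[j] for j in rs),
                products=frozenset(mols[j] for j in ps),
            )
        )
    cat = [
        (mols[j], f"r{i:02d}")
        for i in range(n_rxn)
        for j in range(n_mol)
        if rng.random() < 0.15
    ]
    return CRS(molecules=mols, reactions=rxns, catalysis=cat, food=mols[:n_food])


def random_mixed_crs(rng: np.random.Generator, n_mol=9, n_rxn=9, n_food=3) -> CRS:
    """Like :func:`random_irreversible_crs` but ~30% reversible reactions."""
    base = random_irreversible_crs(rng, n_mol, n_rxn, n_food)
    rxns = [
        Reaction(
            id=r.id,
            reactants=r.reactants,
            products=r.products,
            reversible=bool(rng.random() < 0.3),
        )
        for r in base.reactions.values()
    ]
    return CRS(
        molecules=sorted(base.molecules),
        reactions=rxns,
        catalysis=sorted(base.catalysis),
        food=sorted(base.food),
    )


def small_polymer(seed: int, n=6, t=2, p_cat=0.002) -> CRS:
    """A small binary polymer instance (516 reactions at n=6)."""
    return generate_polymer_crs(PolymerParams(n=n, t=t, p_cat=p_cat, seed=seed))


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------
def naive_closure(crs: CRS, subset) -> frozenset[str]:
    """Closure by repeated full scans: apply every applicable reaction
    (either direction) until nothing changes."""
    present = set(crs.food)
    changed = True
    while changed:
        changed = False
        for rid in subset:
            r = crs.reactions[rid]
            for side_r, side_p in r.directions:
                if side_r <= present and not side_p <= present:
                    present |= side_p
                    changed = True
    return frozenset(present)


def brute_force_maxraf(crs: CRS, max_reactions: int = 12) -> frozenset[str]:
    """Union of all subsets passing the RAF check, by exhaustive search."""
    rids = sorted(crs.reactions)
    assert len(rids) <= max_reactions
    union: set[str] = set()
    for k in range(1, len(rids) + 1):
        for comb in itertools.combinations(rids, k):
            if set(comb) <= union:
                continue
            if check_subset(crs, comb).is_raf:
                union |= set(comb)
    return frozenset(union)


def naive_max_praf(crs: CRS, subset) -> frozenset[str]:
    """fixp by literal repeated application of the one-step map p."""
    from rafkit import map_p

    current = frozenset(subset)
    while True:
        nxt = map_p(crs, current)
        if nxt == current or not nxt:
            return nxt
        current = nxt


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20150428)
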