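"""Uninhibited RAF (u-RAF) detection in systems that allow inhibition.

A u-RAF is an RAF none of whose reactions is inhibited by any molecule of its
own food-set closure.  Finding one is NP-hard in general, but when the set
X_I of inhibitor molecules is small an exact search is feasible: for every
subset K of X_I, reduce the reaction set to

    R_-K = {r : no product of r lies in K} ∩ {r : r inhibited only by K}

and run the ordinary maxRAF algorithm on the reduced system Q_K.  Every
non-empty result is a u-RAF, every maximal u-RAF is the maxRAF of some Q_K,
and a u-RAF exists iff some Q_K has an RAF.  Reactions inhibited by food
molecules can never join a u-RAF and are removed once, up front.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .crs import CRS, compute_closure
from .raf import check_subset, max_raf_modified

__all__ = [
    "URAFResult",
    "URAFSearch",
    "build_reduced_reaction_set",
    "is_uraf",
    "enumerate_urafs",
]


def _inhibitor_set(crs: CRS) -> frozenset[str]:
    # the declared inhibitor pool if the generator recorded one (it may
    # contain molecules that happened to inhibit nothing), else X_I from I
    declared = getattr(crs, "declared_inhibitors", None)
    if declared is not None:
        return frozenset(declared) | crs.inhibitor_molecules
    return crs.inhibitor_molecules


def _entity_products(crs: CRS, rid: str) -> frozenset[str]:
    r = crs.reactions[rid]
    return r.reactants | r.products if r.reversible else r.products


def build_reduced_reaction_set(crs: CRS, K: Iterable[str]) -> frozenset[str]:
    """R_-K: reactions with no product in K and inhibited only by members of K.

    For a reversible reaction "product" means any molecule producible by
    either direction.  Reactions inhibited by a food molecule are excluded
    regardless of K (they can never be part of a u-RAF).
    """
    K = frozenset(K)
    X_I = _inhibitor_set(crs)
    if not K <= X_I:
        raise ValueError(f"K must be a subset of X_I; offending: {sorted(K - X_I)}")
    inh_of = crs.inhibitors_of
    out = set()
    for rid in crs.reactions:
        inh = inh_of[rid]
        if inh & crs.food:
            continue
        if _entity_products(crs, rid) & K:
            continue
        if inh - K:
            continue
        out.add(rid)
    return frozenset(out)


def is_uraf(crs: CRS, subset: Iterable[str]) -> bool:
    """True iff ``subset`` is an RAF and no reaction in it is inhibited by a
    molecule of ``cl_subset(F)``."""
    rids = crs.subset(subset)
    if not check_subset(crs, rids).is_raf:
        return False
    cl = compute_closure(crs, rids).molecules
    inh_of = crs.inhibitors_of
    return all(not (inh_of[rid] & cl) for rid in rids)


@dataclass
class URAFResult:
    """Outcome of one reduced-system maxRAF run.

    ``reduced`` is only materialised for small systems (``None`` otherwise;
    it can always be rebuilt with :func:`build_reduced_reaction_set`).
    """

    K: frozenset[str]
    uraf: frozenset[str]
    closure_calls: int
    reduced_size: int
    reduced: frozenset[str] | None = None


@dataclass
class URAFSearch:
    """All 2^|X_I| reduced-system runs plus the maximal distinct u-RAFs."""

    results: list[URAFResult]
    maximal: list[frozenset[str]]
    food_inhibited_removed: frozenset[str]

    @property
    def largest(self) -> frozenset[str]:
        return max((r.uraf for r in self.results), key=len, default=frozenset())

    def size_distribution(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for r in self.results:
            out[len(r.uraf)] = out.get(len(r.uraf), 0) + 1
        return out


def enumerate_urafs(crs: CRS, guard: int = 20, keep_reduced: int = 5000) -> URAFSearch:
    """Exhaustive u-RAF search over all subsets K of the inhibitor set.

    Raises if |X_I| exceeds ``guard`` (the sweep enumerates 2^|X_I| subsets;
    the general problem is NP-hard).  Subsets are visited in Gray-code order
    so successive K differ by one inhibitor.  Each run computes the maxRAF of
    Q_K restricted to the maxRAF of the uninhibited system (every RAF of Q_K
    lies inside it), then deduplicates and keeps the inclusion-maximal sets.
    """
    X_I = sorted(_inhibitor_set(crs))
    m = len(X_I)
    if m > guard:
        raise ValueError(
            f"|X_I| = {m} exceeds the guard ({guard}): the exhaustive sweep needs 2^{m} "
            "maxRAF runs and the general problem is NP-hard"
        )
    inh_of = crs.inhibitors_of
    food_inhibited = frozenset(
        rid for rid in crs.reactions if inh_of[rid] & crs.food
    )
    eligible = [rid for rid in crs.reactions if rid not in food_inhibited]

    # uninhibited maxRAF bounds every u-RAF
    base = max_raf_modified(crs, eligible)
    M0 = sorted(base.subset)
    net = crs.network().restricted_to(M0) if M0 else None

    # per-eligible-reaction bitmasks over X_I
    bit = {x: 1 << i for i, x in enumerate(X_I)}
    if net is not None:
        n_ent = net.n_ent
        prod_mask = np.zeros(n_ent, np.int64)
        inh_mask = np.zeros(n_ent, np.int64)
        for ei, rid in enumerate(net.ent_ids):
            pm = 0
            for x in _entity_products(crs, rid):
                if x in bit:
                    pm |= bit[x]
            im = 0
            for x in inh_of[rid]:
                im |= bit[x]
            prod_mask[ei] = pm
            inh_mask[ei] = im

    full = (1 << m) - 1
    results: list[URAFResult] = []
    small = len(crs.reactions) <= keep_reduced
    seen: dict[tuple[str, ...], frozenset[str]] = {}
    for g in range(1 << m):
        Kmask = g ^ (g >> 1)  # Gray code
        K = frozenset(X_I[i] for i in range(m) if Kmask >> i & 1)
        if net is None:
            uraf: frozenset[str] = frozenset()
            calls = 0
            searched = 0
        else:
            allowed = ((prod_mask & Kmask) == 0) & ((inh_mask & ~np.int64(Kmask) & full) == 0)
            searched = int(allowed.sum())
            out, calls, _ = net.maxraf_modified(allowed)
            uraf = net.ids_from_mask(out)
        key = tuple(sorted(uraf))
        uraf = seen.setdefault(key, uraf)  # intern duplicates
        reduced = build_reduced_reaction_set(crs, K) if small else None
        results.append(
            URAFResult(
                K=K,
                uraf=uraf,
                closure_calls=calls,
                reduced_size=len(reduced) if reduced is not None else searched,
                reduced=reduced,
            )
        )
    distinct = [s for s in seen.values() if s]
    maximal = [s for s in distinct if not any(s < t for t in distinct)]
    return URAFSearch(results=results, maximal=maximal, food_inhibited_removed=food_inhibited)
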