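"""Maximum-RAF and maximum-pseudo-RAF detection.

Two algorithms compute the (unique) maximum RAF:

* :func:`max_raf_basic` — iterate the map *f* (one food-set closure per
  application) until the first fixed point.
* :func:`max_raf_modified` — alternate a single closure computation with a
  cascading, count-based pruning step that enforces the pseudo-RAF conditions
  using only "active" producing reactions (those fired during the last
  closure).  It returns the identical subset while never making more closure
  calls than the basic algorithm.

Both treat "no RAF" as an explicit empty result.  The closure-call counter is
the unit of work reported everywhere; one call is one closure computation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .crs import CRS, pi

__all__ = [
    "RAFResult",
    "SubsetFlags",
    "max_praf",
    "max_raf_basic",
    "max_raf_modified",
    "check_subset",
]


@dataclass
class RAFResult:
    """Outcome of a maxRAF computation.

    ``subset`` is the maximum RAF (possibly empty); ``closure_calls`` counts
    invocations of the closure procedure; ``outer_iterations`` counts
    f-applications (basic) or closure/prune alternations (modified).
    """

    subset: frozenset[str]
    closure_calls: int
    outer_iterations: int
    algorithm: str

    @property
    def is_empty(self) -> bool:
        return not self.subset


@dataclass
class SubsetFlags:
    """RAF-related predicates for one reaction subset."""

    is_praf: bool
    is_f_generated: bool
    is_raf: bool
    is_empty: bool


def max_praf(crs: CRS, subset: Iterable[str]) -> frozenset[str]:
    """fixp: the unique maximum pseudo-RAF within ``subset`` (or empty).

    Runs in linear time by decremental producer/catalyst counting; performs no
    closure computation.  A reaction survives iff the reactants of at least
    one direction and at least one catalyst all remain available, where a
    molecule is available iff it is food or on a product side of a surviving
    reaction.
    """
    rids = crs.subset(subset)
    cat_of = crs.catalysts_of
    # producers[x] = number of surviving reactions with x on a product side
    producers: dict[str, int] = {}
    for rid in rids:
        r = crs.reactions[rid]
        sides = r.reactants | r.products if r.reversible else r.products
        for x in sides:
            producers[x] = producers.get(x, 0) + 1

    def available(x: str) -> bool:
        return x in crs.food or producers.get(x, 0) > 0

    alive = set(rids)
    # direction requirement bookkeeping: per reaction, list of directions with
    # their unavailable-reactant counts; catalyst availability count
    dir_missing: dict[str, list[int]] = {}
    dir_sides: dict[str, list[frozenset[str]]] = {}
    cat_count: dict[str, int] = {}
    needs: dict[str, list[tuple[str, int]]] = {}  # molecule -> (rid, dir index)
    cat_needs: dict[str, list[str]] = {}  # molecule -> rids catalysed
    stack: list[str] = []
    for rid in rids:
        r = crs.reactions[rid]
        sides = [side for side, _ in r.directions]
        dir_sides[rid] = sides
        miss = []
        for di, side in enumerate(sides):
            m = 0
            for x in side:
                if not available(x):
                    m += 1
                needs.setdefault(x, []).append((rid, di))
            miss.append(m)
        dir_missing[rid] = miss
        c = 0
        for x in cat_of[rid]:
            if available(x):
                c += 1
            cat_needs.setdefault(x, []).append(rid)
        cat_count[rid] = c
        if c == 0 or all(m > 0 for m in miss):
            stack.append(rid)

    def kill(rid: str) -> None:
        if rid not in alive:
            return
        alive.discard(rid)
        r = crs.reactions[rid]
        sides = r.reactants | r.products if r.reversible else r.products
        for x in sides:
            producers[x] -= 1
            if producers[x] == 0 and x not in crs.food:
                newly_unavailable.append(x)

    while stack:
        newly_unavailable: list[str] = []
        while stack:
            kill(stack.pop())
        while newly_unavailable:
            x = newly_unavailable.pop()
            for rid, di in needs.get(x, ()):  # reactant dependents
                if rid not in alive:
                    continue
                dir_missing[rid][di] += 1
                if dir_missing[rid][di] == 1 and all(m > 0 for m in dir_missing[rid]):
                    kill(rid)
            for rid in cat_needs.get(x, ()):  # catalyst dependents
                if rid not in alive:
                    continue
                cat_count[rid] -= 1
                if cat_count[rid] == 0:
                    kill(rid)
    return frozenset(alive)


def max_raf_basic(crs: CRS, subset: Iterable[str] | None = None) -> RAFResult:
    """Maximum RAF by recursive application of *f* to the reaction set."""
    rids = crs.all_reaction_ids() if subset is None else crs.subset(subset)
    net = crs.network()
    active = net.mask_from_ids(rids)
    mask, calls, iters = net.maxraf_basic(active)
    return RAFResult(net.ids_from_mask(mask), calls, iters, "basic")


def max_raf_modified(
    crs: CRS,
    subset: Iterable[str] | None = None,
    active_counting: bool = True,
) -> RAFResult:
    """Maximum RAF by the pRAF-accelerated alternating algorithm.

    With ``active_counting`` (the default) the pruning between closures uses
    per-molecule counts of reactions fired during the last closure, so a
    single closure anchors a whole cascade of removals.  With it disabled the
    plain alternation is used instead: fixp (no closures) followed by one
    f-application per outer iteration.  Both return the identical maxRAF;
    only the closure-call accounting differs.
    """
    rids = crs.all_reaction_ids() if subset is None else crs.subset(subset)
    net = crs.network()
    if active_counting:
        active = net.mask_from_ids(rids)
        mask, calls, iters = net.maxraf_modified(active)
        return RAFResult(net.ids_from_mask(mask), calls, iters, "modified")
    current = frozenset(rids)
    calls = 0
    iters = 0
    while True:
        current = max_praf(crs, current)
        if not current:
            return RAFResult(current, calls, iters, "modified")
        iters += 1
        in_cl, dir_fired, _ = net.closure(net.mask_from_ids(current))
        calls += 1
        keep = net.ids_from_mask(net.filter_f(net.mask_from_ids(current), in_cl, dir_fired))
        if keep == current:
            return RAFResult(current, calls, iters, "modified")
        current = keep


def check_subset(crs: CRS, subset: Iterable[str]) -> SubsetFlags:
    """Evaluate the pseudo-RAF, F-generated and RAF predicates.

    A subset is a pseudo-RAF iff every reaction has all reactants (of some
    direction) and at least one catalyst in ``F ∪ π(R')``; it is F-generated
    iff every reaction can fire within the closure ``cl_R'(F)``; it is an RAF
    iff both hold.  The empty subset satisfies all three vacuously and is
    flagged as empty.
    """
    rids = crs.subset(subset)
    if not rids:
        return SubsetFlags(True, True, True, True)
    avail = crs.food | pi(crs, rids)
    cat_of = crs.catalysts_of
    is_praf = True
    for rid in rids:
        r = crs.reactions[rid]
        if not any(side <= avail for side, _ in r.directions):
            is_praf = False
            break
        if not any(x in avail for x in cat_of[rid]):
            is_praf = False
            break
    net = crs.network()
    active = net.mask_from_ids(rids)
    _, dir_fired, _ = net.closure(active)
    ent_fired = net.entity_fired(dir_fired)
    is_fgen = all(ent_fired[net.ent_index[rid]] for rid in rids)
    return SubsetFlags(is_praf, is_fgen, is_praf and is_fgen, False)
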