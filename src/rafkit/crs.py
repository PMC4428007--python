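"""Chemical reaction systems (CRS) and food-set closure computation.

A CRS is a tuple ``(X, R, C, I, F)``: a molecule set *X*, reaction set *R*,
catalysis pairs *C* (molecule, reaction), optional inhibition pairs *I*, and a
food set ``F ⊆ X`` of molecules freely available from the environment.

Two one-step maps on reaction subsets are provided:

* :func:`map_f` keeps reactions whose reactants and at least one catalyst lie
  in the food-set closure ``cl_R'(F)``.  Its fixed points (reached by
  iteration) are RAF sets.
* :func:`map_p` is the cheaper variant that replaces the closure with
  ``F ∪ π(R')`` (food plus everything the subset produces).  Its fixed points
  are pseudo-RAFs.

Reversible reactions are single entities carrying two directed rules; the
closure may fire either direction and a catalyst catalyses both.  Availability
is purely set-based: a molecule that is present satisfies any multiplicity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "Molecule",
    "Reaction",
    "CRS",
    "ClosureResult",
    "ClosureCounter",
    "compute_closure",
    "map_f",
    "map_p",
    "rho",
    "pi",
]


@dataclass(frozen=True)
class Molecule:
    """A molecule type, identified by a unique string label."""

    id: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("molecule id must be a non-empty string")


@dataclass(frozen=True)
class Reaction:
    """A reaction with reactant set ρ(r) and product set π(r).

    If ``reversible`` is set the reverse rule (products -> reactants) is also
    applicable during closure computation and availability checks, and any
    catalyst catalyses both directions.
    """

    id: str
    reactants: frozenset[str]
    products: frozenset[str]
    reversible: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("reaction id must be a non-empty string")
        if not self.reactants or not self.products:
            raise ValueError(f"reaction {self.id!r}: reactants and products must be non-empty")
        object.__setattr__(self, "reactants", frozenset(self.reactants))
        object.__setattr__(self, "products", frozenset(self.products))

    @property
    def directions(self) -> tuple[tuple[frozenset[str], frozenset[str]], ...]:
        """Applicable (reactant-side, product-side) rules."""
        if self.reversible:
            return ((self.reactants, self.products), (self.products, self.reactants))
        return ((self.reactants, self.products),)

    def molecules(self) -> frozenset[str]:
        return self.reactants | self.products


class CRS:
    """A chemical reaction system with food set, catalysis and inhibition.

    Parameters
    ----------
    molecules:
        Iterable of molecule ids (or :class:`Molecule`).  Molecules referenced
        by reactions/food are added implicitly.
    reactions:
        Iterable of :class:`Reaction`.
    catalysis:
        Pairs ``(x, r)`` meaning molecule ``x`` catalyses reaction ``r``.
    inhibition:
        Pairs ``(x, r)`` meaning molecule ``x`` inhibits reaction ``r``.
    food:
        Ids of the food set ``F ⊆ X``.
    """

    def __init__(
        self,
        molecules: Iterable[str | Molecule] = (),
        reactions: Iterable[Reaction] = (),
        catalysis: Iterable[tuple[str, str]] = (),
        inhibition: Iterable[tuple[str, str]] = (),
        food: Iterable[str] = (),
    ) -> None:
        mols: dict[str, Molecule] = {}
        for m in molecules:
            mol = m if isinstance(m, Molecule) else Molecule(str(m))
            if mol.id in mols:
                raise ValueError(f"duplicate molecule id {mol.id!r}")
            mols[mol.id] = mol
        rxns: dict[str, Reaction] = {}
        for r in reactions:
            if r.id in rxns:
                raise ValueError(f"duplicate reaction id {r.id!r}")
            rxns[r.id] = r
            for x in r.molecules():
                mols.setdefault(x, Molecule(x))
        food_set = frozenset(str(x) for x in food)
        for x in food_set:
            mols.setdefault(x, Molecule(x))
        cat = frozenset((str(x), str(r)) for x, r in catalysis)
        inh = frozenset((str(x), str(r)) for x, r in inhibition)
        for x, r in cat:
            if r not in rxns:
                raise ValueError(f"catalysis refers to unknown reaction {r!r}")
            if x not in mols:
                raise ValueError(f"catalysis refers to unknown molecule {x!r}")
        for x, r in inh:
            if r not in rxns:
                raise ValueError(f"inhibition refers to unknown reaction {r!r}")
            if x not in mols:
                raise ValueError(f"inhibition refers to unknown molecule {x!r}")
        self.molecules: Mapping[str, Molecule] = mols
        self.reactions: Mapping[str, Reaction] = rxns
        self.catalysis: frozenset[tuple[str, str]] = cat
        self.inhibition: frozenset[tuple[str, str]] = inh
        self.food: frozenset[str] = food_set
        self._network = None  # built lazily by rafkit._network

    # -- derived indices ---------------------------------------------------
    @property
    def catalysts_of(self) -> dict[str, frozenset[str]]:
        """c(r): map reaction id -> set of catalyst molecule ids."""
        try:
            return self._catalysts_of
        except AttributeError:
            d: dict[str, set[str]] = {rid: set() for rid in self.reactions}
            for x, r in self.catalysis:
                d[r].add(x)
            self._catalysts_of = {rid: frozenset(s) for rid, s in d.items()}
            return self._catalysts_of

    @property
    def inhibitors_of(self) -> dict[str, frozenset[str]]:
        """in(r): map reaction id -> set of inhibitor molecule ids."""
        try:
            return self._inhibitors_of
        except AttributeError:
            d: dict[str, set[str]] = {rid: set() for rid in self.reactions}
            for x, r in self.inhibition:
                d[r].add(x)
            self._inhibitors_of = {rid: frozenset(s) for rid, s in d.items()}
            return self._inhibitors_of

    @property
    def inhibitor_molecules(self) -> frozenset[str]:
        """X_I: molecules that inhibit at least one reaction."""
        return frozenset(x for x, _ in self.inhibition)

    def reactions_inhibited_by(self, x: str) -> frozenset[str]:
        """R_x: ids of reactions inhibited by molecule ``x``."""
        return frozenset(r for y, r in self.inhibition if y == x)

    def all_reaction_ids(self) -> frozenset[str]:
        return frozenset(self.reactions)

    def subset(self, reaction_ids: Iterable[str]) -> frozenset[str]:
        """Validate and canonicalise a reaction subset of this CRS."""
        rids = frozenset(str(r) for r in reaction_ids)
        unknown = rids - self.reactions.keys()
        if unknown:
            raise KeyError(f"unknown reaction id(s): {sorted(unknown)}")
        return rids

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CRS):
            return NotImplemented
        return (
            set(self.molecules) == set(other.molecules)
            and self.reactions == other.reactions
            and self.catalysis == other.catalysis
            and self.inhibition == other.inhibition
            and self.food == other.food
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"CRS(|X|={len(self.molecules)}, |R|={len(self.reactions)}, "
            f"|C|={len(self.catalysis)}, |I|={len(self.inhibition)}, |F|={len(self.food)})"
        )

    def network(self):
        """The integer-indexed view used by the fast algorithms (cached)."""
        if self._network is None:
            from ._network import ReactionNetwork

            self._network = ReactionNetwork(self)
        return self._network


def rho(crs: CRS, subset: Iterable[str]) -> frozenset[str]:
    """ρ(R'): union of reactant sets (forward direction) over the subset."""
    out: set[str] = set()
    for rid in subset:
        out |= crs.reactions[rid].reactants
    return frozenset(out)


def pi(crs: CRS, subset: Iterable[str]) -> frozenset[str]:
    """π(R'): union of producible molecules over the subset.

    For a reversible reaction both sides are producible (each side is the
    product of one direction), so both contribute.
    """
    out: set[str] = set()
    for rid in subset:
        r = crs.reactions[rid]
        if r.reversible:
            out |= r.reactants
            out |= r.products
        else:
            out |= r.products
    return frozenset(out)


@dataclass
class ClosureResult:
    """Result of a food-set closure computation.

    Attributes
    ----------
    molecules:
        ``cl_R'(F)`` — every molecule producible from the food set by
        repeatedly applying reactions of the subset.
    fired:
        Per-reaction flag: True iff the reaction was applied at least once (in
        some direction) while computing the closure; equivalently, iff all
        reactants of some direction lie in the closure.
    producer_counts:
        Per-molecule count of fired reactions that produce it.
    """

    molecules: frozenset[str]
    fired: dict[str, bool]
    producer_counts: dict[str, int]


@dataclass
class ClosureCounter:
    """Caller-visible counter of closure computations."""

    count: int = 0

    def tick(self) -> None:
        self.count += 1


def compute_closure(crs: CRS, subset: Iterable[str]) -> ClosureResult:
    """Compute ``cl_R'(F)``, the closure of the food set under a reaction subset.

    The closure is the unique least fixed point containing F and is
    independent of the order in which reactions are applied.
    """
    rids = crs.subset(subset)
    net = crs.network()
    active = net.mask_from_ids(rids)
    in_cl, dir_fired, _ = net.closure(active)
    ent_fired = net.entity_fired(dir_fired)
    molecules = net.molecule_ids_from_mask(in_cl)
    fired = {rid: False for rid in rids}
    counts: dict[str, int] = {}
    for ei in range(net.n_ent):
        if not active[ei] or not ent_fired[ei]:
            continue
        rid = net.ent_ids[ei]
        fired[rid] = True
        for x in net.fired_products(ei, dir_fired):
            counts[x] = counts.get(x, 0) + 1
    return ClosureResult(molecules=molecules, fired=fired, producer_counts=counts)


def map_f(
    crs: CRS,
    subset: Iterable[str],
    counter: ClosureCounter | None = None,
) -> frozenset[str]:
    """One application of the map *f*.

    Returns the reactions of the subset whose reactants (of at least one
    direction) and at least one catalyst are present in ``cl_subset(F)``.
    Performs exactly one closure computation.
    """
    rids = crs.subset(subset)
    net = crs.network()
    active = net.mask_from_ids(rids)
    in_cl, dir_fired, _ = net.closure(active)
    if counter is not None:
        counter.tick()
    keep = net.filter_f(active, in_cl, dir_fired)
    return net.ids_from_mask(keep)


def map_p(crs: CRS, subset: Iterable[str]) -> frozenset[str]:
    """One application of the map *p* (no closure computation).

    Availability is tested against ``F ∪ π(subset)``: a reaction is kept iff
    the reactants of at least one direction and at least one catalyst are all
    available.
    """
    rids = crs.subset(subset)
    avail = crs.food | pi(crs, rids)
    cat_of = crs.catalysts_of
    keep: set[str] = set()
    for rid in rids:
        r = crs.reactions[rid]
        if not any(side <= avail for side, _ in r.directions):
            continue
        if not any(x in avail for x in cat_of[rid]):
            continue
        keep.add(rid)
    return frozenset(keep)
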