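"""Generalized RAF framework: gf-compatible subsets of a finite ground set.

Given a finite set Y, a partially ordered value space W, a set function
``f : 2^Y -> W`` and an element function ``g : Y -> W``, define

    ψ(A) = {y ∈ A : g(y) ≤ f(A)}.

A non-empty subset A with ψ(A) = A is *gf-compatible*.  When f is monotone
(A ⊆ B implies f(A) ≤ f(B)), iterating ψ from Y descends to the unique
maximum gf-compatible subset (or to the empty set if none exists) in at most
|Y| steps.

RAF detection is the instance Y = expanded reaction rules (catalysts folded
into reactants), W = 2^X ordered by inclusion, f(A) = cl_A(F) and
g(r) = ρ(r): the gf-compatible subsets correspond exactly to the RAFs.  With
inhibition, W = 2^X × 2^X under the product order, f(A) = (cl_A(F),
X − cl_A(F)) and g(r) = (ρ(r), in(r)); the gf-compatible subsets are then the
u-RAFs, but f is no longer monotone, so the descending iteration carries no
guarantee — that case is represented here and solved by the inhibitor-subset
enumeration in :mod:`rafkit.inhibition` instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Hashable, Iterable

from .crs import CRS
from .hornsat import ExpandedCRS, expand_crs

__all__ = ["GfSystem", "psi", "find_gf_compatible", "raf_as_gf", "RafGfSystem"]


@dataclass(frozen=True)
class GfSystem:
    """A (Y, W, f, g) system with an explicit partial-order comparator.

    ``leq(a, b)`` decides a ≤ b in W; W itself is never materialised, so the
    plain-RAF and inhibition instantiations share one engine.
    """

    elements: tuple[Hashable, ...]
    f: Callable[[frozenset], object]
    g: Callable[[Hashable], object]
    leq: Callable[[object, object], bool]
    monotone: bool

    def ground_set(self) -> frozenset:
        return frozenset(self.elements)


def psi(system: GfSystem, A: Iterable[Hashable]) -> frozenset:
    """One application of ψ(A) = {y ∈ A : g(y) ≤ f(A)}."""
    A = frozenset(A)
    fA = system.f(A)
    return frozenset(y for y in A if system.leq(system.g(y), fA))


def find_gf_compatible(system: GfSystem) -> frozenset:
    """The maximum gf-compatible subset (possibly empty) for monotone f.

    Iterates ψ from the full ground set; by monotonicity the iteration is a
    descending chain whose fixed point contains every gf-compatible subset.
    Raises on systems flagged non-monotone (no correctness guarantee; for the
    inhibition instance use :func:`rafkit.inhibition.enumerate_urafs`).
    """
    if not system.monotone:
        raise ValueError(
            "ψ-iteration requires a monotone f; for inhibition systems use "
            "rafkit.inhibition.enumerate_urafs"
        )
    A = system.ground_set()
    while A:
        nxt = psi(system, A)
        if nxt == A:
            return A
        A = nxt
    return A


@dataclass(frozen=True)
class RafGfSystem:
    """A :class:`GfSystem` encoding RAF (or u-RAF) detection for one CRS.

    ``system`` operates on the ids of expanded rules; ``map_back`` recovers
    original reaction ids from a set of rule ids.
    """

    system: GfSystem
    expanded: ExpandedCRS
    with_inhibition: bool

    def map_back(self, rule_ids: Iterable[str]) -> frozenset[str]:
        return self.expanded.map_back(rule_ids)


def raf_as_gf(crs: CRS, with_inhibition: bool = False) -> RafGfSystem:
    """Encode RAF detection on ``crs`` as a gf-compatibility problem.

    Works over the expanded rule set (uncatalysed reactions deleted, each
    catalyst nominated as a reactant of its own copy).  Without inhibition the
    system is monotone and :func:`find_gf_compatible` returns the rule set of
    the maxRAF.  With inhibition the value space is the pair lattice and the
    system is flagged non-monotone; ψ remains available for *verifying* that
    a known u-RAF is a fixed point.
    """
    expanded = expand_crs(crs)
    net = crs.network()
    rule_by_id = {rule.id: rule for rule in expanded.rules}
    all_mols = frozenset(crs.molecules)
    inh_of = crs.inhibitors_of

    def closure_of(A: frozenset) -> frozenset[str]:
        # f(A) = cl_A(F) over the underlying reactions, regardless of whether
        # catalysts are available; catalysts enter only through g
        if not A:
            return frozenset(crs.food)
        origins = {rule_by_id[rid].origin for rid in A}
        active = net.mask_from_ids(origins)
        in_cl, _, _ = net.closure(active)
        return net.molecule_ids_from_mask(in_cl)

    if not with_inhibition:
        system = GfSystem(
            elements=tuple(rule.id for rule in expanded.rules),
            f=closure_of,
            g=lambda rid: rule_by_id[rid].reactants,
            leq=lambda a, b: a <= b,
            monotone=True,
        )
    else:

        def f_pair(A: frozenset):
            cl = closure_of(A)
            return (cl, all_mols - cl)

        def g_pair(rid: str):
            rule = rule_by_id[rid]
            return (rule.reactants, inh_of[rule.origin])

        system = GfSystem(
            elements=tuple(rule.id for rule in expanded.rules),
            f=f_pair,
            g=g_pair,
            leq=lambda a, b: a[0] <= b[0] and a[1] <= b[1],
            monotone=False,
        )
    return RafGfSystem(system=system, expanded=expanded, with_inhibition=with_inhibition)
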