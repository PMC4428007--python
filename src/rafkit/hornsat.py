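"""Maximum pseudo-RAF detection via HORN-SAT unit propagation.

Finding the maximum pseudo-RAF is equivalent to finding the minimal
satisfying truth assignment of a propositional Horn formula.  The
construction works on the *expanded* CRS, in which catalysis is folded away:
every uncatalysed reaction is deleted, and a reaction with k catalysts is
replaced by k copies, each with one nominated catalyst added as a reactant.

Literals are ``y_r`` (one per expanded reaction rule) and ``y_x`` (one per
molecule), where *true* means "not in the set" / "not available".  The
formula is the conjunction of

* reactant clauses — a rule is excluded if any of its reactants (including
  the nominated catalyst) is unavailable;
* producer clauses — a non-food molecule is unavailable if every rule that
  produces it is excluded;
* food clauses — food molecules are available (unit negative literals).

Each clause has at most one positive literal, so the formula is Horn and the
minimal model is found by linear-time unit propagation; the reactions whose
literals stay *false* form the maximum pseudo-RAF.  This module is an
independent oracle for :func:`rafkit.raf.max_praf`, not the default engine.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .crs import CRS, Reaction

__all__ = [
    "ExpandedRule",
    "ExpandedCRS",
    "HornFormula",
    "expand_crs",
    "build_horn_formula",
    "unit_propagate",
    "horn_max_praf",
]


@dataclass(frozen=True)
class ExpandedRule:
    """One directed rule of the expanded CRS.

    ``reactants`` already includes the nominated catalyst.  A reversible
    original contributes one rule per (catalyst, direction); an irreversible
    one contributes one rule per catalyst.
    """

    id: str
    origin: str  # original reaction id
    catalyst: str
    reactants: frozenset[str]
    products: frozenset[str]


@dataclass(frozen=True)
class ExpandedCRS:
    """Catalysis-free view of a CRS: copies with nominated-catalyst reactants.

    ``copies_of[r]`` lists the rules derived from original reaction ``r``;
    uncatalysed originals are absent.  ``copy_count(r)`` equals the number of
    distinct catalysts of ``r``.
    """

    rules: tuple[ExpandedRule, ...]
    food: frozenset[str]
    molecules: frozenset[str]
    origin_reactions: tuple[Reaction, ...] = ()

    @property
    def copies_of(self) -> dict[str, list[ExpandedRule]]:
        out: dict[str, list[ExpandedRule]] = {}
        for rule in self.rules:
            out.setdefault(rule.origin, []).append(rule)
        return out

    def copy_count(self, rid: str) -> int:
        """Number of catalyst-nominated copies of an original reaction."""
        return len({rule.catalyst for rule in self.copies_of.get(rid, [])})

    def as_crs(self) -> CRS:
        """The expansion as a plain CRS: one copy per (origin, catalyst), each
        catalysed only by its nominated catalyst.  Closure semantics ignore
        catalyst availability, so RAF detection on this CRS mirrors the
        original exactly (the maxRAF maps back onto the original maxRAF)."""
        origin = {r.id: r for r in self.origin_reactions}
        seen: dict[str, Reaction] = {}
        catalysis: list[tuple[str, str]] = []
        for rule in self.rules:
            cid = f"{rule.origin}|{rule.catalyst}"
            if cid in seen:
                continue
            rxn = origin[rule.origin]
            seen[cid] = Reaction(
                id=cid,
                reactants=rxn.reactants,
                products=rxn.products,
                reversible=rxn.reversible,
            )
            catalysis.append((rule.catalyst, cid))
        return CRS(
            molecules=sorted(self.molecules),
            reactions=list(seen.values()),
            catalysis=catalysis,
            food=sorted(self.food),
        )

    def map_back(self, rule_ids: Iterable[str]) -> frozenset[str]:
        """Original reaction ids with at least one rule/copy in ``rule_ids``."""
        by_id: dict[str, str] = {}
        for rule in self.rules:
            by_id[rule.id] = rule.origin
            by_id[f"{rule.origin}|{rule.catalyst}"] = rule.origin
        return frozenset(by_id[r] for r in rule_ids)


def expand_crs(crs: CRS, subset: Iterable[str] | None = None) -> ExpandedCRS:
    """Build the expanded CRS (catalysts folded into reactants)."""
    rids = crs.all_reaction_ids() if subset is None else crs.subset(subset)
    cat_of = crs.catalysts_of
    rules: list[ExpandedRule] = []
    for rid in sorted(rids):
        rxn = crs.reactions[rid]
        cats = sorted(cat_of[rid])
        if not cats:
            continue  # uncatalysed reactions cannot join any pRAF or RAF
        for c in cats:
            for di, (side_r, side_p) in enumerate(rxn.directions):
                tag = f"{rid}|{c}" if len(rxn.directions) == 1 else f"{rid}|{c}|d{di}"
                rules.append(
                    ExpandedRule(
                        id=tag,
                        origin=rid,
                        catalyst=c,
                        reactants=side_r | {c},
                        products=side_p,
                    )
                )
    return ExpandedCRS(
        rules=tuple(rules),
        food=crs.food,
        molecules=frozenset(crs.molecules),
        origin_reactions=tuple(crs.reactions[rid] for rid in sorted(rids)),
    )


@dataclass
class HornFormula:
    """The Horn formula whose minimal model is the maximum pseudo-RAF.

    ``reaction_clauses[(x, r)]`` encodes y_x → y_r; ``producer_clauses[x]``
    encodes (∧_i y_{r_i}) → y_x over the k(x) rules producing x;
    ``food_units`` are the unit clauses ¬y_x for x ∈ F.
    """

    rule_ids: list[str]
    molecule_ids: list[str]
    reaction_clauses: list[tuple[str, str]]  # (molecule, rule): y_x -> y_r
    producer_clauses: dict[str, list[str]]  # molecule -> rules producing it
    food_units: list[str]

    def producer_count(self, x: str) -> int:
        """k(x): number of distinct rules producing molecule x."""
        return len(self.producer_clauses.get(x, []))

    def to_dimacs(self) -> str:
        """DIMACS-like CNF dump for inspection (comment lines name literals)."""
        idx: dict[str, int] = {}
        for x in self.molecule_ids:
            idx[f"y_x:{x}"] = len(idx) + 1
        for r in self.rule_ids:
            idx[f"y_r:{r}"] = len(idx) + 1
        lines = [f"c {v} {k}" for k, v in idx.items()]
        clauses: list[list[int]] = []
        for x in self.food_units:
            clauses.append([-idx[f"y_x:{x}"]])
        for x, rules in self.producer_clauses.items():
            clauses.append([-idx[f"y_r:{r}"] for r in rules] + [idx[f"y_x:{x}"]])
        for x, r in self.reaction_clauses:
            clauses.append([-idx[f"y_x:{x}"], idx[f"y_r:{r}"]])
        lines.insert(0, f"p cnf {len(idx)} {len(clauses)}")
        lines.extend(" ".join(map(str, cl)) + " 0" for cl in clauses)
        return "\n".join(lines) + "\n"


def build_horn_formula(expanded: ExpandedCRS) -> HornFormula:
    """Clauses (reactant, producer, food) for an expanded CRS."""
    reaction_clauses: list[tuple[str, str]] = []
    producer_clauses: dict[str, list[str]] = {}
    for rule in expanded.rules:
        for x in sorted(rule.reactants):
            reaction_clauses.append((x, rule.id))
        for x in rule.products:
            producer_clauses.setdefault(x, []).append(rule.id)
    non_food = sorted(expanded.molecules - expanded.food)
    for x in non_food:
        producer_clauses.setdefault(x, [])
    return HornFormula(
        rule_ids=[rule.id for rule in expanded.rules],
        molecule_ids=sorted(expanded.molecules),
        reaction_clauses=reaction_clauses,
        producer_clauses={x: producer_clauses[x] for x in non_food},
        food_units=sorted(expanded.food),
    )


def unit_propagate(formula: HornFormula) -> tuple[set[str], set[str]]:
    """Minimal model of the Horn formula by unit propagation.

    Returns (true_molecule_literals, true_rule_literals): the literals forced
    to *true* (unavailable molecules / excluded rules).  Formulas of this
    shape are always satisfiable, and the minimal model is independent of the
    clause processing order.  Watched counters (remaining producer counts per
    molecule) give linear time.
    """
    remaining = {x: len(rules) for x, rules in formula.producer_clauses.items()}
    rules_by_reactant: dict[str, list[str]] = {}
    for x, r in formula.reaction_clauses:
        rules_by_reactant.setdefault(x, []).append(r)
    produces: dict[str, list[str]] = {}
    for x, rules in formula.producer_clauses.items():
        for r in rules:
            produces.setdefault(r, []).append(x)
    food = set(formula.food_units)
    mol_true: set[str] = set()
    rule_true: set[str] = set()
    queue = [x for x, k in remaining.items() if k == 0 and x not in food]
    mol_true.update(queue)
    while queue:
        x = queue.pop()
        for r in rules_by_reactant.get(x, ()):  # y_x -> y_r
            if r in rule_true:
                continue
            rule_true.add(r)
            for p in produces.get(r, ()):  # all producers excluded -> y_p
                remaining[p] -= 1
                if remaining[p] == 0 and p not in food and p not in mol_true:
                    mol_true.add(p)
                    queue.append(p)
    return mol_true, rule_true


def horn_max_praf(crs: CRS, subset: Iterable[str] | None = None) -> frozenset[str]:
    """Maximum pseudo-RAF via the Horn-formula minimal model.

    The rules whose literals stay false form the maximum pseudo-RAF of the
    expanded CRS; mapped back to original reaction ids this equals fixp.
    """
    expanded = expand_crs(crs, subset)
    formula = build_horn_formula(expanded)
    _, rule_true = unit_propagate(formula)
    kept = [r for r in formula.rule_ids if r not in rule_true]
    return expanded.map_back(kept)
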