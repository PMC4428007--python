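"""Reading and writing chemical reaction systems.

Two interchangeable on-disk forms are supported:

* a line-oriented text format::

      # comment
      MOLECULES: a b ab
      FOOD: a b
      REACTION r1: a + b -> ab <=>
      CAT: ab -> r1
      INH: x -| r1

  The trailing ``<=>`` marks a reversible reaction.  The ``MOLECULES:`` line
  is optional on input (molecules are otherwise inferred from food and
  reactions) but always written, so write → read round-trips exactly.

* a JSON dialect mirroring the CRS fields one-for-one.

Writers emit canonical sorted output: identical systems serialise to
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

from .crs import CRS, Reaction

__all__ = ["read_crs", "write_crs", "crs_to_json", "crs_from_json", "format_crs"]


class CRSFormatError(ValueError):
    """Malformed CRS file; message carries the offending line number or id."""


def format_crs(crs: CRS) -> str:
    """Render a CRS in the canonical text format."""
    lines = ["# rafkit CRS"]
    lines.append("MOLECULES: " + " ".join(sorted(crs.molecules)))
    lines.append("FOOD: " + " ".join(sorted(crs.food)))
    for rid in sorted(crs.reactions):
        r = crs.reactions[rid]
        lhs = " + ".join(sorted(r.reactants))
        rhs = " + ".join(sorted(r.products))
        arrow = f"{lhs} -> {rhs}" + (" <=>" if r.reversible else "")
        lines.append(f"REACTION {rid}: {arrow}")
    for x, rid in sorted(crs.catalysis):
        lines.append(f"CAT: {x} -> {rid}")
    for x, rid in sorted(crs.inhibition):
        lines.append(f"INH: {x} -| {rid}")
    return "\n".join(lines) + "\n"


def _parse_reaction(body: str, lineno: int) -> tuple[frozenset[str], frozenset[str], bool]:
    reversible = False
    if body.endswith("<=>"):
        reversible = True
        body = body[: -len("<=>")].strip()
    if "->" not in body:
        raise CRSFormatError(f"line {lineno}: reaction lacks '->'")
    lhs, rhs = body.split("->", 1)
    reactants = frozenset(tok for tok in lhs.replace("+", " ").split() if tok)
    products = frozenset(tok for tok in rhs.replace("+", " ").split() if tok)
    if not reactants or not products:
        raise CRSFormatError(f"line {lineno}: empty reactant or product list")
    return reactants, products, reversible


def _parse_text(text: str) -> CRS:
    molecules: list[str] = []
    food: list[str] = []
    reactions: list[Reaction] = []
    catalysis: list[tuple[str, str]] = []
    inhibition: list[tuple[str, str]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("MOLECULES:"):
            molecules.extend(line[len("MOLECULES:"):].split())
        elif line.startswith("FOOD:"):
            food.extend(line[len("FOOD:"):].split())
        elif line.startswith("REACTION"):
            head, _, body = line[len("REACTION"):].partition(":")
            rid = head.strip()
            if not rid or not body.strip():
                raise CRSFormatError(f"line {lineno}: expected 'REACTION <id>: a + b -> c'")
            reactants, products, reversible = _parse_reaction(body.strip(), lineno)
            reactions.append(Reaction(id=rid, reactants=reactants, products=products, reversible=reversible))
        elif line.startswith("CAT:"):
            body = line[len("CAT:"):].strip()
            if "->" not in body:
                raise CRSFormatError(f"line {lineno}: expected 'CAT: x -> <reaction id>'")
            x, rid = (tok.strip() for tok in body.split("->", 1))
            catalysis.append((x, rid))
        elif line.startswith("INH:"):
            body = line[len("INH:"):].strip()
            if "-|" not in body:
                raise CRSFormatError(f"line {lineno}: expected 'INH: x -| <reaction id>'")
            x, rid = (tok.strip() for tok in body.split("-|", 1))
            inhibition.append((x, rid))
        else:
            raise CRSFormatError(f"line {lineno}: unrecognised directive {line.split(':')[0]!r}")
    known = set(molecules) | set(food)
    for r in reactions:
        known |= r.molecules()
    for x, rid in catalysis + inhibition:
        if x not in known:
            raise CRSFormatError(f"unknown molecule id {x!r}")
    rid_set = {r.id for r in reactions}
    for _, rid in catalysis:
        if rid not in rid_set:
            raise CRSFormatError(f"catalysis refers to undefined reaction {rid!r}")
    for _, rid in inhibition:
        if rid not in rid_set:
            raise CRSFormatError(f"inhibition refers to undefined reaction {rid!r}")
    return CRS(
        molecules=sorted(known),
        reactions=reactions,
        catalysis=catalysis,
        inhibition=inhibition,
        food=food,
    )


def crs_to_json(crs: CRS) -> str:
    """Serialise a CRS as canonical (sorted, indented) JSON."""
    doc = {
        "molecules": sorted(crs.molecules),
        "food": sorted(crs.food),
        "reactions": [
            {
                "id": rid,
                "reactants": sorted(crs.reactions[rid].reactants),
                "products": sorted(crs.reactions[rid].products),
                "reversible": crs.reactions[rid].reversible,
            }
            for rid in sorted(crs.reactions)
        ],
        "catalysis": [list(p) for p in sorted(crs.catalysis)],
        "inhibition": [list(p) for p in sorted(crs.inhibition)],
    }
    return json.dumps(doc, indent=1, sort_keys=True) + "\n"


def crs_from_json(text: str) -> CRS:
    doc = json.loads(text)
    return CRS(
        molecules=doc.get("molecules", []),
        reactions=[
            Reaction(
                id=r["id"],
                reactants=frozenset(r["reactants"]),
                products=frozenset(r["products"]),
                reversible=bool(r.get("reversible", False)),
            )
            for r in doc.get("reactions", [])
        ],
        catalysis=[tuple(p) for p in doc.get("catalysis", [])],
        inhibition=[tuple(p) for p in doc.get("inhibition", [])],
        food=doc.get("food", []),
    )


def read_crs(path: str | Path) -> CRS:
    """Read a CRS from a ``.json`` or text-format file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return crs_from_json(text)
    return _parse_text(text)


def write_crs(crs: CRS, path: str | Path) -> None:
    """Write a CRS in the format implied by the file suffix (canonical)."""
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(crs_to_json(crs))
    else:
        path.write_text(format_crs(crs))
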