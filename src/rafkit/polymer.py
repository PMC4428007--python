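"""Binary polymer model generator and hand-built example networks.

Molecules are binary strings of length 1..n; the food set holds all strings of
length <= t.  Every ligation/cleavage pair is one reversible reaction entity:
for each product string ``s`` of length 2..n and each cut position ``i`` there
is one reaction ``s[:i] + s[i:] <-> s``.  Ligation is ordered concatenation,
so ``a+b -> ab`` and ``b+a -> ba`` are distinct entities.  This gives

    |X| = 2^(n+1) - 2,     |R| = sum_{L=2..n} 2^L (L-1).

Catalysis is random: each (molecule, reaction) pair enters C independently
with probability ``p_cat``.  Sampling is done per reaction — draw
k ~ Binomial(|X|, p_cat), then k distinct molecules uniformly — which is
exactly equivalent to per-pair Bernoulli draws but feasible when |X|·|R| is
large.  Inhibition (optional) picks m inhibitor molecules uniformly from
X − F and then assigns (x, r) pairs with probability ``q_inh``.

All randomness flows from a single root seed; independent substreams are used
for catalysis, inhibitor choice and inhibition pairs, so adding inhibition
never perturbs the catalysis draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from itertools import product as _iproduct

import numpy as np

from .crs import CRS, Reaction

__all__ = [
    "PolymerParams",
    "AbstractRAFFamily",
    "generate_polymer_crs",
    "add_inhibition",
    "make_linear_chain",
    "make_cross_catalytic_cycle",
    "make_four_irrraf_family",
    "make_pair_family",
    "pair_family_overlap",
    "polymer_molecule_count",
    "polymer_reaction_count",
]

_MAX_N = 16  # 2^(n+1)-2 molecules; enumeration guard


@dataclass(frozen=True)
class PolymerParams:
    """Parameters of the binary polymer model.

    n: maximum polymer length; t: maximum food-string length (1 <= t < n);
    p_cat: per-(molecule, reaction) catalysis probability; m / q_inh: number
    of inhibitor molecules and per-pair inhibition probability (m=0 disables
    inhibition); seed: root RNG seed.
    """

    n: int
    t: int = 2
    p_cat: float = 0.0
    m: int = 0
    q_inh: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.t < self.n):
            raise ValueError("require 1 <= t < n")
        if not (0.0 <= self.p_cat <= 1.0 and 0.0 <= self.q_inh <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n > _MAX_N:
            raise ValueError(f"n={self.n} exceeds enumeration guard ({_MAX_N})")
        if self.m < 0:
            raise ValueError("m must be non-negative")


def polymer_molecule_count(n: int) -> int:
    return 2 ** (n + 1) - 2


def polymer_reaction_count(n: int) -> int:
    return sum(2**L * (L - 1) for L in range(2, n + 1))


def _all_strings(n: int) -> list[str]:
    out: list[str] = []
    for L in range(1, n + 1):
        out.extend("".join(bits) for bits in _iproduct("01", repeat=L))
    return out


def generate_polymer_crs(params: PolymerParams) -> CRS:
    """Generate a seeded instance of the binary polymer model."""
    n, t = params.n, params.t
    molecules = _all_strings(n)
    food = [x for x in molecules if len(x) <= t]
    reactions: list[Reaction] = []
    for s in molecules:
        L = len(s)
        if L < 2:
            continue
        for i in range(1, L):
            left, right = s[:i], s[i:]
            reactions.append(
                Reaction(
                    id=f"{left}+{right}={s}",
                    reactants=frozenset({left, right}),
                    products=frozenset({s}),
                    reversible=True,
                )
            )
    catalysis: list[tuple[str, str]] = []
    if params.p_cat > 0.0:
        rng = np.random.default_rng([params.seed, 0xCA7])
        n_mol = len(molecules)
        counts = rng.binomial(n_mol, params.p_cat, size=len(reactions))
        for ri in np.flatnonzero(counts):
            k = int(counts[ri])
            for xi in rng.choice(n_mol, size=k, replace=False):
                catalysis.append((molecules[int(xi)], reactions[ri].id))
    crs = CRS(
        molecules=molecules,
        reactions=reactions,
        catalysis=catalysis,
        food=food,
    )
    if params.m > 0:
        crs = add_inhibition(crs, params.m, params.q_inh, params.seed)
    return crs


def add_inhibition(crs: CRS, m: int, q_inh: float, seed: int) -> CRS:
    """Return a copy of ``crs`` with a random inhibition set.

    Exactly ``m`` inhibitor molecules are drawn uniformly from X − F (food
    molecules can never be inhibitors); each (inhibitor, reaction) pair joins
    I independently with probability ``q_inh``.
    """
    if crs.inhibition:
        raise ValueError("CRS already has an inhibition set")
    non_food = sorted(set(crs.molecules) - crs.food)
    if m > len(non_food):
        raise ValueError(f"m={m} exceeds |X - F| = {len(non_food)}")
    rng_pick = np.random.default_rng([seed, 0x1AB])
    rng_pairs = np.random.default_rng([seed, 0x1AC])
    inhibitors = [non_food[int(i)] for i in rng_pick.choice(len(non_food), size=m, replace=False)]
    rids = sorted(crs.reactions)
    inhibition: list[tuple[str, str]] = []
    for x in inhibitors:
        k = int(rng_pairs.binomial(len(rids), q_inh)) if q_inh > 0 else 0
        if k:
            for ri in rng_pairs.choice(len(rids), size=k, replace=False):
                inhibition.append((x, rids[int(ri)]))
        elif q_inh == 0.0:
            pass
    crs2 = CRS(
        molecules=sorted(crs.molecules),
        reactions=[crs.reactions[r] for r in rids],
        catalysis=sorted(crs.catalysis),
        inhibition=inhibition,
        food=sorted(crs.food),
    )
    # record the chosen inhibitor molecules even if they inhibit nothing
    crs2.declared_inhibitors = frozenset(inhibitors)
    return crs2


def make_linear_chain(N: int) -> CRS:
    """A linear chain of N reactions with no RAF and no pseudo-RAF.

    Reaction ``r_i`` transforms ``x_{i-1}`` into ``x_i`` (i = 1..N); each
    molecule ``x_{i+1}`` catalyses the reaction creating ``x_i``; the final
    reaction, creating ``x_N``, is uncatalysed; ``x_0`` is the only food
    molecule.  The basic algorithm needs N-1 closure computations to conclude
    that no RAF exists; the accelerated algorithm needs one.
    """
    if N < 2:
        raise ValueError("N must be at least 2")
    width = len(str(N))
    mol = [f"x{i:0{width}d}" for i in range(N + 1)]
    reactions = [
        Reaction(id=f"r{i:0{width}d}", reactants=frozenset({mol[i - 1]}), products=frozenset({mol[i]}))
        for i in range(1, N + 1)
    ]
    catalysis = [(mol[i + 1], f"r{i:0{width}d}") for i in range(1, N)]
    return CRS(molecules=mol, reactions=reactions, catalysis=catalysis, food=[mol[0]])


def make_cross_catalytic_cycle(k: int = 3) -> CRS:
    """A k-cycle of mutually sustaining reactions: a pseudo-RAF but not an RAF.

    Reaction ``r_i`` consumes food molecule ``f_i`` together with the previous
    cycle product ``p_{i-1}`` and produces ``p_i``, catalysed by ``p_i``.
    Every reactant and catalyst lies in F ∪ π(R), yet nothing can get started
    from the food set alone, so the network is not F-generated.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    food = [f"f{i}" for i in range(1, k + 1)]
    prods = [f"p{i}" for i in range(1, k + 1)]
    reactions = []
    catalysis = []
    for i in range(k):
        rid = f"r{i + 1}"
        reactions.append(
            Reaction(
                id=rid,
                reactants=frozenset({food[i], prods[i - 1]}),
                products=frozenset({prods[i]}),
            )
        )
        catalysis.append((prods[i], rid))
    return CRS(molecules=food + prods, reactions=reactions, catalysis=catalysis, food=food)


@dataclass(frozen=True)
class AbstractRAFFamily:
    """An explicitly listed union-closed family of irreducible RAFs.

    The RAF subsets of the (implicit) CRS are exactly the non-empty unions of
    the listed irrRAFs, so the maximum RAF of any label subset S is the union
    of the listed sets contained in S.  ``classes`` partitions the labels into
    exchangeability classes: two labels share a class iff they belong to
    exactly the same irrRAFs (so they are interchangeable under the sampler).
    """

    labels: tuple[str, ...]
    irrrafs: tuple[frozenset[str], ...]
    classes: tuple[frozenset[str], ...] = field(default=())

    def __post_init__(self) -> None:
        lab = set(self.labels)
        for s in self.irrrafs:
            if not s <= lab:
                raise ValueError("irrRAF contains unknown label")
        for a in self.irrrafs:
            for b in self.irrrafs:
                if a < b:
                    raise ValueError("listed irrRAFs must be minimal (no strict containment)")
        if not self.classes:
            object.__setattr__(self, "classes", self._derive_classes())
        else:
            if tuple(sorted(map(sorted, self.classes))) != tuple(
                sorted(map(sorted, self._derive_classes()))
            ):
                raise ValueError("classes do not match irrRAF membership patterns")

    def _derive_classes(self) -> tuple[frozenset[str], ...]:
        sig: dict[tuple[int, ...], set[str]] = {}
        for x in self.labels:
            key = tuple(i for i, s in enumerate(self.irrrafs) if x in s)
            sig.setdefault(key, set()).add(x)
        return tuple(frozenset(v) for _, v in sorted((min(s), s) for s in sig.values()))

    def all_labels(self) -> frozenset[str]:
        return frozenset(self.labels)

    def maxraf(self, subset) -> frozenset[str]:
        """Union of the listed irrRAFs contained in ``subset``."""
        s = frozenset(subset)
        out: set[str] = set()
        for irr in self.irrrafs:
            if irr <= s:
                out |= irr
        return frozenset(out)


def make_four_irrraf_family() -> AbstractRAFFamily:
    """The 12-reaction counterexample with exactly four irrRAFs A, B, C, D.

    A and B have four reactions each and are disjoint from everything else;
    C and D have three reactions each and share r9 and r10.  Despite C and D
    being smaller, the sampler finds A or B slightly more often because of
    that overlap.
    """
    labels = tuple(f"r{i}" for i in range(1, 13))
    A = frozenset({"r1", "r2", "r3", "r4"})
    B = frozenset({"r5", "r6", "r7", "r8"})
    C = frozenset({"r9", "r10", "r11"})
    D = frozenset({"r9", "r10", "r12"})
    return AbstractRAFFamily(labels=labels, irrrafs=(A, B, C, D))


def make_pair_family(N: int) -> AbstractRAFFamily:
    """The N-pair family with exponentially many irrRAFs.

    2N reactions come in pairs (r_i, r_i'); every irrRAF picks exactly one
    member of each pair, giving 2^N irrRAFs, all of size N.
    """
    if not (1 <= N <= 12):
        raise ValueError("N must be in 1..12 (2^N irrRAFs are enumerated)")
    labels = tuple(f"r{i}" for i in range(1, N + 1)) + tuple(f"r{i}'" for i in range(1, N + 1))
    irrrafs = []
    for choice in _iproduct((0, 1), repeat=N):
        irrrafs.append(
            frozenset(f"r{i + 1}" if c == 0 else f"r{i + 1}'" for i, c in enumerate(choice))
        )
    return AbstractRAFFamily(labels=labels, irrrafs=tuple(irrrafs))


def pair_family_overlap(N: int) -> tuple[Fraction, float]:
    """Exact average overlap O of the N-pair family, (2^(N-1) - 1)/(2^N - 1).

    Each irrRAF shares k of its N reactions with C(N, k) of the other
    2^N - 1 irrRAFs; averaging k/N over all of them gives the closed form.
    """
    if N < 1:
        raise ValueError("N must be at least 1")
    val = Fraction(2 ** (N - 1) - 1, 2**N - 1)
    return val, float(val)
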