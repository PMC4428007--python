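"""Random sampling of irreducible RAFs and sample statistics.

The sampler performs a single pass over a uniformly shuffled ordering of the
starting RAF's reactions.  For each reaction still present it tentatively
deletes it and recomputes the maximum RAF of the remainder; if a non-empty RAF
survives, the current set shrinks to that maxRAF, otherwise the reaction is
retained as necessary.  A reaction retained this way stays necessary for every
later (smaller) current set, so the result is an irreducible RAF.

Because the irrRAF found depends on the ordering, repeated shuffled runs
sample the (generally enormous) space of irrRAFs.  The number of *distinct*
sets among S runs feeds a birthday-problem bound: if all S are distinct, the
CRS contains more than S^2/10 irrRAFs with < 1% type-I error.

Overlap and coverage statistics quantify how much sampled irrRAFs share:
``O_ij = |R_i ∩ R_j| / |R_i|`` (asymmetric), ``O_i`` its mean over j != i,
``O`` the sample mean of ``O_i``; ``C_i`` is the fraction of R_i's reactions
appearing in at least one other sampled set, and ``C`` its sample mean.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Iterable, Sequence

import numpy as np
from numba import njit

from .crs import CRS
from .polymer import AbstractRAFFamily

__all__ = [
    "IrrRAFSample",
    "OverlapStats",
    "BirthdayTest",
    "CrsMaxRAFProvider",
    "FamilyMaxRAFProvider",
    "sample_irrraf",
    "sample_irrrafs",
    "overlap_stats",
    "average_overlap_exact",
    "birthday_test",
    "exact_sampler_distribution",
]


# ---------------------------------------------------------------------------
# maxRAF providers
# ---------------------------------------------------------------------------
class CrsMaxRAFProvider:
    """Maps reaction subsets of a CRS to their maximum RAF.

    Internally restricts the network to the starting subset once, so the many
    small maxRAF computations of the sampler stay cheap.
    """

    def __init__(self, crs: CRS, within: Iterable[str] | None = None):
        self.crs = crs
        if within is None:
            self._net = crs.network()
        else:
            self._net = crs.network().restricted_to(crs.subset(within))

    def maxraf(self, subset: Iterable[str]) -> frozenset[str]:
        net = self._net
        mask = net.mask_from_ids(subset)
        out, _, _ = net.maxraf_modified(mask)
        return net.ids_from_mask(out)


class FamilyMaxRAFProvider:
    """maxRAF provider over an :class:`AbstractRAFFamily` (no concrete CRS)."""

    def __init__(self, family: AbstractRAFFamily):
        self.family = family

    def maxraf(self, subset: Iterable[str]) -> frozenset[str]:
        return self.family.maxraf(subset)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------
def sample_irrraf(provider, start: Iterable[str], rng: np.random.Generator) -> frozenset[str]:
    """Draw one irreducible RAF from the RAF ``start`` by random deletion."""
    start = frozenset(start)
    if provider.maxraf(start) != start:
        raise ValueError("start subset is not an RAF under the given provider")
    order = sorted(start)
    rng.shuffle(order)
    current = set(start)
    for rid in order:
        if rid not in current:
            continue
        reduced = provider.maxraf(current - {rid})
        if reduced:
            current = set(reduced)
    return frozenset(current)


@dataclass
class IrrRAFSample:
    """S independently sampled irrRAFs plus their distinct count."""

    samples: list[frozenset[str]]
    seed: int
    distinct_count: int

    @property
    def S(self) -> int:
        return len(self.samples)

    def sizes(self) -> list[int]:
        return [len(s) for s in self.samples]


def sample_irrrafs(provider, start: Iterable[str], S: int, seed: int) -> IrrRAFSample:
    """Draw S irrRAFs with independent seeded shuffles.

    Distinctness uses canonical identity (the sorted reaction-id tuple); full
    tuples are compared, so no hash collisions are tolerated.
    """
    if S < 1:
        raise ValueError("S must be at least 1")
    rng = np.random.default_rng(seed)
    samples = [sample_irrraf(provider, start, rng) for _ in range(S)]
    distinct = len({tuple(sorted(s)) for s in samples})
    return IrrRAFSample(samples=samples, seed=seed, distinct_count=distinct)


# ---------------------------------------------------------------------------
# overlap / coverage statistics
# ---------------------------------------------------------------------------
@dataclass
class OverlapStats:
    pairwise: np.ndarray  # O_ij, S x S, diagonal set to 1
    per_irrraf_overlap: np.ndarray  # O_i
    per_irrraf_coverage: np.ndarray  # C_i
    average_overlap: float  # O
    average_coverage: float  # C


def _membership_matrix(subsets: Sequence[frozenset[str]]):
    universe = sorted(set().union(*subsets))
    index = {x: i for i, x in enumerate(universe)}
    M = np.zeros((len(subsets), len(universe)), dtype=np.float64)
    for i, s in enumerate(subsets):
        for x in s:
            M[i, index[x]] = 1.0
    return M


def overlap_stats(sample: IrrRAFSample | Sequence[frozenset[str]]) -> OverlapStats:
    """Compute O_ij, O_i, C_i, O and C over a sample of reaction subsets.

    Duplicate subsets are retained: the statistics describe the sample, not
    the distinct sets.  Requires S >= 2.
    """
    subsets = sample.samples if isinstance(sample, IrrRAFSample) else list(sample)
    S = len(subsets)
    if S < 2:
        raise ValueError("overlap statistics require at least two samples")
    M = _membership_matrix(subsets)
    sizes = M.sum(axis=1)
    inter = M @ M.T
    O = inter / sizes[:, None]
    O_i = (O.sum(axis=1) - 1.0) / (S - 1)  # exclude the diagonal (O_ii = 1)
    total = M.sum(axis=0)
    # a reaction of R_i is covered iff it appears in >= 1 other sampled set
    covered = M * (total[None, :] - M >= 1.0)
    C_i = covered.sum(axis=1) / sizes
    return OverlapStats(
        pairwise=O,
        per_irrraf_overlap=O_i,
        per_irrraf_coverage=C_i,
        average_overlap=float(O_i.mean()),
        average_coverage=float(C_i.mean()),
    )


def reaction_share_proportions(
    sample: IrrRAFSample | Sequence[frozenset[str]],
) -> list[dict[str, float]]:
    """p_i(r): per sampled set, the proportion of the other S-1 sets
    containing each of its reactions.  O_i is the mean of p_i(r) over R_i."""
    subsets = sample.samples if isinstance(sample, IrrRAFSample) else list(sample)
    S = len(subsets)
    if S < 2:
        raise ValueError("share proportions require at least two samples")
    count: dict[str, int] = {}
    for s in subsets:
        for x in s:
            count[x] = count.get(x, 0) + 1
    return [{x: (count[x] - 1) / (S - 1) for x in s} for s in subsets]


def average_overlap_exact(subsets: Sequence[frozenset[str]]) -> tuple[Fraction, Fraction]:
    """(O, C) as exact rationals, via the reaction-share identity.

    O_i equals the mean over r in R_i of p_i(r), the proportion of the other
    S-1 sets containing r.  This is an independent code path from the
    pairwise-matrix computation in :func:`overlap_stats`.
    """
    S = len(subsets)
    if S < 2:
        raise ValueError("overlap statistics require at least two samples")
    count: dict[str, int] = {}
    for s in subsets:
        for x in s:
            count[x] = count.get(x, 0) + 1
    O = Fraction(0)
    C = Fraction(0)
    for s in subsets:
        O_i = Fraction(0)
        cov = 0
        for x in s:
            O_i += Fraction(count[x] - 1, S - 1)
            if count[x] >= 2:
                cov += 1
        O += O_i / len(s)
        C += Fraction(cov, len(s))
    return O / S, C / S


# ---------------------------------------------------------------------------
# birthday-problem bound
# ---------------------------------------------------------------------------
@dataclass
class BirthdayTest:
    """Hypothesis test H0: "at most S^2/10 irrRAFs exist"."""

    S: int
    distinct_count: int
    N0: float  # hypothesised bound S^2 / 10
    lam: float  # birthday-collision rate C(S,2)/N0
    p_bound: float  # exp(-lam), an upper bound on P(all distinct | H0)
    reject: bool  # reject H0 iff all S samples are distinct

    @property
    def asserted_lower_bound(self) -> float | None:
        """If H0 is rejected: more than S^2/10 irrRAFs, at <1% type-I error."""
        return self.N0 if self.reject else None


def birthday_test(S: int, distinct_count: int) -> BirthdayTest:
    """Decide whether the sample supports "more than S^2/10 irrRAFs".

    Rejects H0 iff all S sampled irrRAFs are distinct.  The bound
    P(all distinct) <= exp(-C(S,2)/N) holds for any sampling distribution over
    N types, so with N0 = S^2/10 the type-I error is below exp(-5) < 0.01.
    """
    if distinct_count > S:
        raise ValueError("distinct_count cannot exceed S")
    if S < 30:
        warnings.warn("birthday test is calibrated for S >= 30", stacklevel=2)
    N0 = S * S / 10.0
    lam = S * (S - 1) / 2.0 / N0
    return BirthdayTest(
        S=S,
        distinct_count=distinct_count,
        N0=N0,
        lam=lam,
        p_bound=math.exp(-lam),
        reject=distinct_count == S,
    )


# ---------------------------------------------------------------------------
# exact sampler distribution on abstract families
# ---------------------------------------------------------------------------
@njit(cache=True)
def _enumerate_orderings(class_seq, member_masks, irr_masks, start_mask):
    """Run the single-pass sampler on every distinct ordering of class labels.

    ``class_seq`` is the lexicographically smallest multiset permutation; the
    standard next-permutation step enumerates each distinct ordering exactly
    once.  ``member_masks[c]`` lists the bitmask of each member of class c in
    a fixed order: within-class order is irrelevant by exchangeability, so the
    k-th occurrence of class c in an ordering removes its k-th member.
    Returns the termination count per irrRAF and the number of orderings.
    """
    L = class_seq.size
    n_irr = irr_masks.size
    counts = np.zeros(n_irr, np.int64)
    seq = class_seq.copy()
    taken = np.zeros(member_masks.shape[0], np.int64)
    total = 0
    while True:
        # simulate one ordering
        for c in range(taken.size):
            taken[c] = 0
        current = start_mask
        for pos in range(L):
            c = seq[pos]
            label = member_masks[c, taken[c]]
            taken[c] += 1
            if current & label == 0:
                continue
            cand = current & ~label
            red = 0
            for i in range(n_irr):
                if irr_masks[i] & cand == irr_masks[i]:
                    red |= irr_masks[i]
            if red != 0:
                current = red
        for i in range(n_irr):
            if current == irr_masks[i]:
                counts[i] += 1
                break
        total += 1
        # next multiset permutation (lexicographic)
        k = L - 2
        while k >= 0 and seq[k] >= seq[k + 1]:
            k -= 1
        if k < 0:
            break
        j = L - 1
        while seq[j] <= seq[k]:
            j -= 1
        tmp = seq[k]
        seq[k] = seq[j]
        seq[j] = tmp
        lo = k + 1
        hi = L - 1
        while lo < hi:
            tmp = seq[lo]
            seq[lo] = seq[hi]
            seq[hi] = tmp
            lo += 1
            hi -= 1
    return counts, total


def exact_sampler_distribution(
    family: AbstractRAFFamily, max_orderings: int = 10_000_000
) -> dict[frozenset[str], Fraction]:
    """Exact termination probabilities of the irrRAF sampler on a family.

    Enumerates every distinct ordering of exchangeability-class labels
    (uniformly weighted — within-class permutations contribute identical
    factors) and simulates the single-pass sampler deterministically on each.
    """
    labels = list(family.labels)
    if len(labels) > 62:
        raise ValueError("too many labels for bitmask enumeration")
    classes = [sorted(c) for c in family.classes]
    mult = [len(c) for c in classes]
    n_orderings = math.factorial(len(labels))
    for m in mult:
        n_orderings //= math.factorial(m)
    if n_orderings > max_orderings:
        raise ValueError(
            f"{n_orderings} class orderings exceed the guard ({max_orderings}); "
            "use Monte Carlo sampling instead"
        )
    bit = {x: 1 << i for i, x in enumerate(labels)}
    irr_masks = np.asarray(
        [sum(bit[x] for x in s) for s in family.irrrafs], dtype=np.int64
    )
    start_mask = np.int64(0)
    for m in irr_masks:
        start_mask |= m
    class_seq = np.asarray(
        sorted(ci for ci, m in enumerate(mult) for _ in range(m)), dtype=np.int64
    )
    width = max(mult)
    member_masks = np.zeros((len(classes), width), np.int64)
    for ci, members in enumerate(classes):
        for k, x in enumerate(members):
            member_masks[ci, k] = bit[x]
    counts, total = _enumerate_orderings(class_seq, member_masks, irr_masks, start_mask)
    assert total == n_orderings
    assert counts.sum() == total, "sampler did not terminate at a listed irrRAF"
    return {
        family.irrrafs[i]: Fraction(int(counts[i]), total) for i in range(len(family.irrrafs))
    }
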