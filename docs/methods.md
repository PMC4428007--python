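# Methods

## The model

A chemical reaction system (CRS) is a tuple (X, R, C, I, F): molecule types
X, reactions R, catalysis pairs C ⊆ X × R, optional inhibition pairs
I ⊆ X × R, and a food set F ⊆ X of molecules assumed freely available.  The
closure cl_R'(F) of the food set under a reaction subset R' is everything
producible from F by repeatedly applying reactions of R'; it is a least fixed
point and does not depend on application order.  Availability is set-based:
one copy of a molecule satisfies any multiplicity, and no concentrations or
kinetics are modelled.

A subset R' is a **RAF** (reflexively autocatalytic and food-generated) if
every reaction in R' has at least one catalyst in cl_R'(F) and all its
reactants in cl_R'(F).  RAFs are closed under union, so a CRS has a unique
maximum RAF (maxRAF), possibly empty — every API treats "no RAF" as an
explicit empty result rather than an error.  A **pseudo-RAF** weakens the
closure to F ∪ π(R') (food plus everything the subset produces); pseudo-RAFs
are also union-closed, every RAF is a pseudo-RAF, and an F-generated
pseudo-RAF is a RAF.

### Reversible reactions

A ligation/cleavage pair is represented as one reaction entity carrying two
directed rules.  The closure may fire either direction; a catalyst catalyses
both; the RAF conditions hold if at least one direction's reactant side is
satisfied.  For the pseudo-RAF layer, π(r) of a reversible entity contains
both sides (each side is the product of one direction).  This convention
reproduces the binary polymer model's reaction counts (Σ_{L=2..n} 2^L(L−1))
and the reaction-set sizes that make the calibration numbers meaningful
(e.g. maxRAFs of ~1400 entities at n=10).

## Detection algorithms

**Basic.**  Iterate the map f — keep reactions whose reactants and at least
one catalyst lie in the closure of the current subset — until the first fixed
point.  Each application costs one closure computation, the unit of work
reported everywhere.  Reactions with no catalyst at all can never satisfy the
RA condition and are discarded up front without a closure call; by
monotonicity of f this does not change the result, and it gives the expected
operation counts on reference networks (N−1 calls on the N-reaction linear
chain whose final reaction is uncatalysed).  If that pre-filter empties a
non-empty input, one confirming f-application (one closure call) is still
made, so a non-empty input always reports ≥ 1 call.

**Accelerated (pseudo-RAF based).**  One closure per outer iteration, then a
cascading prune that needs no further closures: per-molecule counts of
*active* producing reactions (those fired during the last closure) are
maintained, a reaction is discarded when a needed reactant or its last
available catalyst loses all active producers, and each removal decrements
the counts of its products, possibly cascading.  When a pass removes nothing,
the surviving set is a fixed point of f and hence the maxRAF; when it empties,
no RAF exists.  The result is always identical to the basic algorithm and the
closure-call count never exceeds it (the working set after k closures is
contained in the basic algorithm's after k applications, by monotonicity).
The alternative of running the pure fixp cascade *before* the first closure
would report zero calls on RAF-free networks; computing the first closure up
front matches the call counts expected for the reference chain (exactly one)
and anchors the producer counts in actual producibility rather than the
weaker F ∪ π availability.

**Maximum pseudo-RAF (fixp)** is computed by the same decremental counting
against F ∪ π availability, in linear time and with no closure calls.  An
independent oracle is provided via HORN-SAT: in the expanded CRS (uncatalysed
reactions deleted; each remaining reaction replaced by one copy per catalyst,
and per direction for reversible entities, with the nominated catalyst added
as a reactant) the minimal satisfying assignment of the Horn formula —
reactant clauses, producer clauses, food units — is found by unit propagation
with watched producer counters; reactions whose literals stay false form the
maximum pseudo-RAF.  The two paths are checked for equality on random
systems; the Horn path is an oracle, not the default engine.

**Generalized framework.**  RAF detection is an instance of gf-compatibility:
ψ(A) = {y ∈ A : g(y) ≤ f(A)} with Y the expanded rules, f(A) the closure of
the underlying reactions of A *ignoring catalyst availability*, and g(r) the
reactants of r including its nominated catalyst.  For monotone f, iterating ψ
from Y descends to the unique maximum gf-compatible set; the implementation
takes an explicit comparator for W so the inhibition variant
(W = 2^X × 2^X, f(A) = (cl_A(F), X − cl_A(F)), g(r) = (ρ(r), in(r))) shares
the same engine.  That variant is non-monotone and is deliberately *not*
solved by ψ-iteration — it is only used to verify that detected u-RAFs are ψ
fixed points; the sanctioned solver is the inhibitor-subset enumeration.

## Binary polymer model

Molecules are the binary strings of length 1..n; food is every string of
length ≤ t.  One reversible entity exists per (product string, cut site);
ligation is ordered concatenation, so a+b→ab and b+a→ba are distinct
entities.  Catalysis is assigned per reaction by drawing
k ~ Binomial(|X|, p) and then k distinct molecules uniformly — exactly
equivalent to independent per-pair Bernoulli draws but feasible when
|X|·|R| is large.  Molecules may catalyse reactions they participate in,
including their own producers; food molecules may catalyse.  Inhibition
draws m inhibitor molecules uniformly from X − F, then (x, r) pairs with
probability q per pair.  One root seed feeds independent substreams for
catalysis, inhibitor choice and inhibition pairs, so enabling inhibition
never perturbs the catalysis draw and identical parameters give
byte-identical serialised instances.

Default study conditions used throughout tests and the acceptance script are
the model's standard calibration points: n=8, t=2, p=0.00041 (≈50% of
instances contain a RAF) and p=0.00045 (≈all do); n=12, t=2, p=1.609×10⁻⁵
for the algorithm comparison; n=10, t=2, p=7.92×10⁻⁵, m=10 for the
inhibition study, with q ∈ {p, 10p, 100p}.

At these calibration points the emergence regime is bimodal: instances either
contain a macroscopic maxRAF (hundreds of reactions at n=8, over a thousand
at n=10) or only a tiny accidental one (a handful of self-sustaining
reactions, e.g. a food-fed ligation catalysed by a food molecule).  The
RAF-existence probability counts both; every size, irrRAF and overlap
statistic is conditioned on the macroscopic branch (threshold: 100
reactions), which is the only branch that can host the large all-distinct
irrRAF samples those statistics describe.

What the generator does *not* emulate: template-based or power-law catalysis,
partitioned polymer sets, stoichiometry, kinetics, or real chemistries.
Passing tests therefore demonstrate the algorithms' correctness and the
random model's statistics, not claims about any laboratory system.

## Sampling irreducible RAFs

An irrRAF is a RAF no proper subset of which is a RAF.  The sampler shuffles
the starting RAF's reactions once and makes a single pass: each reaction
still present is tentatively removed, the maxRAF of the remainder is
computed, and the current set either shrinks to that maxRAF or keeps the
reaction as necessary.  A reaction retained because its removal destroyed
every RAF remains necessary for every later, smaller current set, so the
result is irreducible; this is asserted wholesale in tests.  Whether the
procedure should re-iterate passes is a genuinely open design point — a
second pass cannot remove anything from an already irreducible set, and the
single-pass variant reproduces the termination probabilities of the
12-reaction worked example exactly (Pr = 58/231 and 115/462 by enumeration
over all 415,800 orderings of the five exchangeability classes), so the
single pass is taken as definitive.

Distinctness of samples uses the sorted reaction-id tuple — full tuples are
compared, so hash collisions cannot conflate two irrRAFs.  The birthday
bound turns an all-distinct sample of size S into the statement "more than
S²/10 irrRAFs exist" with type-I error below exp(−C(S,2)/(S²/10)) ≈
exp(−5) < 1%, valid for any sampling distribution.

Overlap statistics follow the definitions exactly: O_ij = |R_i ∩ R_j|/|R_i|
(asymmetric), O_i the mean over j ≠ i, O the sample mean of O_i; C_i the
fraction of R_i's reactions present in at least one other sampled set, C its
mean.  Duplicates in a sample are retained.  Two independent code paths (the
pairwise matrix and the reaction-share identity O_i = mean_r p_i(r)) are
kept and compared in tests, exactly on rationals.

## Inhibition

A u-RAF is a RAF none of whose reactions is inhibited by any molecule of its
own closure — a deliberately strong, all-or-nothing notion of inhibition.
Finding u-RAFs is NP-hard in general, but for every subset K of the
inhibitor set X_I, the reduced reaction set R_−K (no product in K, inhibited
only by members of K) has the property that *any* RAF inside it is
automatically uninhibited, and every maximal u-RAF arises as the maxRAF of
some reduced system.  The implementation enumerates all 2^|X_I| subsets
(guarded, default |X_I| ≤ 20), visits them in Gray-code order, computes each
reduced set by bitmask filtering, and restricts every run to the maxRAF of
the uninhibited system — a pure speed-up, since every RAF of a reduced
system lies inside it.  Reactions inhibited by food molecules are removed
once, up front.  Results are deduplicated before the inclusion-maximality
analysis.  For a reversible entity, "product" means any molecule producible
by either direction; this keeps the no-self-inhibition argument valid under
the entity convention.

## Numerical and engineering choices

- The closure and pruning kernels are JIT-compiled (numba) over CSR integer
  arrays; all set-level APIs work with string ids and convert at the
  boundary.  Iteration orders are fixed (sorted ids) everywhere the
  mathematics is order-independent, so outputs are bit-reproducible.
- Sampler-heavy workloads restrict the network to the starting RAF once and
  run the many small maxRAF computations on the restricted index.
- The exact sampler distribution enumerates multiset permutations of
  exchangeability classes (equal weight each; within-class permutations
  contribute identical factors) with a guard at 10⁷ orderings; beyond that
  the Monte Carlo sampler is the fallback.
- Floats in reports are serialised with 17 significant digits so determinism
  is auditable; all CLI randomness flows from explicit seeds recorded in the
  output.
- Degenerate inputs: the empty reaction set reports zero closure calls; an
  entirely uncatalysed (non-empty) reaction set reports exactly one
  confirming call; the empty subset is vacuously a RAF/pseudo-RAF and is
  flagged `is_empty` rather than raising.

## Problem sizes in the shipped checks

The acceptance script uses 800 instances for the RAF-probability estimate,
20 RAF-containing instances × 50 samples for the mean irrRAF size, 20
RAF-containing instances × 100 samples per catalysis level for overlap and
coverage, and 10 RAF-containing instances at n=10 for the inhibition
baseline; the test suite uses 30 instances for the n=12 algorithm
comparison and 2 full 1024-subset sweeps per inhibition level.  These sizes
give 3-SE sampling tolerances comfortably inside the calibration targets
while keeping a full run in the minutes range on one CPU.

## Known limitations

- The average-overlap level measured on freshly generated instances at the
  calibration points comes out somewhat above the published reference values
  (≈0.65 vs 0.539 at p=0.00041; ≈0.56 vs 0.411 at p=0.00045) even though
  every exactly checkable ingredient (maxRAF detection against brute force,
  sampler distribution against enumeration, overlap formulas against the
  closed-form family) agrees to the digit and the surrounding statistics
  (RAF probability, maxRAF and irrRAF sizes, O_ij range, coverage, the sign
  and strength of the O-vs-size trend, the ordering between the two
  catalysis levels) land on target.  The relative statements are robust; the
  absolute overlap level should be treated as implementation-sensitive.
- The u-RAF sweep is exact but exponential in |X_I|; no heuristic search is
  provided for large inhibitor sets.
- The irrRAF sampler characterises the *sampler's* distribution, not the
  uniform distribution over irrRAFs; the birthday bound is the only
  distribution-free statement made about their number.
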