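# Methods

## The model

A state is a pointed epistemic model (ℳ, W_d): a Kripke model
(W, R, V) over finite agent and proposition sets, with a non-empty set
of designated worlds.  Truth at a single world follows the standard
clauses; truth of a multi-pointed model is the conjunction over its
designated worlds.  An action is a pointed event model (ℰ, E_d): events
carry a precondition formula and a postcondition that is a consistent
set of literals (stored as a proposition→bool map; the empty map is ⊤).
The product update keeps the pairs (w, e) with ℳ, w ⊨ pre(e), relates
(w, e) to (v, f) for agent a iff wR_av and eQ_af, overrides the
valuation by the postcondition, and designates surviving pairs of
designated components.  An action *applies* when some designated
event's precondition holds at some designated world; a sequence applies
when every prefix does, step by step.  Applying an inapplicable action
is an error, never an empty model and never a "no" answer — instances
validate applicability at construction.

The decision problem asks whether the goal formula holds after folding
the whole action sequence into the state.  The solver materializes each
intermediate model; the world count after u updates is bounded by
|W⁰|·eᵘ with e the largest event count per action, which makes the
strategy fixed-parameter tractable in (e, u) and entirely adequate at
the problem sizes this package targets.  A polynomial-space lazy
evaluator is deliberately out of scope.

Conventions worth knowing:

* Relations are stored fully explicit.  Drawings of such models
  conventionally omit reflexive loops; `closure()` (reflexive-transitive
  or with symmetry) converts a transcription of a drawing into the
  stored relation.
* Valuations are sparse (set of true propositions per world).
* Product worlds are named `parent|event`; `|` is reserved and rejected
  in user-supplied ids.
* ⊤/⊥ are kept primitive.  The size measure s(·) counts variable
  occurrences and connectives, the depth measure d(·) counts nested
  belief operators, both after expanding ∨, →, B̂; the constants count
  as size-1, depth-0 atoms.  Expanding ⊤ to p ∨ ¬p instead would inflate
  the "constant precondition size" profile of the SAT construction for
  no semantic gain.

Truth evaluation is memoized per (world, subformula node); the test
suite pins its equivalence to an independently written naive recursive
evaluator on randomized instances.

## Parameters

`parameters()` measures: a = |𝒜|, p = |P|, u = number of event models,
e = max events per event model, c = max s(pre(·)) over all events, f =
s(goal), o = d(goal).  c uses s(·) because it is the only size measure
defined for formulas here; f and o are measured on the goal only, not
on preconditions.  With u = 0, both e and c are 0 by convention.

## The hardness constructions

The generators in `dbu.reductions` build DBU instances from classical
problems; each comes with a brute-force oracle of the source problem,
and the equivalence `solve(reduce(x)) == oracle(x)` is asserted over
exhaustive or densely sampled small domains.  That equivalence — not
any transcription of a diagram — is the correctness contract of the
constructions, and it pins every structural fact the constructions are
known for: u = m (TQBF), u = m + l and constant (a, c, e, f, o)
(3CNF-SAT), u = k + C(k,2) and goal size 2·C(k,2) − 1 (Multicolored
Clique), u = k (weighted 2CNF).

**TQBF.**  A truth assignment is encoded as a *group of worlds*: an
equivalence class of the distinguished agent `a` in which a world
"witnesses x_i true" iff it has an R_i edge to a world where the marker
proposition y holds.  The initial model is the all-true group w₀…w_m
with y-worlds w₁'…w_m' attached (w₀, the *base world*, carries no R_i
edges — base worlds are exactly the worlds with no one-step path to a
y-world).  Update i has two events: one copies everything; the other
(precondition B_i¬y ∨ (y ∧ B_iy)) copies each group minus its x_i
witness, yielding the group for the same assignment with x_i false.
The copies are linked only through agent i's relation, so base worlds
of groups differing exactly in x_i end up R_i-neighbors, and classes of
the variable agents never exceed two worlds.  Quantifiers translate to
B_i (∀) and B̂_i (∃), variable occurrences to B̂_aB̂_i y; evaluating the
translated sentence at the designated base world walks the group
structure exactly as the quantifier tree walks assignments.  After m
updates the model contains one group per assignment (2ᵐ groups; for
m = 2: four groups of sizes 3, 2, 2, 1) regardless of the matrix.

**3CNF-SAT** (single agent; a, c, e, f, o all constant).  m two-event
updates with trivial preconditions double a one-world model into the 2ᵐ
assignments over mirror propositions z₁…z_m, all inside one S5 class.
l clause updates then maintain z_{m+1} ≡ "clauses checked so far hold
at this world", each with two complementary-precondition events (mark /
pass) so every world persists exactly once.  The final clause update
tests B̂_a(z_{m+1} ∧ [c_l]) — a *global* condition in a single S5
class, true at every world or none — and broadcasts the verdict into
z_{m+1} everywhere, so the constant goal z_{m+1} can be read off at the
designated world.  The clause updates designate both events (their
preconditions partition the worlds, so the designated world always
survives exactly once and applicability is guaranteed by construction);
the designated state stays a singleton throughout.

**Multicolored Clique** (goal ⋀_{i<j} r_ij, u = k + C(k,2)).  Selection
stages make each world represent a choice of one vertex per color;
colors 1 and 2 are selected in a single stage (one event per cross
pair), which frees one update.  One stage per color pair (i, j) then
maps each world through the event matching its selected (i, j) pair:
the event posts r_ij if that pair is an actual edge and the dummy z
otherwise, so worlds persist one-to-one and r_ij holds exactly at
worlds whose (i, j) selection is adjacent.  The freed final stage is an
existential funnel: its two events test B̂_a(⋀ r_ij) and its negation
(again global in the single S5 class), and the positive event posts all
r_ij, aligning the designated world with "some world is a multicolored
clique".  Here c grows with k (the funnel precondition mentions all
C(k,2) pair markers) and e and p grow with the graph; none of this
affects the pinned f and u, and the reduction remains computable in
time polynomial for each fixed k.

**Weighted 2CNF.**  Weight-k truth of φ equals weight-(m−k) truth of
the literal-complemented φ′, so k updates that each drop one still-true
variable from every group enumerate exactly the assignments with m−k
variables true.  Update i has one event per variable j; the event's
precondition extends the TQBF falsifier with the conjunct B̂_aB̂_j y
("the group still witnesses x_j"), which blocks dropping a variable
twice — otherwise wrong-weight groups would leak into the model and
break the *exactly* k contract.  Groups that cannot drop x_j die under
that event (only their detached y-worlds survive, unreachable from any
designated world).  The designated event of update i is the one
dropping x_i, which is always applicable along the designated path.
An observer agent b has the identity relation initially and the full
relation inside every event model, so the designated world's R_b class
is exactly the set of surviving copies of w₀ — the base worlds of all
live groups — and the goal B̂_b[φ′] asks whether some weight-(m−k)
group satisfies the complemented formula.  Duplicate groups (one per
drop order) are harmless under that existential goal.

## The Sally-Anne fixture

One proposition `basket`; a single-world S5 initial state where both
agents know the marble's place.  The event model has an "Anne moves the
marble" event (pre `basket`, post `¬basket`) and a "nothing happens"
event; Anne observes which happened, Sally — out of the room — points
only at the nothing event.  That arrow is irreflexive at the actual
event, so the event model (and the updated state) is KD45, not S5:
a *false* belief is exactly a consistent belief that fails reflexivity,
and no S5 event model could produce one.  The fixture answers yes to
"Sally believes the marble is in the basket", yes to "Anne believes it
is not", no to "Sally believes it is not".

## The random instance generator

`random_instance(GeneratorConfig(...))` drives the property tests.  Its
defaults model small talk-sized scenarios: 4 worlds, 2 agents, 3
propositions, 2 actions with at most 2 events — the regime the package
targets (the tractable (e, u) corner), and large enough to exercise
every code path of update and evaluation.  S5 frames are drawn as
random partitions, so they are equivalence relations by construction
rather than by rejection.  Preconditions are random formulas of bounded
depth, biased 70% toward modal-free formulas to keep applicability
checks cheap; actions are redrawn (bounded retries, then an explicit
`GenerationError`) until the growing sequence is applicable, which the
decision problem requires of its inputs.  What the generator does *not*
emulate: large or adversarial models, KD45-but-not-S5 frames (only the
Sally-Anne fixture covers those), multi-pointed event designation
beyond what the constructions use, and formulas deeper than a few
operators.  Passing property tests therefore certify the semantics on
the small structured regime, not scalability.

## Numerical and procedural choices

* Test sweeps use fixed seeds; the acceptance script derives all
  randomness from its `--seed` argument.  Sweep sizes (TQBF: all prefix
  patterns m ≤ 3 with ~360 sampled matrices; SAT: 200 3CNFs with m ≤ 3,
  l ≤ 4; MCC: 40 colored graphs with ≤ 6 vertices, k ≤ 3; WSat: all
  weights for 2CNFs with m ≤ 4) were chosen to cover the source-problem
  truth tables densely while keeping the whole suite in seconds.
* Ties and orderings (world enumeration, designated iteration, JSON key
  order) are sorted lexicographically so outputs are reproducible.
* Degenerate inputs: the empty action sequence is always applicable and
  returns the state unchanged; an empty clause list reduces to a ⊤ goal
  (SAT) or a vacuously satisfiable complemented formula (WSat); k = 1
  Multicolored Clique degenerates to "color 1 is inhabited", which the
  input validator guarantees.

## Known limitations

* No bisimulation minimization: updated models keep duplicate modulo-
  bisimulation worlds (e.g. the drop-order duplicates in the weighted
  construction), which is semantically harmless but wasteful.
* KD45 preservation under product update is not claimed or tested in
  general (seriality can be lost when an agent's only considered events
  are filtered out); S5 preservation is tested on the S5 generator.
* The solver is the materializing evaluator only; memory grows with
  |W⁰|·eᵘ, so long sequences of large event models are out of reach by
  design.
* Common knowledge, public-announcement sugar and quantified epistemic
  languages are not part of the formula language.
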