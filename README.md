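# dbu — model checking for dynamic belief update

`dbu` is a dynamic-epistemic-logic (DEL) toolkit built around the
**Dynamic Belief Update** decision problem, a formalization of
theory-of-mind reasoning: given how a situation looks to a set of agents
and a sequence of (partially observed) events, what does an agent end up
believing?

Formally, an instance is a tuple (P, 𝒜, (ℳ₀, W_d), (ℰ₁, E₁)…(ℰ_u, E_u), φ):

* a **pointed epistemic model** (ℳ₀, W_d) — a Kripke model (W, R, V)
  with one accessibility relation R_a per agent plus a non-empty set of
  designated worlds;
* a sequence of **pointed event models** (ℰᵢ, Eᵢ) — events with per-agent
  relations, a precondition formula per event, and postconditions
  (conjunctions of literals) that model factual change;
* a goal formula φ in the language φ ::= p | ¬φ | (φ∧φ) | B_a φ,
  with B̂_a φ := ¬B_a¬φ.

The question is whether

&nbsp;&nbsp;&nbsp;&nbsp;(ℳ₀, W_d) ⊗ (ℰ₁, E₁) ⊗ ⋯ ⊗ (ℰ_u, E_u) ⊨ φ,

where ⊗ is the **product update**: surviving world–event pairs (the
precondition holds), componentwise-intersected relations, and
postcondition-overridden valuations.  The solver materializes each
intermediate model and then evaluates φ — fixed-parameter tractable in
(e, u) because the final model has at most |W⁰|·eᵘ worlds.

The package also extracts the seven complexity parameters of an instance
(a agents, c max precondition size, e max events per action, f goal
size, o modal depth — the "order" of belief attribution, p propositions,
u updates) and ships generators that translate four classical hard
problems — TQBF, 3CNF-SAT, Multicolored Clique, and weight-k 2CNF
satisfiability — into equivalent DBU instances, together with
brute-force oracles for the source problems.  The oracle-equivalence of
each translation is enforced by the test suite.

Who is this for: researchers in epistemic logic, epistemic planning and
computational cognitive science who want executable, tested semantics
for belief update, and concrete hard instances with controlled
parameter profiles.

## Worked example: the Sally-Anne task

Sally puts a marble in a basket; while she is away, Anne moves it to a
box; where does Sally think the marble is?  The initial state is a
single world where `basket` holds and both agents know it.  The one
event model has two events — Anne moves the marble (`post ¬basket`), or
nothing happens — and Sally, who is out of the room, can only point at
the nothing-happened event.

```python
>>> from dbu import sally_anne, solve, parameters
>>> solve(sally_anne("B[sally] basket"))
True
>>> solve(sally_anne("B[anne] ~basket"))
True
>>> solve(sally_anne("B[sally] ~basket"))
False
>>> parameters(sally_anne()).as_dict()
{'a': 2, 'c': 1, 'e': 2, 'f': 2, 'o': 1, 'p': 1, 'u': 1}
```

Sally ends up with a consistent but false first-order belief (modal
depth o = 1): she believes the marble is in the basket.

The quantifier construction is just as direct:

```python
>>> from dbu import QBFInstance, reduce_tqbf, Atom
>>> phi = Atom("x1") | Atom("x2")
>>> solve(reduce_tqbf(QBFInstance([("exists", "x1"), ("forall", "x2")], phi)))
True
>>> solve(reduce_tqbf(QBFInstance([("forall", "x1"), ("forall", "x2")], phi)))
False
```

## Command line

```bash
dbu fixture sally-anne -o sa.json
dbu check sa.json            # prints "yes", exit code 0
dbu params sa.json           # {"a": 2, "c": 1, "e": 2, "f": 2, "o": 1, "p": 1, "u": 1}
dbu validate sa.json --cls kd45
dbu reduce sat formula.cnf -o instance.json
dbu reduce wsat formula.cnf --k 2 -o instance.json
dbu gen --seed 7 -o random.json
```

Instances are stored in a JSON dialect with formulas in a readable text
syntax (`~ & | -> B[agent] D[agent] T F`); the schema ships at
`src/dbu/schema/instance.schema.json`.  QDIMACS, DIMACS CNF and colored
edge-list readers feed the reduction generators.

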