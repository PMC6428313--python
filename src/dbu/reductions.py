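"""Hardness-construction instance generators and brute-force oracles.

Each ``reduce_*`` function maps an instance of a classical decision
problem (TQBF, 3CNF-SAT, Multicolored Clique, weighted 2CNF-SAT) to an
equivalent DBU instance, reproducing the constructions that establish
the problem's complexity landscape.  Each ``oracle_*`` function solves
the source problem directly by exhaustive search at small sizes; the
contract ``solve(reduce_X(x)) == oracle_X(x)`` is the correctness
theorem of each construction and the primary test of this module.

The quantifier construction (TQBF) encodes a truth assignment as a
"group of worlds": an equivalence class of a distinguished agent *a* in
which world w makes variable x_i true iff w has an R_i-edge to a world
where the marker proposition y holds.  Updates double the groups,
peeling one variable at a time; belief operators B_i / B̂_i then walk
between groups that differ only in x_i, simulating ∀ / ∃.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .formulas import (And, Atom, Believes, Dual, Formula, Not, Top,
                       atoms, conjoin, disjoin)
from .models import (EpistemicModel, EventModel, PointedEpistemicModel,
                     PointedEventModel)
from .solver import DBUInstance

__all__ = [
    "QBFInstance", "CNFInstance", "ColoredGraph", "WSatInstance",
    "reduce_tqbf", "reduce_sat", "reduce_mcc", "reduce_wsat",
    "oracle_qbf", "oracle_sat", "oracle_mcc", "oracle_wsat",
]

_EXHAUSTIVE_LIMIT = 10 ** 6


# --- source-problem containers --------------------------------------------

@dataclass(frozen=True)
class QBFInstance:
    """A fully quantified Boolean formula Q_1 x_1 … Q_m x_m. ψ.

    ``prefix`` is a sequence of ("forall" | "exists", variable) pairs;
    ``matrix`` is a propositional formula over exactly those variables.
    """

    prefix: tuple[tuple[str, str], ...]
    matrix: Formula

    def __init__(self, prefix: Sequence[tuple[str, str]], matrix: Formula):
        prefix = tuple((q, str(v)) for q, v in prefix)
        for q, _ in prefix:
            if q not in ("forall", "exists"):
                raise ValueError(f"unknown quantifier {q!r}")
        names = [v for _, v in prefix]
        if len(set(names)) != len(names):
            raise ValueError("a variable is quantified more than once")
        if not atoms(matrix) <= set(names):
            raise ValueError("matrix uses unquantified variables")
        object.__setattr__(self, "prefix", prefix)
        object.__setattr__(self, "matrix", matrix)

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(v for _, v in self.prefix)


@dataclass(frozen=True)
class CNFInstance:
    """A CNF formula over variables 1..num_vars.

    Clauses are tuples of non-zero ints, DIMACS style: ``i`` is the
    positive literal of variable i and ``-i`` its negation.
    """

    num_vars: int
    clauses: tuple[tuple[int, ...], ...]
    max_width: int = 3

    def __init__(self, num_vars: int, clauses: Iterable[Iterable[int]],
                 max_width: int = 3):
        clauses = tuple(tuple(c) for c in clauses)
        if num_vars < 0:
            raise ValueError("negative variable count")
        for clause in clauses:
            if not clause:
                raise ValueError("empty clause")
            if len(clause) > max_width:
                raise ValueError(
                    f"clause {clause} wider than {max_width} literals")
            for lit in clause:
                if lit == 0 or abs(lit) > num_vars:
                    raise ValueError(f"literal {lit} out of range")
        object.__setattr__(self, "num_vars", num_vars)
        object.__setattr__(self, "clauses", clauses)
        object.__setattr__(self, "max_width", max_width)


def _clause_true(clause: tuple[int, ...], assignment: Mapping[int, bool]) -> bool:
    return any(assignment[abs(lit)] == (lit > 0) for lit in clause)


@dataclass(frozen=True)
class ColoredGraph:
    """An undirected vertex-colored graph with colors 1..k."""

    vertices: tuple[str, ...]
    edges: frozenset[frozenset[str]]
    coloring: Mapping[str, int]

    def __init__(self, vertices: Iterable[str],
                 edges: Iterable[Iterable[str]],
                 coloring: Mapping[str, int]):
        vertices = tuple(str(v) for v in vertices)
        vset = set(vertices)
        if len(vset) != len(vertices):
            raise ValueError("duplicate vertices")
        fro = set()
        for e in edges:
            pair = frozenset(str(v) for v in e)
            if len(pair) != 2:
                raise ValueError(f"edge {set(e)} is not a pair of distinct vertices")
            if not pair <= vset:
                raise ValueError(f"edge {set(pair)} outside the vertex set")
            fro.add(pair)
        missing = vset - set(coloring)
        if missing:
            raise ValueError(f"uncolored vertices: {sorted(missing)}")
        object.__setattr__(self, "vertices", vertices)
        object.__setattr__(self, "edges", frozenset(fro))
        object.__setattr__(self, "coloring", dict(coloring))

    def color_class(self, color: int) -> tuple[str, ...]:
        return tuple(v for v in self.vertices if self.coloring[v] == color)

    def adjacent(self, u: str, v: str) -> bool:
        return frozenset((u, v)) in self.edges

    def __hash__(self):
        return hash((self.vertices, self.edges))


@dataclass(frozen=True)
class WSatInstance:
    """Weighted 2CNF satisfiability: is there a satisfying assignment
    that sets exactly k variables to true?"""

    cnf: CNFInstance
    k: int

    def __init__(self, cnf: CNFInstance, k: int):
        if cnf.max_width > 2:
            cnf = CNFInstance(cnf.num_vars, cnf.clauses, max_width=2)
        if not 0 <= k <= cnf.num_vars:
            raise ValueError("weight k out of range")
        object.__setattr__(self, "cnf", cnf)
        object.__setattr__(self, "k", k)


# --- oracles ---------------------------------------------------------------

def _eval_prop(phi: Formula, assignment: Mapping[str, bool]) -> bool:
    from .formulas import Or, Implies, Bot
    if isinstance(phi, Atom):
        return assignment[phi.name]
    if isinstance(phi, Top):
        return True
    if isinstance(phi, Bot):
        return False
    if isinstance(phi, Not):
        return not _eval_prop(phi.operand, assignment)
    if isinstance(phi, And):
        return _eval_prop(phi.left, assignment) and _eval_prop(phi.right, assignment)
    if isinstance(phi, Or):
        return _eval_prop(phi.left, assignment) or _eval_prop(phi.right, assignment)
    if isinstance(phi, Implies):
        return (not _eval_prop(phi.left, assignment)) or _eval_prop(phi.right, assignment)
    raise ValueError(f"not a propositional formula: {phi!r}")


def oracle_qbf(q: QBFInstance) -> bool:
    """Truth of a quantified Boolean formula by quantifier expansion."""
    if len(q.prefix) > 20:
        raise ValueError("instance too large for exhaustive evaluation")

    def rec(i: int, assignment: dict[str, bool]) -> bool:
        if i == len(q.prefix):
            return _eval_prop(q.matrix, assignment)
        quant, var = q.prefix[i]
        results = (rec(i + 1, {**assignment, var: b}) for b in (False, True))
        return all(results) if quant == "forall" else any(results)

    return rec(0, {})


def oracle_sat(c: CNFInstance) -> bool:
    """Satisfiability by enumerating all 2^m assignments."""
    if c.num_vars > 20:
        raise ValueError("instance too large for exhaustive evaluation")
    for bits in itertools.product((False, True), repeat=c.num_vars):
        assignment = {i + 1: bits[i] for i in range(c.num_vars)}
        if all(_clause_true(cl, assignment) for cl in c.clauses):
            return True
    return False


def oracle_mcc(g: ColoredGraph, k: int) -> bool:
    """Multicolored clique by enumerating one vertex per color class."""
    classes = [g.color_class(i) for i in range(1, k + 1)]
    total = 1
    for cls in classes:
        total *= max(len(cls), 1)
        if total > _EXHAUSTIVE_LIMIT:
            raise ValueError("instance too large for exhaustive evaluation")
    if any(not cls for cls in classes):
        return False
    for combo in itertools.product(*classes):
        if all(g.adjacent(u, v) for u, v in itertools.combinations(combo, 2)):
            return True
    return False


def oracle_wsat(w: WSatInstance) -> bool:
    """Weight-k satisfiability by enumerating all k-subsets."""
    m = w.cnf.num_vars
    from math import comb
    if comb(m, w.k) > _EXHAUSTIVE_LIMIT:
        raise ValueError("instance too large for exhaustive evaluation")
    for true_set in itertools.combinations(range(1, m + 1), w.k):
        assignment = {i: i in true_set for i in range(1, m + 1)}
        if all(_clause_true(cl, assignment) for cl in w.cnf.clauses):
            return True
    return False


# --- shared building blocks -------------------------------------------------

def _identity(points: Iterable[str]) -> frozenset[tuple[str, str]]:
    return frozenset((x, x) for x in points)


def _full(points: Iterable[str]) -> frozenset[tuple[str, str]]:
    pts = list(points)
    return frozenset((x, y) for x in pts for y in pts)


def _y() -> Formula:
    return Atom("y")


def _assignment_frame(m: int, extra_agents: Sequence[str] = (),
                      extra_rel: Mapping[str, frozenset] | None = None
                      ) -> PointedEpistemicModel:
    """The initial model of the group-of-worlds constructions.

    Worlds w0..wm plus primed y-worlds w1'..wm'; {w0..wm} is one R_a
    class (the group representing the all-true assignment), and each
    pair {wi, wi'} is an R_i class, so wi witnesses "x_i is true".  The
    base world w0 carries no R_i edges — the base world of a group is by
    definition the world with no edge to a y-world.
    """
    agents = ["a"] + [str(i) for i in range(1, m + 1)] + list(extra_agents)
    group = [f"w{i}" for i in range(m + 1)]
    primes = [f"w{i}'" for i in range(1, m + 1)]
    worlds = group + primes
    relations: dict[str, frozenset] = {"a": _full(group) | _identity(primes)}
    for i in range(1, m + 1):
        pair = [f"w{i}", f"w{i}'"]
        others = [w for w in worlds if w not in pair]
        relations[str(i)] = _full(pair) | _identity(others)
    for agent, rel in (extra_rel or {}).items():
        relations[agent] = rel
    model = EpistemicModel(agents, {"y"}, worlds, relations,
                           {w: {"y"} for w in primes})
    return PointedEpistemicModel(model, {"w0"})


def _falsifier_pre(i: int, require_witness: bool) -> Formula:
    """Precondition of the event that drops variable x_i from a group.

    Copies worlds where B_i¬y holds (no one-step R_i path to a y-world:
    everything except the x_i witness) and y-worlds where y ∧ B_i y holds
    (every y-world except the one R_i-attached to the witness).  With
    ``require_witness`` the group must still contain an x_i witness
    (checked as B̂_aB̂_i y, uniform across a group), so an already-false
    variable cannot be dropped again.
    """
    ag = str(i)
    drop_branch: Formula = Believes(ag, Not(_y()))
    if require_witness:
        drop_branch = And(drop_branch, Dual("a", Dual(ag, _y())))
    keep_y = And(_y(), Believes(ag, _y()))
    return drop_branch | keep_y


# --- TQBF ------------------------------------------------------------------

def reduce_tqbf(q: QBFInstance) -> DBUInstance:
    """TQBF → DBU.

    Builds the m-update construction whose final model contains one
    group of worlds per truth assignment; the goal translates quantifier
    Q_i to B_i (∀) or B̂_i (∃) and each variable occurrence x_i to
    B̂_aB̂_i y.  ``solve`` on the result agrees with ``oracle_qbf``.
    """
    m = len(q.prefix)
    if m == 0:
        raise ValueError("the quantifier prefix must be non-empty")
    state = _assignment_frame(m)
    agents = state.model.agents

    actions = []
    for i in range(1, m + 1):
        events = ["e", "ep"]
        relations: dict[str, frozenset] = {
            agent: (_full(events) if agent == str(i) else _identity(events))
            for agent in agents}
        ev = EventModel(agents, {"y"}, events, relations,
                        pre={"e": Top(), "ep": _falsifier_pre(i, require_witness=False)})
        actions.append(PointedEventModel(ev, {"e"}))

    var_to_index = {v: str(i + 1) for i, (_, v) in enumerate(q.prefix)}

    def translate(phi: Formula) -> Formula:
        from .formulas import Or, Implies, Bot
        if isinstance(phi, Atom):
            return Dual("a", Dual(var_to_index[phi.name], _y()))
        if isinstance(phi, (Top, Bot)):
            return phi
        if isinstance(phi, Not):
            return Not(translate(phi.operand))
        if isinstance(phi, And):
            return And(translate(phi.left), translate(phi.right))
        if isinstance(phi, Or):
            return Or(translate(phi.left), translate(phi.right))
        if isinstance(phi, Implies):
            return Implies(translate(phi.left), translate(phi.right))
        raise ValueError(f"matrix is not propositional: {phi!r}")

    goal = translate(q.matrix)
    for i in range(m, 0, -1):
        quant = q.prefix[i - 1][0]
        goal = Believes(str(i), goal) if quant == "forall" else Dual(str(i), goal)

    return DBUInstance({"y"}, agents, state, actions, goal)


# --- SAT (3CNF) -------------------------------------------------------------

def reduce_sat(c: CNFInstance) -> DBUInstance:
    """3CNF-SAT → DBU with a single agent and constant a, c, e, f, o.

    The m assignment events double a one-world model into the 2^m
    assignments (all in a single S5 class); l clause events then
    maintain z_{m+1} = "all clauses so far hold here", the last of them
    broadcasting satisfiability through the global modality B̂_a so the
    propositional goal z_{m+1} can be read off at the designated world.
    """
    if c.max_width > 3:
        raise ValueError("reduce_sat expects a 3CNF instance")
    m, l = c.num_vars, len(c.clauses)
    props = [f"z{i}" for i in range(1, m + 2)]
    zsat = Atom(f"z{m + 1}")
    agents = {"a"}

    model = EpistemicModel(agents, props, {"w0"}, {"a": {("w0", "w0")}}, {})
    state = PointedEpistemicModel(model, {"w0"})

    def clause_formula(clause: tuple[int, ...]) -> Formula:
        return disjoin([Atom(f"z{lit}") if lit > 0 else Not(Atom(f"z{-lit}"))
                        for lit in clause])

    actions = []
    for i in range(1, m + 1):
        events = ["set", "skip"]
        ev = EventModel(agents, props, events, {"a": _full(events)},
                        pre={"set": Top(), "skip": Top()},
                        post={"set": {f"z{i}": True}, "skip": {}})
        actions.append(PointedEventModel(ev, {"set"}))

    for j in range(1, l + 1):
        cond: Formula = clause_formula(c.clauses[j - 1])
        if j > 1:
            cond = And(zsat, cond)
        if j == l:
            cond = Dual("a", cond)  # global: some world satisfies everything
        events = ["mark", "pass"]
        ev = EventModel(agents, props, events, {"a": _full(events)},
                        pre={"mark": cond, "pass": Not(cond)},
                        post={"mark": {f"z{m + 1}": True},
                              "pass": {f"z{m + 1}": False}})
        # both designated: the preconditions are complementary, so exactly
        # one of them applies to the designated world
        actions.append(PointedEventModel(ev, {"mark", "pass"}))

    goal: Formula = zsat if l > 0 else Top()
    return DBUInstance(props, agents, state, actions, goal)


# --- Multicolored Clique ----------------------------------------------------

def reduce_mcc(g: ColoredGraph, k: int) -> DBUInstance:
    """Multicolored Clique → DBU with u = k + C(k,2) updates and goal
    ⋀_{i<j} r_ij (size 2·C(k,2) − 1).

    Selection stages make each world represent one k-colored, k-sized
    vertex subset (colors 1 and 2 are chosen in a single stage); one
    edge stage per color pair (i, j) marks a world with r_ij when its
    selected pair is an actual edge (and with the dummy z otherwise);
    a final stage broadcasts "some world is a clique" to the designated
    world through B̂_a.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    for v in g.vertices:
        if not 1 <= g.coloring[v] <= k:
            raise ValueError(f"vertex {v!r} has color outside 1..{k}")
    classes = {i: sorted(g.color_class(i)) for i in range(1, k + 1)}
    for i, cls in classes.items():
        if not cls:
            raise ValueError(f"color {i} is unused; the coloring must use 1..{k}")

    xs = {v: f"x:{v}" for v in g.vertices}
    pairs = list(itertools.combinations(range(1, k + 1), 2))
    rs = {(i, j): f"r:{i}:{j}" for i, j in pairs}
    props = set(xs.values()) | set(rs.values()) | {"z"}
    agents = {"a"}

    model = EpistemicModel(agents, props, {"w0"}, {"a": {("w0", "w0")}}, {})
    state = PointedEpistemicModel(model, {"w0"})
    actions = []

    def stage(events: dict[str, tuple[Formula, dict[str, bool]]],
              designated: Iterable[str]) -> None:
        ev = EventModel(agents, props, events.keys(), {"a": _full(events.keys())},
                        pre={e: spec[0] for e, spec in events.items()},
                        post={e: spec[1] for e, spec in events.items()})
        actions.append(PointedEventModel(ev, designated))

    if k == 1:
        stage({f"pick:{v}": (Top(), {xs[v]: True}) for v in classes[1]},
              {f"pick:{classes[1][0]}"})
    else:
        # colors 1 and 2 together, then one stage per remaining color
        first = {f"pick:{v}:{w}": (Top(), {xs[v]: True, xs[w]: True})
                 for v in classes[1] for w in classes[2]}
        stage(first, {f"pick:{classes[1][0]}:{classes[2][0]}"})
        for color in range(3, k + 1):
            stage({f"pick:{v}": (Top(), {xs[v]: True}) for v in classes[color]},
                  {f"pick:{classes[color][0]}"})

        for i, j in pairs:
            events = {}
            for v in classes[i]:
                for w in classes[j]:
                    mark = rs[(i, j)] if g.adjacent(v, w) else "z"
                    events[f"edge:{v}:{w}"] = (And(Atom(xs[v]), Atom(xs[w])),
                                               {mark: True})
            stage(events, {f"edge:{classes[i][0]}:{classes[j][0]}"})

        all_r = conjoin([Atom(rs[p]) for p in pairs])
        found = Dual("a", all_r)
        stage({"yes": (found, {rs[p]: True for p in pairs}),
               "no": (Not(found), {})},
              {"yes", "no"})

    goal = conjoin([Atom(rs[p]) for p in pairs])
    return DBUInstance(props, agents, state, actions, goal)


# --- weighted 2CNF satisfiability -------------------------------------------

def reduce_wsat(w: WSatInstance) -> DBUInstance:
    """{k}-WSat[2CNF] → DBU with u = k updates.

    Complements the formula (x_i ↦ ¬x_i) so that weight-k truth becomes
    weight-(m−k) falsity, then reuses the group-of-worlds machinery:
    each of the k updates drops one still-true variable from every
    group, so the final model's groups are exactly the assignments with
    m−k variables true.  Observer agent b's relation is the identity in
    the initial model and fully connected inside every event model, so
    the designated world's R_b class is precisely the set of surviving
    copies of w0 — the base worlds of all groups — and the goal
    B̂_b[φ′] asks whether some such group satisfies the complemented
    formula.
    """
    m, k = w.cnf.num_vars, w.k
    if m < 2:
        raise ValueError("the construction needs at least two variables")
    if not 0 <= k <= m:
        raise ValueError("weight k out of range")

    r_b = _identity([f"w{i}" for i in range(m + 1)]
                    + [f"w{i}'" for i in range(1, m + 1)])
    state = _assignment_frame(m, extra_agents=["b"], extra_rel={"b": r_b})
    agents = state.model.agents

    actions = []
    for i in range(1, k + 1):
        events = [f"e{j}" for j in range(1, m + 1)]
        relations: dict[str, frozenset] = {"b": _full(events)}
        for agent in agents - {"b"}:
            relations[agent] = _identity(events)
        ev = EventModel(agents, {"y"}, events, relations,
                        pre={f"e{j}": _falsifier_pre(j, require_witness=True)
                             for j in range(1, m + 1)})
        actions.append(PointedEventModel(ev, {f"e{i}"}))

    def x_translated(i: int) -> Formula:
        return Dual("a", Dual(str(i), _y()))

    # φ' complements every literal of φ; its translation reads the group
    clause_formulas = []
    for clause in w.cnf.clauses:
        lits = [Not(x_translated(lit)) if lit > 0 else x_translated(-lit)
                for lit in clause]
        clause_formulas.append(disjoin(lits))
    goal = Dual("b", conjoin(clause_formulas))

    return DBUInstance({"y"}, agents, state, actions, goal)
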