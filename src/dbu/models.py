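"""Epistemic and event models (multi-agent Kripke structures).

An epistemic model is a tuple (W, R, V): worlds, one accessibility
relation per agent, and a valuation.  An event model is the dynamic
counterpart (E, Q, pre, post): events with per-agent relations, a
precondition formula per event, and a postcondition given as a
consistent set of propositional literals (the empty set is ⊤).

Relations are stored fully explicit.  Published drawings of such models
conventionally omit reflexive loops and draw a generator whose
transitive reflexive closure is the intended relation; ``closure`` turns
a transcription of a drawing into the stored relation.

Valuations are sparse: each world maps to the set of propositions true
there; anything absent is false.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .formulas import Formula, Top

__all__ = [
    "EpistemicModel", "PointedEpistemicModel",
    "EventModel", "PointedEventModel",
    "RelationClass", "check_relation_class", "closure", "equivalence_groups",
    "ModelError",
]

Relation = frozenset[tuple[str, str]]

#: world/event ids produced by product update join their parents with this
#: separator; user-supplied ids must not contain it.
ID_SEPARATOR = "|"


class ModelError(ValueError):
    """A structurally invalid model, or an operation applied outside its domain."""


def _freeze_relations(agents: Iterable[str],
                      relations: Mapping[str, Iterable[tuple[str, str]]],
                      points: frozenset[str], what: str) -> dict[str, Relation]:
    agents = set(agents)
    out: dict[str, Relation] = {}
    for agent, pairs in relations.items():
        if agent not in agents:
            raise ModelError(f"relation for undeclared agent {agent!r}")
        rel = frozenset((str(x), str(y)) for x, y in pairs)
        for x, y in rel:
            if x not in points or y not in points:
                raise ModelError(
                    f"relation endpoint ({x!r},{y!r}) outside declared {what}")
        out[agent] = rel
    for agent in agents:
        out.setdefault(agent, frozenset())
    return out


@dataclass(frozen=True)
class EpistemicModel:
    """(W, R, V) over declared agent set A and proposition set P."""

    agents: frozenset[str]
    props: frozenset[str]
    worlds: frozenset[str]
    relations: Mapping[str, Relation]
    valuation: Mapping[str, frozenset[str]]  # world -> true propositions

    def __init__(self, agents, props, worlds,
                 relations: Mapping[str, Iterable[tuple[str, str]]],
                 valuation: Mapping[str, Iterable[str]]):
        object.__setattr__(self, "agents", frozenset(agents))
        object.__setattr__(self, "props", frozenset(props))
        object.__setattr__(self, "worlds", frozenset(worlds))
        if not self.worlds:
            raise ModelError("a model needs at least one world")
        object.__setattr__(self, "relations", _freeze_relations(
            self.agents, relations, self.worlds, "worlds"))
        val: dict[str, frozenset[str]] = {}
        for w, trues in valuation.items():
            if w not in self.worlds:
                raise ModelError(f"valuation for unknown world {w!r}")
            ts = frozenset(trues)
            bad = ts - self.props
            if bad:
                raise ModelError(f"valuation of {w!r} uses undeclared {sorted(bad)}")
            val[w] = ts
        for w in self.worlds:
            val.setdefault(w, frozenset())
        object.__setattr__(self, "valuation", val)

    def true_at(self, world: str, prop: str) -> bool:
        return prop in self.valuation[world]

    def successors(self, agent: str, world: str) -> frozenset[str]:
        return frozenset(v for (w, v) in self.relations[agent] if w == world)

    def with_relations(self, relations: Mapping[str, Relation]) -> "EpistemicModel":
        return EpistemicModel(self.agents, self.props, self.worlds,
                              relations, self.valuation)

    def restrict(self, worlds: Iterable[str]) -> "EpistemicModel":
        """Submodel induced by a non-empty subset of worlds."""
        keep = frozenset(worlds)
        if not keep <= self.worlds:
            raise ModelError("restriction to worlds outside the model")
        return EpistemicModel(
            self.agents, self.props, keep,
            {a: frozenset(p for p in rel if p[0] in keep and p[1] in keep)
             for a, rel in self.relations.items()},
            {w: v for w, v in self.valuation.items() if w in keep})

    def __hash__(self):
        return hash((self.agents, self.props, self.worlds))


@dataclass(frozen=True)
class PointedEpistemicModel:
    """A model plus a non-empty designated world set (the "state")."""

    model: EpistemicModel
    designated: frozenset[str]

    def __init__(self, model: EpistemicModel, designated: Iterable[str]):
        object.__setattr__(self, "model", model)
        object.__setattr__(self, "designated", frozenset(designated))
        if not self.designated:
            raise ModelError("designated world set must be non-empty")
        if not self.designated <= model.worlds:
            raise ModelError("designated worlds outside the model")

    @property
    def single_pointed(self) -> bool:
        return len(self.designated) == 1


@dataclass(frozen=True)
class EventModel:
    """(E, Q, pre, post).

    ``post`` maps each event to a dict {proposition: bool}; the empty
    dict is the trivial postcondition ⊤.
    """

    agents: frozenset[str]
    props: frozenset[str]
    events: frozenset[str]
    relations: Mapping[str, Relation]
    pre: Mapping[str, Formula]
    post: Mapping[str, Mapping[str, bool]]

    def __init__(self, agents, props, events,
                 relations: Mapping[str, Iterable[tuple[str, str]]],
                 pre: Mapping[str, Formula],
                 post: Mapping[str, Mapping[str, bool]] | None = None):
        object.__setattr__(self, "agents", frozenset(agents))
        object.__setattr__(self, "props", frozenset(props))
        object.__setattr__(self, "events", frozenset(events))
        if not self.events:
            raise ModelError("an event model needs at least one event")
        object.__setattr__(self, "relations", _freeze_relations(
            self.agents, relations, self.events, "events"))
        pre = dict(pre)
        for e in self.events:
            pre.setdefault(e, Top())
        for e, phi in pre.items():
            if e not in self.events:
                raise ModelError(f"precondition for unknown event {e!r}")
            if not isinstance(phi, Formula):
                raise ModelError(f"precondition of {e!r} is not a formula")
        object.__setattr__(self, "pre", pre)
        post = {e: dict(m) for e, m in (post or {}).items()}
        for e in self.events:
            post.setdefault(e, {})
        for e, mapping in post.items():
            if e not in self.events:
                raise ModelError(f"postcondition for unknown event {e!r}")
            bad = set(mapping) - self.props
            if bad:
                raise ModelError(f"postcondition of {e!r} uses undeclared {sorted(bad)}")
        object.__setattr__(self, "post", post)

    def successors(self, agent: str, event: str) -> frozenset[str]:
        return frozenset(f for (e, f) in self.relations[agent] if e == event)

    def with_relations(self, relations: Mapping[str, Relation]) -> "EventModel":
        return EventModel(self.agents, self.props, self.events,
                          relations, self.pre, self.post)

    def __hash__(self):
        return hash((self.agents, self.props, self.events))


@dataclass(frozen=True)
class PointedEventModel:
    """An event model plus a non-empty designated event set (the "action")."""

    model: EventModel
    designated: frozenset[str]

    def __init__(self, model: EventModel, designated: Iterable[str]):
        object.__setattr__(self, "model", model)
        object.__setattr__(self, "designated", frozenset(designated))
        if not self.designated:
            raise ModelError("designated event set must be non-empty")
        if not self.designated <= model.events:
            raise ModelError("designated events outside the model")

    @property
    def single_pointed(self) -> bool:
        return len(self.designated) == 1


# --- frame classes ---------------------------------------------------------

RelationClass = str  # "arbitrary" | "KD45" | "S5"

_CLASSES = ("arbitrary", "KD45", "S5")


def _points(model: EpistemicModel | EventModel) -> frozenset[str]:
    return model.worlds if isinstance(model, EpistemicModel) else model.events


def _is_transitive(rel: Relation) -> bool:
    succ: dict[str, set[str]] = {}
    for x, y in rel:
        succ.setdefault(x, set()).add(y)
    return all(z in succ.get(x, ()) for x, y in rel for z in succ.get(y, ()))


def _is_euclidean(rel: Relation) -> bool:
    succ: dict[str, set[str]] = {}
    for x, y in rel:
        succ.setdefault(x, set()).add(y)
    # wRy and wRz imply yRz
    for x, ys in succ.items():
        for y in ys:
            if not ys <= succ.get(y, set()):
                return False
    return True


def _is_serial(rel: Relation, points: frozenset[str]) -> bool:
    with_succ = {x for x, _ in rel}
    return points <= with_succ


def _is_reflexive(rel: Relation, points: frozenset[str]) -> bool:
    return all((x, x) in rel for x in points)


def _is_symmetric(rel: Relation) -> bool:
    return all((y, x) in rel for x, y in rel)


def check_relation_class(model: EpistemicModel | EventModel,
                         cls: RelationClass) -> bool:
    """True iff every agent's relation satisfies the axioms of ``cls``.

    KD45: transitive, Euclidean and serial.  S5: an equivalence relation
    (reflexive, symmetric, transitive).  Checked by pair/triple
    enumeration.
    """
    if cls not in _CLASSES:
        raise ModelError(f"unknown relation class {cls!r}; expected one of {_CLASSES}")
    if cls == "arbitrary":
        return True
    pts = _points(model)
    for rel in model.relations.values():
        if cls == "KD45":
            if not (_is_transitive(rel) and _is_euclidean(rel)
                    and _is_serial(rel, pts)):
                return False
        else:  # S5
            if not (_is_reflexive(rel, pts) and _is_symmetric(rel)
                    and _is_transitive(rel)):
                return False
    return True


def closure(model, mode: str = "reflexive_transitive"):
    """Replace each agent relation by its closure.

    ``mode`` is ``reflexive_transitive`` (inverts the drawing convention)
    or ``reflexive_transitive_symmetric`` (yields an equivalence
    relation).  Idempotent; works on epistemic and event models alike.
    """
    if mode not in ("reflexive_transitive", "reflexive_transitive_symmetric"):
        raise ModelError(f"unknown closure mode {mode!r}")
    pts = _points(model)
    closed: dict[str, Relation] = {}
    for agent, rel in model.relations.items():
        pairs = set(rel)
        if mode == "reflexive_transitive_symmetric":
            pairs |= {(y, x) for x, y in pairs}
        g = nx.DiGraph()
        g.add_nodes_from(pts)
        g.add_edges_from(pairs)
        tc = nx.transitive_closure(g, reflexive=True)
        closed[agent] = frozenset(tc.edges())
    return model.with_relations(closed)


def equivalence_groups(model: EpistemicModel | EventModel,
                       agent: str) -> frozenset[frozenset[str]]:
    """Equivalence classes ("groups of worlds") of one agent's relation.

    Raises ``ModelError`` if the relation is not an equivalence relation;
    the relation is not silently closed.
    """
    if agent not in model.agents:
        raise ModelError(f"unknown agent {agent!r}")
    rel = model.relations[agent]
    pts = _points(model)
    if not (_is_reflexive(rel, pts) and _is_symmetric(rel) and _is_transitive(rel)):
        raise ModelError(
            f"relation of agent {agent!r} is not an equivalence relation")
    succ: dict[str, set[str]] = {x: set() for x in pts}
    for x, y in rel:
        succ[x].add(y)
    # for an equivalence relation the successor set of a point is its class
    return frozenset(frozenset(s) for s in succ.values())
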