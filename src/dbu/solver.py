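"""The Dynamic Belief Update (DBU) decision problem.

An instance is (P, A, initial state, action sequence, goal formula); the
question is whether the goal holds in the state obtained by updating the
initial state with the whole action sequence.  The solver materializes
each intermediate model in turn and then evaluates the goal — the
fixed-parameter-tractable strategy for bounded events-per-action (e) and
number of updates (u), since the final model has at most |W⁰|·eᵘ worlds.

Seven parameters describe an instance's difficulty:

    a   number of agents
    c   maximum size s(·) of the event preconditions
    e   maximum number of events in any event model
    f   size s(·) of the goal formula
    o   modal depth d(·) of the goal — the "order" of belief attribution
    p   number of propositional variables
    u   number of event models (updates)

f, o and c are measured after expanding the surface sugar, with the
constants ⊤/⊥ counted as atoms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .formulas import Formula, atoms, agents as formula_agents, depth, size
from .models import (ModelError, PointedEpistemicModel, PointedEventModel)
from .semantics import apply_sequence, is_applicable, satisfies

__all__ = ["DBUInstance", "ParameterVector", "solve", "parameters"]


@dataclass(frozen=True)
class ParameterVector:
    a: int
    c: int
    e: int
    f: int
    o: int
    p: int
    u: int

    def __post_init__(self):
        if any(v < 0 for v in self.as_dict().values()):
            raise ValueError("parameters must be non-negative")
        if self.o > self.f:
            raise ValueError("modal depth cannot exceed formula size")
        if (self.u == 0) != (self.e == 0) or (self.u == 0) != (self.c == 0):
            raise ValueError("e and c are zero exactly when there are no updates")

    def as_dict(self) -> dict[str, int]:
        return {"a": self.a, "c": self.c, "e": self.e, "f": self.f,
                "o": self.o, "p": self.p, "u": self.u}


@dataclass(frozen=True)
class DBUInstance:
    """A validated DBU instance.

    Construction checks that every symbol in the state, the actions and
    the goal is drawn from the declared sets, and that the action
    sequence is applicable in the initial state (so ``solve`` can never
    conflate "inapplicable" with "no").
    """

    props: frozenset[str]
    agents: frozenset[str]
    state: PointedEpistemicModel
    actions: tuple[PointedEventModel, ...]
    goal: Formula

    def __init__(self, props, agents, state: PointedEpistemicModel,
                 actions: Sequence[PointedEventModel], goal: Formula):
        object.__setattr__(self, "props", frozenset(props))
        object.__setattr__(self, "agents", frozenset(agents))
        object.__setattr__(self, "state", state)
        object.__setattr__(self, "actions", tuple(actions))
        object.__setattr__(self, "goal", goal)
        self._validate()

    def _validate(self) -> None:
        m = self.state.model
        if not (m.agents <= self.agents and m.props <= self.props):
            raise ModelError("state uses symbols outside the declared P and A")
        for i, action in enumerate(self.actions):
            em = action.model
            if not (em.agents <= self.agents and em.props <= self.props):
                raise ModelError(f"action {i} uses symbols outside P and A")
            for e in em.events:
                if not atoms(em.pre[e]) <= self.props:
                    raise ModelError(f"pre of event {e!r} uses undeclared atoms")
                if not formula_agents(em.pre[e]) <= self.agents:
                    raise ModelError(f"pre of event {e!r} uses undeclared agents")
        if not atoms(self.goal) <= self.props:
            raise ModelError("goal uses undeclared propositions")
        if not formula_agents(self.goal) <= self.agents:
            raise ModelError("goal uses undeclared agents")
        if not is_applicable(self.state, self.actions):
            raise ModelError("action sequence is not applicable in the state")


def solve(inst: DBUInstance) -> bool:
    """Decide the instance: update, then model-check the goal."""
    final = apply_sequence(inst.state, inst.actions)
    return satisfies(final, inst.goal)


def parameters(inst: DBUInstance) -> ParameterVector:
    """The seven-parameter vector of an instance.

    c and e are 0 by convention when there are no updates; c and f use
    the size measure s(·), o the modal depth d(·).  f and o are measured
    on the goal only.
    """
    u = len(inst.actions)
    e = max((len(a.model.events) for a in inst.actions), default=0)
    c = max((size(a.model.pre[ev])
             for a in inst.actions for ev in a.model.events), default=0)
    return ParameterVector(
        a=len(inst.agents), c=c, e=e,
        f=size(inst.goal), o=depth(inst.goal),
        p=len(inst.props), u=u)
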