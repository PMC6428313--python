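"""Shared fixtures: the two-world introductory example models and an
independent naive truth evaluator used as an oracle for the memoized
implementation."""

from __future__ import annotations

import pytest

from dbu.formulas import (And, Atom, Believes, Bot, Formula, Not, Top, expand)
from dbu.models import (EpistemicModel, EventModel, PointedEpistemicModel,
                        PointedEventModel)


@pytest.fixture
def fig1_state() -> PointedEpistemicModel:
    """Two worlds w1, w2 over one proposition z: agent a cannot tell them
    apart (full relation), agent b can (identity); z holds only at w1;
    w1 designated."""
    model = EpistemicModel(
        agents={"a", "b"}, props={"z"}, worlds={"w1", "w2"},
        relations={
            "a": {("w1", "w1"), ("w1", "w2"), ("w2", "w1"), ("w2", "w2")},
            "b": {("w1", "w1"), ("w2", "w2")},
        },
        valuation={"w1": {"z"}})
    return PointedEpistemicModel(model, {"w1"})


@pytest.fixture
def fig2_action() -> PointedEventModel:
    """Two events over proposition h, both with trivial preconditions:
    e1 makes h true, e2 makes h false; agent a cannot tell them apart,
    agent b can; e1 designated."""
    model = EventModel(
        agents={"a", "b"}, props={"h", "z"}, events={"e1", "e2"},
        relations={
            "a": {("e1", "e1"), ("e1", "e2"), ("e2", "e1"), ("e2", "e2")},
            "b": {("e1", "e1"), ("e2", "e2")},
        },
        pre={"e1": Top(), "e2": Top()},
        post={"e1": {"h": True}, "e2": {"h": False}})
    return PointedEventModel(model, {"e1"})


def naive_satisfies(state: PointedEpistemicModel, phi: Formula) -> bool:
    """Unmemoized reference evaluator, written independently of the
    production path: plain recursion over the truth clauses."""
    model = state.model
    core = expand(phi)

    def holds(world: str, f: Formula) -> bool:
        if isinstance(f, Atom):
            return f.name in model.valuation[world]
        if isinstance(f, Top):
            return True
        if isinstance(f, Bot):
            return False
        if isinstance(f, Not):
            return not holds(world, f.operand)
        if isinstance(f, And):
            return holds(world, f.left) and holds(world, f.right)
        if isinstance(f, Believes):
            return all(holds(v, f.operand)
                       for (w, v) in model.relations[f.agent] if w == world)
        raise TypeError(f)

    return all(holds(w, core) for w in state.designated)
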