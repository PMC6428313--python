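"""Worked-example instances and a seeded random instance generator.

``sally_anne`` builds the classic false-belief task as a DBU instance.
``random_instance`` draws reproducible random instances for
property-based testing; with the S5 frame option, relations are built
from random partitions so they are equivalence relations by
construction, and preconditions are resampled until the action sequence
is applicable.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .formulas import And, Atom, Believes, Bot, Dual, Formula, Not, Or, Top, parse
from .models import (EpistemicModel, EventModel, PointedEpistemicModel,
                     PointedEventModel)
from .semantics import is_applicable, product_update
from .solver import DBUInstance

__all__ = ["sally_anne", "GeneratorConfig", "random_instance", "GenerationError"]


def sally_anne(goal: Formula | str | None = None) -> DBUInstance:
    """The Sally-Anne false-belief task.

    One proposition ``basket`` ("the marble is in the basket"; its
    negation means it is in the box).  Initially both Sally and Anne
    know the marble is in the basket (a single-world S5 state).  The one
    action is "Sally leaves and Anne moves the marble into the box":
    Anne observes the move, while absent Sally considers only the event
    in which nothing happens — a KD45 (consistent but false belief)
    event model.  With the default goal the instance asks whether Sally
    believes the marble is in the basket; the answer is yes.
    """
    agents = {"sally", "anne"}
    props = {"basket"}
    m0 = EpistemicModel(agents, props, {"w0"},
                        {"sally": {("w0", "w0")}, "anne": {("w0", "w0")}},
                        {"w0": {"basket"}})
    state = PointedEpistemicModel(m0, {"w0"})

    # e_move: Anne moves the marble; e_nothing: nothing happens.
    # Sally, being out of the room, points at e_nothing from both events.
    events = {"e_move", "e_nothing"}
    action = PointedEventModel(
        EventModel(agents, props, events,
                   {"anne": {("e_move", "e_move"), ("e_nothing", "e_nothing")},
                    "sally": {("e_move", "e_nothing"), ("e_nothing", "e_nothing")}},
                   pre={"e_move": Atom("basket"), "e_nothing": Top()},
                   post={"e_move": {"basket": False}, "e_nothing": {}}),
        {"e_move"})

    if goal is None:
        goal = Believes("sally", Atom("basket"))
    elif isinstance(goal, str):
        goal = parse(goal, agents_declared=agents, props_declared=props)
    return DBUInstance(props, agents, state, [action], goal)


class GenerationError(RuntimeError):
    """The generator could not produce an applicable instance within its
    retry budget."""


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    n_worlds: int = 4
    n_agents: int = 2
    n_props: int = 3
    n_actions: int = 2
    max_events: int = 2
    frame: str = "S5"  # "S5" or "arbitrary"
    max_pre_depth: int = 1
    modal_free_bias: float = 0.7  # share of preconditions without modalities
    max_retries: int = 50

    def __post_init__(self):
        if min(self.n_worlds, self.n_agents, self.n_props, self.max_events) < 1:
            raise ValueError("counts must be at least 1")
        if self.n_actions < 0:
            raise ValueError("n_actions must be non-negative")
        if self.frame not in ("S5", "arbitrary"):
            raise ValueError(f"unknown frame {self.frame!r}")


def _random_partition_relation(rng: random.Random, points: list[str]):
    """Random equivalence relation via a random partition of the points."""
    blocks: list[list[str]] = []
    for p in points:
        if blocks and rng.random() < 0.6:
            rng.choice(blocks).append(p)
        else:
            blocks.append([p])
    return frozenset((x, y) for block in blocks for x in block for y in block)


def _random_relation(rng: random.Random, points: list[str], frame: str):
    if frame == "S5":
        return _random_partition_relation(rng, points)
    n = len(points)
    density = rng.uniform(0.2, 0.6)
    return frozenset((x, y) for x in points for y in points
                     if rng.random() < density)


def _random_formula(rng: random.Random, props: list[str], agents: list[str],
                    depth: int, allow_modal: bool) -> Formula:
    if depth == 0:
        roll = rng.random()
        if roll < 0.8:
            return Atom(rng.choice(props))
        return Top() if roll < 0.9 else Bot()
    kind = rng.random()
    if kind < 0.25:
        return Not(_random_formula(rng, props, agents, depth - 1, allow_modal))
    if kind < 0.5:
        return And(_random_formula(rng, props, agents, depth - 1, allow_modal),
                   _random_formula(rng, props, agents, depth - 1, allow_modal))
    if kind < 0.65:
        return Or(_random_formula(rng, props, agents, depth - 1, allow_modal),
                  _random_formula(rng, props, agents, depth - 1, allow_modal))
    if allow_modal and kind < 0.85:
        op = Believes if rng.random() < 0.5 else Dual
        return op(rng.choice(agents),
                  _random_formula(rng, props, agents, depth - 1, allow_modal))
    return Atom(rng.choice(props))


def random_instance(cfg: GeneratorConfig) -> DBUInstance:
    """Draw a random applicable DBU instance; deterministic per seed."""
    rng = random.Random(cfg.seed)
    agents = [f"ag{i}" for i in range(cfg.n_agents)]
    props = [f"p{i}" for i in range(cfg.n_props)]
    worlds = [f"w{i}" for i in range(cfg.n_worlds)]

    relations = {a: _random_relation(rng, worlds, cfg.frame) for a in agents}
    valuation = {w: {p for p in props if rng.random() < 0.5} for w in worlds}
    designated = rng.sample(worlds, rng.randint(1, max(1, cfg.n_worlds // 2)))
    state = PointedEpistemicModel(
        EpistemicModel(agents, props, worlds, relations, valuation), designated)

    actions: list[PointedEventModel] = []
    current = state
    for idx in range(cfg.n_actions):
        action = None
        for _ in range(cfg.max_retries):
            n_events = rng.randint(1, cfg.max_events)
            events = [f"a{idx}e{j}" for j in range(n_events)]
            ev_rel = {a: _random_relation(rng, events, cfg.frame) for a in agents}
            allow_modal = rng.random() >= cfg.modal_free_bias
            pre = {e: _random_formula(rng, props, agents,
                                      rng.randint(0, cfg.max_pre_depth),
                                      allow_modal)
                   for e in events}
            post = {}
            for e in events:
                changes = {}
                for p in rng.sample(props, rng.randint(0, min(2, len(props)))):
                    changes[p] = rng.random() < 0.5
                post[e] = changes
            candidate = PointedEventModel(
                EventModel(agents, props, events, ev_rel, pre, post),
                rng.sample(events, rng.randint(1, n_events)))
            if is_applicable(current, candidate):
                action = candidate
                break
        if action is None:
            raise GenerationError(
                f"no applicable action found for position {idx} "
                f"after {cfg.max_retries} retries (seed {cfg.seed})")
        actions.append(action)
        current = product_update(current, action)

    goal = _random_formula(rng, props, agents, rng.randint(0, 2), True)
    return DBUInstance(props, agents, state, actions, goal)
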