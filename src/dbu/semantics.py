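"""Truth evaluation, applicability, and product update.

Truth in a single-pointed model follows the usual Kripke clauses; truth
in a multi-pointed model is the conjunction over the designated worlds.
The product update of a state (M, W_d) with an action (E, E_d) keeps the
world–event pairs whose precondition holds, intersects relations
componentwise, lets postconditions override the valuation, and pairs up
designated worlds with designated events.

Evaluation is memoized per (world, subformula); the result is identical
to naive recursion (asserted in the test suite against an independent
naive evaluator).
"""

from __future__ import annotations

from typing import Sequence

from .formulas import (And, Atom, Believes, Bot, Formula, Not, Top, expand,
                       atoms, agents as formula_agents)
from .models import (ID_SEPARATOR, EpistemicModel, EventModel, ModelError,
                     PointedEpistemicModel, PointedEventModel)

__all__ = ["satisfies", "is_applicable", "product_update", "apply_sequence",
           "InapplicableActionError"]


class InapplicableActionError(ModelError):
    """An action was applied to a state where no designated event's
    precondition holds at any designated world.  Distinct from a "no"
    answer of the decision problem."""

    def __init__(self, message: str, index: int | None = None):
        super().__init__(message)
        self.index = index


def _check_declared(model: EpistemicModel, phi: Formula) -> None:
    bad_p = atoms(phi) - model.props
    if bad_p:
        raise ModelError(f"formula uses undeclared proposition(s) {sorted(bad_p)}")
    bad_a = formula_agents(phi) - model.agents
    if bad_a:
        raise ModelError(f"formula uses undeclared agent(s) {sorted(bad_a)}")


def _holds(model: EpistemicModel, world: str, phi: Formula,
           memo: dict[tuple[str, int], bool], _ids: dict[int, Formula]) -> bool:
    key = (world, id(phi))
    _ids[id(phi)] = phi  # keep the node alive while memo references its id
    cached = memo.get(key)
    if cached is not None:
        return cached
    if isinstance(phi, Atom):
        value = model.true_at(world, phi.name)
    elif isinstance(phi, Top):
        value = True
    elif isinstance(phi, Bot):
        value = False
    elif isinstance(phi, Not):
        value = not _holds(model, world, phi.operand, memo, _ids)
    elif isinstance(phi, And):
        value = (_holds(model, world, phi.left, memo, _ids)
                 and _holds(model, world, phi.right, memo, _ids))
    elif isinstance(phi, Believes):
        value = all(_holds(model, v, phi.operand, memo, _ids)
                    for v in model.successors(phi.agent, world))
    else:
        raise ModelError(f"not a core formula: {phi!r}")
    memo[key] = value
    return value


def satisfies(state: PointedEpistemicModel, phi: Formula) -> bool:
    """M, W_d ⊨ φ — true iff φ holds at every designated world."""
    _check_declared(state.model, phi)
    core = expand(phi)
    memo: dict[tuple[str, int], bool] = {}
    ids: dict[int, Formula] = {}
    return all(_holds(state.model, w, core, memo, ids)
               for w in sorted(state.designated))


def _action_applies(state: PointedEpistemicModel,
                    action: PointedEventModel) -> bool:
    memo: dict[tuple[str, int], bool] = {}
    ids: dict[int, Formula] = {}
    for e in sorted(action.designated):
        pre = expand(action.model.pre[e])
        _check_declared(state.model, pre)
        for w in sorted(state.designated):
            if _holds(state.model, w, pre, memo, ids):
                return True
    return False


def is_applicable(state: PointedEpistemicModel,
                  actions: Sequence[PointedEventModel] | PointedEventModel) -> bool:
    """Applicability of a single action or an action sequence.

    A single action applies when some designated event's precondition
    holds at some designated world.  A sequence applies when every
    prefix does, each action evaluated in the updated state of the
    prefix before it; the empty sequence always applies.
    """
    if isinstance(actions, PointedEventModel):
        return _action_applies(state, actions)
    current = state
    for action in actions:
        if not _action_applies(current, action):
            return False
        current = product_update(current, action)
    return True


def product_update(state: PointedEpistemicModel,
                   action: PointedEventModel) -> PointedEpistemicModel:
    """(M, W_d) ⊗ (E, E_d).

    Raises ``InapplicableActionError`` when the action does not apply;
    an inapplicable update is an error, not an empty model.
    """
    if not _action_applies(state, action):
        raise InapplicableActionError("action is not applicable in this state")
    m, ev = state.model, action.model
    agents = m.agents | ev.agents
    props = m.props | ev.props

    memo: dict[tuple[str, int], bool] = {}
    ids: dict[int, Formula] = {}
    pre_core = {e: expand(ev.pre[e]) for e in ev.events}
    for e, phi in pre_core.items():
        _check_declared(m, phi)

    pairs: list[tuple[str, str]] = []
    for w in sorted(m.worlds):
        for e in sorted(ev.events):
            if _holds(m, w, pre_core[e], memo, ids):
                pairs.append((w, e))
    names = {pair: pair[0] + ID_SEPARATOR + pair[1] for pair in pairs}
    surviving = set(pairs)

    relations: dict[str, frozenset[tuple[str, str]]] = {}
    for agent in agents:
        r = m.relations.get(agent, frozenset())
        q = ev.relations.get(agent, frozenset())
        rel = set()
        for (w, v) in r:
            for (e, f) in q:
                if (w, e) in surviving and (v, f) in surviving:
                    rel.add((names[(w, e)], names[(v, f)]))
        relations[agent] = frozenset(rel)

    valuation = {}
    for (w, e) in pairs:
        post = ev.post[e]
        trues = {p for p in m.valuation[w] if post.get(p) is not False}
        trues |= {p for p, val in post.items() if val}
        valuation[names[(w, e)]] = frozenset(trues)

    designated = frozenset(
        names[(w, e)] for (w, e) in pairs
        if w in state.designated and e in action.designated)
    model = EpistemicModel(agents, props, frozenset(names.values()),
                           relations, valuation)
    return PointedEpistemicModel(model, designated)


def apply_sequence(state: PointedEpistemicModel,
                   actions: Sequence[PointedEventModel]) -> PointedEpistemicModel:
    """Left fold of ``product_update`` over an action sequence.

    The number of worlds of the result is bounded by |W⁰|·eᵘ where e is
    the maximum number of events per action and u the sequence length.
    Reports the index of the first inapplicable action on failure.
    """
    current = state
    for i, action in enumerate(actions):
        try:
            current = product_update(current, action)
        except InapplicableActionError:
            raise InapplicableActionError(
                f"action {i} of the sequence is not applicable", index=i)
    return current
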