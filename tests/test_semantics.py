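"""Truth evaluation, applicability, and product update."""

import pytest

from dbu.fixtures import GeneratorConfig, random_instance
from dbu.formulas import Atom, Believes, Bot, Top, parse
from dbu.models import (EpistemicModel, EventModel, PointedEpistemicModel,
                        PointedEventModel, ModelError, check_relation_class)
from dbu.semantics import (InapplicableActionError, apply_sequence,
                           is_applicable, product_update, satisfies)

from conftest import naive_satisfies


def true_props(state, world):
    return set(state.model.valuation[world])


class TestSatisfies:
    def test_atomic_fact_at_designated_world(self, fig1_state):
        assert satisfies(fig1_state, Atom("z"))

    def test_belief_requires_truth_at_all_accessible_worlds(self, fig1_state):
        # a cannot rule out w2 where z fails; b can
        assert not satisfies(fig1_state, parse("B[a] z"))
        assert satisfies(fig1_state, parse("B[b] z"))

    def test_belief_is_vacuous_without_successors(self):
        m = EpistemicModel({"a"}, {"p"}, {"w"}, {"a": set()}, {})
        state = PointedEpistemicModel(m, {"w"})
        assert satisfies(state, Believes("a", Bot()))

    def test_undeclared_symbols_rejected(self, fig1_state):
        with pytest.raises(ModelError):
            satisfies(fig1_state, Atom("nope"))
        with pytest.raises(ModelError):
            satisfies(fig1_state, Believes("c", Atom("z")))

    def test_multi_pointed_truth_is_conjunction(self, fig1_state):
        both = PointedEpistemicModel(fig1_state.model, {"w1", "w2"})
        for text in ("z", "~z", "B[a] z", "B[b] z", "z | ~z"):
            phi = parse(text)
            single = all(
                satisfies(PointedEpistemicModel(fig1_state.model, {w}), phi)
                for w in ("w1", "w2"))
            assert satisfies(both, phi) == single


class TestApplicability:
    def test_empty_sequence_always_applicable(self, fig1_state):
        assert is_applicable(fig1_state, [])

    def test_unsatisfiable_designated_precondition(self, fig1_state):
        ev = EventModel({"a", "b"}, {"z"}, {"e"}, {"a": {("e", "e")}},
                        pre={"e": Bot()})
        assert not is_applicable(fig1_state, PointedEventModel(ev, {"e"}))

    def test_trivial_preconditions_apply(self, fig1_state, fig2_action):
        assert is_applicable(fig1_state, fig2_action)
        assert is_applicable(fig1_state, [fig2_action, fig2_action])


class TestProductUpdate:
    def test_two_by_two_update_valuations(self, fig1_state, fig2_action):
        updated = product_update(fig1_state, fig2_action)
        got = {w: true_props(updated, w) for w in updated.model.worlds}
        assert got == {"w1|e1": {"z", "h"}, "w1|e2": {"z"},
                       "w2|e1": {"h"}, "w2|e2": set()}
        assert updated.designated == {"w1|e1"}

    def test_relations_intersect_componentwise(self, fig1_state, fig2_action):
        updated = product_update(fig1_state, fig2_action)
        rb = updated.model.relations["b"]
        # b can tell worlds and events apart, so only diagonal survives
        assert rb == {(w, w) for w in updated.model.worlds}
        assert check_relation_class(updated.model, "S5")

    def test_identity_action_copies_the_state(self, fig1_state):
        ev = EventModel({"a", "b"}, {"z"}, {"e"},
                        {"a": {("e", "e")}, "b": {("e", "e")}},
                        pre={"e": Top()})
        updated = product_update(fig1_state, PointedEventModel(ev, {"e"}))
        m0, m1 = fig1_state.model, updated.model
        mapping = {w: f"{w}|e" for w in m0.worlds}
        assert m1.worlds == set(mapping.values())
        for agent in m0.agents:
            assert m1.relations[agent] == {(mapping[x], mapping[y])
                                           for x, y in m0.relations[agent]}
        for w in m0.worlds:
            assert m1.valuation[mapping[w]] == m0.valuation[w]

    def test_precondition_filters_worlds(self, fig1_state):
        ev = EventModel({"a", "b"}, {"z"}, {"e"},
                        {"a": {("e", "e")}, "b": {("e", "e")}},
                        pre={"e": Atom("z")})
        updated = product_update(fig1_state, PointedEventModel(ev, {"e"}))
        assert updated.model.worlds == {"w1|e"}

    def test_inapplicable_update_is_an_error_not_a_no(self, fig1_state):
        ev = EventModel({"a", "b"}, {"z"}, {"e"}, {"a": {("e", "e")}},
                        pre={"e": Bot()})
        with pytest.raises(InapplicableActionError):
            product_update(fig1_state, PointedEventModel(ev, {"e"}))

    def test_sequence_reports_failing_index(self, fig1_state, fig2_action):
        bad = PointedEventModel(
            EventModel({"a", "b"}, {"z"}, {"e"}, {"a": {("e", "e")}},
                       pre={"e": Bot()}), {"e"})
        with pytest.raises(InapplicableActionError) as err:
            apply_sequence(fig1_state, [fig2_action, bad])
        assert err.value.index == 1

    def test_empty_sequence_returns_state(self, fig1_state):
        assert apply_sequence(fig1_state, []) is fig1_state


class TestRandomizedProperties:
    CONFIGS = [GeneratorConfig(seed=s, n_actions=2, n_worlds=4, n_props=2)
               for s in range(25)]

    @pytest.mark.parametrize("cfg", CONFIGS, ids=lambda c: f"seed{c.seed}")
    def test_memoized_evaluation_matches_naive(self, cfg):
        inst = random_instance(cfg)
        final = apply_sequence(inst.state, inst.actions)
        assert satisfies(final, inst.goal) == naive_satisfies(final, inst.goal)

    @pytest.mark.parametrize("cfg", CONFIGS, ids=lambda c: f"seed{c.seed}")
    def test_s5_preserved_by_update(self, cfg):
        inst = random_instance(cfg)
        assert check_relation_class(inst.state.model, "S5")
        current = inst.state
        for action in inst.actions:
            assert check_relation_class(action.model, "S5")
            current = product_update(current, action)
            assert check_relation_class(current.model, "S5")

    @pytest.mark.parametrize("cfg", CONFIGS, ids=lambda c: f"seed{c.seed}")
    def test_world_count_bound(self, cfg):
        inst = random_instance(cfg)
        final = apply_sequence(inst.state, inst.actions)
        e = max((len(a.model.events) for a in inst.actions), default=0)
        u = len(inst.actions)
        assert len(final.model.worlds) <= len(inst.state.model.worlds) * max(e, 1) ** u

    @pytest.mark.parametrize("cfg", CONFIGS, ids=lambda c: f"seed{c.seed}")
    def test_unreachable_worlds_do_not_affect_truth(self, cfg):
        inst = random_instance(cfg)
        state = inst.state
        # worlds reachable from the designated set under any agent chain
        reachable = set(state.designated)
        frontier = list(reachable)
        while frontier:
            w = frontier.pop()
            for rel in state.model.relations.values():
                for (x, y) in rel:
                    if x == w and y not in reachable:
                        reachable.add(y)
                        frontier.append(y)
        sub = PointedEpistemicModel(state.model.restrict(reachable),
                                    state.designated)
        assert satisfies(sub, inst.goal) == satisfies(state, inst.goal)
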