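"""JSON serialization of DBU instances, and readers for the classical
input formats of the reduction generators (QDIMACS, DIMACS CNF, colored
edge lists).

The instance document dialect::

    {
      "version": "1",
      "agents": ["a", "b"],
      "props": ["z"],
      "state": {
        "worlds": ["w1", "w2"],
        "relations": {"a": [["w1", "w2"], ...], "b": [...]},
        "valuation": {"w1": ["z"]},
        "designated": ["w1"]
      },
      "actions": [
        {
          "events": ["e1", "e2"],
          "relations": {"a": [["e1", "e2"], ...]},
          "pre": {"e1": "T", "e2": "z & B[a] z"},
          "post": {"e1": ["h"], "e2": ["~h"]},
          "designated": ["e1"]
        }
      ],
      "formula": "B[b] h"
    }

Formulas are stored in the text syntax of :mod:`dbu.formulas`, which
keeps documents human-auditable.  Relations are stored fully explicit
(no implicit reflexive loops).  Absent valuation entries mean false;
``post`` lists literals, ``~p`` meaning "set p false".  The machine-
readable schema ships as ``dbu/schema/instance.schema.json``; loading
re-checks every instance invariant including applicability.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

from .formulas import Formula, parse, render
from .models import (ID_SEPARATOR, EpistemicModel, EventModel,
                     PointedEpistemicModel, PointedEventModel)
from .reductions import CNFInstance, ColoredGraph, QBFInstance
from .solver import DBUInstance

__all__ = ["load_instance", "save_instance", "instance_to_dict",
           "instance_from_dict", "SchemaError",
           "read_dimacs_cnf", "read_qdimacs", "read_colored_graph"]

VERSION = "1"


class SchemaError(ValueError):
    """A document that does not match the instance dialect; the message
    carries a JSON-pointer-style path to the offending element."""

    def __init__(self, path: str, message: str):
        super().__init__(f"{path}: {message}")
        self.path = path


def _require(doc: dict, key: str, kind, path: str):
    if key not in doc:
        raise SchemaError(f"{path}/{key}", "missing required field")
    value = doc[key]
    if not isinstance(value, kind):
        raise SchemaError(f"{path}/{key}",
                          f"expected {kind.__name__}, got {type(value).__name__}")
    return value


def _string_list(value: Any, path: str) -> list[str]:
    if not isinstance(value, list) or not all(isinstance(x, str) for x in value):
        raise SchemaError(path, "expected a list of strings")
    return value


def _check_ids(ids: list[str], path: str) -> None:
    for x in ids:
        if not x:
            raise SchemaError(path, "empty identifier")
        if ID_SEPARATOR in x:
            raise SchemaError(path, f"identifier {x!r} contains the reserved "
                                    f"{ID_SEPARATOR!r} separator")


def _relations(doc: Any, points: list[str], agents: list[str], path: str):
    if not isinstance(doc, dict):
        raise SchemaError(path, "expected an object")
    out = {}
    pts = set(points)
    for agent, pairs in doc.items():
        if agent not in agents:
            raise SchemaError(f"{path}/{agent}", "relation for undeclared agent")
        if not isinstance(pairs, list):
            raise SchemaError(f"{path}/{agent}", "expected a list of pairs")
        rel = set()
        for idx, pair in enumerate(pairs):
            if (not isinstance(pair, list) or len(pair) != 2
                    or not all(isinstance(x, str) for x in pair)):
                raise SchemaError(f"{path}/{agent}/{idx}",
                                  "expected a two-element string pair")
            if pair[0] not in pts or pair[1] not in pts:
                raise SchemaError(f"{path}/{agent}/{idx}",
                                  f"endpoint outside declared set: {pair}")
            rel.add((pair[0], pair[1]))
        out[agent] = frozenset(rel)
    return out


def instance_from_dict(doc: dict) -> DBUInstance:
    if not isinstance(doc, dict):
        raise SchemaError("", "document must be a JSON object")
    version = doc.get("version", VERSION)
    if version != VERSION:
        raise SchemaError("/version", f"unsupported version {version!r}")
    agents = _string_list(_require(doc, "agents", list, ""), "/agents")
    props = _string_list(_require(doc, "props", list, ""), "/props")
    if not agents:
        raise SchemaError("/agents", "at least one agent is required")
    if len(set(agents)) != len(agents) or len(set(props)) != len(props):
        raise SchemaError("", "duplicate agent or proposition ids")

    sdoc = _require(doc, "state", dict, "")
    worlds = _string_list(_require(sdoc, "worlds", list, "/state"), "/state/worlds")
    _check_ids(worlds, "/state/worlds")
    relations = _relations(_require(sdoc, "relations", dict, "/state"),
                           worlds, agents, "/state/relations")
    vdoc = _require(sdoc, "valuation", dict, "/state")
    valuation = {}
    for w, trues in vdoc.items():
        if w not in worlds:
            raise SchemaError(f"/state/valuation/{w}", "unknown world")
        ts = _string_list(trues, f"/state/valuation/{w}")
        for p in ts:
            if p not in props:
                raise SchemaError(f"/state/valuation/{w}",
                                  f"undeclared proposition {p!r}")
        valuation[w] = set(ts)
    designated = _string_list(_require(sdoc, "designated", list, "/state"),
                              "/state/designated")
    if not designated:
        raise SchemaError("/state/designated", "must be non-empty")
    model = EpistemicModel(agents, props, worlds, relations, valuation)
    try:
        state = PointedEpistemicModel(model, designated)
    except ValueError as err:
        raise SchemaError("/state/designated", str(err)) from err

    actions = []
    adocs = doc.get("actions", [])
    if not isinstance(adocs, list):
        raise SchemaError("/actions", "expected a list")
    for i, adoc in enumerate(adocs):
        prefix = f"/actions/{i}"
        if not isinstance(adoc, dict):
            raise SchemaError(prefix, "expected an object")
        events = _string_list(_require(adoc, "events", list, prefix),
                              f"{prefix}/events")
        _check_ids(events, f"{prefix}/events")
        ev_rel = _relations(_require(adoc, "relations", dict, prefix),
                            events, agents, f"{prefix}/relations")
        pre_doc = _require(adoc, "pre", dict, prefix)
        pre = {}
        for e, text in pre_doc.items():
            if e not in events:
                raise SchemaError(f"{prefix}/pre/{e}", "unknown event")
            if not isinstance(text, str):
                raise SchemaError(f"{prefix}/pre/{e}", "expected formula text")
            try:
                pre[e] = parse(text, agents_declared=agents, props_declared=props)
            except ValueError as err:
                raise SchemaError(f"{prefix}/pre/{e}", str(err)) from err
        post_doc = adoc.get("post", {})
        if not isinstance(post_doc, dict):
            raise SchemaError(f"{prefix}/post", "expected an object")
        post = {}
        for e, lits in post_doc.items():
            if e not in events:
                raise SchemaError(f"{prefix}/post/{e}", "unknown event")
            changes: dict[str, bool] = {}
            for lit in _string_list(lits, f"{prefix}/post/{e}"):
                negative = lit.startswith("~")
                p = lit[1:] if negative else lit
                if p not in props:
                    raise SchemaError(f"{prefix}/post/{e}",
                                      f"undeclared proposition {p!r}")
                if p in changes and changes[p] != (not negative):
                    raise SchemaError(f"{prefix}/post/{e}",
                                      f"contradictory literals for {p!r}")
                changes[p] = not negative
            post[e] = changes
        designated_e = _string_list(_require(adoc, "designated", list, prefix),
                                    f"{prefix}/designated")
        try:
            actions.append(PointedEventModel(
                EventModel(agents, props, events, ev_rel, pre, post),
                designated_e))
        except ValueError as err:
            raise SchemaError(prefix, str(err)) from err

    ftext = _require(doc, "formula", str, "")
    try:
        goal = parse(ftext, agents_declared=agents, props_declared=props)
    except ValueError as err:
        raise SchemaError("/formula", str(err)) from err

    return DBUInstance(props, agents, state, actions, goal)


def instance_to_dict(inst: DBUInstance) -> dict:
    def rel_doc(relations) -> dict:
        return {a: sorted([x, y] for x, y in rel)
                for a, rel in sorted(relations.items())}

    state = inst.state
    doc = {
        "version": VERSION,
        "agents": sorted(inst.agents),
        "props": sorted(inst.props),
        "state": {
            "worlds": sorted(state.model.worlds),
            "relations": rel_doc(state.model.relations),
            "valuation": {w: sorted(ts)
                          for w, ts in sorted(state.model.valuation.items()) if ts},
            "designated": sorted(state.designated),
        },
        "actions": [],
        "formula": render(inst.goal),
    }
    for action in inst.actions:
        em = action.model
        doc["actions"].append({
            "events": sorted(em.events),
            "relations": rel_doc(em.relations),
            "pre": {e: render(em.pre[e]) for e in sorted(em.events)},
            "post": {e: sorted(p if v else "~" + p
                               for p, v in em.post[e].items())
                     for e in sorted(em.events) if em.post[e]},
            "designated": sorted(action.designated),
        })
    return doc


def load_instance(path: str | Path) -> DBUInstance:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as err:
            raise SchemaError("", f"not valid JSON: {err}") from err
    return instance_from_dict(doc)


def save_instance(inst: DBUInstance, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(instance_to_dict(inst), fh, indent=2, sort_keys=True)
        fh.write("\n")


# --- classical input formats ------------------------------------------------

def read_dimacs_cnf(path: str | Path, max_width: int = 3) -> CNFInstance:
    """Read a DIMACS CNF file ("p cnf <vars> <clauses>" header)."""
    num_vars = None
    clauses: list[tuple[int, ...]] = []
    current: list[int] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("c"):
            continue
        if line.startswith("p"):
            parts = line.split()
            if len(parts) != 4 or parts[1] != "cnf":
                raise ValueError(f"malformed problem line: {line!r}")
            num_vars = int(parts[2])
            continue
        for tok in line.split():
            lit = int(tok)
            if lit == 0:
                if current:
                    clauses.append(tuple(current))
                    current = []
            else:
                current.append(lit)
    if current:
        clauses.append(tuple(current))
    if num_vars is None:
        raise ValueError("missing 'p cnf' problem line")
    return CNFInstance(num_vars, clauses, max_width=max_width)


def read_qdimacs(path: str | Path) -> QBFInstance:
    """Read a QDIMACS file: 'a'/'e' quantifier lines, then CNF clauses."""
    from .formulas import Atom, Not as FNot, conjoin, disjoin

    prefix: list[tuple[str, str]] = []
    clauses: list[list[int]] = []
    current: list[int] = []
    num_vars = 0
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("c"):
            continue
        if line.startswith("p"):
            parts = line.split()
            if len(parts) != 4 or parts[1] != "cnf":
                raise ValueError(f"malformed problem line: {line!r}")
            num_vars = int(parts[2])
            continue
        if line[0] in "ae":
            quant = "forall" if line[0] == "a" else "exists"
            for tok in line.split()[1:]:
                var = int(tok)
                if var == 0:
                    continue
                prefix.append((quant, f"x{var}"))
            continue
        for tok in line.split():
            lit = int(tok)
            if lit == 0:
                if current:
                    clauses.append(current)
                    current = []
            else:
                current.append(lit)
    if current:
        clauses.append(current)
    quantified = {v for _, v in prefix}
    for v in range(1, num_vars + 1):
        if f"x{v}" not in quantified:  # free variables are outer-existential
            prefix.insert(0, ("exists", f"x{v}"))
    matrix = conjoin([
        disjoin([Atom(f"x{lit}") if lit > 0 else FNot(Atom(f"x{-lit}"))
                 for lit in clause])
        for clause in clauses])
    return QBFInstance(prefix, matrix)


def read_colored_graph(edges_path: str | Path,
                       colors_path: str | Path) -> ColoredGraph:
    """Read a whitespace-separated edge list and a "vertex color" map."""
    coloring: dict[str, int] = {}
    for raw in Path(colors_path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"malformed color line: {line!r}")
        coloring[parts[0]] = int(parts[1])
    edges = []
    vertices = set(coloring)
    for raw in Path(edges_path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"malformed edge line: {line!r}")
        edges.append(parts)
        vertices.update(parts)
    return ColoredGraph(sorted(vertices), edges, coloring)
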