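"""Serialization of complete QSSPN models.

The on-disk dialect is a single JSON document bundling the dynamic Petri net
(places, transitions, edges, activity tables), the metabolic part (inline or
a path to a tabular reaction file / SBML), the constraint and objective
couplings and a default simulation configuration.  Keys are emitted in
canonical (sorted) order so diffs are stable, and a semantic model hash is
recorded on write.

Numbers (token counts, thresholds, rates) are serialized as JSON numbers,
never strings.  Time and rate units are arbitrary (a.u., 1/a.u.).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

from .fba import (MetabolicModel, Metabolite, Reaction, FluxObjective,
                  read_reaction_table, read_sbml)
from .petri import ActivityTable, Edge, PetriNet, Place, Transition
from .simulate import ConstraintCoupling, ObjectiveCoupling, QsspnModel, SimulationConfig

FORMAT_NAME = "qsspn-document"
FORMAT_VERSION = 1


class DocumentError(ValueError):
    """Schema violation with a path into the offending document."""

    def __init__(self, path: str, where: str, message: str) -> None:
        self.path = path
        self.where = where
        super().__init__(f"{path}: at {where}: {message}")


@dataclass
class QsspnDocument:
    """A complete, validated model plus its default configuration."""

    model: QsspnModel
    config: SimulationConfig = field(default_factory=SimulationConfig)
    description: str = ""
    metabolism_path: str | None = None  # external reaction table / SBML, if any

    def validate(self) -> list[str]:
        return self.model.validate()


# -- writing ----------------------------------------------------------------

def _table_json(table: ActivityTable | None):
    return None if table is None else [[t, a] for t, a in table.entries]


def _edge_json(edge: Edge) -> dict:
    out = {"place": edge.place, "kind": edge.kind, "weight": edge.weight}
    if edge.table is not None:
        out["table"] = _table_json(edge.table)
    return out


def document_to_json(doc: QsspnDocument) -> dict:
    model = doc.model
    net = model.net
    out: dict = {
        "format": FORMAT_NAME,
        "version": FORMAT_VERSION,
        "description": doc.description,
        "places": [
            {"id": p.id, "name": p.name, "kind": p.kind, "tokens": p.tokens,
             "capacity": p.capacity}
            for p in net.places.values()],
        "transitions": [
            {"id": t.id, "class": t.klass, "rate": t.rate, "delay": t.delay,
             "pre": [_edge_json(e) for e in t.pre],
             "post": [_edge_json(e) for e in t.post]}
            for t in net.transitions.values()],
        "constraints": [
            {"place": c.place,
             "rows": [[thr, {rid: list(b) for rid, b in sorted(overrides.items())}]
                      for thr, overrides in c.rows]}
            for c in model.constraints],
        "objectives": [
            {"place": o.place,
             "objective": dict(sorted(o.objective.coefficients.items())),
             "rows": [[thr, tok] for thr, tok in o.rows]}
            for o in model.objectives],
        "config": {"t_max": doc.config.t_max, "max_timestep": doc.config.max_timestep,
                   "seed": doc.config.seed, "record_mode": doc.config.record_mode,
                   "fba_cache": doc.config.fba_cache},
        "model_hash": model.hash(),
    }
    if doc.metabolism_path is not None:
        out["metabolism"] = {"path": doc.metabolism_path}
    elif model.metabolism is not None:
        m = model.metabolism
        out["metabolism"] = {"inline": {
            "metabolites": [{"id": met.id, "compartment": met.compartment,
                             "external": met.external} for met in m.metabolites.values()],
            "reactions": [{"id": r.id, "stoichiometry": dict(sorted(r.stoichiometry.items())),
                           "lower": r.lower, "upper": r.upper} for r in m.reactions.values()],
        }}
    else:
        out["metabolism"] = None
    return out


def write_document(doc: QsspnDocument, path: str, compact: bool = False) -> None:
    violations = doc.validate()
    if violations:
        raise ValueError("refusing to write invalid document: " + "; ".join(violations))
    payload = document_to_json(doc)
    with open(path, "w") as fh:
        if compact:
            json.dump(payload, fh, sort_keys=True, separators=(",", ":"))
        else:
            json.dump(payload, fh, sort_keys=True, indent=2)
        fh.write("\n")


# -- reading ----------------------------------------------------------------

def _require(data: dict, key: str, path: str, where: str):
    if key not in data:
        raise DocumentError(path, where, f"missing required field {key!r}")
    return data[key]


def _parse_table(raw, path: str, where: str) -> ActivityTable:
    try:
        return ActivityTable(tuple((int(t), float(a)) for t, a in raw))
    except (TypeError, ValueError) as exc:
        raise DocumentError(path, where, f"malformed activity table: {exc}") from exc


def _parse_edge(raw: dict, path: str, where: str) -> Edge:
    table = raw.get("table")
    return Edge(place=str(_require(raw, "place", path, where)),
                kind=str(raw.get("kind", "standard")),
                weight=int(raw.get("weight", 1)),
                table=None if table is None else _parse_table(table, path, where + ".table"))


def document_from_json(data: dict, path: str = "<memory>",
                       base_dir: str = ".") -> QsspnDocument:
    if data.get("format") != FORMAT_NAME:
        raise DocumentError(path, "$.format", f"not a {FORMAT_NAME} file")
    net = PetriNet()
    for i, p in enumerate(_require(data, "places", path, "$")):
        where = f"$.places[{i}]"
        cap = p.get("capacity")
        try:
            net.add_place(Place(id=str(_require(p, "id", path, where)),
                                name=str(p.get("name", "")),
                                kind=str(p.get("kind", "regular")),
                                tokens=int(p.get("tokens", 0)),
                                capacity=None if cap is None else int(cap)))
        except ValueError as exc:
            raise DocumentError(path, where, str(exc)) from exc
    for i, t in enumerate(_require(data, "transitions", path, "$")):
        where = f"$.transitions[{i}]"
        try:
            net.add_transition(Transition(
                id=str(_require(t, "id", path, where)),
                klass=str(t.get("class", "stochastic")),
                rate=float(t.get("rate", 1.0)),
                delay=float(t.get("delay", 0.0)),
                pre=tuple(_parse_edge(e, path, f"{where}.pre[{j}]")
                          for j, e in enumerate(t.get("pre", []))),
                post=tuple(_parse_edge(e, path, f"{where}.post[{j}]")
                           for j, e in enumerate(t.get("post", [])))))
        except ValueError as exc:
            raise DocumentError(path, where, str(exc)) from exc

    metabolism = None
    metabolism_path = None
    raw_met = data.get("metabolism")
    if raw_met:
        if "path" in raw_met:
            metabolism_path = raw_met["path"]
            resolved = os.path.join(base_dir, metabolism_path)
            if not os.path.exists(resolved):
                raise DocumentError(path, "$.metabolism.path",
                                    f"metabolic model file not found: {resolved}")
            if resolved.endswith((".xml", ".sbml")):
                metabolism = read_sbml(resolved)
            else:
                metabolism = read_reaction_table(resolved)
        elif "inline" in raw_met:
            inline = raw_met["inline"]
            metabolism = MetabolicModel()
            for j, m in enumerate(inline.get("metabolites", [])):
                where = f"$.metabolism.inline.metabolites[{j}]"
                metabolism.add_metabolite(Metabolite(
                    str(_require(m, "id", path, where)),
                    str(m.get("compartment", "")), bool(m.get("external", False))))
            for j, r in enumerate(inline.get("reactions", [])):
                where = f"$.metabolism.inline.reactions[{j}]"
                try:
                    metabolism.add_reaction(Reaction(
                        str(_require(r, "id", path, where)),
                        {str(k): float(v) for k, v in
                         _require(r, "stoichiometry", path, where).items()},
                        float(r.get("lower", 0.0)), float(r.get("upper", 1000.0))))
                except ValueError as exc:
                    raise DocumentError(path, where, str(exc)) from exc
        else:
            raise DocumentError(path, "$.metabolism", "expected 'path' or 'inline'")

    constraints = []
    for i, c in enumerate(data.get("constraints", [])):
        where = f"$.constraints[{i}]"
        rows = tuple((int(thr), {str(rid): (float(b[0]), float(b[1]))
                                 for rid, b in overrides.items()})
                     for thr, overrides in _require(c, "rows", path, where))
        constraints.append(ConstraintCoupling(str(_require(c, "place", path, where)), rows))
    objectives = []
    for i, o in enumerate(data.get("objectives", [])):
        where = f"$.objectives[{i}]"
        rows = tuple((float(thr), int(tok)) for thr, tok in _require(o, "rows", path, where))
        objectives.append(ObjectiveCoupling(
            str(_require(o, "place", path, where)),
            FluxObjective({str(k): float(v)
                           for k, v in _require(o, "objective", path, where).items()}),
            rows))

    raw_cfg = data.get("config", {})
    try:
        config = SimulationConfig(
            t_max=float(raw_cfg.get("t_max", 20.0)),
            max_timestep=float(raw_cfg.get("max_timestep", 1.0)),
            seed=int(raw_cfg.get("seed", 0)),
            record_mode=str(raw_cfg.get("record_mode", "events")),
            fba_cache=bool(raw_cfg.get("fba_cache", True)))
    except ValueError as exc:
        raise DocumentError(path, "$.config", str(exc)) from exc

    doc = QsspnDocument(
        model=QsspnModel(net=net, metabolism=metabolism,
                         constraints=tuple(constraints), objectives=tuple(objectives)),
        config=config, description=str(data.get("description", "")),
        metabolism_path=metabolism_path)
    violations = doc.validate()
    if violations:
        raise DocumentError(path, "$", "invalid model: " + "; ".join(violations))
    return doc


def read_document(path: str) -> QsspnDocument:
    """Read and fully validate a QSSPN JSON document."""
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise DocumentError(path, f"line {exc.lineno}", exc.msg) from exc
    return document_from_json(data, path=path, base_dir=os.path.dirname(path) or ".")
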