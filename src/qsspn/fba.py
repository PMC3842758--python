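"""Constraint-based analysis of the quasi-steady-state flux part.

A :class:`MetabolicModel` is a stoichiometric reaction list with flux bounds.
Flux balance analysis maximises a linear flux objective subject to
steady-state mass balance ``S v = 0`` over *internal* metabolites and box
bounds on each reaction; external/boundary metabolites are unconstrained
(standard FBA convention).  The LP is solved fresh on every call with the
deterministic HiGHS solver, so results are reproducible and independent of
call history.

Producibility of a metabolite is the maximal flux through a temporary drain
reaction consuming it; qualitatively a metabolite is producible when that
optimum exceeds a small threshold (default 1e-3).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

#: qualitative producibility cut-off on an objective value
PRODUCIBILITY_THRESHOLD = 1e-3

#: metabolite-id suffix marking external (unbalanced) species in reaction tables
EXTERNAL_SUFFIX = "_ext"


class FbaError(RuntimeError):
    """LP solver failure distinct from an infeasible or unbounded model."""


@dataclass
class Metabolite:
    id: str
    compartment: str = ""
    external: bool = False


@dataclass
class Reaction:
    """``stoichiometry`` maps metabolite id to a signed coefficient
    (negative = consumed, positive = produced)."""

    id: str
    stoichiometry: dict[str, float]
    lower: float = 0.0
    upper: float = 1000.0

    @property
    def reversible(self) -> bool:
        return self.lower < 0.0


@dataclass
class FluxObjective:
    """Linear flux objective, always maximised."""

    coefficients: dict[str, float]


@dataclass
class FbaResult:
    status: str  # optimal | infeasible | unbounded
    objective_value: float | None = None
    fluxes: dict[str, float] | None = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def value_or(self, default: float) -> float:
        """Objective value, with infeasible -> ``default`` and unbounded -> +inf."""
        if self.status == "optimal":
            return self.objective_value  # type: ignore[return-value]
        if self.status == "unbounded":
            return float("inf")
        return default


class MetabolicModel:
    """Stoichiometric model: metabolites, reactions, bounds."""

    def __init__(self, metabolites: list[Metabolite] | None = None,
                 reactions: list[Reaction] | None = None) -> None:
        self.metabolites: dict[str, Metabolite] = {}
        self.reactions: dict[str, Reaction] = {}
        for m in metabolites or []:
            self.add_metabolite(m)
        for r in reactions or []:
            self.add_reaction(r)

    def add_metabolite(self, m: Metabolite) -> Metabolite:
        if m.id in self.metabolites:
            raise ValueError(f"duplicate metabolite id {m.id!r}")
        self.metabolites[m.id] = m
        return m

    def add_reaction(self, r: Reaction) -> Reaction:
        if r.id in self.reactions:
            raise ValueError(f"duplicate reaction id {r.id!r}")
        for met in r.stoichiometry:
            if met not in self.metabolites:
                raise ValueError(f"reaction {r.id!r} references undeclared metabolite {met!r}")
        if r.lower > r.upper:
            raise ValueError(f"reaction {r.id!r}: lower bound exceeds upper bound")
        self.reactions[r.id] = r
        return r

    def internal_metabolites(self) -> list[str]:
        return [m.id for m in self.metabolites.values() if not m.external]

    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str], list[str]]:
        """(S, internal metabolite ids, reaction ids) with S of shape (m, n)."""
        mets = self.internal_metabolites()
        rids = list(self.reactions)
        met_idx = {m: i for i, m in enumerate(mets)}
        S = np.zeros((len(mets), len(rids)))
        for j, rid in enumerate(rids):
            for met, coef in self.reactions[rid].stoichiometry.items():
                i = met_idx.get(met)
                if i is not None:
                    S[i, j] = coef
        return S, mets, rids

    def copy(self) -> "MetabolicModel":
        model = MetabolicModel()
        for m in self.metabolites.values():
            model.add_metabolite(Metabolite(m.id, m.compartment, m.external))
        for r in self.reactions.values():
            model.add_reaction(Reaction(r.id, dict(r.stoichiometry), r.lower, r.upper))
        return model


def maximize(model: MetabolicModel, objective: FluxObjective,
             bound_overrides: dict[str, tuple[float, float]] | None = None) -> FbaResult:
    """Maximise ``c^T v`` s.t. ``S v = 0`` (internal metabolites) and bounds.

    ``bound_overrides`` replaces the (lower, upper) bounds of the named
    reactions for this call only; the model is never mutated.
    """
    overrides = bound_overrides or {}
    for rid in list(overrides) + list(objective.coefficients):
        if rid not in model.reactions:
            raise KeyError(f"unknown reaction id {rid!r}")
    S, _, rids = model.stoichiometric_matrix()
    n = len(rids)
    c = np.zeros(n)
    bounds = []
    for j, rid in enumerate(rids):
        c[j] = objective.coefficients.get(rid, 0.0)
        r = model.reactions[rid]
        lo, hi = overrides.get(rid, (r.lower, r.upper))
        bounds.append((lo, hi))
    res = linprog(-c, A_eq=S if S.size else None, b_eq=np.zeros(S.shape[0]) if S.size else None,
                  bounds=bounds, method="highs")
    if res.status == 0:
        fluxes = {rid: float(v) for rid, v in zip(rids, res.x)}
        return FbaResult("optimal", float(-res.fun), fluxes)
    if res.status == 2:
        return FbaResult("infeasible")
    if res.status == 3:
        return FbaResult("unbounded")
    raise FbaError(f"LP solver failed: {res.message}")


def producibility(model: MetabolicModel, metabolite_id: str,
                  bound_overrides: dict[str, tuple[float, float]] | None = None,
                  drain_limit: float = 1000.0) -> float:
    """Maximal achievable synthesis flux of a metabolite.

    Adds a temporary drain reaction consuming the metabolite, maximises its
    flux, and returns the optimum (0.0 on infeasibility).  The input model is
    left untouched.
    """
    if metabolite_id not in model.metabolites:
        raise KeyError(f"unknown metabolite id {metabolite_id!r}")
    probe = model.copy()
    drain_id = f"__drain_{metabolite_id}"
    while drain_id in probe.reactions:
        drain_id += "_"
    probe.add_reaction(Reaction(drain_id, {metabolite_id: -1.0}, 0.0, drain_limit))
    result = maximize(probe, FluxObjective({drain_id: 1.0}), bound_overrides)
    return result.value_or(0.0)


def knockout_bounds(model: MetabolicModel, reaction_ids: list[str]) -> dict[str, tuple[float, float]]:
    """Bound overrides fixing each listed reaction flux to zero."""
    for rid in reaction_ids:
        if rid not in model.reactions:
            raise KeyError(f"unknown reaction id {rid!r}")
    return {rid: (0.0, 0.0) for rid in reaction_ids}


# ---------------------------------------------------------------------------
# Tabular reaction-list format
#
# One reaction per line:  id <TAB> formula <TAB> lower <TAB> upper
# Formula:  "a A + 2 B -> C"  or  "A <-> B"  (unicode arrows accepted).
# '#' starts a comment; a "# external: m1 m2 ..." header declares external
# metabolites in addition to the EXTERNAL_SUFFIX convention.
# ---------------------------------------------------------------------------

_ARROWS_IRREV = ("->", "→", "=>")
_ARROWS_REV = ("<->", "↔", "<=>")


def _parse_side(text: str) -> list[tuple[float, str]]:
    terms = []
    for chunk in text.split("+"):
        chunk = chunk.strip()
        if not chunk:
            continue
        m = re.match(r"^(\d+(?:\.\d+)?)\s+(\S+)$", chunk)
        if m:
            terms.append((float(m.group(1)), m.group(2)))
        else:
            terms.append((1.0, chunk))
    return terms


def parse_reaction_formula(formula: str) -> tuple[dict[str, float], bool]:
    """Parse "A + 2 B -> C" into a stoichiometry map and a reversibility flag."""
    for arrow in _ARROWS_REV:
        if arrow in formula:
            left, right = formula.split(arrow, 1)
            reversible = True
            break
    else:
        for arrow in _ARROWS_IRREV:
            if arrow in formula:
                left, right = formula.split(arrow, 1)
                reversible = False
                break
        else:
            raise ValueError(f"no reaction arrow in formula {formula!r}")
    stoich: dict[str, float] = {}
    for coef, met in _parse_side(left):
        stoich[met] = stoich.get(met, 0.0) - coef
    for coef, met in _parse_side(right):
        stoich[met] = stoich.get(met, 0.0) + coef
    return stoich, reversible


def read_reaction_table(path: str) -> MetabolicModel:
    """Read a tabular reaction file into a :class:`MetabolicModel`."""
    model = MetabolicModel()
    externals: set[str] = set()
    rows: list[tuple[int, str, dict[str, float], float, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*external\s*:\s*(.*)$", line, re.IGNORECASE)
                if m:
                    externals.update(m.group(1).split())
                continue
            parts = [p.strip() for p in re.split(r"\t+", line)]
            if len(parts) == 1:  # whitespace-tolerant fallback for space-aligned files
                m = re.match(r"^(\S+)\s+(.*?)\s+(-?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)\s+(-?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)$", line)
                if not m:
                    raise ValueError(f"{path}:{lineno}: cannot parse reaction line {line!r}")
                parts = [m.group(1), m.group(2), m.group(3), m.group(4)]
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 fields, got {len(parts)}")
            rid, formula, lo_s, hi_s = parts
            try:
                stoich, _ = parse_reaction_formula(formula)
                lo, hi = float(lo_s), float(hi_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            rows.append((lineno, rid, stoich, lo, hi))
    mets = sorted({met for _, _, stoich, _, _ in rows for met in stoich})
    for met in mets:
        model.add_metabolite(Metabolite(met, external=met in externals or met.endswith(EXTERNAL_SUFFIX)))
    for lineno, rid, stoich, lo, hi in rows:
        try:
            model.add_reaction(Reaction(rid, stoich, lo, hi))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return model


def format_reaction_formula(stoich: dict[str, float]) -> str:
    def side(items: list[tuple[str, float]]) -> str:
        parts = []
        for met, coef in items:
            parts.append(met if coef == 1.0 else f"{coef:g} {met}")
        return " + ".join(parts)

    left = [(m, -c) for m, c in sorted(stoich.items()) if c < 0]
    right = [(m, c) for m, c in sorted(stoich.items()) if c > 0]
    return f"{side(left)} -> {side(right)}".strip()


def write_reaction_table(model: MetabolicModel, path: str) -> None:
    explicit = sorted(m.id for m in model.metabolites.values()
                      if m.external and not m.id.endswith(EXTERNAL_SUFFIX))
    with open(path, "w") as fh:
        fh.write("# reaction table: id\tformula\tlower\tupper\n")
        if explicit:
            fh.write(f"# external: {' '.join(explicit)}\n")
        for r in model.reactions.values():
            fh.write(f"{r.id}\t{format_reaction_formula(r.stoichiometry)}\t{r.lower:g}\t{r.upper:g}\n")


# Optional SBML import ------------------------------------------------------

try:  # pragma: no cover - capability probe
    import cobra as _cobra
    HAS_SBML = True
except Exception:  # pragma: no cover
    _cobra = None
    HAS_SBML = False


def read_sbml(path: str) -> MetabolicModel:
    """Import an SBML (FBC bounds) model.  Requires the optional cobra extra."""
    if not HAS_SBML:
        raise RuntimeError("SBML support unavailable: install the 'sbml' extra (cobra)")
    cm = _cobra.io.read_sbml_model(path)
    model = MetabolicModel()
    for met in cm.metabolites:
        model.add_metabolite(Metabolite(met.id, met.compartment or "", met.id in
                                        {m.id for m in cm.boundary_metabolites}
                                        if hasattr(cm, "boundary_metabolites") else False))
    for rxn in cm.reactions:
        stoich = {met.id: coef for met, coef in rxn.metabolites.items()}
        model.add_reaction(Reaction(rxn.id, stoich, rxn.lower_bound, rxn.upper_bound))
    return model
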