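"""Behaviour detection and ensemble statistics on token-game trajectories.

A *behaviour* is a qualitative pattern of one place's token timecourse:

- ``activation``: the place reaches an upper token threshold within a time
  window and, when ``hold_to_end`` is set, stays at or above it to the end.
- ``inhibition``: the place falls to a lower threshold (and stays, if
  flagged).
- ``constant``: the place never leaves its level after an equilibration
  offset.
- ``burst``: the place reaches the upper threshold and then returns to the
  lower threshold before the end of the simulation.
- ``custom``: a user predicate over the stepwise timecourse.

Ensembles are summarised as the fraction of trajectories exhibiting a
behaviour with an exact (Clopper-Pearson) 95% binomial confidence interval;
a perturbation is called significant when the two intervals do not overlap.
The exact interval matters because the fractions of interest are frequently
0 or 1, where Wald-style intervals degenerate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy import stats

from .petri import ActivityTable, Edge, Place, Transition
from .simulate import Ensemble, QsspnModel, SimulationConfig, Trajectory, run_ensemble

log = logging.getLogger(__name__)

PATTERNS = ("activation", "inhibition", "constant", "burst", "custom")


@dataclass(frozen=True)
class BehaviourDefinition:
    """Qualitative pattern of one place's token timecourse.

    Defaults follow the worked protocol for a 2-token qualitative model:
    upper threshold 2 ("reached maximum (two tokens)"), lower threshold 0,
    window the whole run, and activation holding to the end ("remained at
    maximum until the end").
    """

    place: str
    pattern: str
    upper: int = 2
    lower: int = 0
    window: tuple[float, float] = (0.0, float("inf"))
    hold_to_end: bool = True
    equilibration: float = 0.0
    predicate: Callable[[np.ndarray, np.ndarray], bool] | None = None
    name: str = ""

    @property
    def label(self) -> str:
        return self.name or f"{self.place}:{self.pattern}"


@dataclass(frozen=True)
class BehaviourFraction:
    behaviour: BehaviourDefinition
    n_trajectories: int
    n_positive: int
    fraction: float
    ci95: tuple[float, float]


@dataclass
class KnockoutMatrix:
    """Gene x behaviour matrix of behaviour fractions with significance vs WT.

    ``rows`` maps row label ("WT" or a gene place id) to a dict of behaviour
    label -> BehaviourFraction (None where the simulation failed);
    ``significant`` flags cells whose 95% CI does not overlap the WT cell's.
    """

    behaviours: tuple[BehaviourDefinition, ...]
    rows: dict[str, dict[str, "BehaviourFraction | None"]] = field(default_factory=dict)
    significant: dict[str, dict[str, bool]] = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        records = []
        for row, cells in self.rows.items():
            for label, bf in cells.items():
                if bf is None:
                    records.append({"row": row, "behaviour": label, "fraction": np.nan,
                                    "ci_low": np.nan, "ci_high": np.nan, "significant": False})
                else:
                    records.append({"row": row, "behaviour": label, "fraction": bf.fraction,
                                    "ci_low": bf.ci95[0], "ci_high": bf.ci95[1],
                                    "significant": self.significant.get(row, {}).get(label, False)})
        return pd.DataFrame.from_records(records)

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def detect(trajectory: Trajectory, behaviour: BehaviourDefinition) -> bool:
    """Decide whether one trajectory exhibits the behaviour."""
    if behaviour.pattern not in PATTERNS:
        raise ValueError(f"unknown behaviour pattern {behaviour.pattern!r}")
    times, tokens = trajectory.timecourse(behaviour.place)
    if behaviour.pattern == "custom":
        if behaviour.predicate is None:
            raise ValueError("custom behaviour needs a predicate")
        return bool(behaviour.predicate(times, tokens))
    w0, w1 = behaviour.window
    in_window = (times >= w0) & (times <= w1)
    if behaviour.pattern == "activation":
        hits = np.nonzero(in_window & (tokens >= behaviour.upper))[0]
        if hits.size == 0:
            return False
        if behaviour.hold_to_end:
            return bool(np.all(tokens[hits[0]:] >= behaviour.upper))
        return True
    if behaviour.pattern == "inhibition":
        hits = np.nonzero(in_window & (tokens <= behaviour.lower))[0]
        if hits.size == 0:
            return False
        if behaviour.hold_to_end:
            return bool(np.all(tokens[hits[0]:] <= behaviour.lower))
        return True
    if behaviour.pattern == "constant":
        after = times >= behaviour.equilibration
        if not np.any(after):
            return True
        ref = tokens[np.nonzero(after)[0][0]]
        return bool(np.all(tokens[after] == ref))
    # burst: reach upper, then return to lower before the end
    up = np.nonzero(in_window & (tokens >= behaviour.upper))[0]
    if up.size == 0:
        return False
    return bool(np.any(tokens[up[0]:] <= behaviour.lower))


def clopper_pearson(n_positive: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial CI from beta quantiles; exact at fractions 0 and 1."""
    if not 0 <= n_positive <= n or n < 1:
        raise ValueError("need 0 <= n_positive <= n, n >= 1")
    low = 0.0 if n_positive == 0 else float(stats.beta.ppf(alpha / 2, n_positive, n - n_positive + 1))
    high = 1.0 if n_positive == n else float(stats.beta.ppf(1 - alpha / 2, n_positive + 1, n - n_positive))
    return low, high


def behaviour_fraction(ensemble: list[Trajectory],
                       behaviour: BehaviourDefinition) -> BehaviourFraction:
    """Fraction of trajectories exhibiting the behaviour, with exact 95% CI."""
    n = len(ensemble)
    if n < 1:
        raise ValueError("empty ensemble")
    k = sum(detect(traj, behaviour) for traj in ensemble)
    return BehaviourFraction(behaviour, n, k, k / n, clopper_pearson(k, n))


def compare(reference: BehaviourFraction, perturbed: BehaviourFraction) -> bool:
    """Significant iff the two 95% CIs do not overlap."""
    return (perturbed.ci95[0] > reference.ci95[1]) or (perturbed.ci95[1] < reference.ci95[0])


# ---------------------------------------------------------------------------
# Perturbation encoding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Perturbation:
    """One model edit.

    kinds:
      ``force_level``         — set the place to ``level`` and delete every
                                transition consuming from it; with ``level``
                                equal to the capacity the place is constant.
      ``sirna_knockdown``     — add an siRNA place inhibiting the named
                                translation transition plus an extra mRNA
                                degradation transition at rate ``sirna_rate``.
      ``permanent_activation``— force the place to its capacity (alias of
                                force_level at capacity).
      ``gene_deletion``       — set the place's tokens to 0 (knock-out
                                encoding: the inactive gene carries no token).
    """

    kind: str
    place: str
    level: int | None = None
    translation: str | None = None
    mrna: str | None = None
    sirna_rate: float = 1000.0


def encode_perturbation(model: QsspnModel, perturbation: Perturbation) -> QsspnModel:
    """Return a perturbed copy of the model; the input is untouched."""
    net = model.net.copy()
    if perturbation.place not in net.places:
        raise KeyError(f"unknown place {perturbation.place!r}")
    pert = perturbation
    if pert.kind in ("force_level", "permanent_activation"):
        place = net.places[pert.place]
        level = pert.level
        if level is None or pert.kind == "permanent_activation":
            if place.capacity is None:
                raise ValueError(f"cannot force unbounded place {pert.place!r} to its maximum")
            level = place.capacity
        place.tokens = level
        doomed = [t.id for t in net.transitions.values()
                  if any(e.kind == "standard" and e.place == pert.place for e in t.pre)]
        for tid in doomed:
            del net.transitions[tid]
        log.info("forced %s to %d; removed consuming transitions %s", pert.place, level, doomed)
    elif pert.kind == "sirna_knockdown":
        if pert.translation is None or pert.translation not in net.transitions:
            raise KeyError(f"unknown translation transition {pert.translation!r}")
        mrna = pert.mrna or pert.place
        if mrna not in net.places:
            raise KeyError(f"unknown mRNA place {mrna!r}")
        sirna_id = f"{pert.place}_siRNA"
        net.add_place(Place(sirna_id, kind="regular", tokens=1, capacity=1))
        trans = net.transitions[pert.translation]
        trans.pre = trans.pre + (Edge(sirna_id, "inhibitor", table=ActivityTable.inhibitor(1)),)
        net.add_transition(Transition(
            f"{mrna}_siRNA_degradation", klass="stochastic", rate=pert.sirna_rate,
            pre=(Edge(mrna, "standard", table=ActivityTable.step(1)),
                 Edge(sirna_id, "read", table=ActivityTable.step(1))),
            post=()))
    elif pert.kind == "gene_deletion":
        net.places[pert.place].tokens = 0
    else:
        raise ValueError(f"unknown perturbation kind {pert.kind!r}")
    return replace_net(model, net)


def replace_net(model: QsspnModel, net) -> QsspnModel:
    return QsspnModel(net=net, metabolism=model.metabolism,
                      constraints=model.constraints, objectives=model.objectives)


def knockout_screen(model: QsspnModel, genes: list[str],
                    behaviours: list[BehaviourDefinition],
                    config: SimulationConfig, n: int = 120) -> KnockoutMatrix:
    """WT plus single-gene-deletion ensembles scored against all behaviours.

    Each gene place must carry at least one token initially; its knockout
    sets that count to 0.  Every row runs ``n`` trajectories from the same
    master seed, so the WT row of a screen with no genes is exactly the WT
    ensemble.  Cells whose simulation failed are recorded as missing.
    """
    for g in genes:
        if g not in model.net.places:
            raise KeyError(f"unknown gene place {g!r}")
        if model.net.places[g].tokens < 1:
            raise ValueError(f"gene place {g!r} carries no token in the initial state")
    matrix = KnockoutMatrix(tuple(behaviours))
    wt_fracs = _screen_row(model, behaviours, config, n)
    matrix.rows["WT"] = wt_fracs
    matrix.significant["WT"] = {b.label: False for b in behaviours}
    for gene in genes:
        perturbed = encode_perturbation(model, Perturbation("gene_deletion", gene))
        try:
            fracs = _screen_row(perturbed, behaviours, config, n)
        except Exception as exc:  # noqa: BLE001 - record the hole, keep screening
            log.error("knockout of %s failed: %s", gene, exc)
            fracs = {b.label: None for b in behaviours}
        matrix.rows[gene] = fracs
        matrix.significant[gene] = {
            b.label: (fracs[b.label] is not None and wt_fracs[b.label] is not None
                      and compare(wt_fracs[b.label], fracs[b.label]))
            for b in behaviours}
    return matrix


def _screen_row(model: QsspnModel, behaviours: list[BehaviourDefinition],
                config: SimulationConfig, n: int) -> dict[str, BehaviourFraction]:
    ensemble = run_ensemble(model, config, n)
    if not ensemble:
        raise RuntimeError("all trajectories failed")
    return {b.label: behaviour_fraction(ensemble, b) for b in behaviours}
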