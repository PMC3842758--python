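"""Hybrid quasi-steady-state trajectory generator.

One iteration of the simulator interleaves four kinds of work:

1. *Immediate settlement* — every immediate transition with positive
   propensity fires (in uniformly random order among those enabled) until the
   net is quiescent.  Immediates consume no simulated time.
2. *Coupling refresh* — constraint places whose token count changed are
   translated into flux-bound overrides via their lookup tables; if any bound
   changed, every objective coupling is re-evaluated by FBA and the objective
   places' token counts are set from their value->tokens lookup tables.
   Because objective updates can enable immediates (and vice versa), steps 1
   and 2 alternate until a joint fixed point.
3. *Stochastic sampling* — the waiting time to the next stochastic firing is
   exponential in the total propensity and the transition is chosen with
   probability proportional to its own propensity (Gillespie).  Waiting times
   are re-drawn after every state change, the safe choice for a hybrid
   propensity that may move under the sampled transition mid-wait.
4. *Continuous update* — time advances by at most the configured maximal
   timestep; each continuous transition moves ``floor`` of its accumulated
   ``propensity * dt`` tokens, with the fractional remainder carried across
   steps so slow flows are not silently dropped.

Delayed stochastic transitions are selected like ordinary ones but their
state update (consumption and production alike) happens ``delay`` time units
after selection; a delayed firing whose transition is disabled when the delay
expires is skipped and logged.

The metabolic part is treated as quasi-steady state: FBA re-evaluation is
triggered only by constraint-place changes, and results are cached per
distinct bound-override map.
"""

from __future__ import annotations

import hashlib
import heapq
import json
import logging
import math
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

from .fba import FbaError, FluxObjective, MetabolicModel, maximize
from .petri import (NetState, PetriNet, Transition, fire, is_enabled,
                    transition_propensity, validate_net)

log = logging.getLogger(__name__)


class LivelockError(RuntimeError):
    """Immediate-transition settlement exceeded its iteration cap."""

    def __init__(self, transitions: list[str], cap: int) -> None:
        self.transitions = transitions
        super().__init__(
            f"immediate transitions did not quiesce within {cap} firings; "
            f"cycling transitions: {sorted(set(transitions[-20:]))}")


@dataclass(frozen=True)
class ConstraintCoupling:
    """Maps a constraint place's token count to flux-bound overrides.

    ``rows`` is an ordered tuple of ``(token threshold, {reaction id: (lower,
    upper)})`` with strictly increasing thresholds starting at 0; the row with
    the largest threshold not exceeding the token count applies.
    """

    place: str
    rows: tuple[tuple[int, dict[str, tuple[float, float]]], ...]

    def lookup(self, tokens: int) -> dict[str, tuple[float, float]]:
        idx = bisect_right([t for t, _ in self.rows], tokens) - 1
        if idx < 0:
            raise ValueError(f"constraint coupling on {self.place!r} has no row for {tokens} tokens")
        return self.rows[idx][1]


@dataclass(frozen=True)
class ObjectiveCoupling:
    """Maps an FBA objective value to an objective place's token count.

    ``rows`` is an ordered tuple of ``(objective-value threshold, tokens)``
    with strictly increasing thresholds; the row with the largest threshold
    not exceeding the value applies.  An infeasible LP is read as objective
    value 0; an unbounded one as +inf.
    """

    place: str
    objective: FluxObjective
    rows: tuple[tuple[float, int], ...]

    def lookup(self, value: float) -> int:
        idx = bisect_right([t for t, _ in self.rows], value) - 1
        if idx < 0:
            return 0
        return self.rows[idx][1]


@dataclass
class QsspnModel:
    """Complete runtime model: dynamic net + metabolic part + couplings."""

    net: PetriNet
    metabolism: MetabolicModel | None = None
    constraints: tuple[ConstraintCoupling, ...] = ()
    objectives: tuple[ObjectiveCoupling, ...] = ()

    def validate(self) -> list[str]:
        violations = validate_net(self.net)
        for c in self.constraints:
            if c.place not in self.net.places:
                violations.append(f"constraint coupling references unknown place {c.place!r}")
            elif self.net.places[c.place].kind != "constraint":
                violations.append(f"constraint coupling place {c.place!r} is not typed 'constraint'")
            thresholds = [t for t, _ in c.rows]
            if not thresholds or thresholds[0] != 0:
                violations.append(f"constraint coupling on {c.place!r}: first threshold must be 0")
            if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
                violations.append(f"constraint coupling on {c.place!r}: thresholds not increasing")
            if self.metabolism is not None:
                for _, overrides in c.rows:
                    for rid in overrides:
                        if rid not in self.metabolism.reactions:
                            violations.append(
                                f"constraint coupling on {c.place!r}: unknown reaction {rid!r}")
        for o in self.objectives:
            if o.place not in self.net.places:
                violations.append(f"objective coupling references unknown place {o.place!r}")
            elif self.net.places[o.place].kind != "objective":
                violations.append(f"objective coupling place {o.place!r} is not typed 'objective'")
            thresholds = [t for t, _ in o.rows]
            if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
                violations.append(f"objective coupling on {o.place!r}: thresholds not increasing")
            cap = self.net.places[o.place].capacity if o.place in self.net.places else None
            if cap is not None and any(tok > cap for _, tok in o.rows):
                violations.append(f"objective coupling on {o.place!r}: token value exceeds capacity")
            if self.metabolism is not None:
                for rid in o.objective.coefficients:
                    if rid not in self.metabolism.reactions:
                        violations.append(f"objective coupling on {o.place!r}: unknown reaction {rid!r}")
        if (self.constraints or self.objectives) and self.metabolism is None:
            violations.append("couplings declared but no metabolic model attached")
        return violations

    def hash(self) -> str:
        """Stable digest of the model's semantic content.

        Numbers are normalised to float so that semantically identical models
        built in memory or read from disk hash identically.
        """
        def tbl(table):
            return None if table is None else [[int(t), float(a)] for t, a in table.entries]

        payload = {
            "places": sorted((p.id, p.kind, p.tokens, p.capacity) for p in self.net.places.values()),
            "transitions": sorted(
                (t.id, t.klass, float(t.rate), float(t.delay),
                 [(e.place, e.kind, e.weight, tbl(e.table)) for e in t.pre],
                 [(e.place, e.kind, e.weight, tbl(e.table)) for e in t.post])
                for t in self.net.transitions.values()),
            "reactions": sorted(
                (r.id, sorted((m, float(c)) for m, c in r.stoichiometry.items()),
                 float(r.lower), float(r.upper))
                for r in self.metabolism.reactions.values()) if self.metabolism else None,
            "constraints": sorted(
                (c.place, [(int(t), sorted((rid, [float(b[0]), float(b[1])])
                                           for rid, b in m.items())) for t, m in c.rows])
                for c in self.constraints),
            "objectives": sorted(
                (o.place, sorted((rid, float(v)) for rid, v in o.objective.coefficients.items()),
                 [[float(t), int(tok)] for t, tok in o.rows])
                for o in self.objectives),
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class SimulationConfig:
    t_max: float = 20.0
    max_timestep: float = 1.0
    seed: int = 0
    record_mode: str = "events"  # events | fixed-grid (grid derived on export)
    fba_cache: bool = True
    max_immediate_iterations: int = 100_000

    def __post_init__(self) -> None:
        if self.t_max <= 0:
            raise ValueError("t_max must be positive")
        if self.max_timestep <= 0:
            raise ValueError("max_timestep must be positive")


@dataclass
class Trajectory:
    """Time-ordered record of one token game.

    ``events`` holds ``(time, place, tokens-after-change, source)`` tuples;
    ``source`` tags provenance: ``immediate``, ``stochastic``, ``delayed``,
    ``continuous`` or ``coupling``.  Together with ``initial_state`` the full
    marking is reconstructable at any time.
    """

    initial_state: dict[str, int]
    events: list[tuple[float, str, int, str]] = field(default_factory=list)
    t_end: float = 0.0
    metadata: dict = field(default_factory=dict)

    def timecourse(self, place: str) -> tuple[np.ndarray, np.ndarray]:
        """Stepwise (times, tokens) for one place, starting at t=0."""
        times = [0.0]
        tokens = [self.initial_state[place]]
        for t, p, n, _src in self.events:
            if p == place:
                times.append(t)
                tokens.append(n)
        return np.asarray(times), np.asarray(tokens)

    def state_at(self, t: float) -> dict[str, int]:
        state = dict(self.initial_state)
        for et, p, n, _src in self.events:
            if et > t:
                break
            state[p] = n
        return state

    @property
    def final_state(self) -> dict[str, int]:
        return self.state_at(self.t_end)

    def to_tsv(self, path: str) -> None:
        """Tab-separated event log; metadata in a sidecar ``.json`` file."""
        with open(path, "w") as fh:
            fh.write("time\tplace\ttokens\tsource\n")
            for p, n in sorted(self.initial_state.items()):
                fh.write(f"0\t{p}\t{n}\tinit\n")
            for t, p, n, src in self.events:
                fh.write(f"{t:.9g}\t{p}\t{n}\t{src}\n")
        with open(path + ".json", "w") as fh:
            json.dump(self.metadata | {"t_end": self.t_end}, fh, indent=2, sort_keys=True)

    def to_grid(self, dt: float):
        """Fixed-grid matrix (pandas DataFrame, time x places) for plotting."""
        import pandas as pd

        grid = np.arange(0.0, self.t_end + dt / 2, dt)
        places = sorted(self.initial_state)
        data = np.empty((len(grid), len(places)), dtype=int)
        state = dict(self.initial_state)
        idx = 0
        for gi, gt in enumerate(grid):
            while idx < len(self.events) and self.events[idx][0] <= gt:
                _, p, n, _src = self.events[idx]
                state[p] = n
                idx += 1
            data[gi] = [state[p] for p in places]
        return pd.DataFrame(data, index=grid, columns=places)


class Ensemble(list):
    """List of trajectories; per-trajectory failures land in ``errors``."""

    def __init__(self, trajectories=(), errors: dict[int, Exception] | None = None) -> None:
        super().__init__(trajectories)
        self.errors: dict[int, Exception] = errors or {}


class _CouplingState:
    """Tracks constraint snapshots, the active override map and the FBA cache."""

    def __init__(self, model: QsspnModel, use_cache: bool) -> None:
        self.model = model
        self.use_cache = use_cache
        self.last_tokens: dict[str, int] | None = None
        self.overrides: dict[str, tuple[float, float]] = {}
        self.cache: dict[tuple, dict[str, int]] = {}
        self.fba_calls = 0

    def refresh(self, state: NetState) -> list[tuple[str, int]]:
        """Update objective places if constraint places moved; return changes."""
        model = self.model
        if model.metabolism is None or not model.objectives:
            return []
        tokens = {c.place: state.tokens[c.place] for c in model.constraints}
        if self.last_tokens is not None and tokens == self.last_tokens:
            return self._apply(state, None)
        self.last_tokens = tokens
        overrides: dict[str, tuple[float, float]] = {}
        for c in model.constraints:
            overrides.update(c.lookup(tokens[c.place]))
        if overrides == self.overrides and self.cache:
            return self._apply(state, None)
        self.overrides = overrides
        key = tuple(sorted(overrides.items()))
        if self.use_cache and key in self.cache:
            return self._apply(state, self.cache[key])
        targets: dict[str, int] = {}
        for o in model.objectives:
            result = maximize(model.metabolism, o.objective, overrides)
            self.fba_calls += 1
            if result.status == "infeasible":
                log.warning("infeasible LP for objective place %s; reading value as 0", o.place)
            targets[o.place] = o.lookup(result.value_or(0.0))
        if self.use_cache:
            self.cache[key] = targets
        return self._apply(state, targets)

    def _apply(self, state: NetState, targets: dict[str, int] | None) -> list[tuple[str, int]]:
        if targets is None:
            key = tuple(sorted(self.overrides.items()))
            targets = self.cache.get(key)
            if targets is None:
                return []
        changes = []
        for place, value in targets.items():
            if state.tokens[place] != value:
                state.tokens[place] = value
                changes.append((place, value))
        return changes


class Simulator:
    """Generates token-game trajectories for a :class:`QsspnModel`."""

    def __init__(self, model: QsspnModel, config: SimulationConfig,
                 rng: np.random.Generator | None = None) -> None:
        self.model = model
        self.config = config
        self.rng = rng if rng is not None else np.random.default_rng(config.seed)
        self._immediates = model.net.transitions_of_klass("immediate")
        self._stochastics = model.net.transitions_of_klass("stochastic")
        self._continuous = model.net.transitions_of_klass("continuous")
        self.couplings = _CouplingState(model, config.fba_cache)

    # -- stage primitives ---------------------------------------------------

    def settle_immediate(self, state: NetState,
                         record: list[tuple[float, str, int, str]] | None = None) -> NetState:
        """Fire enabled immediates in uniform-random order until quiescent."""
        cap = self.config.max_immediate_iterations
        fired: list[str] = []
        for _ in range(cap):
            enabled = [t for t in self._immediates if is_enabled(state, t)]
            if not enabled:
                return state
            t = enabled[self.rng.integers(len(enabled))] if len(enabled) > 1 else enabled[0]
            before = dict(state.tokens)
            state = fire(state, t, self.model.net)
            fired.append(t.id)
            if record is not None:
                for pid, n in state.tokens.items():
                    if n != before[pid]:
                        record.append((state.time, pid, n, "immediate"))
        raise LivelockError(fired, cap)

    def sample_stochastic_event(self, state: NetState) -> tuple[Transition | None, float]:
        """Gillespie draw: (transition, waiting time), or (None, inf)."""
        props = np.array([transition_propensity(state, t) for t in self._stochastics])
        # a positive propensity without substrate cannot fire; mask it out
        for i, t in enumerate(self._stochastics):
            if props[i] > 0 and not is_enabled(state, t):
                props[i] = 0.0
        total = props.sum()
        if total <= 0.0:
            return None, math.inf
        wait = self.rng.exponential(1.0 / total)
        choice = self.rng.choice(len(self._stochastics), p=props / total)
        return self._stochastics[choice], wait

    def apply_continuous(self, state: NetState, dt: float,
                         accumulators: dict[str, float],
                         record: list[tuple[float, str, int, str]] | None = None) -> NetState:
        """Advance continuous transitions over ``dt`` with fractional carry."""
        if dt < 0:
            raise ValueError("dt must be non-negative")
        for t in self._continuous:
            p = transition_propensity(state, t)
            acc = accumulators.get(t.id, 0.0) + p * dt
            move = int(math.floor(acc))
            if move >= 1:
                # clamp by available substrate on standard pre-edges
                for edge in t.pre:
                    if edge.kind == "standard":
                        move = min(move, state.tokens[edge.place] // edge.weight)
                if move >= 1 and is_enabled(state, t, move):
                    before = dict(state.tokens)
                    state = fire(state, t, self.model.net, multiplicity=move)
                    acc -= move
                    if record is not None:
                        for pid, n in state.tokens.items():
                            if n != before[pid]:
                                record.append((state.time, pid, n, "continuous"))
                elif move >= 1:
                    acc -= move  # enabled check failed (e.g. zero propensity); drop
            accumulators[t.id] = acc
        return state

    def refresh_couplings(self, state: NetState,
                          record: list[tuple[float, str, int, str]] | None = None) -> NetState:
        changes = self.couplings.refresh(state)
        if record is not None:
            for place, value in changes:
                record.append((state.time, place, value, "coupling"))
        return state

    def _settle_and_couple(self, state: NetState,
                           record: list[tuple[float, str, int, str]]) -> NetState:
        """Alternate immediate settlement and coupling refresh to a fixed point."""
        for _ in range(self.config.max_immediate_iterations):
            state = self.settle_immediate(state, record)
            before = dict(state.tokens)
            state = self.refresh_couplings(state, record)
            if state.tokens == before:
                return state
        raise LivelockError(["<coupling/immediate alternation>"], self.config.max_immediate_iterations)

    # -- main loop ----------------------------------------------------------

    def run(self, initial: NetState | None = None) -> Trajectory:
        cfg = self.config
        state = (initial.copy() if initial is not None else self.model.net.initial_state())
        state.time = 0.0
        record: list[tuple[float, str, int, str]] = []
        traj = Trajectory(dict(state.tokens), record, metadata={
            "seed": cfg.seed, "t_max": cfg.t_max, "max_timestep": cfg.max_timestep,
            "model_hash": self.model.hash(),
        })
        accumulators: dict[str, float] = {}
        pending: list[tuple[float, int, str]] = []  # (fire time, seq, transition id)
        seq = 0
        has_continuous = bool(self._continuous)
        while state.time < cfg.t_max:
            state = self._settle_and_couple(state, record)
            trans, wait = self.sample_stochastic_event(state)
            t_stoch = state.time + wait
            t_pend = pending[0][0] if pending else math.inf
            t_event = min(t_stoch, t_pend)
            if has_continuous:
                t_new = min(t_event, state.time + cfg.max_timestep, cfg.t_max)
            else:
                t_new = min(t_event, cfg.t_max)
            if not math.isfinite(t_new):
                raise RuntimeError("non-finite simulation time")
            dt = t_new - state.time
            state.time = t_new
            if has_continuous and dt > 0:
                state = self.apply_continuous(state, dt, accumulators, record)
            if t_new >= cfg.t_max:
                break
            if pending and t_new >= pending[0][0] and t_pend <= t_stoch:
                _, _, tid = heapq.heappop(pending)
                t = self.model.net.transitions[tid]
                if is_enabled(state, t):
                    before = dict(state.tokens)
                    state = fire(state, t, self.model.net)
                    for pid, n in state.tokens.items():
                        if n != before[pid]:
                            record.append((state.time, pid, n, "delayed"))
                else:
                    log.info("delayed firing of %s skipped: disabled at due time", tid)
            elif trans is not None and t_new >= t_stoch:
                if trans.delay > 0:
                    heapq.heappush(pending, (state.time + trans.delay, seq, trans.id))
                    seq += 1
                elif is_enabled(state, trans):
                    before = dict(state.tokens)
                    state = fire(state, trans, self.model.net)
                    for pid, n in state.tokens.items():
                        if n != before[pid]:
                            record.append((state.time, pid, n, "stochastic"))
            # otherwise the maximal timestep elapsed: loop and re-draw
        traj.t_end = cfg.t_max
        traj.metadata["fba_calls"] = self.couplings.fba_calls
        return traj


def simulate(model: QsspnModel, config: SimulationConfig,
             initial: NetState | None = None) -> Trajectory:
    """Generate one token-game trajectory.

    Identical model, config and seed give a bitwise-identical trajectory.
    """
    violations = model.validate()
    if violations:
        raise ValueError("invalid model: " + "; ".join(violations))
    return Simulator(model, config).run(initial)


def trajectory_seeds(master_seed: int, n: int) -> list[np.random.SeedSequence]:
    """Per-trajectory seed streams spawned from the master seed."""
    return np.random.SeedSequence(master_seed).spawn(n)


def run_ensemble(model: QsspnModel, config: SimulationConfig, n_trajectories: int,
                 initial: NetState | None = None) -> Ensemble:
    """Run ``n_trajectories`` independent trajectories.

    Per-trajectory RNG streams are spawned from the master seed, so the
    ensemble is reproducible and order-independent; failures are collected in
    ``Ensemble.errors`` rather than aborting the sample.
    """
    if n_trajectories < 1:
        raise ValueError("need at least one trajectory")
    violations = model.validate()
    if violations:
        raise ValueError("invalid model: " + "; ".join(violations))
    ensemble = Ensemble()
    for i, seed_seq in enumerate(trajectory_seeds(config.seed, n_trajectories)):
        rng = np.random.default_rng(seed_seq)
        try:
            traj = Simulator(model, config, rng).run(initial)
            traj.metadata["trajectory_index"] = i
            ensemble.append(traj)
        except Exception as exc:  # noqa: BLE001 - contract: collect, don't abort
            log.error("trajectory %d failed: %s", i, exc)
            ensemble.errors[i] = exc
    return ensemble
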