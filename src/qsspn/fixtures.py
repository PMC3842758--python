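"""Bundled, download-free models.

The centrepiece is a qualitative single-gene expression model coupled to a
miniature metabolic network: a gene whose protein product is an enzyme
opening the synthesis route of a small-molecule agonist; the agonist in turn
displaces the transcription factor from the gene's binding site, closing a
negative feedback loop that produces oscillatory qualitative trajectories.
Transcription and translation are immediate (complex formation is rate
limiting), with inhibitory rules capping transcript and protein at two
tokens — two tokens represent the functional steady-state level.

Also provided: the toy metabolic network itself (a 12-reaction stand-in for
a genome-scale hepatocyte reconstruction with the same producibility
semantics), a birth-death net with known stationary mean for simulator
calibration, a pathological two-immediate livelock net, and a seeded random
model generator for property tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fba import FluxObjective, MetabolicModel, Metabolite, Reaction, PRODUCIBILITY_THRESHOLD
from .io import QsspnDocument
from .petri import ActivityTable, Edge, PetriNet, Place, Transition
from .simulate import ConstraintCoupling, ObjectiveCoupling, QsspnModel, SimulationConfig


@dataclass(frozen=True)
class GeneExpressionParams:
    """Tunable knobs of the gene-expression fixture.

    Rates are relative (1/a.u.): transcriptionally active complex formation
    is fast (100), dissociation of the stable transcription-factor-site
    complex slow (10), degradations 1.  ``mrna_max``/``protein_max`` are the
    functional activity levels (2 tokens).  ``include_agonist_coupling=False``
    ablates the negative feedback: the agonist objective place then never
    turns on and transcription runs indefinitely.
    """

    complex_formation_rate: float = 100.0
    dissociation_rate: float = 10.0
    degradation_rate: float = 1.0
    mrna_max: int = 2
    protein_max: int = 2
    producibility_threshold: float = PRODUCIBILITY_THRESHOLD
    include_agonist_coupling: bool = True
    t_max: float = 30.0


def build_toy_metabolism() -> MetabolicModel:
    """12-reaction metabolic network with enzyme-gated agonist synthesis.

    Cholesterol-like substrate enters and is converted to a bile-acid-like
    agonist by an enzyme reaction (``cyp_enzyme``) that is closed by default
    and opened by the Protein constraint place.  Nucleotide and amino-acid
    drains (the dNTPs / AAs objectives) are producible regardless of the
    enzyme; the agonist drain is producible iff the enzyme bound is open.
    """
    mets = [
        Metabolite("chol_ext", external=True), Metabolite("chol"),
        Metabolite("bile"), Metabolite("bile_ext", external=True),
        Metabolite("chol_out_ext", external=True),
        Metabolite("glc_ext", external=True), Metabolite("glc"), Metabolite("atp"),
        Metabolite("nuc_ext", external=True), Metabolite("nuc_pre"), Metabolite("dntp"),
        Metabolite("dntp_ext", external=True),
        Metabolite("aa_ext", external=True), Metabolite("aa_pre"), Metabolite("aa"),
        Metabolite("aa_sink_ext", external=True),
    ]
    rxns = [
        Reaction("chol_in", {"chol_ext": -1, "chol": 1}, 0, 10),
        Reaction("cyp_enzyme", {"chol": -1, "bile": 1}, 0, 0),  # opened by constraint place
        Reaction("bile_out", {"bile": -1, "bile_ext": 1}, 0, 10),
        Reaction("chol_efflux", {"chol": -1, "chol_out_ext": 1}, 0, 1),
        Reaction("glc_in", {"glc_ext": -1, "glc": 1}, 0, 10),
        Reaction("glycolysis", {"glc": -1, "atp": 1}, 0, 10),
        Reaction("nuc_in", {"nuc_ext": -1, "nuc_pre": 1}, 0, 10),
        Reaction("dntp_syn", {"nuc_pre": -1, "atp": -1, "dntp": 1}, 0, 10),
        Reaction("dntp_drain", {"dntp": -1, "dntp_ext": 1}, 0, 10),
        Reaction("aa_in", {"aa_ext": -1, "aa_pre": 1}, 0, 10),
        Reaction("aa_syn", {"aa_pre": -1, "atp": -1, "aa": 1}, 0, 10),
        Reaction("aa_drain", {"aa": -1, "aa_sink_ext": 1}, 0, 10),
    ]
    return MetabolicModel(mets, rxns)


def build_gene_expression_fixture(params: GeneExpressionParams | None = None) -> QsspnDocument:
    """The bundled single-gene negative-feedback fixture.

    Expected qualitative behaviour of a single trajectory: mRNA rises to its
    maximum, then Protein; the agonist objective turns on, transcription
    stops, mRNA decays to 0 before Protein does, and once the enzyme level
    has fallen the agonist turns off and the cycle restarts (oscillation).
    The mRNA timecourse is a burst each cycle.
    """
    p = params or GeneExpressionParams()
    inhib1 = ActivityTable.inhibitor(1)
    on1 = ActivityTable.step(1)
    net = PetriNet(
        places=[
            Place("Gene", "gene present in genome", "regular", 1, 1),
            Place("TF", "transcription factor", "regular", 1, 1),
            Place("BS_free", "free binding site", "regular", 1, 1),
            Place("BS_bound", "TF-bound binding site", "regular", 0, 1),
            Place("Active_Gene", "assembled transcription initiation complex", "regular", 0, 1),
            Place("mRNA", "transcript activity level", "regular", 0, p.mrna_max),
            Place("Protein", "protein activity level; gates the enzyme reaction",
                  "constraint", 0, p.protein_max),
            Place("dNTPs", "nucleotide precursor producibility", "objective", 0, 1),
            Place("AAs", "amino-acid precursor producibility", "objective", 0, 1),
            Place("agonist", "agonist metabolite producibility", "objective", 0, 1),
        ],
        transitions=[
            # TF binds the free site when the agonist is absent
            Transition("tf_binding", "immediate", 1.0, pre=(
                Edge("BS_free", "standard"), Edge("TF", "read", table=on1),
                Edge("agonist", "inhibitor", table=inhib1)),
                post=(Edge("BS_bound"),)),
            # slow dissociation of the stable TF-site complex
            Transition("tf_dissociation", "stochastic", p.dissociation_rate, pre=(
                Edge("BS_bound", "standard"),), post=(Edge("BS_free"),)),
            # the agonist displaces the TF from the site
            Transition("agonist_displacement", "immediate", 1.0, pre=(
                Edge("BS_bound", "standard"), Edge("agonist", "read", table=on1)),
                post=(Edge("BS_free"),)),
            # rate-limiting assembly of the transcriptionally active complex
            Transition("complex_formation", "stochastic", p.complex_formation_rate, pre=(
                Edge("Gene", "read", table=on1), Edge("BS_bound", "read", table=on1),
                Edge("Active_Gene", "inhibitor", table=inhib1)),
                post=(Edge("Active_Gene"),)),
            # agonist-driven disassembly of the active complex
            Transition("complex_decay", "immediate", 1.0, pre=(
                Edge("Active_Gene", "standard"), Edge("BS_bound", "inhibitor", table=inhib1),
                Edge("agonist", "read", table=on1)),
                post=()),
            # immediate transcription, stopped by the mRNA-max inhibitory rule
            Transition("transcription", "immediate", 1.0, pre=(
                Edge("Active_Gene", "read", table=on1), Edge("dNTPs", "read", table=on1),
                Edge("mRNA", "inhibitor", table=ActivityTable.inhibitor(p.mrna_max))),
                post=(Edge("mRNA"),)),
            # no net mRNA degradation while transcription is possible
            Transition("mrna_degradation", "stochastic", p.degradation_rate, pre=(
                Edge("mRNA", "standard", table=on1),
                Edge("Active_Gene", "inhibitor", table=inhib1)),
                post=()),
            # net degradation when precursors run out despite an active gene
            Transition("mrna_degradation_starved", "stochastic", p.degradation_rate, pre=(
                Edge("mRNA", "standard", table=on1),
                Edge("dNTPs", "inhibitor", table=inhib1)),
                post=()),
            # immediate translation of the full-level transcript
            Transition("translation", "immediate", 1.0, pre=(
                Edge("mRNA", "read", table=ActivityTable.step(p.mrna_max)),
                Edge("AAs", "read", table=on1),
                Edge("Protein", "inhibitor", table=ActivityTable.inhibitor(p.protein_max))),
                post=(Edge("Protein"),)),
            # no net protein degradation while any transcript remains
            Transition("protein_degradation", "stochastic", p.degradation_rate, pre=(
                Edge("Protein", "standard", table=on1),
                Edge("mRNA", "inhibitor", table=inhib1)),
                post=()),
            Transition("protein_degradation_starved", "stochastic", p.degradation_rate, pre=(
                Edge("Protein", "standard", table=on1),
                Edge("AAs", "inhibitor", table=inhib1)),
                post=()),
        ])
    thr = p.producibility_threshold
    objectives = [
        ObjectiveCoupling("dNTPs", FluxObjective({"dntp_drain": 1.0}), ((0.0, 0), (thr, 1))),
        ObjectiveCoupling("AAs", FluxObjective({"aa_drain": 1.0}), ((0.0, 0), (thr, 1))),
    ]
    if p.include_agonist_coupling:
        objectives.append(
            ObjectiveCoupling("agonist", FluxObjective({"bile_out": 1.0}), ((0.0, 0), (thr, 1))))
    model = QsspnModel(
        net=net,
        metabolism=build_toy_metabolism(),
        constraints=(ConstraintCoupling("Protein", (
            (0, {"cyp_enzyme": (0.0, 0.0)}),
            (1, {"cyp_enzyme": (0.0, 1000.0)}))),),
        objectives=tuple(objectives))
    return QsspnDocument(model=model, config=SimulationConfig(t_max=p.t_max),
                         description="single-gene negative-feedback fixture with toy metabolism")


def build_birth_death(birth_rate: float = 5.0, death_rate: float = 1.0,
                      capacity: int = 50, t_max: float = 200.0) -> QsspnDocument:
    """Pure birth-death process: stationary token mean is birth/death.

    Birth has no pre-places (constant propensity); death is proportional to
    the token count via a linear activity table, so the stationary law is
    Poisson(birth/death) up to the (generous) capacity truncation.
    """
    net = PetriNet(
        places=[Place("X", "population", "regular", 0, capacity)],
        transitions=[
            Transition("birth", "stochastic", birth_rate, post=(Edge("X"),)),
            Transition("death", "stochastic", death_rate,
                       pre=(Edge("X", "standard", table=ActivityTable.linear(capacity)),),
                       post=()),
        ])
    return QsspnDocument(model=QsspnModel(net=net),
                         config=SimulationConfig(t_max=t_max),
                         description="birth-death calibration net")


def build_immediate_livelock() -> QsspnModel:
    """Two immediates shuttling one token back and forth: never quiescent."""
    net = PetriNet(
        places=[Place("A", tokens=1, capacity=1), Place("B", tokens=0, capacity=1)],
        transitions=[
            Transition("a_to_b", "immediate", pre=(Edge("A", "standard"),), post=(Edge("B"),)),
            Transition("b_to_a", "immediate", pre=(Edge("B", "standard"),), post=(Edge("A"),)),
        ])
    return QsspnModel(net=net)


@dataclass(frozen=True)
class RandomModelParams:
    n_places: int = 6
    n_transitions: int = 6
    max_capacity: int = 5
    max_pre_edges: int = 3
    max_post_edges: int = 2
    max_table_entries: int = 4
    klass_weights: tuple[float, float, float] = (0.6, 0.2, 0.2)  # stochastic/immediate/continuous


def random_model(params: RandomModelParams | None = None, seed: int = 0) -> QsspnDocument:
    """Seeded random valid net (no metabolic part) for property-based tests.

    The same seed always yields an identical document; generated activity
    tables always start at threshold 0 with strictly increasing thresholds.
    """
    p = params or RandomModelParams()
    rng = np.random.default_rng(seed)
    places = []
    for i in range(p.n_places):
        cap = int(rng.integers(1, p.max_capacity + 1))
        places.append(Place(f"p{i}", kind="regular",
                            tokens=int(rng.integers(0, cap + 1)), capacity=cap))
    net = PetriNet(places=places)

    def random_table(inhibitory: bool) -> ActivityTable:
        n_entries = int(rng.integers(1, p.max_table_entries + 1))
        thresholds = [0] + sorted(rng.choice(np.arange(1, p.max_capacity + 2),
                                             size=n_entries - 1, replace=False).tolist())
        activities = np.round(rng.uniform(0.0, 2.0, size=n_entries), 3).tolist()
        if inhibitory:  # positive below a cut-off, 0 at and above it
            activities = [a + 0.001 for a in activities[:-1]] + [0.0]
        return ActivityTable(tuple(zip(thresholds, activities)))

    klasses = np.array(["stochastic", "immediate", "continuous"])
    for i in range(p.n_transitions):
        klass = str(rng.choice(klasses, p=np.asarray(p.klass_weights)))
        n_pre = int(rng.integers(0, p.max_pre_edges + 1))
        n_post = int(rng.integers(0, p.max_post_edges + 1))
        pre = []
        for pid in rng.choice(p.n_places, size=n_pre, replace=False):
            kind = str(rng.choice(["standard", "read", "inhibitor"], p=[0.5, 0.3, 0.2]))
            pre.append(Edge(f"p{pid}", kind,
                            weight=int(rng.integers(1, 3)) if kind == "standard" else 1,
                            table=random_table(kind == "inhibitor")))
        post = [Edge(f"p{pid}", "standard", weight=int(rng.integers(1, 3)))
                for pid in rng.choice(p.n_places, size=n_post, replace=False)]
        net.add_transition(Transition(
            f"t{i}", klass, rate=float(np.round(rng.uniform(0.1, 10.0), 3)),
            delay=float(np.round(rng.uniform(0.0, 1.0), 3))
            if klass == "stochastic" and rng.random() < 0.2 else 0.0,
            pre=tuple(pre), post=tuple(post)))
    return QsspnDocument(model=QsspnModel(net=net),
                         config=SimulationConfig(t_max=5.0, seed=seed),
                         description=f"random net (seed {seed})")
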