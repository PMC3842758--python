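# qsspn

Hybrid simulation of qualitative molecular-interaction networks that couple
gene regulation and signalling to whole-cell metabolism.

## The problem

Genome-scale metabolic reconstructions can be interrogated mechanistically
with constraint-based methods, but their steady-state assumption rules out
transient behaviours — bursts, oscillations, homeostatic responses — that
arise from the *regulatory* layer. Conversely, quantitative dynamic models of
regulation need rate constants and molecule numbers that are rarely measured
for human cell systems. This package implements a quasi-steady-state Petri
net (QSSPN) simulator for exactly this gap: the regulatory and signalling
layer is an extended Petri net whose tokens are discrete activity levels, the
metabolic layer is a stoichiometric model analysed by flux balance analysis
(FBA), and the two are coupled through two special classes of places.

It is aimed at systems biologists who have a qualitative reconstruction
(which interactions exist, which thresholds matter) and qualitative
timecourse data (qRT-PCR, western blots) rather than kinetic parameters.

## The model

**Dynamic part.** Places carry integer token counts `x_i` (discrete activity
levels) with optional capacities. A transition `t` with rate constant `c_t`
has propensity

```
P_t = c_t · Π_i μ_i(x_i)
```

where each pre-place contributes a piecewise-constant activity `μ_i` read
from a lookup table of thresholds `t_1 < t_2 < …` and activities `a_1, a_2,
…` (the entry with the largest threshold ≤ `x_i` applies). Substrates use
standard edges (tokens consumed), catalysts read edges (required, not
consumed), and inhibitors are tables that drop to 0 at a cut-off, so the
propensity stays a pure product. Transitions come in three classes:

- **stochastic** — sampled with the Gillespie algorithm (waiting time
  exponential in the total propensity), optionally with a fixed firing delay;
- **immediate** — fire in zero time whenever their propensity is positive;
- **continuous** — move `⌊∫ P_t dt⌋` tokens per step with a fractional-carry
  accumulator, bounded by a maximal timestep.

**Metabolic part.** A stoichiometric model `S` with flux bounds
`l ≤ v ≤ u`; FBA maximises a linear flux objective `cᵀv` subject to
`S·v = 0` over internal metabolites (HiGHS LP, deterministic).

**Coupling.** *Constraint places* translate their token count into flux-bound
overrides through a lookup table (e.g. enzyme protein absent ⇒ reaction
closed). *Objective places* get their token count from the value of an FBA
objective through a value→tokens table (e.g. metabolite producibility above
10⁻³ ⇒ one token). Metabolism is treated as quasi-steady state: FBA is
re-evaluated only when a constraint place changes, with results cached per
distinct bound-override map.

**Statistics.** Repeated simulation from the same initial marking yields a
Monte Carlo sample of *token game* trajectories. Trajectories are scored
against qualitative behaviour patterns (activation, inhibition, constant,
burst, custom predicates); the fraction exhibiting a behaviour carries an
exact Clopper–Pearson 95% binomial CI, and a perturbation (gene deletion,
siRNA knock-down, forced activation) is called significant when its CI does
not overlap the reference's. A single-gene knockout screen assembles these
calls into a gene × behaviour matrix.

## Worked example

The bundled fixture (`qsspn/data/gene_expression.json`, also available as
`qsspn.fixtures.build_gene_expression_fixture()`) is a single-gene
negative-feedback loop: the gene's protein product is an enzyme that opens
the synthesis route of a small-molecule agonist in a 12-reaction toy
metabolic network; the agonist displaces the transcription factor from the
gene's binding site and shuts transcription down.

```python
from qsspn import read_document, simulate, run_ensemble, SimulationConfig
from qsspn.analysis import BehaviourDefinition, behaviour_fraction
from importlib.resources import files

doc = read_document(str(files("qsspn").joinpath("data/gene_expression.json")))
traj = simulate(doc.model, SimulationConfig(t_max=30.0, seed=1))
for t, place, tokens, source in traj.events[:13]:
    print(f"{t:8.4f}  {place:12s} -> {tokens}  [{source}]")
```

```
  0.0000  BS_free      -> 0  [immediate]
  0.0000  BS_bound     -> 1  [immediate]
  0.0000  dNTPs        -> 1  [coupling]
  0.0000  AAs          -> 1  [coupling]
  0.0098  Active_Gene  -> 1  [stochastic]
  0.0098  mRNA         -> 1  [immediate]
  0.0098  mRNA         -> 2  [immediate]
  0.0098  Protein      -> 1  [immediate]
  0.0098  Protein      -> 2  [immediate]
  0.0098  agonist      -> 1  [coupling]
  0.0098  BS_free      -> 1  [immediate]
  0.0098  BS_bound     -> 0  [immediate]
  0.0098  Active_Gene  -> 0  [immediate]
```

Reading the log: the transcription factor binds its site and the precursor
objective places (dNTPs, AAs) come up producible; the transcriptionally
active complex forms (rate 100/a.u., the rate-limiting step); immediate
transcription and translation raise transcript then protein to their
two-token functional levels; the protein opens the enzyme bound, the agonist
objective crosses its 10⁻³ producibility threshold, and the agonist evicts
the transcription factor — transcription stops. The transcript then decays
to zero (rate 1/a.u.) before the protein, the agonist turns off, and the
cycle restarts: a qualitative oscillation.

```python
sample = run_ensemble(doc.model, SimulationConfig(t_max=30.0, seed=1), 120)
for pattern in ("burst", "activation"):
    bf = behaviour_fraction(sample, BehaviourDefinition("mRNA", pattern))
    print(f"mRNA {pattern:10s}: {bf.n_positive:3d}/120 = {bf.fraction:.3f}  "
          f"95% CI [{bf.ci95[0]:.3f}, {bf.ci95[1]:.3f}]")
```

```
mRNA burst     : 120/120 = 1.000  95% CI [0.970, 1.000]
mRNA activation:   0/120 = 0.000  95% CI [0.000, 0.030]
```

Every trajectory shows the transcript burst (rise to maximum, return to
zero); none shows sustained activation — the negative feedback always
closes. Deleting the gene (`qsspn.analysis.knockout_screen`) drives the
"mRNA reaches 2" fraction from 1.0 to 0.0 with non-overlapping CIs.

The same operations are available from the shell:

```bash
qsspn validate src/qsspn/data/gene_expression.json
qsspn simulate  src/qsspn/data/gene_expression.json --seed 1 -o traj.tsv
qsspn ensemble  src/qsspn/data/gene_expression.json --n 120 --seed 1 -o runs/
qsspn fba       src/qsspn/data/gene_expression.json --objective bile_out
qsspn knockout  src/qsspn/data/gene_expression.json --genes all \
                --behaviours behaviours.json --n 120 -o screen/
```

`qsspn fba` prints `{"objective_value": 0.0, "status": "optimal"}` for the
agonist drain — the enzyme reaction is closed while the protein is absent.

## File formats

Models are single JSON documents (places, transitions with typed edges and
activity tables, couplings, inline or referenced metabolic model, default
configuration); see `src/qsspn/data/gene_expression.json` for a complete
example. Metabolic models may also be tabular reaction lists, one reaction
per line — `id<TAB>A + 2 B -> C<TAB>lower<TAB>upper` — with `#` comments;
metabolites suffixed `_ext` (or listed on a `# external:` header) are
external and exempt from the steady-state constraint. Trajectories export as
TSV event logs with JSON sidecars; screens as TSV matrices.

## Further reading

`docs/methods.md` documents the simulation loop, its numerical choices, the
fixture design and known limitations.
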