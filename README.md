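# degradograph

Degradation graphs for single-snapshot peptidomics: model sequential
proteolysis of a protein as a probabilistic DAG, infer it from observed
peptide abundances, and quantify the proteolytic activity that conventional
peptide summation misses.

Peptidomics and degradomics experiments quantify thousands of endogenous
peptides, but standard analyses treat each peptide as the endpoint of a
single cleavage.  In reality peptides are intermediates: they are produced
by upstream cleavage and consumed by downstream trimming, so summing
abundances systematically underestimates upstream protease activity.  This
package is for computational proteomics researchers who want to analyze
peptide quantification tables (from any search engine, as flat TSV/CSV)
mechanistically rather than as isolated intensities.

## The model

A degradation graph is a DAG G = (V, E) whose nodes are peptides of one
parent protein (plus a root Ω for the intact protein, each node an interval
on the sequence) and whose edges (u → v) are cleavage events with
transition probabilities w(u→v).  Each node keeps the remainder as an
absorption probability,

    w(v→v) = 1 − Σ_{u ∈ C(v)} w(v→u),

so injecting unit mass at Ω yields a marginal distribution **P** over
peptides — the model's prediction of the observed peptidome **Y**.  Two
inference backends recover the graph from a snapshot:

* **Gradient descent** on a softmax parameterization of the weights,
  minimizing Σ_v (P(v) − Y(v))² with closed-form gradients
  ∂**P**/∂w(i→j) = P(Ω→i)·**P**(·|j).
* **Linear programming** over per-edge flows F(u→v) ≥ 0 under unit root
  injection and mass conservation, converted back by
  w(u→v) = F(u→v)/ΣF(x→u).

From a fitted graph the total proteolytic activity is the total edge flow,
and the underestimation ratio

    Δ = Σ_E F(u→v) / Σ_{v≠Ω} Y(v)  (≥ 1)

measures how much abundance summation underestimates it.  The package also
includes an event-based endo/exoproteolysis simulator with regex enzyme
rules (ground truth for validation) and a numpy GraphConv classifier that
recognizes protease-specific degradation patterns from graph structure.
See `docs/methods.md` for the full model description and design choices.

## Worked example

Three overlapping peptides of a toy 21-residue protein, intensities from
one sample:

```python
import math
import degradograph as dg

protein = dg.ProteinRecord("toy", "MDDDIAALVVKRDDAIAALVV")
raw = {"DDDIAALVV": 1000.0, "DDDIA": 400.0, "AALVV": 800.0}

# log-normalize onto the simplex and place peptides on the protein
obs = {}
for pep, intensity in raw.items():
    s = protein.sequence.find(pep)
    obs[(s, s + len(pep))] = math.log(intensity)
total = sum(obs.values())
obs = {k: v / total for k, v in obs.items()}

graph = dg.build_graph(obs, protein)
result = dg.fit(graph, graph.observed(),
                dg.FitConfig(learning_rate=0.1, epochs=8000, seed=7))
print(f"final loss: {result.final_loss:.2e}")
print(f"delta = {dg.underestimation_ratio(result.graph):.3f}")
inflow = dg.node_inflow(result.graph)
for n in graph.nodes:
    print(f"{n.sequence:21s} Y={n.observed_abundance:.3f} inflow={inflow[n.id]:.3f}")
```

prints

```
final loss: 1.14e-07
delta = 1.038
MDDDIAALVVKRDDAIAALVV Y=0.000 inflow=1.000
DDDIAALVV             Y=0.353 inflow=0.391
DDDIA                 Y=0.306 inflow=0.306
AALVV                 Y=0.341 inflow=0.341
```

The fit reproduces the observed distribution (loss ≈ 1e-7).  `DDDIAALVV`
contains both shorter peptides, and the fitted graph routes a little of its
mass onward to them: its inflow (0.391) exceeds its observed abundance
(0.353), and Δ = 1.038 says total cleavage activity is ~4% higher than the
plain abundance sum.  On deeply degraded peptidomes this gap grows to
several-fold — the simulator's `delta_vs_extent` reproduces that trend.

The same pipeline is available from the shell:

```sh
degradograph ingest --fasta protein.fasta --table peptides.tsv \
    --protein-id toy --sample s1 --out graph.json
degradograph fit-gd --graph graph.json --seed 7 --out fitted.json
degradograph quantify --fitted fitted.json --out report.json
```

plus `fit-lp`, `simulate`, `compare` (group fold-change profiles) and
`classify-train`.

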