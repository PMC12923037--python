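# Methods

## The degradation-graph model

Proteolysis of one parent protein is modeled as a directed acyclic graph
G = (V, E).  Nodes are peptides, each identified by its 0-based half-open
interval [start, end) on the protein; a root node Ω spans the whole
sequence.  A directed edge (u → v) means peptide u can be cleaved into
peptide v, and exists only when v's interval is a *proper* sub-interval of
u's — this containment constraint is what guarantees acyclicity.  Each edge
carries a transition probability w(u→v); whatever a node does not pass on
it keeps:

    w(v→v) = 1 − Σ_{u ∈ children(v)} w(v→u),

the node's absorption (stability) probability.  Self-loops are stored as a
per-node scalar, not as edges, so the edge list stays a DAG.

Injecting unit mass at Ω and propagating it in topological order yields the
marginal peptide distribution **P**: P(v) is the probability that a
degradation pathway terminates at v.  Because there are no cycles, all mass
is eventually absorbed and Σ P(v) = 1 for any valid weight assignment.
Three equivalent computations are implemented and cross-checked in the test
suite: the forward pass, a parent-sum recursion
P(v) = Σ_u P(u)/w(u→u) · w(u→v) · w(v→v) (with an explicit
reach-probability fallback when some absorption is exactly zero, where the
ratio form is undefined), and exhaustive path enumeration on small graphs.

The marginal is multilinear in the raw weights, which gives closed-form
gradients: ∂**P**/∂w(i→j) = reach(i) · **P**(·|j) for an edge, and
1_i · reach(i) for an absorption weight, where reach(i) is the cumulative
probability of arriving at i from Ω and **P**(·|j) the distribution obtained
by injecting mass at j.  These match central finite differences to first
order exactly (the test tolerance of 1e-6 is limited only by floating-point
cancellation in the differences).

## Graph construction from an observed peptidome

Observed peptides become nodes; the default "full containment" policy adds
an edge for every proper interval containment (including Ω → v for every
v), the optional "transitive reduction" policy keeps only containments with
no intermediate observed node.  Both are exposed because the edge set is
not identified by the data and the choice trades parameter count against
expressiveness.  Any peptide contained in no other peptide is connected
directly to Ω so mass can reach it.  The topological order is the sort by
(start, −length, end): a proper container starts no later and is strictly
longer at equal start, so this order is topological and deterministic.

Duplicate peptide placements default to the leftmost occurrence
(deterministic); an option splits intensity equally across occurrences.
Intensities are natural-log transformed (configurable base, or disabled),
missing/zero values are imputed at the q = 0.01 quantile of the observed
log-intensities, and the vector is rescaled to sum to one over non-root
nodes.  Each sample yields its own distribution and its own fitted graph;
an averaging mode across samples exists for homogeneous in-vitro digests.

## Inference

**Gradient descent.**  Each node with children carries a logit vector
(one entry per child plus one absorption entry) mapped through a softmax,
so any parameter setting is a valid stochastic assignment and no weight can
reach exactly zero.  The fit minimizes the squared error
Σ_v (P(v) − Y(v))² plus optional L1/L2 penalties on the logits (both 0 by
default).  Gradients use the closed form above, computed in one reverse
(adjoint) sweep over the DAG rather than per edge; edges are grouped by the
topological level of their source so both sweeps are vectorized.  Defaults:
Adam, learning rate 0.01, 2000 epochs, uniform initialization (θ = 0), early
stop when the best loss has not improved by 1e-10 for 50 epochs, and the
best-loss iterate is returned (adaptive optimizers oscillate near
convergence, so the early stop watches the best iterate, not the raw
trajectory).  The observed entry for Ω defaults to 0 — intact protein is
rarely quantified in peptidomics — leaving the root absorption free; its
slow decay toward zero is the main convergence tail, so analyses that need
tight agreement with the LP route (see tests) run a longer schedule
(lr 0.1, up to 20000 epochs).

**Linear programming.**  Equivalently, one non-negative flow variable per
edge under unit root injection (Σ F(Ω→v) = 1) and conservation at every
non-root node (incoming = observed + outgoing).  The system silently
requires the observation to sum to one over non-root nodes; it is rescaled,
with a logged warning, if it does not.  The default objective min Σ F makes
the solution deterministic up to LP degeneracy (flagged as potentially
non-unique); bare feasibility is available.  Solved with HiGHS through
scipy; feasibility is re-checked post hoc at 1e-8 and violating solutions
rejected.  Flows convert to probabilities by w(u→v) = F(u→v)/M(u) with M(u)
the incoming mass (1 at the root); M(u) = 0 nodes get all-zero outgoing
weights and absorption 1.  The forward pass of the converted graph
reproduces the observation to solver precision — the key cross-backend
equivalence, asserted in the acceptance suite at 1e-6.

Both routes fit the same observation but the weights themselves are
underdetermined (different graphs can generate the same marginal); only the
marginals are expected to agree (1e-3 in the cross-backend test).

## Flow quantification

Summing peptide abundances counts each peptide once even when it was both
produced and further degraded.  The total proteolytic activity is instead
the total edge flow, and the underestimation ratio

    Δ = Σ_E F(u→v) / Σ_{v≠Ω} Y(v)

quantifies the bias of abundance summation; Δ ≥ 1 always, with equality
only when every observed peptide is a direct child of Ω.  For a
weight-parameterized fit, flows are F(u→v) = reach(u) · w(u→v) — the unique
definition consistent with the forward model.  Derived summaries: per-node
inflow (= absorbed + outgoing mass, by conservation), per-residue backbone
profiles (each position accumulates the inflow of the peptides covering
it), group log2 fold-changes of mean profiles with an ε = 1e-9 pseudocount,
bottleneck ranking by outflow/(abundance + ε) with ties broken by node id,
and branch partitions assigning each node to the Ω-child subtree carrying
the largest share of its inflow (ties to the lower id; a first-ancestor
rule is available).  "Highest inflow share" is our concretization of
branches as peptide sets sharing degradation ancestry.

## Proteolysis simulator

The simulator emits ground truth for validation: starting from Ω holding
one abundance unit per target peptide, events are drawn until the pool
holds the target number of distinct peptides.  Each event is
endoproteolytic with probability `endo_probability` (default 0.7),
otherwise exoproteolytic:

* endo — substrate drawn ∝ length × abundance; first cut uniform over the
  enzyme's regex-defined sites (positional preferences are pluggable but
  uniform by default, since no empirical preference function is
  established); second cut over the remaining sites weighted by a Gamma
  distribution of the inter-cut distance (shape 2, scale 5 residues —
  roughly the size of well-detected peptides); up to three fragments tile
  the substrate exactly (two when the cuts coincide or only one site
  exists).
* exo — substrate drawn ∝ abundance; one residue removed from a uniformly
  chosen terminus.

Each event moves one unit from the substrate, split equally among its
fragments, so pool mass is conserved; the per-edge moved mass normalized by
each node's arrived mass defines the ground-truth transition weights.
Fragments shorter than 4 residues are kept but flagged (real peptidomics
rarely detects them).  A detection filter removes each observed peptide
independently with a configurable dropout probability and renormalizes,
modeling both rapid biological re-degradation and technical detection
limits.  Everything is reproducible from a single seed, and the event log
replays to the final pool state.

Enzyme rules are zero-width regexes over residue context.  Trypsin defaults
to the canonical "cleave C-terminal to K/R unless followed by P"
(`(?<=[KR])(?!P)`); a literal variant requiring the following proline is
selectable for comparison with cut-pattern notations that invert the
proline rule.  Elastase uses the common A/V/S/G/L/I C-terminal definition.
Custom rules load from JSON.

What the simulator does **not** emulate: ionization-efficiency bias on
intensities, kinetic rates or explicit time, enzyme mixtures within one
run, and missed identification correlated with peptide properties (dropout
is independent per peptide).  Tests passing on simulated data therefore
demonstrate correctness of the inference machinery under the model's own
assumptions, not robustness to every real-data artifact.

## Replicate stability and the fitting schedule used for it

Because the problem is underdetermined, fitted weights vary across random
initializations (N(0, 0.1) logits).  The stability analysis fits five
replicates and reports the mean per-edge coefficient of variation (sample
std / mean) plus the overlap of the top-k edges ranked by flow.  These runs
use plain gradient descent run to convergence (lr 10 on the logit scale,
8000 epochs) rather than Adam: adaptive optimizers take
gradient-normalized steps that keep wandering along the flat solution
manifold after the loss has converged, inflating replicate spread without
improving fit, whereas plain-GD steps vanish with the gradient and each
replicate settles at the manifold point nearest its initialization.  On
tryptic digests of the beta-actin-sized benchmark protein the mean CV stays
in single digits up to graphs of ~380 edges while the top-flow edges are
recovered consistently (see `scripts/acceptance.py`).

## Classifier

Each graph becomes one sample with node features
x_v = [abundance, start/L, end/L, length/L] and the transition weights on
directed parent→child edges (reverse edges optional, off by default; the
root is included with abundance 0).  The model is a two-layer GraphConv
(separate linear transforms for the node itself and its weighted in-neighbor
aggregate), hidden width 64, dropout 0.2 after the first layer, global mean
pooling and a linear log-softmax head, trained with negative log-likelihood
under Adam (lr 0.005, weight decay 1e-4) for 50 epochs with a seeded
stratified 80/20 split.  Forward and backward passes are written in numpy
(the backward pass is verified against finite differences in the tests), so
training is exactly reproducible from the seed.  Mean pooling plus
neighborhood aggregation make predictions invariant to node reordering,
asserted as a property test.

The demonstration task digests four synthetic benchmark proteins (random
sequences at human-like amino-acid frequencies, lengths 375/147/622/267,
labelled synthetic) with trypsin or elastase.  Digestion depth matters: the
protease signature expressible in these features is the relationship
between fragment sizes/positions and the enzyme's site spacing (~9 residues
between tryptic sites versus ~2–3 for elastase), which only emerges once
degradation is deep enough that fragments approach the enzyme-defined limit
lengths.  The benchmark therefore simulates 100 peptides per graph
(25 graphs per protein × enzyme, 200 total); at shallow digestion
(tens of peptides from a 375-residue protein) graphs of the two enzymes are
nearly indistinguishable in these features and any classifier hovers near
chance.

## Numerical choices

* Probability-sum invariants asserted at 1e-9; LP conservation at 1e-8;
  stochastic-weight validation tolerates 1e-6 accumulated rounding.
* Softmax logits are shifted by the per-node maximum before exponentiation.
* Zero-absorption nodes: reach probabilities are tracked explicitly wherever
  the P(u)/w(u→u) ratio could divide by zero.
* Ties: bottlenecks and branch assignment break ties by node id; the
  topological sort key is fully deterministic.
* Degenerate inputs raise early with the offending peptide or node named:
  peptides outside the protein span, observations with root mass or zero
  total, all-dropped detection filters, single-class training sets.

## Known limitations

* Weight identifiability: only marginals (and flow totals under the chosen
  objective) are comparable across methods; individual edge weights are not
  unique and should be interpreted through the stability analysis.
* The min-flow LP objective biases flows toward shortest routes; Δ from an
  LP fit is a lower bound among feasible flow decompositions.
* One graph per (protein, sample); no cross-protein graphs, splicing or
  ligation events.
* The simulator's event-count clock is not physical time; Δ-versus-extent
  trends are qualitative, not kinetic.
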