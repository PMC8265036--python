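# Methods

## Fibers as balanced colorings

A fiber is a class of genes with isomorphic input trees. We compute the
fiber partition as the coarsest balanced coloring of the signed digraph:
starting from a single color, nodes are repeatedly regrouped by the pair
(current color, multiset of (in-neighbour color, edge sign)) until the
class count stabilises. The class count is non-decreasing and the loop
terminates within |V| iterations; edge signs (activation, repression,
dual) are part of the input alphabet, so an activation and a repression
from same-fiber sources are different inputs. Out-degree plays no role:
fibrations are input-driven. Fiber ids are assigned by first occurrence in
ascending node order, so identical inputs always give identical output.

**Source separation.** Strongly connected components with no input from
the rest of the network — isolated genes, input-less genes, and closed
feedback components — admit synchronous solutions with any other such
component, but only for fine-tuned initial conditions; we follow the
convention that distinct no-input source components occupy distinct
fibers. This is enforced *after* refinement: any class mixing nodes of two
or more source components is split per component (downstream nodes caught
in such a class are put in their own sub-class), the partition is
re-refined to restore balance, and the step repeats to a fixed point.
Enforcing the rule by pre-seeding unique colors would be wrong: it would
permanently separate an autorepressor from its targets (the tryptophan
circuit would lose its 3-gene fiber), because a self-loop gene is itself a
source component yet genuinely shares its fiber with downstream genes.
The tie-break leans toward separation: in the rare case that a downstream
gene mimics a source component's input tree exactly, it is not merged
back. Every returned partition is checked balanced post-hoc.

**Oracle.** An independent route computes, for every node, an interned
canonical form of its depth-|V| input tree (bottom-up multiset hashing on
the graph, equivalent to explicit unfolding without the exponential
blow-up) and partitions nodes by equal forms, applying the same source
separation afterwards. Finite depth |V| suffices: equitable-partition
refinement stabilises within |V|−1 rounds. The test suite checks exact
agreement of the two routes on 200 random signed digraphs.

## Fiber numbers |n, ℓ⟩

A fiber's building block is the fiber F plus its external regulators R
(nodes outside F with an edge into F), the edges targeting F, and the
edges of any strongly connected component over F ∪ R containing a member
of F (feedback through the network's SCC, as in Fibonacci fibers).

- **ℓ** is |R|, the number of distinct external regulator nodes.
- **n** is the limiting ratio a_d/a_{d−1} of successive input-tree layer
  sizes of a fiber member, computed on the block restricted to nodes that
  lie on directed cycles reaching F. Acyclic regulators would add a
  constant per layer and mask the growth rate, so they are excluded from
  the growth computation (they only set ℓ). If the restricted tree is
  finite, n = 0. Layer sizes are exact integer path counts (no explicit
  tree is built), the default evaluation depth is 50, and values within
  1e−6 of an integer are snapped. A single loop gives n = 1, two parallel
  signed loops give n = 2 (binary tree), and a two-gene feedback loop
  gives the golden ratio φ = 1.6180… (layer sizes follow a Fibonacci
  recursion; successive ratios at depths 20–50 agree to < 1e−6). n counts
  loops *inside* the fiber: a gene regulated by a looped TF without
  sharing its fiber is still a regulon (n = 0).

Classes follow the numbers: regulon (n = 0), ar-loop (1,0), fff (1,1),
binary-tree (n = 2), fibonacci (non-integer n), other. A block whose
regulator belongs to a multi-gene fiber is a multilayer composite,
labelled with both blocks' numbers, e.g. `|0,1>(+)|1,1>`; detection is one
level deep with deeper chains nested (bounded recursion).

## Admissible dynamics

The simulator instantiates admissibility with Hill kinetics:

    dx_i/dt = −γ_i x_i + β_i · Π_e H_e(x_src)

with H = x^h/(K^h + x^h) for activation, its complement for repression,
and their average (identically 1/2) for dual edges; input-less genes are
constitutive (dx/dt = −γx + β). Defaults γ = 1 (1/time), β = 2
(conc./time), K = 1 (conc.), h = 2, so constitutive genes settle at
β/γ = 2, twice the Hill threshold. Since the equations respect the input
structure, fiber synchrony is guaranteed by theory regardless of this
particular choice; with identical within-fiber parameters the within-fiber
gap obeys d(x_i−x_j)/dt = −γ(x_i−x_j) and decays exponentially, which the
tests verify to 1e−6 at horizon. Parameter mismatch is one knob ε: each
gene's K is multiplied by exp(ε·u), u ~ N(0,1) (seeded), producing the
"almost synchronized" regime; only monotonicity of the median gap in ε is
asserted (grid 0–0.4), not magnitudes. Integration uses an adaptive
explicit Runge–Kutta method (scipy RK45, rtol 1e−8, atol 1e−10); any
integrator meeting the tolerance is acceptable.

## Synthetic studies

`plant_fibered_grn` inverts the fibration: draw a random signed base
digraph (one node kept input-less), break accidental symmetries by adding
distinguishing in-edges until the base colors all-singleton, then lift
selected nodes into fibers of requested sizes, giving every copy the same
(source-representative, sign) in-edge set. The planted partition is
balanced by construction and generation retries with a derived seed until
coloring recovers it exactly — in practice the repair makes this the first
attempt.

`synth_expression` emulates the structure of curated wild-type expression
compendia: per condition each fiber (singletons included) is independently
active with probability `active_fraction`; in active conditions members
take the steady state of the reduced single-input Hill map
(β/γ)·r^h/(K_g^h + r^h) under a condition-specific drive r ~ U(1, 3)
shared within the fiber, with gene-specific K_g = exp(ε·u_g); Gaussian
noise (sd `noise_sd`) is added everywhere and inactive entries are noise
only. Defaults: T = 200 conditions, active_fraction = 0.3,
noise_sd = 0.2, ε = 0.1. Every multi-gene fiber is guaranteed ≥ 2 active
conditions (skipped in the degenerate all-noise case active_fraction = 0).

**Scale.** The default study plants fibers of sizes 2–6 in a 250-node
base at density 0.008 (mean in-degree ≈ 2, like sparse bacterial GRNs), so
~7% of genes sit inside planted fibers — matching the minority share
fibers occupy in real compendia (in *E. coli*, fibers cover roughly 7% of
4096 genes). The proportion matters statistically: the random-set null
must be dominated by background genes, as it is in real data. If fiber
genes dominated the pool, the null would be a heavy mixture (random sets
catching same-fiber pairs) and the normal-tail significance test would be
miscalibrated. Matrix sizes here (hundreds of genes, 200 conditions) are
deliberate desk-scale stand-ins for compendium-scale data.

**What the generator does not emulate:** cross-platform batch structure,
heteroscedastic measurement error, operon-level reporting of individual
genes, correlated activation of functionally related fibers, and graded
(non-binary) activity levels. Passing tests show the statistics behave as
designed under the generative model, not that real compendia satisfy that
model.

## Coexpression statistics

All moments use the population (1/T) convention — most libraries default
to 1/(T−1); the correlation itself is convention-free but the ICV and null
sd are not. A fiber's score is the mean off-diagonal entry of its Pearson
matrix; zero-variance genes yield missing entries which are excluded with
the pair count reduced, and a fiber whose score is undefined is dropped
with a count in the output.

**ICV filtering.** For a gene set, ICV_t = μ_t/σ_t per condition;
conditions strictly above the mean finite ICV are "active". σ_t = 0 gives
ICV = +∞, always selected, with a warning. ICV is invariant under
multiplying the matrix by a positive constant but *not* under additive
shifts (μ_t changes, σ_t does not) — both properties are tested.
Selection by ICV itself induces correlation (for 2-gene sets the null mean
approaches 1), which is exactly why significance is judged against a null
filtered the same way.

**Null and significance.** The null draws `n_samples` random gene sets
(without replacement within a set) from *all* genes in the matrix,
scores each like a fiber, and takes the sample mean and population sd.
For the m observed fibers of a size, Z = (μ_real − μ_m)/(σ/√m) with a
one-sided upper-tail normal p (the hypothesis is a correlation increase);
the significance flag is p < 0.05, i.e. the 1.65σ band. p values are
reported in scientific notation, not floored to 0. The null is recomputed
independently per size and filtering mode; no multiple-testing correction
is applied across sizes (noted in the output metadata). Cross-fiber
correlations use the union of the two fibers' selected conditions. The
functional network thresholds off-diagonal correlations strictly at
C(i,j) > 0.6.

**Known limitation.** The normal-tail p assumes the null of mean
correlations is normal; this holds well when fibered genes are a small
minority of the pool (the compendium-like regime above — shuffle-based
type-I rates land within binomial bounds of 5%), but the test over-rejects
when strongly synchronized fibers dominate the gene pool, since the null
then becomes a skewed mixture. Empirical nulls would be calibrated in that
regime at higher cost.

## Numerical and interface choices

- Node ids are case-sensitive strings; same-sign duplicate edges are
  deduplicated on load with a warning; opposite-sign parallel edges are
  kept (distinct input types).
- Operon collapsing keeps the first TF (member order) fused with the
  operon node; remaining TFs split off keeping their regulatory out-edges;
  incoming edges of a split TF are re-targeted to both the operon node and
  the split TF (configurable, `incoming_to_split_tfs`).
- The sigma-factor list is user-supplied, never hard-coded.
- Input-tree ratio depth 50 and the 1e−6 integer snap are configurable
  defaults; `fiber_numbers` refuses depth < 5 (unreliable ratio).
- Explicit input-tree materialisation refuses above 2,000,000 vertices;
  layer sizes are always available exactly via path counting.
- The base graph is a simple signed digraph: duplicate same-sign base
  edges arising from multiple same-fiber sources are merged.
- All randomness flows through integer seeds (numpy Generator /
  SeedSequence); identical seeds reproduce networks, trajectories, and
  matrices bit-for-bit.
- Test problem sizes (6–12-node ODE networks, 200-condition matrices,
  10,000-sample nulls) are the package's chosen desk-scale defaults; the
  statistics scale unchanged to larger inputs.
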