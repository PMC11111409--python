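# Methods

This note documents the models implemented in `divconflict`, the defaults
and why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical conventions that matter when comparing results
across implementations.

## Conventions

Ages are Myr before present (0 = present, root = maximum depth). Branch age
spans and time slices are half-open, `[younger, older)`: a branch whose
child node lies exactly on a slice's older bound does not cross that slice,
so adjacent slices never double count. Tips within `1e-6` Myr of the present
are extant (the tolerance absorbs floating-point drift in simulated
ultrametric trees and is a parameter of `compute_node_ages`). Newick
serialization orders children lexicographically by their smallest descendant
tip label, so topologically equal trees serialize identically; support
values are carried but never interpreted (no collapsing — that belongs to
tree inference, which is out of scope here). Gene-tree polytomies simply
yield fewer bipartitions; no resolution is imputed.

## Birth–death species-tree simulation

`simulate_bd_tree` runs a forward-time birth–death process with
piecewise-constant rates from a single origin lineage, using interval-wise
thinning of an exponential clock (exact for piecewise-constant rates), and
rejects whole replicates until exactly `n_extant` lineages survive. The
returned tree is rooted at the first speciation event. Conditioning by
rejection rather than by generalized sampling approaches is exact and cheap
at the 100-tip scale used here (acceptance probability is a fraction of a
percent; a replicate costs a few hundred events).

The experiment presets place rate shifts at 6 and 2 Ma: `experiment1`
(λ = 0.75/0.075/0.75 Myr⁻¹, μ = 0), `experiment2` (λ = 0.75 throughout,
μ = 0/0.675/0, same net rates), `experiment2-no-present-recovery`
(extinction stays at 0.675 through the present, isolating the pull of the
present), and `high-ne` (experiment1 with Nₑ = 50,000). The origin age
defaults to 10 Ma: the presets fix the shift times but not the origin, and
a 10-Ma origin puts the expected extant count (≈ e⁴·⁸ ≈ 120) just above the
100-tip target, which keeps rejection sampling efficient while leaving a
substantial pre-shift era.

## Multispecies coalescent

`simulate_msc_gene_trees` samples one haploid lineage per extant species
and coalesces pairs at rate `g/(2·Nₑ)` per Myr within each species-tree
branch (censored at the branch top; lineages surviving above the root
coalesce freely). `Nₑ` is the haploid-equivalent effective size — the
`2·Nₑ`-generations pairwise rate is the declared convention — and `g`
(generations per Myr) defaults to 10,000, under which Nₑ = 5,000 makes one
Myr of branch one coalescent unit, an intermediate-ILS regime. The
simulator is validated against the analytic three-taxon law: the
probability that a gene tree lacks the species grouping across an internal
branch of T coalescent units is (2/3)e^(−T).

## Conflict statistics

`per_branch_conflict` classifies every gene tree against every internal
non-root species-tree branch (terminal branches and the root edge carry no
informative bipartition). Two proportions are always computed:

* **strict** (default): (conflicting + uninformative) / n_genes — every
  gene tree that does not display the branch's bipartition counts against
  it;
* **informative-only**: conflicting / (conflicting + congruent) — taxon-poor
  gene trees are removed from the denominator so missing data does not
  masquerade as conflict.

Strict is the default because it is the literal "does not share a congruent
bipartition" reading; both are reported in all outputs. The through-time
series averages the active proportion, unweighted, over the internal
branches crossing each slice (default width 2.5 Myr, anchored at the
present; the oldest slice may be narrower). The conflict–duration
regression uses log₁₀ duration by default because branch durations span
orders of magnitude; the transform is a parameter. Zero variance in either
regression variable returns slope 0, r² 0, p 1.

## Sampling fraction

The estimator asks how many lineages a hypothetical fully sampled tree
would have at each 1-Myr grid age (both endpoints included), given the
observed genus-sampled tree and checklist counts. In an extant-only binary
tree the lineage count at age *t* is `1 + #{internal nodes older than t}`.

Augmentation processes are constant-rate reconstructed birth–death
processes whose net rate solves the expected-growth identity
`E[N(duration)] = n` with one (stem) or two (crown) starting lineages —
parameter-free given the checklist — split by a global turnover ε = μ/λ
(default 0, pure birth; conditioning on the extant count removes most of
the sensitivity to ε). Each subtree is drawn *exactly* from the conditioned
process: its speciation ages are i.i.d. with the standard conditioned-age
density (closed-form inverse CDF; truncated exponential in the pure-birth
case) and each new lineage attaches uniformly among lineages alive at its
age. Exact conditioning replaces a rejection loop on the extant count: for
a genus with m checklist species rejection succeeds with probability of
order 1/m at cost O(m) per attempt, which is intractable for
thousand-species genera, while the conditioned construction is O(m) total
and reproduces the same distribution. It also makes the present-day
fraction equal sampled/checklist exactly in every replicate.

Placement of whole unsampled genera is an exposed policy:

* `conditioned` (default): the origin age is drawn from the family's
  stem-growth process (rate `ln(G)/family-stem-age`, G the checklist genus
  count; the family stem is observed exactly because the family-level
  backbone is completely sampled), and the genus attaches uniformly among
  family lineages alive at that age — on the family stem branch itself when
  the origin predates the sampled family crown, which with sparse genus
  sampling underestimates the true crown.
* `uniform`: a time-proportional uniform point on the family crown-group
  branches. This is the least-informative rule but concentrates origins
  near the present (where most branch length lies) and is measurably
  miscalibrated against ground truth; it is retained for comparison.

Unsampled genera are grafted before the within-genus fill-ins, and the
genus stem ages used for the fill-ins are measured on the partially
augmented tree: an attached unsampled sister genus legitimately shortens a
sampled genus's stem, which in a one-tip-per-genus tree is otherwise biased
old (it reflects the nearest *sampled* relative only).

**Known limitation.** When a sampled genus's entire sister clade is
unsampled, its observed stem can be several-fold older than the true stem
and no estimator that sees only the sampled tree can recover this; the
fill-in species of such genera are then spread over too old an interval.
On ground-truth fixtures this appears as the true curve grazing the upper
replicate band at young ages; across fixture seeds the 5–95% band covers
the truth at ~95% of grid points on average, with occasional fixtures in
the high-80s. Real checklists with clustered unsampled diversity will show
the same behaviour.

## Taxonomy generator

`generate_taxonomy` builds the complete ground-truth world hierarchically:
a family skeleton whose crown is pinned at the root age (default 100 Ma),
genus clades grown from family stems, and species clades from genus stems,
each level a reconstructed pure-birth clade conditioned on its tip count
(i.i.d. truncated-exponential ages, uniform sequential attachment), which
makes genera and families monophyletic by construction. Default shapes are
checklist-like: 10 families, geometric genus counts (mean ≈ 8/family),
geometric species counts (mean ≈ 12.5/genus), genus sampling probability
0.6, one representative tip per sampled genus — a desk-scale miniature of a
vascular-plant checklist (hundreds of thousands of species in ~13,000
genera, roughly sixty percent of genera sampled, one tip per genus). Every
family force-samples at least `min(2, n_genera)` genera so each family
retains a crown group, mirroring complete family-level backbone sampling.
What the generator does **not** emulate: extinction (the complete tree is
extant-only), non-monophyletic genera, taxonomic error in checklist counts,
and rate variation across clades — so passing ground-truth tests shows the
estimator is internally calibrated, not that real checklists satisfy its
assumptions.

## LTT curves and slope heatmaps

Each clade's lineage count starts at 2 at its crown node. Steepness per
5-Myr bin (grid anchored at age 0 so clades align) is the difference of
`ln(count + 1)` between bin edges divided by the bin width; the `+1` guards
the logarithm at low counts and only shifts the lowest-count bins (it is
exposed as `log_offset`). The per-clade slope sequence is smoothed with
Tukey's running median in the plain 3R variant — repeated window-3 medians
with end values copied, iterated to a fixed point — chosen as the simplest
fully specified variant. The bin containing the crown node is omitted (the
0→2 jump would dominate any colour scale) and bins older than the crown are
undefined. On reconstructed pure-birth trees the interior-bin slope
estimates the birth rate, the calibration the test suite checks.

## Episodic birth–death likelihood

Let E(t) be the probability that a lineage alive at age t leaves no sampled
descendant (sampling probability ρ at the present) and Φ(t) the density of
leaving exactly one. With piecewise-constant λ, μ both satisfy standard
backward equations solvable in closed form interval by interval; the
survival probability is stitched continuously at window boundaries, and the
per-interval Φ-ratio has the closed form `e^{−rΔ} r² / (A + B e^{−rΔ})²`
with A = λ(1−E₀), B = λE₀−μ, evaluated in log space so extreme `|r|Δ`
cannot overflow, with a series-safe λ→μ limit. The log-likelihood of the
ranked reconstructed tree, conditioned on the crown age and survival of
both crown lineages, is

    ln L = ln (n−1)! + Σᵢ [ln λ(xᵢ) + ln Φ(xᵢ)] + 2 ln Φ(T) − 2 ln(1 − E(T))

over the n−2 internal node ages xᵢ below the root. The `(n−1)!` ranked-tree
factor is a convention choice (it cancels in all comparisons) fixed so that
the μ = 0, ρ = 1 case reduces exactly to the product of exponential waiting
densities of the pure-birth process — the closed-form oracle in the tests,
alongside a constant-rate closed form and a stiff ODE integration of the
backward equations.

Windows are built by tiling `[root, 0]` with `min_width` windows (default
5 Myr) anchored at the present and merging, scanning from the present
toward the root, until every window holds at least `min_events` branching
events (default 50); a sub-threshold root-most remainder is absorbed into
the adjacent younger window, and a tree with too few events yields the
single window `[root, 0]`. Events are internal nodes strictly below the
crown; an event age tied with a boundary belongs to the older window.
`windows_from_boundaries` builds windows at user-chosen ages instead, which
is what simulation studies with known shift times want.

Fitting maximizes the likelihood over the variant's free parameters (EQUAL:
scalar λ, μ; VAR_SPEC: per-window λ, scalar μ; VAR_EXT: scalar λ,
per-window μ) with L-BFGS-B on log-transformed rates bounded in
[10⁻⁶, 10²] Myr⁻¹, from five deterministic log-spaced starts between 10⁻²
and 10¹ (extinction starts at a fifth of the speciation start). The
multi-start guards against the well-known flatness of the likelihood in μ;
on a single pure-birth tree μ̂ is a ridge direction and individually noisy,
which is why recovery checks use medians across replicate trees. Model
choice is by AIC = 2k − 2 ln L; this maximum-likelihood treatment replaces
Bayesian MCMC with marginal-likelihood comparison deliberately — the
likelihood is the shared object, and ML keeps the pipeline deterministic
and desk-scale. ρ defaults to 1 for synthetic data; clade-specific sampling
fractions are out of scope.

## Pipeline and reproducibility

`run_pipeline` executes simulate → conflict → LTT → fit for each replicate
from a single validated YAML document (unknown keys rejected, seed
mandatory). The master seed spawns per-(replicate, stage) children via
`numpy.random.SeedSequence(seed, spawn_key=(replicate, stage))`, so any
replicate can be re-run in isolation; identical config + seed reproduces
byte-identical TSV artifacts (floats are written with a fixed `%.10g`
format). Every stage is a single call into the library modules — the
orchestrator adds no computation of its own.

## Problem sizes

The validation suite and `scripts/acceptance.py` use: 20,000 gene trees for
the three-taxon coalescent check; 10 replicate 100-tip trees × 100 gene
trees for the conflict-direction checks; 25 random 8-taxon trees × 50 gene
trees for the brute-force conflict equality; 100 augmentation replicates on
a ~1,000-species checklist fixture; 50 pure-birth trees (n = 100) and 20
episodic replicates for rate recovery; and 100 pure-birth trees (n = 200)
for the LTT calibration. These sizes make every stochastic check pass or
fail by a comfortable margin at interactive runtimes.
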