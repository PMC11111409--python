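# divconflict

Macroevolutionary analyses on dated phylogenies: gene-tree conflict through
time, the fraction of extant lineages a sparsely sampled tree represents,
lineage-through-time (LTT) steepness, and episodic birth–death
diversification-rate fitting — together with the simulation machinery
(birth–death species trees, multispecies-coalescent gene trees,
checklist-style taxonomies) needed to validate every step on synthetic data.

The package targets questions of the kind raised by large flowering-plant
phylogenomic datasets: does gene-tree discordance, generated by incomplete
lineage sorting (ILS), rise and fall with the speciation rate? How much of
the extant diversity does a one-tip-per-genus tree actually represent at
each moment in the past, and how does that limit diversification inference
near the present?

## The models

**Gene-tree conflict.** For each internal branch of a dated species tree
with bipartition *B*, a gene tree is *congruent* if *B* restricted to the
gene's taxon set is informative and displayed by the gene tree,
*uninformative* if the restriction collapses, and *conflicting* otherwise.
Per-branch conflict is aggregated into a through-time series by averaging
over the branches crossing each 2.5-Myr time slice, and regressed (OLS) on
log₁₀ branch duration — duration being a proxy for the local
diversification rate. Under the multispecies coalescent a branch of
duration *t* Myr spans *t·g/(2Nₑ)* coalescent units and the probability
that a three-taxon gene tree lacks the species grouping is (2/3)e^(−T),
which is the analytic anchor of the simulator's test suite.

**Sampling fraction.** Missing diversity recorded in a checklist is grafted
back onto the tree: unsampled species of a sampled genus grow from the genus
stem, whole unsampled genera from their family's branches, each as a
reconstructed constant-rate birth–death subtree *conditioned* on its
checklist count, with the net rate set by the expected-growth identity
r = ln(n)/T. The estimate at age *t* is the ratio of lineage counts,
observed over augmented, on a 1-Myr grid, with uncertainty from repeated
augmentations.

**Diversification.** LTT steepness is the binned difference of
ln(lineages+1) in 5-Myr bins, Tukey-3R-smoothed. The episodic birth–death
model has piecewise-constant rates λᵢ, μᵢ on adaptive windows (smallest 5
Myr, each holding ≥ 50 branching events), a sampling probability ρ at the
present, and is conditioned on the crown age and survival of both crown
lineages; three variants (shared rates, per-window λ, per-window μ) are fit
by bounded quasi-Newton maximum likelihood and compared by AIC.

## Worked example

Simulate one experiment: a 100-tip species tree whose speciation rate is
0.75 species Myr⁻¹ except for a ten-fold slowdown between 6 and 2 Ma, with
100 coalescent gene trees at Nₑ = 5,000:

```python
import divconflict as dc

schedule, msc = dc.experiment_preset("experiment1")
species = dc.prune_extinct(dc.simulate_bd_tree(schedule, 100, seed=7))
genes = dc.simulate_msc_gene_trees(
    species, dc.MSCConfig(effective_population_size=5_000, n_genes=100, seed=8))

profile = dc.per_branch_conflict(species, genes)
series = dc.conflict_through_time(profile, species, slice_width=2.5)
print(series.table.to_string(index=False))
```

```
 older_bound  younger_bound  midpoint  mean_conflict  n_branches
    2.500000            0.0  1.250000       0.490263          76
    5.000000            2.5  3.750000       0.028750          16
    7.500000            5.0  6.250000       0.291613          31
    8.926878            7.5  8.213439       0.391111           9
```

Mean conflict collapses from ~0.29–0.49 in the fast-speciation eras to
0.03 inside the 6–2 Ma slowdown: ILS-driven conflict tracks the speciation
rate. The duration regression agrees (longer branches, less conflict):

```python
corr = dc.conflict_rate_correlation(profile)
# slope=-0.370  r2=0.707  p=2.62e-27
```

and the episodic model, fitted with windows at the true shift times,
recovers the imposed rates (truth: 0.75 / 0.075 / 0.75):

```python
windows = dc.windows_from_boundaries(species, [6.0, 2.0])
fit = dc.fit_episodic_model(species, windows, variant=dc.VAR_SPEC)
print(fit.to_frame().to_string(index=False))
```

```
 older_bound  younger_bound  n_events   lambda       mu  net_rate
    8.926878            6.0        18 0.767499 0.000001  0.767498
    6.000000            2.0         5 0.054475 0.000001  0.054474
    2.000000            0.0        75 0.637391 0.000001  0.637390
```

The same stages are available from the shell
(`divconflict simulate|conflict|sampfrac|ltt|fitdiv|run|summarize`), and
`divconflict run --config experiment.yaml` executes a whole replicated
experiment reproducibly from one seeded YAML document.

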