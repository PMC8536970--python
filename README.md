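# benthos

Community-assembly analysis for benthic 16S OTU data: null-model
partitioning of deterministic vs stochastic assembly processes,
random-matrix-theory (RMT) co-occurrence networks with Zi–Pi keystone
identification, and PCA + dbRDA model selection that attributes
environmental parameters and keystone taxa to selection- or
dispersal-related processes.

It is written for microbial ecologists who have an OTU count table
(samples × taxa), a rooted phylogeny over the taxa, an environmental
table and a sample-to-group map — the typical output of a 16S amplicon
workflow — and want to ask *which assembly processes structured these
communities, and which factors drive them*. A synthetic-data generator
emulating a 4-group × 8-replicate sediment study design makes every
stage testable without sequence data.

## The statistics at the core

**βMNTD / βNTI.** For samples *k, l*, the β-mean nearest taxon distance
is the abundance-weighted mean of each taxon's patristic distance to
its closest relative in the other sample. βNTI is its z-score against a
null that shuffles taxon labels across the tips of the regional pool
(taxa present in ≥ 1 sample), 999 replicates:

    βNTI = (βMNTD_obs − mean βMNTD_null) / sd βMNTD_null

**RC_bray.** The Raup–Crick metric locates the observed Bray–Curtis
dissimilarity within a null ensemble that preserves each sample's
richness and total abundance, drawing taxon membership ∝ regional
occupancy and filling individuals ∝ regional relative abundance:

    RC = 2·[(#null < obs) + ½·(#null = obs)]/reps − 1  ∈ [−1, 1]

**Five-way classification of each sample pair.** βNTI ≥ 2 →
heterogeneous (variable) selection; βNTI ≤ −2 → homogeneous selection;
otherwise RC ≥ 0.95 → dispersal limitation (with drift), RC ≤ −0.95 →
homogenizing dispersal, else undominated. Contributions are summarised
at regional, within-group and between-group scope.

**Networks.** Per group, taxon–taxon Pearson correlations are
hard-thresholded at the lowest cutoff where the nearest-neighbour
spacing distribution of the unfolded eigenvalue spectrum follows the
Poisson law (signal) rather than the Wigner/GOE law (noise). Greedy
modularity gives modules; each node gets a within-module degree z-score
Zi and participation coefficient Pi = 1 − Σ_t (k_it/k_i)². Zi > 2.5
marks module hubs, Pi > 0.62 connectors, both network hubs — together
the keystone taxa.

**Driver attribution.** Environmental factors and keystone abundances
are min–max scaled and combined by PCA; the axes are fitted to the βNTI
and RC_bray matrices by distance-based RDA with forward selection on
adjusted R² and max-statistic permutation p-values. The variable with
the highest |loading| on a retained axis is that axis's primary factor:
selection-related if the axis was retained for βNTI, dispersal-related
if retained for RC_bray only.

## Worked example

```python
import benthos as b
from benthos.simulate import preset, simulate_dataset

# two habitats (TO/BO at one niche optimum, TN/BN at another),
# strong environmental filtering on phylogenetically conserved traits
spec = preset("selection_divergent", n_taxa=100, depth=2000, seed=42)
table, env, groups, tree, traits = simulate_dataset(spec)

model = b.CommunityAssembly(table, tree, groups)
res = model.fit(reps=999, seed=42)
print(res.summary().loc[["regional", "within:TO", "between:TO-TN", "between:TO-BO"]])
```

prints (percentages of sample pairs per process):

```
               homogeneous_selection  heterogeneous_selection  dispersal_limitation  homogenizing_dispersal  undominated  n_pairs
scope
regional                         0.0                     57.9                   0.0                    33.9          8.3      496
within:TO                        0.0                     14.3                   0.0                    60.7         25.0       28
between:TO-TN                    0.0                    100.0                   0.0                     0.0          0.0       64
between:TO-BO                    0.0                      6.3                   0.0                    71.9         21.9       64
```

Read: every pair of samples straddling the two niche optima (TO–TN) is
classified heterogeneous selection — the communities are more
phylogenetically divergent than the tip-shuffling null expects — while
pairs sharing an optimum (within:TO, and TO–BO, which sit at the same
optimum in this preset) are near-identical draws from the same filtered
pool and mostly register as homogenizing dispersal or undominated.
496 = C(32,2) pairs in total.

The full pipeline (rarefy → diversity → processes → networks/keystones
→ keystone-only processes → driver attribution) runs from the shell:

```sh
benthos simulate --preset selection_divergent --seed 42 --out data/
benthos run --otu data/otu_table.tsv --tree data/tree.nwk \
            --env data/env.tsv --groups data/groups.tsv --out run1/
benthos report run1/
```

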