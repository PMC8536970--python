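# Methods

This note records the models, conventions and numerical choices behind
`benthos`, in the order the pipeline applies them, together with the
design decisions that were genuinely open and the limitations a user
should know about. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and rarefaction

Counts stay integers until explicitly converted to relative abundances
(count / sample total). The canonical orientation is samples × taxa;
readers normalise. Missing environmental values are a hard error — the
intended data are complete, and silent imputation would leak into every
downstream ordination. Rarefaction draws a multivariate hypergeometric
sample per row (subsampling without replacement), so taxon support can
only shrink and every row total equals the requested depth exactly; the
default depth is the minimum sample total, and depth and seed are
recorded in the run manifest. Whether an abundance prefilter should
precede or follow rarefaction is left to the caller — both orders are
expressible (`select_taxa` then `rarefy`, or the reverse) and neither is
asserted as canonical.

## Diversity conventions

Shannon entropy is reported in nats (natural log), with a `base`
switch. Chao1 uses S_obs + F1²/(2 F2) and falls back to the
bias-corrected S_obs + F1(F1−1)/2 only when F2 = 0; this branch
structure is why the estimator is hand-coded rather than delegated
(scikit-bio's bias-corrected form divides by F2 + 1 unconditionally).
ANOSIM uses mid-ranks for ties and the add-one permutation convention,
so the smallest attainable p with 999 permutations is 0.001. The group
presence rule is ≥ ⌈n/2⌉ positive samples (4 of 8 in the reference
design; 1 of 2 at the boundary). PCoA reports negative eigenvalues
as-is and restricts coordinates to positive-eigenvalue axes. NMDS is
deliberately absent: it is a presentation-only alternative to the PCoA
ordination and adds no inference.

## βMNTD / βNTI

βMNTD is abundance-weighted by default (`abundance_weighted=False`
gives the presence-based variant): for the pair (k, l), each taxon in k
contributes its patristic distance to the nearest taxon present in l,
weighted by its relative abundance in k, and the two directions are
averaged. Shared taxa contribute distance 0.

The βNTI null shuffles taxon labels across the regional pool — the taxa
present in at least one sample of the analysed table — which preserves
both community abundance structure and the tree shape while randomising
which tip carries which abundance. One permutation per replicate is
shared by all sample pairs (the standard shared-randomisation scheme):
per-pair marginal null distributions are identical to per-pair
shuffling, results are independent of pair evaluation order, and the
cost drops by a factor of the pair count. Pairs whose null standard
deviation is zero (star phylogenies; *identical* communities, whose
shared taxa remain shared under every consistent relabelling) are
reported as βNTI = 0 with an explicit `degenerate` flag rather than
NaN. The tree is implicitly pruned to the analysed taxa by the pool
definition; passing a larger tree changes nothing because the null only
permutes pool tips.

## RC_bray

Per replicate, one null community is built for every sample: its
observed richness S and total N are preserved; S taxa are drawn without
replacement with probability ∝ regional occupancy; each receives one
individual and the remaining N − S are assigned multinomially ∝
regional relative abundance over the drawn taxa. All pairs in a
replicate are compared on the same set of null communities (same
shared-randomisation argument as above). RC = 2[(#null < obs) +
½(#null = obs)]/reps − 1, clamped to [−1, 1]; equality uses a 1e−12
tolerance.

## Process classification

βNTI ≥ 2 → heterogeneous (variable) selection; βNTI ≤ −2 → homogeneous
selection; the βNTI test takes precedence, then RC ≥ 0.95 → dispersal
limitation, RC ≤ −0.95 → homogenizing dispersal, else undominated.
Some papers print the two selection inequalities swapped; the mapping
here is the canonical one in the quantitative framework — observed
phylogenetic turnover *above* the null means divergent environments
are selecting different lineages. Contribution percentages are
reported to 1 decimal with round-half-up, and counts always sum to the
number of pairs in scope (the classification is exhaustive and
mutually exclusive).

## RMT threshold and networks

Per group, taxa passing the presence rule are correlated (Pearson, on
relative abundances by default; `counts` and `log` transforms exposed
because the field is not settled on one). Both correlation signs form
edges: |r| ≥ s_t.

The threshold scan (default 0.30–0.99 in 0.01 steps) hard-thresholds
the correlation matrix, computes its eigenvalues, collapses degenerate
mass (repeated eigenvalues at 1 from isolated rows), unfolds the
spectrum with a smoothing cubic spline fitted to the cumulative
spectral density, and tests the nearest-neighbour spacing distribution
against the Poisson law P(d) = e^(−d) with a chi-square test on
⌈√#spacings⌉ equal-probability bins. The spline smoothing target is 2
ranks of squared residual per eigenvalue: tight enough to follow the
density, loose enough not to fit the staircase (an over-fitted
unfolding produces picket-fence spacings that no threshold would ever
pass). s_t is the lowest cutoff with p > 0.05 that stays consistent
for the next two steps. Matrices under 20 nodes, or scans with no
consistent cutoff, fall back to a configured threshold (default 0.80)
with a logged warning — spectral statistics are meaningless at that
size.

Modules come from greedy (CNM) modularity maximisation, which is
deterministic at this scale; module ids are ordered by size with ties
broken by lowest member id. Zi is the within-module degree z-score
(0, flagged, when a module's degree sd is 0); Pi = 1 − Σ_t (k_it/k_i)².
Role thresholds are strict inequalities: Zi > 2.5 module hub, Pi > 0.62
connector, both → network hub; keystones are all non-peripheral nodes.

## Driver attribution

Environmental factors and keystone relative abundances are min–max
scaled per column (constant columns dropped with a warning) and
combined in one PCA — joint scaling puts a pH range and an abundance
range on the same footing. PCA axes are sign-fixed so the
largest-|loading| variable on each axis loads positively; attribution
uses absolute loadings, so the convention is cosmetic.

βNTI and RC matrices are z-score-like, not metric distances, so the
dbRDA response is shifted by its off-diagonal minimum when negative
entries are present (proper dissimilarities pass through untouched) and
embedded by principal coordinates with a Lingoes correction, which adds
the smallest constant making all eigenvalues non-negative. Forward
selection then adds the predictor axis with the largest adjusted-R²
gain (Ezekiel correction), subject to three stopping rules: the gain
must be positive, the model's adjusted R² may not exceed the
full-model adjusted R² (computed on at most n − 2 predictors — a
saturated model has no adjusted R²), and the added axis must pass a
permutation test at α = 0.05. The permutation test is a max-statistic
Freedman–Lane test: reduced-model residuals are permuted and the
observed gain is compared with the null distribution of the *largest*
gain over all remaining candidates. This explicitly accounts for
having picked the best of many axes; a naive per-axis test inflates
the family-wise error roughly k-fold and retains spurious axes from
pure noise far more often than α.

A factor with the top |loading| on a βNTI-retained axis is
selection-related; on an axis retained by RC but not βNTI,
dispersal-related (an axis retained by both counts as selection).
Environmental variables and taxa are ranked jointly and separately.
RDA explained variance uses the Hellinger transform by default
(identity available), and the random-subcommunity control scores
`n_draws` random k-taxon subsets with the same RDA, ranking the
keystone set with add-one empirical p-values in both tails.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *study design* — 4 groups × 8 replicates,
six named sediment chemistry factors with group-structured means tied
to a latent niche axis, a Yule phylogeny (unit birth rate, with the
post-nth-birth exponential wait added so E[root-to-tip] = Σ_{k=2..n}
1/k), Brownian niche traits, and multinomial sampling of `depth`
individuals — under two mechanisms:

* **selection**: sampling weights ∝ metacommunity × Gaussian niche
  kernel exp(−(z_i − e_s)²/2σ_w²), with optima and σ_w in units of the
  tip-trait standard deviation so defaults transfer across trees;
* **neutral**: per-group local pools drifted from the metacommunity on
  the log scale, mixed with the metacommunity by a dispersal parameter
  m ∈ [0, 1].

An optional per-sample lognormal weight perturbation
(`sample_drift_sd`) models within-habitat ecological drift.

Four presets define the recovery conditions: `selection_divergent`
(two optima ±1.2 trait-SD, σ_w = 0.35, 200 taxa, depth 5000),
`selection_homogeneous` (400 taxa, four spread optima, depth 400,
sample drift 2.0, assessed within groups with presence-based βMNTD —
drift scrambles abundances while selection constrains membership),
`neutral_limited` (m = 0.02) and `neutral_homogenizing` (m = 1). The
default scale keeps a full 999-replicate βNTI + RC run under a minute
on one CPU; the 1195-taxon study scale is reachable by raising
`n_taxa`.

What the generator does *not* emulate: sequencing artefacts (chimeras,
copy-number variation), compositional bias, temporal dynamics, and
spatially explicit dispersal. Passing the recovery tests therefore
shows the estimators respond correctly to cleanly generated selection
and dispersal signals, not that real sediment data are this separable.

## Known limitations

* **Homogeneous selection is the structurally hard regime.** With a
  consistent tip-relabelling null, taxa shared by two samples stay
  shared, so near-identical filtered communities carry almost no βNTI
  signal; detection requires replicates that are sparse,
  membership-scrambled subsets of one clade inside a broader regional
  pool. The `selection_homogeneous` preset creates exactly that
  situation and still recovers the dominant process only marginally at
  some seeds — consistent with how rarely strong homogeneous selection
  is resolved in practice. The other three regimes recover their
  generating process by wide margins.
* βNTI degenerates (flagged 0) for star phylogenies and identical
  communities; downstream classification then rests on RC alone.
* The RMT scan needs ≥ 20 connected taxa to say anything; small groups
  fall back to a fixed threshold.
* Drift is never estimated directly — "undominated" aggregates weak
  selection, weak dispersal and drift, as the five-way rule defines it.
* Monte-Carlo resolution: with 999 replicates the granularity of RC is
  0.002 and βNTI stability is about ±0.3 at this scale; raising `reps`
  tightens both at linear cost.
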