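# Methods

## Data model

The universal container is a dense gene x region x timepoint array of
non-negative expression densities with NaN marking unmeasured cells.
Missingness is explicit everywhere: a region absent at an age simply has no
rows in the input table, and no statistic ever reads a missing cell as zero.
Age labels are opaque ordered strings (E11.5 … P56); nothing downstream does
arithmetic on ages, so the curve and fit operate on ordinal ranks — the
quadratic fit of the hourglass curve therefore describes shape on a
categorical age axis, not a rate per day.  Gene and region identifiers match
exactly and case-sensitively.

## Dissimilarity

d(R1, R2) = 1 − Pearson correlation of the two regions' expression vectors,
computed over the genes observed in both regions (pairwise-complete).  A
pair with fewer than 3 common genes, or with a zero-variance vector, is a
missing matrix entry rather than a NaN that propagates: downstream means are
taken over the valid pairs and the validity mask is carried along.  The
per-age summary keeps mean, median, quartiles and 1.5 x IQR whiskers.

The one-way ANOVA over ages treats each pair dissimilarity as an
observation.  The fully degenerate case (zero between-group variation)
returns F = 0, p = 1 rather than NaN.

Robustness procedures: (i) random gene subsets, sampled without replacement
from a single seeded generator; (ii) per-age removal of the k genes with the
largest across-region sample SD, recomputed at every age on raw densities
(the removal set may differ between ages); (iii) leave-one-region-out with a
mean/SD envelope over exclusions; (iv) ontology-level curves where a parent
region's profile is the unweighted NaN-aware mean of its constituent leaves
— a declared convention standing in for atlas-level per-parent
quantification, which a text table cannot provide.

## Contribution profiles and enrichment

ΔD_g(t) = D̄(t) − D̄_without_g(t) is recomputed honestly: the gene-deleted
dataset goes through the identical dissimilarity code path, with the
reference pair mask enforced (if deleting a gene makes a pair unscorable the
computation errors out instead of silently changing the mask).  No
incremental downdating is used, so the values agree with a brute-force
oracle to machine precision.

Clustering is k-means (k-means++ seeding, 10 restarts, best inertia kept)
on raw, unstandardized profiles — the contribution scale is meaningful and
standardizing would erase exactly the magnitude structure the categories
share.  The default grid is k = 10, 15, …, 50.

Enrichment is an upper-tail hypergeometric test of each (cluster, category)
cell, restricted to categories with at least 10 annotated genes in the
clustered universe (and to a caller-supplied whitelist such as
nervous-system terms when one is given).  The double FDR corrects in two
stages: Benjamini–Hochberg across all (cluster, category) tests within each
clustering, then, per category, BH across the k grid, where each (k,
category) is summarized by its minimum stage-1 q over clusters — a category
is called through its best cluster.  (An alternative raw-p summary is
available behind a flag.)  Categories pass at stage-2 q < 0.01.  The
hierarchy screen then discards any enriched category with an enriched DAG
descendant at strictly lower q, keeping the most refined terms.

Phase labels pool all cluster-gene contributions over embryonic ages
(E11.5–E18.5) and postnatal developmental ages (P4–P28) and compare the two
pools.  The pools are unpaired and of unequal size, so the two-sample
Mann–Whitney rank-sum test is used (a signed-rank test is undefined for
unpaired pools); at p < 0.05 the cluster takes the phase with the larger
median, otherwise "neither".  Contribution profiles are computed on
developmental ages only when an adult age (P56) is present.

## Region analysis

The region-specific index divides a region's mean dissimilarity to all
others by D̄(t); exchangeable regions have index 1 in expectation, and the
index is undefined (an error) when D̄(t) = 0.

Non-metric MDS minimizes Kruskal stress-1 by alternating isotonic regression
of configuration distances on the input dissimilarities with a Guttman
transform (unit weights).  One start is classical (Torgerson) scaling —
exact whenever the input is realizable in the target dimension, which is
what makes near-zero stress attainable deterministically — plus seeded
random restarts (default 10 total), 500-iteration cap, 1e-8 relative stress
tolerance.  Missing dissimilarities are imputed with the maximum observed
value (conservative separation).  Ties in the monotone regression are pooled
(secondary approach).

Procrustes alignment allows translation, rotation, reflection and isotropic
scaling; the disparity is the minimized squared difference between
unit-norm-standardized configurations (the classical statistic), while the
aligned coordinates are returned in the reference's original frame.  Across
ages the embedding is chained: each age aligns to the previous aligned
configuration, keeping trajectories visually continuous.

Lineage analysis correlates pair dissimilarity with the path distance
between the regions' embryonic origins on a fixed unit-branch tree: root →
{forebrain → {telencephalon, diencephalon}, midbrain, hindbrain}; same
origin = 0, telencephalon–diencephalon = midbrain–hindbrain = 2, all other
pairs = 3.  This is the simplest tree consistent with the four origin
classes; ages where either vector is constant are excluded with a warning.

Per-region gene rankings use the regional analogue of ΔD: the mean
dissimilarity of the focus region to all others, with and without each gene,
again recomputed from scratch per gene.

## Gene families

Global alignment uses BLOSUM50 with a linear gap penalty of 8 per gap
symbol (no separate opening/extension), via Biopython's pairwise aligner;
score ≥ 0 marks a sequence-similar ("family") pair.  One protein sequence
per gene id is required; duplicate FASTA ids are an error.  Spatial
correlation is Pearson r across regions at the two edge ages of the series
(the peak-dissimilarity ages of an hourglass-shaped dataset); matched pairs
with r < −0.2 / r > +0.2 form the anti-correlated / co-expressed strata.

## Cross-species comparison

For every (source age, target age) pair, each mapped region set is averaged
into one profile, ortholog genes missing on either side are dropped
pairwise, and Spearman rho (average ranks for ties) is computed per region
pair, then averaged over region pairs.  Averaging correlations rather than
profiles preserves region-specific signal; profile-averaging is available
behind a flag.  Parallel region curves collapse each mapped set into a
single averaged region inside its own dataset and compute the
region-specific index there, so the two species' curves are each normalized
to their own brain-wide dissimilarity.

## Synthetic data

The generator emulates a quantified ISH atlas:

value(g, r, t) = baseline(g) + envelope(program(g), t) · pattern(g, r)
+ lineage · block(g, origin(r)) + breakaway(g, r, t) + noise, clipped at 0,

with i.i.d. standard-normal region loadings, per-gene baselines
Uniform(3, 6) (clipping at zero is then rare enough not to bias
correlations), and additive Gaussian noise (sd 0.1 by default).  Defaults:
200 genes, 12 regions, the seven developmental ages E11.5–P28.

* **Envelope.**  U-shaped by default (quadratic in age rank, 1.0 at the
  ends, 0.05 at the midpoint).  "Construction" genes (30%) follow its
  declining limb, "plasticity" genes (30%) the rising limb, the rest carry
  no regional signal; the mean dissimilarity then dips mid-series.
* **Lineage blocks.**  Regions cycle through the four origin classes and
  share a per-(gene, block) loading scaled by 0.3.  A gene-independent
  additive offset per region — the naive reading of "block offset" — cannot
  work here: it is constant along the gene axis and Pearson correlation is
  invariant to it, so block structure is planted as shared gene loadings
  instead.
* **Planted GO categories.**  One category per program: a block of 20
  program genes whose envelope is amplified 2x.  Coherence is the point —
  a category is recoverable by profile clustering only if its genes share a
  contribution profile; random samples of program genes scatter across
  magnitude-driven clusters and are not reliably detected.  Twenty
  size-matched random distractor categories provide the calibrated null.
* **Paralog pairs.**  Five pairs of construction genes whose region-loading
  sample correlation is set exactly to the target (−0.6 by default) by
  Gram–Schmidt construction; the realized expression-level correlation is
  mildly attenuated by noise and lineage variance.
* **Breakaway region.**  Optional.  Drivers (20 genes) are marker-like:
  flat mean-level baseline everywhere, no lineage loading, and an equal
  positive deviation on the breakaway region.  The per-age deviation is
  solved in closed form from the model's expected covariances so that the
  region's expected specialization index follows an increasing target
  profile (1.25, 1.45, 1.65 over the postnatal ages; mirrored over
  embryonic ages for an early-specializing variant).  The closed-form solve
  matters: dissimilarity saturates near 1 while the brain-wide mean keeps
  rising, so no fixed open-loop ramp keeps the normalized index increasing.
  Equal positive deviations (rather than signed random loadings) keep every
  driver's planted share identical — so the driver set is recoverable by
  contribution rank — and cannot be clipped at zero.
* **Counterpart species.**  A monotone warp (strictly increasing, possibly
  fractional source-age ranks, linearly interpolated) resamples the source
  timeline; seeded noise is added after interpolation and an identity
  ortholog map is emitted.  Strict monotonicity is required because a
  non-strict warp creates exact Spearman ties at zero noise, making ridge
  recovery ill-posed.

Each verification experiment plants exactly the signal it probes: the
enrichment-calibration run plants nothing (distractors only) and the
breakaway run disables the planted categories, whose amplified variance
would otherwise push the required breakaway dissimilarity past its
saturation ceiling.

What the generator does **not** emulate: ISH pixel noise and registration
error, cell-density confounds, count-like mean-variance relationships,
correlated gene modules beyond the planted ones, or regions appearing and
disappearing across ages.  Passing tests therefore demonstrate that the
statistics recover the structures they target under an additive Gaussian
model — not that real atlas data are free of the artefacts listed above.

## Problem sizes and determinism

Verification experiments use 200-gene x 12-region datasets (500 genes for
the enrichment study, 30 x 8 x 5 for exact-oracle checks), 20 seeds for
recovery fractions and 50 for null calibration — sizes at which every
planted effect is comfortably detectable and a full run stays interactive.
All stochastic entry points (generator, subsetting, k-means, NMDS restarts)
take explicit integer seeds; identical seeds give bit-identical results.

## Known limitations

* The stage-2 FDR input (minimum stage-1 q per category within each k) is
  one of several defensible summaries; the raw-p alternative is provided but
  not default.
* NMDS ties are pooled rather than left free (primary approach); for the
  atlas-scale matrices used here the difference is negligible, as exact ties
  are rare.
* The lineage tree is fixed and four-leaved; finer origin taxonomies would
  need a caller-supplied distance.
* With very few regions (< 5) the leave-one-region-out envelope is noisy and
  bracketing of the full curve is checked empirically, not guaranteed.
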