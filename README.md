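# regiospec

Quantifying the regional specialization of gene expression across brain
development.

## The problem

In situ hybridization atlases of the developing mouse brain provide, for
thousands of genes, an *expression density* per anatomical region at each
developmental age (E11.5 through P56).  A natural question is how distinct
the regional transcriptomes are at each age: anatomical regionalization
suggests steadily increasing specialization, but quantifying it shows a
counter-intuitive **hourglass**: inter-region dissimilarity *falls* through
embryonic development, reaches a "neurotypic" minimum around birth, and
rises again postnatally — with the early phase driven by circuit-construction
programs and the late phase by plasticity and neural-activity programs, and
with the cerebellar territories (rhombomere 1, isthmus) diverging from the
rest of the brain after birth.

`regiospec` implements that analysis as a tested, reusable pipeline for
anyone working with region x time expression tables (atlas quantifications,
bulk dissections), together with a synthetic-data generator that plants every
signal the pipeline is supposed to detect, with known ground truth.

## The statistics

* **Dissimilarity.** A region at age *t* is its vector of expression
  densities over genes; for regions R1, R2 the dissimilarity is
  d(R1, R2) = 1 − PCC (Pearson correlation), in [0, 2].  The mean over all
  region pairs, D̄(t), traced over ages, is the hourglass curve (summarized
  with median/quartiles/whiskers, fitted with an OLS quadratic, tested with
  one-way ANOVA over ages).  Robustness: random gene subsets, per-age removal
  of the most variable genes, leave-one-region-out, and re-aggregation at
  coarser levels of the region ontology.
* **Gene contributions.** ΔD_g(t) = D̄(t) − D̄_without_g(t), the leave-one-out
  contribution of gene *g*; profiles are clustered with k-means over a grid
  of k (default 10–50 step 5), clusters are tested for GO enrichment with an
  upper-tail hypergeometric test, corrected with a **double FDR**
  (Benjamini–Hochberg within each clustering, then per category across the
  k grid), screened so only the most refined enriched categories remain, and
  labelled embryonic/postnatal with a two-sample rank test on pooled
  contributions.  A category's contribution index is the mean ΔD of its genes.
* **Regions.** A region's specialization index is its mean dissimilarity to
  all other regions divided by D̄(t).  Regions are embedded in 2D with
  non-metric MDS (Kruskal stress-1, monotone regression + Guttman
  majorization) and chained Procrustes alignment across ages; dissimilarity
  is correlated with embryonic-lineage tree distance (telencephalon /
  diencephalon / midbrain / hindbrain).
* **Gene families.** Within-category gene pairs are scored with global
  Needleman–Wunsch alignment (BLOSUM50, linear gap penalty 8; score ≥ 0 is a
  sequence match) against their regional expression correlation, flagging
  "similar sequence, complementary expression" pairs (r < −0.2).
* **Cross-species.** Ortholog expression profiles of two species are compared
  with Spearman correlation for every pair of ages (averaged over mapped
  region pairs); the matrix ridge traces the developmental-time translation
  between the species.

## Worked example

```python
from regiospec import synthetic_data as syn
from regiospec import dissimilarity as dis

cfg = syn.SyntheticConfig(seed=1)          # 200 genes, 12 regions, 7 ages
dataset, truth = syn.generate(cfg)
curve = dis.curve(dataset)
print(curve["mean"].round(4).to_dict())
print("quadratic:", [round(c, 4) for c in dis.fit_quadratic(curve)])
print("ANOVA p:", dis.age_anova(dis.dissimilarity_set(dataset)))
```

prints

```
{'E11.5': 0.3521, 'E13.5': 0.1705, 'E15.5': 0.107, 'E18.5': 0.1022,
 'P4': 0.1109, 'P14': 0.1747, 'P28': 0.3538}
quadratic: [0.0294, -0.1756, 0.3409]
ANOVA p: 8.517672249748023e-168
```

The mean inter-region dissimilarity starts high at E11.5 (0.35), bottoms out
around birth (E18.5–P4, ≈0.10) and climbs back to 0.35 by P28 — the hourglass
the generator planted through its U-shaped signal envelope.  The positive
quadratic coefficient captures the U shape; the ANOVA confirms the age effect
on pair dissimilarities.

The same analyses are scriptable from the shell:

```bash
regiospec simulate --config cfg.json --out data/
regiospec hourglass --expr data/expression.tsv --robustness loro --out out/
regiospec contrib   --expr data/expression.tsv --go data/go_annotations.tsv \
                    --obo go.obo --kgrid 10:50:5 --seed 1 --out out/
regiospec regions   --expr data/expression.tsv --ontology data/ontology.tsv \
                    --focus r11 --out out/
regiospec run       --config run.json     # end-to-end with a manifest
```

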