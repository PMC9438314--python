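# mucometa

Functional and taxonomic analysis of **mucus-associated shotgun metagenomes**
in a cancer cohort — for microbiome researchers who have already assembled
and annotated their reads and want the downstream statistics: function
quantification, tumor-size group comparison, pathway scoring, a
two-community density decomposition, contig-based taxonomy and survival
association.

## The model

The package consumes per-sample **annotated contig tables** (contig length
*L*, mean read depth *D*, taxonomic lineage, and per-gene KEGG-ortholog
calls with mapped-read counts) and builds:

* **MFA table** — the Metagenome Function Abundance of KO *k* in sample *s*
  is the total number of reads covering genes annotated with *k*, over all
  organisms; normalized to reads per million sequenced reads
  (`raw × 10⁶ / total_reads`), optionally log2-transformed and
  median-centred per KO.
* **Tumor-size groups** — the *k* = 14 largest tumors (LT-group) vs the 14
  smallest (ST-group). Every KO found in ≥ 1 sample is tested with Fisher's
  exact test (presence/absence) and a two-sided Mann–Whitney test
  (abundance), selected at unadjusted *p* < 0.05 on either test; direction
  is assigned by prevalence when Fisher is significant, else by mean
  abundance.
* **Pathway enrichment score** — with pct_G the percentage of group *G*'s
  differential KOs overlapping a pathway,
  `score = (pct_ST − pct_LT) / (pct_ST + pct_LT)` ∈ [−1, 1]
  (positive = ST-enriched). A per-sample **activity score** is the mean
  log2 normalized abundance of a pathway's KOs.
* **Two-community decomposition** — the direction-specific KO sets define
  two normal curves N(μ, σ²) on the log2-abundance axis; each group's
  density of *all* KO abundances is then fitted as a non-negative linear
  combination of the two fixed curves (NNLS on a kernel density estimate).
  The amplitude ratios between groups quantify how strongly each microbial
  community dominates each group.
* **Taxonomy** — a taxon's abundance is Σ *L×D* over its contigs,
  normalized per sample; the same weighting restricted to contigs encoding
  a pathway's enzymes yields the pathway's representative taxa.
* **Survival** — pathway activity dichotomised at the first quartile
  (Low/High), Kaplan–Meier curves with the log-rank test, and Cox
  proportional-hazards regression for recurrence-free survival.

A **synthetic cohort generator** (`mucometa.generate_cohort`) emulates the
assumed data structure — two latent KO communities with log-normal
abundance whose per-sample mixing weight tracks tumor size, carried by
distinct taxonomic orders — and records its ground truth, so every stage
is testable end to end.

## Worked example

```python
import pandas as pd
import mucometa as mm

# toy: two metagenomes of 18 and 19 cells, one read per gene
table = mm.build_mfa(pd.concat(mm.toy_figs2().values(), ignore_index=True))
print(table.values)
#> sample_id   A   B
#> ko_id
#> F1          4  15
#> F2         14   4

# synthetic cohort of 41 patients, 500 KOs per community
contigs, clinical, totals, truth = mm.generate_cohort(mm.CohortParams(seed=7))
norm = mm.normalize(mm.build_mfa(contigs, totals))
groups = mm.assign_size_groups(clinical, k=14)
diff = mm.differential_kos(norm, groups)
print(mm.dominance_report(groups, norm, diff).summary())
#> Community dominance report
#>   LT-abundant curve N(1.843, 2.419^2), ST-abundant curve N(4.698, 1.283^2)
#>   LT-group: coef_LT=1.0416 coef_ST=0.0397 R^2=0.950
#>   ST-group: coef_LT=0.4785 coef_ST=0.3810 R^2=0.883
#>   LT-community amplitude ratio (LT/ST group): 2.177 (difference +0.5631)
#>   ST-community amplitude ratio (LT/ST group): 0.104 (difference -0.3414)
```

The amplitude ratios say the LT-associated community's density component
is ~2× stronger in the large-tumor group than in the small-tumor group,
while the ST-associated component shrinks — the planted dominance gradient,
recovered. Per-sample functional richness behaves the same way:

```python
print(mm.functional_richness(mm.build_mfa(contigs, totals), clinical).summary())
#> Functional richness across 41 samples: median 993 unique KOs
#>   Pearson r vs tumor size: 0.717 (p = 1.34e-07)
#>   Rank-sum p, stage I/II vs III/IV: 0.077
```

The same chain is scriptable from a shell:

```bash
mucometa simulate --n 41 --seed 7 --out sim/
mucometa run-all --contigs sim/contigs.tsv --clinical sim/clinical.csv \
    --total-reads sim/total_reads.tsv --pathway-map sim/pathway_map.tsv \
    --cazy-map sim/cazy_map.tsv --out results/
```

## Layout

`src/mucometa/` — library (`mfa`, `differential`, `pathway`,
`decomposition`, `taxonomy`, `clustering`, `survival`, `synthetic`,
`pipeline`, `cli`); `tests/` — pytest suite; `docs/methods.md` — the
modelling and design notes.
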