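# Methods notes

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices a maintainer would want to know.

## Function quantification (MFA)

The abundance of a molecular function (KEGG ortholog, KO) in a metagenome
is the total count of sequencing reads covering genes annotated with that
KO, summed over all organisms. Genes without a KO call are ignored — the
quantity is a function profile, deliberately blind to which species encodes
the function. Normalisation divides by the sample's *total sequenced
reads* (supplied as metadata, since it includes reads on unannotated genes
and unassembled reads) and multiplies by 10⁶; this is reads-per-million,
comparable across samples of different depth.

*Pseudocount.* Zeros survive the prevalence filter, so the log2 transform
used before clustering and for activity scores adds a pseudocount, default
1 on the normalized (RPM) scale — it keeps zeros finite and the transform
monotone. It is configurable, and 0 is allowed when the caller guarantees
positivity. The decomposition stage pools only *nonzero* entries ("KOs
found in the group"), so its default pseudocount is 0; adding 1 there would
compress the low-abundance tail of the density and bias the fitted curves
(this is visible in practice: with pseudocount 1 the recovered sd of a
planted sd-2.6 community drops to ~1.9).

*Median centring* is per KO row (each function relative to its
cohort-typical level), the heatmap convention; per-sample centring is
available via `axis="sample"` since nothing forces the choice.

## Differential abundance

Groups are the 14 largest (LT) and 14 smallest (ST) tumors; ties at the
rank boundary break by (size, patient id) so labels are independent of
input order. Each KO found in at least one sample is tested with

* Fisher's exact test (two-sided, minimum-likelihood rule) on the 2×2
  presence × group table, and
* a two-sided Mann–Whitney test on normalized abundances — exact null when
  both groups have ≤ 12 observations and no ties, otherwise the normal
  approximation with tie correction (at the default 14 vs 14 the
  approximation is standard practice).

Selection is *p* < 0.05 on either test, deliberately unadjusted (the
selection feeds set-level pathway summaries rather than per-KO claims);
Benjamini–Hochberg q-values are emitted as reference columns only.
Direction: Fisher-significant KOs go to the more prevalent group ("more
common"); otherwise the higher mean wins. A Fisher-significant KO with
exactly equal prevalences (possible with unequal margins) falls back to the
mean rule — the direction rule's unstated corner case. Fisher p-values are
memoised by table counts; with 14+14 margins only a few hundred distinct
tables exist, which makes the per-KO loop cheap.

## Pathway scores

The enrichment score compares a pathway's share of each direction's
differential KO set: pct_G = 100·|pathway ∩ G|/|G| and
score = (pct_ST − pct_LT)/(pct_ST + pct_LT). The denominator is the
*direction set's size*, not the pathway's, so the score is the relative
skew of the pathway across the two communities' differential repertoires.
The sign convention (positive = ST-enriched) follows the ST-first order of
the formula and is stated everywhere it surfaces. Pathways are reported
when the favoured side's overlap reaches a floor (defaults 9 KOs for
LT-favouring, 4 for ST-favouring), suppressing pathways "enriched" on one
or two KOs.

The activity score is the per-sample mean of log2(RPM + pseudocount) over
the pathway's KOs; one shared pseudocount serves both this and the
clustering transform.

## Two-community decomposition

The decomposition assumes each group's overall KO log2-abundance density is
a superposition of two community-specific normal densities whose *shapes*
are known (estimated as the sample mean/sd of the direction-specific KOs,
each in its own group's samples) and whose *amplitudes* are free:

    f(x) ≈ c_LT · N(x; μ_LT, σ_LT²) + c_ST · N(x; μ_ST, σ_ST²)

Amplitudes are estimated by non-negative least squares of a Gaussian KDE
(Silverman bandwidth, 512-point grid spanning the data range ± 3·max σ)
against the two pdfs. NNLS rather than unconstrained regression because
density components cannot be negative; no intercept because a mixture of
densities has no baseline. This is intentionally *not* an EM mixture fit —
the curves stay fixed, mirroring the two-stage design the analysis
implements. Identical curves raise a collinearity error. The reported
dominance measure is the amplitude ratio LT-group/ST-group per curve
(differences are also emitted, since a ratio and a difference are both
defensible readings of "increased by"); the ratio is invariant to the
KDE's overall scale.

Caveat: when the two curves overlap heavily (the default synthetic cohort's
effective curves overlap after dominance shifts), NNLS can park one
amplitude at zero in the group where that community is shifted away from
its curve. The cross-group *ratios* remain directionally correct — that is
the quantity tests rely on.

## Taxonomy

A contig of length L and mean depth D accounts for ≈ L·D bases of read
mass; taxa are quantified by Σ L·D over their contigs, normalized by the
sample total (columns sum to 1). Depth is a per-contig scalar; no per-base
weighting. Lineages use a fixed 7-rank ';'-separated dialect with "NA" for
unassigned ranks; anything unparseable pools into "unclassified", which
keeps rank roll-ups exact (order-level abundances equal the sum of their
family-level children).

Differential taxa reuse the KO machinery but route by prevalence: taxa in
< 50% of samples ("rare") are judged by Fisher, the rest ("common") by
Mann–Whitney. The 50% threshold is a package choice — "rare" and "common"
have no canonical boundary — and is configurable and logged in the output.

Pathway-representative taxa: contigs carrying ≥ 1 gene of the pathway's
KOs, weighted L·D, normalized within the selected subset (so the profile
answers "who carries this pathway here", not "how much of the community is
this"). Under the alternate whole-sample normalisation the profile is
bounded by the full taxon abundance — a subset identity the tests check.

## Clustering

Agglomerative clustering of both axes with correlation distance
(1 − Pearson) and average linkage — the defaults of the Cluster 3.0 lineage
of expression-clustering tools, exposed as configuration. Axes are sorted
before linkage so memberships cannot depend on input order. Sub-clusters
are a second cut of the same tree (k = 4), the simplest reading of "2 large
clusters and 4 sub-clusters". Constant rows/columns make correlation
distance undefined and raise. Cluster–clinical association: rank-sum for
continuous variables, Fisher for stage (I/II vs III/IV) and nodal status,
between the two most populous clusters. KO-cluster × pathway enrichment is
upper-tail hypergeometric over the clustered-KO universe.

## Survival

Activity scores are dichotomised at the first quartile — linear
interpolation quantile, ties at the boundary going to Low ("falling within
the first quarter") — which is rank-invariant. BMI splits at the WHO 25.0
boundary (≥ 25 = Overweight/Obese); age and tumor size at the cohort
median. Curves are Kaplan–Meier product-limit estimates; the two-group
log-rank test compares them; Cox proportional-hazards regression (Efron
ties, via lifelines) estimates hazard ratios with Wald CIs. Degenerate
inputs (no events, constant covariates, empty groups) raise informative
errors rather than returning unstable fits.

## Synthetic cohort generator

The generator emulates the structure the analysis assumes, with defaults
chosen as the study conditions:

| parameter | default | meaning |
|---|---|---|
| n_patients | 41 | cohort size |
| tumor_size_range | 1.8–11.5 cm | uniform tumor sizes |
| n_kos_per_community | 500 | KO repertoire per latent community |
| μ_A, σ_A | 2.5, 2.6 | log2-RPM profile, LT-associated community A |
| μ_B, σ_B | 5.0, 1.3 | log2-RPM profile, ST-associated community B |
| dominance_slope | 0.1 /cm | change of A's mixing weight per cm |
| within_ko_sd | 0.8 | within-KO across-sample noise |
| mean_total_reads | 2×10⁷ | sequencing depth scale |
| hazard_beta | 1.2 | log-hazard gain per unit A-dominance |

The sds 2.6/1.3 are the two communities' observed density spreads; the
means put the LT-associated community roughly half as abundant as the
ST-associated one. Community A's KO abundance in patient *i* is
2^(b_k + log2 w_i + ε), with per-KO baseline b_k and noise ε split so the
*marginal* log2 distribution is exactly Normal(μ_A, σ_A); w_i is the
mixing weight, 0.5 at mid-range tumor size, clamped to [0.05, 0.95], and
w_B = 1 − w_A. Read counts per gene are Poisson with mean
depth × gene_length / read_length (realized depth is back-computed from
the draw, so L·D tracks read mass) — rare functions drop out of
low-weight communities, which is what makes richness rise with tumor
size. Contig lineages are drawn 85/15 from the community's major order
(Clostridiales-like for A, Bacteroidales-like for B) vs the other.
Pathway membership chunks each community's repertoire into 5 synthetic
pathways; CAZy annotations skew glycoside hydrolases (GH) onto community A
and glycosyltransferases (GT) onto B. RFS is exponential with hazard
increasing in w_A, censored by an independent Uniform(12, 60) month
administrative time — roughly 30% censoring, so tests see both events and
censoring. The ground-truth record stores every latent quantity and can
compute the *implied* curve of a community over any sample set (mean/sd of
the equal-weight mixture over per-sample offsets), which is what recovery
tests compare against.

What the generator does **not** emulate: compositional coupling between
communities beyond the two-way weight, strain-level variation, chimeric or
misassigned contigs, GC/length coverage bias, batch effects, or any
HPV/treatment covariates. Passing tests therefore demonstrate the
pipeline's statistical machinery under its own assumptions, not robustness
to real-data artefacts.

*Toy fixture.* The two-metagenome worked example (18 and 19 cells, four
species, circles carrying F1 and ovals F2, one read per gene) is encoded
exactly; the example's original B-side per-function counts are
internally inconsistent with its stated cell total, so B is encoded with
15 F1-cells + 4 F2-cells (honouring the totals, which are stated twice)
and the discrepancy is flagged in the fixture's docstring.

## Problem sizes and determinism

Multi-seed checks (direction recovery, null amplitude ratios, planted-order
detection, Cox coverage) use 10–50 replicate seeds at 200–500 KOs per
community — sizes at which every Monte-Carlo margin asserted (≥ 90% rates,
ratio bounds) held with comfortable slack during development. All
randomness flows through explicit `numpy.random.default_rng` seeds; the
pipeline itself is deterministic given its inputs, and re-running a config
byte-reproduces every table.

## Known limitations

* The Mann–Whitney normal approximation is used at 14 vs 14 even with few
  ties; exact-with-ties is not implemented.
* The decomposition's amplitude estimates are only as good as the KDE;
  heavy curve overlap can zero one amplitude within a group (ratios across
  groups remain usable).
* `cluster_clinical_association` compares only the two main clusters;
  sub-cluster associations must be requested by cutting the tree again.
* The CLI exposes the common paths, not every library option.
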