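# Methods

## Extracellular feature engine

A transmembrane protein is represented by its sequence plus typed topology
segments (extracellular / transmembrane / intracellular, 1-based inclusive
coordinates, UniProt convention). Features are computed over extracellular
segments only, after discarding segments shorter than `min_segment`
(default 10 residues): such stubs sit too close to the membrane to present
meaningful surface chemistry. The filter applies per segment, not to the
concatenation — "subsequence" is read as an individual topology segment —
and qualifying segments are pooled, which is the natural reading given
that all five features are additive in residue composition.

Parameter choices a user may care about:

- **Charge sets.** Positive = {R, H, K}, negative = {D, E}. Histidine is
  counted as positive even though its imidazole (pKa ≈ 6) is only
  partially protonated at physiological pH; the feature is a count of
  potentially positive residues, not a pH-resolved net charge.
- **Weight vector W.** Average molecular masses of the *free* amino acids
  (G = 75.07 Da), configurable to residue (dehydrated) masses via a
  property-table TSV. Absolute EW values (hence median-EW summaries)
  depend on this choice; comparisons between protein groups are
  insensitive to it because the two tables differ by a constant 18.02 Da
  per residue.
- **Hydropathy vector H.** Kyte–Doolittle, the standard hydropathy index.
- **Ambiguity codes** (X, B, Z, J, U, O): excluded from counts and sums
  with a logged warning — a conservative choice; any other letter is an
  error.

EC = EP − EN holds by construction; permutation invariance and additivity
over segment splits are exact and property-tested.

## Expression-weighted sample features

S_EP, S_EN, S_EW, S_EH are plain expression-weighted sums over an
explicitly supplied protein set (in the pipeline: proteins whose genes
pass the DEG rule). The weights are raw TPM values — no z-scoring or log
transform — so the features are exactly linear: homogeneous under global
expression scaling and additive over disjoint protein subsets, which the
tests check to machine precision. Count-scale weights are accepted with a
warning but change the meaning of cross-sample comparisons (library-size
effects).

## Differential expression

The pipeline is deliberately self-contained: DESeq-style median-of-ratios
size factors (reference = per-gene geometric mean over samples, restricted
to genes expressed everywhere; library-size fallback otherwise), then a
two-sided Welch t-test on log2(normalized + 1). log₂FC is computed on
normalized class means with a +1 pseudocount (zero-safe; mildly attenuates
fold changes of low-expressed genes). The selection rule is |log₂FC| ≥ 1
(inclusive) and p < 0.05 (strict), on **raw** p-values — no FDR
correction. That matches the stated thresholds of the analysis this
package implements but deviates from common practice; users scanning many
thousands of genes for discovery should apply their own multiplicity
control. A negative-binomial Wald test can be substituted by plugging an
external DE table into downstream stages (the protein set for aggregation
is an explicit input).

Type-I error of the Welch-on-log pipeline is close to nominal at the
cohort sizes used (44/529 and 30/30 are both tested; ≈5% of null genes at
p < 0.05).

## Co-expression screening

Pearson correlation with the exact t-transform p-value; pairs are retained
only for PCC strictly > 0.6 **and** p < 1e-4, one-sided positive (negative
co-expression is never retained). Constant-expression genes are skipped
with a warning. Caveat: Pearson is outlier-sensitive; on heavy-tailed
expression marginals (e.g. log-normal with σ ≈ 1) a shared extreme sample
can push |r| above 0.6 between independent genes. The null-behavior tests
therefore use light-tailed noise; on real data consider rank-based
correlation or log-transforming first.

## Gene-set score (Fenton-reaction level)

A single-sample, ssGSEA-style rank-weighted running sum: within each
sample genes are ranked by expression (average ranks on ties); walking
from the most- to the least-expressed gene, the score accumulates the
difference between the cumulative weighted-rank distribution of set
members (weight = rank^0.25) and the cumulative uniform distribution of
non-members, normalized by the gene count. It is a monotone rank
statistic: invariant under any within-sample monotone transform and
increasing in the members' ranks. It is a stand-in for GSVA's kernel-based
estimator — the directional claim it supports (higher Fenton-reaction
score in the positive class) is recoverable by any monotone rank score,
and the sample ordering agrees with an independent ssGSEA implementation
(Spearman ρ > 0.9 on a planted fixture, tested).

## Enrichment

Hypergeometric upper tail of the query/set overlap within an explicit
universe; sets are intersected with the universe first; enriched means
p < 1e-4 strict. Collections are user-supplied GMT files.

## Classification

- **Model:** SVC with Gaussian (RBF) kernel, C = 1.0, `gamma="scale"`,
  `class_weight="balanced"` for the ≈1:12 class imbalance.
- **Standardization:** features are standardized by a scaler fit on the
  training fold. This is required, not cosmetic: S_EW is O(1e8–1e9) while
  enzyme TPMs are O(1–100), and an RBF kernel on raw mixed scales reduces
  to whichever feature has the largest variance.
- **SVM-RFE:** the canonical formulation ranks by the squared weights of a
  *linear*-kernel SVM, eliminating one feature per round; an RBF machine
  exposes no per-feature weight, so ranking uses the linear kernel while
  the final classifier stays Gaussian. Constant features are ranked but
  flagged. Ties (e.g. duplicated columns) resolve deterministically by
  column order.
- **Cross-validation:** stratified 5-fold, shuffled with the run seed;
  out-of-fold decision scores are pooled into one ROC curve (deterministic
  and well-defined at small positive counts, unlike per-fold averaging
  with ~9 positives per fold). AUC is the trapezoidal area and equals the
  Mann–Whitney P(score_pos > score_neg) + ½P(tie), tested to 1e-9.
- **Leakage:** feature selection runs inside each training fold by
  default; a feature informative only in its own test fold cannot inflate
  the pooled AUC (probe-tested). `outside_cv=True` mimics a global
  pre-selection for comparison and is leakage-prone by construction.

## Net-proton reaction accounting

Reaction strings ("A + 2 B → C + H+") are parsed into stoichiometric term
lists; " + " with surrounding spaces separates terms, so species-internal
plus signs (NAD+, H+) and internal linkage arrows ("(1<->1')") survive.
Only explicit proton species count — spellings "H+", "H^+^", "H⁺" are
normalized — and water/hydroxide are never decomposed. Net H⁺ = product
minus substrate proton coefficients; producing/consuming/neutral follows
the sign. Bidirectional arrows are rejected (the packaged table uses only
forward reactions). The packaged table lists the 16 proton-producing
reactions catalyzed by enzymes upregulated in brain-metastasized primary
tumors, with group-median TPMs.

## Synthetic cohorts: what they emulate, and what they do not

Counts are negative binomial (variance = μ + αμ², α = 0.2 by default,
typical of inter-patient bulk RNA-seq) with log-normal gene means
(meanlog = ln 100, sdlog = 1) and log-normal library factors (sdlog =
0.15). The TPM-like matrix divides counts by simulated gene lengths
(uniform 500–5000 nt) and rescales columns to 1e6. Class structure:
44 positive vs 529 negative samples; 100 planted transmembrane DE genes
(97% down in the positive class), 20 informative enzymes (up in the
positive class) among 200 enzyme genes; negative-class destination
subgroups (bone/liver/lung, proportions 113:215:261 normalized) carry no
planted signal. The planted |log₂FC| defaults to 1.5: an effect exactly at
the selection threshold of 1 would be recovered only ~half the time under
symmetric estimation noise, while 1.5 sits clearly beyond it; the
enzyme-gene count is scaled down from the ~2,800 of a genome-wide
catalogue to keep recursive elimination at one-feature-per-round desk
sized, preserving the 1:10 informative-to-background structure.

Protein records sample residues with probability ∝ exp(0.1·KD), a mild
hydrophobic tilt (mean KD ≈ +0.4 per residue) so that summed extracellular
hydropathy — and hence S_EH — is positive in expectation and planted
downregulation lowers *all four* sample features in the positive class.
Real extracellular domains are on average hydrophilic (negative EH), so
absolute EH/S_EH levels in the synthetic data are not representative;
orderings driven by expression differences are.

Not emulated: tumor purity, batch effects, multi-destination metastases,
correlated gene-gene structure beyond the planted means, and survival.
Consequently, passing tests demonstrate that the machinery recovers
planted structure under idealized NB noise at realistic sample sizes — not
that the biological claims hold on real cohorts, which require TCGA-scale
data and curated annotations.

## Problem sizes and determinism

Default test and pipeline runs use the 573-sample cohort with 2000 genes
and 200 enzymes; the classifier block over five seeds (three feature
configurations plus a permutation null) completes in well under five
minutes on one CPU. Every stochastic step — cohort draws, fold shuffling,
permutations — derives from a single integer seed, and identical
configurations reproduce byte-identical artifacts (tested). Degenerate
inputs fail loudly: inverted coordinate ranges, classes smaller than the
fold count, empty gene-set intersections, missing feature genes (listed by
name), single-class ROC input.

## Known limitations

- Raw p-values by design (see above).
- The Welch-on-log DE test is not a negative-binomial Wald test; at very
  small counts or extreme dispersion its power differs from DESeq-style
  models.
- The gene-set score reproduces GSVA only directionally, not numerically.
- Reaction accounting is bookkeeping over explicit proton terms; it does
  not balance mass or charge and ignores pH-dependent protonation.
- With 4 physical features and ~9 positives per fold, single-run null AUC
  has a standard deviation near 0.05; null statements are made about
  means over seeds.
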