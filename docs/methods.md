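# Methods

This note records the models, conventions and design choices behind
`correaevo`, at the level of detail a maintainer or reviewer needs to
judge what the package computes and what its passing tests do and do not
establish.

## Problem setting

Matched specimens from the Correa cascade — normal mucosa (NM),
intestinal metaplasia (IM), low-grade and high-grade intraepithelial
neoplasia (LGIN, HGIN) and early gastric cancer (EGC) — are sequenced per
stage for the same patient. The analysis asks three questions: which
genes and pathways are altered at each stage; how genomically similar
each precursor stage is to the patient's EGC; and which of three
evolutionary modes best describes the patient's cascade — linear
(LGIN → HGIN → EGC), punctuated (EGC seeded directly from the LGIN
clone), or independent (EGC from a lineage separate from both
precursors). A companion validation module evaluates TP53/PRKDC/PCLO
marker status as a predictor of LGIN progression.

## Somatic filter cascade

Candidate calls (VarScan2-style, minimum VAF 2%) pass rules evaluated in
a fixed order, each rejected record carrying the first failing rule:
`min_vaf` (< 2%), `min_depth` (< 20), `min_base_quality` (< 15),
`min_alt_reads` (< 5), `both_strands` (support on one strand only),
`strand_bias`, `population_frequency` (> 1% in 1000 Genomes, ExAC ALL or
ExAC EAS), `blacklist`. Conventions the rule list does not pin down:

* **Strand bias ≤ 10%** is read as the minor-strand share of supporting
  reads, `min(fwd, rev) / alt_reads ≥ 0.10`. This makes the
  both-strands rule a weaker special case, consistent with the rules'
  ordering; the fraction is configurable.
* **Missing population frequencies pass** the frequency rule: absence
  from the databases is precisely how novel somatic variants present.
* **The blacklist is an input**, a user-supplied site list; the package
  does not reconstruct the normal pool behind it.
* **Variant identity** is `(chrom, pos, ref, alt)`, 1-based VCF
  coordinates; gene and effect annotations are carried metadata.
  Multi-allelic VCF records are decomposed before filtering.
* A record with zero depth but non-zero supporting reads is a data
  integrity error, not a filter rejection.

Sample-level QC: lesions need > 200× pre-deduplication and > 60×
post-deduplication mean coverage (normals > 100×/> 30×), and a total DNA
damage OScore ≥ 35 in either role. The OScore itself is consumed as an
input; its computation (a Picard-style damage estimate) is not
reimplemented.

## Variant-presence posterior

Sharing statistics are distorted when a truly shared variant falls just
below the calling threshold in one stage. The presence model scores each
(variant, lesion) cell from raw evidence — depth `d`, alt reads `a` —
by comparing two hypotheses: absent (`a ~ Binom(d, ε)`, sequencing error
only) and present, with the true variant fraction `f` uniform on
`[f_lo, f_hi]`, giving the marginal likelihood
`L1 = mean_f Binom(a; d, f)`. With prior π the posterior is
`πL1 / (πL1 + (1−π)L0)`.

Defaults: π = 0.5 (symmetric), ε = 0.005 (typical FFPE error after
deduplication), f ~ U(0.05, 0.5) (clonal heterozygous variant under
partial purity), 200 quadrature nodes. The prior average is evaluated by
Gauss–Legendre quadrature on the configured number of nodes; because the
integrand is a polynomial of degree `d` in `f`, 200 nodes are exact up
to d = 399 and near machine precision beyond, which the test suite
verifies against the independent closed-form incomplete-beta solution to
1e−6. Likelihoods are computed in log space so deep coverage cannot
underflow. Binary presence calls threshold the posterior at 0.5
(configurable); cells with no called variant and no pileup lookup are
flagged missing, never imputed.

This is a deliberately transparent simplification of tree-based
multi-sample callers: no neoplastic-content estimation, no phylogenetic
tree search. The pipeline's similarity statistics therefore default to
raw filtered calls, with the posterior available as an alternative
presence definition.

## Similarity, tiers and trajectory calls

Jaccard similarity and the "concordance ratio" are one formula —
`|A∩B| / |A∪B|` — presented as a fraction or a percentage of the shared
plus discordant variants; genetic distance is the symmetric-difference
count, so `J = 1 − distance/union`. CNV events compare on
`(gene, direction)`. NM-control variant keys are subtracted from every
lesion set by default (the NM sample is the germline/artifact
background); a flag disables this.

Concordance tiers count precursor stages at or above a 20% concordance
threshold with EGC (boundary inclusive): CT1 ≥ 2 stages, CT2 exactly
one, CT3 none.

The trajectory rule, applied to `(J_LE, J_HE, J_LH)`:

1. **independent** iff `J_LH > max(J_LE, J_HE)` **and**
   `max(J_LE, J_HE) < floor`;
2. else **linear** iff `J_HE ≥ J_LE`;
3. else **punctuated**.

The floor quantifies "limited similarity to EGC"; it is not derivable
from the rule's verbal description, so it is an explicit parameter,
default 0.15, chosen midway between the EGC similarities the generator's
independent model produces (≈ 0.03) and its progression models' weakest
EGC similarity (≈ 0.19), and exposed in configuration. Ties resolve
conservatively toward the majority (linear) model: `J_HE = J_LE` is
linear, and `J_LH` equal to the EGC maximum is not independent. The rule
is scale-free (multiplying the triple and floor by a common factor
preserves the call), IM participates in pairwise matrices but not in the
rule.

Patient clustering uses agglomerative average linkage on Euclidean
distances between concordance vectors (linkage and metric are
conventional choices, configurable at the call site), with a
deterministic leaf order and a Newick export of the dendrogram.

## Landscape and enrichment

A patient is "mutated" in a gene at a stage when the kept calls include
≥ 1 non-synonymous small variant (missense, nonsense, frameshift,
splice-site, in-frame indel) — the oncoplot convention; synonymous
variants never count and CNV events are excluded from frequency counts
by default. Top-n rankings break ties alphabetically. Stage contrasts
are two-sided Fisher tests on mutated/not-mutated counts.

A pathway is **abnormal** in a sample iff one or more of its genes is
mutated. The ten canonical oncogenic pathway gene sets ship as an
editable GMT seeded with each pathway's well-established core members
(cell cycle, Hippo, Myc, Notch, Nrf2, PI3K, RTK-RAS, TGF-β, TP53, WNT);
no external service is queried at run time. Over-representation uses the
upper hypergeometric tail P(X ≥ k) with the collection's gene universe
as background, flagged at unadjusted p < 0.01; a Benjamini–Hochberg
column is available but off by default.

## Instability indices

The four indices use declared textbook definitions (each switchable, and
named in the output): TMB = non-synonymous mutations per callable
megabase (default 35 Mb exome); CIS = genome-length fraction in segments
with |log2 ratio| ≥ 0.2; LOH = genome-length fraction with minor copy
number 0; ITH = MATH score, `100·1.4826·MAD(VAF)/median(VAF)`, requiring
≥ 3 positive VAFs. Their absolute values are definition-dependent;
the tested claims are relative (e.g. rising CIS/LOH trends across the
cascade), not absolute reference values.

## Statistics kit

* **Fisher exact, two-sided**: sum of hypergeometric probabilities of
  all same-margin tables whose point probability does not exceed the
  observed one (with 1e−7 relative slack for floating-point pmf noise;
  a full-support sum snaps to exactly 1). The point-probability rule is
  stated because other two-sided conventions exist and give different
  values. Verified against exact integer-arithmetic enumeration for
  every table with N ≤ 60.
* **Wilcoxon rank-sum**: exact by full enumeration when the smaller
  group has ≤ 8 observations and the pooled data are untied (two-sided p
  is twice the smaller tail, capped at 1); otherwise a normal
  approximation with tie and continuity corrections.
* **Kruskal–Wallis + Dunn**: tie-corrected H against χ²(k−1); Dunn z
  from the pooled-rank variance with tie correction, unadjusted by
  default (Holm/Bonferroni optional, via statsmodels).
* **Cuzick trend**: `T = Σ_g z_g R_g` over pooled mid-ranks with group
  scores defaulting to 1..k in the Correa order; z from the tie-corrected
  permutation-null mean and variance; two-sided normal p. For small
  samples an exact mode enumerates the full assignment null of T
  (≤ 200,000 arrangements) and reports the two-sided tail by distance
  from the null mean — at N = 12 the discrete null makes the normal
  approximation coarse at the 0.005 level, so oracle-agreement tests use
  the exact mode. Degenerate inputs (all observations equal) are flagged
  with p = 1.

## IHC scoring and marker evaluation

TP53 is mutant-type for > 50% diffuse strong nuclear positivity
(missense pattern) or complete absence (nonsense pattern), wild-type
otherwise. PRKDC sums a percent-positive score (< 5% → 0, 5–25% → 1,
25–50% → 2, ≥ 50% → 3; boundaries lower-inclusive at 5% and 25%, since
the printed ranges overlap at their endpoints) and an intensity score
(none 0, light yellow 1, brown-yellow 2); sums ≤ 3 are negative. MMR is
deficient when any of MLH1/PMS2/MSH2/MSH6 lacks expression. PCLO has no
published rubric and is consumed as a provided binary status.

Marker rules are evaluated against the binary progression outcome:
sensitivity = positive fraction among progressors, specificity =
negative fraction among stable patients, with a Fisher contrast;
`"A or B"` is positive when either component is.

## The cohort simulator

The generator's defaults are the emulated study conditions: 14 patients,
an 8/3/3 linear/punctuated/independent mixture, NM + four lesion stages,
~150 variants per stage (the reference cohort's per-stage totals divided
by 14 give 112–203), 300× mean depth within the 200–500× band the
protocol targets, purity 0.8, error rate 0.005, C>T-dominant
substitutions, and driver genes (TP53, PRKDC, PCLO, DNAH5, APC) with
stage-increasing hit probabilities seeded from the stage frequencies
reported in gastric carcinogenesis cohorts.

Sharing structure per model (fractions of the per-stage budget): linear
trunk 0.30 with an extra HGIN∩EGC branch of 0.25; punctuated moves that
branch to LGIN∩EGC; independent has a 0.40 LGIN∩HGIN pool with only
0.02–0.03 of trunk/EGC overlap. IM shares ~1% with EGC. Read evidence
per variant is depth ~ Poisson(mean) and alt ~ Binomial(depth,
VAF·purity) with a balanced binomial strand split; each sample adds
~10 background error-rate sites and ~5 NM-shared artifact sites (what NM
subtraction removes). Variants live on a synthetic 35 Mb exome (seven
5 Mb contigs tiled into 50 kb gene bins, the first bins reserved for the
driver genes). CNV events reuse the mutation sharing skeleton on
(gene, direction) keys; per-stage segment sets carry rising alteration
and LOH probabilities so instability trends are testable. A fixed seed
reproduces the whole cohort byte-for-byte, including emitted VCFs.

What the simulator does **not** emulate: subclonal phylogenies beyond
stage-set sharing, mutational signatures beyond the substitution-type
weights, copy-number segmentation noise, purity variation within a
lesion, and alignment-level artifacts. Passing recovery tests therefore
show the pipeline is correct and well-calibrated under the stated
generative model — not that real cascades are this cleanly separated;
on real data the trajectory floor and the filter thresholds carry real
degrees of freedom.

## Problem sizes and numerics

The acceptance script and test suite use: 100 simulated patients per
trajectory model plus 50 seeds of the 14-patient mixture (recovery),
10,000 candidates for the filter oracle, nine patients at 200× for
presence calibration, 2,000 null cohorts of 4 × 14 for the Cuzick
type-I error, a 10⁵-draw Monte-Carlo permutation oracle on a 3 × 4 toy,
and the exhaustive 635,375-table Fisher grid at N ≤ 60 — sizes chosen so
the whole run completes in about 90 seconds while leaving Monte-Carlo
margins an order of magnitude smaller than the tested thresholds.
Floating-point conventions worth knowing: concordance percentages round
to two decimals; VCF emission stores float fields as 32-bit (the
simulator quantizes base qualities so files round-trip exactly); TSV
emission uses 17-significant-digit floats with round-trip parsing.

## Known limitations

* The presence model ignores neoplastic cell content and copy number at
  the site; its posterior is only as calibrated as the uniform-VAF prior.
* The trajectory rule is a deterministic partition of the Jaccard
  triple; it reports no uncertainty, and patients near the floor or near
  J_LE ≈ J_HE flip calls under resampling noise.
* CIS/LOH/ITH absolute levels depend on the declared definitions and
  are not comparable across pipelines without aligning those choices.
* The bundled pathway GMT is a curated seed of core members, editable by
  design; enrichment universes should be replaced with the user's own
  callable gene set for real analyses.
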