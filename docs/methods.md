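# Methods

## Model and procedure

`chemoselect` analyses cohorts in which each patient contributes three
exome call sets: normal tissue, tumour before chemotherapy, and tumour
after chemotherapy.  The underlying model is clonal selection: a somatic
variant carried by a clone that therapy depletes falls in prevalence
between the two tumour samples; a variant carried by a surviving or
expanding clone rises.  Prevalence is observed through the mutant allele
frequency (MAF = alt reads / total reads).  Because the samples are
assumed to be essentially pure tumour cell populations (as obtained by
laser-capture microdissection), no purity or copy-number correction is
applied and raw MAFs are treated as comparable between timepoints; for a
heterozygous somatic variant in a pure diploid tumour, MAF ≈ CCF/2, where
CCF is the fraction of cancer cells carrying the variant.

The stages, in execution order:

1. **Hard filter** — keep calls with 5 ≤ depth ≤ 800 and QUAL ≥ 30
   (inclusive bounds; a missing QUAL fails the filter).  Applied
   identically to tumour and normal samples.
2. **Somatic definition** — exact key subtraction of germline calls,
   where a key is (chrom, pos, ref, alt) after multi-allelic splitting
   and parsimony trimming.  Matched mode subtracts the patient's own
   normal; pooled mode subtracts the union of all normals' post-filter
   keys.  Pooling is motivated by the heterozygote-miss model: with fair
   allele sampling, a het site shows zero alt reads with probability
   (1/2)^n at depth n (`het_miss_probability`), so a 15-read normal
   misses ~0.003 % of het sites — hundreds of variants against the
   4.1–5 million non-reference positions of a typical germline
   (`expected_missed_germline`, which assumes the all-heterozygous worst
   case).  The miss model deliberately ignores base error and mapping
   bias.  Pooled mode is the default.
3. **Selection classification** — per patient, each somatic variant seen
   at either timepoint is classified once: present only pre → group A;
   present only post → group B; present at both → A if ΔMAF < −t, B if
   ΔMAF > +t, otherwise unchanged.  "Present" means called *and*
   surviving the hard filter, so a variant filtered at one timepoint
   counts as unique to the other.  The threshold t is an absolute MAF
   difference, default 0.05, with strict inequality.  At exact float
   equality with the threshold a variant is unchanged; the boundary is
   float-sensitive, as with any strict comparison on ratios of read
   counts.
4. **Gene recurrence** — selected variants map to genes through a
   user-supplied variant→gene table (a variant mapping to several genes
   supports each; unmapped variants are reported, never silently
   dropped).  A (gene, direction) entry is recurrent when its variants
   occur in ≥ 2 different patients (patients, not variants, are
   counted).  Recurrent entries form list C; a gene recurrent in both
   directions contributes two entries but one distinct gene and is
   flagged, since simultaneous gain- and loss-of-function selection on
   one gene is considered unlikely.  Genes with variants in both
   directions but no single-direction recurrence are reported and
   excluded.
5. **Enrichment** — one-sided hypergeometric over-representation of the
   A, B and C gene lists against a GMT collection, with BH step-up
   adjustment across the sets tested for each list.  The default
   universe is the set of gene symbols appearing in the variant→gene
   table; set members outside the universe are ignored in both K and k.
6. **Priority score** — `n_patients + n_damaging + 1[pathway]` per
   recurrent entry.  A variant is damaging when SIFT < 0.05 (strict) or
   PolyPhen2 calls it possibly or probably damaging; counting "possibly"
   as damaging is configurable (`count_possibly`).  `n_damaging` counts
   damaging variants, not patients, so it can exceed `n_patients`.  The
   pathway bonus goes to genes belonging to any of the top-3 enriched
   sets of lists A, B or C *that are also significant* (BH q <
   `pathway_q_max`, default 0.05).  The significance gate is this
   package's design choice: the bonus is meant to reward membership of a
   genuinely over-represented pathway, and without the gate the top-3
   sets of a noise-dominated list hand the +1 to an arbitrary fraction
   of the universe (`pathway_q_max: 1.0` restores the plain top-3
   rule).  Ties beyond the score order (patients, damaging, pathway
   flag) break alphabetically so output is deterministic.  Entries with
   score ≥ 5 (configurable) form the highest-priority candidates.
7. **Outcome validation** — for each candidate gene in an expression
   cohort (z-scores plus survival time and a died-of-disease indicator):
   AUC for discriminating died vs alive/lost, computed by the rank
   (Mann–Whitney) identity and oriented ≥ 0.5; an expression cutpoint
   maximising Youden's J over midpoints between adjacent observed
   values (ties in J break toward the more balanced split, then the
   lower cutpoint); a two-sided Mann–Whitney U test between the two
   status groups — exact enumeration for pooled n ≤ 20 without ties,
   otherwise tie-corrected normal approximation with continuity
   correction; Kaplan–Meier curves and a two-group log-rank test (χ²,
   1 df) on the dichotomized groups.  Mann–Whitney p-values are BH
   adjusted across the genes tested and a gene is significant only if
   raw p < 0.05 *and* q < the FDR threshold (default 0.05).  Alive and
   lost-to-follow-up patients are censored.  The Mann–Whitney p doubles
   as the ROC p-value via the standard AUC/U equivalence.  Constant
   expression yields AUC 0.5 and no cutpoint split; a dichotomization
   leaving one group empty yields an undefined (NaN) log-rank p; groups
   with no events give χ² = 0, p = 1 by convention.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `min_depth`/`max_depth` | 5 / 800 | inclusive read-depth bounds (reads) |
| `min_qual` | 30 | Phred quality floor |
| `subtraction_mode` | pooled | germline definition (matched or pooled) |
| `maf_delta_threshold` | 0.05 | absolute MAF change for selection (strict) |
| `min_patients` | 2 | recurrence requirement for list C |
| `sift_cutoff` | 0.05 | SIFT damaging bound (strict) |
| `priority_threshold` | 5 | minimum additive score for top candidates |
| `enrichment_top_n` | 3 | sets per list eligible for the pathway bonus |
| `pathway_q_max` | 0.05 | significance gate on bonus-eligible sets |
| `fdr_threshold` | 0.05 | BH threshold in outcome validation |

## The synthetic-data generator

`SyntheticCohortConfig`/`generate_cohort` emulate the statistical
structure the analysis assumes, at desk scale, with full planted truth:

* **Cohort**: 6 patients; six planted drivers spanning the design space —
  losses to zero at recurrence 2–3 (CCF 0.6→0), a partial loss 0.6→0.3
  (recurrence 3), a strong loss 0.7→0.1 (recurrence 4), and gains
  0.2→0.8 / 0.2→0.7 (recurrence 2–3).  Passengers (120 per patient) draw
  CCF ~ U(0.1, 0.9) and drift between timepoints with σ = 0.02 — well
  below the classification threshold, so passenger entries into lists
  A/B arise from read-sampling noise, as they would in real data at
  ~30× depth.
* **Genome scaffold**: 2000 gene symbols with disjoint loci.  The size
  is chosen so that the rate of chance same-gene collisions among a few
  hundred selected variants is comparable, relative to scale, to an
  exome: collision-driven recurrent genes appear (tens per run, mirroring
  the noise the method must tolerate) without swamping the planted
  signal.
* **Germline**: per patient 400 het + 150 hom sites drawn from a shared
  pool of twice that size, so common variants recur across patients and
  the pooled union strictly exceeds each matched set.  Reads at a site
  are Poisson(depth) truncated ≥ 1 with binomial alt counts at the
  error-adjusted allele frequency; a variant is "called" only when ≥ 1
  alt read is observed, which reproduces the (1/2)^depth heterozygote
  miss mechanism exactly.  2 % of calls receive decoy QUAL < 30 to
  exercise the filter.
* **Annotations**: driver SIFT ~ U(0, 0.05) and mostly
  probably-damaging PolyPhen2 calls; passenger SIFT ~ U(0.05, 1) with
  PolyPhen2 benign/possibly/probably at 0.90/0.07/0.03 (≈10 % of
  passengers damaging by the either-tool rule, a deliberate noise
  floor).
* **Pathways**: one planted set holding all driver genes plus 4 random
  extras, among 30 random decoy sets of 15–25 genes.
* **Survival cohort**: n = 300, one z-scored expression column per
  driver plus 8 null genes; event times exponential with log-hazard
  log(1/120 months⁻¹) + log(2)·z per planted prognostic gene, censoring
  uniform on (1, 240) months.

Identical configuration and seed give byte-identical files (a single
`numpy.random.default_rng` stream with fixed iteration order).

What the generator does **not** model — and hence what passing tests do
not show about real data: impure tumours and stromal contamination,
copy-number alterations and non-diploid MAFs, subclonal phylogenies,
mapping artifacts and systematic sequencing error, indel realignment
ambiguity beyond parsimony trimming, linkage between germline sites, and
correlated gene expression in the survival cohort.  True left-alignment
of indels additionally requires the reference sequence, which is not
among the pipeline inputs; parsimony trimming (strip shared suffix, then
shared prefix) canonicalises padded representations, which is sufficient
for self-consistent call sets.

## Numerical and design choices

* Burden summaries round half away from zero (so a mean of 290.5 reports
  as 291); mean percent change is computed per sample against the
  matched-mode count, then averaged; samples with a zero matched count
  are excluded from that column's mean with a warning.
* Duplicate variant keys within one VCF keep the highest-QUAL record.
* The hypergeometric upper tail is computed with `scipy.stats.hypergeom`
  (exact, log-space internally); BH, Kaplan–Meier, log-rank and the ROC
  scan are implemented directly and cross-checked in the test suite
  against statsmodels, lifelines and exhaustive/permutation oracles.
* Enrichment results sort by (p, set id); all determinism-sensitive
  orderings carry an explicit final tie-break.
* Problem sizes in the test suite (cohort scale, 25 seeds for
  recovery properties, 500 null cohorts for the type-I check, 10⁵
  permutation resamples) were chosen as the smallest scales at which the
  statistical assertions have comfortable Monte-Carlo margins.

## Known limitations

* MAF-based selection cannot separate clonal dynamics from copy-number
  change; the pipeline assumes none.
* Exact-key germline subtraction cannot remove germline variants
  represented differently by the caller across samples (beyond
  parsimony trimming) and performs no population-frequency filtering.
* Pooled subtraction can delete a true somatic variant that coincides
  exactly with another patient's germline variant; this is accepted as
  the cost of suppressing het-miss false positives.
* The enrichment stage is a plain over-representation test: no ontology
  propagation, no rank statistics, and results depend on the chosen
  universe and GMT collection.
* Outcome validation treats genes independently; no multivariate or
  Cox-style adjustment is attempted.
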