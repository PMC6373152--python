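# Methods

## Editing measurement model

Every analysis starts from per-site base counts: for sample *s* and genomic
adenosine *j* the caller table supplies the sense-oriented tallies
`(A, C, G, T)` of the reads covering the position. The per-site editing
level is the canonical `G/(A+G)`; it is *undefined* — not zero — when no
A or G read covers the site, and undefined cells are excluded from all
downstream statistics. Coverage `A+C+G+T` is retained separately.

Coordinates are 1-based in site tables (the caller dialect) and 0-based
half-open in interval files (BED); conversion happens only at the file
boundary. The reader trusts the producing tool's strand resolution and never
re-complements counts. The mapping/base-quality thresholds (defaults 60 and
30) gate rows only where the table carries the necessary column (MeanQ);
mapping quality is not present per row, so that filter is recorded as
unenforceable instead of being silently approximated.

## Pooled editing indexes

All four indexes are *weighted averages* in the pooled-count sense: reads
are summed over the selected sites before a single division, so highly
expressed sites dominate and barely covered sites cannot inject noise.

| index | site selection | denominator |
|---|---|---|
| AEI | every measured adenosine inside an Alu interval, SNP-masked | `Σ (A+C+G+T)` |
| nREI | catalog sites in non-repetitive regions | `Σ (A+G)` |
| REI | catalog recoding sites (any region class) | `Σ (A+G)` |
| DEI | discovered subtype-discriminating sites | `Σ (A+G)` |

The two denominators are deliberate: the AEI is a transcriptome-scale
mismatch ratio over all aligned bases, whereas the catalog indexes pool the
per-site editing level. The AEI applies no coverage floor (it must remain a
per-read ratio over all Alu adenosines, cataloged or not); the catalog
indexes apply the 10-read site floor by default, configurable. An index
whose denominator is empty is NaN, never 0. Indexes are stored as fractions
in [0, 1]; reports render percentages.

## Differential recoding analysis

A sample *supports* a site when coverage ≥ 10 and editing ≥ 1 %; a site is
*informative* when supported by ≥ 2 samples in **each** group (the rule is
conjunctive — both groups must be estimable). Unsupported cells are missing
data in group medians. Informative sites are tested with a two-tailed
Mann-Whitney U (exact null distribution when the pooled size is ≤ 20 with no
ties, otherwise a tie-corrected normal approximation with continuity
correction; the reported U is `min(U_x, U_y)`), corrected across sites with
Benjamini-Hochberg step-up. Direction calls (over-/under-edited in group 1)
require q ≤ α (default 0.05); the "top site" gate additionally requires
|Δ median| ≥ 0.15. Both gates are parameters. The 1 % frequency threshold is
applied per sample, matching the support-rule phrasing.

## Stratification

Signature sites are those detected (non-missing) in at least a 140/145
fraction of the cohort — expressed as a fraction so the rule transfers to
any cohort size — and located in exons, introns or UTRs. Missing cells
among signature sites are imputed with the per-site median (deterministic
and structure-preserving; the choice is ours, since nothing in the method
definition pins it down). Euclidean sample distances are agglomerated with
the **ward.D** criterion: the Lance-Williams update applied to the
*unsquared* distances, the convention of R's `hclust(method="ward.D")`,
implemented directly because SciPy ships only the squared-distance Ward-D2
variant (the implementation is verified against `hclust` and against the
SciPy root-transform equivalence). Ties in the merge order break on the
smallest cluster-id pair, and the tree is cut by merge order (union-find),
which remains well defined even under height inversions. At k = 2 the
cluster with the higher grand-mean editing over the signature sites is
INO-1; an exact tie falls back to the cluster holding the lexicographically
smallest sample id, with a warning.

DEI site discovery runs every pairwise subtype contrast per non-repetitive
site and selects a site significant in ≥ 1 contrast; multiplicity is
controlled across sites within each contrast (BH by default, raw p
optionally). Raw frequencies are clustered, not standardized values (a
`--standardize`-style transform can be applied upstream if desired).

## Ordination

Nonmetric MDS uses `1 − Spearman ρ` between sample editing profiles
(pairwise-complete) as the dissimilarity. The optimizer is an explicit
SMACOF loop: isotonic regression of configuration distances on the
dissimilarity order produces the disparities, a Guttman transform updates
the configuration, and Kruskal stress-1
`sqrt(Σ(d − d̂)² / Σ d²)` is tracked per iteration (the trace is part of the
result, and is non-increasing on well-posed inputs). Defaults: 2 dimensions,
first start from classical scaling and the remaining restarts random
(default 8 in the pipeline, 20 in the library function), 300 iterations
maximum, stop when the stress change falls below 1e-7. A constant sample
profile makes ρ undefined and is a fatal error naming the sample.

## Survival

High/low groups come from an inclusive threshold (value ≥ cutoff is high,
matching the "≥ 40 %" site-level convention). The default AEI
dichotomization is the per-sex median — fixed published cutoffs are
cohort-specific, while the per-sex median reproduces the near-half splits
those cutoffs produce — with a flag for a fixed value. Kaplan-Meier and the
two-group log-rank (observed − expected with hypergeometric variance,
χ² with 1 df) are computed directly in NumPy: both are a few lines over the
risk-set table and the calibration suite runs thousands of replicates;
lifelines is the cross-check in the tests and provides the Cox
proportional-hazards fits (Efron tie handling, Wald CIs, complete cases per
model). Sex strata with fewer than 4 analyzable samples are skipped;
degenerate splits refuse to test rather than return a meaningless p.

## Synthetic cohorts

The generator emulates the statistical structure the analyses assume:

* **catalog** — ALU/REP/NONREP sites on a synthetic chromosome, ALU sites
  inside emitted 300-bp Alu intervals, recoding flags per class (defaults
  0.10/0.05/0.40, echoing the observed preponderance of non-repetitive and
  Alu recoding sites), genic features, plus decoy heterozygous SNP
  positions inside Alu elements that mimic ~50 % editing until masked;
* **counts** — coverage ~ NegBin(mean 50, dispersion 5); the editing rate
  of sample × site is `expit(site baseline + shifts + sample offset +
  jitter)` with logit-normal site heterogeneity (sd 0.5), per-sample offset
  (sd 0.15) and per-cell jitter (sd 0.3) — beta-binomial-like
  overdispersion with analytically computable means; edited reads are
  binomial in the A+G portion, with a 0.2 % non-A/G noise rate;
* **effects** — class baselines 1.5 %/3 %/12 % (ALU/REP/NONREP), a broad
  tumor under-editing shift of −1 logit on 80 % of sites (tumor indexes
  fall to roughly half of normal, as in real glioma cohorts), 2 over-edited
  recoding sites at +1.2 logit, and a two-cluster tumor substructure
  (+0.15 frequency at 50 genic signature sites in half the tumors);
* **clinical** — exponential overall survival with log-hazard
  `β_sex · z(AEI)` (defaults β_male = −0.8, β_female = +0.8: high Alu
  editing protective in males, harmful in females), uniform censoring to a
  30 % rate, 60 % male cohort, independent binary molecular covariates at
  literature-scale prevalences.

Default scale (60 tumors + 40 normals, 500 sites) runs in well under a
minute; the calibration and recovery tests use smaller variants of the same
generator. All randomness flows from the single config seed, and every
emitted file records it.

What the generator does **not** emulate: genomic linkage between sites,
editing–expression coupling, realistic coordinates or read-level artifacts
(mapping bias, strand errors). Passing recovery tests therefore demonstrate
correctness of the statistical machinery under the stated generative model,
not robustness to alignment-level confounders.

## Numerical choices and degenerate inputs

* Empty index denominators, all-identical Mann-Whitney inputs (p = 1),
  zero-event log-rank (p = 1 with warning) and constant Cox covariates are
  all handled explicitly rather than raised from library internals.
* BH q-values are clipped at 1 and returned in input order; p-values are
  clipped away from 0.
* Non-converged or singular Cox fits are flagged per term, not raised.
* Pipeline outputs are written with a fixed `%.10g` float format, making
  two runs from identical inputs and seed byte-identical (the manifest,
  which records wall-clock timings, is the one deliberate exception).

## Known limitations

* Mann-Whitney exact enumeration is capped at pooled n = 20; beyond that
  the tie-corrected normal approximation is used even when an exact test
  would be feasible.
* The informativeness rule assumes exactly two groups; multi-group designs
  are handled only through pairwise contrasts (subtype discovery).
* Cox fits use complete cases per model; no imputation of molecular
  covariates.
* Hyper-editing (clustered edits invisible to standard alignment) and any
  expression-level analyses are out of scope.
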