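# Methods

`endopanel` re-implements, as a tested pipeline over synthetic data, a
targeted-panel tumor/normal analysis of endometrial carcinoma: somatic
variant discovery and review, a pathogenicity filtering/tiering cascade,
substitution-spectrum-based molecular group assignment with POLE hotspot
assessment, and the univariate clinicopathologic statistics. This note
describes the models and rules, the tunable parameters and their
defaults, what the synthetic-data generator does and does not emulate,
and the design decisions taken where the procedure was genuinely open.

## Somatic discovery

Two workflows run per sample pair and are merged:

* **Paired workflow** — a tumor call is somatic when the site is absent
  from the matched normal or present below the germline allele-fraction
  threshold.
* **Single-sample workflow** — tumor calls whose key (chrom, pos, ref,
  alt) does not appear in the normal call set at all, with no fraction
  threshold; quality problems are deferred to review.

Calls found by only one workflow must be present in the raw caller
output (a key lookup standing in for the caller's native file) or they
are excluded as unverified. The merged set then passes a programmatic
review emulating sequence-level visual inspection: calls flagged
`low_quality` or `sequencing_error` upstream are excluded for quality,
and calls with normal-tissue evidence at or above the germline threshold
are excluded as germline. Survivors are the sample's **unfiltered
somatic variants** — the burden statistic used everywhere downstream.

The original review criteria are qualitative (performed by eye in a
genome viewer); the numeric stand-ins are configuration with defaults
`germline_af = 0.10` (allele fraction at which a call is "visibly
present" in the normal) and `min_depth = 20` (below this the normal
gives no usable evidence). Both are recorded in output metadata. The
review is idempotent, and retained ⊆ merged ⊆ (paired ∪ single) holds by
construction and is property-tested.

## Filtering and tiering

Standard filters remove calls with caller p-value > 0.05 or population
minor allele frequency > 1% (both strict, matching the stated
inequalities), and route synonymous calls to a separate predictor
stream. Missense survivors are scored by the two impact predictors:
SIFT < 0.05 and PolyPhen-2 ≥ 0.5 each call deleterious; concordantly
benign calls (SIFT > 0.05 **and** PolyPhen < 0.5) are filtered out;
discordant calls are retained for further investigation.

Tier assignment, in order, with each firing clause kept in a rule trace:

1. ClinVar *pathogenic* → **pathogenic** (an assertion dominates scores).
2. ClinVar *benign* → reported benign-annotated, excluded from the
   pathogenic/candidate streams. This mirrors the handling of the benign
   POLE catalytic-domain variant that SIFT alone calls deleterious.
3. Concordantly benign predictions → filtered out.
4. COSMIC occurrence count > 500 → **pathogenic**.
5. Driver-INDEL catalog (dbCID): exact allele entry → **pathogenic**;
   a same-gene interval overlapping the INDEL's span with a different
   allele → **candidate**. The source procedure consults the catalog but
   does not state how its entries combine with the tiers; this mapping
   (a catalogued driver allele is treated as pathogenic evidence, an
   overlapping locus as candidate-level evidence) is this package's
   design choice.
6. Deleterious predictor evidence — concordant, or discordant with at
   least one deleterious call — → **candidate**.
7. COSMIC count 1–500 → **candidate**.
8. Otherwise → variant of uncertain significance (VUS).

A COSMIC count of exactly 500 is not covered by the stated "> 500" /
"fewer than 500" phrasing; it falls to the candidate clause and the
trace records the clause that fired. "Filtered somatic SNVs/INDELs"
count every call surviving the benign filters including VUS, so
filtered ≥ pathogenic + candidate always holds (consistent with the
published attrition tables). Nonsense/frameshift calls without predictor
scores tier on assertion/count evidence alone.

Synonymous calls get the mean of the TraP, SilVA and FATHMM-MKL scores;
a mean strictly above 0.308 flags predicted deleterious synonymous
change. A missing component score yields an explicit unscored result.

## Spectrum, hypermutation, groups, POLE

Substitution spectra are strand-collapsed to the six pyrimidine-reference
classes (G>T ≡ C>A and so on); collapse is an involution and conserves
the SNV count. A twelve-class raw mode exists.

**Hypermutation detection** defaults to a gap rule formalising detection
"by eye": sort post-review SNV burdens, find the largest relative gap
between consecutive values at or above the cohort median, and flag
everything above it when the relative gap is ≥ 0.5 (no qualifying gap →
no flags; cohorts under 5 samples are rejected). Because the rule runs on
post-review counts, samples whose raw burden is inflated by
sequencing-error calls are judged on their surviving calls and are not
flagged. A fixed-cutoff mode (default 184, the bottom of the observed
ultramutated range) is available.

**Group assignment** is a total function evaluated per sample in
configurable precedence order (default 1, 2, 3, 4):

* Group 1 — burden > 570 **and** C>A > 9 **and** C>G < 1 (fixed mode),
  or the cohort's 75th/75th/25th percentiles in quartile mode;
* Group 2 — any MMR-gene (MLH1, MSH2, MSH6, PMS2) pathogenic/candidate
  hit;
* Group 3 — a TP53 hit without an MMR hit;
* Group 4 — everything else.

Quartile thresholds use the nearest-rank convention by default (the
convention id is recorded in output; a linear-interpolation convention is
selectable) and must be resolved once per cohort, making assignments
invariant under cohort permutation. Group 1 is given precedence over
Group 2 because ultramutated tumors frequently carry co-occurring MMR
hits yet are treated as the POLE-like class.

A known internal inconsistency of the source procedure is reproduced
faithfully rather than repaired: the printed fixed Group-1 thresholds
(burden > 570, C>G < 1) cannot describe the same study's ultramutated
samples (burden median ≈ 346, IQR 209–402; C>G median 3). Under either
fixed or quartile mode, samples drawn from those published distributions
essentially never satisfy the C>G clause, and rarely the burden clause.
The classifier implements the rule as printed; the synthetic generator
is calibrated to the published medians; the resulting Group-1 recall on
calibrated cohorts is ≈ 0 and is reported as measured. Hypermutation
detection (the gap rule) is the operative route by which ultramutated
samples are actually recovered, exactly as in the source, where the six
samples were found by inspection of the burden distribution rather than
by the printed thresholds.

**POLE assessment** filters add-on-assay calls to caller p ≤ 0.05,
exonic, non-synonymous, then classifies each against the exonuclease
hotspot list (p.Pro286Arg, p.Val411Leu), the ClinVar assertion, and the
protein-domain flag. The sample's status is the most severe per-variant
status under the ordering hotspot > other_pathogenic > unknown_in_domain
> unknown_outside_domain > benign_only > none; the ordering below
"hotspot" is reported metadata, not a biological claim.

## Clinical statistics

The odds ratio is the cross-product (a·d)/(b·c) with the Woolf/Wald
interval exp(ln OR ± z·√(1/a+1/b+1/c+1/d)) — identical to the Wald
interval of a univariate logistic regression on one binary covariate,
which is why no iterative fit is used. z defaults to the exact 97.5%
normal quantile (1.959964): with the rounded shorthand 1.96 two of the
published wide intervals miss their printed value by one unit in the
second decimal, while the exact quantile reproduces every printed bound.
Cells are oriented with serous histology as exposure and endometrioid as
reference. Zero cells are reported as incalculable (N/A) to match the
published convention for perfectly-predicting subgroups; a
Haldane–Anscombe correction is available behind a flag.

Categorical comparisons use Fisher's exact test for 2×2 tables when any
expected cell is below 5 and the Pearson chi-square (no continuity
correction) otherwise, recording the choice. Continuous comparisons
default to the Mann–Whitney U test (continuity- and tie-corrected normal
approximation) for the skewed variant-count covariates and the
two-sample t-test for age; an exact-enumeration mode exists. Distribution
summaries are mean ± SD or median with nearest-rank quartiles, matching
the classifier's quantile convention.

A calibration fact worth stating precisely: at enumerable sample sizes
the exact two-sided Mann–Whitney p-values are coarse fractions, so the
continuity-corrected normal approximation differs from the exact value
by up to 0.088 at n = m = 2, 0.031 at n = m = 4, and still 0.011 at
n = m = 8, taking the worst case over all achievable U. An
Edgeworth-corrected tail using the exact excess kurtosis of U,
γ₂ = −(6/5)(n²+m²+nm+n+m)/(nm(N+1)), reduces the worst case to 0.0024
for min(n, m) ≥ 5 but is still off by 0.065 at n = m = 2. No
normal-family approximation meets a uniform 0.01 bound over all
2 ≤ n, m ≤ 8; the package therefore keeps the field-standard corrected
normal approximation, and its measured worst-case deviation is reported
by the acceptance script rather than hidden behind an exact-method
substitution.

## Synthetic cohort generator

The generator is first-class, tested code; its defaults are the study
conditions.

* **Composition** (47 samples): 12 grade-1 + 10 grade-2 endometrioid,
  12 grade-3 endometrioid of which 6 ultramutated-with-POLE and 2
  artifact-dominated, and 13 serous.
* **Burden** is Poisson per sample: rates 65 / 75 / 62 / 63 for grade-1,
  grade-2, grade-3-non-ultramutated and serous (set to the published
  per-stratum medians, ≈ 67 overall), 345 for ultramutated (published
  median 346.5), 310 for artifact-dominated (the two excluded samples
  had 249 and 311 raw calls). INDELs are a 6% fraction (2% in
  ultramutated), matching the published variant-vs-SNV medians.
* **Spectra** are multinomial with per-stratum class probabilities
  proportional to the published six-class medians; the ultramutated
  spectrum is C>A- and C>T-rich (63 : 3 : 49.5 : 5.5 : 19.5 : 18).
  Half of all SNVs are emitted on the purine strand so the complement
  collapse is exercised.
* **Drivers** are planted per gene with per-histology probabilities
  taken from the published mutation rates (e.g. PTEN 0.83 in grade-1
  endometrioid vs 0.15 in serous; TP53 0.77 in serous; MMR genes only in
  the ultramutated profile, per-gene 0.25–0.35 so ≈ 5 of 6 samples carry
  at least one). Ultramutated samples carry P286R with probability 4/6,
  V411L 1/6, and fall back to the stoploss variant outside the
  functional domains when both hotspots miss, so every ultramutated
  sample has a POLE mutation. Each planted event is a concrete catalog
  variant with canonical HGVS.
* **Germline** variants (Poisson rate 25) appear in tumor and normal at
  concordant fractions near 0.5 or 1.0 (±0.04 noise), giving the
  discovery threshold a real contrast; somatic fractions are uniform on
  (0.1, 0.9).
* **Artifacts**: 2% of somatic calls are flagged `sequencing_error`
  (72% in the artifact-dominated profile, so raw burden sits inside the
  ultramutated range while post-review burden does not).
* **Annotation fixture**: planted drivers receive the curated evidence
  that tiers them as intended; passenger missense calls draw SIFT and
  PolyPhen from a mixture that is 82% concordantly benign; synonymous
  passengers draw the three synonymous predictor scores from Beta(1,
  3.5) (≈ 20% exceed the 0.308 mean threshold, matching the published
  106/520 rate); 35% of passenger records carry a population MAF above
  1%, and roughly a third of passenger calls carry a caller p-value
  above 0.05. Together these reproduce the published attrition: ≈ 87% of
  unfiltered SNVs removed, medians ≈ 8–10 filtered SNVs, 1–2 pathogenic
  and 2–5 candidate calls per non-ultramutated sample.
* **Clinical covariates** are drawn per histology from the published
  contingency structure (age 60.9 ± 11.2 vs 70.7 ± 7.0; stage, site,
  treatment and recurrence probabilities from the printed counts; the
  recurrence probabilities 7/34 and 8/13 are directly configurable).
* **Determinism**: the cohort is a pure function of (config, seed); each
  sample draws from a spawned child stream of one root seed sequence.

What the generator does **not** emulate, hence what passing tests do not
show about real data: read-level error processes and strand artifacts
(quality flags are sampled labels, not modelled from reads); linkage
between a sample's passenger calls and its clinical covariates beyond
histology; the enrichment of genuinely functional variants in
ultramutated tumors (the same passenger background applies to all
profiles, so ultramutated filtered-call medians sit below the published
ones — the published per-sample medians require the study's raw data and
are treated as structurally, not numerically, reproducible); mutational
signatures beyond six collapsed classes; and real genomic coordinates
(genes are laid out on a synthetic grid; all rules key on identifiers,
not positions).

## Numerical and degenerate-input conventions

Quantiles: nearest-rank by default everywhere, recorded in output.
Thresholds: strict inequalities as printed. Ties in the hypermutation
gap rule resolve to the largest gap seen first in ascending order.
Degenerate inputs are explicit errors (quartiles on < 4 samples,
hypermutation on < 5, empty groups in rank tests, zero-margin tables →
N/A results rather than exceptions where a published table prints N/A).
Problem sizes in the test suite and acceptance script — 100 and 40
seeded cohorts respectively, 1,000 randomized rule fixtures, 2,000
simulated tables, exact enumeration at n, m ≤ 8 and margins ≤ 15 — were
chosen as the package's own verification workload; all statistical
checks are seeded and deterministic.

## Known limitations

* The fixed Group-1 thresholds are reproduced as printed and therefore
  classify essentially no sample drawn from the published ultramutated
  distributions (see above); use hypermutation detection, or quartile
  mode with cohort-appropriate spectra, to recover ultramutated samples.
* The severity ordering of POLE statuses below "hotspot" is a reporting
  convention.
* Microsatellite instability, copy-number state and methylation are out
  of scope: panel SNV/INDEL data alone cannot assign the MSI or
  copy-number classes, and the package reproduces that boundary rather
  than repairing it.
* Restricted-denominator rows of the published clinical table (nodal
  sites among patients with lymphadenectomy only) are supported through
  configuration but not reproduced by default, since the published
  denominators for those rows are not derivable from the printed counts.
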