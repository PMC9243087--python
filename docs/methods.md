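# Methods

## The contamination problem and the two-step filter

Matched-normal filtering assumes the normal library is tumor-free. In
advanced myeloma the blood control carries circulating tumor cells
(CTCs), so genuine somatic mutations are re-observed in the normal at
allele fractions far above germline-noise levels. The filter therefore
runs in two steps.

**Step 1 (normal only).** A normal-library call is *contaminated* when
it (1) has at least `min_alt_reads` (default 5) supporting reads,
(2) has population minor allele frequency below `max_population_maf`
(default 0.05%), (3) survives the pooled recurrent-artifact database
after hotspot white-listing, and — only when its VAF is below
`low_vaf_cutoff` (default 5%) — (4) passes the oxidative-damage
orientation check and (5) shows alt reads on both strands. The
per-sample threshold is the maximum VAF over contaminated calls, or
absent when none pass.

**Step 2 (tumor vs normal).** A tumor call is somatic when it passes
criteria (1)–(5) and its VAF in the matched normal is ≤ the threshold
(inclusive: a somatic call observed exactly at the contamination
maximum must not be rejected) or ≤ `default_normal_vaf` (2%) when the
threshold is absent. Sites missing from the normal call set count as
normal VAF 0. Contaminated normal calls absent from the tumor's
somatic set are reported as *blood-only* — variants carried by CTCs
but not present at the biopsy site.

Design points:

* The oxidative-damage (8-oxo-G) rule is applied only to C>A/G>T SNVs
  below the low-VAF cutoff and is implemented as an orientation-balance
  requirement — reject when all alt reads share one read-pair
  orientation (F1R2/F2R1). Variant records therefore carry orientation
  counts alongside per-strand depths.
* Strand/orientation checks apply to indels only up to 5 bp, the
  stated limit of strand-specific read counting; longer indels skip
  criteria (4)–(5).
* The artifact pool is rebuilt from the cohort's own normals: a
  (contig, pos, ref, alt) entry is pooled when called in at least
  `min_recurrence` normals (default 3; the recurrence cutoff behind
  large production artifact databases is not standardized, so it is
  configurable), with white-listed hotspot sites removed because
  recurrent oncogenic positions are more likely real than artifactual.
* Tumor/normal calls are matched by exact (contig, pos, ref, alt) key.

## Clonality model

For variant *i* with allele fraction VAF in a tumor of purity *p* and
local total copy number *cn* (normal cells fixed at 2 copies):

```
u_i = ((1 − p)·2 + p·cn_i) / p · VAF_i = CCF_i · m_i
m_i = u_i  if u_i ≥ 1,  else 1
```

so CCF = u/m, and every u ≥ 1 maps to CCF 1. This literal piecewise
rule is the default; a rounded-multiplicity mode (m = max(1, round u))
used by some CCF tools is available but off, because the package
treats the printed relations as the contract. A mutation is clonal at
CCF ≥ 0.8, absorbing purity and copy-number uncertainty. u is capped
at 10³ (flagged) to keep pathological purity/VAF combinations finite;
positions not covered by any segment default to copy 2 with a warning;
copy-0 segments with observed alt reads are inconsistent and skipped.

**Mutual exclusivity.** Patients enter the hotspot matrix when they
carry at least one group-member variant with CCF ≥ 0.05; each
patient×group cell is clonal / subclonal / absent. The statistic is
the number of both-clonal group pairs per patient summed over
patients; the null permutes each group's column independently,
preserving per-group frequencies. The reported p-value is the
conservative (1 + #{null ≤ obs}) / (1 + N) form; because the statistic
is a small integer, this p is discrete and conservative, so a
randomized tie-broken variant — exactly Uniform(0,1) under the null —
is provided for calibration studies. Calibration must be run on
matrices that satisfy the exchangeability null, i.e. without the
row-inclusion rule (the generator's `drop_empty=False`), since
conditioning rows on "≥1 mutation" breaks column exchangeability.

## APOBEC enrichment

Per sample, the 2×2 table [[mut_in, mut_out], [ctx_in, ctx_out]]
counts deamination-class substitutions (C>T/C>G at C; G>A/G>C at G)
inside vs outside the TCW motif (reverse complement WGA), against the
panel's reference C/G opportunities counted once per base; bases at
contig edges without a full trinucleotide count as out-of-motif.
Opportunities are counted on the reference, not adjusted for sample
copy number. The one-sided (enrichment) Fisher exact p is corrected
across the cohort by Benjamini–Hochberg; enriched means FDR < 0.05
(strict). The mutations-vs-opportunities table layout follows the
standard motif-enrichment framework; at realistic opportunity counts
(10⁴–10⁵) the alternative layout differs negligibly. Mutation rate is
point mutations per Mb of panel footprint; the hypermutation threshold
is not a community constant and defaults to 10/Mb (configurable, an
assumption). Hypermutated samples are labelled APOBEC when also
enriched, otherwise "undefined mechanism".

## Cohort comparison and resistance screening

Gene-level tests count each patient at most once, requiring a
non-synonymous consequence (missense, stop-gain, start-loss, splice,
frameshift or in-frame indel) at VAF ≥ 5% — the inclusion rule that
makes counts comparable across cohorts sequenced at different depths.
Fisher exact tests (two-sided for the landscape scan, one-sided for
targeted enrichment claims) are BH-corrected across genes. Focal
deletions are segments with total copy < 2 (hemizygous or homozygous —
the comparison does not distinguish, zygosity is retained in output)
shorter than 20 Mb overlapping the gene by ≥ 1 base. Driver consensus
nominates genes with FDR < 0.2 in ≥ 2 tools. The resistance catalog is
an editable three-column table (gene, drug class, alteration type)
with a closed alteration vocabulary; the default encodes iMiD
(CRBN, CUL4B), glucocorticoid (NR3C1) and anti-CD38 (CD38, including
exon skipping and fusions). Expression-by-mutation uses the exact
rank-sum null for tie-free groups up to 12 per side and the
tie-corrected normal approximation with continuity correction
otherwise; two constant groups give p = 1 by convention.

## Exact-test numerics

Fisher p-values are computed by exact integer enumeration: all
hypergeometric probabilities of a 2×2 table share the denominator
C(N, c1), so one-sided tails and the two-sided "sum of probabilities ≤
observed" rule reduce to integer comparisons, eliminating
floating-point tie ambiguity. Tables with N > 10,000 (e.g.
sequence-opportunity margins) use the floating hypergeometric path,
where the absolute error is irrelevant to any reported digit. BH
adjustment is delegated to statsmodels and checked against a literal
step-up oracle in the tests.

## The synthetic cohort generator

The generator emulates, at read-count level (no reads/BAMs):

* **Panel.** A toy reference drawn i.i.d. uniform over ACGT (motif
  opportunities are therefore counted, never assumed), organized into
  2 kb exons × 5 per gene with 500 b gaps across ~1.25 Mb contigs;
  named driver/resistance genes carry hotspot codon sites
  (white-listed). Default footprint 5 Mb — the real panel's footprint
  is not a published constant, so this is a free parameter.
* **Patients.** Purity ~ U(0.4, 0.95) (plasma-cell selection yields
  high but variable tumor content); 2–4 clones: a trunk at CCF 1 plus
  subclones on the grid {0.1…0.6}; copy segments per contig with total
  copy {1, 2, 3, 4} at weights {0.10, 0.70, 0.15, 0.05}; all segments
  are autosomal-style with normal copy 2, matching the literal model.
* **Mutations.** Somatic burden 3.5 point events/Mb (a
  relapsed-myeloma-like cohort average); each somatic variant sits in
  one clone (trunk weight 0.5), multiplicity 1 throughout, with
  expected tumor VAF from the inverse of the clonality relation; reads
  are Binomial(depth, VAF) at Poisson depth ~600× (normal scaled by
  0.75, mirroring typical tumor/normal coverage ratios). Indels
  (fraction 0.1) are ≤ 5 bp. Half of SNVs are deamination-class;
  among those, `apobec_weight` is the probability of placement at a
  TCW/WGA site (background draws exclude deamination-class changes so
  the weight stays a clean conditional).
* **Contamination.** Each patient's normal contains the tumor variants
  at VAF = f·CCF·m / ((1−f)·2 + f·cn) for contamination fraction
  f ~ U(0, 0.3), plus ~1 blood-only variant per contaminated patient.
* **Confounders.** Common polymorphisms (MAF ∈ {0.1%, 1%, 10%},
  float32-quantized so VCF round-trips are bit-exact; heterozygous VAF
  0.5 in both libraries, deliberately ignoring local copy number —
  they exist to exercise the MAF criterion, not to model allelic
  imbalance) and recurrent artifacts shared across ≥3 samples per
  pooled site, drawn at VAF ~ U(0.5%, 3%) — squarely inside the
  low-VAF gate the filter reserves for artifact checks — with either
  all-one-strand or all-one-orientation (damage-class) read support.
  One pool site sits at a white-listed hotspot to exercise
  white-listing.
* **Hotspot process.** Group frequencies default to KRAS 26% / NRAS
  25% / BRAF 15% with clonal probability 0.7. With exclusivity
  enforcement (default), at most one group stays clonal per patient;
  the demoted ones move to the patient's lowest-CCF subclone, keeping
  truly-subclonal demotions well clear of the 0.8 clonal boundary
  under measurement noise.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: mapping and alignment error, indel
realignment artifacts, homopolymer/PCR noise (the published logistic
indel model is out of scope), GC- and capture-bias in depth, subclonal
copy number, multiplicity > 1, kataegis clustering, and germline
allelic imbalance. Calibration results transfer to real panels only to
the extent that read counts at a called site behave binomially.

**Noise-free mode** replaces sampling with expected counts and carries
the exact expected VAF in memory (`vaf_expected`); downstream CCF
computation then inverts the clonality relation exactly (the pipeline
inversion check). VCF FORMAT floats are 32-bit, so this field is not
serialized; fixture round-trips are bit-exact for sampled
(integer-count) bundles.

## Problem sizes used in the shipped checks

The test-suite and acceptance script measure: CCF recovery on ~1,300
variants over 30 patients at 1 Mb (median |CCF − truth| at depth 600
is ~0.02 against the 0.05 contract); filter-oracle agreement on 10,000
randomized calls; recall/leakage on 3×10 patients at contamination
{0, 0.1, 0.3}; Fisher enumeration on all 164,176 tables with margins
≤ 30; APOBEC calibration on 200 samples at 60 events/Mb (≈60
SNVs/sample); exclusivity on a 100-patient enforced cohort, 100
unconstrained 200-patient replicates, and 1,000 null calibration
replicates; comparison power on 100 replicates of 200-vs-200 cohorts
with one gene's frequency doubled; and a byte-identical rerun of the
default 50-patient, 5 Mb end-to-end pipeline.

## Known limitations

* No CCF confidence intervals and no subclone-tree reconstruction;
  one-dimensional VAF clustering is out of scope.
* The per-sample contamination threshold is a maximum over passing
  calls, so a single borderline artifact that clears all five criteria
  can inflate the tolerance; the pooled-artifact and strand checks are
  the only guards, exactly as in the two-step scheme itself.
* Whether the 2% default should apply per-variant rather than
  per-sample when contamination is borderline is ambiguous; it is
  applied per-sample as stated.
* Hotspot-group codon membership ships as an editable resource
  (`clonality.DEFAULT_HOTSPOT_GROUPS`); real analyses should adjust it
  to their panel's annotation.
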