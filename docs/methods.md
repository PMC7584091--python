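# Methods

## Setting and model

Maternal plasma contains cell-free DNA from two genomes: the mother's and
the foetus's. At a total foetal fraction `f`, reads from a plasma
sequencing library derive from the foetal genome with probability `f`;
since the foetus inherits one haplotype per locus from each parent, a
haplotype carried by the foetus but absent from the mother — necessarily
the paternally transmitted one — appears at expected relative frequency
`f/2`. Microhaplotype markers (2+ SNPs within one short amplicon, read out
as a phased string over {A,C,G,T}) make this signal observable in single
reads: every read that spans the amplicon reports one complete haplotype,
so the plasma locus profile is a direct mixture measurement with no
phasing step.

The inference compares two hypotheses per case: the alleged father is the
biological father, versus an unrelated man from the reference population.
Per locus the evidence reduces to two counts — haplotypes shared between
the parents, and plasma candidates (non-maternal haplotypes inside the
foetal detection window) matching the alleged father. Loci supporting
neither connection are discrepant; the case decision is exclusion with ≥ 2
discrepant loci, inconclusive with exactly 1, and otherwise the per-locus
paternity indices multiply into `CPI` with `W = CPI/(1+CPI)`.

## Paternity index

For an unambiguous obligate paternal haplotype `h` with population
frequency `p`: `PI = T/p`, with transmission probability `T = 1`
(homozygous father) or `0.5` (heterozygous). When plasma shows no foreign
candidate but the parents share haplotypes, the paternal transmission is
hidden among the maternal haplotypes; the index is then the likelihood
ratio over the plasma-consistent set: numerator = fraction of the father's
two haplotype copies lying in the maternal set, denominator = total
population frequency of the maternal haplotypes (capped at 1). This
reduces to `T/p` when the consistent set is a single haplotype and equals
a brute-force enumeration of paternal transmissions (verified in the test
suite). When both father haplotypes appear as candidates, one must be an
artefact; the more frequent haplotype in the population is taken as the
true paternal one.

Population frequencies come from the reference panel, pooled across
populations by default (a population filter is available). A haplotype
absent from a panel of `n` chromosomes receives frequency `1/(n+1)` — the
same add-one logic at every panel size, giving 1/5009 at the full
2504-sample reference scale. A discrepant locus inside an otherwise
consistent case is attributable to mutation: with a per-locus SNP mutation
rate of 1e-8/generation and a floor haplotype frequency of 2e-4, its index
is 5e-5 regardless of how many SNPs differ (the factor is already so small
that refining it cannot change a decision).

`CPI` is accumulated in log10 space and `W` evaluated through the logistic
function, so a hundred loci with indices anywhere in [1e-5, 1e5] neither
overflow nor underflow. Prior odds are fixed at 1:1 (the forensic
convention). For inconclusive cases `W` over the consistent loci is
reported with a prominent flag; whether the discrepant locus's mutation
index enters `W` is a config switch, off by default (audit only). `W` is
never reported for exclusions.

## Decision thresholds

All rule boundaries, with their strictness:

| quantity | rule |
|---|---|
| genomic locus callable | coverage > 20 (strict) |
| noise floor for genotype rules | relative frequency > 10% (strict) |
| homozygous | one haplotype > 80% (strict) |
| heterozygous | two haplotypes in [20%, 80%] (inclusive) |
| three-haplotype profile | exactly two > 35% (strict) → heterozygous |
| plasma locus usable | coverage ≥ 1000 |
| maternal haplotype confirmation | each ≥ 12%; any non-maternal > 12% dismisses the locus |
| foetal detection window | [1%, 12%] inclusive |
| read filters | mapping quality > 20 (strict), unique alignment, CIGAR ops ⊆ {M, =, X}; base quality < 20 masked to `-` |
| partial haplotype rescue | known fraction ≥ 0.70, unique total match |
| exclusion / inconclusive | ≥ 2 / exactly 1 discrepant loci |
| reporting | W > 0.99; ≥ 15 usable markers recommended (`low_marker_flag` below) |

The upper bound of the foetal window doubles as the artefact guard: an
apparent paternal-only fraction above 12% would imply a ~25% total foetal
fraction, implausible at typical gestational ages, so the locus is
dismissed rather than trusted. A profile with `k = 0` or `k > 3`
haplotypes above the noise floor is a no-call (the rule table is silent
there, and such profiles indicate contamination or assay failure). The
70% rescue boundary is taken as retained-at-exactly-70%; note that for 2-
and 3-SNP loci any masked base already falls below 70%, so rescue
effectively begins at 4 SNPs.

## Foreign plasma candidates: two readings

A plasma candidate in the foetal window that matches *no* alleged-father
haplotype admits two interpretations, and the package implements both as
`foreign_candidates=`:

* `"ignore"` (default): the verdict depends only on the shared/matched
  counts. This is the right reading for real semiconductor plasma data,
  where sequencing artefacts routinely reach the same 1–12% range as the
  genuine foetal signal — an unexplained candidate is most likely noise.
* `"exclude"`: an unexplained candidate makes the locus discrepant unless
  some candidate matches the father. This is the right reading for
  genotype-level simulation and for synthetic data with a calibrated, low
  error rate: there the candidate *is* the child's true paternal
  haplotype, and ignoring it discards the strongest evidence against a
  non-father. The marker-count power study is a full-trio design (the
  child's haplotypes are known), so the simulation module and the
  end-to-end synthetic benchmarks use this mode; with it, the scaled-down
  study reproduces the expected behaviour (false inclusions < 1% beyond
  ~13 markers, non-fathers excluded essentially always), while the lenient
  mode plateaus around 92% exclusion because any father sharing a common
  haplotype with the mother can never be excluded at that locus.

## Statistical tests

Microhaplotypes are highly multi-allelic, so genotype tables are sparse
and asymptotic chi-square tests on them unreliable. Hardy–Weinberg
equilibrium is therefore tested by a Monte-Carlo exact test: the observed
2n allele copies are permuted and re-paired into genotypes (each perfect
matching equally likely under the null conditional on allele counts), and
the p-value is the add-one-corrected fraction of permutations whose
chi-square distance from the HWE expectation reaches the observed one
(2000 permutations by default; the permutation pass is vectorised). The
suite verifies agreement with full enumeration of all (2n−1)!! pairings at
n ≤ 5 and type-I calibration at α = 0.05 over seeded replicates. Linkage
equilibrium between two loci uses the chi-square independence test on the
joint haplotype table over phased chromosomes, switching to a seeded
permutation null whenever any expected cell is below 5. The 20-locus
screen reports raw p-values plus a Bonferroni-adjusted pass column; the
correction for the multi-test screen is a package choice, as is α = 0.05.

ROC construction wraps scikit-learn's threshold sweep; AUC is checked
against the Mann–Whitney pairwise statistic. In the cross-evaluation,
pairs with exactly one discrepant locus are dropped (inconclusive), and
excluded pairs score 0 since `W` is undefined for them.

## Synthetic data generator

The generator emulates the three inputs the pipeline consumes.

*Panels.* Each locus gets `K ≥ 3` distinct haplotypes over biallelic SNPs;
base frequencies are symmetric-Dirichlet(α = 1.2), and each population
redraws from Dirichlet(base × c) with c = 50 — a Balding–Nichols-style
perturbation with F_st ≈ 1/(1+c) ≈ 0.02, matching mild continental
differentiation. Individuals are sampled under within-population
Hardy–Weinberg. Defaults (20 loci, K = 6, 4 populations × 50 samples) give
pooled per-locus `A_e` centred near 4, the 3–5 range of a curated forensic
panel. Panels round-trip exactly through the phased-VCF writer/reader.

*Families.* Mother and father are distinct panel samples (same population
on request); the child takes one haplotype of each, uniformly per locus; a
non-father case adds an independent third sample as alleged father.

*Reads.* Per-base substitution errors (uniform over the three other bases)
at 0.5% by default; base qualities a two-point Q30/Q10 mixture with 3%
low — enough to exercise the masking path without modelling full quality
profiles; 5% of reads truncated to a SNP prefix/suffix (producing
partials); ~1% each of low-mapq, insertion-bearing and non-unique reads so
every filter branch fires. Plasma reads draw from the child's haplotypes
with probability `f` (default 8%, a typical first-trimester value) and the
mother's otherwise. Genomic libraries default to 200× per locus and plasma
to 2000×, comfortably above the 20×/1000× floors.

What the generator does *not* model: indel errors (the pipeline rejects
indel CIGARs anyway), PCR duplicates, GC bias, cfDNA fragment-length
structure, maternal copy-number or vanishing-twin artefacts, and —
importantly — the bursty locus-specific error haplotypes of semiconductor
sequencing that reach the foetal window in real data. Passing the
synthetic benchmarks therefore demonstrates the correctness of the
decision logic and the statistics under calibrated noise, not robustness
to platform-specific artefacts; that is why the lenient
`foreign_candidates="ignore"` mode remains the default for real data.

## Problem sizes

The validation suite and the acceptance script use desk-scale versions of
the study designs: the marker-count study runs 500 per-population plus 500
pooled non-father replicates (and 500 true-father replicates) on the
default 20-locus panel, against the full-scale design of 26 000 + 26 000
replicates on a 2504-sample reference; end-to-end read-level benchmarks
run 100 true-father and 100 non-father cases (≈ 48 000 simulated reads
each); foetal-fraction recovery uses 50 replicates × 6 loci at 2000×. The
full-scale external inputs (the public phase-3 reference VCFs, clinical
trio BAMs) are supported as inputs but are deliberately not fetched or
required anywhere.

## Known limitations

* Kinship alternatives (brother, uncle) are not modelled; the likelihood
  ratio contrasts the alleged father only with an unrelated man, and no
  co-ancestry (theta) correction is applied.
* The foetal-fraction summary is a median over informative loci; no
  shrinkage or per-locus amplification-efficiency model.
* The HWE/LE screen tests pooled panels by default; strong population
  structure inflates rejections (Wahlund effect), so screening within
  populations or using the Bonferroni column is advisable for structured
  panels.
* Phasing of the reference panel is trusted as given; unphased
  heterozygous genotypes are dropped (or abort, configurable), never
  statistically phased.
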