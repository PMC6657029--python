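# Methods

## The analysis

The pipeline quantifies how somatic mutations in the MHC class I pathway
— the invariant subunit B2M and the polymorphic HLA-A/B/C heavy chains —
relate to the mutational and immunological state of a tumor. Patients are
grouped by escape-mutation status: `WT` (no B2M/HLA mutation), `B2M_MUT`,
`HLA_MUT`, `BOTH`, and `SYN_ONLY` (only synonymous B2M/HLA mutations;
these patients are removed from every contrast because a synonymous
change neither disrupts presentation nor counts as wild-type evidence).
Patients in `BOTH` carry the mutation of either gene and are counted on
both mutant sides of group contrasts; the allele-specific bias analyses
use strictly `HLA_MUT` patients, whose signal is not confounded by a
simultaneous B2M lesion.

### Presentation scores

For each mutation and each of a patient's 6 HLA allele slots, the input
is the best (minimum) binding percentile rank of the peptides covering
that mutation (lower = stronger predicted binding; homozygous allele
pairs occupy two slots and contribute duplicate values). The PHBR-I
score is the harmonic mean of the six per-slot best ranks,

    PHBR = 6 / (1/r1 + ... + 1/r6),

which is dominated by the strongest-binding allele: a mutation needs only
one good presenter to be presentable. Scores ≤ 2 (inclusive) are called
binding. Allele-specific analyses instead call a mutation binding *at a
slot* when that slot's best rank is ≤ the same cutoff; this is
deliberately not PHBR, because "neoantigens binding the mutated allele"
is an allele-level notion. The cutoff is a parameter (default 2.0)
everywhere.

Per-patient binding fractions use as denominator the patient's expressed
missense and indel mutations (the classes that generate candidate
neoantigen peptides); patients with an empty denominator are excluded
from group summaries. Group curves report the median fraction across
patients at each cutoff and are nondecreasing in the cutoff by
construction.

### Expression, burden, MSI, immune activity

A mutation is *expressed* when ≥ 5 RNA-seq reads cover its position
(inclusive; configurable). *Nonsynonymous* means missense, nonsense,
frameshift or in-frame indel, or splice-site — the class list is
enumerated explicitly, with splice variants included since they disrupt
the coding product. Per-patient burden is the expressed nonsynonymous
count plus a pseudocount of 1. MANTIS microsatellite scores are binarized
at 0.4, the boundary assigned to MSI-H (configurable). The cytolytic
score is `z(GZMA log2 TPM) + z(PRF1 log2 TPM)` with z-scores computed
across the analyzed cohort (population SD), so it sums to zero over that
cohort; CD8⁺ T-cell and NK levels are consumed deconvolution outputs and
only the contrast layer touches them.

### Timing

The allelic fraction `AF = t_alt_count / t_depth` proxies clonality.
Each escape mutation is annotated with its mid-rank percentile among the
patient's expressed mutations:

    percentile = 100 · (c_below + 0.5 · c_tied_others) / (n − 1),

counting over the *other* n−1 mutations, so a unique minimum scores
exactly 0, a unique maximum exactly 100, and ties split symmetrically.
This definition is invariant under strictly monotone transforms of AF.
Patients with fewer than two expressed mutations have no defined
percentile and are excluded. Percentile > 60 classifies a mutation as
early (clonal), < 40 as late (subclonal); the band in between is
intermediate and excluded from the early/late contrast. A mutation lies
in a CNV region when a same-patient segment with |log2FC| strictly
greater than 0.1 covers its position; by default such mutations are only
flagged, and a robustness variant (`exclude_cnv`) drops them from both
the ranking set and the output.

### Residue annotation

Structure-level inputs are precomputed per-PDB-entry tables of relative
solvent-accessible surface area (RSA) per UniProt position plus predicted
B2M–HLA interface position sets; computing RSA or interfaces from atomic
coordinates is out of scope. Per structure: interface membership wins;
otherwise RSA > 15 → surface, RSA < 5 → core, RSA in [5, 15] → ambiguous
(strict boundaries). Across all structures of a protein (multiple PDB
entries and alleles) the final label is one pooled plurality vote over
all structure-level labels; ties and never-observed positions resolve to
ambiguous. Pooling was chosen over nested two-stage consensus because it
is order-independent and reproduces the documented behaviour of both
tie-like cases (an interface-minority position resolving to surface; an
intermediate-RSA position staying ambiguous). Positions use full-length
UniProt numbering; subtracting the 24-residue signal peptide maps HLA
positions to IMGT/HLA mature numbering. Hotspots are positions mutated
strictly more often than a per-gene threshold (HLA-A: 3, HLA-B: 3,
HLA-C: 1; configurable). Domain enrichment builds a 2×2 table of
(mutations in/out of domain) × (residues in/out of domain), reports the
sample cross-product odds ratio (a zero cell is flagged unbounded) and a
two-sided Fisher exact p.

### Statistics

All two-group tests are two-sided: unpaired Mann-Whitney U for group
comparisons, paired Wilcoxon signed-rank on (mutated-slot count − mean of
the other five slots) for allele bias (zero differences dropped;
all-zero input flagged degenerate), two-sample Kolmogorov-Smirnov for
percentile distributions, Fisher exact for 2×2 tables (statistic =
sample odds ratio). Rank tests use the exact null for tie-free samples
up to n = 25 and the tie-corrected normal approximation above.
Multiple-comparison control is Benjamini-Hochberg, applied within one
family per stratified analysis (per-tumor-type burden; each per-type
immune variable separately); pan-cancer single tests are reported raw.
Per-tumor-type analyses first merge the COAD and READ codes to CRC and
then drop tumor types with fewer than 5 mutated patients.

## The synthetic-cohort generator

Access-controlled patient data cannot ship with the package, so the
generator emulates the joint structure the analysis assumes. What it
reproduces, and the defaults chosen as realistic study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_patients` | 500 | cohort size (analyses in this package use 400–2000) |
| `frac_b2m_mut` / `frac_hla_mut` / `frac_both` | 0.10 / 0.20 / 0.01 | escape-group fractions, rounded deterministically to counts |
| `frac_syn_only` | 0.02 | patients with only synonymous B2M/HLA mutations |
| `frac_msi` | 0.15 | MSI-H fraction |
| `msi_enrichment_or` | 15 | target odds ratio of escape mutations in MSI-H tumors |
| `baseline_burden_mean` | 50 | mean expressed nonsynonymous count, WT MSS patient |
| `burden_dispersion` | 10 | negative-binomial size (overdispersion) |
| `burden_multiplier_b2m/hla/msi` | 2 / 2 / 5 | fold-changes on the NB mean (multiplicative) |
| `bias_strength` | 0.15 | P(redraw a neoantigen's mutated-slot rank below the cutoff) |
| `early_bias_multiplier` | 2 | bias multiplier for clonal (high-VAF) HLA escape |
| `rank_log_min` / `rank_log_max` | 0.7 / 100 | support of the log-uniform per-slot rank draw |
| `vaf_model` | Beta(8,1.5); 50/50 Beta(8,1.5)/Beta(1.5,8) | B2M high-skewed; HLA bimodal mixture |
| `depth_mean` | 80 | Poisson sequencing depth; alt reads ~ Binomial(depth, VAF) |
| `expressed_prob` | 0.7 | P(a passenger mutation is expressed) |
| `cnv_fraction` | 0.2 | per-chromosome probability of a CNV segment |
| `homozygous_fraction` | 0.1 | patients with a duplicated allele in one gene |
| `silent_rate` | 0.35 | silent mutations per nonsynonymous mean |
| `immune_shift` | 0.5 | additive shift of immune readouts in mutant groups |

Escape-group fractions are set well above their population frequencies
(roughly 1–6% in large tumor cohorts) so that desk-scale cohorts contain
enough mutant patients for every contrast; effect sizes, not prevalences,
are the quantities the recovery tests check.

Design notes:

* **Burden** is negative-binomial because real tumor mutation counts are
  strongly overdispersed; only group-level location summaries are being
  emulated, so the dispersion is a single shared parameter. Total
  nonsynonymous counts are drawn with mean `baseline/expressed_prob ×
  multipliers` and thinned by the expression probability, leaving the
  expressed mean at the configured value.
* **Ranks** are i.i.d. log-uniform on (`rank_log_min`, 100] per slot.
  The lower bound 0.7 was calibrated analytically so that a few percent
  of mutations are binding at the PHBR ≤ 2 cutoff (per-slot P(rank ≤ 2)
  ≈ 0.21, P(PHBR ≤ 2) ≈ 0.08), the scale a realistic rank predictor
  produces; pushing the bound much lower makes the harmonic mean collapse
  and nearly every mutation binding.
* **Mutated-allele bias**: for expressed missense/indel mutations of
  HLA-mutant patients, with probability `bias_strength` the mutated
  slot's rank is redrawn log-uniformly below the binding cutoff. Patients
  whose HLA escape VAF came from the clonal high mixture component get
  the bias multiplied by `early_bias_multiplier` (capped at 1),
  reproducing the observation that early escape associates with more
  mutated-allele binders.
* **MSI coupling** draws the count of escape∩MSI-H patients from
  Fisher's noncentral hypergeometric distribution at the target odds
  ratio, so the downstream sample odds ratio concentrates on the target;
  given group and MSI status, burden and the remaining variables are
  conditionally independent (a modeling choice — the joint distribution
  beyond enrichment is not characterized by the data being emulated).
* **Escape mutations are always expressed** (RNA reads ≥ 5): they are
  the analyzed events, and the timing and bias analyses condition on
  observing them in RNA.
* **Genome model** is abstract — 22 autosomes × 100 Mb, passenger
  positions uniform, escape genes at fixed loci; CNV segments are whole
  chromosomes with |log2FC| drawn in (0.15, 1], plus neutral segments
  (|log2FC| ≤ 0.1) that exercise the strict threshold.
* Group counts round deterministically (`floor(x + 0.5)`), and a fixed
  seed reproduces every table byte-identically (all randomness flows
  through one `numpy` generator; file readers use exact string→float
  conversion so write/read round-trips are lossless).

### What the generator does not emulate

No peptide or sequence simulation (ranks are drawn, not predicted), no
subclonal phylogeny (VAF mixtures stand in for clone structure), no
purity/ploidy distortion of AF beyond binomial sampling noise, no
correlation between a mutation's rank and its VAF or expression, no
tumor-type-specific burden or MSI profiles, and no LOH or epigenetic
silencing of HLA (patients with those lesions would dilute the WT group
in real data). Passing tests therefore demonstrate that the pipeline
recovers the effects it is designed to detect and stays calibrated under
their absence — not that real cohorts satisfy these distributional
assumptions.

## Numerical and degenerate-input choices

* Exact rank-test nulls switch to the normal approximation above n = 25
  or in the presence of ties; the tie-corrected approximation is used
  with continuity correction.
* Fisher's sample odds ratio with a zero off-diagonal cell is reported
  as unbounded (∞, flagged); an all-zero cross product is undefined
  (NaN, flagged); degenerate margins give p = 1 with a flag.
* Percentiles of a single-mutation tumor are undefined; the patient is
  excluded rather than imputed.
* BH adjustment validates p ∈ [0, 1], enforces monotonicity from the
  largest rank down and caps at 1; a single-test family is returned
  unchanged.
* Empty cohorts and header-only files round-trip as empty tables; every
  reader rejects records violating invariants (alt > depth, rank ≤ 0,
  start > end, missing allele slots) before anything reaches analysis
  code.

## Problem sizes used by the test suite

Simulation-based checks use cohorts of n = 2000 over 50 seeds for effect
recovery (burden multiplier, MSI odds ratio, bias detection, B2M-vs-HLA
percentile separation) and n = 400 over 200 seeds for null calibration
(every contrast's type-I error within [0.02, 0.09] at α = 0.05); seed
sequences are fixed so runs are reproducible. The end-to-end pipeline
check uses a 500-patient cohort. `scripts/acceptance.py` recomputes the
headline quantities on a fresh 2000-patient cohort from a user-supplied
seed.

## Known limitations

* The generator's conditional-independence structure makes some joint
  effects (e.g. MSI-specific VAF patterns of HLA mutations) absent by
  construction.
* Allele-slot identity is positional (slots 1–2 = HLA-A, 3–4 = HLA-B,
  5–6 = HLA-C); allele-level rank variation between the two slots of a
  homozygous pair is not modeled beyond independent draws.
* The structural module trusts its input tables; no validation against
  actual PDB content is possible or attempted.
* Exact Wilcoxon/Mann-Whitney p-values with heavily tied count data fall
  back to the approximation; at very small stratum sizes those p-values
  are conservative.
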