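# mhcescape

Analysis of somatic immune-escape mutations in the MHC class I pathway.

Tumors can evade T-cell surveillance by mutating the machinery that
presents neoantigens: the invariant scaffold **B2M** or the polymorphic
**HLA-A/B/C** heavy chains. `mhcescape` implements, as a tested and
reusable pipeline, the statistical analysis that relates such escape
mutations to

* **tumor mutation burden** — expressed nonsynonymous mutation counts
  (plus a pseudocount of 1), contrasted pan-cancer and per tumor type
  (COAD+READ merged to CRC, types with < 5 mutated patients dropped),
* **presentable neoantigen load** — the PHBR-I score of a mutation, the
  harmonic mean across a patient's 6 HLA allele slots of the best
  (minimum) binding percentile rank, `PHBR = 6 / Σᵢ 1/rᵢ`, with scores
  ≤ 2 called *binding*; per-patient binding fractions and allele-specific
  binder counts (mutated vs unmutated HLA allele, paired Wilcoxon),
* **mutation timing** — tumor allelic fraction `t_alt_count / t_depth`,
  expressed as a within-tumor percentile; percentile > 60 = early
  (clonal), < 40 = late (subclonal); CNV regions (|log2FC| > 0.1) can be
  excluded as a robustness variant,
* **microsatellite instability** — MANTIS scores binarized at 0.4, with
  Fisher exact tests for enrichment of escape mutations in MSI-H tumors,
* **immune activity** — the cytolytic score (sum of cohort-z-scored log2
  TPM of *GZMA* and *PRF1*) plus consumed CD8⁺ T-cell / NK deconvolution
  levels,
* **residue-level structure** — consensus annotation of B2M/HLA positions
  as interface / core (RSA < 5) / surface (RSA > 15) / ambiguous from
  precomputed per-structure tables, hotspot detection, and domain-level
  mutation enrichment (odds ratio + Fisher exact p).

Real patient-level inputs of this kind are access-controlled, so the
package ships a first-class synthetic-cohort generator
(`mhcescape.synthetic_cohort`) that reproduces the statistical structure
the analysis assumes — group-specific burden inflation, mutated-allele
binding bias, clonal-high B2M vs bimodal HLA escape VAFs, and MSI
enrichment at a target odds ratio — so every stage is testable end to
end, including null (type-I error) calibration.

## Worked example

```python
from mhcescape import CohortConfig, generate_cohort, run_pipeline, phbr_score

# a mutation strongly presented by one allele is called binding
print(round(phbr_score([0.5, 0.5, 0.5, 50, 50, 50]), 3))   # 0.99  (<= 2: binding)
print(round(phbr_score([1, 2, 3, 4, 5, 6]), 3))            # 2.449 (> 2: non-binding)

cohort = generate_cohort(CohortConfig(n_patients=500, seed=23))
results = run_pipeline(cohort)          # MSS-restricted, cutoff 2
print(results["burden_pan"][["label", "statistic", "raw_p"]])
print(results["msi"][["label", "statistic", "raw_p"]])
```

prints (seed 23):

```
               label  statistic         raw_p
0   burden:B2M-vs-WT    10104.0  1.815007e-15
1   burden:HLA-vs-WT    19172.5  5.969302e-24
2  burden:B2M-vs-HLA     1175.0  7.024205e-01
                    label  statistic         raw_p
0  msi-enrichment:B2M_MUT  13.176471  3.930920e-11
1  msi-enrichment:HLA_MUT  12.606061  5.425283e-16
```

i.e. both escape groups carry significantly higher expressed
nonsynonymous burden than wild-type patients (with no B2M-vs-HLA
difference at these equal multipliers), and escape mutations are ~13-fold
enriched among MSI-H tumors, consistent with the generator's configured
odds ratio of 15 at this cohort size.

The same analyses are available from the shell:

```bash
mhc-escape simulate --n-patients 500 --seed 23 --out cohort/
mhc-escape pipeline cohort/ --out results/           # all stages
mhc-escape timing cohort/ --out results/ --exclude-cnv
```

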