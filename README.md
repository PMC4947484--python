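# deltag

Tag-SNP imputation of the **KLRC2/NKG2C 16-kb deletion** genotype from SNP
genotyping data, together with the population-genetic statistics used to
validate and apply the imputed calls.

## The problem

The *KLRC2* gene on chromosome 12p13 encodes the activating NK-cell receptor
NKG2C. A 16-kb deletion haplotype removes the gene, so every individual
carries one of three genotypes: wt/wt, wt/del or del/del. The deletion is a
structural variant and is not typed by standard SNP genotyping arrays; it is
normally assayed by sequence-specific primer PCR, which is slow and
laborious. Because the deletion sits on a haplotype shared with nearby SNPs,
its genotype can instead be *imputed* from array SNPs that are in strong
linkage disequilibrium (LD) with it.

`deltag` implements that imputation pipeline for cohorts in which a subset of
samples has both experimental deletion calls and SNP genotypes:

1. **LD scan** (`deltag.ld_scan`) — pairwise r² between the deletion-allele
   dosage and every SNP in the region; SNPs with r² > 0.2 become candidate
   tag SNPs. Both the genotype-dosage (composite) estimator and a
   haplotype-frequency EM estimator are provided.
2. **Variable importance** (`deltag.tag_model`) — a random forest of the
   three-state genotype on the candidate SNPs, with out-of-bag permutation
   importance ranking the candidates.
3. **Minimal model selection** — the forest is retrained on the top
   1..k SNPs; the model with the fewest misclassifications (ties broken by
   higher unweighted Cohen's kappa, then fewer SNPs) becomes the final
   classifier, typically 1–3 tag SNPs.
4. **Imputation** — the final model is applied to samples lacking
   experimental calls; samples missing any model-SNP genotype are excluded
   and listed.
5. **Validation and application** (`deltag.agreement`,
   `deltag.popgen_stats`) — 3×3 cross-tabulation with unweighted/weighted
   Cohen's kappa and asymptotic CIs; Hardy–Weinberg likelihood-ratio (G)
   test; allele-level cross-population odds ratios (logistic regression on
   alleles, equivalent to the 2×2 allele-table OR); multivariable
   case-control logistic association of genotype with disease, adjusted for
   age and sex, with a joint genotype LRT (df = 2); Monte-Carlo power for an
   additive model.
6. **Synthetic cohorts** (`deltag.simulate`) — a generator that plants a
   deletion variant at configurable frequency, tag SNPs at specified target
   r² (via the two-locus haplotype table f(del,alt) = p·q + D, with
   Lewontin-bound validation), unlinked noise SNPs in HWE, and a binary
   phenotype under a logistic model — the test bed for everything above.

## Statistics in brief

* **LD**: r² = corr(x, y)² on dosage vectors (pairwise-complete), or
  D²/(p_A q_A p_B q_B) at the EM fixed point of the two-locus haplotype
  likelihood.
* **Cohen's kappa**: κ = (p_o − p_e)/(1 − p_e), with linear
  (1 − |i−j|/(k−1)) or quadratic Fleiss–Cohen (1 − (i−j)²/(k−1)²) weights;
  SE by the large-sample Fleiss–Cohen–Everitt formula; 95% CI κ ± 1.96·SE.
* **HWE**: G = 2 Σ O ln(O/E) against (q²n, 2pqn, p²n), df = 1.
* **Association**: logit P(case) = β₀ + β₁·1[wt/del] + β₂·1[del/del] +
  β_age·age + β_sex·1[female] (+ ethnicity indicators); Wald CIs per term,
  LRT for the joint genotype effect.

## Worked example

Agreement between experimental and imputed genotypes, from a published
training-set cross-tabulation (rows: experimental; columns: imputed):

```python
import numpy as np
from deltag import agreement, popgen_stats as ps
from deltag.agreement import ConfusionMatrix

cm = ConfusionMatrix(np.array([[119, 2, 0], [10, 127, 3], [0, 3, 45]]))
prop, pct = agreement.overall_accuracy(cm)
print(f"overall accuracy: {np.trace(cm.counts):.0f}/{cm.n} = {pct}")
for w in ("none", "quadratic"):
    est = agreement.cohen_kappa(cm, w)
    print(f"kappa ({w}): {est.kappa:.3f} (95% CI {est.ci95[0]:.3f}-{est.ci95[1]:.3f})")

east = ps.GenotypeCounts(155, 76, 13, "East-Africans")
print(f"deletion-allele frequency: {ps.allele_frequency(east):.3f}")
print(f"HWE LRT p: {ps.hwe_lrt(ps.GenotypeCounts(329, 156, 24)).p:.2f}")
print(f"allelic OR (0.332 vs 0.209): "
      f"{ps.allelic_odds_ratio((0.332, None), (0.209, None)).odds_ratio:.2f}")
```

prints

```
overall accuracy: 291/309 = 94.17%
kappa (none): 0.906 (95% CI 0.864-0.948)
kappa (quadratic): 0.942 (95% CI 0.914-0.969)
deletion-allele frequency: 0.209
HWE LRT p: 0.33
allelic OR (0.332 vs 0.209): 1.88
```

So 291 of 309 training samples are imputed correctly (94.17%); chance-
corrected agreement is 0.91 unweighted and 0.94 with quadratic weights
(near-miss errors — e.g. wt/del called wt/wt — are down-weighted). The
East-African control deletion-allele frequency is 20.9%, those genotype
counts are compatible with Hardy–Weinberg equilibrium (p = 0.33), and a
population with a 33.2% deletion frequency has 1.88 times the odds of
carrying the deletion allele.

### The full pipeline, from the shell

```bash
deltag simulate -o fix --seed 11          # synthetic cohort: 3 planted tags + 100 noise SNPs
deltag ld-scan fix/genotypes.vcf fix/deletion_calls.tsv -o scan.tsv
# INFO deltag: 3 of 103 SNPs pass r2 > 0.2
deltag train fix/genotypes.vcf fix/deletion_calls.tsv --scan scan.tsv \
       -o model.joblib --report report.tsv --seed 11
# INFO deltag.tag_model: selected 3-SNP model (tag_1+tag_3+tag_2): 1991/2000 correct, kappa 0.993
deltag impute model.joblib fix/genotypes.vcf -o imputed.tsv
deltag evaluate fix/deletion_calls.tsv imputed.tsv
```

The scan table ranks the three planted tags first (r² = 0.943, 0.884,
0.860 at this seed); the selection report shows accuracy rising from 97.5%
(1 SNP) to 99.6% (3 SNPs); and `evaluate` reports κ = 0.993 for the
re-imputed training cohort. Other subcommands: `assoc` (logistic
association), `hwe` (G test on genotype counts), `freq` (cross-population
allele-frequency comparison from published counts).

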