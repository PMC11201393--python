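# skinmut

Somatic-mutation × transcriptome interaction analysis for non-melanoma
skin cancer (NMSC) cohorts with paired tumor–blood sequencing, aimed at
studies where the question is not just *which* genes are mutated or
differentially expressed, but whether the **presence of a non-synonymous
somatic mutation in a driver gene changes the magnitude of differential
expression** of genes and pathways — and how an environmental exposure
(here, arsenic measured as the urinary arsenic/creatinine ratio, UACR)
modulates that effect.

Sun-exposed healthy skin carries its own somatic burden with a UVR
signature (excess C>T and G>A substitutions), so a somatic variant found
in a tumor is not automatically cancer-associated. The triage layer here
therefore compares tumor tissue against paired blood (the germline proxy)
*and* against an independent set of healthy-skin samples, partitioning
unique somatic loci into tumor-only, shared, and healthy-only categories.

## What it computes

**Variant triage** — per patient: remove tissue calls present in the
paired blood, apply the low-frequency detection thresholds
(coverage ≥ 10, supporting reads ≥ 2, variant-allele frequency ≥ 2%,
variant quality ≥ Q60), keep only calls inside the targeted panel, drop
known common germline variants (local blacklist). Cohort level: three-way
locus classification, tumor mutation burden (TMB, mutations/Mb of target),
the 12-class substitution spectrum, Kruskal–Wallis group comparisons, and
the per-gene, per-sample mutation incidence ranking.

**Gene-level interaction ANOVA** — on log₂(CPM+1) expression values, a
pooled-variance one-way model over `healthy` + K tumor subgroups (e.g.
tumor without / with a non-synonymous driver mutation). For subgroup k
with log₂ effect d_k = ȳ_k − ȳ_healthy, the reported signed fold change is

    FC(d) = 2^d        if d ≥ 0
    FC(d) = −2^(−d)    if d < 0

with 95% CIs transformed endpoint-wise from the log₂ scale. The
*interaction p* is the F test (K−1 numerator df) that all tumor-subgroup
effects are equal; the *combined p* collapses the tumor subgroups and
equals the pooled two-sample t test. Differential expression is selected
at |FC| ≥ 3 and Benjamini–Hochberg FDR ≤ 0.05.

**Gene-set ANOVA** — the fixed-effects model
`Y = μ + T + G + T×G + T×Mut + ε` over all member genes of a set: each
gene keeps its own cell means, residual variance is pooled across member
genes, and the set-level effect per subgroup is the unweighted mean of the
member genes' log₂ effects. The T×Mut interaction tests whether the
set-level effect differs across mutation-defined subgroups, including the
four-way mutation × exposure stratification (UACR dichotomized at
192 µg/g creatinine, boundary → low).

**Enrichment** — category over-representation of the DE list by 1-df
Pearson chi-square over a fixed background, scored as −log₁₀(p).

**Synthetic cohort generator** — paired tissue/blood VCFs, target BED,
blacklist, raw count matrix, sample sheet and GMT sets with a complete
`TruthRecord`, so the whole pipeline is testable end-to-end with exact
truth recovery. See `docs/methods.md` for the generative model.

## Worked example

```python
import pandas as pd
from skinmut import (
    CohortConfig, generate_cohort, classify_loci, mutation_status_matrix,
    tmb_summary, cpm_log2, fit_geneset_model, geneset_report,
)
from skinmut.triage import FilterParams, TriageConfig, triage_sample

cohort = generate_cohort(CohortConfig(seed=0))   # 26 BCC + 6 SCC + 16 healthy
cfg = TriageConfig(target_regions=cohort.target_regions,
                   germline_blacklist=cohort.blacklist)
somatic = {
    sid: triage_sample(
        cohort.tissue_calls[sid],
        cohort.blood_calls[cohort.sample_sheet.loc[sid, "blood_id"]],
        FilterParams(), cfg)
    for sid in cohort.sample_sheet.index
}
sheet = cohort.sample_sheet
tumor = [s for s in sheet.index if sheet.loc[s, "tissue"] != "healthy"]
healthy = [s for s in sheet.index if sheet.loc[s, "tissue"] == "healthy"]
triage = classify_loci({s: somatic[s] for s in tumor},
                       {s: somatic[s] for s in healthy})
print(triage.category_summary())
print(tmb_summary({s: len(somatic[s]) for s in sheet.index},
                  sheet["tissue"].to_dict(), panel_size_mb=1.7))

status = mutation_status_matrix(triage, ["PTCH1"])
expr = cpm_log2(cohort.counts)
labels = pd.Series({s: ("healthy" if s in healthy
                        else f"mut{status.loc[s, 'PTCH1']}")
                    for s in sheet.index})
gsa = [fit_geneset_model(expr, members, labels, name=name)
       for name, members in cohort.gene_sets.items()]
print(geneset_report(gsa))
```

Output:

```
              unique_loci  genes  total_calls
category
NMSC_ONLY            4760    400         4767
SHARED                 28     28          181
HEALTHY_ONLY         2480    400         2480

         n_samples  median_mutations  median_tmb
group
BCC             26             153.0          90
SCC              6             145.0          85
healthy         16             161.5          95

                 set  n_genes  p_interaction  fc_mut0  ...  fc_mut1  ...
  HEDGEHOG_SIGNALING       30       9.61e-81     1.95  ...     3.39  ...
BASAL_CELL_CARCINOMA       30       4.11e-54     2.29  ...     3.79  ...
        NULL_PATHWAY       30        0.00103    -1.09  ...    -1.18  ...
```

Reading this: triage recovered every planted somatic locus (the 28 SHARED
loci are the generator's recurrent hotspots seen in both tumor and healthy
skin); median TMB is ~90 mutations/Mb in each group, as expected when
tumor and sun-exposed healthy skin carry similar somatic rates; and the
affected pathways show the planted pattern — tumors *with* a
non-synonymous PTCH1 mutation overexpress the pathway more strongly
(FC 3.4–3.8) than tumors without (FC 2.0–2.3), with very small interaction
p-values driven by the large pooled residual df of the fixed-effects fit.
The null pathway's slight FC below 1 is the compositional side effect of
CPM normalization when other genes are up-regulated.

The same flow runs from the shell:

```sh
skinmut simulate --seed 0 --out cohort/
skinmut all --config pipeline.yaml --out results/
```

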