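# thindex

Tumor-heterogeneity (TH) index from targeted panel sequencing.

Intratumor heterogeneity — a tumor being a mixture of genetically distinct
subclones — predicts recurrence, metastasis and drug resistance, but most
heterogeneity measures need whole-exome data.  `thindex` implements a
heterogeneity statistic computable from the routine diagnostic assay
itself: the variant allele frequencies (VAFs) of somatic mutations called
in a targeted cancer gene panel (e.g. a 381-gene design) are assigned to
ten equal-width bins and summarized by Shannon's diversity index,

    H' = − Σᵢ pᵢ ln pᵢ ,  pᵢ = fraction of VAFs in bin i,

so a clonal tumor (one VAF cluster) scores near 0 and a tumor whose VAFs
spread across many bins scores up to ln 10 ≈ 2.30.  Cohorts are
dichotomized into high/low TH at a cutoff (default 1.30, a cohort-average
value; the cohort mean can be recomputed for any dataset).

The package is aimed at cancer-genomics analysts who want to compute the
TH index from variant tables, validate its behavior, and evaluate its
prognostic value.  It provides:

- **`thindex.variants`** — variant table I/O (VCF with per-sample `AD`, or
  a tab-delimited dialect), the pre-filters (germline / false-positive
  flags, population allele frequency, depth) and panel restriction;
- **`thindex.th`** — binned-VAF Shannon index, high/low classification,
  cohort-mean cutoff;
- **`thindex.purity`** — tumor purity from germline SNPs in copy-altered
  regions via the allele-frequency model
  AAF = (P·Y + (1−P)) / (P·X + 2(1−P)) and its closed-form inversion;
- **`thindex.simulate`** — a subclonal tumor / cohort generator (clone
  fractions, purity, binomial read sampling, stage mix, proportional-
  hazards outcomes) so every analysis is testable without patient data;
- **`thindex.panel_eval`** — panel down-sampling robustness curves,
  TH-vs-clonality rank-sum test, purity/mutation-count confounder checks;
- **`thindex.prognosis`** — stage linear-by-linear trend test,
  Kaplan-Meier / log-rank stratification, feature × TH extreme-group
  comparisons, and Harrell's C-index under resampling.

See `docs/methods.md` for the model, conventions and limitations.

## Worked example

Simulate a 120-patient cohort (stage mix, purity 0.2–1.0, 1–6 subclones
with hazard ratio 2 for high TH), compute TH from the generated read
counts, and test the TH stratification:

```python
from thindex.simulate import CohortConfig, simulate_cohort, cohort_clinical_frame
from thindex.prognosis import km_logrank

tumors, records = simulate_cohort(CohortConfig(n_samples=120), seed=7)
df = cohort_clinical_frame(records)
df = df[df.th_group.isin(["high", "low"])]
print(f"n = {len(df)}, mean TH = {df.th_value.mean():.3f}")
km = km_logrank(df.time, df.event, df.th_group)
print(f"log-rank p = {km.pvalue:.4g}")
print(df.groupby('th_group').time.median())
```

prints

```
n = 120, mean TH = 0.909
log-rank p = 0.0002679
th_group
high    2.975044
low     4.652259
```

The cohort's mean TH (0.909) is the high/low cutoff; the high-TH group
(72 patients above the mean) has a median survival of 3.0 months against
4.7 for the low-TH group, and the log-rank test detects the difference
(p ≈ 2.7 × 10⁻⁴) — the prognostic signal the simulator attached to the
measured TH group is recovered by the analysis chain.

The same pipeline is scriptable from the shell:

```bash
thindex simulate cohort --seed 7 --out demo/          # variants.tsv + clinical.csv
thindex th compute --variants demo/variants.tsv --panel panel.txt --cutoff mean
thindex purity estimate --snps snps.tsv
thindex prognosis run --clinical demo/clinical.csv --out results/
```

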