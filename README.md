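# imprintqc

Quantitative analysis of DNA methylation at human imprinted differentially
methylated regions (DMRs) from bisulfite pyrosequencing (PSQ) data.

Imprinted genes are expressed from one parental allele, and each imprinted
locus carries at least one DMR — a region methylated on exactly one allele,
so that normal tissue reads out close to 50% aggregate methylation. Because
DMR methylation is established early and maintained through differentiation,
imprinted DMRs are sensitive reporters of epigenetic stability in healthy
tissue, cancer and congenital imprinting disorders. `imprintqc` is written
for epigenetics researchers who quantify DMR methylation with per-CpG PSQ
assays and need the surrounding statistics: assay design and validation,
differential-methylation calling, stability comparisons, population
screening and treatment response.

## What it computes

- **Assay catalog** (`imprintqc.catalog`): a packaged catalog of 49 PSQ
  assays covering the known human imprinted DMRs (name, position,
  parent-of-origin mark, germ-line/somatic timing, average somatic
  methylation, genomic context, CpG-island status, CTCF occupancy class,
  CpG density), plus readers for long-format methylation tables and BED
  interval sets.
- **In-silico assay design** (`imprintqc.design`): bisulfite conversion,
  Wallace-rule melting temperatures, and an exhaustive, deterministic
  search for CpG-free, SNP-free primer pairs near 56 °C flanking a 3–9 CpG
  target, with the universal biotinylated second-round tag.
- **Validation** (`imprintqc.validation`): linearity against the
  0/25/50/75/100% methylated-DNA mixture series, technical-replicate
  agreement (OLS + Bland–Altman limits `bias ± 1.96·SD`), and
  input-titration sensitivity with allelic-dropout detection.
- **DMR analysis** (`imprintqc.dmr`): the differential window
  `mean ± k·SD` of 50% standards (k = 1.5 gives the published 35.73–65.03%
  band), hypo/differential/hyper classification per assay × tissue,
  intra-CpG variability by parental class, tissue-deviation t-tests,
  CpG density over a 500 bp window, and feature associations (CTCF,
  CpG island, genomic position, density).
- **Population and treatment** (`imprintqc.population`): per-DMR reference
  intervals (`mean ± z·SD`, 95%/99%), outlier flagging, per-individual
  burden ANOVA, cis-cluster correlation, and percent methylation reduction
  under demethylating treatment.
- **Synthetic data** (`imprintqc.simulate`): seeded generators for tissue
  panels, blood cohorts, standard series and design regions, each paired
  with its ground truth for recovery testing.

## Worked example

```python
import imprintqc as iq

# the published differential window from 50% standards
window = iq.derive_dmr_window([40.61, 50.38, 60.15], k=1.5)
print(window.lower_rounded, window.upper_rounded)   # 35.73 65.03

# classify published somatic averages against it
for value in (45.23, 12.07, 88.27):
    print(value, iq.classify_value(value, window))
# 45.23 differential      (a canonical germ-line DMR)
# 12.07 hypomethylated    (no promoter DMR; silenced-allele locus)
# 88.27 hypermethylated

# catalog breakdown
catalog = iq.load_assay_catalog()
summary = iq.summarize_catalog(catalog)
print(summary.count("timing", iq.Timing.GERMLINE))  # 17 germ-line DMR assays
```

The window bounds say: a tissue whose mean PSQ read falls inside
35.73–65.03% is consistent with one methylated and one unmethylated
parental allele; readings outside indicate loss (hypo) or gain (hyper) of
the imprint in that tissue.

The same steps are scriptable from the shell:

```bash
imprintqc catalog summarize
imprintqc window --readings 40.61,50.38,60.15
imprintqc simulate --kind tissue-panel --seed 1 --out panel.csv
imprintqc classify --table panel.csv
imprintqc run-all --seed 1 --out results/
```

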