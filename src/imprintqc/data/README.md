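# Packaged assay catalog

`assay_catalog.csv` is the published catalog of bisulfite pyrosequencing
assays for the known human imprinted differentially methylated regions
(DMRs), transcribed as printed: 49 assay rows. The accompanying report text
refers to "50 assays"; the printed characteristics table contains 49 rows
and is shipped verbatim rather than silently amended. The identity of the
unlisted assay is unresolved (plausibly a second IGF2R-region assay).

Columns:

- `name` — assay identifier, unique.
- `chromosome`, `position` — 1-based genomic coordinate on the catalog's
  original assembly, kept as opaque coordinates (no liftover).
- `parental_mark` — Maternal / Paternal / None / Unknown parent-of-origin
  methylation mark.
- `timing` — Germ-line, Germ-line# (flagged as provisional in the source
  table), Somatic, None, Unknown.
- `avg_somatic_methylation` — mean pyrosequencing methylation percentage
  across adult somatic tissues.
- `location_category` — genomic context, normalized to a fixed vocabulary
  (`promoter`, `isoform_promoter`, `embedded_gene_promoter`,
  `antisense_promoter`, `five_prime_upstream`, `intergenic`,
  `gene_body_exonic`, `gene_body_intronic`); the source table's spellings
  are inconsistent and were mapped once here.
- `cpg_island` — Yes/No, UCSC CpG-island annotation.
- `ctcf_class` — N (no CTCF binding), YV (variable across cell lines),
  Y (constitutive) from cell-line occupancy data.
- `cpg_density` — CpG sites per 100 bp in a 500 bp window centred on the
  amplicon mid-point (always a multiple of 0.2).
- `cluster_id` — imprinted-cluster co-membership on the same chromosome,
  assigned here from the well known cluster structure of imprinted loci;
  empty for singleton assays.
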