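# teatlas

Transposable elements (TEs) make up roughly half of the human genome and are a
major source of *cis*-regulatory sequence. Their active/repressed chromatin
states differ between tissues, so TE-derived regulatory elements are natural
candidates for tissue-specific gene regulation. `teatlas` is a Python package
for quantifying that contribution from standard epigenomic peak files, for
researchers analyzing ENCODE-style functional-genomics data across cell-line
panels:

1. **Regulatory atlases.** Per assay class — DNase hypersensitive sites (DHS),
   activating-histone ChIP-seq peaks (HA: H3K4me3/H3K27ac/H3K9ac/H3K79me2),
   repressive-histone peaks (HR: H3K27me3/H3K9me3) — the peak sets of N cell
   lines are merged into non-overlapping regions, classified base-pair-wise as
   *shared* (covered by all N lines), *cell-line specific* (≥1 but not all) or
   *cell-line unique* (exactly one), and partitioned into gene-neighboring
   (within 5 Kb of a TSS) versus distal sequence.
2. **TE composition and age.** From a RepeatMasker-style annotation, each
   region category gets a bp-level composition table (total TE bp and per-class
   bp for SINE/LINE/LTR/DNA), a 2×2 Pearson chi-square test of class
   over/under-representation against the genome, and an insertion-age profile
   using percent divergence from the family consensus (milliDiv/10) as the age
   proxy, compared between categories by a two-tailed Welch t-test.
3. **Gene scores.** Each gene's *regulatory TE density* in a cell line is

   `density = TE-derived regulatory bp / total regulatory bp` within TSS ± 5 Kb,

   giving a gene × cell-line matrix per assay (undefined where a gene has no
   regulatory sequence). Genes with density ≥ 0.1 (DHS, HR) or ≥ 0.3 (HA) are
   called TE-regulated; cross-cell-line Pearson correlations and the sharing
   spectrum (genes called in exactly k of N lines) summarize tissue
   specificity.
4. **Tissue-specific genes (TSGs).** For a TSG catalog and a cell-line → tissue
   map, the package contrasts TSG densities in the own tissue versus all
   others (Welch t-test, called fractions) and catalogs *tissue-exclusive*
   TSGs: density ≥ 0.1 in the own tissue and exactly 0 everywhere else.

A seeded synthetic-cohort generator (`teatlas.simulate`) emulates all input
formats with planted, exactly-known structure, so the entire pipeline is
testable end to end without downloading anything.

## Worked example

```sh
teatlas simulate --outdir demo --seed 1
teatlas all --config demo/pipeline.yaml
```

This generates a six-cell-line cohort (blood ×2, liver, lung, brain, skin;
7.6 Mb toy genome, 48% TE) and runs every stage. The TSG contrast table
(`demo/results/tsg_contrasts.tsv`) then reads, for DHS:

```
tissue  assay  mean_density_own  mean_density_other  t      p_value   fraction_called_own  fraction_called_other
blood   DHS    0.4147            0.0444              18.23  3.5e-16   1.000                0.0
liver   DHS    0.4139            0.0444              10.16  5.1e-07   1.000                0.0
...
```

i.e. this cohort's tissue-specific genes use ~41% TE-derived regulatory
sequence near their TSS in their own tissue's cell line but ~4% elsewhere —
the planted tissue-specific signal, recovered with p ≪ 0.05. The
tissue-exclusive catalog (`tissue_exclusive.tsv`) lists exactly the 20 genes
planted with the exclusive pattern, and `enrichment_DHS.tsv` shows the
planted LTR over-representation in open chromatin (LTR share of TE bp 0.24
vs 0.19 genome-wide, chi-square p < 1e-100).

Each stage is also available as a library call (`build_atlas`,
`split_by_sharing`, `compose_te`, `chi_square_representation`, `age_profile`,
`density_matrix`, `call_te_regulated`, `tsg_contrast`,
`tissue_exclusive_genes`, …); see the module docstrings and
`docs/methods.md` for the underlying model and conventions.

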