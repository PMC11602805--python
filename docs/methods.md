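# Methods

## Coordinate model and interval engine

All coordinates are 0-based half-open (BED convention); any 1-based input
dialect is converted at the file boundary and every record is validated
against a `GenomeLayout` before anything downstream sees it. The interval
engine represents a region set as per-chromosome sorted disjoint intervals
and implements union, intersection, subtraction, complement and k-of-N
coverage selection as a single endpoint-sweep primitive (coverage-depth
selection). Abutting intervals coalesce during normalization: "merged,
non-overlapping regions" is read as a coverage set, which leaves bp totals
unchanged and makes region counts deterministic. Strand is ignored
throughout — peaks are unstranded and the TSS flank is symmetric. The engine
is verified against a per-base boolean-array oracle on thousands of seeded
random instances and cross-checked against bedtools.

## Atlas construction and sharing

Per assay (DHS, HA, HR) the cell-line peak sets are merged into a union
atlas. Presence of a cell line in a merged region requires ≥ 1 bp of
overlap by default (`min_overlap_bp`); 1 bp is the weakest faithful reading
of "present in" and is configurable. Sharing is evaluated at two levels:

* **per merged region** (presence mask popcount) for the "present in k of N
  lines" spectrum; with N = 1 the shared/specific distinction degenerates —
  the region is classified shared and the pipeline warns;
* **per base pair after re-fragmentation** (`split_by_sharing`) for all bp
  accounting: a bp is shared iff covered by all N lines, specific if covered
  by ≥ 1 but not all, unique if by exactly one. A merged region that is only
  partially shared therefore splits into several fragments, and the
  shared + specific region counts can exceed the overall count. This
  bp-level reading is forced by the arithmetic of published composition
  tables of this kind, where specific region counts exceed overall counts.

Gene-neighboring context is the intersection with the union of TSS ± 5 Kb
windows (flank default 5,000 bp), so a bp near two TSSs counts once and
every context split is an exact partition (conservation is asserted in
tests). The three-way assay overlap is reported as a seven-part Venn
decomposition of bp with the three-way union as denominator, alongside
per-set fractions, since either normalization is defensible.

## TE composition, enrichment and age

Composition is bp accounting against the normalized union of TE footprints:
double-covered bp count once in total TE bp; per-class bp is computed
against each class's own union, so a bp under two classes can appear in both
class rows but only once in the total. Fragment counts are maximal
contiguous pieces of TE∩region coverage (abutting pieces coalesce), a
deterministic convention chosen over raw-record counting. The repClass →
{SINE, LINE, LTR, DNA} mapping is total with everything else (simple
repeats, satellites, retroposons, …) in OTHER; only the four named classes
are analyzed explicitly and the mapping is config-overridable.

Class enrichment in a region category versus the genome is a 2×2 Pearson
chi-square without continuity correction on bp counts
{class, other-TE} × {regions, genome} — length fractions rather than element
counts, matching the convention that regulatory TE contribution is measured
in sequence length (element-count tables are still exported). The
significance level for calling a direction defaults to α = 1e-4, mirroring
the usual p < 0.0001 reporting style for such genome-scale contrasts, and is
configurable; a zero margin yields an undefined p and direction "none" with
a warning.

Insertion age is proxied by percent divergence from the family consensus
(milliDiv/10; a fractional div% column is used verbatim when present). A TE
belongs to a region category's age profile when it overlaps the category by
≥ 1 bp, so a TE straddling a boundary contributes its full divergence to
both profiles; a majority-bp membership rule is available. Profiles are
histograms with 1-percentage-point bins by default. Mean ages are compared
with a two-tailed Welch (unequal-variance) t-test; the pooled-variance test
is a flag away. Two identical constant groups are reported as t = 0, p = 1
rather than NaN. Groups with n < 2 are flagged undefined.

Human-specific TE (HSTE) status comes from a separate BED-like list matched
by exact coordinates (default) or ≥ 90% reciprocal overlap, since deposited
HSTE coordinates may be trimmed relative to RepeatMasker. The HSTE ratio of
a region bucket is the human-specific share of the TE *records* overlapping
it.

## Gene scoring and TE-regulated calls

Regulatory TE density is per (gene, cell line, assay): TE-covered
regulatory bp divided by total regulatory bp within TSS ± 5 Kb, computed
against each cell line's own peak set — not the merged atlas — because the
cross-cell-line matrix is the object of interest; the atlas serves the
composition and sharing analyses. A gene with zero regulatory bp in a cell
line has an *undefined* density, carried as missing and excluded from means,
correlations and calls: treating it as 0 would conflate "no regulation
detected" with "regulation without TEs" (a zero-densities mode would be a
one-line change at the call site). Cell-line correlations are
pairwise-complete Pearson with a minimum of 3 complete pairs; an
average-linkage utility on distance 1 − r is provided but rendering is out
of scope.

TE-regulated calls use inclusive thresholds density ≥ 0.1 for DHS and HR
and ≥ 0.3 for HA (HA neighborhoods run a higher density baseline). The
fast-path matrix computation (prefix-sum range queries) is asserted equal to
the per-gene definition in tests.

## Tissue-specific-gene analyses

Contrasts treat each defined (gene, cell line) density as one observation:
own group = the tissue's TSGs in that tissue's cell line(s), other group =
the same genes in all remaining cell lines; Welch t-test plus called
fractions. Tissue-exclusive calls require density ≥ 0.1 (all assays) in the
own tissue — the maximum over its cell lines by default, switchable to mean
or all-lines-pass — and exactly 0 in every other tissue's cell line where
defined. An undefined density elsewhere counts as satisfying "0" (no
TE-derived regulatory sequence exists there); a strict mode requires a
defined zero. HR is excluded from TSG contrasts by default; the operations
accept any assay.

## Synthetic cohort

The generator emulates the statistical structure of a multi-cell-line
epigenomic cohort on a 7.6 Mb two-chromosome toy genome, with every planted
quantity recorded in a truth table:

* **Genome.** 48% TE by bp; class mix SINE/LINE/LTR/DNA/OTHER =
  0.28/0.36/0.19/0.07/0.10 of TE bp; divergences per class from truncated
  normals, SINEs from a two-component mixture (means 8 and 25, sd 3) giving
  the characteristic bimodal age profile, LINE/LTR/DNA unimodal (means
  26/22/24, sd 4). TEs never overlap, so bp truth is unambiguous. The
  youngest TEs (divergence < 5) are flagged human-specific at rate 0.6.
* **Cell lines.** Six lines over five tissues (blood carrying two), so
  multi-line-tissue code paths are exercised.
* **Atlas chromosome (3 Mb).** Per assay, archetype regions are planted in
  disjoint slots as shared (all lines), subset (2..N−1 lines) or unique
  (one line), with per-line ±25 bp jitter producing realistic ragged merges
  and partial sharing. Slots are drawn with weights
  mult^(class share of slot TE bp) implementing the per-(assay, class)
  enrichment multipliers (defaults DHS-LTR 2×, HA-SINE 2×, HR-LTR 2×), times
  an age factor exp(coef × divergence residual). The residual is taken
  relative to the slot's class-expected mean divergence, making the age bias
  class-neutral: shared regions prefer TEs old *for their class* (+0.25 per
  %) and unique regions young ones (−0.35 per %). An absolute-divergence
  bias would instead select almost exclusively young SINEs for unique
  regions and erase the planted LTR enrichment.
* **Gene chromosome (4.6 Mb).** 500 TSSs at 9 Kb spacing. Each gene's
  ±3.8 Kb core hosts disjoint per-assay lanes holding the planted regulatory
  peaks; the 9 Kb spacing keeps every neighbor's peaks outside this gene's
  ±5 Kb window, and filler TEs avoid all planted peaks, so each planted
  density is exact by construction (TE fragments totalling round(d·L) bp are
  placed inside each L-bp peak). Categories: background genes (density
  U(0, 0.05) in all lines), TE-regulated genes (U(0.4, 0.6), 50 genes), and
  12 TSGs per tissue split into elevated (own U(0.32, 0.6), others
  U(0.02, 0.08)), exclusive (own U(0.2, 0.6), others exactly 0 via TE-free
  peaks) and deliberately leaky genes (others ≥ 0.01, which must *not* be
  recovered as exclusive). Gene-zone TE class choice is SINE-biased (×1.8),
  echoing gene-proximal SINE overrepresentation. Peak lengths follow the
  assay targets (DHS ≈ 220 bp, HA ≈ 1,900 bp, HR ≈ 950 bp).

The default layout is sized so that 500 cross-contamination-free gene
neighborhoods and a separate atlas zone coexist; infeasible parameter
combinations (TE fraction unattainable, lanes that do not fit, neighborhoods
reaching each other's lanes) are rejected before any file is written.
Generation is fully deterministic per seed (byte-identical bundles).

What the generator does *not* emulate — and hence what passing recovery
tests cannot show about real data: nucleotide sequence and mappability,
peak-calling noise and replicate variability, overlapping TE records and
nested insertions, genome-scale linkage between TE classes and gene density,
and expression data (the TSG catalog is an input, as in the real analysis).
Recovery results on the cohort validate the pipeline's arithmetic and
inference machinery, not the biology.

## Pipeline, problem sizes and determinism

The pipeline stages (atlas, compose, age, scores, tsg, report) are
self-contained: each recomputes what it needs from the configured inputs, so
any stage can run standalone and stage-order errors cannot arise; a missing
input file is reported with the cell line and assay it belongs to. All
outputs are TSV/BED with dot decimals and no thousands separators; reports
print percentages at one decimal and relative class percentages as whole
integers, so derived-quantity comparisons are well defined. A JSON manifest
records the config, package version and seed of each run; identical config
and seed reproduce every output byte-for-byte, independent of the
`--threads` option.

Default problem sizes — 7.6 Mb genome, ~11,000 TE records, six cell lines,
500 genes, ~330 atlas archetypes per assay — were chosen so a full
generate-plus-analyze cycle completes in seconds while every statistical
recovery (chi-square directions, age contrasts, TSG contrasts) remains
decisively powered; the oracle-equivalence suite fuzzes ≥ 1,000 random
instances per operation on ≤ 100 Kb layouts where per-base arrays are exact
and cheap.

## Known limitations

* Per-family (as opposed to per-class) analyses, Kimura-corrected
  divergence and phylogenetic dating are out of scope.
* The chi-square enrichment treats bp as independent observations, as is
  conventional for this table style; spatial autocorrelation of TE placement
  is not modeled, so p-values on real genomes are anti-conservative and
  should be read as orderings.
* GO enrichment itself is external; the package only exports the two-column
  gene/cluster table such tools ingest.
* With a single cell line the sharing analysis is degenerate (warned, not
  refused).
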