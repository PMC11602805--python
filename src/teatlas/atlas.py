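"""Cross-cell-line regulatory-region atlases.

For one assay class (DHS = DNase-seq open chromatin, HA = activating-histone
ChIP-seq, HR = repressive-histone ChIP-seq) the peak sets of all cell lines
are merged into a list of non-overlapping regions.  Each merged region
carries a presence mask over cell lines; sharing is additionally evaluated
per base pair after re-fragmentation, because a merged region can be covered
by all cell lines in its core but by fewer at its fringes.  Region counts of
the shared/specific split are recomputed after the split, so the specific
count can exceed the overall count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .intervals import GenomeLayout, IntervalSet, coverage_select, presence_mask

__all__ = [
    "ASSAYS",
    "AtlasRegion",
    "Atlas",
    "AtlasSummary",
    "build_atlas",
    "split_by_sharing",
    "partition_gene_neighboring",
    "cross_assay_overlap",
    "overlap_fraction",
    "summarize_atlas",
]

ASSAYS = ("DHS", "HA", "HR")

SHARED = "shared"
SPECIFIC = "cellline_specific"
UNIQUE = "cellline_unique"


@dataclass(frozen=True)
class AtlasRegion:
    """One merged regulatory region with its per-cell-line presence mask."""

    chrom: str
    start: int
    end: int
    assay: str
    presence: tuple[bool, ...]

    @property
    def popcount(self) -> int:
        return sum(self.presence)

    @property
    def sharing_class(self) -> str:
        """shared iff present in all cell lines; unique iff in exactly one.

        With a single cell line the two coincide and the region is classified
        shared (degenerate case; the pipeline warns when N == 1).
        """
        n = len(self.presence)
        k = self.popcount
        return SHARED if k == n else (UNIQUE if k == 1 else SPECIFIC)


@dataclass
class Atlas:
    """Merged atlas for one assay: union regions plus the source peak sets."""

    assay: str
    celllines: list[str]
    per_cellline: dict[str, IntervalSet]
    union: IntervalSet
    regions: list[AtlasRegion]

    @property
    def layout(self) -> GenomeLayout:
        return self.union.layout

    def region_sharing_spectrum(self) -> dict[int, int]:
        """Number of merged regions present in exactly k cell lines."""
        out: dict[int, int] = {}
        for r in self.regions:
            out[r.popcount] = out.get(r.popcount, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (r.chrom, r.start, r.end, r.popcount, r.sharing_class)
            for r in self.regions
        ]
        return pd.DataFrame(
            rows, columns=["chrom", "start", "end", "popcount", "sharing_class"]
        )


def build_atlas(
    per_cellline_peaks: Mapping[str, IntervalSet],
    assay: str,
    min_overlap_bp: int = 1,
) -> Atlas:
    """Merge per-cell-line peak sets into non-overlapping atlas regions."""
    if not per_cellline_peaks:
        raise ValueError("need at least one cell line")
    celllines = list(per_cellline_peaks)
    if len(celllines) == 1:
        warnings.warn(
            "atlas built from a single cell line: shared vs cell-line-specific "
            "is degenerate (every region is classified shared)",
            stacklevel=2,
        )
    sets = dict(per_cellline_peaks)
    it = iter(sets.values())
    union = next(it)
    for s in it:
        union = union.union(s)
    if union.total_bp == 0:
        warnings.warn(f"empty union for assay {assay}: atlas has no regions",
                      stacklevel=2)
    intervals, mask = presence_mask(union, sets, min_overlap_bp=min_overlap_bp)
    regions = [
        AtlasRegion(c, s, e, assay, tuple(bool(b) for b in mask[i]))
        for i, (c, s, e) in enumerate(intervals)
    ]
    return Atlas(assay, celllines, sets, union, regions)


def split_by_sharing(atlas: Atlas) -> dict[str, IntervalSet]:
    """Partition atlas coverage by bp-level sharing.

    A base pair is *shared* when covered by every cell line, *specific* when
    covered by at least one but not all, and *unique* (a subset of specific)
    when covered by exactly one.  Region counts are those of the
    re-fragmented sets, so a region partially shared splits into several.
    """
    n = len(atlas.celllines)
    layout = atlas.layout
    arrays = {c: [atlas.per_cellline[cl].chrom_array(c) for cl in atlas.celllines]
              for c in layout.chroms}
    shared = IntervalSet(layout, {c: coverage_select(a, n) for c, a in arrays.items()})
    specific = IntervalSet(
        layout, {c: coverage_select(a, 1, n - 1) for c, a in arrays.items()}
    ) if n > 1 else IntervalSet.empty(layout)
    unique = IntervalSet(
        layout, {c: coverage_select(a, 1, 1) for c, a in arrays.items()}
    ) if n > 1 else IntervalSet.empty(layout)
    return {SHARED: shared, SPECIFIC: specific, UNIQUE: unique}


def partition_gene_neighboring(
    regions: IntervalSet, tss_windows: IntervalSet
) -> dict[str, IntervalSet]:
    """Split a region set into gene-neighboring (within any TSS window) and distal."""
    gn = regions.intersect(tss_windows)
    return {"gene_neighboring": gn, "distal": regions.subtract(tss_windows)}


def cross_assay_overlap(
    dhs: IntervalSet, ha: IntervalSet, hr: IntervalSet
) -> dict[str, int]:
    """7-part Venn decomposition (bp) of the three assay atlases.

    Keys: ``dhs_only, ha_only, hr_only, dhs_ha, dhs_hr, ha_hr, dhs_ha_hr``;
    the parts are disjoint and sum to the bp of the three-way union.
    """
    triple = dhs.intersect(ha).intersect(hr)
    dhs_ha = dhs.intersect(ha).subtract(hr)
    dhs_hr = dhs.intersect(hr).subtract(ha)
    ha_hr = ha.intersect(hr).subtract(dhs)
    return {
        "dhs_only": dhs.subtract(ha).subtract(hr).total_bp,
        "ha_only": ha.subtract(dhs).subtract(hr).total_bp,
        "hr_only": hr.subtract(dhs).subtract(ha).total_bp,
        "dhs_ha": dhs_ha.total_bp,
        "dhs_hr": dhs_hr.total_bp,
        "ha_hr": ha_hr.total_bp,
        "dhs_ha_hr": triple.total_bp,
    }


def overlap_fraction(a: IntervalSet, b: IntervalSet) -> float:
    """Fraction of a's base pairs overlapped by b (0 for an empty a)."""
    if a.total_bp == 0:
        return 0.0
    return a.overlap_bp(b) / a.total_bp


@dataclass
class AtlasSummary:
    """Total bp, region count and average length per category and context.

    ``table`` is indexed by (category, context) with categories
    ``overall / shared / cellline_specific`` and contexts
    ``genome_wide / gene_neighboring``.
    """

    assay: str
    table: pd.DataFrame

    def cell(self, category: str, context: str) -> pd.Series:
        return self.table.loc[(category, context)]

    @property
    def pct_gene_neighboring(self) -> float:
        """Percent of overall coverage that lies within TSS windows."""
        gw = self.cell("overall", "genome_wide")["total_bp"]
        gn = self.cell("overall", "gene_neighboring")["total_bp"]
        return 100.0 * gn / gw if gw else float("nan")

    @property
    def pct_cellline_specific(self) -> float:
        gw = self.cell("overall", "genome_wide")["total_bp"]
        sp = self.cell("cellline_specific", "genome_wide")["total_bp"]
        return 100.0 * sp / gw if gw else float("nan")

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")


def summarize_atlas(atlas: Atlas, tss_windows: IntervalSet) -> AtlasSummary:
    """Fill every (category x context) cell of the atlas summary."""
    parts = split_by_sharing(atlas)
    category_sets = {
        "overall": atlas.union,
        SHARED: parts[SHARED],
        SPECIFIC: parts[SPECIFIC],
    }
    rows = []
    for category, cset in category_sets.items():
        for context, ctx_set in (
            ("genome_wide", cset),
            ("gene_neighboring", cset.intersect(tss_windows)),
        ):
            bp = ctx_set.total_bp
            cnt = ctx_set.region_count
            rows.append(
                {
                    "category": category,
                    "context": context,
                    "total_bp": bp,
                    "region_count": cnt,
                    "average_length_bp": (bp / cnt) if cnt else float("nan"),
                }
            )
    table = pd.DataFrame(rows).set_index(["category", "context"])
    return AtlasSummary(atlas.assay, table)
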