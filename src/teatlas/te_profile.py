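"""TE composition, class enrichment, age profiles and human-specific ratios.

Composition is base-pair accounting: the TE content of a region set is the
bp of the set covered by the union of TE annotations (double-covered bp
counted once), with per-class bp computed against each class's own union.
Enrichment of a TE class within a region category versus the genome is a
2x2 Pearson chi-square on bp counts {class, other TE} x {regions, genome} —
length fractions, not element counts, following the convention that
regulatory TE contribution is measured in sequence length.

Insertion age is proxied by percent divergence of each TE copy from its
family consensus; a TE contributes its divergence to a region category's
age profile when it overlaps that category by at least 1 bp (configurable
to a majority-bp rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .formats import TE_CLASSES, TERecord
from .intervals import GenomeLayout, IntervalSet

__all__ = [
    "TECompositionTable",
    "EnrichmentResult",
    "AgeProfile",
    "TTestResult",
    "te_union",
    "compose_te",
    "chi_square_representation",
    "age_profile",
    "te_members",
    "compare_mean_divergence",
    "hste_ratio",
]


def te_union(
    tes: Iterable[TERecord], layout: GenomeLayout, te_class: str | None = None
) -> IntervalSet:
    """Normalized union of TE footprints, optionally restricted to one class."""
    return IntervalSet.from_pairs(
        layout,
        (
            (r.chrom, r.start, r.end)
            for r in tes
            if te_class is None or r.te_class == te_class
        ),
    )


@dataclass
class TECompositionTable:
    """bp and fragment accounting of TE content for one region category.

    ``te_fragment_count`` counts maximal contiguous pieces of TE-within-region
    coverage (abutting same-class pieces coalesce); ``class_bp`` covers the
    four explicit classes, with the remainder in ``other_bp``.
    """

    label: str
    total_regulatory_bp: int
    te_bp: int
    te_fragment_count: int
    class_bp: dict[str, int]
    class_fragments: dict[str, int]

    @property
    def te_pct(self) -> float:
        """TE fraction of the region set, in [0, 1]."""
        return self.te_bp / self.total_regulatory_bp if self.total_regulatory_bp else float("nan")

    @property
    def other_bp(self) -> int:
        return self.te_bp - sum(self.class_bp.values())

    def relative_pct(self, te_class: str) -> float:
        """Class bp as a fraction of total TE bp, in [0, 1]."""
        return self.class_bp[te_class] / self.te_bp if self.te_bp else float("nan")

    def to_row(self) -> dict:
        row = {
            "category": self.label,
            "total_regulatory_bp": self.total_regulatory_bp,
            "te_bp": self.te_bp,
            "te_pct": self.te_pct,
            "te_fragments": self.te_fragment_count,
        }
        for c in TE_CLASSES:
            row[f"{c}_bp"] = self.class_bp[c]
        return row


def compose_te(
    regions: IntervalSet,
    tes: Sequence[TERecord],
    label: str = "",
) -> TECompositionTable:
    """TE composition of a region set (overlapping TE input records allowed)."""
    layout = regions.layout
    all_union = te_union(tes, layout)
    te_cover = regions.intersect(all_union)
    class_bp: dict[str, int] = {}
    class_frags: dict[str, int] = {}
    for c in TE_CLASSES:
        cover = regions.intersect(te_union(tes, layout, c))
        class_bp[c] = cover.total_bp
        class_frags[c] = cover.region_count
    return TECompositionTable(
        label=label,
        total_regulatory_bp=regions.total_bp,
        te_bp=te_cover.total_bp,
        te_fragment_count=te_cover.region_count,
        class_bp=class_bp,
        class_fragments=class_frags,
    )


@dataclass(frozen=True)
class EnrichmentResult:
    """Chi-square over/under-representation call for one TE class."""

    te_class: str
    observed_bp: int          # class bp in the region set
    observed_te_bp: int       # all-TE bp in the region set
    background_bp: int        # class bp in the background (genome)
    background_te_bp: int     # all-TE bp in the background
    chi2_stat: float
    p_value: float
    direction: str            # over | under | none

    @property
    def observed_fraction(self) -> float:
        return self.observed_bp / self.observed_te_bp if self.observed_te_bp else float("nan")

    @property
    def background_fraction(self) -> float:
        return self.background_bp / self.background_te_bp if self.background_te_bp else float("nan")


def chi_square_representation(
    comp: TECompositionTable,
    genome_background: TECompositionTable,
    te_class: str,
    alpha: float = 1e-4,
) -> EnrichmentResult:
    """Pearson chi-square (no continuity correction) for one class's share of TE bp.

    Contingency: rows {te_class bp, other-TE bp}, columns {region set, genome}.
    ``direction`` is ``over``/``under`` only when the relative fraction differs
    in that direction *and* p < alpha (default 1e-4, matching the convention
    of reporting enrichment at p < 0.0001).
    """
    a, b = comp.class_bp[te_class], comp.te_bp - comp.class_bp[te_class]
    c, d = (
        genome_background.class_bp[te_class],
        genome_background.te_bp - genome_background.class_bp[te_class],
    )
    table = np.array([[a, b], [c, d]], dtype=np.float64)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        import warnings

        warnings.warn(
            f"degenerate contingency for {te_class}: zero margin, p undefined",
            stacklevel=2,
        )
        chi2, p = float("nan"), float("nan")
        direction = "none"
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        obs = a / (a + b)
        bg = c / (c + d)
        if p < alpha and obs > bg:
            direction = "over"
        elif p < alpha and obs < bg:
            direction = "under"
        else:
            direction = "none"
    return EnrichmentResult(
        te_class=te_class,
        observed_bp=a,
        observed_te_bp=comp.te_bp,
        background_bp=c,
        background_te_bp=genome_background.te_bp,
        chi2_stat=float(chi2),
        p_value=float(p),
        direction=direction,
    )


@dataclass
class AgeProfile:
    """Divergence histogram and mean for the TEs of one class in one category."""

    te_class: str
    label: str
    bin_width: float
    divergences: np.ndarray

    @property
    def n(self) -> int:
        return int(self.divergences.size)

    @property
    def mean_divergence(self) -> float:
        return float(self.divergences.mean()) if self.n else float("nan")

    def histogram(self) -> tuple[np.ndarray, np.ndarray]:
        """(bin_edges, counts); counts sum to n."""
        if self.n == 0:
            return np.array([0.0, self.bin_width]), np.array([0])
        top = np.ceil(max(self.divergences.max(), self.bin_width) / self.bin_width)
        edges = np.arange(0, (top + 1) * self.bin_width, self.bin_width)
        counts, edges = np.histogram(self.divergences, bins=edges)
        return edges, counts

    def to_frame(self) -> pd.DataFrame:
        edges, counts = self.histogram()
        return pd.DataFrame(
            {
                "te_class": self.te_class,
                "category": self.label,
                "bin_low": edges[:-1],
                "count": counts,
            }
        )


def te_members(
    regions: IntervalSet,
    tes: Sequence[TERecord],
    rule: str = "any",
) -> list[TERecord]:
    """TE records belonging to a region category.

    ``rule="any"``: membership by >= 1 bp overlap (default; a TE straddling
    two categories contributes to both).  ``rule="majority"``: more than half
    of the TE's length must lie inside the region set.
    """
    out = []
    by_chrom: dict[str, list[tuple[int, TERecord]]] = {}
    for i, r in enumerate(tes):
        by_chrom.setdefault(r.chrom, []).append((i, r))
    keep = np.zeros(len(tes), dtype=bool)
    for chrom, items in by_chrom.items():
        if chrom not in regions.layout:
            raise ValueError(f"TE record on unknown chromosome {chrom!r}")
        starts = np.array([r.start for _, r in items], dtype=np.int64)
        ends = np.array([r.end for _, r in items], dtype=np.int64)
        ov = regions.overlap_bp_ranges(chrom, starts, ends)
        if rule == "any":
            sel = ov >= 1
        elif rule == "majority":
            sel = ov * 2 > (ends - starts)
        else:
            raise ValueError(f"unknown membership rule {rule!r}")
        for (i, _), s in zip(items, sel):
            keep[i] = s
    return [r for i, r in enumerate(tes) if keep[i]]


def age_profile(
    regions: IntervalSet,
    tes: Sequence[TERecord],
    bin_width: float = 1.0,
    label: str = "",
    rule: str = "any",
) -> dict[str, AgeProfile]:
    """Per-class age profile of the TEs overlapping a region set."""
    members = te_members(regions, tes, rule=rule)
    out: dict[str, AgeProfile] = {}
    for c in TE_CLASSES + ("OTHER",):
        divs = np.array(
            [r.divergence_pct for r in members if r.te_class == c], dtype=np.float64
        )
        out[c] = AgeProfile(c, label, bin_width, divs)
    return out


@dataclass(frozen=True)
class TTestResult:
    t_stat: float
    p_value: float
    n_a: int
    n_b: int

    @property
    def ok(self) -> bool:
        """False when either group was too small for the test (p undefined)."""
        return self.n_a >= 2 and self.n_b >= 2


def compare_mean_divergence(
    a: AgeProfile | np.ndarray,
    b: AgeProfile | np.ndarray,
    equal_var: bool = False,
) -> TTestResult:
    """Two-sample two-tailed t-test on divergence values.

    Welch (unequal variance) by default; ``equal_var=True`` restores the
    pooled-variance test.  Groups with n < 2 yield an undefined result
    (``ok`` is False) rather than an exception.
    """
    va = a.divergences if isinstance(a, AgeProfile) else np.asarray(a, dtype=float)
    vb = b.divergences if isinstance(b, AgeProfile) else np.asarray(b, dtype=float)
    if va.size < 2 or vb.size < 2:
        return TTestResult(float("nan"), float("nan"), va.size, vb.size)
    if va.var(ddof=1) == 0 and vb.var(ddof=1) == 0 and va.mean() == vb.mean():
        # two identical constant groups: no evidence of difference
        return TTestResult(0.0, 1.0, va.size, vb.size)
    t, p = stats.ttest_ind(va, vb, equal_var=equal_var)
    return TTestResult(float(t), float(p), va.size, vb.size)


def hste_ratio(
    regions_by_bucket: Mapping[str, IntervalSet],
    tes: Sequence[TERecord],
    rule: str = "any",
) -> dict[str, tuple[int, int, float | None]]:
    """Human-specific-TE share of the TEs overlapping each region bucket.

    Returns ``bucket -> (hste_count, te_count, ratio)`` with ``ratio`` None
    when the bucket overlaps no TEs.
    """
    out: dict[str, tuple[int, int, float | None]] = {}
    for bucket, regions in regions_by_bucket.items():
        members = te_members(regions, tes, rule=rule)
        n = len(members)
        h = sum(1 for r in members if r.is_human_specific)
        out[bucket] = (h, n, (h / n) if n else None)
    return out
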