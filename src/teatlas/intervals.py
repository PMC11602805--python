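"""Exact set arithmetic on genomic intervals.

Everything downstream — atlas construction, TE composition, gene scoring —
reduces to operations on :class:`IntervalSet`: a per-chromosome collection of
sorted, disjoint, half-open ``[start, end)`` intervals tied to a
:class:`GenomeLayout`.  The implementation is an event sweep over interval
endpoints (coverage-depth selection), which makes union, intersection,
subtraction and k-of-N coverage queries all instances of one primitive.

Coordinates are 0-based half-open throughout (BED convention).  Strand is
ignored: peaks and TSS-flanking windows are unstranded and the flank is
symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomeLayout",
    "IntervalSet",
    "LayoutMismatchError",
    "coverage_select",
    "window_around",
    "presence_mask",
]


class LayoutMismatchError(ValueError):
    """Two interval sets built on different genome layouts were combined."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths defining the coordinate space.

    Parameters
    ----------
    entries
        Sequence of ``(chrom_name, length_bp)`` pairs.  Names must be unique
        and lengths positive.  The order given here is the canonical
        iteration order for every downstream container.
    """

    entries: tuple[tuple[str, int], ...]

    def __init__(self, entries: Iterable[tuple[str, int]]):
        ents = tuple((str(c), int(n)) for c, n in entries)
        names = [c for c, _ in ents]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in layout")
        for c, n in ents:
            if n <= 0:
                raise ValueError(f"chromosome {c!r} has non-positive length {n}")
        object.__setattr__(self, "entries", ents)

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.entries)

    def length(self, chrom: str) -> int:
        for c, n in self.entries:
            if c == chrom:
                return n
        raise KeyError(f"unknown chromosome {chrom!r}")

    def __contains__(self, chrom: str) -> bool:
        return any(c == chrom for c, _ in self.entries)

    @property
    def total_bp(self) -> int:
        return sum(n for _, n in self.entries)

    def validate(self, chrom: str, start: int, end: int) -> None:
        """Raise if ``[start, end)`` is not a valid interval on this layout."""
        if chrom not in self:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if not (0 <= start < end <= self.length(chrom)):
            raise ValueError(
                f"invalid interval {chrom}:{start}-{end} "
                f"(chrom length {self.length(chrom)})"
            )


def _merge_pairs(arr: np.ndarray) -> np.ndarray:
    """Coalesce a (n, 2) array of raw intervals into sorted disjoint ones.

    Overlapping *and abutting* intervals are merged, so the result satisfies
    ``end_i < start_{i+1}``.
    """
    if arr.shape[0] == 0:
        return arr.reshape(0, 2)
    order = np.lexsort((arr[:, 1], arr[:, 0]))
    arr = arr[order]
    starts, ends = arr[:, 0], arr[:, 1]
    # new run begins where start > running max of previous ends
    run_end = np.maximum.accumulate(ends)
    new_run = np.empty(len(arr), dtype=bool)
    new_run[0] = True
    new_run[1:] = starts[1:] > run_end[:-1]
    idx = np.flatnonzero(new_run)
    out = np.empty((len(idx), 2), dtype=np.int64)
    out[:, 0] = starts[idx]
    last = np.append(idx[1:], len(arr)) - 1
    out[:, 1] = run_end[last]
    return out


def _depth_segments(arrays: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sweep endpoints of several disjoint-sorted interval arrays.

    Returns ``(bounds_lo, bounds_hi, depth)`` for maximal segments of constant
    coverage depth > 0 consideration domain (segments of depth 0 between
    covered ones are included so callers can select any depth band).
    """
    if not arrays or all(a.shape[0] == 0 for a in arrays):
        empty = np.empty(0, dtype=np.int64)
        return empty, empty, empty
    pts = np.concatenate(
        [a[:, 0] for a in arrays if a.shape[0]] + [a[:, 1] for a in arrays if a.shape[0]]
    )
    n = pts.shape[0] // 2
    delta = np.concatenate([np.ones(n, dtype=np.int64), -np.ones(n, dtype=np.int64)])
    order = np.lexsort((delta, pts))  # at ties, ends (-1) processed first
    pts_s = pts[order]
    cov = np.cumsum(delta[order])
    uniq, last = np.unique(pts_s[::-1], return_index=True)
    last = pts_s.shape[0] - 1 - last  # index of last event at each unique point
    depth = cov[last]
    return uniq[:-1], uniq[1:], depth[:-1]


def coverage_select(
    arrays: Sequence[np.ndarray], lo: int, hi: int | None = None
) -> np.ndarray:
    """Merged intervals where coverage depth over ``arrays`` lies in [lo, hi]."""
    b0, b1, depth = _depth_segments(arrays)
    if b0.shape[0] == 0:
        return np.empty((0, 2), dtype=np.int64)
    mask = depth >= lo if hi is None else (depth >= lo) & (depth <= hi)
    if not mask.any():
        return np.empty((0, 2), dtype=np.int64)
    return _merge_pairs(np.stack([b0[mask], b1[mask]], axis=1))


class IntervalSet:
    """Sorted disjoint half-open intervals on one genome layout.

    Construct via :meth:`from_pairs` (which normalizes arbitrary input) or the
    set-algebra methods of an existing instance.  Instances are immutable in
    practice; all operations return new sets.
    """

    __slots__ = ("layout", "_ivs", "_total_bp")

    def __init__(self, layout: GenomeLayout, per_chrom: Mapping[str, np.ndarray]):
        # internal constructor: per_chrom arrays must already be normalized
        self.layout = layout
        self._ivs: dict[str, np.ndarray] = {
            c: np.asarray(per_chrom.get(c, np.empty((0, 2), dtype=np.int64)), dtype=np.int64)
            for c in layout.chroms
        }
        self._total_bp = int(
            sum((a[:, 1] - a[:, 0]).sum() for a in self._ivs.values())
        )

    # -- construction -----------------------------------------------------

    @classmethod
    def from_pairs(
        cls, layout: GenomeLayout, pairs: Iterable[tuple[str, int, int]]
    ) -> "IntervalSet":
        """Normalize raw ``(chrom, start, end)`` triples into an IntervalSet."""
        buckets: dict[str, list[tuple[int, int]]] = {c: [] for c in layout.chroms}
        for chrom, start, end in pairs:
            layout.validate(chrom, start, end)
            buckets[chrom].append((int(start), int(end)))
        per_chrom = {
            c: _merge_pairs(np.array(v, dtype=np.int64).reshape(-1, 2))
            for c, v in buckets.items()
        }
        return cls(layout, per_chrom)

    @classmethod
    def empty(cls, layout: GenomeLayout) -> "IntervalSet":
        return cls(layout, {})

    @classmethod
    def whole_genome(cls, layout: GenomeLayout) -> "IntervalSet":
        return cls(
            layout,
            {c: np.array([[0, layout.length(c)]], dtype=np.int64) for c in layout.chroms},
        )

    # -- basic accessors --------------------------------------------------

    @property
    def total_bp(self) -> int:
        """Sum of interval lengths across all chromosomes."""
        return self._total_bp

    @property
    def region_count(self) -> int:
        return sum(a.shape[0] for a in self._ivs.values())

    def chrom_array(self, chrom: str) -> np.ndarray:
        """(n, 2) int64 array of intervals on ``chrom`` (may be empty)."""
        return self._ivs[chrom]

    def to_pairs(self) -> list[tuple[str, int, int]]:
        out: list[tuple[str, int, int]] = []
        for c in self.layout.chroms:
            for s, e in self._ivs[c]:
                out.append((c, int(s), int(e)))
        return out

    def __iter__(self) -> Iterator[tuple[str, int, int]]:
        return iter(self.to_pairs())

    def __len__(self) -> int:
        return self.region_count

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.layout == other.layout and all(
            np.array_equal(self._ivs[c], other._ivs[c]) for c in self.layout.chroms
        )

    def __repr__(self) -> str:
        return f"IntervalSet({self.region_count} regions, {self.total_bp} bp)"

    def _check_layout(self, other: "IntervalSet") -> None:
        if self.layout != other.layout:
            raise LayoutMismatchError("interval sets built on different layouts")

    # -- set algebra ------------------------------------------------------

    def union(self, other: "IntervalSet") -> "IntervalSet":
        self._check_layout(other)
        return IntervalSet(
            self.layout,
            {
                c: coverage_select([self._ivs[c], other._ivs[c]], 1)
                for c in self.layout.chroms
            },
        )

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        self._check_layout(other)
        return IntervalSet(
            self.layout,
            {
                c: coverage_select([self._ivs[c], other._ivs[c]], 2)
                for c in self.layout.chroms
            },
        )

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        self._check_layout(other)
        return self.intersect(other.complement())

    def complement(self) -> "IntervalSet":
        per_chrom = {}
        for c in self.layout.chroms:
            bounds = np.array([[0, self.layout.length(c)]], dtype=np.int64)
            per_chrom[c] = coverage_select([bounds, self._ivs[c]], 1, 1)
        return IntervalSet(self.layout, per_chrom)

    def overlap_bp(self, other: "IntervalSet") -> int:
        """Base pairs shared between the two sets."""
        return self.intersect(other).total_bp

    def __or__(self, other: "IntervalSet") -> "IntervalSet":
        return self.union(other)

    def __and__(self, other: "IntervalSet") -> "IntervalSet":
        return self.intersect(other)

    def __sub__(self, other: "IntervalSet") -> "IntervalSet":
        return self.subtract(other)

    # -- fast range queries ----------------------------------------------

    def overlap_bp_ranges(
        self, chrom: str, starts: np.ndarray, ends: np.ndarray
    ) -> np.ndarray:
        """Covered bp of this set within each query range, vectorized.

        Uses prefix sums of covered length: for a disjoint sorted set the
        covered bp below position x is piecewise linear, so per-query overlap
        is two evaluations.  Exactly equals ``overlap_bp`` with a one-interval
        set but O(log n) per query.
        """
        ivs = self._ivs[chrom]
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if ivs.shape[0] == 0:
            return np.zeros(starts.shape, dtype=np.int64)
        s, e = ivs[:, 0], ivs[:, 1]
        prefix = np.concatenate([[0], np.cumsum(e - s)])

        def covered_below(x: np.ndarray) -> np.ndarray:
            i = np.searchsorted(s, x, side="right")  # intervals starting before/at x
            base = prefix[i]
            # subtract the part of interval i-1 beyond x, if x falls inside it
            inside = i > 0
            j = np.maximum(i - 1, 0)
            overhang = np.clip(e[j] - x, 0, None)
            # only counts when x < e[j] and x >= s[j]
            overhang = np.where(inside & (x < e[j]), np.minimum(overhang, e[j] - s[j]), 0)
            return base - overhang

        return covered_below(ends) - covered_below(starts)


def window_around(
    points: Sequence, flank_bp: int, layout: GenomeLayout
) -> tuple[dict[str, tuple[str, int, int]], IntervalSet]:
    """Symmetric windows of ``flank_bp`` on either side of each TSS.

    ``points`` are objects with ``gene_id``, ``chrom`` and ``position``
    attributes.  Windows are clipped to chromosome bounds.  Returns the
    per-gene window and the normalized union of all windows (a bp near two
    TSSs counts once in the union).
    """
    if flank_bp <= 0:
        raise ValueError("flank_bp must be positive")
    per_gene: dict[str, tuple[str, int, int]] = {}
    pairs = []
    for p in points:
        lo = max(0, p.position - flank_bp)
        hi = min(layout.length(p.chrom), p.position + flank_bp)
        per_gene[p.gene_id] = (p.chrom, lo, hi)
        pairs.append((p.chrom, lo, hi))
    return per_gene, IntervalSet.from_pairs(layout, pairs)


def presence_mask(
    union: IntervalSet,
    per_sample_sets: Mapping[str, IntervalSet],
    min_overlap_bp: int = 1,
) -> tuple[list[tuple[str, int, int]], np.ndarray]:
    """Per-union-interval presence of each sample.

    ``union`` must be the true normalized union of the sample sets; a sample
    extending outside it is an error.  Bit ``(i, s)`` is set iff sample ``s``
    overlaps union interval ``i`` by at least ``min_overlap_bp``.

    Returns the interval list (layout chromosome order, then start) and a
    boolean matrix of shape ``(n_intervals, n_samples)`` with samples in the
    mapping's iteration order.
    """
    samples = list(per_sample_sets)
    intervals = union.to_pairs()
    mask = np.zeros((len(intervals), len(samples)), dtype=bool)
    # index of first union interval per chromosome, for piece -> interval mapping
    offsets: dict[str, int] = {}
    off = 0
    for c in union.layout.chroms:
        offsets[c] = off
        off += union.chrom_array(c).shape[0]
    for j, name in enumerate(samples):
        sample = per_sample_sets[name]
        union._check_layout(sample)
        if sample.subtract(union).total_bp != 0:
            raise ValueError(
                f"sample {name!r} extends outside the union; "
                "pass the true union of all sample sets"
            )
        for c in union.layout.chroms:
            uarr = union.chrom_array(c)
            if uarr.shape[0] == 0:
                continue
            pieces = coverage_select([uarr, sample.chrom_array(c)], 2)
            if pieces.shape[0] == 0:
                continue
            # each piece lies within exactly one union interval
            idx = np.searchsorted(uarr[:, 0], pieces[:, 0], side="right") - 1
            bp = np.zeros(uarr.shape[0], dtype=np.int64)
            np.add.at(bp, idx, pieces[:, 1] - pieces[:, 0])
            mask[offsets[c] : offsets[c] + uarr.shape[0], j] |= bp >= min_overlap_bp
    return intervals, mask
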