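"""Readers and writers for the standard file formats the pipeline touches.

All coordinates are converted to / validated as 0-based half-open at this
boundary; nothing downstream ever sees an unvalidated record.

Formats
-------
narrowPeak
    10-column tab-separated BED6+4 (ENCODE peak format).
rmsk
    Tab-separated RepeatMasker table, either with a named header containing
    at least ``genoName genoStart genoEnd strand repName repClass repFamily
    milliDiv`` (default) or the UCSC positional dialect.
TSS
    BED4+strand: ``chrom  pos  pos+1  gene_id  .  strand`` with an optional
    seventh gene-name column.
TSG catalog / cell-line map
    Two-column TSVs ``tissue<TAB>gene_id`` and ``cellline<TAB>tissue``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .intervals import GenomeLayout, IntervalSet

__all__ = [
    "GenomeLayout",
    "PeakRecord",
    "TERecord",
    "TSSRecord",
    "TSGCatalog",
    "FormatError",
    "DEFAULT_CLASS_MAP",
    "TE_CLASSES",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_rmsk_table",
    "write_rmsk_table",
    "read_tss_bed",
    "write_tss_bed",
    "read_tsg_catalog",
    "write_tsg_catalog",
    "read_cellline_map",
    "read_bed3",
    "write_bed3",
    "read_genome_layout",
    "write_genome_layout",
    "write_gene_cluster_table",
    "flag_human_specific",
    "peaks_to_intervals",
]

#: The four TE classes analyzed explicitly; everything else maps to OTHER.
TE_CLASSES = ("SINE", "LINE", "LTR", "DNA")

#: repClass -> te_class. Total mapping: raw classes absent here become OTHER.
DEFAULT_CLASS_MAP = {"SINE": "SINE", "LINE": "LINE", "LTR": "LTR", "DNA": "DNA"}


class FormatError(ValueError):
    """A file failed validation; the message carries file and line context."""


@dataclass(frozen=True)
class PeakRecord:
    """One narrowPeak line. Columns 7-10 are preserved verbatim on round-trip."""

    chrom: str
    start: int
    end: int
    name: str
    score: float
    strand: str
    signal: float
    p: float
    q: float
    summit: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TERecord:
    """One RepeatMasker annotation row.

    ``divergence_pct`` is the percent divergence from the family consensus
    (milliDiv / 10), the insertion-age proxy used throughout.
    """

    chrom: str
    start: int
    end: int
    strand: str
    rep_name: str
    te_class: str
    rep_family: str
    divergence_pct: float
    is_human_specific: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TSSRecord:
    """Principal-transcript transcription start site of one gene."""

    gene_id: str
    gene_name: str
    chrom: str
    position: int
    strand: str


@dataclass
class TSGCatalog:
    """Tissue-specific-gene catalog plus the cell-line -> tissue map."""

    tissue_to_genes: dict[str, set[str]]
    cellline_to_tissue: dict[str, str]

    def __post_init__(self) -> None:
        for cl, t in self.cellline_to_tissue.items():
            self.tissue_to_genes.setdefault(t, set())

    @property
    def tissues(self) -> list[str]:
        return sorted(self.tissue_to_genes)

    def celllines_of(self, tissue: str) -> list[str]:
        return sorted(
            cl for cl, t in self.cellline_to_tissue.items() if t == tissue
        )


# ---------------------------------------------------------------------------
# helpers

def _lines(path: str | Path):
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield ln, line


def _err(path, ln, msg) -> FormatError:
    return FormatError(f"{path}:{ln}: {msg}")


def _check_interval(layout: GenomeLayout, chrom: str, start: int, end: int,
                    path, ln) -> None:
    if chrom not in layout:
        raise _err(path, ln, f"unknown chromosome {chrom!r}")
    if not (0 <= start < end <= layout.length(chrom)):
        raise _err(
            path, ln,
            f"invalid interval {chrom}:{start}-{end} "
            f"(chrom length {layout.length(chrom)})",
        )


# ---------------------------------------------------------------------------
# narrowPeak

def read_narrowpeak(path: str | Path, layout: GenomeLayout) -> list[PeakRecord]:
    """Read an ENCODE narrowPeak (BED6+4) file, validating against *layout*."""
    out: list[PeakRecord] = []
    for ln, line in _lines(path):
        f = line.split("\t")
        if len(f) != 10:
            raise _err(path, ln, f"expected 10 tab-separated columns, got {len(f)}")
        try:
            rec = PeakRecord(
                chrom=f[0], start=int(f[1]), end=int(f[2]), name=f[3],
                score=float(f[4]), strand=f[5], signal=float(f[6]),
                p=float(f[7]), q=float(f[8]), summit=int(f[9]),
            )
        except ValueError as exc:
            raise _err(path, ln, f"malformed narrowPeak line: {exc}") from None
        if rec.strand not in ("+", "-", "."):
            raise _err(path, ln, f"invalid strand {rec.strand!r}")
        _check_interval(layout, rec.chrom, rec.start, rec.end, path, ln)
        out.append(rec)
    return out


def write_narrowpeak(records: Iterable[PeakRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{_num(r.score)}\t"
                f"{r.strand}\t{_num(r.signal)}\t{_num(r.p)}\t{_num(r.q)}\t{r.summit}\n"
            )


def _num(x: float) -> str:
    # integer-valued floats print without a trailing .0 for clean round-trips
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def peaks_to_intervals(records: Iterable[PeakRecord], layout: GenomeLayout) -> IntervalSet:
    """Collapse peak records into their (normalized) genomic footprint."""
    return IntervalSet.from_pairs(layout, ((r.chrom, r.start, r.end) for r in records))


# ---------------------------------------------------------------------------
# RepeatMasker table

_RMSK_REQUIRED = (
    "genoName", "genoStart", "genoEnd", "strand",
    "repName", "repClass", "repFamily", "milliDiv",
)

# column order of the UCSC rmsk dump (headerless positional dialect)
_UCSC_COLS = (
    "bin", "swScore", "milliDiv", "milliDel", "milliIns", "genoName",
    "genoStart", "genoEnd", "genoLeft", "strand", "repName", "repClass",
    "repFamily", "repStart", "repEnd", "repLeft", "id",
)


def read_rmsk_table(
    path: str | Path,
    layout: GenomeLayout,
    class_map: Mapping[str, str] | None = None,
    dialect: str = "header",
) -> list[TERecord]:
    """Read a RepeatMasker-style TE table.

    ``dialect`` is ``"header"`` (named columns, default) or ``"ucsc"``
    (positional UCSC rmsk dump).  A fractional ``divPct`` column, when
    present, is used verbatim instead of milliDiv/10.
    """
    cmap = dict(DEFAULT_CLASS_MAP if class_map is None else class_map)
    rows = list(_lines(path))
    if not rows:
        return []
    if dialect == "header":
        header = rows[0][1].split("\t")
        header = [h.lstrip("#") for h in header]
        missing = [c for c in _RMSK_REQUIRED if c not in header and not
                   (c == "milliDiv" and "divPct" in header)]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {missing}")
        col = {h: i for i, h in enumerate(header)}
        body = rows[1:]
    elif dialect == "ucsc":
        col = {h: i for i, h in enumerate(_UCSC_COLS)}
        body = rows
    else:
        raise ValueError(f"unknown rmsk dialect {dialect!r}")

    use_divpct = "divPct" in col
    out: list[TERecord] = []
    for ln, line in body:
        f = line.split("\t")
        try:
            chrom = f[col["genoName"]]
            start = int(f[col["genoStart"]])
            end = int(f[col["genoEnd"]])
            if use_divpct:
                div = float(f[col["divPct"]])
            else:
                milli = float(f[col["milliDiv"]])
                if milli < 0:
                    raise _err(path, ln, f"negative milliDiv {milli}")
                div = milli / 10.0
            rec = TERecord(
                chrom=chrom, start=start, end=end,
                strand=f[col["strand"]],
                rep_name=f[col["repName"]],
                te_class=cmap.get(f[col["repClass"]], "OTHER"),
                rep_family=f[col["repFamily"]],
                divergence_pct=div,
            )
        except FormatError:
            raise
        except (ValueError, IndexError) as exc:
            raise _err(path, ln, f"malformed rmsk row: {exc}") from None
        if div < 0:
            raise _err(path, ln, f"negative divergence {div}")
        _check_interval(layout, rec.chrom, rec.start, rec.end, path, ln)
        out.append(rec)
    return out


def write_rmsk_table(records: Iterable[TERecord], path: str | Path) -> None:
    """Write TE records in the named-header dialect (milliDiv in tenths of %)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_RMSK_REQUIRED) + "\n")
        for r in records:
            milli = int(round(r.divergence_pct * 10))
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.strand}\t{r.rep_name}\t"
                f"{r.te_class}\t{r.rep_family}\t{milli}\n"
            )


# ---------------------------------------------------------------------------
# TSS table

def read_tss_bed(path: str | Path, layout: GenomeLayout) -> list[TSSRecord]:
    """Read a TSS BED (chrom, pos, pos+1, gene_id, ., strand[, gene_name])."""
    out: list[TSSRecord] = []
    seen: set[str] = set()
    for ln, line in _lines(path):
        f = line.split("\t")
        if len(f) < 6:
            raise _err(path, ln, f"expected >=6 columns, got {len(f)}")
        try:
            pos, pos1 = int(f[1]), int(f[2])
        except ValueError as exc:
            raise _err(path, ln, f"malformed TSS line: {exc}") from None
        if pos1 != pos + 1:
            raise _err(path, ln, "TSS record must span exactly 1 bp")
        gene_id = f[3]
        if gene_id in seen:
            raise _err(path, ln, f"duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        _check_interval(layout, f[0], pos, pos1, path, ln)
        out.append(TSSRecord(
            gene_id=gene_id,
            gene_name=f[6] if len(f) > 6 else gene_id,
            chrom=f[0], position=pos, strand=f[5],
        ))
    return out


def write_tss_bed(records: Iterable[TSSRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.position}\t{r.position + 1}\t{r.gene_id}\t.\t"
                f"{r.strand}\t{r.gene_name}\n"
            )


# ---------------------------------------------------------------------------
# TSG catalog and cell-line map

def read_tsg_catalog(
    tsg_path: str | Path, cellline_map_path: str | Path
) -> TSGCatalog:
    tissue_to_genes: dict[str, set[str]] = {}
    n = 0
    for ln, line in _lines(tsg_path):
        f = line.split("\t")
        if len(f) != 2:
            raise _err(tsg_path, ln, f"expected 2 columns (tissue, gene), got {len(f)}")
        tissue_to_genes.setdefault(f[0], set()).add(f[1])
        n += 1
    if n == 0:
        raise FormatError(f"{tsg_path}: empty TSG catalog (no tissues)")
    cellline_to_tissue = read_cellline_map(cellline_map_path)
    return TSGCatalog(tissue_to_genes, cellline_to_tissue)


def write_tsg_catalog(catalog: TSGCatalog, tsg_path: str | Path,
                      cellline_map_path: str | Path) -> None:
    with open(tsg_path, "w") as fh:
        for tissue in sorted(catalog.tissue_to_genes):
            for gene in sorted(catalog.tissue_to_genes[tissue]):
                fh.write(f"{tissue}\t{gene}\n")
    with open(cellline_map_path, "w") as fh:
        for cl in sorted(catalog.cellline_to_tissue):
            fh.write(f"{cl}\t{catalog.cellline_to_tissue[cl]}\n")


def read_cellline_map(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for ln, line in _lines(path):
        f = line.split("\t")
        if len(f) != 2:
            raise _err(path, ln, f"expected 2 columns (cellline, tissue), got {len(f)}")
        if f[0] in out:
            raise _err(path, ln, f"duplicate cell line {f[0]!r}")
        out[f[0]] = f[1]
    return out


# ---------------------------------------------------------------------------
# BED3 / layout / exports

def read_bed3(path: str | Path, layout: GenomeLayout) -> IntervalSet:
    pairs = []
    for ln, line in _lines(path):
        f = line.split("\t")
        if len(f) < 3:
            raise _err(path, ln, f"expected >=3 columns, got {len(f)}")
        try:
            start, end = int(f[1]), int(f[2])
        except ValueError as exc:
            raise _err(path, ln, f"malformed BED line: {exc}") from None
        _check_interval(layout, f[0], start, end, path, ln)
        pairs.append((f[0], start, end))
    return IntervalSet.from_pairs(layout, pairs)


def write_bed3(intervals: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_genome_layout(path: str | Path) -> GenomeLayout:
    """Two-column TSV ``chrom<TAB>length`` (samtools .fai-style prefix)."""
    entries = []
    for ln, line in _lines(path):
        f = line.split("\t")
        if len(f) < 2:
            raise _err(path, ln, "expected chrom<TAB>length")
        entries.append((f[0], int(f[1])))
    if not entries:
        raise FormatError(f"{path}: empty genome layout")
    return GenomeLayout(entries)


def write_genome_layout(layout: GenomeLayout, path: str | Path) -> None:
    with open(path, "w") as fh:
        for c, n in layout.entries:
            fh.write(f"{c}\t{n}\n")


def write_gene_cluster_table(
    calls: Iterable[tuple[str, str]], path: str | Path
) -> None:
    """Two-column gene/cluster TSV for GO-enrichment web tools.

    ``calls`` are ``(gene_id, cluster_name)`` pairs; output is sorted by
    cluster then gene, one pair per line, deduplicated.
    """
    uniq = sorted(set(calls), key=lambda gc: (gc[1], gc[0]))
    with open(path, "w") as fh:
        for gene, cluster in uniq:
            fh.write(f"{gene}\t{cluster}\n")


# ---------------------------------------------------------------------------
# human-specific TE flagging

def flag_human_specific(
    tes: Sequence[TERecord],
    hste: IntervalSet,
    mode: str = "exact",
    min_reciprocal: float = 0.9,
) -> list[TERecord]:
    """Return TE records with ``is_human_specific`` set from an HSTE list.

    ``mode="exact"`` flags TEs whose (chrom, start, end) appears verbatim in
    the HSTE set; ``mode="reciprocal"`` requires >= ``min_reciprocal``
    overlap of both the TE and the HSTE interval (coordinates in deposited
    HSTE lists may be trimmed relative to RepeatMasker).
    """
    if mode == "exact":
        key = {(c, s, e) for c, s, e in hste}
        return [
            r if ((r.chrom, r.start, r.end) not in key)
            else TERecord(**{**_as_dict(r), "is_human_specific": True})
            for r in tes
        ]
    if mode != "reciprocal":
        raise ValueError(f"unknown HSTE matching mode {mode!r}")
    out = []
    for r in tes:
        flagged = False
        arr = hste.chrom_array(r.chrom)
        if arr.shape[0]:
            i = np.searchsorted(arr[:, 0], r.end)
            for s, e in arr[max(0, i - 2): i + 1]:
                ov = min(e, r.end) - max(s, r.start)
                if ov > 0 and ov >= min_reciprocal * (e - s) and ov >= min_reciprocal * r.length:
                    flagged = True
                    break
        out.append(
            TERecord(**{**_as_dict(r), "is_human_specific": True}) if flagged else r
        )
    return out


def _as_dict(r: TERecord) -> dict:
    return {
        "chrom": r.chrom, "start": r.start, "end": r.end, "strand": r.strand,
        "rep_name": r.rep_name, "te_class": r.te_class,
        "rep_family": r.rep_family, "divergence_pct": r.divergence_pct,
        "is_human_specific": r.is_human_specific,
    }
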