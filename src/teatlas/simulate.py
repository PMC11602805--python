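"""Seeded synthetic-cohort generator.

Produces a complete miniature cohort — genome layout, RepeatMasker-style TE
annotation, per-(cell line, assay) narrowPeak files, TSS table, TSG catalog,
cell-line map and a human-specific-TE list — in exactly the formats of
:mod:`teatlas.formats`, together with a truth table recording every planted
label, so the whole pipeline is testable without any downloads.

Planted statistical structure
-----------------------------
* genome ~48% TE by bp, four classes with class-specific divergence models
  (SINEs bimodal: a young and an old component; LINEs/LTRs/DNA unimodal old);
* one chromosome hosts the *atlas zone*: per-assay archetype regions planted
  as all-cell-line shared, subset-specific or single-cell-line unique, with
  placement weights implementing per-(assay, class) enrichment multipliers
  and an age bias (shared regions prefer older TEs, unique regions younger);
* the other chromosome hosts the *gene zone*: evenly spaced TSSs whose
  neighborhoods carry planted regulatory peaks with exact TE coverage, giving
  each (gene, cell line, assay) a known regulatory TE density — background
  genes low, TE-regulated genes high, tissue-specific genes elevated (or
  exclusive, or deliberately leaky) in their own tissue's cell lines;
* human-specific TEs are a random subset of the youngest TEs, so their share
  is highest where young TEs concentrate (cell-line-unique regions).

Gene-zone lanes for different cell-line groups are disjoint and free of
filler TEs, so planted densities are exact by construction and the truth
table records the realized values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formats import (
    PeakRecord,
    TERecord,
    TSGCatalog,
    TSSRecord,
    write_bed3,
    write_genome_layout,
    write_narrowpeak,
    write_rmsk_table,
    write_tsg_catalog,
    write_tss_bed,
)
from .intervals import GenomeLayout, IntervalSet

__all__ = ["CohortSpec", "InfeasibleSpecError", "generate", "load_truth",
           "truth_positive_genes", "truth_exclusive_genes", "truth_compare"]


class InfeasibleSpecError(ValueError):
    """The requested cohort cannot be realized (e.g. TE fraction unattainable)."""


_DEFAULT_CELLLINES = {
    "GM12878": "blood",
    "Karpas-422": "blood",
    "HepG2": "liver",
    "IMR-90": "lung",
    "SK-N-SH": "brain",
    "GM23248": "skin",
}

# (mean, sd, clip_lo, clip_hi) of peak lengths per assay, bp
_DEFAULT_PEAK_LEN = {
    "DHS": (220.0, 25.0, 140, 300),
    "HA": (1900.0, 60.0, 1700, 1990),
    "HR": (950.0, 60.0, 700, 1130),
}

# divergence mixture per class: list of (weight, mean, sd); truncated at 0
_DEFAULT_DIVERGENCE = {
    "SINE": [(0.5, 8.0, 3.0), (0.5, 25.0, 3.0)],
    "LINE": [(1.0, 26.0, 4.0)],
    "LTR": [(1.0, 22.0, 4.0)],
    "DNA": [(1.0, 24.0, 4.0)],
    "OTHER": [(1.0, 20.0, 5.0)],
}

_DEFAULT_TE_LEN = {  # (mean, sd, lo) of TE element lengths, bp
    "SINE": (300.0, 80.0, 60),
    "LINE": (900.0, 250.0, 120),
    "LTR": (500.0, 150.0, 80),
    "DNA": (300.0, 90.0, 60),
    "OTHER": (200.0, 60.0, 40),
}


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort; defaults are the study conditions."""

    seed: int = 0
    layout: GenomeLayout = field(
        default_factory=lambda: GenomeLayout(
            [("chr1", 3_000_000), ("chr2", 4_600_000)]
        )
    )
    atlas_chrom: str = "chr1"
    gene_chrom: str = "chr2"
    celllines: dict[str, str] = field(
        default_factory=lambda: dict(_DEFAULT_CELLLINES)
    )
    genome_te_fraction: float = 0.48
    class_mix: dict[str, float] = field(
        default_factory=lambda: {
            "SINE": 0.28, "LINE": 0.36, "LTR": 0.19, "DNA": 0.07, "OTHER": 0.10
        }
    )
    divergence_models: dict[str, list[tuple[float, float, float]]] = field(
        default_factory=lambda: {k: list(v) for k, v in _DEFAULT_DIVERGENCE.items()}
    )
    te_length_models: dict[str, tuple[float, float, int]] = field(
        default_factory=lambda: dict(_DEFAULT_TE_LEN)
    )
    peak_length_models: dict[str, tuple[float, float, int, int]] = field(
        default_factory=lambda: dict(_DEFAULT_PEAK_LEN)
    )
    # atlas-zone archetype counts per assay
    n_shared: int = 70
    n_subset: int = 140
    n_unique_per_line: int = 20
    # per-(assay, class) enrichment multipliers applied as placement weights
    enrichment_multipliers: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "DHS": {"LTR": 2.0},
            "HA": {"SINE": 2.0},
            "HR": {"LTR": 2.0},
        }
    )
    shared_age_coef: float = 0.25    # log-weight per % divergence, shared regions
    unique_age_coef: float = -0.35   # idem, unique regions (younger preferred)
    peak_jitter_bp: int = 25
    # gene zone
    n_genes: int = 500
    gene_spacing_bp: int = 9000
    gene_zone_half_bp: int = 3800
    n_te_regulated: int = 50
    tsg_per_tissue: int = 12
    n_exclusive_per_tissue: int = 4
    n_leaky_per_tissue: int = 2
    # planted density ranges (lo, hi) per gene category
    density_background: tuple[float, float] = (0.0, 0.05)
    density_te_regulated: tuple[float, float] = (0.4, 0.6)
    density_tsg_own: tuple[float, float] = (0.32, 0.6)
    density_tsg_other: tuple[float, float] = (0.02, 0.08)
    density_exclusive_own: tuple[float, float] = (0.2, 0.6)
    density_leaky_other: tuple[float, float] = (0.01, 0.04)
    gene_zone_sine_bias: float = 1.8  # SINE weight multiplier for gene-zone TEs
    min_fragment_bp: int = 15
    # human-specific TEs
    hste_divergence_max: float = 5.0
    hste_fraction: float = 0.6

    @property
    def assays(self) -> tuple[str, ...]:
        return tuple(self.peak_length_models)

    @property
    def tissues(self) -> list[str]:
        return sorted(set(self.celllines.values()))

    def validate(self) -> None:
        if not (0 < self.genome_te_fraction < 1):
            raise InfeasibleSpecError("genome_te_fraction must be in (0, 1)")
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise InfeasibleSpecError("class_mix must sum to 1")
        for lo, hi in (
            self.density_background, self.density_te_regulated,
            self.density_tsg_own, self.density_tsg_other,
            self.density_exclusive_own, self.density_leaky_other,
        ):
            if not (0 <= lo <= hi <= 1):
                raise InfeasibleSpecError("density ranges must satisfy 0<=lo<=hi<=1")
        # lane plan must fit inside the gene zone
        widths = self._lane_widths()
        need = sum(w for _, _, w in widths) + 90 * len(widths)
        if need > 2 * self.gene_zone_half_bp:
            raise InfeasibleSpecError(
                f"gene-zone lanes need {need} bp but the zone holds "
                f"{2 * self.gene_zone_half_bp}"
            )
        # gene zone must fit on the gene chromosome
        span = self._first_tss() + (self.n_genes - 1) * self.gene_spacing_bp \
            + self.gene_zone_half_bp
        if span > self.layout.length(self.gene_chrom):
            raise InfeasibleSpecError(
                f"{self.n_genes} genes at {self.gene_spacing_bp} bp spacing do "
                f"not fit on {self.gene_chrom}"
            )
        # neighborhood windows of adjacent genes must not reach each other's lanes
        if self.gene_spacing_bp - self.gene_zone_half_bp < 5000:
            raise InfeasibleSpecError(
                "gene spacing too tight: a neighbor's 5 Kb flank reaches this "
                "gene's peak lanes"
            )
        n_tsg = self.tsg_per_tissue * len(self.tissues)
        if self.n_te_regulated + n_tsg > self.n_genes:
            raise InfeasibleSpecError("more planted genes than n_genes")
        if self.n_exclusive_per_tissue + self.n_leaky_per_tissue > self.tsg_per_tissue:
            raise InfeasibleSpecError("exclusive + leaky exceed tsg_per_tissue")

    def _first_tss(self) -> int:
        return max(5000, self.gene_zone_half_bp) + 2200

    def _lane_widths(self) -> list[tuple[str, str, int]]:
        """(assay, lane, width) in fixed order; lane A = own group, B = rest."""
        out = []
        for assay in self.assays:
            hi = self.peak_length_models[assay][3]
            for lane in ("A", "B"):
                out.append((assay, lane, hi + 20))
        return out


# ---------------------------------------------------------------------------
# RNG helpers

def _draw_divergence(rng: np.random.Generator, model, n: int) -> np.ndarray:
    weights = np.array([w for w, _, _ in model], dtype=float)
    weights /= weights.sum()
    comp = rng.choice(len(model), size=n, p=weights)
    means = np.array([m for _, m, _ in model])[comp]
    sds = np.array([s for _, _, s in model])[comp]
    return np.clip(rng.normal(means, sds), 0.0, None)


def _draw_peak_len(rng, model, n=1) -> np.ndarray:
    mean, sd, lo, hi = model
    return np.clip(np.rint(rng.normal(mean, sd, n)), lo, hi).astype(np.int64)


# ---------------------------------------------------------------------------
# generator internals

class _TEStore:
    """Accumulates TE records before writing; supports fast chr1 queries."""

    def __init__(self) -> None:
        self.rows: list[dict] = []

    def add(self, chrom, start, end, te_class, div, strand) -> None:
        self.rows.append(
            dict(chrom=chrom, start=int(start), end=int(end),
                 te_class=te_class, div=float(div), strand=strand)
        )

    def to_records(self) -> list[TERecord]:
        fam = {"SINE": "Alu", "LINE": "L1", "LTR": "ERVL", "DNA": "hAT",
               "OTHER": "Unknown"}
        recs = []
        self.rows.sort(key=lambda r: (r["chrom"], r["start"]))
        for i, r in enumerate(self.rows):
            recs.append(TERecord(
                chrom=r["chrom"], start=r["start"], end=r["end"],
                strand=r["strand"], rep_name=f"{r['te_class']}_{i}",
                te_class=r["te_class"], rep_family=fam[r["te_class"]],
                divergence_pct=round(r["div"], 1),
            ))
        return recs


def _plant_fragments(rng, spec: CohortSpec, peak_start: int, peak_len: int,
                     te_bp: int, store: _TEStore, chrom: str) -> None:
    """Place TE fragments totalling exactly te_bp inside one planted peak."""
    if te_bp <= 0:
        return
    mf = spec.min_fragment_bp
    nf = max(1, min(3, te_bp // (4 * mf)))
    parts = np.full(nf, mf, dtype=np.int64)
    parts += rng.multinomial(te_bp - mf * nf, np.full(nf, 1.0 / nf))
    gaps = rng.multinomial(peak_len - te_bp, np.full(nf + 1, 1.0 / (nf + 1)))
    # gene-zone class mix is SINE-biased (gene-proximal SINE overrepresentation)
    w = np.array([spec.class_mix[c] for c in ("SINE", "LINE", "LTR", "DNA", "OTHER")])
    w[0] *= spec.gene_zone_sine_bias
    w /= w.sum()
    classes = ("SINE", "LINE", "LTR", "DNA", "OTHER")
    pos = peak_start
    for i in range(nf):
        pos += int(gaps[i])
        c = classes[rng.choice(5, p=w)]
        div = float(_draw_divergence(rng, spec.divergence_models[c], 1)[0])
        strand = "+" if rng.random() < 0.5 else "-"
        store.add(chrom, pos, pos + int(parts[i]), c, div, strand)
        pos += int(parts[i])


def _fill_interval(rng, spec: CohortSpec, chrom: str, start: int, length: int,
                   quota: int, store: _TEStore) -> int:
    """Fill one TE-free interval with non-overlapping TEs totalling ~quota bp."""
    if quota < 30 or length < 40:
        return 0
    quota = min(quota, length - 10)
    classes = ("SINE", "LINE", "LTR", "DNA", "OTHER")
    # count-level class probabilities chosen so *bp* shares follow class_mix
    p = np.array([spec.class_mix[c] / spec.te_length_models[c][0] for c in classes])
    p /= p.sum()
    lens: list[int] = []
    kinds: list[str] = []
    total = 0
    while total < quota:
        c = classes[rng.choice(5, p=p)]
        mean, sd, lo = spec.te_length_models[c]
        L = int(np.clip(np.rint(rng.normal(mean, sd)), lo, None))
        L = min(L, quota - total) if total + L > quota else L
        if L < 20:
            if lens:
                lens[-1] += quota - total
                total = quota
                break
            L = max(L, 20)
            L = min(L, quota)
        lens.append(L)
        kinds.append(c)
        total += L
    n = len(lens)
    gaps = rng.multinomial(length - total, np.full(n + 1, 1.0 / (n + 1)))
    pos = start
    for i in range(n):
        pos += int(gaps[i])
        div = float(_draw_divergence(rng, spec.divergence_models[kinds[i]], 1)[0])
        strand = "+" if rng.random() < 0.5 else "-"
        store.add(chrom, pos, pos + lens[i], kinds[i], div, strand)
        pos += lens[i]
    return total


def _slot_stats(te_arr: np.ndarray, te_class: np.ndarray, te_div: np.ndarray,
                wins: np.ndarray, classes: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Per-window class-overlap bp matrix and bp-weighted mean divergence."""
    starts, ends = te_arr[:, 0], te_arr[:, 1]
    nw = wins.shape[0]
    class_bp = np.zeros((nw, len(classes)))
    mean_div = np.zeros(nw)
    cidx = {c: i for i, c in enumerate(classes)}
    for w in range(nw):
        s, e = wins[w]
        i0 = np.searchsorted(ends, s, side="right")
        i1 = np.searchsorted(starts, e, side="left")
        if i1 <= i0:
            mean_div[w] = np.nan
            continue
        ov = np.minimum(ends[i0:i1], e) - np.maximum(starts[i0:i1], s)
        ov = np.clip(ov, 0, None)
        tot = ov.sum()
        mean_div[w] = (te_div[i0:i1] * ov).sum() / tot if tot else np.nan
        for j, c in enumerate(te_class[i0:i1]):
            class_bp[w, cidx[c]] += ov[j]
    return class_bp, mean_div


# ---------------------------------------------------------------------------
# main entry points

def generate(spec: CohortSpec, outdir: str | Path) -> dict[str, Path]:
    """Write the full synthetic bundle; deterministic given ``spec.seed``.

    Returns a mapping of logical names to file paths: ``layout, rmsk, tss,
    tsg, cellline_map, hste, truth`` plus ``peaks`` (directory) and
    ``peak_files`` handled as ``{(cellline, assay): path}``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    outdir = Path(outdir)
    (outdir / "peaks").mkdir(parents=True, exist_ok=True)
    layout = spec.layout
    celllines = list(spec.celllines)
    n_lines = len(celllines)
    store = _TEStore()
    truth_rows: list[dict] = []
    peaks: dict[tuple[str, str], list[tuple[int, str, int, int]]] = {
        (cl, a): [] for cl in celllines for a in spec.assays
    }
    chrom_order = {c: i for i, c in enumerate(layout.chroms)}

    # ---- gene zone -------------------------------------------------------
    tissues = spec.tissues
    gene_ids = [f"G{i:04d}" for i in range(spec.n_genes)]
    first = spec._first_tss()
    tss_records = [
        TSSRecord(
            gene_id=g, gene_name=g, chrom=spec.gene_chrom,
            position=first + i * spec.gene_spacing_bp,
            strand="+" if i % 2 == 0 else "-",
        )
        for i, g in enumerate(gene_ids)
    ]

    # category assignment
    perm = list(rng.permutation(spec.n_genes))
    cursor = 0
    te_reg_genes = [gene_ids[i] for i in perm[cursor:cursor + spec.n_te_regulated]]
    cursor += spec.n_te_regulated
    tsg_assign: dict[str, tuple[str, str]] = {}  # gene -> (tissue, subtype)
    tissue_to_genes: dict[str, set[str]] = {t: set() for t in tissues}
    for t in tissues:
        block = [gene_ids[i] for i in perm[cursor:cursor + spec.tsg_per_tissue]]
        cursor += spec.tsg_per_tissue
        for j, g in enumerate(block):
            if j < spec.n_exclusive_per_tissue:
                sub = "tsg_exclusive"
            elif j < spec.n_exclusive_per_tissue + spec.n_leaky_per_tissue:
                sub = "tsg_leaky"
            else:
                sub = "tsg_elevated"
            tsg_assign[g] = (t, sub)
            tissue_to_genes[t].add(g)
    background = {g for g in gene_ids} - set(te_reg_genes) - set(tsg_assign)

    lane_defs = spec._lane_widths()
    lane_off: dict[tuple[str, str], int] = {}
    lane_w_map: dict[tuple[str, str], int] = {}
    off = 0
    for assay, lane, w in lane_defs:
        lane_off[(assay, lane)] = off
        lane_w_map[(assay, lane)] = w
        off += w + 90

    def planted_bp(density: float, L: int, force_nonzero: bool) -> int:
        bp = int(round(density * L))
        if bp == 0:
            return spec.min_fragment_bp if force_nonzero else 0
        if bp < spec.min_fragment_bp:
            return spec.min_fragment_bp if force_nonzero else 0
        return bp

    gene_peaks_footprint: list[tuple[str, int, int]] = []
    for i, g in enumerate(gene_ids):
        tss = tss_records[i].position
        zone0 = tss - spec.gene_zone_half_bp
        if g in background:
            label, tissue = "background", ""
        elif g in te_reg_genes:
            label, tissue = "te_regulated", ""
        else:
            tissue, label = tsg_assign[g]
        truth_rows.append(dict(kind="gene", assay="", chrom="", start=-1, end=-1,
                               gene_id=g, tissue=tissue, group="", label=label,
                               value=np.nan))
        own_lines = (
            [cl for cl in celllines if spec.celllines[cl] == tissue]
            if tissue else []
        )
        for assay in spec.assays:
            L_A = int(_draw_peak_len(rng, spec.peak_length_models[assay])[0])
            L_B = int(_draw_peak_len(rng, spec.peak_length_models[assay])[0])
            for lane, L in (("A", L_A), ("B", L_B)):
                lane_start = zone0 + lane_off[(assay, lane)]
                lane_w = lane_w_map[(assay, lane)]
                offset = int(rng.integers(0, lane_w - L + 1))
                p0 = lane_start + offset
                # choose the lane's cell-line group and planted density
                if label in ("background", "te_regulated"):
                    if lane == "B":
                        continue  # single lane holds all cell lines
                    members = celllines
                    lo, hi = (spec.density_background if label == "background"
                              else spec.density_te_regulated)
                    d = float(rng.uniform(lo, hi))
                    bp = planted_bp(d, L, force_nonzero=False)
                    group = "all"
                else:
                    if lane == "A":
                        members = own_lines
                        lo, hi = (spec.density_exclusive_own
                                  if label in ("tsg_exclusive", "tsg_leaky")
                                  else spec.density_tsg_own)
                        d = float(rng.uniform(lo, hi))
                        bp = planted_bp(d, L, force_nonzero=True)
                        group = "own"
                    else:
                        members = [cl for cl in celllines if cl not in own_lines]
                        if label == "tsg_exclusive":
                            d, bp = 0.0, 0
                        elif label == "tsg_leaky":
                            d = float(rng.uniform(*spec.density_leaky_other))
                            bp = planted_bp(d, L, force_nonzero=True)
                        else:
                            d = float(rng.uniform(*spec.density_tsg_other))
                            bp = planted_bp(d, L, force_nonzero=True)
                        group = "other"
                _plant_fragments(rng, spec, p0, L, bp, store, spec.gene_chrom)
                gene_peaks_footprint.append((spec.gene_chrom, p0, p0 + L))
                for cl in members:
                    peaks[(cl, assay)].append(
                        (chrom_order[spec.gene_chrom], spec.gene_chrom, p0, p0 + L)
                    )
                truth_rows.append(dict(
                    kind="density", assay=assay, chrom=spec.gene_chrom,
                    start=p0, end=p0 + L, gene_id=g, tissue=tissue,
                    group=group, label=label, value=bp / L,
                ))

    # ---- genome-wide TE fill --------------------------------------------
    total_bp = layout.total_bp
    target_te = int(round(spec.genome_te_fraction * total_bp))
    planted_te = sum(r["end"] - r["start"] for r in store.rows)
    footprint = IntervalSet.from_pairs(layout, gene_peaks_footprint)
    free = footprint.complement()
    needed = target_te - planted_te
    if needed < 0:
        raise InfeasibleSpecError(
            "planted gene-zone TEs already exceed the requested genome TE fraction"
        )
    if needed > 0.85 * free.total_bp:
        raise InfeasibleSpecError(
            f"cannot reach TE fraction {spec.genome_te_fraction}: would require "
            f"{needed} bp of TEs in {free.total_bp} bp of free sequence"
        )
    f = needed / free.total_bp
    for chrom, s, e in free:
        _fill_interval(rng, spec, chrom, s, e - s,
                       int(round(f * (e - s))), store)

    # ---- human-specific flags -------------------------------------------
    hste_pairs: list[tuple[str, int, int]] = []
    for r in sorted(store.rows, key=lambda r: (r["chrom"], r["start"])):
        if r["div"] < spec.hste_divergence_max and rng.random() < spec.hste_fraction:
            hste_pairs.append((r["chrom"], r["start"], r["end"]))

    # ---- atlas zone ------------------------------------------------------
    chr1 = spec.atlas_chrom
    chr1_rows = sorted(
        (r for r in store.rows if r["chrom"] == chr1), key=lambda r: r["start"]
    )
    te_arr = np.array([[r["start"], r["end"]] for r in chr1_rows], dtype=np.int64)
    te_cls = np.array([r["te_class"] for r in chr1_rows])
    te_div = np.array([r["div"] for r in chr1_rows])
    genome_mean_div = float(te_div.mean()) if te_div.size else 20.0
    jit = spec.peak_jitter_bp
    classes = ("SINE", "LINE", "LTR", "DNA", "OTHER")
    for assay in spec.assays:
        mean, sd, lo, hi = spec.peak_length_models[assay]
        slot_w = hi + 2 * jit + 50
        n_slots = layout.length(chr1) // slot_w
        slot_starts = np.arange(n_slots, dtype=np.int64) * slot_w
        wins = np.stack(
            [slot_starts + 50, slot_starts + 50 + int(mean)], axis=1
        )
        class_bp, mdiv = _slot_stats(te_arr, te_cls, te_div, wins, classes)
        te_bp_slot = class_bp.sum(axis=1)
        share = np.divide(
            class_bp, te_bp_slot[:, None],
            out=np.zeros_like(class_bp), where=te_bp_slot[:, None] > 0,
        )
        # class-expected divergence per slot, so the age bias below is
        # class-neutral (old-for-their-class, not old-therefore-LINE)
        class_mean_div = np.array([
            sum(w * m for w, m, _ in spec.divergence_models[c])
            / sum(w for w, _, _ in spec.divergence_models[c])
            for c in classes
        ])
        expected_div = share @ class_mean_div
        resid = np.where(
            (te_bp_slot > 0) & ~np.isnan(mdiv), mdiv - expected_div, 0.0
        )
        mdiv = np.where(np.isnan(mdiv), genome_mean_div, mdiv)
        mults = spec.enrichment_multipliers.get(assay, {})
        logw = np.zeros(n_slots)
        for j, c in enumerate(classes):
            m = mults.get(c, 1.0)
            if m != 1.0:
                logw += share[:, j] * np.log(m)
        available = np.ones(n_slots, dtype=bool)
        n_unique = spec.n_unique_per_line * n_lines
        plan = (
            [("shared", spec.n_shared, spec.shared_age_coef)]
            + [("subset", spec.n_subset, 0.0)]
            + [("unique", n_unique, spec.unique_age_coef)]
        )
        unique_line_iter = [cl for cl in celllines for _ in range(spec.n_unique_per_line)]
        u = 0
        for category, count, age_coef in plan:
            if count == 0:
                continue
            lw = logw + age_coef * resid
            lw = np.clip(lw, -30, 30)
            w = np.exp(lw) * available
            if available.sum() < count:
                raise InfeasibleSpecError(
                    f"not enough atlas slots for assay {assay} ({category})"
                )
            idx = rng.choice(n_slots, size=count, replace=False, p=w / w.sum())
            available[idx] = False
            for si in idx:
                L = int(_draw_peak_len(rng, spec.peak_length_models[assay])[0])
                base = int(slot_starts[si]) + 50
                if category == "shared":
                    members = celllines
                elif category == "unique":
                    members = [unique_line_iter[u]]
                    u += 1
                else:
                    k = int(rng.integers(2, n_lines))  # 2..N-1
                    members = [celllines[t] for t in
                               sorted(rng.choice(n_lines, size=k, replace=False))]
                for cl in members:
                    shift = int(rng.integers(-jit, jit + 1))
                    peaks[(cl, assay)].append(
                        (chrom_order[chr1], chr1, base + shift, base + shift + L)
                    )
                truth_rows.append(dict(
                    kind="region", assay=assay, chrom=chr1, start=base,
                    end=base + L, gene_id="", tissue="", group="",
                    label=category, value=float(len(members)),
                ))

    # ---- write bundle ----------------------------------------------------
    paths: dict[str, Path] = {}
    paths["layout"] = outdir / "genome.tsv"
    write_genome_layout(layout, paths["layout"])
    paths["rmsk"] = outdir / "rmsk.tsv"
    write_rmsk_table(store.to_records(), paths["rmsk"])
    paths["tss"] = outdir / "tss.bed"
    write_tss_bed(tss_records, paths["tss"])
    catalog = TSGCatalog(tissue_to_genes, dict(spec.celllines))
    paths["tsg"] = outdir / "tsg.tsv"
    paths["cellline_map"] = outdir / "celllines.tsv"
    write_tsg_catalog(catalog, paths["tsg"], paths["cellline_map"])
    paths["hste"] = outdir / "hste.bed"
    write_bed3(IntervalSet.from_pairs(layout, hste_pairs), paths["hste"])
    for (cl, assay), rows in peaks.items():
        rows.sort()
        recs = [
            PeakRecord(
                chrom=chrom, start=s, end=e, name=f"{cl}_{assay}_{i}",
                score=500.0, strand=".", signal=10.0, p=5.0, q=3.0,
                summit=(e - s) // 2,
            )
            for i, (_, chrom, s, e) in enumerate(rows)
        ]
        p = outdir / "peaks" / f"{cl}_{assay}.narrowPeak"
        write_narrowpeak(recs, p)
        paths[f"peaks/{cl}/{assay}"] = p
    truth = pd.DataFrame(truth_rows, columns=[
        "kind", "assay", "chrom", "start", "end", "gene_id", "tissue",
        "group", "label", "value",
    ])
    paths["truth"] = outdir / "truth.tsv"
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# truth-table utilities

def load_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False,
                       na_values=[""], dtype={"gene_id": str, "label": str})


def truth_positive_genes(truth: pd.DataFrame, assay: str, threshold: float) -> set[str]:
    """Genes whose planted density reaches the cutoff in >=1 cell line."""
    d = truth[(truth["kind"] == "density") & (truth["assay"] == assay)]
    return set(d.loc[d["value"] >= threshold, "gene_id"])


def truth_exclusive_genes(truth: pd.DataFrame) -> set[tuple[str, str]]:
    """(tissue, gene) pairs planted with the tissue-exclusive pattern."""
    g = truth[(truth["kind"] == "gene") & (truth["label"] == "tsg_exclusive")]
    return {(t, gid) for t, gid in zip(g["tissue"], g["gene_id"])}


def truth_compare(
    truth_sets: Mapping[str, set],
    predicted_sets: Mapping[str, set],
) -> dict[str, dict[str, float]]:
    """Precision/recall of predicted label sets against planted truth sets.

    Keys present in either mapping are reported; a missing side counts as
    the empty set.  Precision of an empty prediction and recall of an empty
    truth are reported as 1.0 (nothing to get wrong).
    """
    report: dict[str, dict[str, float]] = {}
    for key in sorted(set(truth_sets) | set(predicted_sets)):
        t = set(truth_sets.get(key, set()))
        p = set(predicted_sets.get(key, set()))
        tp = len(t & p)
        report[key] = {
            "n_truth": len(t),
            "n_predicted": len(p),
            "precision": tp / len(p) if p else 1.0,
            "recall": tp / len(t) if t else 1.0,
        }
    return report
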