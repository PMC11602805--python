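"""Config-driven orchestration of the full analysis.

A :class:`PipelineConfig` names the input files (peak files per cell line
and assay, TE annotation, TSS table, TSG catalog, cell-line map, optional
human-specific-TE list) and the analysis parameters (5 Kb flank, per-assay
density cutoffs, presence threshold, significance levels, divergence bin
width).  :class:`Pipeline` exposes one method per stage — atlas, compose,
age, scores, tsg, report — each writing TSV/BED outputs into the output
directory, plus a machine-readable run manifest.  Stages recompute what
they need from the inputs, so they can run independently; ``report``
assembles sheets from the in-process results.

All numeric output uses dot decimals and no thousands separators.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import (
    ASSAYS,
    build_atlas,
    cross_assay_overlap,
    split_by_sharing,
    summarize_atlas,
)
from .formats import (
    GenomeLayout,
    flag_human_specific,
    peaks_to_intervals,
    read_bed3,
    read_cellline_map,
    read_genome_layout,
    read_narrowpeak,
    read_rmsk_table,
    read_tsg_catalog,
    read_tss_bed,
    write_bed3,
    write_gene_cluster_table,
)
from .gene_scores import (
    DEFAULT_FLANK_BP,
    DEFAULT_THRESHOLDS,
    call_te_regulated,
    cellline_correlation,
    density_matrix,
    sharing_spectrum,
)
from .intervals import IntervalSet, window_around
from .report import composition_sheet, summary_sheet
from .te_profile import (
    age_profile,
    chi_square_representation,
    compare_mean_divergence,
    compose_te,
    hste_ratio,
    te_union,
)
from .tsg import tissue_exclusive_genes, tsg_contrast

__all__ = ["PipelineConfig", "Pipeline", "StageDependencyError"]

log = logging.getLogger("teatlas")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


class StageDependencyError(RuntimeError):
    """A stage was invoked before the subcommand it depends on."""


@dataclass
class PipelineConfig:
    layout: str
    rmsk: str
    tss: str
    tsg: str
    cellline_map: str
    peaks_dir: str
    outdir: str
    hste: str | None = None
    assays: tuple[str, ...] = ASSAYS
    flank_bp: int = DEFAULT_FLANK_BP
    thresholds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    exclusive_threshold: float = 0.1
    min_overlap_bp: int = 1
    alpha: float = 1e-4
    bin_width: float = 1.0
    tsg_assays: tuple[str, ...] = ("DHS", "HA")  # HR excluded from TSG contrasts
    rmsk_dialect: str = "header"
    hste_match: str = "exact"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.assays = tuple(cfg.assays)
        cfg.tsg_assays = tuple(cfg.tsg_assays)
        return cfg

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["assays"] = list(self.assays)
        d["tsg_assays"] = list(self.tsg_assays)
        return d

    def validate_paths(self) -> None:
        for key in ("layout", "rmsk", "tss", "tsg", "cellline_map", "peaks_dir"):
            p = Path(getattr(self, key))
            if not p.exists():
                raise FileNotFoundError(f"config.{key}: {p} does not exist")
        for a, t in self.thresholds.items():
            if not (0 < t <= 1):
                raise ValueError(f"threshold for {a} must be in (0, 1], got {t}")


class Pipeline:
    """Runs the analysis stages over one configured input bundle."""

    def __init__(self, config: PipelineConfig):
        config.validate_paths()
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self._cache: dict[str, object] = {}

    # -- inputs -----------------------------------------------------------

    def _timed(self, stage: str):
        t0 = time.monotonic()
        log.info("stage %s: start", stage)
        return lambda: log.info("stage %s: done in %.1fs", stage, time.monotonic() - t0)

    def load_inputs(self) -> dict:
        if "inputs" in self._cache:
            return self._cache["inputs"]
        done = self._timed("load")
        cfg = self.config
        layout = read_genome_layout(cfg.layout)
        tes = read_rmsk_table(cfg.rmsk, layout, dialect=cfg.rmsk_dialect)
        if cfg.hste:
            hste = read_bed3(cfg.hste, layout)
            tes = flag_human_specific(tes, hste, mode=cfg.hste_match)
        tss = read_tss_bed(cfg.tss, layout)
        catalog = read_tsg_catalog(cfg.tsg, cfg.cellline_map)
        celllines = sorted(catalog.cellline_to_tissue)
        peaks: dict[str, dict[str, IntervalSet]] = {}
        for assay in cfg.assays:
            peaks[assay] = {}
            for cl in celllines:
                p = Path(cfg.peaks_dir) / f"{cl}_{assay}.narrowPeak"
                if not p.exists():
                    raise FileNotFoundError(
                        f"peak file {p} missing for cell line {cl}, assay {assay}"
                    )
                peaks[assay][cl] = peaks_to_intervals(
                    read_narrowpeak(p, layout), layout
                )
        _, windows = window_around(tss, cfg.flank_bp, layout)
        inputs = dict(layout=layout, tes=tes, tss=tss, catalog=catalog,
                      celllines=celllines, peaks=peaks, windows=windows)
        self._cache["inputs"] = inputs
        done()
        return inputs

    # -- stages -----------------------------------------------------------

    def atlases(self) -> dict:
        if "atlases" in self._cache:
            return self._cache["atlases"]
        inp = self.load_inputs()
        out = {
            assay: build_atlas(inp["peaks"][assay], assay,
                               min_overlap_bp=self.config.min_overlap_bp)
            for assay in self.config.assays
        }
        self._cache["atlases"] = out
        return out

    def stage_atlas(self) -> None:
        done = self._timed("atlas")
        inp = self.load_inputs()
        atlases = self.atlases()
        for assay, atl in atlases.items():
            atl.to_frame().to_csv(
                self.outdir / f"atlas_regions_{assay}.tsv", sep="\t", index=False
            )
            parts = split_by_sharing(atl)
            for name, ivs in parts.items():
                write_bed3(ivs, self.outdir / f"atlas_{assay}_{name}.bed")
            write_bed3(atl.union, self.outdir / f"atlas_{assay}_overall.bed")
            summary = summarize_atlas(atl, inp["windows"])
            summary_sheet(summary).to_csv(
                self.outdir / f"atlas_summary_{assay}.tsv", sep="\t", index=False
            )
        if set(self.config.assays) >= {"DHS", "HA", "HR"}:
            venn = cross_assay_overlap(
                atlases["DHS"].union, atlases["HA"].union, atlases["HR"].union
            )
            pd.Series(venn).rename("bp").to_csv(
                self.outdir / "cross_assay_venn.tsv", sep="\t"
            )
        done()

    def _category_sets(self, assay: str) -> dict[str, IntervalSet]:
        inp = self.load_inputs()
        atl = self.atlases()[assay]
        parts = split_by_sharing(atl)
        windows = inp["windows"]
        sets = {
            "overall": atl.union,
            "shared": parts["shared"],
            "cellline_specific": parts["cellline_specific"],
            "cellline_unique": parts["cellline_unique"],
        }
        out = {}
        for cat, ivs in sets.items():
            out[f"{cat}/genome_wide"] = ivs
            out[f"{cat}/gene_neighboring"] = ivs.intersect(windows)
        return out

    def compositions(self) -> dict:
        if "compositions" in self._cache:
            return self._cache["compositions"]
        inp = self.load_inputs()
        genome = compose_te(
            IntervalSet.whole_genome(inp["layout"]), inp["tes"], label="genome"
        )
        comps: dict[str, dict] = {"genome": genome}
        for assay in self.config.assays:
            comps[assay] = {
                key: compose_te(ivs, inp["tes"], label=f"{assay}:{key}")
                for key, ivs in self._category_sets(assay).items()
            }
        self._cache["compositions"] = comps
        return comps

    def stage_compose(self) -> None:
        done = self._timed("compose")
        comps = self.compositions()
        genome = comps["genome"]
        for assay in self.config.assays:
            sheet = composition_sheet({"genome": genome, **comps[assay]})
            sheet.to_csv(self.outdir / f"composition_{assay}.tsv", sep="\t",
                         index=False)
            rows = []
            for key, comp in comps[assay].items():
                if comp.te_bp == 0:
                    continue
                for c in ("SINE", "LINE", "LTR", "DNA"):
                    r = chi_square_representation(comp, genome, c,
                                                  alpha=self.config.alpha)
                    rows.append({
                        "category": key, "te_class": c, "chi2": r.chi2_stat,
                        "p_value": r.p_value, "direction": r.direction,
                        "observed_fraction": r.observed_fraction,
                        "background_fraction": r.background_fraction,
                    })
            pd.DataFrame(rows).to_csv(
                self.outdir / f"enrichment_{assay}.tsv", sep="\t", index=False
            )
        done()

    def stage_age(self) -> None:
        done = self._timed("age")
        inp = self.load_inputs()
        tes = inp["tes"]
        for assay in self.config.assays:
            sets = self._category_sets(assay)
            profiles = {
                key: age_profile(ivs, tes, bin_width=self.config.bin_width,
                                 label=key)
                for key, ivs in sets.items()
                if key.endswith("genome_wide") or key == "overall/gene_neighboring"
            }
            hist = pd.concat(
                [p.to_frame() for profs in profiles.values() for p in profs.values()],
                ignore_index=True,
            )
            hist.to_csv(self.outdir / f"age_profiles_{assay}.tsv", sep="\t",
                        index=False)
            rows = []
            pairs = [
                ("shared/genome_wide", "cellline_specific/genome_wide"),
                ("overall/genome_wide", "overall/gene_neighboring"),
            ]
            for a_key, b_key in pairs:
                for c in ("SINE", "LINE", "LTR", "DNA"):
                    tt = compare_mean_divergence(profiles[a_key][c],
                                                 profiles[b_key][c])
                    rows.append({
                        "comparison": f"{a_key} vs {b_key}", "te_class": c,
                        "mean_a": profiles[a_key][c].mean_divergence,
                        "mean_b": profiles[b_key][c].mean_divergence,
                        "t": tt.t_stat, "p_value": tt.p_value,
                        "n_a": tt.n_a, "n_b": tt.n_b,
                    })
            pd.DataFrame(rows).to_csv(
                self.outdir / f"age_comparisons_{assay}.tsv", sep="\t", index=False
            )
            buckets = {
                k.split("/")[0]: v for k, v in sets.items()
                if k.endswith("genome_wide") and not k.startswith("overall")
            }
            ratios = hste_ratio(buckets, tes)
            pd.DataFrame(
                [
                    {"bucket": b, "hste": h, "te": n,
                     "ratio": r if r is not None else float("nan")}
                    for b, (h, n, r) in ratios.items()
                ]
            ).to_csv(self.outdir / f"hste_ratios_{assay}.tsv", sep="\t", index=False)
        done()

    def matrices(self) -> dict[str, pd.DataFrame]:
        if "matrices" in self._cache:
            return self._cache["matrices"]
        inp = self.load_inputs()
        te_set = te_union(inp["tes"], inp["layout"])
        out = {
            assay: density_matrix(
                inp["tss"], inp["peaks"][assay], te_set,
                assay=assay, flank_bp=self.config.flank_bp,
            )
            for assay in self.config.assays
        }
        self._cache["matrices"] = out
        return out

    def calls(self) -> dict[str, pd.DataFrame]:
        if "calls" in self._cache:
            return self._cache["calls"]
        out = {
            assay: call_te_regulated(m, assay, self.config.thresholds)
            for assay, m in self.matrices().items()
        }
        self._cache["calls"] = out
        return out

    def stage_scores(self) -> None:
        done = self._timed("scores")
        for assay, matrix in self.matrices().items():
            matrix.to_csv(self.outdir / f"density_{assay}.tsv", sep="\t",
                          na_rep="NA", index_label="gene_id")
            r, n = cellline_correlation(matrix)
            r.to_csv(self.outdir / f"correlation_{assay}.tsv", sep="\t")
            n.to_csv(self.outdir / f"correlation_n_{assay}.tsv", sep="\t")
            calls = self.calls()[assay]
            calls.to_csv(self.outdir / f"calls_{assay}.tsv", sep="\t", index=False,
                         na_rep="NA")
            spec = sharing_spectrum(calls)
            pd.Series(spec).rename_axis("k").rename("genes").to_csv(
                self.outdir / f"spectrum_{assay}.tsv", sep="\t"
            )
            called = calls[calls["called"]]
            write_gene_cluster_table(
                zip(called["gene_id"], called["cellline"]),
                self.outdir / f"gene_clusters_{assay}.tsv",
            )
        done()

    def stage_tsg(self) -> None:
        done = self._timed("tsg")
        inp = self.load_inputs()
        catalog = inp["catalog"]
        contrast_rows = []
        excl_rows = []
        for assay in self.config.tsg_assays:
            matrix = self.matrices()[assay]
            calls = self.calls()[assay]
            for tissue in catalog.tissues:
                if not catalog.tissue_to_genes.get(tissue):
                    continue
                c = tsg_contrast(catalog, matrix, calls, tissue, assay)
                contrast_rows.append({
                    "tissue": tissue, "assay": assay,
                    "mean_density_own": c.mean_density_own,
                    "mean_density_other": c.mean_density_other,
                    "t": c.t_stat, "p_value": c.p_value,
                    "n_own": c.n_own, "n_other": c.n_other,
                    "fraction_called_own": c.fraction_called_own,
                    "fraction_called_other": c.fraction_called_other,
                })
                for call in tissue_exclusive_genes(
                    catalog, matrix, tissue, assay,
                    threshold=self.config.exclusive_threshold,
                ):
                    excl_rows.append({
                        "tissue": tissue, "assay": assay,
                        "gene_id": call.gene_id,
                        "own_density": call.own_density,
                    })
        pd.DataFrame(contrast_rows).to_csv(
            self.outdir / "tsg_contrasts.tsv", sep="\t", index=False
        )
        pd.DataFrame(excl_rows, columns=["tissue", "assay", "gene_id",
                                         "own_density"]).to_csv(
            self.outdir / "tissue_exclusive.tsv", sep="\t", index=False
        )
        done()

    def stage_report(self) -> None:
        done = self._timed("report")
        inp = self.load_inputs()
        sheets = []
        for assay in self.config.assays:
            summary = summarize_atlas(self.atlases()[assay], inp["windows"])
            sheets.append(summary_sheet(summary))
        pd.concat(sheets, ignore_index=True).to_csv(
            self.outdir / "report_summary.tsv", sep="\t", index=False
        )
        comps = self.compositions()
        frames = []
        for assay in self.config.assays:
            sheet = composition_sheet({"genome": comps["genome"], **comps[assay]})
            sheet.insert(0, "assay", assay)
            frames.append(sheet)
        pd.concat(frames, ignore_index=True).to_csv(
            self.outdir / "report_composition.tsv", sep="\t", index=False
        )
        done()

    def write_manifest(self, stages: list[str]) -> None:
        manifest = {
            "teatlas_version": __version__,
            "config": self.config.to_dict(),
            "stages": stages,
            "seed": self.config.seed,
        }
        with open(self.outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")

    def run_all(self) -> None:
        stages = ["atlas", "compose", "age", "scores", "tsg", "report"]
        for s in stages:
            getattr(self, f"stage_{s}")()
        self.write_manifest(stages)
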