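"""Shared fixtures: per-base oracles and a session-scoped synthetic cohort."""

from __future__ import annotations

import numpy as np
import pytest

from teatlas.intervals import GenomeLayout, IntervalSet
from teatlas.pipeline import Pipeline, PipelineConfig
from teatlas.simulate import CohortSpec, generate, load_truth


# ---------------------------------------------------------------------------
# per-base boolean-array oracle

class BaseOracle:
    """Brute-force per-base implementation of every interval operation.

    Represents a set of intervals on a small layout as one boolean array per
    chromosome; set algebra becomes elementwise boolean algebra.  Used as
    the independent ground truth for the interval engine.
    """

    def __init__(self, layout: GenomeLayout, pairs=()):
        self.layout = layout
        self.cov = {c: np.zeros(layout.length(c), dtype=bool) for c in layout.chroms}
        for chrom, s, e in pairs:
            self.cov[chrom][s:e] = True

    @classmethod
    def from_set(cls, ivs: IntervalSet) -> "BaseOracle":
        return cls(ivs.layout, ivs.to_pairs())

    def op(self, other: "BaseOracle", fn) -> "BaseOracle":
        out = BaseOracle(self.layout)
        for c in self.layout.chroms:
            out.cov[c] = fn(self.cov[c], other.cov[c])
        return out

    def union(self, o):
        return self.op(o, np.logical_or)

    def intersect(self, o):
        return self.op(o, np.logical_and)

    def subtract(self, o):
        return self.op(o, lambda a, b: a & ~b)

    @property
    def total_bp(self) -> int:
        return int(sum(a.sum() for a in self.cov.values()))

    def to_pairs(self) -> list[tuple[str, int, int]]:
        out = []
        for c in self.layout.chroms:
            a = self.cov[c]
            d = np.diff(np.concatenate([[0], a.astype(np.int8), [0]]))
            for s, e in zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)):
                out.append((c, int(s), int(e)))
        return out

    def to_set(self) -> IntervalSet:
        return IntervalSet.from_pairs(self.layout, self.to_pairs())


def random_pairs(rng: np.random.Generator, layout: GenomeLayout, n: int,
                 max_len: int = 400) -> list[tuple[str, int, int]]:
    out = []
    for _ in range(n):
        chrom = layout.chroms[rng.integers(len(layout.chroms))]
        L = layout.length(chrom)
        s = int(rng.integers(0, L - 1))
        e = int(min(L, s + 1 + rng.integers(max_len)))
        out.append((chrom, s, e))
    return out


@pytest.fixture
def small_layout() -> GenomeLayout:
    return GenomeLayout([("chr1", 10_000), ("chr2", 8_000)])


# ---------------------------------------------------------------------------
# session cohort: default-parameter synthetic bundle plus a pipeline run

class Cohort:
    def __init__(self, root, paths, pipeline, truth):
        self.root = root
        self.paths = paths
        self.pipeline = pipeline
        self.truth = truth


@pytest.fixture(scope="session")
def cohort(tmp_path_factory) -> Cohort:
    """Default synthetic cohort (seed 1) with a fully run pipeline."""
    root = tmp_path_factory.mktemp("cohort")
    spec = CohortSpec(seed=1)
    paths = generate(spec, root)
    cfg = PipelineConfig(
        layout=str(paths["layout"]), rmsk=str(paths["rmsk"]),
        tss=str(paths["tss"]), tsg=str(paths["tsg"]),
        cellline_map=str(paths["cellline_map"]), hste=str(paths["hste"]),
        peaks_dir=str(root / "peaks"), outdir=str(root / "results"),
    )
    pipeline = Pipeline(cfg)
    pipeline.run_all()
    return Cohort(root, paths, pipeline, load_truth(paths["truth"]))


def tiny_spec(**overrides) -> CohortSpec:
    """A scaled-down cohort for fast generator unit tests."""
    defaults = dict(
        seed=0,
        layout=GenomeLayout([("chr1", 400_000), ("chr2", 700_000)]),
        n_genes=60,
        n_shared=12, n_subset=20, n_unique_per_line=3,
        n_te_regulated=8, tsg_per_tissue=4,
        n_exclusive_per_tissue=2, n_leaky_per_tissue=1,
    )
    defaults.update(overrides)
    return CohortSpec(**defaults)
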