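"""TE composition, chi-square enrichment, age profiles, HSTE ratios."""

import numpy as np
import pytest
from scipy import stats

from teatlas.formats import TERecord
from teatlas.intervals import GenomeLayout, IntervalSet
from teatlas.te_profile import (
    TECompositionTable,
    age_profile,
    chi_square_representation,
    compare_mean_divergence,
    compose_te,
    hste_ratio,
    te_members,
    te_union,
)

from conftest import BaseOracle, random_pairs


@pytest.fixture
def layout():
    return GenomeLayout([("chr1", 50_000)])


def _te(chrom, s, e, cls="SINE", div=10.0, hs=False):
    return TERecord(chrom, s, e, "+", f"{cls}_x", cls, cls, div, hs)


def test_compose_basic(layout):
    regions = IntervalSet.from_pairs(layout, [("chr1", 0, 100)])
    comp = compose_te(regions, [_te("chr1", 50, 150)])
    assert comp.te_bp == 50
    assert comp.te_pct == 0.5
    assert comp.class_bp["SINE"] == 50
    assert comp.te_fragment_count == 1


def test_compose_abutting_fragments_coalesce(layout):
    regions = IntervalSet.from_pairs(layout, [("chr1", 0, 100)])
    comp = compose_te(regions, [_te("chr1", 0, 10), _te("chr1", 10, 20)])
    assert comp.class_bp["SINE"] == 20
    assert comp.class_fragments["SINE"] == 1
    assert comp.te_fragment_count == 1


def test_compose_double_covered_bp_counted_once(layout):
    regions = IntervalSet.from_pairs(layout, [("chr1", 0, 100)])
    # overlapping SINE and LINE: te_bp counts each bp once,
    # but class accounting sees both classes
    comp = compose_te(regions, [_te("chr1", 0, 60, "SINE"), _te("chr1", 40, 80, "LINE")])
    assert comp.te_bp == 80
    assert comp.class_bp["SINE"] == 60 and comp.class_bp["LINE"] == 40
    assert comp.te_pct <= 1.0


def test_compose_fuzzed_against_oracle(layout):
    rng = np.random.default_rng(17)
    for _ in range(60):
        region_pairs = random_pairs(rng, layout, int(rng.integers(1, 60)))
        te_pairs = random_pairs(rng, layout, int(rng.integers(1, 80)))
        regions = IntervalSet.from_pairs(layout, region_pairs)
        tes = [_te(c, s, e) for c, s, e in te_pairs]
        comp = compose_te(regions, tes)
        oracle = BaseOracle(layout, region_pairs).intersect(
            BaseOracle(layout, te_pairs)
        )
        assert comp.te_bp == oracle.total_bp
        assert comp.te_bp <= regions.total_bp


def _chi2_oracle(table):
    """Independent Pearson chi-square: sum (O-E)^2 / E over a 2x2 table."""
    t = np.asarray(table, dtype=float)
    rows = t.sum(axis=1, keepdims=True)
    cols = t.sum(axis=0, keepdims=True)
    expected = rows @ cols / t.sum()
    chi2 = ((t - expected) ** 2 / expected).sum()
    return chi2, stats.chi2.sf(chi2, df=1)


def _comp(class_bp, te_bp, label=""):
    cb = {"SINE": 0, "LINE": 0, "LTR": 0, "DNA": 0}
    cb.update(class_bp)
    return TECompositionTable(label, te_bp * 2, te_bp, 1, cb, dict.fromkeys(cb, 1))


def test_chi_square_identical_fractions_is_null():
    comp = _comp({"LTR": 100}, 1000)
    bg = _comp({"LTR": 1000}, 10_000)
    r = chi_square_representation(comp, bg, "LTR")
    assert r.chi2_stat == pytest.approx(0.0, abs=1e-12)
    assert r.direction == "none"


def test_chi_square_equals_independent_formula():
    # one hand-checkable contingency plus 100 random tables
    comp = _comp({"LTR": 90}, 100)
    bg = _comp({"LTR": 50}, 100)
    r = chi_square_representation(comp, bg, "LTR", alpha=0.05)
    chi2, p = _chi2_oracle([[90, 10], [50, 50]])
    assert r.chi2_stat == pytest.approx(chi2, rel=1e-9)
    assert r.p_value == pytest.approx(p, rel=1e-9)
    assert r.direction == "over"

    rng = np.random.default_rng(23)
    for _ in range(100):
        a, b, c, d = rng.integers(1, 10_000, size=4)
        r = chi_square_representation(
            _comp({"SINE": int(a)}, int(a + b)),
            _comp({"SINE": int(c)}, int(c + d)),
            "SINE",
        )
        chi2, p = _chi2_oracle([[a, b], [c, d]])
        assert r.chi2_stat == pytest.approx(chi2, rel=1e-9)
        assert r.p_value == pytest.approx(p, rel=1e-9)


def test_chi_square_zero_margin_warns():
    comp = _comp({}, 100)      # zero LTR everywhere -> zero row margin
    bg = _comp({}, 1000)
    with pytest.warns(UserWarning, match="zero margin"):
        r = chi_square_representation(comp, bg, "LTR")
    assert r.direction == "none" and np.isnan(r.p_value)


def _welch_oracle(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, p


def test_welch_t_matches_closed_form():
    a, b = [10.0, 12.0, 14.0], [20.0, 22.0, 24.0]
    tt = compare_mean_divergence(np.array(a), np.array(b))
    t, p = _welch_oracle(a, b)
    assert tt.t_stat == pytest.approx(t, rel=1e-12)
    assert tt.p_value == pytest.approx(p, rel=1e-12)

    rng = np.random.default_rng(31)
    for _ in range(50):
        a = rng.normal(20, 4, size=rng.integers(3, 40))
        b = rng.normal(22, 6, size=rng.integers(3, 40))
        tt = compare_mean_divergence(a, b)
        t, p = _welch_oracle(a, b)
        assert tt.t_stat == pytest.approx(t, rel=1e-10)
        assert tt.p_value == pytest.approx(p, rel=1e-10)


def test_t_test_degenerate_groups():
    same = np.array([5.0, 5.0, 5.0])
    tt = compare_mean_divergence(same, same.copy())
    assert (tt.t_stat, tt.p_value) == (0.0, 1.0)
    tiny = compare_mean_divergence(np.array([1.0]), np.array([1.0, 2.0]))
    assert not tiny.ok and np.isnan(tiny.p_value)


def test_age_profile_membership_and_histogram(layout):
    regions = IntervalSet.from_pairs(layout, [("chr1", 0, 1000)])
    tes = [
        _te("chr1", 500, 600, "SINE", 5.0),     # inside
        _te("chr1", 990, 1200, "SINE", 7.0),    # 10 bp overlap -> member (any)
        _te("chr1", 2000, 2100, "SINE", 30.0),  # outside
        _te("chr1", 100, 300, "LINE", 25.0),
    ]
    profs = age_profile(regions, tes, bin_width=1.0)
    assert profs["SINE"].n == 2
    assert profs["SINE"].mean_divergence == pytest.approx(6.0)
    edges, counts = profs["SINE"].histogram()
    assert counts.sum() == 2
    assert profs["LINE"].n == 1
    # majority rule drops the 10-bp grazer
    members = te_members(regions, tes, rule="majority")
    assert [m.divergence_pct for m in members if m.te_class == "SINE"] == [5.0]


def test_hste_ratio(layout):
    bucket = IntervalSet.from_pairs(layout, [("chr1", 0, 10_000)])
    tes = [_te("chr1", i * 500, i * 500 + 100, hs=(i < 2)) for i in range(10)]
    ratios = hste_ratio({"b": bucket, "empty": IntervalSet.empty(layout)}, tes)
    assert ratios["b"] == (2, 10, 0.2)
    assert ratios["empty"] == (0, 0, None)


def test_te_union_class_filter(layout):
    tes = [_te("chr1", 0, 100, "SINE"), _te("chr1", 200, 300, "LINE")]
    assert te_union(tes, layout).total_bp == 200
    assert te_union(tes, layout, "SINE").total_bp == 100
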