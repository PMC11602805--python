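"""File-format readers/writers: validation, conversions, round-trips."""

import pytest

from teatlas.formats import (
    FormatError,
    GenomeLayout,
    PeakRecord,
    TERecord,
    TSSRecord,
    flag_human_specific,
    read_bed3,
    read_cellline_map,
    read_narrowpeak,
    read_rmsk_table,
    read_tsg_catalog,
    read_tss_bed,
    write_bed3,
    write_gene_cluster_table,
    write_narrowpeak,
    write_rmsk_table,
    write_tss_bed,
)
from teatlas.intervals import IntervalSet


@pytest.fixture
def layout():
    return GenomeLayout([("chr1", 100_000), ("chr2", 50_000)])


def test_narrowpeak_field_mapping(tmp_path, layout):
    p = tmp_path / "a.narrowPeak"
    p.write_text("chr1\t100\t250\tpeak1\t0\t.\t5.2\t3.1\t2.0\t75\n")
    (rec,) = read_narrowpeak(p, layout)
    assert rec == PeakRecord("chr1", 100, 250, "peak1", 0.0, ".", 5.2, 3.1, 2.0, 75)


def test_narrowpeak_empty_file(tmp_path, layout):
    p = tmp_path / "empty.narrowPeak"
    p.write_text("")
    assert read_narrowpeak(p, layout) == []


def test_narrowpeak_errors_cite_line_and_chrom(tmp_path, layout):
    p = tmp_path / "bad.narrowPeak"
    p.write_text(
        "chr1\t1\t2\ta\t0\t.\t1\t1\t1\t0\n"
        "chr1\t5\t9\tb\t0\t.\t1\t1\t1\t0\n"
        "chr1\t50\t40\tc\t0\t.\t1\t1\t1\t0\n"
    )
    with pytest.raises(FormatError, match=r":3:"):
        read_narrowpeak(p, layout)
    p.write_text("chrMystery\t1\t2\ta\t0\t.\t1\t1\t1\t0\n")
    with pytest.raises(FormatError, match="chrMystery"):
        read_narrowpeak(p, layout)


def test_narrowpeak_round_trip(tmp_path, layout):
    recs = [
        PeakRecord("chr1", 10, 500, "p1", 312.0, "+", 7.25, 3.5, 2.0, 245),
        PeakRecord("chr2", 0, 50_000, "p2", 0.0, ".", 0.0, 0.0, 0.0, 1),
    ]
    p = tmp_path / "rt.narrowPeak"
    write_narrowpeak(recs, p)
    assert read_narrowpeak(p, layout) == recs


def test_rmsk_millidiv_conversion_and_class_fallback(tmp_path, layout):
    p = tmp_path / "rmsk.tsv"
    p.write_text(
        "genoName\tgenoStart\tgenoEnd\tstrand\trepName\trepClass\trepFamily\tmilliDiv\n"
        "chr1\t100\t400\t+\tAluY\tSINE\tAlu\t205\n"
        "chr1\t500\t600\t-\t(TA)n\tSimple_repeat\tSimple\t0\n"
    )
    recs = read_rmsk_table(p, layout)
    assert recs[0].divergence_pct == 20.5 and recs[0].te_class == "SINE"
    assert recs[1].te_class == "OTHER"


def test_rmsk_errors(tmp_path, layout):
    p = tmp_path / "rmsk.tsv"
    p.write_text("genoName\tgenoStart\tgenoEnd\tstrand\trepName\trepClass\trepFamily\n"
                 "chr1\t1\t2\t+\tx\tSINE\tAlu\n")
    with pytest.raises(FormatError, match="milliDiv"):
        read_rmsk_table(p, layout)
    p.write_text("genoName\tgenoStart\tgenoEnd\tstrand\trepName\trepClass\trepFamily\tmilliDiv\n"
                 "chr1\t1\t2\t+\tx\tSINE\tAlu\t-5\n")
    with pytest.raises(FormatError, match="negative milliDiv"):
        read_rmsk_table(p, layout)
    p.write_text("genoName\tgenoStart\tgenoEnd\tstrand\trepName\trepClass\trepFamily\tmilliDiv\n"
                 "chr9\t1\t2\t+\tx\tSINE\tAlu\t10\n")
    with pytest.raises(FormatError, match="chr9"):
        read_rmsk_table(p, layout)


def test_rmsk_ucsc_positional_dialect(tmp_path, layout):
    p = tmp_path / "rmsk_ucsc.tsv"
    # bin swScore milliDiv milliDel milliIns genoName genoStart genoEnd ...
    p.write_text(
        "585\t2000\t105\t10\t5\tchr1\t300\t600\t-100\t+\tL1PA5\tLINE\tL1\t1\t300\t0\t7\n"
    )
    (rec,) = read_rmsk_table(p, layout, dialect="ucsc")
    assert (rec.chrom, rec.start, rec.end) == ("chr1", 300, 600)
    assert rec.divergence_pct == 10.5 and rec.te_class == "LINE"


def test_rmsk_fractional_divpct_column(tmp_path, layout):
    p = tmp_path / "rmsk_div.tsv"
    p.write_text(
        "genoName\tgenoStart\tgenoEnd\tstrand\trepName\trepClass\trepFamily\tdivPct\n"
        "chr1\t100\t400\t+\tAluY\tSINE\tAlu\t12.7\n"
    )
    (rec,) = read_rmsk_table(p, layout)
    assert rec.divergence_pct == 12.7  # used verbatim, no /10


def test_rmsk_round_trip(tmp_path, layout):
    recs = [
        TERecord("chr1", 100, 400, "+", "AluY", "SINE", "Alu", 20.5),
        TERecord("chr2", 10, 900, "-", "L1PA3", "LINE", "L1", 8.3),
    ]
    p = tmp_path / "rt.tsv"
    write_rmsk_table(recs, p)
    back = read_rmsk_table(p, layout)
    assert [(r.chrom, r.start, r.end, r.divergence_pct) for r in back] == [
        ("chr1", 100, 400, 20.5), ("chr2", 10, 900, 8.3)
    ]


def test_tss_duplicate_gene_rejected(tmp_path, layout):
    p = tmp_path / "tss.bed"
    p.write_text("chr1\t100\t101\tG1\t.\t+\nchr1\t200\t201\tG1\t.\t-\n")
    with pytest.raises(FormatError, match="duplicate gene_id"):
        read_tss_bed(p, layout)


def test_tss_round_trip(tmp_path, layout):
    recs = [TSSRecord("G1", "Gene-One", "chr1", 5_000, "+"),
            TSSRecord("G2", "G2", "chr2", 100, "-")]
    p = tmp_path / "tss.bed"
    write_tss_bed(recs, p)
    assert read_tss_bed(p, layout) == recs


def test_tsg_catalog(tmp_path):
    tsg = tmp_path / "tsg.tsv"
    tsg.write_text("liver\tALB\nliver\tOTC\nbrain\tGRIK4\n")
    cmap = tmp_path / "cl.tsv"
    cmap.write_text("HepG2\tliver\nSK-N-SH\tbrain\nIMR-90\tlung\n")
    cat = read_tsg_catalog(tsg, cmap)
    assert cat.tissue_to_genes["liver"] == {"ALB", "OTC"}
    # tissue known only from the cell-line map gets an (empty) entry
    assert cat.tissue_to_genes["lung"] == set()
    assert cat.celllines_of("liver") == ["HepG2"]

    empty = tmp_path / "empty.tsv"
    empty.write_text("")
    with pytest.raises(FormatError, match="empty TSG catalog"):
        read_tsg_catalog(empty, cmap)


def test_cellline_map_duplicate(tmp_path):
    p = tmp_path / "cl.tsv"
    p.write_text("HepG2\tliver\nHepG2\tlung\n")
    with pytest.raises(FormatError, match="duplicate cell line"):
        read_cellline_map(p)


def test_bed3_round_trip(tmp_path, layout):
    s = IntervalSet.from_pairs(layout, [("chr1", 5, 10), ("chr2", 0, 50_000)])
    p = tmp_path / "x.bed"
    write_bed3(s, p)
    assert read_bed3(p, layout) == s


def test_gene_cluster_table_sorted(tmp_path):
    p = tmp_path / "gc.tsv"
    write_gene_cluster_table(
        [("geneB", "HepG2"), ("geneA", "HepG2"), ("geneA", "A549")], p
    )
    assert p.read_text() == "geneA\tA549\ngeneA\tHepG2\ngeneB\tHepG2\n"


def test_flag_human_specific_exact_and_reciprocal(layout):
    tes = [
        TERecord("chr1", 100, 400, "+", "AluYa5", "SINE", "Alu", 1.0),
        TERecord("chr1", 1000, 1300, "+", "AluY", "SINE", "Alu", 12.0),
    ]
    hste_exact = IntervalSet.from_pairs(layout, [("chr1", 100, 400)])
    out = flag_human_specific(tes, hste_exact, mode="exact")
    assert [r.is_human_specific for r in out] == [True, False]

    # trimmed coordinates: exact match fails, >=90% reciprocal overlap succeeds
    hste_trim = IntervalSet.from_pairs(layout, [("chr1", 105, 395)])
    out = flag_human_specific(tes, hste_trim, mode="exact")
    assert not any(r.is_human_specific for r in out)
    out = flag_human_specific(tes, hste_trim, mode="reciprocal")
    assert [r.is_human_specific for r in out] == [True, False]
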