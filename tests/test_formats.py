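"""Parsers and writers: the two per-cytosine dialects, GTF, and mtable."""

import gzip
import math

import numpy as np
import pandas as pd
import pytest

from methgene import formats
from methgene.core import MethylationProfile, MEASUREMENT_KEYS, MEASUREMENTS
from methgene.formats import (
    FormatError,
    ParseError,
    parse_cgmap,
    parse_cx_report,
    read_gene_models,
    read_mtable,
    write_mtable,
)


def _write(tmp_path, name, lines, compress=False):
    path = tmp_path / name
    data = "\n".join(lines) + "\n"
    if compress:
        path = tmp_path / (name + ".gz")
        with gzip.open(path, "wt") as fh:
            fh.write(data)
    else:
        path.write_text(data)
    return path


class TestCGmap:
    def test_watson_and_crick_rows(self, tmp_path):
        path = _write(tmp_path, "a.cgmap", [
            "Chr1\tC\t1002\tCG\tCG\t0.75\t3\t4",
            "Chr1\tG\t1003\tCG\tCG\t0.0\t0\t6",
        ])
        sites = list(parse_cgmap(path))
        assert sites[0] == formats.CytosineSite("Chr1", 1002, "+", "CG", 3, 4)
        assert sites[1] == formats.CytosineSite("Chr1", 1003, "-", "CG", 0, 6)

    def test_zero_coverage_rows_dropped(self, tmp_path):
        path = _write(tmp_path, "a.cgmap", ["Chr1\tC\t10\tCHH\tCT\t0.0\t0\t0"])
        assert list(parse_cgmap(path)) == []

    def test_gzip_transparent(self, tmp_path):
        path = _write(tmp_path, "a.cgmap", ["Chr1\tC\t1002\tCG\tCG\t0.75\t3\t4"], compress=True)
        assert len(list(parse_cgmap(path))) == 1

    @pytest.mark.parametrize("line,message", [
        ("Chr1\tC\t1002\tCG\tCG\t0.75\t3", "expected 8"),
        ("Chr1\tC\t1002\tCG\tCG\t0.75\tthree\t4", "non-integer"),
        ("Chr1\tC\t1002\tCpG\tCG\t0.75\t3\t4", "unknown context"),
        ("Chr1\tT\t1002\tCG\tCG\t0.75\t3\t4", "C or G"),
        ("Chr1\tC\t1002\tCG\tCG\t0.75\t5\t4", "outside"),
    ])
    def test_malformed_lines_name_the_line(self, tmp_path, line, message):
        path = _write(tmp_path, "bad.cgmap", ["Chr1\tC\t1\tCG\tCG\t1.0\t4\t4", line])
        with pytest.raises(ParseError, match="line 2") as exc:
            list(parse_cgmap(path))
        assert message in str(exc.value)


class TestCXReport:
    def test_counts_summed(self, tmp_path):
        path = _write(tmp_path, "a.cx", ["Chr1\t1002\t+\t3\t1\tCG\tCGA"])
        (site,) = parse_cx_report(path)
        assert (site.n_methylated, site.n_total) == (3, 4)

    def test_uncovered_sites_retained(self, tmp_path):
        path = _write(tmp_path, "a.cx", ["Chr1\t900\t-\t0\t0\tCHH\tCTA"])
        (site,) = parse_cx_report(path)
        assert site.n_total == 0 and site.strand == "-"

    def test_malformed_column_count(self, tmp_path):
        path = _write(tmp_path, "bad.cx", ["Chr1\t900\t-\t0\t0\tCHH"])
        with pytest.raises(ParseError, match="line 1"):
            list(parse_cx_report(path))

    def test_dialects_agree_on_simulated_methylome(self, sim_methylome):
        """The paired encodings of one methylome parse to the same covered-site set."""
        from_cgmap = set(parse_cgmap(sim_methylome.cgmap_path))
        from_cx = {s for s in parse_cx_report(sim_methylome.cx_path) if s.n_total > 0}
        assert from_cgmap == from_cx

    def test_parsed_counts_match_simulator_ground_truth(self, sim_methylome):
        truth_sites = {s for s in sim_methylome.truth.all_sites() if s.n_total > 0}
        assert set(parse_cgmap(sim_methylome.cgmap_path)) == truth_sites


class TestGeneModels:
    def test_promoter_derivation_both_strands(self, tmp_path):
        path = _write(tmp_path, "g.gtf", [
            'Chr1\tx\tgene\t10000\t12000\t.\t+\t.\tgene_id "A"; gene_biotype "protein_coding";',
            'Chr1\tx\tgene\t10000\t12000\t.\t-\t.\tgene_id "B";',
            'Chr1\tx\tgene\t1000\t3000\t.\t+\t.\tgene_id "C";',
        ])
        genes = {g.gene_id: g for g in read_gene_models(path)}
        assert (genes["A"].promoter_start, genes["A"].promoter_end) == (7500, 10500)
        assert (genes["B"].promoter_start, genes["B"].promoter_end) == (11500, 14500)
        assert (genes["C"].promoter_start, genes["C"].promoter_end) == (1, 1500)
        assert genes["B"].biotype == "unknown"

    def test_no_gene_features_is_an_error(self, tmp_path):
        path = _write(tmp_path, "g.gtf", [
            'Chr1\tx\texon\t10\t20\t.\t+\t.\tgene_id "A";',
        ])
        with pytest.raises(FormatError, match="no gene features"):
            read_gene_models(path)

    def test_duplicate_gene_id_named_in_error(self, tmp_path):
        row = 'Chr1\tx\tgene\t10\t20\t.\t+\t.\tgene_id "DUP";'
        path = _write(tmp_path, "g.gtf", [row, row])
        with pytest.raises(FormatError, match="DUP"):
            read_gene_models(path)

    def test_custom_promoter_offsets(self, tmp_path):
        path = _write(tmp_path, "g.gtf", [
            'Chr1\tx\tgene\t10000\t12000\t.\t+\t.\tgene_id "A";',
        ])
        (gene,) = read_gene_models(path, promoter_upstream=1000, promoter_downstream=200)
        assert (gene.promoter_start, gene.promoter_end) == (9000, 10200)


def _profile(gene_id, values):
    return MethylationProfile(
        gene_id=gene_id,
        values={MEASUREMENT_KEYS[m]: v for m, v in zip(MEASUREMENTS, values)},
        n_sites={MEASUREMENT_KEYS[m]: 5 for m in MEASUREMENTS},
    )


class TestMtable:
    def test_all_nan_profile_serializes_as_nan_row(self, tmp_path):
        path = tmp_path / "m.mtable"
        write_mtable([_profile("AT1G00001", [math.nan] * 6)], path)
        assert path.read_text().splitlines()[1] == "AT1G00001\tNaN\tNaN\tNaN\tNaN\tNaN\tNaN"

    def test_empty_collection_gives_header_only(self, tmp_path):
        path = tmp_path / "m.mtable"
        write_mtable([], path)
        assert path.read_text() == "\t".join(formats.MTABLE_HEADER) + "\n"

    def test_round_trip_identity_at_serialized_precision(self, tmp_path, rng):
        values = rng.random((30, 6)).round(4)
        values[rng.random((30, 6)) < 0.2] = math.nan
        profiles = [_profile(f"G{i:03d}", row) for i, row in enumerate(values)]
        path = tmp_path / "m.mtable"
        write_mtable(profiles, path)
        frame = read_mtable(path)
        np.testing.assert_array_equal(frame.to_numpy(), values)
        assert list(frame.index) == [f"G{i:03d}" for i in range(30)]

    def test_repeated_writes_are_byte_identical(self, tmp_path, rng):
        profiles = [_profile(f"G{i}", rng.random(6)) for i in range(200)]
        p1, p2 = tmp_path / "a", tmp_path / "b"
        write_mtable(profiles, p1)
        write_mtable(profiles, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_header_mismatch(self, tmp_path):
        path = _write(tmp_path, "bad.mtable", ["gene\tx1\tx2\tx3\tx4\tx5\tx6"])
        with pytest.raises(FormatError, match="header"):
            read_mtable(path)

    def test_non_numeric_cell_reports_gene(self, tmp_path):
        path = _write(tmp_path, "bad.mtable", [
            "\t".join(formats.MTABLE_HEADER),
            "GX\t0.1\t0.2\toops\t0.3\t0.4\t0.5",
        ])
        with pytest.raises(ParseError, match="GX"):
            read_mtable(path)

    def test_headerless_mode(self, tmp_path):
        path = _write(tmp_path, "no_header.mtable", ["GX\t0.1\t0.2\t0.3\t0.4\t0.5\t0.6"])
        frame = read_mtable(path, header=False)
        assert frame.loc["GX", "pmt_CG"] == pytest.approx(0.1)

    def test_dataframe_input_round_trips(self, tmp_path):
        frame = pd.DataFrame(
            [[0.1, 0.2, 0.3, 0.4, 0.5, math.nan]], index=["GY"], columns=list(MEASUREMENTS)
        )
        path = tmp_path / "m.mtable"
        write_mtable(frame, path)
        back = read_mtable(path)
        assert math.isnan(back.loc["GY", "gene_CHH"])
        assert back.loc["GY", "pmt_CG"] == pytest.approx(0.1)
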