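"""I/O round trips and validation behaviour of the format readers."""
import numpy as np
import pandas as pd
import pytest

from tsgkit import formats
from tsgkit.formats import FormatError, ValidationError


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


# --------------------------------------------------------------- expression

class TestReadExpression:
    def _paths(self, tmp_path, matrix, meta=None):
        if meta is None:
            meta = (
                "sample_id\tspecies\ttissue\treplicate\n"
                "s1\tpig\ttestis\t1\ns2\tpig\tbrain\t1\n"
            )
        return (
            _write(tmp_path, "m.tsv", matrix),
            _write(tmp_path, "meta.tsv", meta),
        )

    def test_minimal_well_formed(self, tmp_path):
        m, meta = self._paths(tmp_path, "gene_id\ts1\ts2\ng1\t1.5\t2\ng2\t0\t3\n")
        table = formats.read_expression(m, meta)
        assert table.values.shape == (2, 2)
        assert table.tissues() == ["brain", "testis"]

    def test_na_cell_is_parse_error_naming_the_cell(self, tmp_path):
        m, meta = self._paths(tmp_path, "gene_id\ts1\ts2\ng1\tNA\t2\n")
        with pytest.raises(FormatError, match="g1.*s1"):
            formats.read_expression(m, meta)

    def test_missing_metadata_lists_orphan_sample(self, tmp_path):
        m, meta = self._paths(
            tmp_path,
            "gene_id\ts1\ts2\ng1\t1\t2\n",
            "sample_id\tspecies\ttissue\treplicate\ns1\tpig\ttestis\t1\n",
        )
        with pytest.raises(ValidationError, match="s2"):
            formats.read_expression(m, meta)

    def test_duplicate_gene_rejected(self, tmp_path):
        m, meta = self._paths(tmp_path, "gene_id\ts1\ts2\ng1\t1\t2\ng1\t3\t4\n")
        with pytest.raises(ValidationError, match="duplicate"):
            formats.read_expression(m, meta)

    def test_negative_value_rejected(self, tmp_path):
        m, meta = self._paths(tmp_path, "gene_id\ts1\ts2\ng1\t-1\t2\n")
        with pytest.raises(ValidationError, match="negative"):
            formats.read_expression(m, meta)


# --------------------------------------------------------------- orthogroups

class TestReadOrthogroups:
    def test_minimal_line(self, tmp_path):
        p = _write(tmp_path, "g.txt", "F1: pig|g1 cattle|g2\n")
        og = formats.read_orthogroups(p)
        assert og.families == {"F1": {"pig": ["g1"], "cattle": ["g2"]}}

    def test_multi_copy_family(self, tmp_path):
        p = _write(tmp_path, "g.txt", "F1: pig|g1 pig|g2\n")
        og = formats.read_orthogroups(p)
        assert og.families["F1"]["pig"] == ["g1", "g2"]

    def test_missing_colon_is_parse_error(self, tmp_path):
        p = _write(tmp_path, "g.txt", "F1 pig|g1\n")
        with pytest.raises(FormatError, match="':'"):
            formats.read_orthogroups(p)

    def test_member_without_pipe_is_parse_error(self, tmp_path):
        p = _write(tmp_path, "g.txt", "F1: pigg1\n")
        with pytest.raises(FormatError, match="pigg1"):
            formats.read_orthogroups(p)

    def test_gene_in_two_families_rejected(self, tmp_path):
        p = _write(tmp_path, "g.txt", "F1: pig|g1 cattle|c1\nF2: pig|g1 sheep|s1\n")
        with pytest.raises(ValidationError, match="g1"):
            formats.read_orthogroups(p)


# ---------------------------------------------------------------------- GMT

class TestReadGmt:
    def test_minimal(self, tmp_path):
        p = _write(tmp_path, "s.gmt", "S1\tdesc\tg1\tg2\n")
        coll = formats.read_gmt(p)
        assert coll["S1"].genes == ("g1", "g2")

    def test_duplicate_members_deduplicated_with_warning(self, tmp_path, caplog):
        p = _write(tmp_path, "s.gmt", "S1\tdesc\tg1\tg1\tg2\n")
        with caplog.at_level("WARNING"):
            coll = formats.read_gmt(p)
        assert coll["S1"].genes == ("g1", "g2")
        assert any("duplicate" in r.message for r in caplog.records)

    def test_too_few_fields_is_parse_error(self, tmp_path):
        p = _write(tmp_path, "s.gmt", "S1\tdesc\n")
        with pytest.raises(FormatError):
            formats.read_gmt(p)

    def test_duplicate_set_id_rejected(self, tmp_path):
        p = _write(tmp_path, "s.gmt", "S1\td\tg1\nS1\td\tg2\n")
        with pytest.raises(ValidationError, match="S1"):
            formats.read_gmt(p)


# ---------------------------------------------------------------------- PSI

class TestReadPsi:
    header = "event_id\tgene_id\tevent_type\ttissue\tpsi\n"

    def test_fraction_scale_autodetected(self, tmp_path):
        rows = "".join(
            f"E{i}\tg{i}\tSE\ttestis\t{0.5 if i else 0.9}\n" for i in range(25)
        )
        p = _write(tmp_path, "p.tsv", self.header + rows)
        psi = formats.read_psi(p)
        assert set(psi.df["psi"].round(6)) <= {50.0, 90.0}

    def test_explicit_percent_scale_keeps_small_values(self, tmp_path):
        rows = "".join(f"E{i}\tg{i}\tSE\ttestis\t0.5\n" for i in range(25))
        p = _write(tmp_path, "p.tsv", self.header + rows)
        psi = formats.read_psi(p, scale="percent")
        assert (psi.df["psi"] == 0.5).all()

    def test_missing_values_become_nan(self, tmp_path):
        p = _write(tmp_path, "p.tsv", self.header + "E1\tg1\tSE\ttestis\tNA\n")
        psi = formats.read_psi(p)
        assert psi.df["psi"].isna().all()

    def test_unknown_event_type_rejected(self, tmp_path):
        p = _write(tmp_path, "p.tsv", self.header + "E1\tg1\tXX\ttestis\t50\n")
        with pytest.raises(ValidationError, match="XX"):
            formats.read_psi(p)

    def test_out_of_range_rejected(self, tmp_path):
        p = _write(tmp_path, "p.tsv", self.header + "E1\tg1\tSE\ttestis\t120\n")
        with pytest.raises(ValidationError):
            formats.read_psi(p)


# ---------------------------------------------------------------------- GTF

class TestReadGtf:
    def test_gene_records(self, tmp_path):
        text = (
            'chr1\tsrc\tgene\t100\t900\t.\t+\t.\tgene_id "g1";\n'
            'chr2\tsrc\tgene\t50\t60\t.\t-\t.\tgene_id "g2";\n'
        )
        ann = formats.read_gtf_annotation(_write(tmp_path, "a.gtf", text))
        assert ann.genes.loc["g1", "strand"] == "+"
        assert ann.genes.loc["g2", "end"] == 60

    def test_transcript_fallback_spans(self, tmp_path):
        text = (
            'chr1\tsrc\ttranscript\t100\t500\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
            'chr1\tsrc\ttranscript\t300\t900\t.\t+\t.\tgene_id "g1"; transcript_id "t2";\n'
        )
        ann = formats.read_gtf_annotation(_write(tmp_path, "a.gtf", text))
        assert (ann.genes.loc["g1", ["start", "end"]] == [100, 900]).all()
        assert ann.transcripts == {"t1": "g1", "t2": "g1"}

    def test_dot_strand_rejected(self, tmp_path):
        text = 'chr1\tsrc\tgene\t100\t900\t.\t.\t.\tgene_id "g1";\n'
        with pytest.raises(ValidationError, match="strand"):
            formats.read_gtf_annotation(_write(tmp_path, "a.gtf", text))


# -------------------------------------------------------------------- edges

class TestReadEdges:
    def test_single_edge(self, tmp_path):
        el = formats.read_edges(_write(tmp_path, "e.tsv", "g1\tg2\n"))
        assert len(el) == 1

    def test_empty_file(self, tmp_path):
        el = formats.read_edges(_write(tmp_path, "e.tsv", ""))
        assert len(el) == 0

    def test_scores_parsed(self, tmp_path):
        el = formats.read_edges(_write(tmp_path, "e.tsv", "g1\tg2\t900\ng2\tg3\n"))
        assert el.df["score"].tolist()[0] == 900.0
        assert np.isnan(el.df["score"].tolist()[1])


# --------------------------------------------------------------- motif hits

def test_read_motif_hits_fimo_layout(tmp_path):
    text = (
        "motif_id\tmotif_alt_id\tsequence_name\tstart\tstop\tstrand\tscore"
        "\tp-value\tq-value\tmatched_sequence\n"
        "TF1\tTF1\tg1\t10\t20\t+\t12.5\t1e-5\t0.01\tACGTACGT\n"
    )
    hits = formats.read_motif_hits(_write(tmp_path, "h.tsv", text))
    assert len(hits) == 1
    assert hits.df.loc[0, "p_value"] == 1e-5


def test_motif_hit_start_after_stop_rejected(tmp_path):
    text = (
        "motif_id\tmotif_alt_id\tsequence_name\tstart\tstop\tstrand\tscore"
        "\tp-value\tq-value\tmatched_sequence\n"
        "TF1\tTF1\tg1\t30\t20\t+\t1\t1e-5\t0.01\tAC\n"
    )
    with pytest.raises(ValidationError):
        formats.read_motif_hits(_write(tmp_path, "h.tsv", text))


# ------------------------------------------------------- write / round trip

def test_write_table_round_trip_preserves_values(tmp_path):
    rng = np.random.default_rng(11)
    df = pd.DataFrame(
        {
            "gene_id": [f"g{i:03d}" for i in range(40)],
            "value": rng.lognormal(0, 3, 40),
            "count": rng.integers(0, 100, 40),
        }
    )
    path = tmp_path / "t.tsv"
    formats.write_table(df, path, comments=["round trip"])
    back = formats.read_table(path)
    merged = df.merge(back, on="gene_id", suffixes=("", "_rt"))
    assert len(merged) == len(df)
    assert np.allclose(merged["value"], merged["value_rt"], rtol=1e-11, atol=0)
    assert (merged["count"] == merged["count_rt"]).all()


def test_write_table_row_order_is_input_order_independent(tmp_path):
    df = pd.DataFrame({"gene_id": ["b", "a", "c"], "v": [2.0, 1.0, 3.0]})
    p1, p2 = tmp_path / "1.tsv", tmp_path / "2.tsv"
    formats.write_table(df, p1)
    formats.write_table(df.iloc[::-1], p2)
    assert p1.read_bytes() == p2.read_bytes()
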