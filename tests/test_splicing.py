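"""Splicing presence rules, gene counts and isoform contribution rates."""
import numpy as np
import pandas as pd
import pytest

from oracles import oracle_tsg_calls
from tsgkit.formats import EVENT_TYPES, IsoformTable, PsiTable
from tsgkit.splicing import (
    contribution_rates,
    count_spliced_genes,
    event_presence,
    transcript_specific,
)


def _psi(rows):
    df = pd.DataFrame(rows, columns=["event_id", "gene_id", "event_type", "tissue", "psi"])
    return PsiTable(df)


def _iso(rows):
    return IsoformTable(
        pd.DataFrame(rows, columns=["gene_id", "isoform_id", "tissue", "fpkm"])
    )


class TestEventPresence:
    @pytest.mark.parametrize(
        "psi,expected",
        [(4.999, False), (5.0, True), (50.0, True), (95.0, True), (95.001, False),
         (96.0, False), (np.nan, False)],
    )
    def test_inclusive_bounds_and_missing(self, psi, expected):
        df = event_presence(_psi([("e", "g", "SE", "testis", psi)]))
        assert bool(df["present"].iloc[0]) is expected


class TestCountSplicedGenes:
    def test_gene_counted_once_per_tissue_and_type(self):
        psi = _psi(
            [
                ("e1", "g1", "SE", "testis", 50.0),
                ("e2", "g1", "SE", "testis", 60.0),  # same gene/type: dedup
                ("e3", "g1", "RI", "testis", 50.0),
                ("e4", "g2", "SE", "brain", 50.0),
                ("e5", "g3", "SE", "brain", 99.0),   # absent
            ]
        )
        s = count_spliced_genes(psi)
        assert s.per_tissue["testis"] == 1 and s.per_tissue["brain"] == 1
        assert s.per_tissue_type.loc["testis", "SE"] == 1
        assert s.per_tissue_type.loc["testis", "RI"] == 1
        assert s.n_spliced_genes == 2
        assert s.type_proportions["SE"] == 1.0 and s.type_proportions["RI"] == 0.5

    def test_totals_match_brute_force_recount_on_random_table(self):
        rng = np.random.default_rng(9)
        rows = []
        tissues = ["testis", "brain", "liver"]
        for e in range(300):
            gene = f"g{rng.integers(0, 40)}"
            etype = EVENT_TYPES[rng.integers(0, len(EVENT_TYPES))]
            for t in tissues:
                psi = float(rng.uniform(0, 100)) if rng.random() > 0.1 else np.nan
                rows.append((f"e{e}", gene, etype, t, psi))
        s = count_spliced_genes(_psi(rows))
        # brute force from raw rows
        present = [
            (e, g, et, t)
            for e, g, et, t, p in rows
            if p == p and 5.0 <= p <= 95.0
        ]
        for t in tissues:
            assert s.per_tissue[t] == len({g for _, g, _, tt in present if tt == t})
        for et in EVENT_TYPES:
            want = len({g for _, g, ett, _ in present if ett == et})
            got = (
                s.type_proportions[et] * s.n_spliced_genes
                if s.n_spliced_genes
                else 0
            )
            assert round(got) == want


class TestContributionRates:
    matrix = pd.DataFrame({"testis": [10.0]}, index=["g1"])

    def test_worked_example_nine_elevenths(self):
        iso = _iso([("g1", "i1", "testis", 9.0), ("g1", "i2", "testis", 1.0)])
        rec, med = contribution_rates(iso, self.matrix)
        assert rec["rate"].iloc[0] == pytest.approx(9 / 11, abs=1e-12)
        assert med["testis"] == pytest.approx(9 / 11, abs=1e-12)

    def test_single_isoform_gene_excluded(self):
        iso = _iso([("g1", "i1", "testis", 10.0)])
        rec, _ = contribution_rates(iso, self.matrix)
        assert rec.empty

    def test_zero_expression_gives_zero_rate(self):
        iso = _iso([("g1", "i1", "testis", 0.0), ("g1", "i2", "testis", 0.0)])
        matrix = pd.DataFrame({"testis": [0.0]}, index=["g1"])
        rec, _ = contribution_rates(iso, matrix)
        assert rec["rate"].iloc[0] == 0.0

    def test_mismatched_gene_value_recomputed_from_isoform_sum(self, caplog):
        iso = _iso([("g1", "i1", "testis", 9.0), ("g1", "i2", "testis", 1.0)])
        matrix = pd.DataFrame({"testis": [99.0]}, index=["g1"])  # inconsistent
        with caplog.at_level("WARNING"):
            rec, _ = contribution_rates(iso, matrix)
        assert rec["rate"].iloc[0] == pytest.approx(9 / 11, abs=1e-12)
        assert any("mismatch" in r.message for r in caplog.records)

    def test_tie_broken_by_lexicographic_isoform_id(self):
        iso = _iso([("g1", "zz", "testis", 5.0), ("g1", "aa", "testis", 5.0)])
        rec, _ = contribution_rates(iso, pd.DataFrame({"testis": [10.0]}, index=["g1"]))
        assert rec["fpkm_top"].iloc[0] == 5.0  # deterministic pick

    def test_rate_strictly_below_one_on_random_tables(self):
        rng = np.random.default_rng(10)
        rows = []
        for g in range(30):
            k = int(rng.integers(2, 5))
            for t in ("testis", "brain"):
                vals = rng.lognormal(2, 2, k)
                rows.extend((f"g{g}", f"g{g}.i{j}", t, float(vals[j])) for j in range(k))
        iso = _iso(rows)
        gm = iso.df.pivot_table(index="gene_id", columns="tissue", values="fpkm", aggfunc="sum")
        rec, _ = contribution_rates(iso, gm)
        f = rec["fpkm_gene"]
        assert (rec["rate"] < 1).all()
        assert (rec["rate"] <= f / (f + 1) + 1e-12).all()

    def test_requested_gene_without_isoforms_skipped_with_warning(self, caplog):
        iso = _iso([("g1", "i1", "testis", 9.0), ("g1", "i2", "testis", 1.0)])
        with caplog.at_level("WARNING"):
            rec, _ = contribution_rates(iso, self.matrix, gene_set=["g1", "ghost"])
        assert set(rec["gene_id"]) == {"g1"}
        assert any("no isoform rows" in r.message for r in caplog.records)


class TestTranscriptSpecific:
    def test_single_tissue_transcript_called(self):
        rows = [("g1", "t1", tis, 10.0 if tis == "testis" else 0.0)
                for tis in ("testis", "brain", "liver")]
        rows += [(f"g{j}", f"t{j}", tis, 5.0)
                 for j in range(2, 12) for tis in ("testis", "brain", "liver")]
        res = transcript_specific(_iso(rows))
        assert "t1" in res.genes_for("testis")

    def test_dim_transcript_not_called(self):
        rows = [("g1", "t1", tis, 0.5 if tis == "testis" else 0.0)
                for tis in ("testis", "brain", "liver")]
        rows += [(f"g{j}", f"t{j}", tis, 5.0)
                 for j in range(2, 12) for tis in ("testis", "brain", "liver")]
        res = transcript_specific(_iso(rows))
        assert res.calls[res.calls["gene_id"] == "t1"].empty

    def test_agrees_with_brute_force_on_random_table(self):
        rng = np.random.default_rng(11)
        tissues = ["testis", "brain", "liver", "heart"]
        rows = []
        for j in range(100):
            vals = rng.lognormal(1, 1.5, len(tissues))
            if rng.random() < 0.15:
                vals[rng.integers(0, len(tissues))] *= 50
            for t, v in zip(tissues, vals):
                rows.append((f"g{j}", f"t{j}", t, float(v)))
        iso = _iso(rows)
        res = transcript_specific(iso)
        matrix = iso.df.pivot_table(index="isoform_id", columns="tissue", values="fpkm")
        got = set(zip(res.calls["gene_id"], res.calls["tissue"]))
        assert got == oracle_tsg_calls(matrix)
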