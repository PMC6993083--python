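"""I/O layer: dialects, invariant-based skipping, report round trips."""

import gzip
import math

import pytest

from smrkit import sumstats_io as io
from smrkit.smr_core import SmrResult

from conftest import make_gwas, make_qtl


class TestReadGwas:
    def test_well_formed_file(self, gwas_file):
        res = io.read_gwas(gwas_file, "smrkit-gwas")
        assert len(res.records) == 3
        assert res.n_skipped == 0
        assert res.records[0].snp_id == "rs1"
        assert res.records[1].beta == pytest.approx(-0.05)
        assert res.records[2].chrom == "2"

    def test_zero_se_row_skipped(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text(
            "snp\tchrom\tpos\teffect_allele\tother_allele\teaf\tbeta\tse\tpvalue\tn\n"
            "rs1\t1\t1000\tA\tG\t0.3\t0.10\t0.02\t5e-7\t100\n"
            "rs2\t1\t2000\tC\tT\t0.2\t0.05\t0\t6e-7\t100\n")
        res = io.read_gwas(p, "smrkit-gwas")
        assert len(res.records) == 1
        assert res.n_skipped == 1
        assert res.skip_reasons["nonpositive_se"] == 1

    def test_odds_ratio_converted_by_natural_log(self, tmp_path):
        # independent oracle: math.log evaluated inline
        dialect = io.Dialect(snp="SNP", effect_allele="A1", other_allele="A2",
                             odds_ratio="OR", se="SE", pvalue="P")
        p = tmp_path / "g.tsv"
        p.write_text("SNP\tA1\tA2\tOR\tSE\tP\nrs1\tA\tG\t1.105\t0.02\t1e-5\n")
        res = io.read_gwas(p, dialect)
        assert res.records[0].beta == pytest.approx(math.log(1.105))
        assert res.records[0].beta == pytest.approx(0.09985, abs=5e-6)

    def test_missing_column_names_the_column(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("snp\teffect_allele\tother_allele\tse\tpvalue\n"
                     "rs1\tA\tG\t0.02\t1e-5\n")
        with pytest.raises(io.DialectError, match="beta"):
            io.read_gwas(p, "smrkit-gwas")

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        with pytest.raises(io.EmptyInputError):
            io.read_gwas(p, "smrkit-gwas")

    def test_duplicate_snp_keeps_first(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text(
            "snp\tchrom\tpos\teffect_allele\tother_allele\teaf\tbeta\tse\tpvalue\tn\n"
            "rs1\t1\t1000\tA\tG\t0.3\t0.10\t0.02\t5e-7\t100\n"
            "rs1\t1\t1000\tA\tG\t0.3\t0.99\t0.02\t5e-7\t100\n")
        res = io.read_gwas(p, "smrkit-gwas")
        assert len(res.records) == 1
        assert res.records[0].beta == pytest.approx(0.10)
        assert res.skip_reasons["duplicate"] == 1

    def test_rows_equal_retained_plus_skipped(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text(
            "snp\tchrom\tpos\teffect_allele\tother_allele\teaf\tbeta\tse\tpvalue\tn\n"
            "rs1\t1\t1\tA\tG\t0.3\t0.1\t0.02\t5e-7\t100\n"
            "rs2\t1\t2\tA\tA\t0.3\t0.1\t0.02\t5e-7\t100\n"   # identical alleles
            "rs3\t1\t3\tA\tG\t0.3\t0.1\t0.02\t0\t100\n"      # p = 0
            "rs4\t1\t4\tA\tG\t0.3\txx\t0.02\t5e-7\t100\n"    # unparseable
            "rs5\t1\t5\tA\tG\t0.3\t0.1\t0.02\t5e-7\t100\n")
        res = io.read_gwas(p, "smrkit-gwas")
        assert res.n_rows == len(res.records) + res.n_skipped == 5
        assert len(res.records) == 2

    def test_gzip_transparent(self, tmp_path, gwas_file):
        gz = tmp_path / "g.tsv.gz"
        gz.write_bytes(gzip.compress(gwas_file.read_bytes()))
        assert len(io.read_gwas(gz, "smrkit-gwas").records) == 3

    def test_megastroke_dialect(self, tmp_path):
        p = tmp_path / "ms.out"
        p.write_text("MarkerName Allele1 Allele2 Freq1 Effect StdErr P-value\n"
                     "rs1 a g 0.31 0.021 0.017 0.2164\n")
        res = io.read_gwas(p, "megastroke")
        rec = res.records[0]
        assert rec.effect_allele == "A" and rec.other_allele == "G"
        assert rec.eaf == pytest.approx(0.31)
        assert rec.pos is None


class TestReadQtl:
    def test_two_probes_five_snps(self, qtl_file):
        res = io.read_qtl(qtl_file, "smrkit-qtl")
        assert len(res.records) == 10
        by_probe = {}
        for r in res.records:
            by_probe.setdefault(r.probe_id, []).append(r)
        assert sorted(by_probe) == ["PRB1", "PRB2"]
        assert all(len(v) == 5 for v in by_probe.values())

    def test_trans_record_retained_and_flagged(self):
        rec = make_qtl(probe_chrom="1", snp_chrom="2")
        assert rec.trans
        assert not make_qtl().trans

    def test_duplicate_snp_probe_keeps_first(self, tmp_path):
        header = ("snp\tprobe\tgene\tprobe_chrom\tprobe_pos\tsnp_chrom\t"
                  "snp_pos\teffect_allele\tother_allele\teaf\tbeta\tse\t"
                  "pvalue\tfdr\n")
        row = "rs1\tPRB1\tG1\t1\t100\t1\t200\tA\tG\t0.3\t{b}\t0.02\t1e-9\tNA\n"
        p = tmp_path / "q.tsv"
        p.write_text(header + row.format(b=0.2) + row.format(b=0.9))
        res = io.read_qtl(p, "smrkit-qtl")
        assert len(res.records) == 1
        assert res.records[0].beta == pytest.approx(0.2)
        assert res.skip_reasons["duplicate"] == 1

    def test_qtl_dialect_requires_probe_fields(self):
        d = io.Dialect(snp="snp", effect_allele="a1", other_allele="a2",
                       beta="b", se="se", pvalue="p")
        with pytest.raises(io.DialectError, match="probe"):
            d.required_qtl_columns()

    def test_unknown_preset(self, gwas_file):
        with pytest.raises(io.DialectError, match="nope"):
            io.read_gwas(gwas_file, "nope")


def _result(probe="PRB1", gene="GENEA", snp="rs1", p=1e-6, b=0.3):
    return SmrResult(probe_id=probe, gene_symbol=gene, top_snp=snp, b_xy=b,
                     se_xy=0.05, T_smr=24.0, p_smr=p, n_cis_snps=7)


class TestWriteResults:
    def test_empty_results_header_only(self, tmp_path):
        out = tmp_path / "r.tsv"
        io.write_results([], out)
        lines = out.read_text().splitlines()
        assert lines == ["\t".join(io.RESULT_COLUMNS)]

    def test_sorted_ascending_p(self, tmp_path):
        out = tmp_path / "r.tsv"
        io.write_results([_result(probe="A", p=9.0e-6),
                          _result(probe="B", p=4.0e-6)], out)
        lines = out.read_text().splitlines()[1:]
        assert lines[0].split("\t")[6] == "B"
        assert float(lines[0].split("\t")[1]) == pytest.approx(4.0e-6)

    def test_round_trip_to_three_significant_digits(self, tmp_path):
        out = tmp_path / "r.tsv"
        orig = _result(p=2.34567e-8, b=0.31415)
        io.write_results([orig], out)
        back = io.read_results(out)[0]
        assert back.p_smr == pytest.approx(orig.p_smr, rel=1e-3)
        assert back.b_xy == pytest.approx(orig.b_xy, rel=1e-3)
        assert back.T_smr == pytest.approx(orig.T_smr, rel=1e-3)
        assert back.top_snp == orig.top_snp
        assert back.gene_symbol == orig.gene_symbol
        assert back.n_cis_snps == orig.n_cis_snps

    def test_gene_falls_back_to_probe_id(self, tmp_path):
        out = tmp_path / "r.tsv"
        io.write_results([_result(gene=None)], out)
        assert out.read_text().splitlines()[1].split("\t")[2] == "PRB1"


class TestRecordRoundTrip:
    def test_gwas_write_read(self, tmp_path):
        recs = [make_gwas(snp_id=f"rs{i}", beta=0.01 * i - 0.02, eaf=0.25,
                          chrom="3", pos=1000 + i, n=500.0)
                for i in range(1, 5)]
        p = tmp_path / "g.tsv"
        io.write_gwas(recs, p)
        back = io.read_gwas(p, "smrkit-gwas").records
        assert [r.snp_id for r in back] == [r.snp_id for r in recs]
        for a, b in zip(recs, back):
            assert b.beta == pytest.approx(a.beta, rel=1e-9)
            assert b.se == pytest.approx(a.se, rel=1e-9)
            assert b.pvalue == pytest.approx(a.pvalue, rel=1e-9)

    def test_qtl_write_read(self, tmp_path):
        recs = [make_qtl(snp_id=f"rs{i}", beta=-0.3 + 0.1 * i, eaf=0.4)
                for i in range(1, 4)]
        p = tmp_path / "q.tsv"
        io.write_qtl(recs, p)
        back = io.read_qtl(p, "smrkit-qtl").records
        for a, b in zip(recs, back):
            assert (b.snp_id, b.probe_id) == (a.snp_id, a.probe_id)
            assert b.beta == pytest.approx(a.beta, rel=1e-9)
            assert b.snp_pos == a.snp_pos


class TestRecordInvariants:
    @pytest.mark.parametrize("kw,reason", [
        (dict(se=0.0), "nonpositive_se"),
        (dict(se=-1.0), "nonpositive_se"),
        (dict(p=0.0), "pvalue_out_of_range"),
        (dict(p=1.5), "pvalue_out_of_range"),
        (dict(ea="A", oa="A"), "identical_alleles"),
        (dict(beta=float("nan")), "nonfinite_beta"),
    ])
    def test_gwas_invariants(self, kw, reason):
        with pytest.raises(io.InvalidRecordError, match=reason):
            make_gwas(**kw)

    def test_z_is_finite(self):
        assert math.isfinite(make_gwas().z)
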