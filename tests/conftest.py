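"""Shared fixtures: small in-memory records and on-disk fixture files."""

import pytest

from smrkit.sumstats_io import GwasRecord, QtlRecord


def make_gwas(snp_id="rs1", ea="A", oa="G", beta=0.1, se=0.02, p=1e-6,
              **kw) -> GwasRecord:
    return GwasRecord(snp_id=snp_id, effect_allele=ea, other_allele=oa,
                      beta=beta, se=se, pvalue=p, **kw)


def make_qtl(snp_id="rs1", probe_id="PRB1", ea="A", oa="G", beta=0.2,
             se=0.02, p=1e-10, probe_chrom="1", probe_pos=1_000_000,
             snp_chrom="1", snp_pos=1_050_000, **kw) -> QtlRecord:
    return QtlRecord(snp_id=snp_id, probe_id=probe_id, probe_chrom=probe_chrom,
                     probe_pos=probe_pos, snp_chrom=snp_chrom, snp_pos=snp_pos,
                     effect_allele=ea, other_allele=oa, beta=beta, se=se,
                     pvalue=p, **kw)


@pytest.fixture
def gwas_file(tmp_path):
    """Well-formed 3-row GWAS file in the smrkit-gwas dialect."""
    p = tmp_path / "gwas.tsv"
    p.write_text(
        "snp\tchrom\tpos\teffect_allele\tother_allele\teaf\tbeta\tse\tpvalue\tn\n"
        "rs1\t1\t1000\tA\tG\t0.3\t0.10\t0.02\t5e-7\t10000\n"
        "rs2\t1\t2000\tC\tT\t0.2\t-0.05\t0.01\t6e-7\t10000\n"
        "rs3\t2\t3000\tG\tA\t0.4\t0.02\t0.02\t0.3\t10000\n"
    )
    return p


@pytest.fixture
def qtl_file(tmp_path):
    """2 probes x 5 SNPs in the smrkit-qtl dialect."""
    header = ("snp\tprobe\tgene\tprobe_chrom\tprobe_pos\tsnp_chrom\tsnp_pos\t"
              "effect_allele\tother_allele\teaf\tbeta\tse\tpvalue\tfdr\n")
    rows = []
    for probe, gene, ppos in (("PRB1", "GENEA", 1_000_000),
                              ("PRB2", "GENEB", 5_000_000)):
        for i in range(5):
            rows.append(f"rs{i + 1}\t{probe}\t{gene}\t1\t{ppos}\t1\t"
                        f"{ppos + 1000 * (i + 1)}\tA\tG\t0.3\t0.2\t0.02\t"
                        f"1e-{9 + i}\tNA\n")
    p = tmp_path / "qtl.tsv"
    p.write_text(header + "".join(rows))
    return p
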