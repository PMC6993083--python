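"""Reading and writing GWAS / QTL summary-statistic tables and result reports.

Input files are whitespace- or tab-delimited text with a header row; gzip
compression is handled transparently (by file extension).  Column layouts
differ between consortia, so every reader takes a :class:`Dialect` that maps
logical field names to file column names.  Named presets cover the layouts
this package reads and writes itself.

Rows that violate record invariants (non-positive SE, p outside (0, 1],
identical alleles, unparseable numbers) are skipped and counted, never
silently dropped: ``n_rows == len(records) + n_skipped`` always holds.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GwasRecord",
    "QtlRecord",
    "Dialect",
    "DIALECTS",
    "ParseResult",
    "DialectError",
    "EmptyInputError",
    "InvalidRecordError",
    "read_gwas",
    "read_qtl",
    "write_gwas",
    "write_qtl",
    "write_results",
    "read_results",
]


class DialectError(ValueError):
    """A required column is missing from the file or the dialect mapping."""


class EmptyInputError(ValueError):
    """The input file contains no data at all."""


class InvalidRecordError(ValueError):
    """A record violates a field invariant; carries the reason string."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------


def _check_common(effect_allele: str, other_allele: str, beta: float, se: float,
                  pvalue: float) -> None:
    if not effect_allele or not other_allele:
        raise InvalidRecordError("missing_allele")
    if effect_allele == other_allele:
        raise InvalidRecordError("identical_alleles")
    if not math.isfinite(se) or se <= 0:
        raise InvalidRecordError("nonpositive_se")
    if not math.isfinite(beta):
        raise InvalidRecordError("nonfinite_beta")
    if not (0.0 < pvalue <= 1.0):
        raise InvalidRecordError("pvalue_out_of_range")


@dataclass(frozen=True, slots=True)
class GwasRecord:
    """One SNP's association with the trait.

    ``beta`` is on the log-odds scale for case/control traits; odds-ratio
    columns are converted at read time.  Positions are 1-based.  ``chrom``
    and ``pos`` are optional because rsID-keyed files (e.g. MEGASTROKE-style
    outputs) do not carry them; all downstream matching is by rsID.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    chrom: Optional[str] = None
    pos: Optional[int] = None
    eaf: Optional[float] = None
    n: Optional[float] = None

    def __post_init__(self):
        _check_common(self.effect_allele, self.other_allele, self.beta,
                      self.se, self.pvalue)
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise InvalidRecordError("eaf_out_of_range")

    @property
    def z(self) -> float:
        return self.beta / self.se


@dataclass(frozen=True, slots=True)
class QtlRecord:
    """One SNP x probe molecular association (expression or methylation).

    The same type serves eQTL and mQTL rows; ``gene_symbol`` is typically
    absent for methylation probes and ``fdr`` is only present for sources
    that publish it.  A record whose SNP and probe sit on different
    chromosomes is retained but flagged ``trans``.
    """

    snp_id: str
    probe_id: str
    probe_chrom: str
    probe_pos: int
    snp_chrom: str
    snp_pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    gene_symbol: Optional[str] = None
    eaf: Optional[float] = None
    fdr: Optional[float] = None

    def __post_init__(self):
        _check_common(self.effect_allele, self.other_allele, self.beta,
                      self.se, self.pvalue)

    @property
    def z(self) -> float:
        return self.beta / self.se

    @property
    def trans(self) -> bool:
        return str(self.snp_chrom) != str(self.probe_chrom)

    @property
    def distance(self) -> int:
        """|snp_pos - probe_pos|; meaningful only for cis records."""
        return abs(int(self.snp_pos) - int(self.probe_pos))


# ---------------------------------------------------------------------------
# dialects
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Dialect:
    """Maps logical field names to column names of a concrete file layout.

    Exactly one of ``beta`` / ``odds_ratio`` must be set; odds ratios are
    converted to the log scale (natural log) at read time so downstream code
    sees a single effect scale.  QTL-only fields may be left ``None`` for
    GWAS layouts and vice versa.
    """

    snp: str
    effect_allele: str
    other_allele: str
    se: str
    pvalue: str
    beta: Optional[str] = None
    odds_ratio: Optional[str] = None
    chrom: Optional[str] = None
    pos: Optional[str] = None
    eaf: Optional[str] = None
    n: Optional[str] = None
    # QTL-only
    probe: Optional[str] = None
    gene: Optional[str] = None
    probe_chrom: Optional[str] = None
    probe_pos: Optional[str] = None
    snp_chrom: Optional[str] = None
    snp_pos: Optional[str] = None
    fdr: Optional[str] = None

    def __post_init__(self):
        if (self.beta is None) == (self.odds_ratio is None):
            raise DialectError("dialect needs exactly one of beta / odds_ratio")

    def required_gwas_columns(self) -> list[str]:
        eff = self.beta if self.beta is not None else self.odds_ratio
        return [self.snp, self.effect_allele, self.other_allele, eff,
                self.se, self.pvalue]

    def required_qtl_columns(self) -> list[str]:
        for name in ("probe", "probe_chrom", "probe_pos", "snp_chrom", "snp_pos"):
            if getattr(self, name) is None:
                raise DialectError(f"QTL dialect missing mapping for '{name}'")
        return self.required_gwas_columns() + [
            self.probe, self.probe_chrom, self.probe_pos,
            self.snp_chrom, self.snp_pos]


#: Named dialect presets.  "megastroke" follows the METAL-style layout of the
#: MEGASTROKE consortium downloads (rsID-keyed, no positions).  The "smrkit-*"
#: presets are this package's own fixture/output layout, so synthetic fixtures
#: exercise the same I/O path as real data.
DIALECTS: dict[str, Dialect] = {
    "megastroke": Dialect(
        snp="MarkerName", effect_allele="Allele1", other_allele="Allele2",
        eaf="Freq1", beta="Effect", se="StdErr", pvalue="P-value",
    ),
    "smrkit-gwas": Dialect(
        snp="snp", chrom="chrom", pos="pos",
        effect_allele="effect_allele", other_allele="other_allele",
        eaf="eaf", beta="beta", se="se", pvalue="pvalue", n="n",
    ),
    "smrkit-qtl": Dialect(
        snp="snp", probe="probe", gene="gene",
        probe_chrom="probe_chrom", probe_pos="probe_pos",
        snp_chrom="snp_chrom", snp_pos="snp_pos",
        effect_allele="effect_allele", other_allele="other_allele",
        eaf="eaf", beta="beta", se="se", pvalue="pvalue", fdr="fdr",
    ),
}


def resolve_dialect(dialect: "Dialect | str") -> Dialect:
    if isinstance(dialect, Dialect):
        return dialect
    try:
        return DIALECTS[dialect]
    except KeyError:
        raise DialectError(
            f"unknown dialect preset {dialect!r}; known: {sorted(DIALECTS)}"
        ) from None


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


@dataclass
class ParseResult:
    """Outcome of parsing one file: retained records plus a skip audit."""

    records: list = field(default_factory=list)
    n_rows: int = 0
    skip_reasons: Counter = field(default_factory=Counter)

    @property
    def n_skipped(self) -> int:
        return sum(self.skip_reasons.values())

    def __len__(self) -> int:
        return len(self.records)


def _load_frame(path, dialect: Dialect, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=r"\s+", dtype=str, engine="python",
                         compression="infer")
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"no data in {path}") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DialectError(
            f"missing required column(s) {missing} in {path}; "
            f"present: {list(df.columns)}")
    return df

def _get(row, col):
    if col is None:
        return None
    v = row[col]
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "NA":
        return None
    return v


def _fnum(row, col):
    v = _get(row, col)
    if v is None:
        return None
    try:
        return float(v)
    except (TypeError, ValueError):
        raise InvalidRecordError("unparseable_number")


def _effect_to_beta(row, dialect: Dialect) -> float:
    if dialect.beta is not None:
        b = _fnum(row, dialect.beta)
        if b is None:
            raise InvalidRecordError("missing_beta")
        return b
    orv = _fnum(row, dialect.odds_ratio)
    if orv is None:
        raise InvalidRecordError("missing_or")
    if orv <= 0:
        raise InvalidRecordError("nonpositive_or")
    return math.log(orv)


def read_gwas(path, dialect: "Dialect | str" = "smrkit-gwas") -> ParseResult:
    """Parse a GWAS summary-statistics file into :class:`GwasRecord` rows.

    Invalid rows are skipped and tallied by reason; duplicate rsIDs keep the
    first occurrence (tallied under ``"duplicate"``).  Odds-ratio columns are
    natural-log transformed to betas.
    """
    dialect = resolve_dialect(dialect)
    df = _load_frame(path, dialect, dialect.required_gwas_columns())
    out = ParseResult(n_rows=len(df))
    seen: set[str] = set()
    for row in df.to_dict("records"):
        try:
            snp = _get(row, dialect.snp)
            if not snp:
                raise InvalidRecordError("missing_snp_id")
            if snp in seen:
                raise InvalidRecordError("duplicate")
            pos = _fnum(row, dialect.pos)
            rec = GwasRecord(
                snp_id=str(snp),
                chrom=(None if _get(row, dialect.chrom) is None
                       else str(_get(row, dialect.chrom))),
                pos=None if pos is None else int(pos),
                effect_allele=str(_get(row, dialect.effect_allele) or "").upper(),
                other_allele=str(_get(row, dialect.other_allele) or "").upper(),
                beta=_effect_to_beta(row, dialect),
                se=_fnum(row, dialect.se) if _fnum(row, dialect.se) is not None
                   else float("nan"),
                pvalue=_fnum(row, dialect.pvalue)
                       if _fnum(row, dialect.pvalue) is not None else -1.0,
                eaf=_fnum(row, dialect.eaf),
                n=_fnum(row, dialect.n),
            )
        except InvalidRecordError as e:
            if e.reason == "duplicate":
                logger.warning("duplicate SNP %s in %s; keeping first", snp, path)
            out.skip_reasons[e.reason] += 1
            continue
        seen.add(rec.snp_id)
        out.records.append(rec)
    assert out.n_rows == len(out.records) + out.n_skipped
    return out


def read_qtl(path, dialect: "Dialect | str" = "smrkit-qtl") -> ParseResult:
    """Parse a per-SNP-per-probe QTL file into :class:`QtlRecord` rows.

    Duplicate ``(snp, probe)`` pairs keep the first occurrence.  Trans
    records (SNP and probe on different chromosomes) are retained; callers
    inspect ``QtlRecord.trans``.
    """
    dialect = resolve_dialect(dialect)
    df = _load_frame(path, dialect, dialect.required_qtl_columns())
    out = ParseResult(n_rows=len(df))
    seen: set[tuple[str, str]] = set()
    for row in df.to_dict("records"):
        try:
            snp = _get(row, dialect.snp)
            probe = _get(row, dialect.probe)
            if not snp or not probe:
                raise InvalidRecordError("missing_key")
            key = (str(snp), str(probe))
            if key in seen:
                raise InvalidRecordError("duplicate")
            ppos = _fnum(row, dialect.probe_pos)
            spos = _fnum(row, dialect.snp_pos)
            if ppos is None or spos is None:
                raise InvalidRecordError("missing_position")
            rec = QtlRecord(
                snp_id=str(snp),
                probe_id=str(probe),
                gene_symbol=(None if _get(row, dialect.gene) is None
                             else str(_get(row, dialect.gene))),
                probe_chrom=str(_get(row, dialect.probe_chrom)),
                probe_pos=int(ppos),
                snp_chrom=str(_get(row, dialect.snp_chrom)),
                snp_pos=int(spos),
                effect_allele=str(_get(row, dialect.effect_allele) or "").upper(),
                other_allele=str(_get(row, dialect.other_allele) or "").upper(),
                beta=_effect_to_beta(row, dialect),
                se=_fnum(row, dialect.se) if _fnum(row, dialect.se) is not None
                   else float("nan"),
                pvalue=_fnum(row, dialect.pvalue)
                       if _fnum(row, dialect.pvalue) is not None else -1.0,
                eaf=_fnum(row, dialect.eaf),
                fdr=_fnum(row, dialect.fdr),
            )
        except InvalidRecordError as e:
            if e.reason == "duplicate":
                logger.warning("duplicate (snp, probe) %s in %s; keeping first",
                               key, path)
            out.skip_reasons[e.reason] += 1
            continue
        seen.add(key)
        out.records.append(rec)
    assert out.n_rows == len(out.records) + out.n_skipped
    return out


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

_G = "%.10g"


def _fmt(v, spec=_G) -> str:
    return "NA" if v is None else (spec % v if isinstance(v, float) else str(v))


def write_gwas(records: Iterable[GwasRecord], path) -> None:
    """Write GWAS records in the ``smrkit-gwas`` dialect (tab-delimited)."""
    cols = ["snp", "chrom", "pos", "effect_allele", "other_allele",
            "eaf", "beta", "se", "pvalue", "n"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in records:
            fh.write("\t".join([
                r.snp_id, _fmt(r.chrom), _fmt(r.pos),
                r.effect_allele, r.other_allele, _fmt(r.eaf),
                _fmt(r.beta), _fmt(r.se), _fmt(r.pvalue), _fmt(r.n),
            ]) + "\n")


def write_qtl(records: Iterable[QtlRecord], path) -> None:
    """Write QTL records in the ``smrkit-qtl`` dialect (tab-delimited)."""
    cols = ["snp", "probe", "gene", "probe_chrom", "probe_pos",
            "snp_chrom", "snp_pos", "effect_allele", "other_allele",
            "eaf", "beta", "se", "pvalue", "fdr"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in records:
            fh.write("\t".join([
                r.snp_id, r.probe_id, _fmt(r.gene_symbol),
                str(r.probe_chrom), str(r.probe_pos),
                str(r.snp_chrom), str(r.snp_pos),
                r.effect_allele, r.other_allele, _fmt(r.eaf),
                _fmt(r.beta), _fmt(r.se), _fmt(r.pvalue), _fmt(r.fdr),
            ]) + "\n")


RESULT_COLUMNS = ["SNP", "P-value", "Gene", "b_xy", "se_xy", "T_SMR",
                  "probe_id", "n_cis_snps"]


def write_results(results, path) -> None:
    """Write per-probe test outcomes as a TSV report, ascending p.

    Column shape mirrors a SNP / P-value / Gene table, extended with the
    estimate, its SE, the test statistic, the probe id and the candidate
    count.  P-values use scientific notation with 3+ significant digits.
    """
    rows = sorted(results, key=lambda r: (r.p_smr, r.probe_id))
    with open(path, "w") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in rows:
            gene = r.gene_symbol if r.gene_symbol else r.probe_id
            fh.write("\t".join([
                r.top_snp, "%.3e" % r.p_smr, gene,
                "%.6g" % r.b_xy,
                "NA" if r.se_xy is None else "%.6g" % r.se_xy,
                "%.6g" % r.T_smr, r.probe_id, str(r.n_cis_snps),
            ]) + "\n")


def read_results(path) -> list:
    """Read back a report written by :func:`write_results`."""
    from .smr_core import SmrResult  # local import: avoid cycle

    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise DialectError(f"result file missing column(s) {missing}")
    out = []
    for row in df.to_dict("records"):
        out.append(SmrResult(
            probe_id=row["probe_id"],
            gene_symbol=None if row["Gene"] == row["probe_id"] else row["Gene"],
            top_snp=row["SNP"],
            b_xy=float(row["b_xy"]),
            se_xy=None if row["se_xy"] == "NA" else float(row["se_xy"]),
            T_smr=float(row["T_SMR"]),
            p_smr=float(row["P-value"]),
            n_cis_snps=int(row["n_cis_snps"]),
        ))
    return out
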