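"""Allele harmonization of GWAS and QTL summary statistics.

Two summary-statistic sets report effects relative to whichever allele each
study chose as the "effect" allele.  Before the trait and molecular z-scores
can be paired per SNP they must refer to the same allele: if the QTL record's
alleles are swapped relative to the GWAS record, its beta is negated.
Strand-ambiguous variants (A/T, C/G) cannot be oriented from alleles alone
and are dropped by default, with an optional frequency-based rescue.
Matching is keyed on rsID throughout.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional

from .sumstats_io import GwasRecord, QtlRecord

logger = logging.getLogger(__name__)

__all__ = [
    "HarmonizedTriple",
    "HarmonizationError",
    "AmbiguityPolicy",
    "align_alleles",
    "intersect",
]

_VALID_ALLELES = frozenset("ACGT")
_AMBIGUOUS_PAIRS = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})


class HarmonizationError(ValueError):
    """A (GWAS, QTL) pair cannot be aligned; ``reason`` is a tally key."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass(frozen=True)
class AmbiguityPolicy:
    """How to treat strand-ambiguous (A/T, C/G) variants.

    Default: drop.  With ``rescue_by_frequency`` a pair is kept when both
    sides report an allele frequency clearly away from 0.5
    (``|eaf - 0.5| > min_maf_distance``) and the frequencies are concordant
    under the chosen orientation; otherwise it is still rejected.
    """

    rescue_by_frequency: bool = False
    min_maf_distance: float = 0.08
    max_freq_diff: float = 0.2


@dataclass(frozen=True)
class HarmonizedTriple:
    """An allele-aligned (SNP, trait, molecular) pair.

    ``b_zx``/``se_zx`` are expressed on the GWAS record's effect allele; when
    the source QTL record was coded on the opposite allele, ``flipped`` is
    true and ``b_zx`` is the negation of the source beta.  Probe metadata
    (position, gene, QTL p-value) is carried along for downstream cis
    instrument selection.
    """

    snp_id: str
    probe_id: str
    b_zy: float
    se_zy: float
    b_zx: float
    se_zx: float
    flipped: bool
    ambiguous: bool
    p_zx: float
    snp_pos: Optional[int] = None
    snp_chrom: Optional[str] = None
    probe_pos: Optional[int] = None
    probe_chrom: Optional[str] = None
    gene_symbol: Optional[str] = None

    @property
    def z_zy(self) -> float:
        return self.b_zy / self.se_zy

    @property
    def z_zx(self) -> float:
        return self.b_zx / self.se_zx


def _is_snv(a: str) -> bool:
    return len(a) == 1 and a in _VALID_ALLELES


def align_alleles(g: GwasRecord, q: QtlRecord,
                  policy: AmbiguityPolicy = AmbiguityPolicy(),
                  ) -> HarmonizedTriple:
    """Align one QTL record onto the GWAS record's effect allele.

    Returns a :class:`HarmonizedTriple`, or raises
    :class:`HarmonizationError` with a rejection reason
    (``indel``, ``strand_ambiguous``, ``ambiguous_frequency``,
    ``allele_mismatch``).  A ``snp_id`` mismatch is a programming error
    (``ValueError``), not a data rejection.
    """
    if g.snp_id != q.snp_id:
        raise ValueError(
            f"align_alleles called with mismatched SNPs {g.snp_id!r} != {q.snp_id!r}")

    ga, go = g.effect_allele, g.other_allele
    qa, qo = q.effect_allele, q.other_allele
    if not all(_is_snv(a) for a in (ga, go, qa, qo)):
        raise HarmonizationError("indel")

    ambiguous = (ga, go) in _AMBIGUOUS_PAIRS
    if (ga, go) == (qa, qo):
        flipped = False
    elif (ga, go) == (qo, qa):
        flipped = True
    else:
        raise HarmonizationError("allele_mismatch")

    if ambiguous:
        if not policy.rescue_by_frequency:
            raise HarmonizationError("strand_ambiguous")
        _check_frequency_rescue(g, q, flipped, policy)

    b_zx = -q.beta if flipped else q.beta
    return HarmonizedTriple(
        snp_id=g.snp_id,
        probe_id=q.probe_id,
        b_zy=g.beta, se_zy=g.se,
        b_zx=b_zx, se_zx=q.se,
        flipped=flipped, ambiguous=ambiguous,
        p_zx=q.pvalue,
        snp_pos=q.snp_pos, snp_chrom=q.snp_chrom,
        probe_pos=q.probe_pos, probe_chrom=q.probe_chrom,
        gene_symbol=q.gene_symbol,
    )


def _check_frequency_rescue(g: GwasRecord, q: QtlRecord, flipped: bool,
                            policy: AmbiguityPolicy) -> None:
    if g.eaf is None or q.eaf is None:
        raise HarmonizationError("ambiguous_frequency")
    if (abs(g.eaf - 0.5) <= policy.min_maf_distance
            or abs(q.eaf - 0.5) <= policy.min_maf_distance):
        raise HarmonizationError("ambiguous_frequency")
    q_eaf_aligned = 1.0 - q.eaf if flipped else q.eaf
    if abs(g.eaf - q_eaf_aligned) > policy.max_freq_diff:
        raise HarmonizationError("ambiguous_frequency")


def intersect(gwas: Iterable[GwasRecord], qtl: Iterable[QtlRecord],
              policy: AmbiguityPolicy = AmbiguityPolicy(),
              ) -> tuple[list[HarmonizedTriple], Counter]:
    """Pair every QTL record whose SNP appears in the GWAS set.

    Returns the surviving triples plus a tally: rejection reasons, the
    number of sign flips (``flipped``) and QTL rows with no GWAS partner
    (``no_gwas_match``).  An empty intersection is valid but warned.
    """
    by_snp: dict[str, GwasRecord] = {}
    for g in gwas:
        by_snp.setdefault(g.snp_id, g)

    triples: list[HarmonizedTriple] = []
    tally: Counter = Counter()
    for q in qtl:
        g = by_snp.get(q.snp_id)
        if g is None:
            tally["no_gwas_match"] += 1
            continue
        try:
            t = align_alleles(g, q, policy)
        except HarmonizationError as e:
            tally[e.reason] += 1
            continue
        if t.flipped:
            tally["flipped"] += 1
        triples.append(t)
    if not triples:
        logger.warning("empty harmonized intersection (tally: %s)", dict(tally))
    return triples, tally
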