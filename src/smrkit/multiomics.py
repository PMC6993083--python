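"""Integration stages downstream of single-dataset testing.

Covers three things: intersecting significant gene sets between analyses
(e.g. two cohorts of the same trait), de-duplicating significant SNPs across
analyses with provenance (one SNP can reach significance through several
probes/genes), and cross-referencing those SNPs against methylation-QTL
evidence.  The cross-reference runs in two modes because "significant in the
mQTL data" is ambiguous: ``"smr"`` re-uses the full test machinery with the
methylation probe as the molecular phenotype, while ``"lookup"`` checks the
nominal mQTL association p-value directly.

Per-source mQTL eligibility filters (window and p/FDR cutoffs differ between
published brain mQTL sources) are provided as record-level pre-filters to be
applied right after reading.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .smr_core import SmrResult, resolve_alpha
from .sumstats_io import QtlRecord

logger = logging.getLogger(__name__)

__all__ = [
    "CrossRefResult",
    "SnpProvenance",
    "MqtlSourceFilter",
    "MQTL_SOURCE_FILTERS",
    "filter_mqtl_records",
    "overlap_genes",
    "unique_snps",
    "cross_reference_mqtl",
]


# ---------------------------------------------------------------------------
# per-source mQTL eligibility filters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MqtlSourceFilter:
    """Record-level eligibility rule for one mQTL source.

    ``window_bp`` bounds |snp_pos - probe_pos|; ``p_max`` and ``fdr_max``
    (either may be None) bound the nominal association.  FDR values are
    treated as an input column, never recomputed.
    """

    name: str
    window_bp: int
    p_max: Optional[float] = None
    fdr_max: Optional[float] = None

    def admits(self, rec: QtlRecord) -> bool:
        if rec.distance > self.window_bp:
            return False
        if self.p_max is not None and not rec.pvalue < self.p_max:
            return False
        if self.fdr_max is not None:
            if rec.fdr is None or not rec.fdr < self.fdr_max:
                return False
        return True


MQTL_SOURCE_FILTERS: dict[str, MqtlSourceFilter] = {
    "rosmap-like": MqtlSourceFilter("rosmap-like", window_bp=5_000),
    "hannon-like": MqtlSourceFilter("hannon-like", window_bp=500_000,
                                    p_max=1.0e-10),
    "jaffe-like": MqtlSourceFilter("jaffe-like", window_bp=20_000,
                                   fdr_max=0.1),
}


def filter_mqtl_records(records: Iterable[QtlRecord],
                        source: "MqtlSourceFilter | str",
                        ) -> list[QtlRecord]:
    """Keep only records admitted by the source's eligibility rule."""
    if isinstance(source, str):
        source = MQTL_SOURCE_FILTERS[source]
    return [r for r in records if source.admits(r)]


# ---------------------------------------------------------------------------
# gene overlap and SNP de-duplication
# ---------------------------------------------------------------------------


def overlap_genes(results_a: Iterable[SmrResult],
                  results_b: Iterable[SmrResult]) -> set[str]:
    """Intersection of gene symbols between two significant result sets.

    Case-normalized (upper); probes without a gene symbol are ignored.
    Commutative and idempotent.
    """
    def genes(results):
        return {r.gene_symbol.upper() for r in results if r.gene_symbol}

    return genes(results_a) & genes(results_b)


@dataclass(frozen=True)
class SnpProvenance:
    """One way a SNP reached significance: which analysis, probe, gene."""

    analysis: str
    probe_id: str
    gene_symbol: Optional[str]
    p_smr: float


def unique_snps(all_significant: Mapping[str, Iterable[SmrResult]],
                ) -> dict[str, list[SnpProvenance]]:
    """De-duplicate significant instrument SNPs across analyses.

    Input maps an analysis label to its thresholded results.  Output maps
    each rsID (counted once, however many probes or analyses it appears in)
    to the list of provenance entries that contributed it.  Iteration order
    is sorted rsID for determinism.
    """
    out: dict[str, list[SnpProvenance]] = {}
    for label in sorted(all_significant):
        for r in all_significant[label]:
            out.setdefault(r.top_snp, []).append(
                SnpProvenance(label, r.probe_id, r.gene_symbol, r.p_smr))
    return dict(sorted(out.items()))


# ---------------------------------------------------------------------------
# mQTL cross-reference
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CrossRefResult:
    """Methylation evidence for one query SNP."""

    snp_id: str
    probes: tuple  # of (probe_id, p) pairs, ascending p

    @property
    def n_methylation_probes(self) -> int:
        return len(self.probes)

    @property
    def best_mqtl_p(self) -> Optional[float]:
        return min((p for _, p in self.probes), default=None)


def cross_reference_mqtl(snps: Iterable[str],
                         mqtl_results: "Sequence[SmrResult] | Sequence[QtlRecord]",
                         alpha_policy: str = "bonferroni",
                         mode: str = "smr",
                         ) -> tuple[list[CrossRefResult], tuple[int, int]]:
    """Check which query SNPs show significant methylation-QTL evidence.

    mode "smr":    ``mqtl_results`` are per-probe test results from running
                   the engine on methylation data; a query SNP scores a hit
                   for every significant probe it instruments.
    mode "lookup": ``mqtl_results`` are raw mQTL records; a hit is a nominal
                   association below the resolved cutoff.

    Every query SNP appears in the output, hit or not.  Returns the
    per-SNP results plus the summary ``(n_query, n_with_any_hit)``.
    """
    snps = sorted(set(snps))
    if mode == "smr":
        alpha = resolve_alpha(alpha_policy, len(mqtl_results))
        hits: dict[str, list[tuple[str, float]]] = {}
        for r in mqtl_results:
            if r.p_smr < alpha:
                hits.setdefault(r.top_snp, []).append((r.probe_id, r.p_smr))
    elif mode == "lookup":
        alpha = resolve_alpha(alpha_policy, len(mqtl_results))
        hits = {}
        for rec in mqtl_results:
            if rec.pvalue < alpha:
                hits.setdefault(rec.snp_id, []).append(
                    (rec.probe_id, rec.pvalue))
    else:
        raise ValueError(f"unknown cross-reference mode {mode!r}")

    out = []
    for snp in snps:
        probes = tuple(sorted(hits.get(snp, []), key=lambda x: (x[1], x[0])))
        out.append(CrossRefResult(snp_id=snp, probes=probes))
    n_query = len(out)
    n_hit = sum(1 for c in out if c.n_methylation_probes > 0)
    logger.info("%d of %d query SNPs significant in mQTL", n_hit, n_query)
    return out, (n_query, n_hit)


def write_crossref(results: Sequence[CrossRefResult], summary, path) -> None:
    """TSV report of the cross-reference, one row per query SNP."""
    with open(path, "w") as fh:
        fh.write("SNP\tn_methylation_probes\tbest_mqtl_p\tprobes\n")
        for c in results:
            best = "NA" if c.best_mqtl_p is None else "%.3e" % c.best_mqtl_p
            plist = ",".join("%s:%.3e" % pq for pq in c.probes)
            fh.write(f"{c.snp_id}\t{c.n_methylation_probes}\t{best}\t{plist}\n")
        fh.write(f"# {summary[1]} of {summary[0]} query SNPs significant in mQTL\n")
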