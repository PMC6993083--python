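"""Per-probe Mendelian-randomization test from paired summary statistics.

For each molecular probe the top cis SNP (smallest QTL p-value within a
window around the probe, below an instrument-strength threshold) serves as
the instrument.  The effect of the molecular phenotype on the trait is the
Wald ratio of the two per-allele effects, and the test statistic is the
harmonic combination of the two squared z-scores,

    T = z_zy^2 * z_zx^2 / (z_zy^2 + z_zx^2),

referred to a chi-square distribution with one degree of freedom.  ``T`` is
symmetric in its arguments and bounded by ``min(z_zy^2, z_zx^2)``.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from scipy.stats import chi2

from .harmonize import AmbiguityPolicy, HarmonizedTriple, intersect
from .sumstats_io import GwasRecord, QtlRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SmrConfig",
    "SmrResult",
    "select_instrument",
    "estimate_bxy",
    "smr_statistic",
    "smr_pvalue",
    "delta_se_bxy",
    "run_smr",
    "resolve_alpha",
    "apply_threshold",
]

#: Default instrument threshold: genome-wide significance.
DEFAULT_P_QTL_MAX = 5e-8
#: Default cis window half-width around a probe, in base pairs.
DEFAULT_WINDOW_BP = 1_000_000


@dataclass(frozen=True)
class SmrConfig:
    window_bp: int = DEFAULT_WINDOW_BP
    p_qtl_max: float = DEFAULT_P_QTL_MAX
    alpha_policy: str = "bonferroni"
    ambiguity: AmbiguityPolicy = field(default_factory=AmbiguityPolicy)


@dataclass(frozen=True)
class SmrResult:
    """Outcome of the test for one probe."""

    probe_id: str
    gene_symbol: Optional[str]
    top_snp: str
    b_xy: float
    se_xy: Optional[float]
    T_smr: float
    p_smr: float
    n_cis_snps: int


def select_instrument(triples_for_probe: Sequence[HarmonizedTriple],
                      probe_pos: int,
                      window_bp: int = DEFAULT_WINDOW_BP,
                      p_qtl_max: float = DEFAULT_P_QTL_MAX,
                      ) -> Optional[HarmonizedTriple]:
    """Pick the instrument SNP for one probe, or ``None``.

    Candidates must lie within ``window_bp`` of the probe position and have
    QTL p <= ``p_qtl_max``.  Among candidates the smallest QTL p wins; ties
    break by larger |z_zx|, then lexicographically smaller rsID, so selection
    is fully deterministic.
    """
    probes = {t.probe_id for t in triples_for_probe}
    if len(probes) > 1:
        raise ValueError(f"triples span multiple probes: {sorted(probes)}")
    candidates = [
        t for t in triples_for_probe
        if t.snp_pos is not None
        and abs(int(t.snp_pos) - int(probe_pos)) <= window_bp
        and t.p_zx <= p_qtl_max
    ]
    if not candidates:
        return None
    return min(candidates, key=lambda t: (t.p_zx, -abs(t.z_zx), t.snp_id))


def estimate_bxy(b_zy: float, b_zx: float) -> float:
    """Wald-ratio estimate of the molecular-phenotype-on-trait effect."""
    if b_zx == 0:
        raise ZeroDivisionError("undefined instrument: b_zx == 0")
    return b_zy / b_zx


def smr_statistic(z_zy: float, z_zx: float) -> float:
    """Combined chi-square(1) statistic from the two z-scores.

    Returns 0 when either z is 0; raises on the degenerate all-zero input.
    """
    a2 = z_zy * z_zy
    b2 = z_zx * z_zx
    if a2 == 0.0 and b2 == 0.0:
        raise ValueError("degenerate input: both z-scores are zero")
    if a2 == 0.0 or b2 == 0.0:
        return 0.0
    # harmonic form avoids overflow for large |z|
    return 1.0 / (1.0 / a2 + 1.0 / b2)


def smr_pvalue(T_smr: float) -> float:
    """Upper-tail chi-square(1) probability at ``T_smr``."""
    if T_smr < 0:
        raise ValueError(f"negative test statistic: {T_smr}")
    return float(chi2.sf(T_smr, df=1))


def delta_se_bxy(b_zy: float, se_zy: float, b_zx: float, se_zx: float) -> float:
    """First-order delta-method standard error of the Wald ratio.

    |b_zy/b_zx| * sqrt((se_zy/b_zy)^2 + (se_zx/b_zx)^2), with the b_zy = 0
    limit handled as se_zy/|b_zx|.
    """
    if b_zx == 0:
        raise ZeroDivisionError("undefined instrument: b_zx == 0")
    if b_zy == 0:
        return se_zy / abs(b_zx)
    bxy = b_zy / b_zx
    return abs(bxy) * math.sqrt((se_zy / b_zy) ** 2 + (se_zx / b_zx) ** 2)


def _test_triple(t: HarmonizedTriple, n_cis: int) -> SmrResult:
    T = smr_statistic(t.z_zy, t.z_zx)
    return SmrResult(
        probe_id=t.probe_id,
        gene_symbol=t.gene_symbol,
        top_snp=t.snp_id,
        b_xy=estimate_bxy(t.b_zy, t.b_zx),
        se_xy=delta_se_bxy(t.b_zy, t.se_zy, t.b_zx, t.se_zx),
        T_smr=T,
        p_smr=smr_pvalue(T),
        n_cis_snps=n_cis,
    )


def run_smr(gwas: Iterable[GwasRecord], qtl: Iterable[QtlRecord],
            config: SmrConfig = SmrConfig(),
            ) -> tuple[list[SmrResult], Counter]:
    """Full single-dataset analysis: harmonize, pick instruments, test.

    Returns one result per probe with a surviving instrument, ordered by
    ascending p then probe id, plus the harmonization tally.  Deterministic
    given inputs and config; all probes without an eligible instrument are
    counted under ``no_instrument`` in the tally.
    """
    triples, tally = intersect(gwas, qtl, config.ambiguity)
    by_probe: dict[str, list[HarmonizedTriple]] = {}
    for t in triples:
        by_probe.setdefault(t.probe_id, []).append(t)

    results: list[SmrResult] = []
    for probe_id in sorted(by_probe):
        group = by_probe[probe_id]
        best = select_instrument(group, probe_pos=group[0].probe_pos,
                                 window_bp=config.window_bp,
                                 p_qtl_max=config.p_qtl_max)
        if best is None:
            tally["no_instrument"] += 1
            continue
        results.append(_test_triple(best, n_cis=len(group)))
    if not results:
        logger.warning("no probe yielded a testable instrument")
    results.sort(key=lambda r: (r.p_smr, r.probe_id))
    return results, tally


def resolve_alpha(alpha_policy: str, n_tests: int) -> float:
    """Turn a policy string into a numeric cutoff.

    ``"bonferroni"`` -> 0.05 / n_tests; ``"fixed:x"`` -> x.
    """
    if alpha_policy == "bonferroni":
        if n_tests <= 0:
            return 0.05
        return 0.05 / n_tests
    if alpha_policy.startswith("fixed:"):
        return float(alpha_policy.split(":", 1)[1])
    raise ValueError(f"unknown alpha policy {alpha_policy!r}")


def apply_threshold(results: Sequence[SmrResult],
                    alpha_policy: str = "bonferroni") -> list[SmrResult]:
    """Subset of results significant under the resolved cutoff."""
    if not results:
        return []
    alpha = resolve_alpha(alpha_policy, len(results))
    return [r for r in results if r.p_smr < alpha]
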