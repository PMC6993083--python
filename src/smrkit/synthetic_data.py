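"""Linked synthetic GWAS + eQTL + mQTL summary statistics with known truth.

Summary statistics are simulated directly at the summary level: each
observed per-allele effect is drawn normally around its true value with the
analytic standard error ``1/sqrt(2 n maf (1-maf))`` implied by the sample
size and allele frequency, and the p-value is the two-sided normal tail of
the resulting z-score.  This matches the two-sample summary-data setting the
analysis operates in and is orders of magnitude faster than simulating
individual-level genotypes.  SNPs are independent (no LD), since the
analysis uses single top-SNP instruments.

Three trait architectures are supported per probe region: ``null`` (no SNP
affects the trait), ``causal`` (every SNP's trait effect is the product of
its molecular effect and a shared causal effect), and
``independent_pleiotropy`` (the instrument SNP affects the trait directly,
with an effect drawn independently of its molecular effect).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from .sumstats_io import GwasRecord, QtlRecord

__all__ = [
    "SimConfig",
    "SnpTruth",
    "ProbeTruth",
    "SimTruth",
    "MQTL_WINDOW_PRESETS",
    "simulate_qtl_stats",
    "simulate_gwas_stats",
    "simulate_mqtl_stats",
]

SCENARIOS = ("null", "causal", "independent_pleiotropy")

# unordered non-complementary allele pairs; complementary (A/T, C/G) pairs
# are strand-ambiguous and only injected on request
_SAFE_PAIRS = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G")]
_AMBIGUOUS_PAIRS = [("A", "T"), ("C", "G")]

#: Methylation-source window presets: half-width of the probe region, plus
#: the record-level eligibility rule the source applies to what it releases.
MQTL_WINDOW_PRESETS: dict[str, dict] = {
    "rosmap-like": {"window_bp": 5_000},
    "hannon-like": {"window_bp": 500_000, "p_max": 1.0e-10},
    "jaffe-like": {"window_bp": 20_000, "fdr_max": 0.1},
}

_MIN_P = 5e-324  # smallest subnormal float; keeps p in (0, 1]


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for one synthetic dataset."""

    n_snps: int = 20
    n_probes: int = 10
    maf_range: tuple[float, float] = (0.1, 0.45)
    n_gwas: int = 50_000
    n_qtl: int = 2_000
    true_b_zx: float = 0.5
    true_b_xy: float = 0.3
    scenario: str = "causal"
    seed: int = 0
    probe_window_bp: int = 1_000_000
    b_zx_jitter: float = 0.0
    ambiguous_fraction: float = 0.0
    swap_fraction: float = 0.0

    def __post_init__(self):
        if self.n_probes < 1 or self.n_snps < 1:
            raise ValueError("n_probes and n_snps must be >= 1")
        if self.n_gwas < 10 or self.n_qtl < 10:
            raise ValueError("sample sizes must be >= 10")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 0.5):
            raise ValueError("maf_range must lie within (0, 0.5)")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if not (0.0 <= self.b_zx_jitter < 1.0):
            raise ValueError("b_zx_jitter must be in [0, 1)")
        if not (0.0 <= self.ambiguous_fraction <= 1.0
                and 0.0 <= self.swap_fraction <= 1.0):
            raise ValueError("fractions must be in [0, 1]")


@dataclass(frozen=True)
class SnpTruth:
    snp_id: str
    chrom: str
    pos: int
    maf: float
    effect_allele: str
    other_allele: str
    true_b_zx: float


@dataclass(frozen=True)
class ProbeTruth:
    probe_id: str
    gene_symbol: Optional[str]
    chrom: str
    pos: int
    instrument_snp: str
    true_b_xy: float
    snps: tuple  # of SnpTruth


@dataclass(frozen=True)
class SimTruth:
    scenario: str
    probes: tuple  # of ProbeTruth

    def panel(self) -> list[SnpTruth]:
        return [s for p in self.probes for s in p.snps]


def _se(n: float, maf: float) -> float:
    return 1.0 / math.sqrt(2.0 * n * maf * (1.0 - maf))


def _two_sided_p(z: float) -> float:
    return max(2.0 * float(norm.sf(abs(z))), _MIN_P)


def _draw_alleles(rng: np.random.Generator, ambiguous_fraction: float):
    pool = _AMBIGUOUS_PAIRS if rng.random() < ambiguous_fraction else _SAFE_PAIRS
    a, b = pool[rng.integers(len(pool))]
    return (a, b) if rng.random() < 0.5 else (b, a)


def _build_panel(cfg: SimConfig, rng: np.random.Generator, probe_index: int,
                 probe_id: str, gene: Optional[str], window_bp: int,
                 instrument: Optional[SnpTruth] = None,
                 instrument_b_zx: Optional[float] = None,
                 id_base: int = 0) -> ProbeTruth:
    """Lay out one probe region: positions, frequencies, alleles, truth."""
    chrom = str(probe_index % 22 + 1)
    pos = 2_000_000 + (probe_index // 22) * (2 * cfg.probe_window_bp + 3_000_000)
    lo, hi = cfg.maf_range
    instr_idx = int(rng.integers(cfg.n_snps))
    # per-region variation of the instrument effect (keeps its sign)
    instr_effect = cfg.true_b_zx * (
        1.0 + cfg.b_zx_jitter * float(rng.uniform(-1.0, 1.0)))
    snps = []
    for j in range(cfg.n_snps):
        offset = int(rng.integers(-window_bp, window_bp + 1))
        if j == instr_idx and instrument is not None:
            b_zx = instr_effect if instrument_b_zx is None else instrument_b_zx
            snps.append(replace(instrument, chrom=chrom, pos=pos + offset,
                                true_b_zx=b_zx))
            continue
        ea, oa = _draw_alleles(rng, cfg.ambiguous_fraction)
        b_zx = instr_effect if j == instr_idx else 0.0
        if j == instr_idx and instrument_b_zx is not None:
            b_zx = instrument_b_zx
        snps.append(SnpTruth(
            snp_id=f"rs{id_base + probe_index * 10_000 + j + 1}",
            chrom=chrom, pos=pos + offset,
            maf=float(rng.uniform(lo, hi)),
            effect_allele=ea, other_allele=oa,
            true_b_zx=b_zx,
        ))
    return ProbeTruth(
        probe_id=probe_id, gene_symbol=gene, chrom=chrom, pos=pos,
        instrument_snp=snps[instr_idx].snp_id,
        true_b_xy=(cfg.true_b_xy if cfg.scenario == "causal" else 0.0),
        snps=tuple(snps),
    )


def _observe_qtl(truth: SimTruth, cfg: SimConfig,
                 rng: np.random.Generator) -> list[QtlRecord]:
    records = []
    for probe in truth.probes:
        for s in probe.snps:
            se = _se(cfg.n_qtl, s.maf)
            beta = s.true_b_zx + se * rng.standard_normal()
            swap = rng.random() < cfg.swap_fraction
            records.append(QtlRecord(
                snp_id=s.snp_id, probe_id=probe.probe_id,
                gene_symbol=probe.gene_symbol,
                probe_chrom=probe.chrom, probe_pos=probe.pos,
                snp_chrom=s.chrom, snp_pos=s.pos,
                effect_allele=s.other_allele if swap else s.effect_allele,
                other_allele=s.effect_allele if swap else s.other_allele,
                beta=-beta if swap else beta,
                se=se,
                pvalue=_two_sided_p(beta / se),
                eaf=(1.0 - s.maf) if swap else s.maf,
            ))
    return records


def simulate_qtl_stats(config: SimConfig) -> tuple[list[QtlRecord], SimTruth]:
    """Generate expression-QTL records plus their generative truth.

    Per probe, one SNP carries the molecular effect ``true_b_zx`` and the
    rest are null.  Reproducible given ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, 1])
    probes = tuple(
        _build_panel(config, rng, i, probe_id=f"PRB{i + 1:05d}",
                     gene=f"GENE{i + 1}", window_bp=config.probe_window_bp)
        for i in range(config.n_probes)
    )
    truth = SimTruth(scenario=config.scenario, probes=probes)
    rng_obs = np.random.default_rng([config.seed, 2])
    return _observe_qtl(truth, config, rng_obs), truth


def simulate_gwas_stats(config: SimConfig, truth: SimTruth,
                        cohort: int = 0) -> list[GwasRecord]:
    """Generate trait summary statistics on the truth's SNP panel.

    True trait effects follow the configured scenario; observation noise is
    independent of the QTL draw (two-sample design) and of other cohorts.
    """
    if truth.scenario != config.scenario:
        raise ValueError(
            f"truth scenario {truth.scenario!r} != config {config.scenario!r}")
    rng = np.random.default_rng([config.seed, 100 + cohort])
    records = []
    seen: set[str] = set()
    for probe in truth.probes:
        for s in probe.snps:
            if s.snp_id in seen:  # shared instrument across probes
                continue
            seen.add(s.snp_id)
            if config.scenario == "causal":
                b_zy_true = config.true_b_xy * s.true_b_zx
            elif config.scenario == "independent_pleiotropy":
                direct = rng.normal(0.0, abs(config.true_b_xy) or 0.1)
                b_zy_true = direct if s.snp_id == probe.instrument_snp else 0.0
            else:  # null
                b_zy_true = 0.0
            se = _se(config.n_gwas, s.maf)
            beta = b_zy_true + se * rng.standard_normal()
            records.append(GwasRecord(
                snp_id=s.snp_id, chrom=s.chrom, pos=s.pos,
                effect_allele=s.effect_allele, other_allele=s.other_allele,
                beta=beta, se=se, pvalue=_two_sided_p(beta / se),
                eaf=s.maf, n=float(config.n_gwas),
            ))
    return records


def _bh_fdr(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg q-values (monotone step-up)."""
    m = len(pvalues)
    order = np.argsort(pvalues)
    q = np.empty(m)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        prev = min(prev, pvalues[idx] * m / rank)
        q[idx] = prev
    return q.tolist()


def simulate_mqtl_stats(config: SimConfig, preset: str = "rosmap-like",
                        linked: Optional[Sequence[tuple[SnpTruth, bool]]] = None,
                        ) -> tuple[list[QtlRecord], SimTruth]:
    """Generate methylation-QTL records under a per-source window preset.

    The preset fixes the probe-region half-width and applies that source's
    release rule to the emitted records (p-value cutoff for the
    ``hannon-like`` source, FDR cutoff for the ``jaffe-like`` source, where
    the FDR column is a Benjamini-Hochberg transform of the generated
    p-values).

    ``linked`` plants probes tied to an existing SNP panel: each
    ``(snp, has_effect)`` entry becomes one methylation probe whose
    instrument is that SNP — carrying ``true_b_zx`` if ``has_effect``, else
    null.  This is how cross-dataset fixtures share instruments with the
    expression panel.
    """
    spec = MQTL_WINDOW_PRESETS[preset]
    window = spec["window_bp"]
    rng = np.random.default_rng([config.seed, 3])
    probes = []
    n_probes = len(linked) if linked is not None else config.n_probes
    for i in range(n_probes):
        instrument = instrument_b_zx = None
        if linked is not None:
            instrument, has_effect = linked[i]
            instrument_b_zx = config.true_b_zx if has_effect else 0.0
        probes.append(_build_panel(
            config, rng, i, probe_id=f"cg{i + 1:07d}", gene=None,
            window_bp=window, instrument=instrument,
            instrument_b_zx=instrument_b_zx, id_base=5_000_000))
    truth = SimTruth(scenario=config.scenario, probes=tuple(probes))
    rng_obs = np.random.default_rng([config.seed, 4])
    records = _observe_qtl(truth, config, rng_obs)

    if "fdr_max" in spec:
        qvals = _bh_fdr([r.pvalue for r in records])
        records = [replace(r, fdr=q) for r, q in zip(records, qvals)]
        records = [r for r in records if r.fdr < spec["fdr_max"]]
    if "p_max" in spec:
        records = [r for r in records if r.pvalue < spec["p_max"]]
    return records, truth
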