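"""Instrument selection from an exposure GWAS and instrument-strength metrics.

The selection pipeline applies, in order: a genome-wide significance filter
(P < 5e-8, strict), greedy LD clumping (r² < 0.01 within a 10,000 kb window,
keeping the lower-P SNP of any correlated pair), a minor-allele-frequency
filter (MAF >= 1%), and outcome matching with proxy lookup (r² > 0.8, strict)
for instruments absent from the outcome GWAS.

Instrument strength per SNP uses the variance explained by an additively
coded variant on a standardized trait, R² = 2 β² EAF (1 − EAF), and the
F-statistic F = R² (n − k − 1) / (k (1 − R²)).  A mean per-SNP F above 10 is
the conventional bound for suitable instruments; sets at or below it carry a
weak-instrument warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gwas_io import GwasSummary, LDMatrix, VariantAssociation

logger = logging.getLogger(__name__)

__all__ = [
    "InstrumentParams", "InstrumentSet", "WeakInstrumentWarning",
    "select_genome_wide", "clump", "filter_maf", "find_proxy",
    "variance_explained", "f_statistic", "build_instrument_set",
]


class InstrumentError(ValueError):
    """Instrument selection cannot proceed (e.g. zero surviving SNPs)."""


class WeakInstrumentWarning(UserWarning):
    pass


@dataclass(frozen=True)
class InstrumentParams:
    """Thresholds of the selection pipeline (defaults as commonly reported)."""

    p_threshold: float = 5e-8
    clump_r2: float = 0.01
    clump_window_kb: float = 10_000.0
    maf_min: float = 0.01
    proxy_r2: float = 0.8
    proxy_eaf_tol: float = 0.2  # max |EAF_proxy - EAF_request| when using a proxy


@dataclass
class InstrumentSet:
    """Selected instruments with per-SNP strength metrics and provenance.

    ``outcome_snp_id`` maps each instrument to the outcome record to use
    (itself, or a proxy in high LD when the SNP is absent from the outcome).
    ``mean_f`` averages per-SNP F values (each with k = 1); ``overall_f``
    is the joint F from the summed R² with k = number of instruments.
    """

    snps: list[VariantAssociation]
    per_snp_r2: np.ndarray
    total_r2: float
    k: int
    mean_f: float
    overall_f: float
    n: int
    outcome_snp_id: dict = field(default_factory=dict)   # snp_id -> outcome snp_id
    provenance: dict = field(default_factory=dict)       # snp_id -> set of flags
    n_candidates: dict = field(default_factory=dict)     # counts after each step

    @property
    def snp_ids(self) -> list[str]:
        return [v.snp_id for v in self.snps]

    def proxy_used(self, snp_id: str) -> bool:
        return self.outcome_snp_id.get(snp_id, snp_id) != snp_id


def select_genome_wide(g: GwasSummary, p_threshold: float = 5e-8) -> list[VariantAssociation]:
    """Variants reaching genome-wide significance: pvalue strictly below
    ``p_threshold``.  An empty result is allowed (and logged)."""
    kept = [v for v in g.iter_variants() if v.pvalue < p_threshold]
    if not kept:
        logger.info("select_genome_wide: no variant below %g", p_threshold)
    return kept


def clump(
    candidates: list[VariantAssociation],
    ld: LDMatrix,
    r2_threshold: float = 0.01,
    window_kb: float = 10_000.0,
) -> list[VariantAssociation]:
    """Greedy LD clumping keeping the most significant SNP per region.

    Candidates are taken by ascending p-value (ties broken by snp_id); each
    index SNP removes all remaining same-chromosome SNPs within half the
    total window (``window_kb * 1000 / 2`` bp either side) whose r² with it
    is at or above ``r2_threshold``.  Pairs absent from ``ld`` count as
    r² = 0.  Index SNPs are returned in selection order.
    """
    for v in candidates:
        if v.pos is None and v.snp_id not in ld:
            raise InstrumentError(
                f"cannot assess LD for {v.snp_id}: no position and not in LD matrix"
            )
    half_window_bp = window_kb * 1000.0 / 2.0
    remaining = sorted(candidates, key=lambda v: (v.pvalue, v.snp_id))
    kept: list[VariantAssociation] = []
    while remaining:
        index = remaining.pop(0)
        kept.append(index)
        survivors = []
        for v in remaining:
            in_window = (v.chrom == index.chrom
                         and abs(v.pos - index.pos) <= half_window_bp)
            if in_window and ld.get(index.snp_id, v.snp_id) >= r2_threshold:
                continue
            survivors.append(v)
        remaining = survivors
    return kept


def filter_maf(candidates: list[VariantAssociation], maf_min: float = 0.01) -> list[VariantAssociation]:
    """Keep SNPs whose minor allele frequency is at least ``maf_min``
    (MAF exactly at the bound is kept: the exclusion rule is MAF < 1%)."""
    return [v for v in candidates if min(v.eaf, 1.0 - v.eaf) >= maf_min]


def find_proxy(
    snp_id: str,
    outcome: GwasSummary,
    ld: LDMatrix,
    r2_min: float = 0.8,
) -> VariantAssociation | None:
    """Best-LD proxy for a SNP absent from the outcome GWAS.

    Among outcome variants with r² strictly above ``r2_min`` to ``snp_id``,
    returns the one with maximal r²; ties broken by smaller p-value, then
    lexicographic snp_id.  Returns None when no variant qualifies or when
    ``snp_id`` is unknown to the LD matrix (with a warning).
    """
    if snp_id not in ld:
        logger.warning("find_proxy: %s not in LD matrix; no proxy available", snp_id)
        return None
    best: tuple | None = None
    for cand_id in outcome.snp_ids:
        if cand_id == snp_id:
            continue
        r2 = ld.get(snp_id, cand_id)
        if r2 > r2_min:
            v = outcome.get(cand_id)
            key = (-r2, v.pvalue, v.snp_id)
            if best is None or key < best[0]:
                best = (key, v)
    return None if best is None else best[1]


def variance_explained(beta: float, eaf: float) -> float:
    """Variance of a standardized trait explained by one additively coded
    SNP: R² = 2 β² EAF (1 − EAF)."""
    if not 0.0 <= eaf <= 1.0:
        raise ValueError("eaf must lie in [0, 1]")
    return 2.0 * beta * beta * eaf * (1.0 - eaf)


def f_statistic(r2_total: float, n: int, k: int) -> float:
    """Instrument-strength F-statistic, F = R² (n − k − 1) / (k (1 − R²))."""
    if not 0.0 <= r2_total < 1.0:
        raise ValueError("r2_total must lie in [0, 1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    if n <= k + 1:
        raise ValueError("n must exceed k + 1")
    return r2_total * (n - k - 1) / (k * (1.0 - r2_total))


def build_instrument_set(
    exposure: GwasSummary,
    outcome: GwasSummary,
    ld: LDMatrix,
    params: InstrumentParams | None = None,
) -> InstrumentSet:
    """Run the full selection pipeline and compute strength metrics.

    Steps: genome-wide significance filter, LD clumping, MAF filter, then
    outcome matching with proxy fallback.  Proxies are only accepted when
    their outcome EAF is orientation-consistent with the requested SNP's
    exposure EAF (|difference| < ``proxy_eaf_tol``), since LD sign
    information is not part of an r² matrix.  Raises if nothing survives;
    warns if mean F <= 10.
    """
    params = params or InstrumentParams()
    counts = {}

    step1 = select_genome_wide(exposure, params.p_threshold)
    counts["genome_wide"] = len(step1)
    step2 = clump(step1, ld, params.clump_r2, params.clump_window_kb)
    counts["clump"] = len(step2)
    step3 = filter_maf(step2, params.maf_min)
    counts["maf"] = len(step3)

    kept: list[VariantAssociation] = []
    outcome_map: dict[str, str] = {}
    provenance: dict[str, set] = {}
    for v in step3:
        flags = {"genome_wide", "clump_kept", "maf_pass"}
        if v.snp_id in outcome:
            outcome_map[v.snp_id] = v.snp_id
        else:
            proxy = find_proxy(v.snp_id, outcome, ld, params.proxy_r2)
            if proxy is None:
                logger.info("dropping %s: absent from outcome, no proxy", v.snp_id)
                continue
            if abs(proxy.eaf - v.eaf) >= params.proxy_eaf_tol:
                logger.info(
                    "dropping %s: proxy %s EAF %.3f inconsistent with exposure EAF %.3f",
                    v.snp_id, proxy.snp_id, proxy.eaf, v.eaf,
                )
                continue
            logger.info("using proxy %s for %s", proxy.snp_id, v.snp_id)
            outcome_map[v.snp_id] = proxy.snp_id
            flags.add("proxy_used")
        kept.append(v)
        provenance[v.snp_id] = flags
    counts["outcome_matched"] = len(kept)

    if not kept:
        raise InstrumentError("no instruments survive selection")

    per_snp_r2 = np.array([variance_explained(v.beta, v.eaf) for v in kept])
    total_r2 = float(per_snp_r2.sum())
    k = len(kept)
    per_snp_f = np.array([
        f_statistic(min(r2, 1.0 - 1e-12), int(v.n), 1)
        for r2, v in zip(per_snp_r2, kept)
    ])
    mean_f = float(per_snp_f.mean())
    n = exposure.n_total
    overall_f = f_statistic(min(total_r2, 1.0 - 1e-12), n, k) if n > k + 1 else float("nan")

    if mean_f <= 10.0:
        warnings.warn(
            f"mean F-statistic {mean_f:.2f} <= 10: instruments may be weak",
            WeakInstrumentWarning,
        )
    return InstrumentSet(
        snps=kept, per_snp_r2=per_snp_r2, total_r2=total_r2, k=k,
        mean_f=mean_f, overall_f=overall_f, n=n,
        outcome_snp_id=outcome_map, provenance=provenance, n_candidates=counts,
    )
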