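"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the statistical structure of summary-level MR inputs:
per-SNP effects ``gamma_j`` on a standardized quantitative exposure, outcome
effects on the log-odds scale composed of a causal part plus a pleiotropic
part (``Gamma_j = beta * gamma_j + alpha_j``), sampling noise scaled by
sample size and allele frequency, block LD structure, and correlated
exposures for multivariable scenarios.  Exposure and outcome noise are
independent, matching the two-sample design (non-overlapping cohorts).

Standard-error model (standardized traits, additive coding):

* exposure:  ``se_x = 1 / sqrt(2 * n_exposure * eaf * (1 - eaf))``
* binary outcome: ``se_y = 1 / sqrt(2 * eaf * (1 - eaf) * n_eff)`` with
  ``n_eff = n_cases * n_controls / (n_cases + n_controls)``

No genotype-level data are simulated; these approximations reproduce the
familiar coupling of power to sample size and allele frequency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .gwas_io import CANONICAL_COLUMNS, GwasSummary, LDMatrix

__all__ = [
    "SimulationConfig", "TruthRecord",
    "simulate_two_sample", "simulate_ld_block_gwas", "simulate_mvmr",
]

_NONPALINDROMIC_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                         ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Parameters of the two-sample summary-statistics generator.

    ``gamma_dist`` is a tuple spec for per-SNP exposure effects:
    ``("normal", loc, scale)``, ``("uniform", low, high)`` or
    ``("signed_uniform", low, high)`` (magnitude uniform on [low, high],
    random sign).  The signed-uniform default keeps instrument effects
    bounded away from zero, emulating variants that have already cleared
    genome-wide significance.
    """

    n_snps: int = 100
    n_exposure: int = 100_000
    n_outcome_cases: int = 20_000
    n_outcome_controls: int = 20_000
    causal_effect: float = 0.0          # true log-OR of outcome per SD exposure
    gamma_dist: tuple = ("signed_uniform", 0.02, 0.06)
    pleiotropy_mean: float = 0.0        # mu_alpha
    pleiotropy_sd: float = 0.0          # sigma_alpha
    outlier_fraction: float = 0.0
    outlier_scale: float = 5.0          # sd multiplier for outlier alphas
    eaf_range: tuple = (0.05, 0.95)
    palindromic_fraction: float = 0.2
    ld_block_size: int = 1
    ld_within_block_r2: float = 0.0
    se_scale: float = 1.0               # multiplies both SEs (1e-6 ~ noise-free limit)
    seed: int = 0

    def validate(self) -> None:
        if self.n_snps < 3:
            raise ConfigError("n_snps must be >= 3")
        if min(self.n_exposure, self.n_outcome_cases, self.n_outcome_controls) <= 0:
            raise ConfigError("sample sizes must be positive")
        lo, hi = self.eaf_range
        if not (0.01 < lo < hi < 0.99):
            raise ConfigError("eaf_range must satisfy 0.01 < low < high < 0.99")
        if not (0.0 <= self.outlier_fraction < 1.0):
            raise ConfigError("outlier_fraction must be in [0, 1)")
        if self.ld_block_size < 1:
            raise ConfigError("ld_block_size must be >= 1")
        if not (0.0 <= self.ld_within_block_r2 < 1.0):
            raise ConfigError("ld_within_block_r2 must be in [0, 1)")
        if self.gamma_dist[0] not in ("normal", "uniform", "signed_uniform"):
            raise ConfigError(f"unknown gamma_dist kind {self.gamma_dist[0]!r}")
        if self.se_scale <= 0:
            raise ConfigError("se_scale must be positive")


@dataclass
class TruthRecord:
    """Ground truth behind one simulated dataset, for recovery tests."""

    causal_effect: object                 # float, or length-K vector for MVMR
    per_snp_gamma: np.ndarray             # (J,) or (J, K)
    per_snp_alpha: np.ndarray             # (J,)
    outlier_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    exposure_correlation: np.ndarray | None = None


def _draw_gamma(rng: np.random.Generator, dist: tuple, size) -> np.ndarray:
    kind = dist[0]
    if kind == "normal":
        return rng.normal(dist[1], dist[2], size=size)
    if kind == "uniform":
        return rng.uniform(dist[1], dist[2], size=size)
    # signed_uniform: magnitude uniform, random sign
    mag = rng.uniform(dist[1], dist[2], size=size)
    sign = rng.choice([-1.0, 1.0], size=size)
    return mag * sign


def _gamma_sd(dist: tuple) -> float:
    """Standard deviation of the gamma_dist spec (used for MVMR scaling)."""
    kind, a, b = dist
    if kind == "normal":
        return float(b)
    if kind == "uniform":
        return float((b - a) / math.sqrt(12.0))
    # signed uniform magnitude: E=0, E[g^2] = (a^2 + ab + b^2)/3
    return float(math.sqrt((a * a + a * b + b * b) / 3.0))


def _alleles(rng: np.random.Generator, n: int, palindromic_fraction: float):
    pal = rng.random(n) < palindromic_fraction
    ea, oa = [], []
    for is_pal in pal:
        pairs = _PALINDROMIC_PAIRS if is_pal else _NONPALINDROMIC_PAIRS
        e, o = pairs[rng.integers(len(pairs))]
        ea.append(e)
        oa.append(o)
    return np.array(ea), np.array(oa)


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.clip(p, np.nextafter(0.0, 1.0), 1.0)


def _summary_frame(snp_ids, chrom, pos, ea, oa, eaf, beta, se, n) -> pd.DataFrame:
    df = pd.DataFrame({
        "snp_id": snp_ids, "chrom": chrom, "pos": pos,
        "effect_allele": ea, "other_allele": oa,
        "eaf": eaf, "beta": beta, "se": se,
        "pvalue": _two_sided_p(np.asarray(beta), np.asarray(se)),
        "n": n,
    })
    return df[CANONICAL_COLUMNS]


def _positions(rng: np.random.Generator, n_snps: int, block_size: int = 1):
    """Chromosome/position layout; members of an LD block share a chromosome
    and sit within a few kb of each other, distinct blocks are far apart."""
    n_blocks = math.ceil(n_snps / block_size)
    chroms, positions = [], []
    for b in range(n_blocks):
        chrom = str(b % 22 + 1)
        base = 1_000_000 + (b // 22) * 50_000_000
        for m in range(block_size):
            j = b * block_size + m
            if j >= n_snps:
                break
            chroms.append(chrom)
            positions.append(base + m * 1000)
    return np.array(chroms), np.array(positions, dtype=int)


def simulate_two_sample(cfg: SimulationConfig):
    """Simulate exposure and outcome summary statistics with known truth.

    Per SNP j: ``gamma_j ~ gamma_dist``; ``alpha_j ~ N(mu_alpha,
    sigma_alpha^2)``, with sd inflated by ``outlier_scale`` for a random
    ``outlier_fraction`` of SNPs; true outcome effect ``Gamma_j = beta *
    gamma_j + alpha_j``.  Observed effects add independent Gaussian noise at
    the analytic standard errors; p-values are two-sided Wald.

    Returns ``(exposure, outcome, truth)``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    J = cfg.n_snps
    eaf = rng.uniform(cfg.eaf_range[0], cfg.eaf_range[1], size=J)
    gamma = _draw_gamma(rng, cfg.gamma_dist, J)

    alpha = rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, size=J)
    n_out = int(round(cfg.outlier_fraction * J))
    outliers = rng.choice(J, size=n_out, replace=False) if n_out else np.array([], dtype=int)
    if n_out:
        alpha[outliers] = rng.normal(
            cfg.pleiotropy_mean, cfg.outlier_scale * cfg.pleiotropy_sd, size=n_out
        )
    big_gamma = cfg.causal_effect * gamma + alpha

    se_x = cfg.se_scale / np.sqrt(2.0 * cfg.n_exposure * eaf * (1.0 - eaf))
    n_eff = cfg.n_outcome_cases * cfg.n_outcome_controls / (
        cfg.n_outcome_cases + cfg.n_outcome_controls
    )
    se_y = cfg.se_scale / np.sqrt(2.0 * eaf * (1.0 - eaf) * n_eff)

    bx = rng.normal(gamma, se_x)
    by = rng.normal(big_gamma, se_y)

    snp_ids = np.array([f"rs{i + 1}" for i in range(J)])
    chrom, pos = _positions(rng, J)
    ea, oa = _alleles(rng, J, cfg.palindromic_fraction)

    exposure = GwasSummary(
        trait_name="exposure", trait_type="quantitative", n_total=cfg.n_exposure,
        variants=_summary_frame(snp_ids, chrom, pos, ea, oa, eaf, bx, se_x,
                                np.full(J, cfg.n_exposure)),
    )
    n_total = cfg.n_outcome_cases + cfg.n_outcome_controls
    outcome = GwasSummary(
        trait_name="outcome", trait_type="binary", n_total=n_total,
        n_cases=cfg.n_outcome_cases,
        variants=_summary_frame(snp_ids, chrom, pos, ea, oa, eaf, by, se_y,
                                np.full(J, n_total)),
    )
    truth = TruthRecord(
        causal_effect=cfg.causal_effect, per_snp_gamma=gamma,
        per_snp_alpha=alpha, outlier_indices=np.sort(outliers),
    )
    return exposure, outcome, truth


def simulate_ld_block_gwas(cfg: SimulationConfig):
    """Simulate an exposure GWAS with block LD structure plus its r² matrix.

    SNPs are partitioned into blocks of ``ld_block_size``; within-block r²
    is constant at ``ld_within_block_r2`` and between-block r² is 0.  Within
    a block all members share one underlying effect plus a small jitter, so
    clumping at a threshold below the within-block r² should retain exactly
    one SNP per block.
    """
    cfg.validate()
    if cfg.ld_block_size < 2:
        raise ConfigError("simulate_ld_block_gwas requires ld_block_size >= 2")
    rng = np.random.default_rng(cfg.seed)
    J = cfg.n_snps
    B = cfg.ld_block_size
    n_blocks = math.ceil(J / B)

    eaf = rng.uniform(cfg.eaf_range[0], cfg.eaf_range[1], size=J)
    block_effect = _draw_gamma(rng, cfg.gamma_dist, n_blocks)
    block_of = np.arange(J) // B
    gamma = block_effect[block_of] * (1.0 + rng.normal(0.0, 0.02, size=J))

    se_x = cfg.se_scale / np.sqrt(2.0 * cfg.n_exposure * eaf * (1.0 - eaf))
    bx = rng.normal(gamma, se_x)

    snp_ids = np.array([f"rs{i + 1}" for i in range(J)])
    chrom, pos = _positions(rng, J, block_size=B)
    ea, oa = _alleles(rng, J, cfg.palindromic_fraction)

    gwas = GwasSummary(
        trait_name="exposure", trait_type="quantitative", n_total=cfg.n_exposure,
        variants=_summary_frame(snp_ids, chrom, pos, ea, oa, eaf, bx, se_x,
                                np.full(J, cfg.n_exposure)),
    )
    r2 = np.where(block_of[:, None] == block_of[None, :], cfg.ld_within_block_r2, 0.0)
    np.fill_diagonal(r2, 1.0)
    ld = LDMatrix(snp_ids=list(snp_ids), r2=r2)
    return gwas, ld


def simulate_mvmr(cfg: SimulationConfig, k_exposures: int,
                  direct_effects, exposure_corr):
    """Simulate K correlated exposures and one binary outcome.

    Per-SNP effect vectors on the K exposures are drawn multivariate normal
    with correlation ``exposure_corr`` and per-exposure sd matching
    ``gamma_dist``; the outcome effect is ``sum_k direct_effects[k] *
    gamma_jk + alpha_j``.  A correlated exposure with a null direct effect
    then shows a nonzero univariable estimate — the pattern multivariable
    MR is designed to resolve.

    Returns ``(list of exposure GwasSummary, outcome GwasSummary, truth)``.
    """
    cfg.validate()
    direct_effects = np.asarray(direct_effects, dtype=float)
    exposure_corr = np.asarray(exposure_corr, dtype=float)
    if direct_effects.shape != (k_exposures,):
        raise ConfigError("direct_effects must have length k_exposures")
    if exposure_corr.shape != (k_exposures, k_exposures):
        raise ConfigError("exposure_corr must be K x K")
    try:
        chol = np.linalg.cholesky(exposure_corr)
    except np.linalg.LinAlgError as exc:
        raise ConfigError("exposure_corr must be positive definite") from exc

    rng = np.random.default_rng(cfg.seed)
    J, K = cfg.n_snps, k_exposures
    eaf = rng.uniform(cfg.eaf_range[0], cfg.eaf_range[1], size=J)
    sd = _gamma_sd(cfg.gamma_dist)
    gamma = rng.standard_normal((J, K)) @ chol.T * sd  # correlated true effects

    alpha = rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, size=J)
    big_gamma = gamma @ direct_effects + alpha

    se_x = cfg.se_scale / np.sqrt(2.0 * cfg.n_exposure * eaf * (1.0 - eaf))
    n_eff = cfg.n_outcome_cases * cfg.n_outcome_controls / (
        cfg.n_outcome_cases + cfg.n_outcome_controls
    )
    se_y = cfg.se_scale / np.sqrt(2.0 * eaf * (1.0 - eaf) * n_eff)

    snp_ids = np.array([f"rs{i + 1}" for i in range(J)])
    chrom, pos = _positions(rng, J)
    ea, oa = _alleles(rng, J, cfg.palindromic_fraction)

    exposures = []
    for k in range(K):
        bx = rng.normal(gamma[:, k], se_x)  # independent noise per exposure GWAS
        exposures.append(GwasSummary(
            trait_name=f"exposure_{k + 1}", trait_type="quantitative",
            n_total=cfg.n_exposure,
            variants=_summary_frame(snp_ids, chrom, pos, ea, oa, eaf, bx, se_x,
                                    np.full(J, cfg.n_exposure)),
        ))
    by = rng.normal(big_gamma, se_y)
    n_total = cfg.n_outcome_cases + cfg.n_outcome_controls
    outcome = GwasSummary(
        trait_name="outcome", trait_type="binary", n_total=n_total,
        n_cases=cfg.n_outcome_cases,
        variants=_summary_frame(snp_ids, chrom, pos, ea, oa, eaf, by, se_y,
                                np.full(J, n_total)),
    )
    truth = TruthRecord(
        causal_effect=direct_effects, per_snp_gamma=gamma, per_snp_alpha=alpha,
        exposure_correlation=exposure_corr,
    )
    return exposures, outcome, truth
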