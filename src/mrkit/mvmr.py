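"""Multivariable MR: joint direct effects of K exposures on one outcome.

The combined instrument set is the union of each exposure's instruments,
re-clumped jointly (index SNP = smallest p across exposures) so correlated
instruments contributed by different exposures are not double-counted.
SNPs missing from any exposure or from the outcome are dropped
(complete-case) and logged.  All traits are harmonized to the first
exposure's effect-allele frame.

Estimation is weighted multivariable linear regression of the outcome
effects on the K columns of exposure effects, no intercept, weights
1/se_outcome²; the coefficient covariance carries a multiplicative
overdispersion factor max(1, Q/(J−K)) and per-exposure p-values use
t(J−K), matching the univariable IVW conventions.  With K = 1 the estimate
reduces exactly to the fixed-effect univariable IVW slope.

``conditional_f`` is a descriptive per-exposure instrument-strength proxy:
the mean weighted chi-square of that exposure's instrument effects left
after projecting out the other exposures' columns.  It is reported, not
used as a gate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import Z95, to_odds_ratio
from .gwas_io import GwasSummary, LDMatrix, VariantAssociation
from .harmonize import DEFAULT_EAF_BAND, Exclusion, harmonize_pair
from .instruments import InstrumentParams, InstrumentSet, build_instrument_set, clump

logger = logging.getLogger(__name__)

__all__ = [
    "MVMRInput", "MVMRModel", "MVMRResults",
    "assemble_mvmr_input", "mvmr_ivw", "mvmr_with_covariates",
]


@dataclass
class MVMRInput:
    """J SNPs x K exposures design for multivariable MR (no missing cells)."""

    snp_ids: list[str]
    exposure_betas: np.ndarray   # (J, K)
    exposure_ses: np.ndarray     # (J, K)
    outcome_beta: np.ndarray     # (J,)
    outcome_se: np.ndarray       # (J,)
    exposure_names: list[str]

    def __post_init__(self) -> None:
        self.exposure_betas = np.atleast_2d(np.asarray(self.exposure_betas, float))
        self.exposure_ses = np.atleast_2d(np.asarray(self.exposure_ses, float))
        self.outcome_beta = np.asarray(self.outcome_beta, float)
        self.outcome_se = np.asarray(self.outcome_se, float)
        J, K = self.exposure_betas.shape
        if len(self.snp_ids) != J or self.exposure_ses.shape != (J, K):
            raise ValueError("inconsistent MVMR input shapes")
        if len(self.exposure_names) != K:
            raise ValueError("exposure_names must have length K")
        if J <= K:
            raise ValueError(f"need more SNPs than exposures (J={J}, K={K})")
        for arr in (self.exposure_betas, self.exposure_ses,
                    self.outcome_beta, self.outcome_se):
            if not np.all(np.isfinite(arr)):
                raise ValueError("MVMR input contains missing/non-finite cells")

    @property
    def J(self) -> int:
        return self.exposure_betas.shape[0]

    @property
    def K(self) -> int:
        return self.exposure_betas.shape[1]


@dataclass
class MVMRResults:
    """Per-exposure direct effects with uncertainties and a summary table."""

    exposure_names: list[str]
    beta: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    pvalue: np.ndarray
    or_: np.ndarray
    or_ci_low: np.ndarray
    or_ci_high: np.ndarray
    conditional_f: np.ndarray
    n_snp: int
    df_resid: int
    q_stat: float
    model: "MVMRModel" = None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "exposure": self.exposure_names,
            "beta": self.beta, "se": self.se,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "pvalue": self.pvalue,
            "or": self.or_, "or_ci_low": self.or_ci_low,
            "or_ci_high": self.or_ci_high,
            "conditional_f": self.conditional_f,
            "n_snp": self.n_snp,
        })

    def summary(self) -> str:
        lines = [
            "Multivariable Mendelian randomization",
            "=" * 72,
            f"No. SNPs: {self.n_snp}   residual df: {self.df_resid}   "
            f"Q: {self.q_stat:.2f}",
            f"{'exposure':<16}{'beta':>9}{'se':>8}{'OR':>8}"
            f"{'95% CI':>18}{'p':>10}{'cond.F':>8}",
        ]
        for i, name in enumerate(self.exposure_names):
            lines.append(
                f"{name:<16}{self.beta[i]:>9.4f}{self.se[i]:>8.4f}"
                f"{self.or_[i]:>8.3f}"
                f"{f'({self.or_ci_low[i]:.3f}-{self.or_ci_high[i]:.3f})':>18}"
                f"{self.pvalue[i]:>10.3g}{self.conditional_f[i]:>8.1f}"
            )
        return "\n".join(lines)


def _collinear_pairs(X: np.ndarray, names: list[str]) -> list[tuple[str, str]]:
    """Name near-perfectly correlated exposure columns for error messages."""
    pairs = []
    C = np.corrcoef(X, rowvar=False)
    K = X.shape[1]
    for i in range(K):
        for j in range(i + 1, K):
            if abs(C[i, j]) > 1.0 - 1e-10:
                pairs.append((names[i], names[j]))
    return pairs


def mvmr_ivw(m: MVMRInput) -> MVMRResults:
    """Weighted multivariable regression of outcome on exposure effects."""
    X, y = m.exposure_betas, m.outcome_beta
    w = 1.0 / (m.outcome_se ** 2)
    J, K = m.J, m.K

    Xw = X * np.sqrt(w)[:, None]
    if np.linalg.matrix_rank(Xw) < K:
        pairs = _collinear_pairs(X, m.exposure_names)
        detail = f" (collinear: {pairs})" if pairs else ""
        raise ValueError("rank-deficient exposure design" + detail)

    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * y)
    beta = np.linalg.solve(xtwx, xtwy)
    resid = y - X @ beta
    q = float(np.sum(w * resid * resid))
    df = J - K
    cov = np.linalg.inv(xtwx) * max(1.0, q / df)
    se = np.sqrt(np.diag(cov))
    pvalue = 2.0 * stats.t.sf(np.abs(beta) / se, df)
    pvalue = np.clip(pvalue, np.nextafter(0.0, 1.0), 1.0)

    ors = np.array([to_odds_ratio(b, s) for b, s in zip(beta, se)])

    # descriptive conditional instrument strength: mean weighted chi-square
    # of each exposure's effects after removing the other columns' span
    cond_f = np.empty(K)
    for k in range(K):
        xk = X[:, k]
        if K == 1:
            ek = xk
        else:
            others = np.delete(X, k, axis=1)
            ow = others * np.sqrt(w)[:, None]
            coef, *_ = np.linalg.lstsq(ow, xk * np.sqrt(w), rcond=None)
            ek = xk - others @ coef
        cond_f[k] = float(np.mean(ek ** 2 / m.exposure_ses[:, k] ** 2))

    return MVMRResults(
        exposure_names=list(m.exposure_names),
        beta=beta, se=se,
        ci_low=beta - Z95 * se, ci_high=beta + Z95 * se,
        pvalue=pvalue,
        or_=ors[:, 0], or_ci_low=ors[:, 1], or_ci_high=ors[:, 2],
        conditional_f=cond_f, n_snp=J, df_resid=df, q_stat=q,
    )


def _align_to_frame(ref: VariantAssociation, va: VariantAssociation,
                    policy: str, eaf_band: tuple):
    """Align any trait's association onto a reference allele frame; returns
    (beta, se) or None if the variant cannot be oriented."""
    rec = harmonize_pair(ref, va, policy=policy, eaf_band=eaf_band)
    if isinstance(rec, Exclusion):
        return None
    return rec.beta_outcome, rec.se_outcome


def assemble_mvmr_input(
    instrument_sets: list[InstrumentSet],
    exposures: list[GwasSummary],
    outcome: GwasSummary,
    ld: LDMatrix,
    params: InstrumentParams | None = None,
    policy: str = "exclude",
    eaf_band: tuple = DEFAULT_EAF_BAND,
) -> MVMRInput:
    """Build the joint design from per-exposure instrument sets.

    The union of instruments is re-clumped jointly (keeping the SNP with
    the smallest minimum p across exposures); SNPs missing from any
    exposure or the outcome are dropped with a log line, and all traits are
    harmonized to the first exposure's allele frame.
    """
    if len(instrument_sets) < 2 and len(exposures) >= 2:
        raise ValueError("need one instrument set per exposure")
    if len(instrument_sets) != len(exposures):
        raise ValueError("instrument_sets and exposures must align")
    params = params or InstrumentParams()

    union_ids = sorted({v.snp_id for iset in instrument_sets for v in iset.snps})

    # complete-case: the SNP must appear in every exposure and the outcome
    usable = [s for s in union_ids
              if all(s in e for e in exposures) and s in outcome]
    for s in sorted(set(union_ids) - set(usable)):
        logger.info("assemble_mvmr_input: dropping %s (missing from a trait)", s)

    # joint re-clump on min-p across exposures
    candidates = []
    for s in usable:
        records = [e.get(s) for e in exposures]
        best = min(records, key=lambda v: v.pvalue)
        candidates.append(best)
    kept = clump(candidates, ld, params.clump_r2, params.clump_window_kb)
    kept_ids = sorted(v.snp_id for v in kept)

    names = [e.trait_name for e in exposures]
    rows_bx, rows_sx, out_b, out_s, final_ids = [], [], [], [], []
    for s in kept_ids:
        ref = exposures[0].get(s)
        bx = [ref.beta]
        sx = [ref.se]
        ok = True
        for e in exposures[1:]:
            aligned = _align_to_frame(ref, e.get(s), policy, eaf_band)
            if aligned is None:
                ok = False
                break
            bx.append(aligned[0])
            sx.append(aligned[1])
        if not ok:
            logger.info("assemble_mvmr_input: dropping %s (alleles unresolvable)", s)
            continue
        aligned = _align_to_frame(ref, outcome.get(s), policy, eaf_band)
        if aligned is None:
            logger.info("assemble_mvmr_input: dropping %s (outcome unresolvable)", s)
            continue
        rows_bx.append(bx)
        rows_sx.append(sx)
        out_b.append(aligned[0])
        out_s.append(aligned[1])
        final_ids.append(s)

    if len(final_ids) <= len(exposures):
        raise ValueError(
            f"too few SNPs after assembly (J={len(final_ids)}, K={len(exposures)})"
        )
    return MVMRInput(
        snp_ids=final_ids,
        exposure_betas=np.array(rows_bx), exposure_ses=np.array(rows_sx),
        outcome_beta=np.array(out_b), outcome_se=np.array(out_s),
        exposure_names=names,
    )


class MVMRModel:
    """Multivariable MR model; ``fit()`` returns :class:`MVMRResults`.

    Build directly from an :class:`MVMRInput`, or from GWAS summaries with
    :meth:`from_gwas`, which selects instruments per exposure (and per
    covariate), assembles the joint design, and records it on the model.
    """

    def __init__(self, data: MVMRInput):
        self.data = data

    @classmethod
    def from_gwas(cls, exposures: list[GwasSummary], outcome: GwasSummary,
                  ld: LDMatrix, params: InstrumentParams | None = None,
                  covariates: list[GwasSummary] | None = None,
                  policy: str = "exclude",
                  eaf_band: tuple = DEFAULT_EAF_BAND) -> "MVMRModel":
        params = params or InstrumentParams()
        traits = list(exposures) + list(covariates or [])
        isets = [build_instrument_set(t, outcome, ld, params) for t in traits]
        m = assemble_mvmr_input(isets, traits, outcome, ld, params,
                                policy=policy, eaf_band=eaf_band)
        model = cls(m)
        model.instrument_sets = isets
        return model

    def fit(self) -> MVMRResults:
        res = mvmr_ivw(self.data)
        res.model = self
        return res


def mvmr_with_covariates(
    instrument_sets: list[InstrumentSet],
    exposures: list[GwasSummary],
    covariate_sets: list[InstrumentSet],
    covariates: list[GwasSummary],
    outcome: GwasSummary,
    ld: LDMatrix,
    params: InstrumentParams | None = None,
    policy: str = "exclude",
    eaf_band: tuple = DEFAULT_EAF_BAND,
) -> MVMRResults:
    """MVMR with the exposure list extended by covariate traits (e.g.
    lifestyle risk factors); identical machinery, K extended."""
    m = assemble_mvmr_input(
        list(instrument_sets) + list(covariate_sets),
        list(exposures) + list(covariates),
        outcome, ld, params, policy=policy, eaf_band=eaf_band,
    )
    return mvmr_ivw(m)
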