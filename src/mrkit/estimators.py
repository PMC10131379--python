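"""Univariable two-sample MR estimators and diagnostics.

Given J harmonized SNP pairs (bx_j, sx_j) on the exposure and (by_j, sy_j)
on the outcome, each estimator targets the causal effect theta of one SD of
exposure on the log-odds of the outcome:

* Wald ratio (single SNP): theta_j = by_j / bx_j, first-order delta SE
  sy_j / |bx_j|.
* IVW: inverse-variance-weighted meta-analysis of the Wald ratios with
  weights w_j = bx_j^2 / sy_j^2, algebraically the weighted least-squares
  slope of by on bx through the origin.  Cochran's Q over the per-SNP
  ratios measures heterogeneity (chi-square, J - 1 df); the multiplicative
  random-effects variant inflates the SE by max(1, sqrt(Q / (J - 1))).
* MR-Egger: weighted regression of by on bx with a free intercept after
  orienting bx_j >= 0; the intercept estimates directional pleiotropy
  (valid under InSIDE), the slope is the causal effect.  t(J - 2)
  reference, SE floor as above with J - 2 df.
* Weighted median: weighted 50th percentile of the ratios (consistent when
  valid instruments carry a weight majority); parametric-bootstrap SE.
* Weighted mode: peak of a weighted Gaussian kernel density over the
  ratios (consistent when the largest group of instruments is valid);
  parametric-bootstrap SE.

Results are exposed statsmodels-style: build an :class:`MRModel` from a
:class:`~mrkit.harmonize.HarmonizedSet` or a DataFrame, call ``fit`` (or
``fit_all``) and read the returned :class:`MRResults`, which carries the
estimate, its uncertainty, odds-ratio scale, heterogeneity and pleiotropy
diagnostics, and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .harmonize import HarmonizedSet

__all__ = [
    "MRModel", "MRResults", "MREstimate", "HeterogeneityResult",
    "PleiotropyResult", "wald_ratio", "ivw", "egger", "weighted_median",
    "weighted_mode", "to_odds_ratio", "METHODS",
]

Z95 = 1.96  # conventional reporting quantile for 95% intervals

METHODS = ("ivw", "egger", "weighted_median", "weighted_mode")


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q over per-SNP causal estimates."""

    q: float
    df: int
    pvalue: float


@dataclass(frozen=True)
class PleiotropyResult:
    """MR-Egger intercept: average directional pleiotropy."""

    intercept: float
    se: float
    pvalue: float


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate on log-OR and OR scales."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    or_: float
    or_ci_low: float
    or_ci_high: float
    n_snp: int


def to_odds_ratio(beta: float, se: float) -> tuple[float, float, float]:
    """Exponentiate a log-OR and its 95% CI: (exp(b), exp(b ± 1.96 se))."""
    if se <= 0:
        raise ValueError("se must be positive")
    return (float(np.exp(beta)),
            float(np.exp(beta - Z95 * se)),
            float(np.exp(beta + Z95 * se)))


def _estimate(method: str, beta: float, se: float, n_snp: int,
              df_t: int | None = None) -> MREstimate:
    """Package beta/se into an MREstimate; normal reference unless ``df_t``."""
    beta, se = float(beta), float(se)
    if df_t is None:
        p = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else (1.0 if beta == 0 else 0.0)
    else:
        p = 2.0 * stats.t.sf(abs(beta) / se, df_t) if se > 0 else (1.0 if beta == 0 else 0.0)
    or_, lo, hi = to_odds_ratio(beta, se) if se > 0 else (np.exp(beta),) * 3
    return MREstimate(
        method=method, beta=beta, se=se,
        ci_low=beta - Z95 * se, ci_high=beta + Z95 * se,
        pvalue=float(min(max(p, np.nextafter(0.0, 1.0)), 1.0)),
        or_=or_, or_ci_low=lo, or_ci_high=hi, n_snp=n_snp,
    )


def wald_ratio(bx: float, by: float, sy: float) -> MREstimate:
    """Single-SNP causal estimate: beta = by / bx, se = sy / |bx|."""
    if bx == 0:
        raise ValueError("exposure effect bx must be nonzero")
    return _estimate("wald", by / bx, sy / abs(bx), 1)


def _ivw_core(bx, by, sy):
    w = bx * bx / (sy * sy)
    beta = float(np.sum(w * (by / bx)) / np.sum(w))
    se_fixed = float(np.sqrt(1.0 / np.sum(w)))
    return w, beta, se_fixed


def ivw(h: HarmonizedSet, model: str = "multiplicative_random"):
    """IVW meta-analysis of the Wald ratios.

    Returns ``(MREstimate, HeterogeneityResult | None)``; the Q statistic
    needs at least two SNPs.  ``model`` is ``"fixed"`` or
    ``"multiplicative_random"`` (SE inflated by max(1, sqrt(Q/(J-1)))).
    """
    if model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW model {model!r}")
    bx, by, sy = h.beta_exposure, h.beta_outcome, h.se_outcome
    J = len(bx)
    if J == 0:
        raise ValueError("IVW requires at least one SNP")
    w, beta, se = _ivw_core(bx, by, sy)
    het = None
    if J >= 2:
        theta = by / bx
        q = float(np.sum(w * (theta - beta) ** 2))
        het = HeterogeneityResult(q=q, df=J - 1,
                                  pvalue=float(stats.chi2.sf(q, J - 1)))
        if model == "multiplicative_random":
            se *= max(1.0, np.sqrt(q / (J - 1)))
    method = "ivw_fixed" if model == "fixed" else "ivw_mre"
    return _estimate(method, beta, se, J), het


def egger(h: HarmonizedSet):
    """MR-Egger regression: slope (causal effect) and intercept (pleiotropy).

    Each SNP is oriented so bx_j >= 0; a weighted regression of by on bx
    with intercept follows, weights 1/sy².  Returns ``(MREstimate,
    PleiotropyResult, HeterogeneityResult)``; needs at least three SNPs.
    """
    bx, by, sy = h.beta_exposure.copy(), h.beta_outcome.copy(), h.se_outcome
    J = len(bx)
    if J < 3:
        raise ValueError("MR-Egger requires at least three SNPs")
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign

    w = 1.0 / (sy * sy)
    X = np.column_stack([np.ones(J), bx])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * by)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = by - X @ coef
    q = float(np.sum(w * resid * resid))
    cov_fixed = np.linalg.inv(xtwx)
    infl = max(1.0, np.sqrt(q / (J - 2)))
    se_int = float(np.sqrt(cov_fixed[0, 0]) * infl)
    se_slope = float(np.sqrt(cov_fixed[1, 1]) * infl)

    est = _estimate("egger", coef[1], se_slope, J, df_t=J - 2)
    p_int = 2.0 * stats.t.sf(abs(coef[0]) / se_int, J - 2)
    pleio = PleiotropyResult(intercept=float(coef[0]), se=se_int,
                             pvalue=float(min(max(p_int, np.nextafter(0.0, 1.0)), 1.0)))
    het = HeterogeneityResult(q=q, df=J - 2, pvalue=float(stats.chi2.sf(q, J - 2)))
    return est, pleio, het


def _weighted_percentile(values: np.ndarray, weights: np.ndarray,
                         q: float = 0.5) -> float:
    """Weighted percentile with linear interpolation across cumulative
    weights (midpoint convention: knot j sits at cum_j - w_j/2)."""
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    w = w / w.sum()
    knots = np.cumsum(w) - 0.5 * w
    return float(np.interp(q, knots, v))


def _ratios(h: HarmonizedSet):
    bx, by, sy = h.beta_exposure, h.beta_outcome, h.se_outcome
    if np.any(bx == 0):
        raise ValueError("zero exposure effect encountered; cannot form ratios")
    theta = by / bx
    se_theta = sy / np.abs(bx)
    w = bx * bx / (sy * sy)
    return theta, se_theta, w


def weighted_median(h: HarmonizedSet, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted-median estimator with parametric-bootstrap SE.

    Consistent when SNPs contributing a majority of the inverse-variance
    weight are valid instruments.  The bootstrap resamples each ratio from
    N(theta_j, se_theta_j²) and is deterministic under ``seed``.
    """
    J = len(h)
    if J < 3:
        raise ValueError("weighted median requires at least three SNPs")
    theta, se_theta, w = _ratios(h)
    beta = _weighted_percentile(theta, w, 0.5)
    rng = np.random.default_rng(seed)
    draws = rng.normal(theta, se_theta, size=(n_boot, J))
    boots = np.array([_weighted_percentile(d, w, 0.5) for d in draws])
    return _estimate("weighted_median", beta, boots.std(ddof=1), J)


def _silverman_bandwidth(theta: np.ndarray, w: np.ndarray,
                         factor: float = 1.0) -> float:
    """Modified Silverman rule on weighted ratios: 0.9 min(sd, MAD/0.6745)
    J^(-1/5), with weighted sd and MAD about the weighted median."""
    wm = _weighted_percentile(theta, w, 0.5)
    wn = w / w.sum()
    sd = float(np.sqrt(np.sum(wn * (theta - wm) ** 2)))
    mad = _weighted_percentile(np.abs(theta - wm), w, 0.5) / 0.6745
    s = min(sd, mad) if mad > 0 else sd
    return factor * 0.9 * s * len(theta) ** (-0.2)


def _mode_point(theta: np.ndarray, w: np.ndarray, bandwidth_factor: float,
                grid_size: int = 512) -> float:
    h = _silverman_bandwidth(theta, w, bandwidth_factor)
    if h == 0.0 or np.ptp(theta) == 0.0:
        return float(theta[0])  # all ratios identical
    grid = np.linspace(theta.min() - 3 * h, theta.max() + 3 * h, grid_size)
    z = (grid[:, None] - theta[None, :]) / h
    dens = np.exp(-0.5 * z * z) @ (w / w.sum())
    return float(grid[np.argmax(dens)])  # argmax returns the lowest tied point


def weighted_mode(h: HarmonizedSet, bandwidth_factor: float = 1.0,
                  n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted-mode estimator (kernel-density peak of the ratios).

    Consistent when the largest weight-group of instruments shares the true
    ratio.  Bandwidth is a modified Silverman rule scaled by
    ``bandwidth_factor``; SE by parametric bootstrap as for the median.
    """
    J = len(h)
    if J < 3:
        raise ValueError("weighted mode requires at least three SNPs")
    theta, se_theta, w = _ratios(h)
    beta = _mode_point(theta, w, bandwidth_factor)
    rng = np.random.default_rng(seed)
    draws = rng.normal(theta, se_theta, size=(n_boot, J))
    boots = np.array([_mode_point(d, w, bandwidth_factor) for d in draws])
    return _estimate("weighted_mode", beta, boots.std(ddof=1), J)


@dataclass
class MRResults:
    """Fitted causal estimate plus diagnostics for one method.

    Attributes mirror :class:`MREstimate` (``beta``, ``se``, ``ci_low``,
    ``ci_high``, ``pvalue``, ``or_`` ...) with optional ``heterogeneity``
    and ``pleiotropy`` blocks, a back-reference to the model, and a
    ``summary()`` table.
    """

    estimate: MREstimate
    model: "MRModel" = None
    heterogeneity: HeterogeneityResult | None = None
    pleiotropy: PleiotropyResult | None = None

    def __getattr__(self, name):
        est = object.__getattribute__(self, "estimate")
        if hasattr(est, name):
            return getattr(est, name)
        raise AttributeError(name)

    def conf_int(self) -> tuple[float, float]:
        return self.estimate.ci_low, self.estimate.ci_high

    def summary(self) -> str:
        e = self.estimate
        lines = [
            "Two-sample Mendelian randomization",
            "=" * 50,
            f"Method:       {e.method}",
            f"No. SNPs:     {e.n_snp}",
            f"beta (logOR): {e.beta: .4f}  (SE {e.se:.4f})",
            f"95% CI:       [{e.ci_low: .4f}, {e.ci_high: .4f}]",
            f"OR:           {e.or_:.3f}  (95% CI {e.or_ci_low:.3f}-{e.or_ci_high:.3f})",
            f"p-value:      {e.pvalue:.3g}",
        ]
        if self.heterogeneity is not None:
            het = self.heterogeneity
            lines.append(
                f"Cochran Q:    {het.q:.2f} on {het.df} df (p = {het.pvalue:.3g})"
            )
        if self.pleiotropy is not None:
            pl = self.pleiotropy
            lines.append(
                f"Egger intercept: {pl.intercept: .4g} (SE {pl.se:.3g}, p = {pl.pvalue:.3g})"
            )
        return "\n".join(lines)


class MRModel:
    """Univariable two-sample MR model over a harmonized SNP set.

    Parameters
    ----------
    data : HarmonizedSet
        Exposure/outcome effect pairs on a common effect-allele frame.

    Examples
    --------
    >>> model = MRModel.from_dataframe(df)
    >>> res = model.fit(method="ivw")
    >>> print(res.summary())
    """

    def __init__(self, data: HarmonizedSet):
        self.data = data

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       beta_exposure: str = "beta_exposure",
                       se_exposure: str = "se_exposure",
                       beta_outcome: str = "beta_outcome",
                       se_outcome: str = "se_outcome",
                       snp_id: str | None = "snp_id") -> "MRModel":
        ids = df[snp_id].astype(str).tolist() if snp_id and snp_id in df.columns else None
        h = HarmonizedSet.from_arrays(
            beta_exposure=df[beta_exposure].to_numpy(float),
            se_exposure=df[se_exposure].to_numpy(float),
            beta_outcome=df[beta_outcome].to_numpy(float),
            se_outcome=df[se_outcome].to_numpy(float),
            snp_ids=ids,
        )
        return cls(h)

    @property
    def n_snp(self) -> int:
        return len(self.data)

    def fit(self, method: str = "ivw", ivw_model: str = "multiplicative_random",
            n_boot: int = 1000, seed: int = 0,
            bandwidth_factor: float = 1.0) -> MRResults:
        """Fit one estimator; see the module docstring for the menu
        ("ivw", "egger", "weighted_median", "weighted_mode", "wald")."""
        h = self.data
        if method == "ivw":
            est, het = ivw(h, model=ivw_model)
            return MRResults(estimate=est, model=self, heterogeneity=het)
        if method == "egger":
            est, pleio, het = egger(h)
            return MRResults(estimate=est, model=self, heterogeneity=het,
                             pleiotropy=pleio)
        if method == "weighted_median":
            return MRResults(estimate=weighted_median(h, n_boot, seed), model=self)
        if method == "weighted_mode":
            return MRResults(
                estimate=weighted_mode(h, bandwidth_factor, n_boot, seed),
                model=self)
        if method == "wald":
            if len(h) != 1:
                raise ValueError("wald method applies to a single SNP")
            return MRResults(
                estimate=wald_ratio(h.beta_exposure[0], h.beta_outcome[0],
                                    h.se_outcome[0]),
                model=self)
        raise ValueError(f"unknown method {method!r}")

    def fit_all(self, methods=METHODS, **kwargs) -> dict[str, MRResults]:
        return {m: self.fit(method=m, **kwargs) for m in methods}

    def fit_presso(self, n_sim: int = 1000, outlier_alpha: float = 0.05,
                   seed: int = 0):
        """MR-PRESSO global/outlier/distortion tests; see :mod:`mrkit.presso`."""
        from .presso import presso
        return presso(self.data, n_sim=n_sim, outlier_alpha=outlier_alpha, seed=seed)

    def scatter_data(self) -> pd.DataFrame:
        """Per-SNP effects for scatter plots (bx, sx, by, sy per SNP)."""
        h = self.data
        return pd.DataFrame({
            "snp_id": h.snp_ids,
            "beta_exposure": h.beta_exposure, "se_exposure": h.se_exposure,
            "beta_outcome": h.beta_outcome, "se_outcome": h.se_outcome,
        })
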