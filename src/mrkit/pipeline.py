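"""Study orchestration: exposures x outcomes, FDR control, result tables.

``run_univariable`` loops over every exposure-outcome pair, selects
instruments, harmonizes, runs the enabled estimators plus heterogeneity,
Egger-intercept and MR-PRESSO diagnostics, and applies Benjamini-Hochberg
FDR within each (outcome, method) family across exposures — mirroring the
common forest-plot layout where each method column carries its own FDR.
``run_mvmr`` assembles the combined instrument set and reports per-exposure
direct effects.

Failures are row-level: a pair with zero surviving instruments is flagged
and the study continues.  All randomness derives from one master seed via
``numpy.random.SeedSequence(master, spawn_key=...)``, so reruns with the
same config and seed are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from statsmodels.stats.multitest import multipletests

from . import estimators as est
from .gwas_io import GwasSummary, LDMatrix, read_gwas, read_ld_matrix
from .harmonize import DEFAULT_EAF_BAND, harmonize_all
from .instruments import InstrumentError, InstrumentParams, build_instrument_set
from .mvmr import MVMRModel

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "benjamini_hochberg", "run_univariable", "run_mvmr"]

DEFAULT_METHODS = list(est.METHODS)

RESULT_COLUMNS = [
    "exposure", "outcome", "method", "n_snp", "beta", "se", "ci_low", "ci_high",
    "or", "or_ci_low", "or_ci_high", "pvalue", "fdr_q", "q_stat", "q_pvalue",
    "egger_intercept", "egger_intercept_p", "mean_f", "flags",
]


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Step-up Benjamini-Hochberg q-values, returned in input order.

    q_(i) = min over j >= i of (m p_(j) / j), capped at 1.  All p-values
    must lie in (0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class StudyConfig:
    """Layout and knobs of one study run.

    ``exposures`` / ``outcomes`` are lists of ``(name, summary-file path)``
    pairs (or in-memory :class:`GwasSummary` objects via the ``*_data``
    fields); ``ld_source`` a square/long-format LD TSV.
    """

    exposures: list = field(default_factory=list)    # [(name, path)]
    outcomes: list = field(default_factory=list)     # [(name, path)]
    ld_source: str | None = None
    thresholds: InstrumentParams = field(default_factory=InstrumentParams)
    palindromic_policy: str = "exclude"
    eaf_band: tuple = DEFAULT_EAF_BAND
    methods: list = field(default_factory=lambda: list(DEFAULT_METHODS))
    ivw_model: str = "multiplicative_random"
    run_presso: bool = True
    presso_nsim: int = 1000
    n_boot: int = 1000
    fdr_alpha: float = 0.05
    fdr_family: str = "outcome_method"   # or "pooled"
    seed: int = 0
    output_dir: str | None = None
    # optional in-memory data, bypassing file reads (keyed by name)
    exposure_data: dict = field(default_factory=dict)
    outcome_data: dict = field(default_factory=dict)
    ld_data: LDMatrix | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.fdr_alpha < 1.0):
            raise ValueError("fdr_alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        thr = InstrumentParams(**raw.pop("thresholds", {}))
        raw["exposures"] = [tuple(x) for x in raw.get("exposures", [])]
        raw["outcomes"] = [tuple(x) for x in raw.get("outcomes", [])]
        if "eaf_band" in raw:
            raw["eaf_band"] = tuple(raw["eaf_band"])
        return cls(thresholds=thr, **raw)

    def _load_exposure(self, name: str, path) -> GwasSummary:
        if name in self.exposure_data:
            return self.exposure_data[name]
        return read_gwas(path, trait_meta={"trait_name": name})

    def _load_outcome(self, name: str, path) -> GwasSummary:
        if name in self.outcome_data:
            return self.outcome_data[name]
        return read_gwas(path, trait_meta={"trait_name": name})

    def _load_ld(self) -> LDMatrix:
        if self.ld_data is not None:
            return self.ld_data
        if self.ld_source is None:
            raise ValueError("no LD source configured")
        return read_ld_matrix(self.ld_source)


def _derived_seed(master: int, *key: int) -> int:
    """Child seed from the master seed and a structural key (< 2^31)."""
    ss = np.random.SeedSequence(master, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _format_table(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(lambda x: "" if pd.isna(x) else f"{x:.10g}")
    return out


def _write_outputs(cfg: StudyConfig, table: pd.DataFrame,
                   scatter: dict, exclusions: list, log_lines: list) -> None:
    if cfg.output_dir is None:
        return
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    _format_table(table).to_csv(out / "results.tsv", sep="\t", index=False)
    sdir = out / "scatter"
    sdir.mkdir(exist_ok=True)
    for (exp_name, out_name), df in sorted(scatter.items()):
        _format_table(df).to_csv(sdir / f"{exp_name}_{out_name}.tsv",
                                 sep="\t", index=False)
    pd.DataFrame(exclusions, columns=["exposure", "outcome", "snp_id", "reason"]) \
        .to_csv(out / "exclusions.tsv", sep="\t", index=False)
    (out / "run.log").write_text("\n".join(log_lines) + "\n")


def run_univariable(cfg: StudyConfig) -> pd.DataFrame:
    """Run the univariable study grid; returns the results table.

    One row per (exposure, outcome, method), with heterogeneity, Egger
    intercept and instrument-strength columns repeated per method row and
    MR-PRESSO rows added when enabled.  FDR q-values are assigned within
    each (outcome, method) family across exposures by default.
    """
    ld = cfg._load_ld()
    rows = []
    scatter: dict = {}
    exclusions: list = []
    log_lines = [
        f"seed\t{cfg.seed}",
        f"thresholds\t{cfg.thresholds}",
        f"methods\t{','.join(cfg.methods)}",
        f"palindromic_policy\t{cfg.palindromic_policy}",
        f"fdr_family\t{cfg.fdr_family}",
    ]

    for i, (exp_name, exp_path) in enumerate(cfg.exposures):
        exposure = cfg._load_exposure(exp_name, exp_path)
        for j, (out_name, out_path) in enumerate(cfg.outcomes):
            outcome = cfg._load_outcome(out_name, out_path)
            base = dict(exposure=exp_name, outcome=out_name)
            try:
                iset = build_instrument_set(exposure, outcome, ld, cfg.thresholds)
                h = harmonize_all(iset, outcome, policy=cfg.palindromic_policy,
                                  eaf_band=cfg.eaf_band)
            except (InstrumentError, ValueError) as exc:
                logger.warning("pair (%s, %s) failed: %s", exp_name, out_name, exc)
                rows.append({**base, "method": "none", "flags": f"failed:{exc}"})
                continue
            for excl in h.exclusions:
                exclusions.append((exp_name, out_name, excl.snp_id, excl.reason))
            model = est.MRModel(h)
            scatter[(exp_name, out_name)] = model.scatter_data()

            het = pleio = None
            for m_idx, method in enumerate(cfg.methods):
                seed = _derived_seed(cfg.seed, i, j, m_idx)
                try:
                    res = model.fit(method=method, ivw_model=cfg.ivw_model,
                                    n_boot=cfg.n_boot, seed=seed)
                except ValueError as exc:
                    rows.append({**base, "method": method,
                                 "flags": f"failed:{exc}"})
                    continue
                if res.heterogeneity is not None and method == "ivw":
                    het = res.heterogeneity
                if res.pleiotropy is not None:
                    pleio = res.pleiotropy
                rows.append({
                    **base, "method": res.method, "n_snp": res.n_snp,
                    "beta": res.beta, "se": res.se,
                    "ci_low": res.ci_low, "ci_high": res.ci_high,
                    "or": res.or_, "or_ci_low": res.or_ci_low,
                    "or_ci_high": res.or_ci_high, "pvalue": res.pvalue,
                    "q_stat": res.heterogeneity.q if res.heterogeneity else np.nan,
                    "q_pvalue": res.heterogeneity.pvalue if res.heterogeneity else np.nan,
                    "egger_intercept": res.pleiotropy.intercept if res.pleiotropy else np.nan,
                    "egger_intercept_p": res.pleiotropy.pvalue if res.pleiotropy else np.nan,
                    "mean_f": iset.mean_f, "flags": "",
                })
            if cfg.run_presso and len(h) >= 4:
                seed = _derived_seed(cfg.seed, i, j, 1000)
                pr = model.fit_presso(n_sim=cfg.presso_nsim, seed=seed)
                rows.append({
                    **base, "method": "mr_presso", "n_snp": pr.n_snp,
                    "beta": pr.beta_corrected if pr.beta_corrected is not None
                            else pr.beta_raw,
                    "pvalue": pr.global_pvalue, "mean_f": iset.mean_f,
                    "flags": f"outliers:{len(pr.outlier_indices)}",
                })

    table = pd.DataFrame(rows)
    for col in RESULT_COLUMNS:
        if col not in table.columns:
            table[col] = np.nan
    table = table[RESULT_COLUMNS]

    # FDR within each family; mr_presso global p is a diagnostic, not an
    # effect test, and is left out of the FDR families
    table["fdr_q"] = np.nan
    estimate_rows = table["method"].isin(
        {"ivw_fixed", "ivw_mre", "egger", "weighted_median", "weighted_mode", "wald"}
    ) & table["pvalue"].notna()
    if cfg.fdr_family == "pooled":
        groups = [table.index[estimate_rows]]
    else:
        groups = [idx for _, idx in
                  table.index[estimate_rows].to_series()
                  .groupby([table.loc[estimate_rows, "outcome"],
                            table.loc[estimate_rows, "method"]]).groups.items()]
        groups = [pd.Index(g) for g in groups]
    for idx in groups:
        if len(idx):
            table.loc[idx, "fdr_q"] = benjamini_hochberg(table.loc[idx, "pvalue"])

    _write_outputs(cfg, table, scatter, exclusions, log_lines)
    return table


def run_mvmr(cfg: StudyConfig, covariates: list | None = None) -> pd.DataFrame:
    """Run MVMR of all configured exposures on each outcome.

    ``covariates`` is an optional list of ``(name, path)`` pairs (or names
    resolved through ``cfg.exposure_data``) whose traits extend the
    exposure matrix.  Returns one row per exposure per outcome with the
    combined instrument count, FDR-adjusted within each outcome.
    """
    ld = cfg._load_ld()
    exposures = [cfg._load_exposure(n, p) for n, p in cfg.exposures]
    covs = [cfg._load_exposure(n, p) for n, p in (covariates or [])]
    rows = []
    for out_name, out_path in cfg.outcomes:
        outcome = cfg._load_outcome(out_name, out_path)
        model = MVMRModel.from_gwas(
            exposures, outcome, ld, cfg.thresholds,
            covariates=covs or None,
            policy=cfg.palindromic_policy, eaf_band=cfg.eaf_band,
        )
        res = model.fit()
        logger.info("MVMR on %s: J = %d combined instruments", out_name, res.n_snp)
        df = res.to_dataframe()
        df.insert(1, "outcome", out_name)
        df["fdr_q"] = benjamini_hochberg(df["pvalue"])
        rows.append(df)
    table = pd.concat(rows, ignore_index=True)
    if cfg.output_dir is not None:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        _format_table(table).to_csv(out / "mvmr_results.tsv", sep="\t", index=False)
    return table
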