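"""Shared helpers for the test suite: small synthetic datasets with known
truth, built through the package's own generator."""

from __future__ import annotations

import numpy as np
import pandas as pd
from hypothesis import HealthCheck, settings

import mrkit as mk
from mrkit.gwas_io import GwasSummary

settings.register_profile(
    "det", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


def h_from(exposure: GwasSummary, outcome: GwasSummary) -> mk.HarmonizedSet:
    """Harmonized set straight from paired simulated summaries (shared
    variants and allele frames, so no harmonization is needed)."""
    return mk.HarmonizedSet.from_arrays(
        beta_exposure=exposure.variants["beta"].to_numpy(),
        se_exposure=exposure.variants["se"].to_numpy(),
        beta_outcome=outcome.variants["beta"].to_numpy(),
        se_outcome=outcome.variants["se"].to_numpy(),
        snp_ids=list(exposure.variants.index),
    )


def simulate_h(seed: int, causal_effect: float = 0.0, n_snps: int = 100,
               **kwargs) -> mk.HarmonizedSet:
    cfg = mk.SimulationConfig(causal_effect=causal_effect, n_snps=n_snps,
                              seed=seed, **kwargs)
    exposure, outcome, _ = mk.simulate_two_sample(cfg)
    return h_from(exposure, outcome)


def two_exposure_study(seed: int, beta_true: float = 0.25):
    """One causal and one null exposure against a combined outcome, with
    disjoint SNP sets and an identity LD matrix."""
    cfg_a = mk.SimulationConfig(causal_effect=beta_true, n_snps=100, seed=seed)
    cfg_b = mk.SimulationConfig(causal_effect=0.0, n_snps=100, seed=seed + 50_000)
    exp_a, out_a, _ = mk.simulate_two_sample(cfg_a)
    exp_b, out_b, _ = mk.simulate_two_sample(cfg_b)
    for g in (exp_b, out_b):
        df = g.variants.copy()
        df["snp_id"] = ["rsB" + s[2:] for s in df["snp_id"]]
        df["pos"] = df["pos"] + 10_000_000
        g.variants = df.set_index("snp_id", drop=False)
    outcome = GwasSummary(
        trait_name="outcome", trait_type="binary",
        n_total=out_a.n_total, n_cases=out_a.n_cases,
        variants=pd.concat([out_a.variants, out_b.variants]),
    )
    ids = list(exp_a.variants.index) + list(exp_b.variants.index)
    ld = mk.LDMatrix(snp_ids=ids, r2=np.eye(len(ids)))
    return exp_a, exp_b, outcome, ld


def study_config(exp_a, exp_b, outcome, ld, **kwargs) -> mk.StudyConfig:
    defaults = dict(
        exposures=[("expA", None), ("expB", None)],
        outcomes=[("lc", None)],
        exposure_data={"expA": exp_a, "expB": exp_b},
        outcome_data={"lc": outcome},
        ld_data=ld, seed=0, n_boot=100, presso_nsim=200,
    )
    defaults.update(kwargs)
    return mk.StudyConfig(**defaults)
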