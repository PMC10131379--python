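"""Instrument selection: thresholds, clumping, proxies, strength metrics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import mrkit as mk
from mrkit.gwas_io import GwasSummary, LDMatrix, VariantAssociation
from mrkit.instruments import InstrumentError, WeakInstrumentWarning

import pandas as pd


def va(snp_id, pvalue=1e-9, chrom="1", pos=100, eaf=0.3, beta=0.05,
       se=0.005, ea="A", oa="G", n=100_000):
    return VariantAssociation(snp_id=snp_id, chrom=chrom, pos=pos,
                              effect_allele=ea, other_allele=oa, eaf=eaf,
                              beta=beta, se=se, pvalue=pvalue, n=n)


def gwas_of(variants, trait_name="exp", n_total=100_000):
    df = pd.DataFrame([v.__dict__ for v in variants])
    return GwasSummary(trait_name=trait_name, trait_type="quantitative",
                       n_total=n_total, variants=df)


def ld_of(pairs, snp_ids):
    idx = {s: i for i, s in enumerate(snp_ids)}
    r2 = np.eye(len(snp_ids))
    for a, b, v in pairs:
        r2[idx[a], idx[b]] = r2[idx[b], idx[a]] = v
    return LDMatrix(snp_ids=list(snp_ids), r2=r2)


class TestSelectGenomeWide:
    def test_threshold_is_strict(self):
        g = gwas_of([va("a", 4.9e-8), va("b", 5e-8), va("c", 1e-9)])
        kept = mk.select_genome_wide(g)
        assert sorted(v.snp_id for v in kept) == ["a", "c"]

    def test_no_significant_variant_gives_empty_list(self):
        g = gwas_of([va("a", 0.5), va("b", 0.5)])
        assert mk.select_genome_wide(g) == []

    def test_matches_brute_force_on_simulation(self):
        cfg = mk.SimulationConfig(n_snps=200, gamma_dist=("normal", 0, 0.03), seed=1)
        g, _, _ = mk.simulate_two_sample(cfg)
        kept = {v.snp_id for v in mk.select_genome_wide(g)}
        brute = {v.snp_id for v in g.iter_variants() if v.pvalue < 5e-8}
        assert kept == brute


class TestClump:
    def test_lower_p_snp_retained_in_ld_pair(self):
        a, b = va("a", 1e-10, pos=100), va("b", 1e-9, pos=1100)
        ld = ld_of([("a", "b", 0.5)], ["a", "b"])
        kept = mk.clump([a, b], ld, 0.01, 10_000)
        assert [v.snp_id for v in kept] == ["a"]

    def test_pair_outside_window_both_kept(self):
        a, b = va("a", 1e-10, pos=100), va("b", 1e-9, pos=100 + 20_000_000_0)
        ld = ld_of([("a", "b", 0.5)], ["a", "b"])
        kept = mk.clump([a, b], ld, 0.01, 10_000)
        assert len(kept) == 2

    def test_r2_below_threshold_both_kept(self):
        a, b = va("a", 1e-10, pos=100), va("b", 1e-9, pos=1100)
        ld = ld_of([("a", "b", 0.009)], ["a", "b"])
        assert len(mk.clump([a, b], ld, 0.01, 10_000)) == 2

    @staticmethod
    def _brute_force(cands, ld, r2_thr, window_kb):
        """Independent reference: repeatedly scan the full list for the
        best remaining candidate, then mark its LD neighbours removed."""
        half = window_kb * 1000 / 2
        alive = {v.snp_id: v for v in cands}
        out = []
        while alive:
            best = min(alive.values(), key=lambda v: (v.pvalue, v.snp_id))
            out.append(best.snp_id)
            del alive[best.snp_id]
            for s in list(alive):
                v = alive[s]
                if (v.chrom == best.chrom and abs(v.pos - best.pos) <= half
                        and ld.get(best.snp_id, v.snp_id) >= r2_thr):
                    del alive[s]
        return out

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        ids = [f"s{i}" for i in range(n)]
        cands = [va(ids[i], pvalue=float(rng.uniform(1e-12, 1e-6)),
                    chrom=str(rng.integers(1, 3)),
                    pos=int(rng.integers(1, 5_000_000))) for i in range(n)]
        raw = rng.uniform(0, 1, (n, n)) * (rng.random((n, n)) < 0.2)
        r2 = np.triu(raw, 1)
        r2 = r2 + r2.T
        np.fill_diagonal(r2, 1.0)
        ld = LDMatrix(snp_ids=ids, r2=r2)
        kept = [v.snp_id for v in mk.clump(cands, ld, 0.1, 2000)]
        assert kept == self._brute_force(cands, ld, 0.1, 2000)

    def test_output_pairwise_r2_compatible(self):
        rng = np.random.default_rng(11)
        n = 40
        ids = [f"s{i}" for i in range(n)]
        cands = [va(ids[i], pvalue=float(rng.uniform(1e-12, 1e-6)), chrom="1",
                    pos=int(rng.integers(1, 500_000))) for i in range(n)]
        raw = np.triu(rng.uniform(0, 1, (n, n)), 1)
        r2 = raw + raw.T
        np.fill_diagonal(r2, 1.0)
        ld = LDMatrix(snp_ids=ids, r2=r2)
        kept = mk.clump(cands, ld, 0.3, 10_000)
        for i, u in enumerate(kept):
            for w in kept[i + 1:]:
                if u.chrom == w.chrom and abs(u.pos - w.pos) <= 5_000_000:
                    assert ld.get(u.snp_id, w.snp_id) < 0.3


class TestFilterMaf:
    def test_high_eaf_removed_boundary_kept(self):
        kept = mk.filter_maf([va("a", eaf=0.995), va("b", eaf=0.01),
                              va("c", eaf=0.5)], 0.01)
        assert sorted(v.snp_id for v in kept) == ["b", "c"]

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        cands = [va(f"s{i}", eaf=float(rng.uniform(0, 1))) for i in range(100)]
        kept = {v.snp_id for v in mk.filter_maf(cands, 0.01)}
        brute = {v.snp_id for v in cands if min(v.eaf, 1 - v.eaf) >= 0.01}
        assert kept == brute


class TestFindProxy:
    def _outcome(self):
        return gwas_of([va("p1", 0.5), va("p2", 0.2), va("p3", 0.2)], "out")

    def test_highest_r2_proxy_returned(self):
        ld = ld_of([("q", "p1", 0.85), ("q", "p2", 0.95)],
                   ["q", "p1", "p2", "p3"])
        proxy = mk.find_proxy("q", self._outcome(), ld)
        assert proxy.snp_id == "p2"

    def test_r2_bound_is_strict(self):
        ld = ld_of([("q", "p1", 0.8)], ["q", "p1", "p2", "p3"])
        assert mk.find_proxy("q", self._outcome(), ld, 0.8) is None

    def test_no_candidate_in_ld_gives_none(self):
        ld = ld_of([], ["q", "p1", "p2", "p3"])
        assert mk.find_proxy("q", self._outcome(), ld) is None

    def test_unknown_snp_gives_none(self):
        ld = ld_of([], ["p1", "p2", "p3"])
        assert mk.find_proxy("not_there", self._outcome(), ld) is None

    def test_r2_tie_broken_by_pvalue(self):
        ld = ld_of([("q", "p1", 0.9), ("q", "p2", 0.9)],
                   ["q", "p1", "p2", "p3"])
        assert mk.find_proxy("q", self._outcome(), ld).snp_id == "p2"


class TestStrengthFormulas:
    def test_variance_explained_oracle(self):
        assert mk.variance_explained(0.1, 0.5) == pytest.approx(0.005, rel=1e-12)
        assert mk.variance_explained(0.0, 0.3) == 0.0
        assert mk.variance_explained(0.2, 0.0) == 0.0
        assert mk.variance_explained(0.2, 1.0) == 0.0

    @given(beta=st.floats(-1, 1), eaf=st.floats(0, 1))
    def test_variance_explained_matches_direct_arithmetic(self, beta, eaf):
        assert mk.variance_explained(beta, eaf) == pytest.approx(
            2 * beta ** 2 * eaf * (1 - eaf), rel=1e-12, abs=1e-300)

    def test_f_statistic_oracle(self):
        assert mk.f_statistic(0.0, 100, 1) == 0.0
        assert mk.f_statistic(0.005, 100_000, 1) == pytest.approx(
            0.005 * 99_998 / 0.995, rel=1e-12)

    @given(st.floats(1e-6, 0.5), st.floats(1e-6, 0.5))
    def test_f_statistic_monotone_in_r2(self, a, b):
        if a == b:
            return
        lo, hi = sorted((a, b))
        assert mk.f_statistic(lo, 1000, 3) < mk.f_statistic(hi, 1000, 3)

    @pytest.mark.parametrize("r2,n,k", [(1.0, 100, 1), (0.5, 3, 2), (0.1, 10, 0)])
    def test_f_statistic_domain_errors(self, r2, n, k):
        with pytest.raises(ValueError):
            mk.f_statistic(r2, n, k)


class TestBuildInstrumentSet:
    def _inputs(self, seed=1, **kw):
        cfg = mk.SimulationConfig(causal_effect=0.1, n_snps=150, seed=seed, **kw)
        exposure, outcome, _ = mk.simulate_two_sample(cfg)
        ld = LDMatrix(snp_ids=list(exposure.variants.index),
                      r2=np.eye(len(exposure.variants)))
        return exposure, outcome, ld

    def test_strong_instruments_no_warning(self, recwarn):
        exposure, outcome, ld = self._inputs()
        iset = mk.build_instrument_set(exposure, outcome, ld)
        assert iset.mean_f > 10
        assert not any(isinstance(w.message, WeakInstrumentWarning)
                       for w in recwarn.list)
        assert set(iset.snp_ids) <= set(exposure.snp_ids)
        assert iset.k == len(iset.snps)
        assert iset.total_r2 == pytest.approx(iset.per_snp_r2.sum())

    def test_weak_instruments_warn(self):
        exposure, outcome, ld = self._inputs(
            gamma_dist=("signed_uniform", 0.001, 0.002), n_exposure=200_000)
        # force tiny-effect SNPs through the significance filter
        params = mk.InstrumentParams(p_threshold=1.0)
        with pytest.warns(WeakInstrumentWarning):
            mk.build_instrument_set(exposure, outcome, ld, params)

    def test_zero_survivors_is_hard_error(self):
        exposure, outcome, ld = self._inputs()
        params = mk.InstrumentParams(p_threshold=1e-300)
        with pytest.raises(InstrumentError):
            mk.build_instrument_set(exposure, outcome, ld, params)

    def test_maf_and_clump_commute_when_disjoint(self):
        # fixture where no SNP is hit by both filters
        a = va("a", 1e-10, pos=100, eaf=0.3)
        b = va("b", 1e-9, pos=1100, eaf=0.4)       # clumped away against a
        c = va("c", 1e-9, pos=90_000_000, eaf=0.995)  # MAF-filtered
        ld = ld_of([("a", "b", 0.5)], ["a", "b", "c"])
        one = mk.filter_maf(mk.clump([a, b, c], ld, 0.01, 10_000), 0.01)
        other = mk.clump(mk.filter_maf([a, b, c], 0.01), ld, 0.01, 10_000)
        assert [v.snp_id for v in one] == [v.snp_id for v in other] == ["a"]

    def test_proxy_substitution(self):
        exp = gwas_of([va("q", 1e-9, eaf=0.3)])
        outcome = gwas_of([va("p1", 0.5, eaf=0.31)], "out")
        ld = ld_of([("q", "p1", 0.95)], ["q", "p1"])
        iset = mk.build_instrument_set(exp, outcome, ld)
        assert iset.outcome_snp_id["q"] == "p1"
        assert iset.proxy_used("q")

    def test_eaf_inconsistent_proxy_dropped(self):
        exp = gwas_of([va("q", 1e-9, eaf=0.1)])
        outcome = gwas_of([va("p1", 0.5, eaf=0.9)], "out")
        ld = ld_of([("q", "p1", 0.95)], ["q", "p1"])
        with pytest.raises(InstrumentError):
            mk.build_instrument_set(exp, outcome, ld)
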