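"""Allele harmonization: flips, strand repair, palindromic policies,
and the downstream allele-coding invariance."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import mrkit as mk
from mrkit.harmonize import Exclusion, HarmonizationError, HarmonizedRecord
from mrkit.gwas_io import VariantAssociation

from conftest import h_from

from test_instruments import gwas_of, ld_of, va


class TestIsPalindromic:
    @pytest.mark.parametrize("a1,a2,expected", [
        ("A", "T", True), ("T", "A", True), ("C", "G", True), ("G", "C", True),
        ("A", "G", False), ("A", "C", False), ("G", "T", False),
    ])
    def test_truth_table(self, a1, a2, expected):
        assert mk.is_palindromic(a1, a2) is expected


class TestHarmonizePair:
    def test_identical_alleles_pass_through(self):
        rec = mk.harmonize_pair(va("s", ea="A", oa="G", beta=0.1),
                                va("s", ea="A", oa="G", beta=-0.05))
        assert rec.beta_outcome == -0.05 and not rec.flags

    def test_swapped_alleles_flip_sign_and_eaf(self):
        rec = mk.harmonize_pair(va("s", ea="A", oa="G", beta=0.1),
                                va("s", ea="G", oa="A", beta=-0.05, eaf=0.7))
        assert rec.beta_outcome == 0.05
        assert rec.eaf_outcome == pytest.approx(0.3)
        assert "allele_flipped" in rec.flags

    def test_strand_complement_repair(self):
        # outcome reported on the opposite strand: A/G vs T/C
        rec = mk.harmonize_pair(va("s", ea="A", oa="G", beta=0.1),
                                va("s", ea="T", oa="C", beta=0.04))
        assert rec.beta_outcome == 0.04 and not rec.flags

    def test_strand_complement_plus_swap_flips(self):
        rec = mk.harmonize_pair(va("s", ea="A", oa="G", beta=0.1),
                                va("s", ea="C", oa="T", beta=0.04))
        assert rec.beta_outcome == -0.04
        assert "allele_flipped" in rec.flags

    def test_unconcordant_alleles_excluded(self):
        res = mk.harmonize_pair(va("s", ea="A", oa="G"),
                                va("s", ea="A", oa="C"))
        assert isinstance(res, Exclusion) and res.reason == "excluded_ambiguous"

    def test_palindromic_excluded_by_default(self):
        res = mk.harmonize_pair(va("s", ea="A", oa="T", eaf=0.2),
                                va("s", ea="A", oa="T", eaf=0.2))
        assert isinstance(res, Exclusion)

    def test_palindromic_ambiguous_eaf_dropped_under_infer(self):
        res = mk.harmonize_pair(va("s", ea="A", oa="T", eaf=0.50),
                                va("s", ea="A", oa="T", eaf=0.2),
                                policy="infer_by_eaf")
        assert isinstance(res, Exclusion)

    def test_palindromic_inferred_keeps_orientation_when_eafs_agree(self):
        rec = mk.harmonize_pair(va("s", ea="A", oa="T", eaf=0.2),
                                va("s", ea="A", oa="T", eaf=0.25, beta=0.04),
                                policy="infer_by_eaf")
        assert rec.beta_outcome == 0.04
        assert "palindromic_inferred" in rec.flags

    def test_palindromic_inferred_flips_when_eafs_disagree(self):
        rec = mk.harmonize_pair(va("s", ea="A", oa="T", eaf=0.2),
                                va("s", ea="A", oa="T", eaf=0.75, beta=0.04),
                                policy="infer_by_eaf")
        assert rec.beta_outcome == -0.04
        assert rec.eaf_outcome == pytest.approx(0.25)

    @given(
        exp_pair=st.sampled_from([("A", "G"), ("C", "T"), ("A", "T"), ("C", "G")]),
        out_pair=st.sampled_from([("A", "G"), ("G", "A"), ("T", "C"), ("C", "T"),
                                  ("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]),
        eaf_exp=st.floats(0.05, 0.95),
        eaf_out=st.floats(0.05, 0.95),
        policy=st.sampled_from(["exclude", "infer_by_eaf"]),
    )
    def test_idempotent_on_own_output(self, exp_pair, out_pair, eaf_exp,
                                      eaf_out, policy):
        exp = va("s", ea=exp_pair[0], oa=exp_pair[1], eaf=eaf_exp, beta=0.1)
        out = va("s", ea=out_pair[0], oa=out_pair[1], eaf=eaf_out, beta=0.03)
        first = mk.harmonize_pair(exp, out, policy=policy)
        if isinstance(first, Exclusion):
            return
        again = mk.harmonize_pair(exp, first.outcome_as_variant(exp), policy=policy)
        assert isinstance(again, HarmonizedRecord)
        assert again.beta_outcome == pytest.approx(first.beta_outcome, rel=1e-15)
        assert again.eaf_outcome == pytest.approx(first.eaf_outcome, rel=1e-15)

    def test_snp_id_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mk.harmonize_pair(va("s1"), va("s2"))


def _mismatch_fixture():
    """3 instruments whose outcome records have swapped alleles, 2
    palindromic instruments, 2 clean ones."""
    exp_vars, out_vars = [], []
    specs = [("f1", "flip"), ("f2", "flip"), ("f3", "flip"),
             ("p1", "palindromic"), ("p2", "palindromic"),
             ("c1", "clean"), ("c2", "clean")]
    for i, (sid, kind) in enumerate(specs):
        if kind == "palindromic":
            ea, oa = "A", "T"
            exp_vars.append(va(sid, ea=ea, oa=oa, pos=100 + i, eaf=0.2))
            out_vars.append(va(sid, ea=ea, oa=oa, pos=100 + i, eaf=0.2, beta=0.03))
        elif kind == "flip":
            exp_vars.append(va(sid, ea="A", oa="G", pos=100 + i))
            out_vars.append(va(sid, ea="G", oa="A", pos=100 + i, beta=0.03, eaf=0.7))
        else:
            exp_vars.append(va(sid, ea="A", oa="G", pos=100 + i))
            out_vars.append(va(sid, ea="A", oa="G", pos=100 + i, beta=0.03))
    exposure = gwas_of(exp_vars)
    outcome = gwas_of(out_vars, "out")
    ld = ld_of([], [v.snp_id for v in exp_vars])
    return mk.build_instrument_set(exposure, outcome, ld), outcome


class TestHarmonizeAll:
    def test_clean_set_passes_through(self):
        cfg = mk.SimulationConfig(n_snps=50, palindromic_fraction=0.0, seed=2)
        exposure, outcome, _ = mk.simulate_two_sample(cfg)
        ld = mk.LDMatrix(snp_ids=list(exposure.variants.index), r2=np.eye(50))
        iset = mk.build_instrument_set(
            exposure, outcome, ld, mk.InstrumentParams(p_threshold=1.0))
        h = mk.harmonize_all(iset, outcome)
        order = np.argsort(exposure.variants.index)
        np.testing.assert_allclose(
            h.beta_outcome, outcome.variants["beta"].to_numpy()[order])

    def test_flips_and_palindromic_exclusions_counted(self):
        iset, outcome = _mismatch_fixture()
        h = mk.harmonize_all(iset, outcome, policy="exclude")
        assert len(h) == 5                      # 2 palindromic excluded
        assert len(h.exclusions) == 2
        flipped = [s for s, f in h.flags.items() if "allele_flipped" in f]
        assert sorted(flipped) == ["f1", "f2", "f3"]
        for sid in flipped:
            i = h.snp_ids.index(sid)
            assert h.beta_outcome[i] == -0.03

    def test_all_excluded_raises(self):
        exp = gwas_of([va("p1", ea="A", oa="T", eaf=0.5, pos=1)])
        out = gwas_of([va("p1", ea="A", oa="T", eaf=0.5, pos=1)], "out")
        iset = mk.build_instrument_set(exp, out, ld_of([], ["p1"]))
        with pytest.raises(HarmonizationError):
            mk.harmonize_all(iset, out, policy="exclude")

    def test_band_tightening_is_monotone(self):
        iset, outcome = _mismatch_fixture()
        narrow = mk.harmonize_all(iset, outcome, policy="infer_by_eaf",
                                  eaf_band=(0.48, 0.52))
        wide = mk.harmonize_all(iset, outcome, policy="infer_by_eaf",
                                eaf_band=(0.1, 0.9))
        assert len(wide.exclusions) >= len(narrow.exclusions)


class TestAlleleCodingInvariance:
    def test_downstream_estimates_invariant_to_recoding(self):
        """Swapping effect/other allele (with beta negation and EAF
        complement) in the outcome file must leave every estimator's
        result unchanged to 1e-12."""
        cfg = mk.SimulationConfig(causal_effect=0.2, n_snps=60,
                                  palindromic_fraction=0.0, seed=8)
        exposure, outcome, _ = mk.simulate_two_sample(cfg)
        ld = mk.LDMatrix(snp_ids=list(exposure.variants.index), r2=np.eye(60))
        params = mk.InstrumentParams(p_threshold=1.0)

        recoded_df = outcome.variants.copy()
        flip = np.arange(len(recoded_df)) % 2 == 0
        recoded_df.loc[flip, ["effect_allele", "other_allele"]] = \
            recoded_df.loc[flip, ["other_allele", "effect_allele"]].to_numpy()
        recoded_df.loc[flip, "beta"] = -recoded_df.loc[flip, "beta"]
        recoded_df.loc[flip, "eaf"] = 1.0 - recoded_df.loc[flip, "eaf"]
        recoded = mk.GwasSummary(trait_name="out", trait_type="binary",
                                 n_total=outcome.n_total,
                                 n_cases=outcome.n_cases, variants=recoded_df)

        res_a, res_b = [], []
        for out_g in (outcome, recoded):
            iset = mk.build_instrument_set(exposure, out_g, ld, params)
            h = mk.harmonize_all(iset, out_g)
            model = mk.MRModel(h)
            vals = [model.fit("ivw").beta, model.fit("egger").beta,
                    model.fit("weighted_median", n_boot=50, seed=0).beta,
                    model.fit("weighted_mode", n_boot=50, seed=0).beta]
            (res_a if out_g is outcome else res_b).extend(vals)
        np.testing.assert_allclose(res_a, res_b, rtol=1e-12, atol=1e-14)
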