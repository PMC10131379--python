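"""Allele harmonization: place exposure and outcome effects on one frame.

Summary files from different arrays may report a variant on either strand
and with either allele as the effect allele.  Harmonization rewrites the
outcome association onto the exposure's effect-allele frame: swapped alleles
negate the outcome beta (and complement the EAF); alleles that only match
after strand complementing are complemented first.  Palindromic variants
(A/T or C/G) cannot be resolved from alleles alone; they are excluded by
default, or oriented by allele-frequency agreement under the ``infer_by_eaf``
policy unless either EAF falls in the ambiguity band around 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .gwas_io import GwasSummary, VariantAssociation
from .instruments import InstrumentSet

logger = logging.getLogger(__name__)

__all__ = ["HarmonizedSet", "is_palindromic", "harmonize_pair", "harmonize_all",
           "HarmonizationError"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
DEFAULT_EAF_BAND = (0.42, 0.58)


class HarmonizationError(ValueError):
    pass


def is_palindromic(a1: str, a2: str) -> bool:
    """True iff the allele pair is strand-ambiguous ({A,T} or {C,G})."""
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


@dataclass(frozen=True)
class HarmonizedRecord:
    snp_id: str
    beta_exposure: float
    se_exposure: float
    eaf_exposure: float
    beta_outcome: float
    se_outcome: float
    eaf_outcome: float
    flags: frozenset

    def outcome_as_variant(self, template: VariantAssociation) -> VariantAssociation:
        """The harmonized outcome record expressed on the exposure frame."""
        return replace(
            template,
            beta=self.beta_outcome, se=self.se_outcome, eaf=self.eaf_outcome,
        )


@dataclass(frozen=True)
class Exclusion:
    snp_id: str
    reason: str


def harmonize_pair(
    exp: VariantAssociation,
    out: VariantAssociation,
    policy: str = "exclude",
    eaf_band: tuple = DEFAULT_EAF_BAND,
    allow_proxy: bool = False,
) -> HarmonizedRecord | Exclusion:
    """Harmonize one outcome association onto the exposure's allele frame.

    ``policy`` governs palindromic variants: ``"exclude"`` drops them;
    ``"infer_by_eaf"`` orients by EAF agreement, dropping the variant if
    either trait's EAF lies inside ``eaf_band``.  Non-palindromic variants
    are passed through, sign-flipped (swapped alleles), strand-complemented,
    or excluded as unconcordant.  Idempotent on its own output.  Differing
    snp_ids are a usage error unless ``allow_proxy`` marks the outcome
    record as a proxy-mapped substitute.
    """
    if policy not in ("exclude", "infer_by_eaf"):
        raise ValueError(f"unknown palindromic policy {policy!r}")
    if exp.snp_id != out.snp_id and not allow_proxy:
        raise ValueError(
            f"snp_id mismatch: {exp.snp_id} vs {out.snp_id} (pass "
            "allow_proxy=True for proxy-mapped records)")

    exp_pair = (exp.effect_allele, exp.other_allele)
    out_pair = (out.effect_allele, out.other_allele)

    if is_palindromic(*exp_pair):
        if set(out_pair) != set(exp_pair):
            return Exclusion(exp.snp_id, "excluded_ambiguous")
        if policy == "exclude":
            return Exclusion(exp.snp_id, "excluded_ambiguous")
        lo, hi = eaf_band
        if lo <= exp.eaf <= hi or lo <= out.eaf <= hi:
            return Exclusion(exp.snp_id, "excluded_ambiguous")
        # letter-based alignment first, then flip again if the EAFs sit on
        # opposite sides of 0.5 (interpreted as a strand flip)
        flipped = out_pair != exp_pair
        aligned_eaf = 1.0 - out.eaf if flipped else out.eaf
        strand_flip = (aligned_eaf < 0.5) != (exp.eaf < 0.5)
        net_flip = flipped ^ strand_flip
        flags = {"palindromic", "palindromic_inferred"}
        if net_flip:
            flags.add("allele_flipped")
        beta = -out.beta if net_flip else out.beta
        eaf = 1.0 - out.eaf if net_flip else out.eaf
        return HarmonizedRecord(
            snp_id=exp.snp_id, beta_exposure=exp.beta, se_exposure=exp.se,
            eaf_exposure=exp.eaf, beta_outcome=beta, se_outcome=out.se,
            eaf_outcome=eaf, flags=frozenset(flags),
        )

    def _match(pair):
        if pair == exp_pair:
            return False
        if pair == (exp_pair[1], exp_pair[0]):
            return True
        return None

    flip = _match(out_pair)
    if flip is None:
        comp_pair = (_COMPLEMENT[out_pair[0]], _COMPLEMENT[out_pair[1]])
        flip = _match(comp_pair)
        if flip is None:
            return Exclusion(exp.snp_id, "excluded_ambiguous")
    flags = {"allele_flipped"} if flip else set()
    beta = -out.beta if flip else out.beta
    eaf = 1.0 - out.eaf if flip else out.eaf
    return HarmonizedRecord(
        snp_id=exp.snp_id, beta_exposure=exp.beta, se_exposure=exp.se,
        eaf_exposure=exp.eaf, beta_outcome=beta, se_outcome=out.se,
        eaf_outcome=eaf, flags=frozenset(flags),
    )


@dataclass
class HarmonizedSet:
    """Exposure/outcome effect pairs on a common effect-allele frame.

    Vectors are aligned and ordered by ``snp_ids``; excluded SNPs are absent
    from the vectors, recorded in ``exclusions`` as (snp_id, reason).
    """

    snp_ids: list[str]
    beta_exposure: np.ndarray
    se_exposure: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    eaf_exposure: np.ndarray
    flags: dict          # snp_id -> frozenset of flags
    exclusions: list     # list of Exclusion

    def __post_init__(self) -> None:
        self.beta_exposure = np.asarray(self.beta_exposure, dtype=float)
        self.se_exposure = np.asarray(self.se_exposure, dtype=float)
        self.beta_outcome = np.asarray(self.beta_outcome, dtype=float)
        self.se_outcome = np.asarray(self.se_outcome, dtype=float)
        self.eaf_exposure = np.asarray(self.eaf_exposure, dtype=float)
        n = len(self.snp_ids)
        for v in (self.beta_exposure, self.se_exposure, self.beta_outcome,
                  self.se_outcome, self.eaf_exposure):
            if len(v) != n:
                raise ValueError("harmonized vectors must share length with snp_ids")

    def __len__(self) -> int:
        return len(self.snp_ids)

    @classmethod
    def from_arrays(cls, beta_exposure, se_exposure, beta_outcome, se_outcome,
                    snp_ids=None, eaf_exposure=None) -> "HarmonizedSet":
        n = len(beta_exposure)
        if snp_ids is None:
            snp_ids = [f"snp{i + 1}" for i in range(n)]
        if eaf_exposure is None:
            eaf_exposure = np.full(n, np.nan)
        return cls(
            snp_ids=list(snp_ids), beta_exposure=beta_exposure,
            se_exposure=se_exposure, beta_outcome=beta_outcome,
            se_outcome=se_outcome, eaf_exposure=eaf_exposure,
            flags={}, exclusions=[],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "snp_id": self.snp_ids,
            "beta_exposure": self.beta_exposure,
            "se_exposure": self.se_exposure,
            "beta_outcome": self.beta_outcome,
            "se_outcome": self.se_outcome,
            "eaf_exposure": self.eaf_exposure,
            "flags": [",".join(sorted(self.flags.get(s, ()))) for s in self.snp_ids],
        })

    def subset(self, mask) -> "HarmonizedSet":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        ids = [self.snp_ids[i] for i in idx]
        return HarmonizedSet(
            snp_ids=ids,
            beta_exposure=self.beta_exposure[idx],
            se_exposure=self.se_exposure[idx],
            beta_outcome=self.beta_outcome[idx],
            se_outcome=self.se_outcome[idx],
            eaf_exposure=self.eaf_exposure[idx],
            flags={s: self.flags[s] for s in ids if s in self.flags},
            exclusions=list(self.exclusions),
        )


def harmonize_all(
    instruments: InstrumentSet,
    outcome: GwasSummary,
    policy: str = "exclude",
    eaf_band: tuple = DEFAULT_EAF_BAND,
) -> HarmonizedSet:
    """Harmonize every instrument against its outcome record (or proxy).

    The result is ordered by snp_id; exclusions are logged with reasons.
    Raises :class:`HarmonizationError` if every SNP is excluded.
    """
    if not instruments.snps:
        raise HarmonizationError("empty instrument set")
    records: list[HarmonizedRecord] = []
    exclusions: list[Exclusion] = []
    for v in sorted(instruments.snps, key=lambda s: s.snp_id):
        out_id = instruments.outcome_snp_id.get(v.snp_id, v.snp_id)
        if out_id not in outcome:
            exclusions.append(Exclusion(v.snp_id, "missing_from_outcome"))
            continue
        out = outcome.get(out_id)
        if out_id != v.snp_id:
            # proxy at a different locus: allele letters are not comparable,
            # orientation comes from the EAF-consistency gate applied when
            # the proxy was accepted into the instrument set
            res = HarmonizedRecord(
                snp_id=v.snp_id, beta_exposure=v.beta, se_exposure=v.se,
                eaf_exposure=v.eaf, beta_outcome=out.beta, se_outcome=out.se,
                eaf_outcome=out.eaf, flags=frozenset({"proxy_used"}),
            )
        else:
            res = harmonize_pair(v, out, policy=policy, eaf_band=eaf_band)
            if isinstance(res, Exclusion):
                logger.info("harmonize_all: excluded %s (%s)", res.snp_id, res.reason)
                exclusions.append(res)
                continue
        records.append(res)
    if not records:
        raise HarmonizationError("all SNPs excluded during harmonization")
    return HarmonizedSet(
        snp_ids=[r.snp_id for r in records],
        beta_exposure=np.array([r.beta_exposure for r in records]),
        se_exposure=np.array([r.se_exposure for r in records]),
        beta_outcome=np.array([r.beta_outcome for r in records]),
        se_outcome=np.array([r.se_outcome for r in records]),
        eaf_exposure=np.array([r.eaf_exposure for r in records]),
        flags={r.snp_id: r.flags for r in records},
        exclusions=exclusions,
    )
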