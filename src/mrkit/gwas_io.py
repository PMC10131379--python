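"""Reading, writing and validating GWAS summary statistics and LD matrices.

The canonical on-disk format for summary statistics is a tab-separated table
with one header row and columns ``snp_id, chrom, pos, effect_allele,
other_allele, eaf, beta, se, pvalue, n``.  Other dialects (e.g.
GWAS-Catalog-style headers) can be ingested by supplying a ``column_map``.
LD is read either as a square matrix (first column = row snp ids, remaining
headers = snp ids) or as long-format ``snp_a, snp_b, r2`` triples.

Rows failing validation are dropped with a logged count rather than aborting:
real summary files routinely contain malformed tails, and all downstream
quality control is filter-based anyway.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset({"A", "C", "G", "T"})

#: canonical column order for summary-statistics files
CANONICAL_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n",
]


class FormatError(ValueError):
    """Malformed input file (missing columns, asymmetric LD, bad diagonal)."""


class InputError(ValueError):
    """Empty or unusable input."""


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP's summary association with one trait.

    ``beta`` is the per-effect-allele effect: SD units for quantitative
    traits, log-odds for binary traits.  ``eaf`` is the effect-allele
    frequency.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: float

    def is_valid(self) -> bool:
        return (
            self.effect_allele in VALID_ALLELES
            and self.other_allele in VALID_ALLELES
            and self.effect_allele != self.other_allele
            and 0.0 <= self.eaf <= 1.0
            and self.se > 0.0
            and 0.0 < self.pvalue <= 1.0
            and self.n > 0
            and np.isfinite(self.beta)
        )

    def flipped(self) -> "VariantAssociation":
        """The same association reported on the opposite effect allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            eaf=1.0 - self.eaf,
            beta=-self.beta,
        )


@dataclass
class GwasSummary:
    """A trait's full set of variant associations plus trait metadata.

    ``variants`` is a DataFrame with the canonical columns, indexed by
    ``snp_id`` (snp ids unique).
    """

    trait_name: str
    trait_type: str  # "quantitative" | "binary"
    n_total: int
    variants: pd.DataFrame
    n_cases: int | None = None
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.trait_type == "binary":
            if self.n_cases is None or self.n_cases >= self.n_total:
                raise ValueError("binary trait requires n_cases < n_total")
        df = self.variants
        if "snp_id" in df.columns:
            df = df.set_index("snp_id", drop=False)
        if not df.index.is_unique:
            dup = df.index[df.index.duplicated()].tolist()
            raise ValueError(f"duplicate snp_ids: {dup[:5]}")
        self.variants = df

    def __len__(self) -> int:
        return len(self.variants)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self.variants.index

    @property
    def snp_ids(self) -> list[str]:
        return list(self.variants.index)

    def get(self, snp_id: str) -> VariantAssociation:
        row = self.variants.loc[snp_id]
        return VariantAssociation(
            snp_id=str(row["snp_id"]), chrom=str(row["chrom"]), pos=int(row["pos"]),
            effect_allele=str(row["effect_allele"]), other_allele=str(row["other_allele"]),
            eaf=float(row["eaf"]), beta=float(row["beta"]), se=float(row["se"]),
            pvalue=float(row["pvalue"]), n=float(row["n"]),
        )

    def iter_variants(self) -> Iterable[VariantAssociation]:
        for snp_id in self.variants.index:
            yield self.get(snp_id)

    def subset(self, snp_ids: Sequence[str]) -> "GwasSummary":
        return GwasSummary(
            trait_name=self.trait_name, trait_type=self.trait_type,
            n_total=self.n_total, n_cases=self.n_cases,
            variants=self.variants.loc[list(snp_ids)].copy(),
        )

    def equals(self, other: "GwasSummary", rtol: float = 1e-12) -> bool:
        if (self.trait_name, self.trait_type, self.n_total, self.n_cases) != (
            other.trait_name, other.trait_type, other.n_total, other.n_cases
        ):
            return False
        a, b = self.variants, other.variants
        if list(a.index) != list(b.index):
            return False
        for col in ("chrom", "effect_allele", "other_allele"):
            if not (a[col].astype(str) == b[col].astype(str)).all():
                return False
        if not (a["pos"].astype(int) == b["pos"].astype(int)).all():
            return False
        for col in ("eaf", "beta", "se", "pvalue", "n"):
            if not np.allclose(a[col].astype(float), b[col].astype(float),
                               rtol=rtol, atol=0.0):
                return False
        return True


@dataclass
class LDMatrix:
    """Pairwise squared-correlation (r²) matrix over a set of SNPs."""

    snp_ids: list[str]
    r2: np.ndarray
    positions: pd.DataFrame | None = None  # optional columns chrom, pos indexed by snp_id
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.snp_ids)
        if self.r2.shape != (k, k):
            raise FormatError("r2 matrix shape does not match snp_ids")
        if not np.allclose(self.r2, self.r2.T, atol=1e-8):
            raise FormatError("LD matrix is asymmetric beyond tolerance 1e-8")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-8):
            raise FormatError("LD matrix diagonal must be 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1.0 + 1e-8:
            raise FormatError("LD r2 entries must lie in [0, 1]")
        # enforce exact symmetry / diagonal after tolerance check
        self.r2 = np.clip((self.r2 + self.r2.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(self.r2, 1.0)
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def get(self, a: str, b: str, default: float = 0.0) -> float:
        """r² between two SNPs; absent pairs default to ``default``."""
        if a == b:
            return 1.0
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return default
        return float(self.r2[ia, ib])


def _apply_column_map(df: pd.DataFrame, column_map: Mapping[str, str] | None) -> pd.DataFrame:
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    return df


def read_gwas(
    path,
    column_map: Mapping[str, str] | None = None,
    trait_meta: Mapping | None = None,
) -> GwasSummary:
    """Read a delimited summary-statistics table into a validated GwasSummary.

    Parameters
    ----------
    path : str or Path
        Delimited table with a header row (delimiter is sniffed; the
        canonical format is tab-separated).
    column_map : mapping, optional
        Maps canonical column names to the file's header names, e.g.
        ``{"snp_id": "rsid", "pvalue": "p"}``.
    trait_meta : mapping, optional
        ``trait_name``, ``trait_type``, ``n_total``, ``n_cases``.  Defaults
        to a quantitative trait with ``n_total`` = max per-variant n.

    Rows violating the per-variant invariants (non-ACGT or identical alleles,
    ``se <= 0``, ``eaf`` outside [0, 1], ``pvalue`` outside (0, 1], ``n <= 0``)
    are dropped and counted in ``n_dropped`` and the module log.
    """
    import csv
    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    except (pd.errors.EmptyDataError, csv.Error) as exc:
        raise InputError(f"empty or undelimited input file: {path}") from exc
    df = _apply_column_map(df, column_map)
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing mandatory column(s): {missing}")
    df = df[CANONICAL_COLUMNS].copy()

    for col in ("eaf", "beta", "se", "pvalue", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce")
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()

    ok = (
        df["effect_allele"].isin(VALID_ALLELES)
        & df["other_allele"].isin(VALID_ALLELES)
        & (df["effect_allele"] != df["other_allele"])
        & df["eaf"].between(0.0, 1.0)
        & (df["se"] > 0.0)
        & (df["pvalue"] > 0.0) & (df["pvalue"] <= 1.0)
        & (df["n"] > 0)
        & np.isfinite(df["beta"])
        & df["pos"].notna()
        & df["snp_id"].notna()
    )
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("read_gwas: dropped %d invalid row(s) from %s", n_dropped, path)
    df = df[ok].copy()
    df["pos"] = df["pos"].astype(int)
    df["chrom"] = df["chrom"].astype(str)
    df["snp_id"] = df["snp_id"].astype(str)

    meta = dict(trait_meta or {})
    meta.setdefault("trait_name", "trait")
    meta.setdefault("trait_type", "quantitative")
    meta.setdefault("n_total", int(df["n"].max()) if len(df) else 0)
    return GwasSummary(
        trait_name=meta["trait_name"], trait_type=meta["trait_type"],
        n_total=int(meta["n_total"]), n_cases=meta.get("n_cases"),
        variants=df, n_dropped=n_dropped,
    )


def write_gwas(g: GwasSummary, path) -> None:
    """Write a GwasSummary as a canonical tab-separated table.

    Deterministic column order; floats keep full (shortest round-trip)
    precision so ``read_gwas`` inverts this to better than 1e-12 relative.
    An empty variant set yields a header-only file.
    """
    df = g.variants.reset_index(drop=True)[CANONICAL_COLUMNS] if len(g.variants) \
        else pd.DataFrame(columns=CANONICAL_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_ld_matrix(path) -> LDMatrix:
    """Read an LD r² matrix from a square or long-format TSV.

    Long format has exactly the header ``snp_a, snp_b, r2``; anything else
    is treated as square (first column = row snp ids, remaining headers =
    column snp ids).  Pairs absent from long format default to r² = 0;
    the diagonal must be 1 where given and asymmetries beyond 1e-8 are
    format errors.
    """
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"empty LD file: {path}") from exc
    cols = [c.lower() for c in df.columns]
    if cols == ["snp_a", "snp_b", "r2"]:
        snp_ids = sorted(set(df.iloc[:, 0].astype(str)) | set(df.iloc[:, 1].astype(str)))
        idx = {s: i for i, s in enumerate(snp_ids)}
        r2 = np.zeros((len(snp_ids), len(snp_ids)))
        np.fill_diagonal(r2, 1.0)
        for a, b, v in df.itertuples(index=False):
            v = float(v)
            ia, ib = idx[str(a)], idx[str(b)]
            if ia == ib:
                if abs(v - 1.0) > 1e-8:
                    raise FormatError(f"diagonal r2 for {a} is {v}, expected 1")
                continue
            if r2[ia, ib] != 0.0 and abs(r2[ia, ib] - v) > 1e-8:
                raise FormatError(f"conflicting r2 entries for pair ({a}, {b})")
            r2[ia, ib] = r2[ib, ia] = v
        return LDMatrix(snp_ids=snp_ids, r2=r2)
    # square format
    row_ids = df.iloc[:, 0].astype(str).tolist()
    col_ids = [str(c) for c in df.columns[1:]]
    if row_ids != col_ids:
        raise FormatError("square LD matrix row ids do not match column headers")
    r2 = df.iloc[:, 1:].to_numpy(dtype=float)
    return LDMatrix(snp_ids=row_ids, r2=r2)


def write_ld_matrix(ld: LDMatrix, path) -> None:
    """Write an LDMatrix in the square TSV format ``read_ld_matrix`` accepts."""
    df = pd.DataFrame(ld.r2, columns=ld.snp_ids)
    df.insert(0, "snp_id", ld.snp_ids)
    df.to_csv(path, sep="\t", index=False)
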