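"""Replicated-stratum Cochran–Mantel–Haenszel association scan over pools.

Four pools arranged as a 2x2 design of two traits (a focal trait crossed
with an orthogonal one) give, at each biallelic site, K=2 stratified 2x2
allele-count tables: within each level of the orthogonal trait, the high-
versus low-focal-trait pools are contrasted on major/minor allele counts.
The CMH chi-square statistic pools the per-stratum association evidence,

    chi2 = (|sum_k (a_k - E[a_k])| - cc)^2 / sum_k Var(a_k),

with hypergeometric conditional moments E[a_k] = r1_k c1_k / n_k and
Var(a_k) = r1_k r2_k c1_k c2_k / (n_k^2 (n_k - 1)), referred to a 1-df
chi-square.  The Mantel–Haenszel common odds ratio summarises effect size
and p-values are Benjamini–Hochberg adjusted genome-wide.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .pool_io import NUC_INDEX, NUC_SORT_ORDER, NUCLEOTIDES, SyncRecord

__all__ = [
    "StratifiedTable",
    "CmhResult",
    "PoolDesign",
    "build_strata",
    "cmh_test",
    "mh_common_or",
    "bh_adjust",
    "scan",
]


@dataclass
class StratifiedTable:
    """K stratified 2x2 tables of (high-pool major, high-pool minor;
    low-pool major, low-pool minor) allele counts."""

    tables: np.ndarray  # shape (K, 2, 2)
    alleles: tuple[str, str] = ("", "")  # (major, minor)

    def __post_init__(self) -> None:
        self.tables = np.asarray(self.tables, dtype=float)
        if self.tables.ndim != 3 or self.tables.shape[1:] != (2, 2):
            raise ValueError("tables must have shape (K, 2, 2)")
        if self.tables.shape[0] < 1:
            raise ValueError("need at least one stratum")
        if (self.tables < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.tables.sum(axis=(1, 2)) <= 0).any():
            raise ValueError("every stratum must have a positive margin")

    @property
    def k(self) -> int:
        return self.tables.shape[0]

    def swapped(self) -> "StratifiedTable":
        """Exchange the high/low pool rows in every stratum."""
        return StratifiedTable(self.tables[:, ::-1, :], self.alleles)


@dataclass
class CmhResult:
    chrom: str
    pos: int
    major: str
    minor: str
    chi2: float
    p: float
    or_mh: float
    p_adj: float = np.nan
    degenerate: bool = False


@dataclass
class PoolDesign:
    """Maps each pool (by column order in the sync file) to its
    (trait1 stratum, trait2 stratum) cell; values are 'high'/'low'."""

    cells: Sequence[tuple[str, str]]

    def __post_init__(self) -> None:
        cells = [(str(a), str(b)) for a, b in self.cells]
        expected = {(a, b) for a in ("high", "low") for b in ("high", "low")}
        if set(cells) != expected or len(cells) != 4:
            raise ValueError(
                "design must assign exactly one pool to each of the four "
                "(trait1, trait2) high/low cells"
            )
        self.cells = cells

    def pool_index(self, trait1: str, trait2: str) -> int:
        return self.cells.index((trait1, trait2))

    @classmethod
    def standard(cls) -> "PoolDesign":
        """Pool order 1..4 = high/high, high/low, low/high, low/low."""
        return cls([("high", "high"), ("high", "low"),
                    ("low", "high"), ("low", "low")])


def choose_allele_pair(record: SyncRecord) -> tuple[str, str] | None:
    """Two most frequent nucleotides summed over pools; ties broken by
    nucleotide order A < C < G < T.  Returns None for a site with fewer
    than two observed alleles (monomorphic after pairing)."""
    totals = record.allele_totals()
    ranked = sorted(NUCLEOTIDES, key=lambda n: (-totals[n], NUC_SORT_ORDER[n]))
    major, minor = ranked[0], ranked[1]
    if totals[minor] == 0:
        return None
    return major, minor


def build_strata(
    record: SyncRecord,
    design: PoolDesign,
    contrast: str = "trait1",
) -> StratifiedTable | None:
    """Stratified 2x2 tables for one site.

    With ``contrast='trait1'`` the strata are the trait2 levels and the
    rows within each stratum contrast the trait1-high against the
    trait1-low pool (the converse orientation is selected with
    ``contrast='trait2'``).  Returns None for sites without two alleles.
    """
    if record.n_pools != 4:
        raise ValueError("build_strata expects exactly 4 pools")
    pair = choose_allele_pair(record)
    if pair is None:
        return None
    major, minor = pair
    i_maj, i_min = NUC_INDEX[major], NUC_INDEX[minor]
    if contrast not in ("trait1", "trait2"):
        raise ValueError("contrast must be 'trait1' or 'trait2'")
    tables = []
    for stratum_level in ("high", "low"):
        if contrast == "trait1":
            hi = design.pool_index("high", stratum_level)
            lo = design.pool_index("low", stratum_level)
        else:
            hi = design.pool_index(stratum_level, "high")
            lo = design.pool_index(stratum_level, "low")
        tables.append(
            [
                [record.pools[hi, i_maj], record.pools[hi, i_min]],
                [record.pools[lo, i_maj], record.pools[lo, i_min]],
            ]
        )
    return StratifiedTable(np.array(tables, dtype=float), (major, minor))


def cmh_test(
    t: StratifiedTable, continuity: bool = False
) -> tuple[float, float]:
    """CMH chi-square and p-value (1 df) over the strata.

    Degenerate input (zero conditional variance in every stratum, e.g. a
    fixed allele in all pools of every stratum) returns ``(0.0, 1.0)``.
    """
    a = t.tables[:, 0, 0]
    r1 = t.tables[:, 0, :].sum(axis=1)
    r2 = t.tables[:, 1, :].sum(axis=1)
    c1 = t.tables[:, :, 0].sum(axis=1)
    c2 = t.tables[:, :, 1].sum(axis=1)
    n = t.tables.sum(axis=(1, 2))
    expect = r1 * c1 / n
    with np.errstate(divide="ignore", invalid="ignore"):
        var = r1 * r2 * c1 * c2 / (n * n * (n - 1.0))
    var = np.where(n > 1, var, 0.0)
    total_var = float(np.nansum(var))
    if total_var <= 0.0:
        return 0.0, 1.0
    dev = abs(float(np.sum(a - expect)))
    if continuity:
        dev = max(dev - 0.5, 0.0)
    chi2 = dev * dev / total_var
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def mh_common_or(t: StratifiedTable) -> float:
    """Mantel–Haenszel common odds ratio
    ``(sum_k a_k d_k / n_k) / (sum_k b_k c_k / n_k)``.

    Returns ``nan`` when the denominator is zero (undefined; reported,
    never fabricated).
    """
    a = t.tables[:, 0, 0]
    b = t.tables[:, 0, 1]
    c = t.tables[:, 1, 0]
    d = t.tables[:, 1, 1]
    n = t.tables.sum(axis=(1, 2))
    num = float(np.sum(a * d / n))
    den = float(np.sum(b * c / n))
    if den == 0.0:
        return np.nan
    return num / den


def bh_adjust(p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def scan(
    records: Iterable[SyncRecord],
    design: PoolDesign,
    contrast: str = "trait1",
    continuity: bool = False,
) -> pd.DataFrame:
    """CMH scan over (already filtered / optionally resampled) sites.

    Returns a tidy frame with one row per retained biallelic site:
    chrom, pos, major, minor, chi2, p, or_mh, p_adj.  Deterministic given
    the input order.  Sites without two alleles are excluded.
    """
    rows = []
    for rec in records:
        table = build_strata(rec, design, contrast=contrast)
        if table is None:
            continue
        chi2, p = cmh_test(table, continuity=continuity)
        rows.append(
            {
                "chrom": rec.chrom,
                "pos": rec.pos,
                "major": table.alleles[0],
                "minor": table.alleles[1],
                "chi2": chi2,
                "p": p,
                "or_mh": mh_common_or(table),
            }
        )
    out = pd.DataFrame(
        rows, columns=["chrom", "pos", "major", "minor", "chi2", "p", "or_mh"]
    )
    if len(out):
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
    else:
        out["p_adj"] = pd.Series(dtype=float)
    return out
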