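"""QTL-seq style bulked-segregant analysis with simulation-derived thresholds.

Two phenotype-selected bulks of a segregating population are sequenced and
compared at donor-diagnostic SNPs.  The per-site SNP-index is the fraction
of reads carrying the donor (alternate) allele; the delta SNP-index is the
high-bulk minus low-bulk difference.  Significance thresholds come from
simulating the null sampling process — genotype sampling of bulk members
followed by binomial read sampling at the observed depth — for the relevant
population structure.

Besides the textbook F2 and RIL models this module implements a tetraploid
backcross model (``BC4x``): a dominant donor haplotype carried on one of
four homologues, segregating 1:1, so a bulk of carriers has an expected
donor-allele frequency of exactly 0.25 and a non-carrier bulk of 0.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cmh_scan import bh_adjust
from .pool_io import NUC_INDEX, NUC_SORT_ORDER, NUCLEOTIDES, SyncRecord

logger = logging.getLogger(__name__)

__all__ = [
    "PopulationModel",
    "snp_index",
    "simulate_bulk_freq",
    "simulate_null_delta",
    "ThresholdTable",
    "windowed_delta",
    "call_qtl",
    "bulk_depths_from_sync",
]


@dataclass(frozen=True)
class PopulationModel:
    """Expected bulk allele-frequency structure of a mapping population.

    ``linked_freq`` gives the expected donor-allele frequency of the
    (low bulk, high bulk) at a site perfectly linked to the selected locus;
    ``carrier_dosage`` is the donor-allele dosage fraction of one carrier.
    """

    kind: str
    linked_freq: tuple[float, float]
    segregation: float  # carrier fraction among progeny
    carrier_dosage: float

    def __post_init__(self) -> None:
        lo, hi = self.linked_freq
        if not (0.0 <= lo <= 1.0 and 0.0 <= hi <= 1.0):
            raise ValueError("linked frequencies must lie in [0, 1]")

    @classmethod
    def bc4x(cls) -> "PopulationModel":
        """Tetraploid backcross: dominant donor haplotype on 1/4 homologues,
        1:1 carrier segregation, expected bulk frequencies 0 : 0.25."""
        return cls("BC4x", (0.0, 0.25), 0.5, 0.25)

    @classmethod
    def f2(cls) -> "PopulationModel":
        return cls("F2", (0.0, 1.0), 0.75, 0.5)

    @classmethod
    def ril(cls) -> "PopulationModel":
        return cls("RIL", (0.0, 1.0), 0.5, 1.0)

    @classmethod
    def from_name(cls, name: str) -> "PopulationModel":
        try:
            return {"BC4X": cls.bc4x, "F2": cls.f2, "RIL": cls.ril}[name.upper()]()
        except KeyError:
            raise ValueError(f"unknown population type {name!r}") from None


def snp_index(ref: int, alt: int) -> float:
    """Fraction of reads carrying the alternate (donor) allele."""
    depth = ref + alt
    if depth <= 0:
        raise ValueError("snp_index undefined at zero depth")
    return alt / depth


def simulate_bulk_freq(
    model: PopulationModel,
    bulk_size: int,
    bulk: str = "high",
    linked: bool = True,
    reps: int = 1,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Donor-allele frequency of one bulk, ``reps`` independent draws.

    linked=True: the site co-segregates perfectly with the selection
    criterion, so the high bulk is all carriers (BC4x: exactly 0.25 for any
    bulk size) and the low bulk carries no donor allele.  linked=False: a
    null site segregating independently of the phenotype — bulk members'
    genotypes are drawn from the population's segregation (BC4x/RIL:
    Binomial(bulk_size, 1/2) carriers; F2: 1:2:1 dosage {0, 1/2, 1}).
    """
    if bulk_size < 1:
        raise ValueError("bulk_size must be >= 1")
    if bulk not in ("high", "low"):
        raise ValueError("bulk must be 'high' or 'low'")
    rng = np.random.default_rng(rng)
    if linked:
        value = model.linked_freq[1] if bulk == "high" else model.linked_freq[0]
        return np.full(reps, value, dtype=float)
    if model.kind in ("BC4X", "BC4x", "RIL"):
        carriers = rng.binomial(bulk_size, model.segregation, size=reps)
        return carriers * model.carrier_dosage / bulk_size
    if model.kind == "F2":
        # genotype dosages 0 : 1/2 : 1 in a 1:2:1 ratio
        counts = rng.multinomial(bulk_size, [0.25, 0.5, 0.25], size=reps)
        return (counts[:, 1] * 0.5 + counts[:, 2]) / bulk_size
    raise ValueError(f"unknown population type {model.kind!r}")


def simulate_null_delta(
    model: PopulationModel,
    bulk_size: int,
    depth: int,
    reps: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Null distribution of delta SNP-index at a given read depth.

    Per replicate: draw each bulk's null genotype frequency
    (:func:`simulate_bulk_freq` with ``linked=False``), then binomial read
    sampling at ``depth`` per bulk; delta = high-bulk minus low-bulk index.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if reps < 100:
        raise ValueError("reps must be >= 100")
    rng = np.random.default_rng(rng)
    f_hi = simulate_bulk_freq(model, bulk_size, "high", linked=False, reps=reps, rng=rng)
    f_lo = simulate_bulk_freq(model, bulk_size, "low", linked=False, reps=reps, rng=rng)
    idx_hi = rng.binomial(depth, f_hi) / depth
    idx_lo = rng.binomial(depth, f_lo) / depth
    return idx_hi - idx_lo


def _empirical_two_sided_p(null: np.ndarray, value: float, min_tail: int = 10) -> float:
    """Two-sided p of ``value`` against a simulated null sample.

    Uses the (count+1)/(reps+1) empirical tail when at least ``min_tail``
    null draws are as extreme as ``value``; beyond the resolution of the
    simulation the tail is extended with a normal fit to the same null
    sample (the null delta is a standardised sum of binomial variates and
    is well approximated as Gaussian in its far tail).
    """
    reps = null.size
    centred = value - null.mean()
    n_hi = int(np.count_nonzero(null >= value))
    n_lo = int(np.count_nonzero(null <= value))
    n_tail = n_hi if centred >= 0 else n_lo
    if n_tail >= min_tail:
        p = 2.0 * (n_tail + 1) / (reps + 1)
        return min(1.0, p)
    sd = float(null.std())
    if sd == 0.0:
        return 1.0 if centred == 0.0 else 0.0
    return float(min(1.0, 2.0 * stats.norm.sf(abs(centred) / sd)))


class ThresholdTable:
    """Simulated null quantiles of delta SNP-index, indexed by read depth.

    Holds, per depth, the full simulated null sample so that confidence
    bands and empirical p-values can be read off; null distributions of the
    tricube-smoothed statistic (the mean of ``n_eff`` independent null site
    deltas) are generated on demand and cached.
    """

    def __init__(
        self,
        model: PopulationModel,
        bulk_size: int,
        depths: Sequence[int],
        reps: int = 10_000,
        seed: int | None = None,
    ) -> None:
        self.model = model
        self.bulk_size = bulk_size
        self.reps = reps
        self._seed = seed
        self.depths = sorted({int(d) for d in depths if d > 0})
        if not self.depths:
            raise ValueError("need at least one positive depth")
        self._null: dict[tuple[int, int], np.ndarray] = {}
        for d in self.depths:
            self._null[(d, 1)] = self._simulate(d, 1)

    def _simulate(self, depth: int, n_eff: int) -> np.ndarray:
        # independent child stream per (depth, n_eff) keeps the table
        # extensible without replaying earlier draws
        rng = np.random.default_rng(
            None if self._seed is None else [self._seed, depth, n_eff]
        )
        draws = simulate_null_delta(
            self.model, self.bulk_size, depth, self.reps * n_eff, rng
        )
        if n_eff == 1:
            return np.sort(draws)
        return np.sort(draws.reshape(self.reps, n_eff).mean(axis=1))

    def nearest_depth(self, depth: int) -> int:
        if depth not in self.depths:
            logger.warning("depth %d absent from threshold table; using nearest", depth)
        arr = np.asarray(self.depths)
        return int(arr[np.argmin(np.abs(arr - depth))])

    def null(self, depth: int, n_eff: int = 1) -> np.ndarray:
        d = self.nearest_depth(int(depth))
        key = (d, max(1, int(round(n_eff))))
        if key not in self._null:
            self._null[key] = self._simulate(*key)
        return self._null[key]

    def band(self, depth: int, confidence: float = 0.95, n_eff: int = 1) -> tuple[float, float]:
        """Symmetric two-sided null quantile band at ``confidence``."""
        null = self.null(depth, n_eff)
        alpha = (1.0 - confidence) / 2.0
        return (
            float(np.quantile(null, alpha)),
            float(np.quantile(null, 1.0 - alpha)),
        )

    def pvalue(self, delta: float, depth: int, n_eff: int = 1) -> float:
        return _empirical_two_sided_p(self.null(depth, n_eff), delta)


def _tricube(u: np.ndarray) -> np.ndarray:
    w = (1.0 - np.abs(u) ** 3) ** 3
    return np.where(np.abs(u) < 1.0, w, 0.0)


def windowed_delta(
    sites: pd.DataFrame, window: float = 1_000_000.0
) -> pd.DataFrame:
    """Tricube-weighted mean delta evaluated at each SNP position.

    ``sites`` needs columns chrom, pos, delta and (optionally) depth; it
    must be sorted by chrom then pos.  For each SNP, neighbours within
    ``window/2`` receive weight w(u) = (1-|u|^3)^3 with u = distance /
    (window/2).  Adds columns ``delta_smoothed``, ``n_snps`` (SNPs in the
    window), ``n_eff`` (effective number of independent sites,
    (sum w)^2 / sum w^2) and ``depth_eff`` (weighted mean depth) to a copy
    of the input.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    for col in ("chrom", "pos", "delta"):
        if col not in sites.columns:
            raise ValueError(f"sites frame lacks required column {col!r}")
    by_chrom = sites.groupby("chrom", sort=False)["pos"]
    if not by_chrom.apply(lambda s: s.is_monotonic_increasing).all():
        raise ValueError("sites must be sorted by chrom, pos")

    half = window / 2.0
    out = sites.copy().reset_index(drop=True)
    smoothed = np.empty(len(out))
    n_snps = np.empty(len(out), dtype=int)
    n_eff = np.empty(len(out))
    depth_eff = np.full(len(out), np.nan)
    have_depth = "depth" in out.columns
    for _, grp in out.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy(dtype=float)
        delta = grp["delta"].to_numpy(dtype=float)
        depth = grp["depth"].to_numpy(dtype=float) if have_depth else None
        lo = np.searchsorted(pos, pos - half, side="right")
        hi = np.searchsorted(pos, pos + half, side="left")
        for j, gidx in enumerate(grp.index):
            sl = slice(lo[j], hi[j])
            w = _tricube((pos[sl] - pos[j]) / half)
            sw = w.sum()
            smoothed[gidx] = float((w * delta[sl]).sum() / sw)
            n_snps[gidx] = int((w > 0).sum())
            n_eff[gidx] = float(sw * sw / (w * w).sum())
            if depth is not None:
                depth_eff[gidx] = float((w * depth[sl]).sum() / sw)
    out["delta_smoothed"] = smoothed
    out["n_snps"] = n_snps
    out["n_eff"] = n_eff
    out["depth_eff"] = depth_eff
    return out


def call_qtl(
    windows: pd.DataFrame,
    thresholds: ThresholdTable,
    fdr: float = 0.001,
    min_snps: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Call significant QTL intervals from windowed delta SNP-index.

    Per SNP, a two-sided empirical p of the smoothed delta is taken against
    the simulated null of the smoothed statistic (mean of ``n_eff`` null
    site deltas at the nearest simulated depth), then BH-adjusted
    genome-wide; SNPs with adjusted p below ``fdr`` are significant.  Runs
    of consecutive significant SNPs (at least ``min_snps`` long, the guard
    against isolated exceedances) merge into intervals spanning first to
    last member SNP.

    Returns ``(per_snp, intervals)`` frames.
    """
    out = windows.copy().reset_index(drop=True)
    if "depth_eff" in out.columns and out["depth_eff"].notna().all():
        depth_col = out["depth_eff"]
    elif "depth" in out.columns:
        depth_col = out["depth"]
    else:
        raise ValueError("windows frame needs a depth or depth_eff column")
    n_eff = out["n_eff"] if "n_eff" in out.columns else pd.Series(1.0, index=out.index)
    pvals = np.array(
        [
            thresholds.pvalue(d, int(round(dep)), n_eff=int(round(ne)))
            for d, dep, ne in zip(out["delta_smoothed"], depth_col, n_eff)
        ]
    )
    out["p"] = pvals
    out["p_adj"] = bh_adjust(pvals)
    out["significant"] = out["p_adj"] < fdr

    intervals = []
    for chrom, grp in out.groupby("chrom", sort=False):
        sig = grp["significant"].to_numpy()
        pos = grp["pos"].to_numpy()
        delta = grp["delta_smoothed"].to_numpy()
        start = None
        for j in range(len(sig) + 1):
            if j < len(sig) and sig[j]:
                if start is None:
                    start = j
            elif start is not None:
                run = slice(start, j)
                if j - start >= min_snps:
                    peak = start + int(np.argmax(np.abs(delta[run])))
                    intervals.append(
                        {
                            "chrom": chrom,
                            "start": int(pos[start]),
                            "end": int(pos[j - 1]),
                            "n_snps": j - start,
                            "peak_pos": int(pos[peak]),
                            "peak_delta": float(delta[peak]),
                        }
                    )
                start = None
    interval_df = pd.DataFrame(
        intervals,
        columns=["chrom", "start", "end", "n_snps", "peak_pos", "peak_delta"],
    )
    return out, interval_df


def bulk_depths_from_sync(
    records: Iterable[SyncRecord],
    high_pool: int,
    low_pool: int,
) -> pd.DataFrame:
    """Per-bulk ref/alt depths from sync records for one bulk pairing.

    The alternate (donor) allele at each site is the most frequent non-
    reference nucleotide summed over the two bulks (ties broken by
    nucleotide order A < C < G < T).  Zero-depth sites are skipped with a
    log entry.  Output columns: chrom, pos, ref, alt, per-bulk ref/alt
    depths, per-bulk SNP-index, delta and the mean per-bulk depth used for
    threshold lookup.
    """
    rows = []
    for rec in records:
        i_ref = NUC_INDEX[rec.ref]
        two = rec.pools[[high_pool, low_pool], :]
        totals = two.sum(axis=0)
        candidates = [n for n in NUCLEOTIDES if n != rec.ref]
        alt = sorted(
            candidates, key=lambda n: (-totals[NUC_INDEX[n]], NUC_SORT_ORDER[n])
        )[0]
        i_alt = NUC_INDEX[alt]
        rh, ah = int(two[0, i_ref]), int(two[0, i_alt])
        rl, al = int(two[1, i_ref]), int(two[1, i_alt])
        if rh + ah == 0 or rl + al == 0:
            logger.info("skipping zero-depth site %s:%d", rec.chrom, rec.pos)
            continue
        idx_hi = snp_index(rh, ah)
        idx_lo = snp_index(rl, al)
        rows.append(
            {
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": alt,
                "ref_high": rh,
                "alt_high": ah,
                "ref_low": rl,
                "alt_low": al,
                "index_high": idx_hi,
                "index_low": idx_lo,
                "delta": idx_hi - idx_lo,
                "depth": 0.5 * (rh + ah + rl + al),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt",
            "ref_high", "alt_high", "ref_low", "alt_low",
            "index_high", "index_low", "delta", "depth",
        ],
    )
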