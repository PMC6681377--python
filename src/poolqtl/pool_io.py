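"""Reading, writing and conditioning of Popoolation2 ``sync`` pooled counts.

The sync format carries one line per genomic site::

    chrom <TAB> pos <TAB> ref <TAB> A:T:C:G:N:del [<TAB> A:T:C:G:N:del ...]

with one colon-separated count column per sequencing pool.  Positions are
1-based inclusive.  This module provides a lossless reader/writer, the
standard site filters (minor-allele count floor, per-pool coverage window)
and with-replacement resampling of each pool to a fixed target depth so that
association statistics are comparable across sites of unequal coverage.
"""

from __future__ import annotations

import gzip
from collections.abc import Iterable, Iterator, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: order of the count columns inside one sync pool field
SYNC_COLS = ("A", "T", "C", "G", "N", "del")

#: the four true nucleotide alleles (N/del never form the tested pair)
NUCLEOTIDES = ("A", "T", "C", "G")

#: index of each nucleotide in the sync column order
NUC_INDEX = {n: i for i, n in enumerate(SYNC_COLS)}

#: allele-pair tie-break follows alphabetical nucleotide order A < C < G < T
NUC_SORT_ORDER = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class SyncRecord:
    """Per-site, per-pool nucleotide counts (the pooled-sequencing unit).

    Attributes
    ----------
    chrom : str
        Chromosome / contig name.
    pos : int
        1-based position.
    ref : str
        Reference nucleotide.
    pools : numpy.ndarray
        Integer array of shape ``(n_pools, 6)`` with columns in
        :data:`SYNC_COLS` order.
    """

    chrom: str
    pos: int
    ref: str
    pools: np.ndarray

    def __post_init__(self) -> None:
        self.pools = np.asarray(self.pools, dtype=np.int64)
        if self.pools.ndim != 2 or self.pools.shape[1] != 6:
            raise ValueError("pools must have shape (n_pools, 6)")
        if (self.pools < 0).any():
            raise ValueError(
                f"negative count at {self.chrom}:{self.pos}"
            )

    @property
    def n_pools(self) -> int:
        return self.pools.shape[0]

    def depths(self) -> np.ndarray:
        """Per-pool read depth (all six columns count toward depth)."""
        return self.pools.sum(axis=1)

    def allele_totals(self) -> dict[str, int]:
        """Counts of A/T/C/G summed over all pools."""
        tot = self.pools.sum(axis=0)
        return {n: int(tot[NUC_INDEX[n]]) for n in NUCLEOTIDES}

    def to_line(self) -> str:
        fields = [self.chrom, str(self.pos), self.ref]
        fields += [":".join(str(c) for c in row) for row in self.pools]
        return "\t".join(fields)

    @classmethod
    def from_line(cls, line: str) -> "SyncRecord":
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 4:
            raise ValueError(f"sync line has {len(parts)} fields, need >= 4")
        chrom, pos, ref = parts[0], int(parts[1]), parts[2]
        pools = np.array(
            [[int(c) for c in col.split(":")] for col in parts[3:]],
            dtype=np.int64,
        )
        if pools.shape[1] != 6:
            raise ValueError("each pool field must hold 6 ':'-separated counts")
        return cls(chrom, pos, ref, pools)


def _open_text(path: str | Path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_sync(path: str | Path) -> Iterator[SyncRecord]:
    """Stream :class:`SyncRecord` from a (optionally gzipped) sync file.

    Malformed lines raise :class:`ValueError` carrying the 1-based line
    number.  An empty file yields an empty stream.
    """
    with _open_text(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                yield SyncRecord.from_line(line)
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed sync line {lineno}: {exc}") from exc


def write_sync(records: Iterable[SyncRecord], path: str | Path) -> None:
    """Write records to ``path`` (gz-transparent); round-trips with read_sync."""
    with _open_text(path, "w") as fh:
        for rec in records:
            fh.write(rec.to_line() + "\n")


@dataclass
class FilterParams:
    """Site-filter settings mirroring the Popoolation2 CMH-test flags.

    ``min_count`` is the allele-count floor applied to counts summed over
    every pool (a site must have at least two nucleotides reaching it, i.e.
    be polymorphic with a sufficiently supported minor allele).
    ``min_coverage``/``max_coverage`` bound each pool's depth;
    ``max_coverage`` may be a per-pool sequence.
    """

    min_count: int = 6
    min_coverage: int = 4
    max_coverage: int | Sequence[int] = 120

    def __post_init__(self) -> None:
        maxes = np.atleast_1d(np.asarray(self.max_coverage, dtype=np.int64))
        if (maxes < self.min_coverage).any():
            raise ValueError("min_coverage must be <= max_coverage")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")

    def max_for_pool(self, i: int, n_pools: int) -> int:
        maxes = np.atleast_1d(np.asarray(self.max_coverage, dtype=np.int64))
        if maxes.size == 1:
            return int(maxes[0])
        if maxes.size != n_pools:
            raise ValueError(
                f"max_coverage list has {maxes.size} entries for {n_pools} pools"
            )
        return int(maxes[i])


def site_passes(record: SyncRecord, params: FilterParams) -> bool:
    """Apply the three site rules: polymorphism floor and coverage window."""
    depths = record.depths()
    n_pools = record.n_pools
    if (depths < params.min_coverage).any():
        return False
    for i in range(n_pools):
        if depths[i] > params.max_for_pool(i, n_pools):
            return False
    totals = record.allele_totals()
    n_ok = sum(1 for n in NUCLEOTIDES if totals[n] >= params.min_count)
    return n_ok >= 2


def filter_sites(
    records: Iterable[SyncRecord], params: FilterParams
) -> list[SyncRecord]:
    """Keep sites that are polymorphic (>=2 alleles each reaching
    ``min_count`` summed across pools) with every pool's depth inside
    ``[min_coverage, max_coverage]``.  Filtering is total and idempotent.
    """
    return [rec for rec in records if site_passes(rec, params)]


def resample_counts(
    record: SyncRecord,
    target: int,
    rng: np.random.Generator | int | None = None,
) -> SyncRecord:
    """Resample every pool's counts with replacement to exactly ``target`` reads.

    Each resampled read is drawn with probability proportional to the pool's
    original counts (a multinomial draw).  A zero-depth pool cannot be
    resampled and raises :class:`ValueError` naming the pool and site.
    """
    if target < 1:
        raise ValueError("target depth must be >= 1")
    rng = np.random.default_rng(rng)
    depths = record.depths()
    new_pools = np.zeros_like(record.pools)
    for i in range(record.n_pools):
        if depths[i] == 0:
            raise ValueError(
                f"cannot resample zero-depth pool {i + 1} at "
                f"{record.chrom}:{record.pos}"
            )
        probs = record.pools[i] / depths[i]
        new_pools[i] = rng.multinomial(target, probs)
    return SyncRecord(record.chrom, record.pos, record.ref, new_pools)


def resample_all(
    records: Iterable[SyncRecord],
    target: int,
    seed: int | None = None,
) -> list[SyncRecord]:
    """Genome-wide :func:`resample_counts`; all output depths equal ``target``."""
    rng = np.random.default_rng(seed)
    return [resample_counts(rec, target, rng) for rec in records]
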