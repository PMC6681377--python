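"""Allele-of-origin assignment from homeo-SNPs and introgression fingerprinting.

In an interspecific hybrid, fixed nucleotide differences between the two
parental species (homeo-SNPs) let expression counts at those sites be split
by species of origin.  Summed over the sites inside each gene model, the
donor-allele proportion traces which chromosomal segments carry the donor
haplotype: a donor introgression shows an abrupt step — roughly the
heterozygous expression proportion in carriers, and essentially zero in
non-carriers — whose boundaries fingerprint a recombination-suppressed
donor block.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "HomeoSnp",
    "AseGeneRecord",
    "read_homeo_index",
    "read_genes_bed",
    "assign_counts",
    "gene_proportions",
    "detect_introgression",
    "naive_log2_ratio",
]

_NUCS = ("A", "C", "G", "T")


@dataclass(frozen=True)
class HomeoSnp:
    """A fixed interspecific difference: recipient allele_a vs donor allele_b."""

    chrom: str
    pos: int
    allele_a: str
    allele_b: str

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b:
            raise ValueError(f"alleles identical at {self.chrom}:{self.pos}")


@dataclass
class AseGeneRecord:
    """Per-gene counts split by species of origin."""

    gene_id: str
    chrom: str
    start: int
    end: int
    count_a: int
    count_b: int
    count_ambiguous: int
    n_sites: int

    @property
    def informative(self) -> bool:
        return self.count_a + self.count_b > 0

    @property
    def proportion_b(self) -> float:
        """Donor-allele proportion on informative counts; NaN if none."""
        tot = self.count_a + self.count_b
        return self.count_b / tot if tot > 0 else float("nan")


def _index_frame(index) -> pd.DataFrame:
    if isinstance(index, pd.DataFrame):
        df = index[["chrom", "pos", "allele_a", "allele_b"]].copy()
    else:
        df = pd.DataFrame(
            [(s.chrom, s.pos, s.allele_a, s.allele_b) for s in index],
            columns=["chrom", "pos", "allele_a", "allele_b"],
        )
    if df.duplicated(subset=["chrom", "pos"]).any():
        dup = df[df.duplicated(subset=["chrom", "pos"])].iloc[0]
        raise ValueError(
            f"homeo-SNP index has duplicate position {dup['chrom']}:{dup['pos']}"
        )
    return df


def read_homeo_index(path: str | Path) -> pd.DataFrame:
    """TSV with columns chrom, pos, allele_a, allele_b (gz-transparent)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return _index_frame(df)


def read_genes_bed(path: str | Path) -> pd.DataFrame:
    """Gene spans from BED (0-based half-open), converted to 1-based inclusive."""
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "gene_id"], dtype={"chrom": str},
    )
    df["start"] = df["start"].astype(int) + 1
    df["end"] = df["end"].astype(int)
    return df


def assign_counts(site_counts: pd.DataFrame, index) -> pd.DataFrame:
    """Split per-site nucleotide counts by species of origin.

    ``site_counts`` needs columns chrom, pos and the nucleotide counts
    A, C, G, T.  At indexed sites, reads matching allele_a (recipient) or
    allele_b (donor) are assigned; any other nucleotide is ambiguous.
    Sites absent from the index contribute only ambiguous counts.
    Conservation: count_a + count_b + count_ambiguous equals site depth.
    """
    idx = _index_frame(index)
    merged = site_counts.merge(idx, on=["chrom", "pos"], how="left")
    depth = merged[list(_NUCS)].sum(axis=1).to_numpy()
    count_a = np.zeros(len(merged), dtype=np.int64)
    count_b = np.zeros(len(merged), dtype=np.int64)
    known = merged["allele_a"].notna().to_numpy()
    for nuc in _NUCS:
        col = merged[nuc].to_numpy()
        count_a = np.where(
            known & (merged["allele_a"].to_numpy() == nuc), count_a + col, count_a
        )
        count_b = np.where(
            known & (merged["allele_b"].to_numpy() == nuc), count_b + col, count_b
        )
    out = merged[["chrom", "pos"]].copy()
    out["count_a"] = count_a
    out["count_b"] = count_b
    out["count_ambiguous"] = depth - count_a - count_b
    return out


def gene_proportions(
    site_assignments: pd.DataFrame, genes: pd.DataFrame
) -> list[AseGeneRecord]:
    """Sum species-of-origin counts over the sites contained in each gene.

    ``genes`` needs columns gene_id, chrom, start, end (1-based inclusive);
    overlapping genes are counted independently.  Genes without informative
    sites come back flagged (``informative`` False, proportion NaN).
    """
    records = []
    for g in genes.itertuples(index=False):
        mask = (
            (site_assignments["chrom"] == g.chrom)
            & (site_assignments["pos"] >= g.start)
            & (site_assignments["pos"] <= g.end)
        )
        sub = site_assignments.loc[mask]
        rec = AseGeneRecord(
            gene_id=str(g.gene_id),
            chrom=str(g.chrom),
            start=int(g.start),
            end=int(g.end),
            count_a=int(sub["count_a"].sum()),
            count_b=int(sub["count_b"].sum()),
            count_ambiguous=int(sub["count_ambiguous"].sum()),
            n_sites=int(len(sub)),
        )
        if not rec.informative:
            logger.info("gene %s has no informative site", rec.gene_id)
        records.append(rec)
    return records


def genes_to_frame(records: Iterable[AseGeneRecord]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": r.gene_id,
            "chrom": r.chrom,
            "start": r.start,
            "end": r.end,
            "count_a": r.count_a,
            "count_b": r.count_b,
            "count_ambiguous": r.count_ambiguous,
            "n_sites": r.n_sites,
            "proportion_b": r.proportion_b,
            "informative": r.informative,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "chrom", "start", "end", "count_a", "count_b",
            "count_ambiguous", "n_sites", "proportion_b", "informative",
        ],
    )


def detect_introgression(
    carrier: pd.DataFrame,
    non_carrier: pd.DataFrame,
    tau_absent: float = 0.02,
    tau_present: float = 0.2,
    min_genes: int = 5,
) -> pd.DataFrame:
    """Donor-introgression intervals from paired carrier/non-carrier profiles.

    Both inputs are gene frames (as from :func:`genes_to_frame`) sharing
    gene_id.  A donor block is a maximal run of at least ``min_genes``
    consecutive informative genes whose donor proportion is at least
    ``tau_present`` in the carrier group while the same genes stay at or
    below ``tau_absent`` in the non-carrier group.  Detection uses
    proportions only, so it is invariant to per-gene depth rescaling.
    Returns intervals (chrom, start, end, n_genes) spanning the first gene
    start to the last gene end of each run.
    """
    if not (0.0 <= tau_absent < tau_present <= 1.0):
        raise ValueError("need 0 <= tau_absent < tau_present <= 1")
    merged = carrier.merge(
        non_carrier[["gene_id", "proportion_b", "informative"]],
        on="gene_id",
        suffixes=("_carrier", "_noncarrier"),
    ).sort_values(["chrom", "start"], kind="stable")
    informative = (
        merged["informative_carrier"] & merged["informative_noncarrier"]
    ).to_numpy()
    if informative.sum() < min_genes:
        logger.warning("fewer than %d informative genes overall", min_genes)
        return pd.DataFrame(columns=["chrom", "start", "end", "n_genes"])

    intervals = []
    for chrom, grp in merged.groupby("chrom", sort=False):
        grp = grp[grp["informative_carrier"] & grp["informative_noncarrier"]]
        hit = (
            (grp["proportion_b_carrier"] >= tau_present)
            & (grp["proportion_b_noncarrier"] <= tau_absent)
        ).to_numpy()
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        run_start = None
        for j in range(len(hit) + 1):
            if j < len(hit) and hit[j]:
                if run_start is None:
                    run_start = j
            elif run_start is not None:
                if j - run_start >= min_genes:
                    intervals.append(
                        {
                            "chrom": chrom,
                            "start": int(starts[run_start]),
                            "end": int(ends[j - 1]),
                            "n_genes": j - run_start,
                        }
                    )
                run_start = None
    return pd.DataFrame(intervals, columns=["chrom", "start", "end", "n_genes"])


def naive_log2_ratio(
    counts_x: pd.Series | np.ndarray,
    counts_y: pd.Series | np.ndarray,
    pseudocount: float = 0.5,
) -> np.ndarray:
    """Exploratory per-gene log2 ratio of library-size-normalised counts.

    Not an inferential statistic: no dispersion model, no shrinkage, no
    p-values — a quick-look contrast only.
    """
    x = np.asarray(counts_x, dtype=float)
    y = np.asarray(counts_y, dtype=float)
    x_norm = (x + pseudocount) / (x.sum() + pseudocount * x.size)
    y_norm = (y + pseudocount) / (y.sum() + pseudocount * y.size)
    return np.log2(x_norm / y_norm)
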