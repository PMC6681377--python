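"""Synthetic cohorts, pools, pooled counts, expression and metabolite tables.

This generator produces data with the statistical structure the scan stages
assume, so the whole pipeline is testable end to end without sequencing
data:

* a segregating hybrid cohort in which a dominant major QTL on a donor
  haplotype produces bimodal segregation of the focal trait (ascorbic acid
  semantics, mg/100 g FW), while a second trait (fruit weight) segregates
  independently;
* a 2x2 pool design crossing the two traits, each pool holding the
  phenotypic extremes of its cell;
* pooled sequencing counts in Popoolation2 sync format at donor-diagnostic
  SNPs.  Inside a recombination-suppressed terminal block the donor
  haplotype is inherited as one unit, so every carrier contributes the
  donor allele at a fixed dosage fraction (0.25 for a tetraploid backcross
  carrier) at every block SNP; outside the block, sites segregate freely
  (Mendelian 1:1 per individual, independently per SNP);
* gene-level allele-of-origin expression counts showing the introgression
  step, and a log-normal metabolite feature table with planted fold
  changes.

Coordinates are 1-based inclusive everywhere, matching the sync convention.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ase import AseGeneRecord, genes_to_frame
from .pool_io import NUC_INDEX, SyncRecord

__all__ = [
    "GenomeModel",
    "QtlModel",
    "TraitParams",
    "Cohort",
    "PoolSpec",
    "simulate_cohort",
    "construct_pools",
    "simulate_pool_counts",
    "simulate_ase_counts",
    "simulate_metabolite_table",
    "write_cohort",
    "write_design",
    "load_config",
    "simulate_study",
]

_NUCS = ("A", "C", "G", "T")


@dataclass
class GenomeModel:
    """Chromosome sizes, donor-diagnostic SNP positions and the
    recombination-suppressed block inherited as one unit."""

    chromosomes: list[tuple[str, int]]
    snp_positions: dict[str, np.ndarray]
    suppressed_block: tuple[str, int, int]

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        for chrom, pos in self.snp_positions.items():
            pos = np.asarray(pos, dtype=np.int64)
            self.snp_positions[chrom] = pos
            if chrom not in lengths:
                raise ValueError(f"snp_positions references unknown chromosome {chrom}")
            if pos.size and (np.diff(pos) <= 0).any():
                raise ValueError(f"positions on {chrom} must be strictly increasing")
            if pos.size and (pos < 1).any():
                raise ValueError("positions are 1-based and must be >= 1")
            if pos.size and pos[-1] > lengths[chrom]:
                raise ValueError(f"position beyond end of {chrom}")
        bc, bs, be = self.suppressed_block
        if bc not in lengths:
            raise ValueError(f"suppressed block on unknown chromosome {bc}")
        if not (1 <= bs <= be <= lengths[bc]):
            raise ValueError("suppressed block must lie within its chromosome")

    @classmethod
    def regular(
        cls,
        n_chrom: int = 29,
        chrom_length: int = 25_000_000,
        snps_per_chrom: int = 200,
        block: tuple[str, int, int] = ("chr26", 1, 10_000_000),
    ) -> "GenomeModel":
        """Evenly spaced diagnostic SNPs on equal-length chromosomes."""
        chroms = [(f"chr{i + 1}", chrom_length) for i in range(n_chrom)]
        step = chrom_length / (snps_per_chrom + 1)
        pos = np.round(np.arange(1, snps_per_chrom + 1) * step).astype(np.int64)
        return cls(
            chromosomes=chroms,
            snp_positions={name: pos.copy() for name, _ in chroms},
            suppressed_block=block,
        )

    def chrom_length(self, chrom: str) -> int:
        return dict(self.chromosomes)[chrom]

    def nearest_snp(self, chrom: str, pos: int) -> int:
        """Position of the diagnostic SNP closest to ``pos`` on ``chrom``."""
        arr = self.snp_positions[chrom]
        if arr.size == 0:
            raise ValueError(f"no SNPs on {chrom}")
        return int(arr[np.argmin(np.abs(arr - pos))])

    def in_block(self, chrom: str, pos: np.ndarray | int) -> np.ndarray | bool:
        bc, bs, be = self.suppressed_block
        return (chrom == bc) & (np.asarray(pos) >= bs) & (np.asarray(pos) <= be)


@dataclass
class QtlModel:
    """A dominant major QTL carried on a donor haplotype.

    ``effect`` is added to the focal trait of every carrier (carrier status,
    not dosage, sets the effect).  ``donor_dosage_fraction`` is the fraction
    of a carrier's chromatids bearing the donor allele: 0.25 for a
    tetraploid backcross carrier (one donor homologue of four), 0.5 for a
    diploid heterozygote.
    """

    locus: tuple[str, int] = ("chr26", 7_587_065)  # nearest default-grid SNP to 7.6 Mbp
    effect: float = 250.0
    dominance: bool = True
    donor_dosage_fraction: float = 0.25

    def __post_init__(self) -> None:
        if not (0.0 < self.donor_dosage_fraction <= 0.5):
            raise ValueError("donor_dosage_fraction must be in (0, 0.5]")


@dataclass
class TraitParams:
    """Within-genotype-class trait distributions.

    Defaults reproduce the published pool phenotype summaries when combined
    with the 250-unit dominant effect: non-carrier focal-trait mean 94 with
    SD 33 (so carriers centre near 344), and an independent second trait
    (fruit-weight semantics) with mean 76, SD 22.  Families shift the focal
    trait by a normal random effect with SD ``family_sd``.
    """

    trait1_mean: float = 94.0
    trait1_sd: float = 33.0
    trait2_mean: float = 76.0
    trait2_sd: float = 22.0
    family_sd: float = 15.0
    n_families: int = 11

    def __post_init__(self) -> None:
        for name in ("trait1_sd", "trait2_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.family_sd < 0:
            raise ValueError("family_sd must be non-negative")
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")


@dataclass
class Cohort:
    """Simulated individuals with QTL carrier status and two phenotypes."""

    individuals: pd.DataFrame  # columns: id, family, carrier, trait1, trait2
    trait_params: TraitParams

    def carriers(self) -> pd.Series:
        return self.individuals.set_index("id")["carrier"]

    def __len__(self) -> int:
        return len(self.individuals)


@dataclass
class PoolSpec:
    """One sequencing pool: a cell of the 2x2 trait design."""

    pool_id: int
    trait1: str  # 'high' | 'low'
    trait2: str
    member_ids: list[str]


def simulate_cohort(
    genome: GenomeModel,
    qtl: QtlModel,
    n: int,
    seed: int | None = None,
    params: TraitParams | None = None,
    segregation: float = 0.5,
    rng: np.random.Generator | None = None,
) -> Cohort:
    """Simulate a segregating cohort with a dominant major-QTL focal trait.

    Carriers occur at the configured segregation ratio (1:1 by default) and
    receive ``qtl.effect`` on trait1; trait2 is drawn independently of
    carrier status; both traits are normal within genotype class.
    """
    if n < 4:
        raise ValueError("n must be >= 4")
    params = params or TraitParams()
    chrom, pos = qtl.locus
    if pos not in genome.snp_positions.get(chrom, np.empty(0)):
        raise ValueError(
            f"QTL locus {chrom}:{pos} is not among the genome's SNP positions"
        )
    rng = rng if rng is not None else np.random.default_rng(seed)
    carrier = rng.random(n) < segregation
    family = rng.integers(0, params.n_families, size=n)
    fam_eff = rng.normal(0.0, params.family_sd, size=params.n_families)
    trait1 = (
        params.trait1_mean
        + fam_eff[family]
        + qtl.effect * carrier
        + rng.normal(0.0, params.trait1_sd, size=n)
    )
    trait2 = rng.normal(params.trait2_mean, params.trait2_sd, size=n)
    df = pd.DataFrame(
        {
            "id": [f"ind{i + 1:04d}" for i in range(n)],
            "family": [f"fam{f + 1:02d}" for f in family],
            "carrier": carrier,
            "trait1": trait1,
            "trait2": trait2,
        }
    )
    return Cohort(individuals=df, trait_params=params)


def construct_pools(cohort: Cohort, n_per_pool: int = 20) -> list[PoolSpec]:
    """Allocate phenotypic extremes to the four pools of the 2x2 design.

    The cohort is split at the trait2 median into high/low strata; within
    each stratum the top ``n_per_pool`` individuals by trait1 form the
    trait1-high pool and the bottom ``n_per_pool`` the trait1-low pool.
    Deterministic given the cohort (stable rank order, ties by id).
    Pool ids follow the published layout: 1 = high/high, 2 = high/low,
    3 = low/high, 4 = low/low (trait1/trait2).
    """
    df = cohort.individuals
    order2 = df.sort_values(["trait2", "id"], ascending=[False, True], kind="stable")
    n_high = len(df) // 2
    strata = {"high": order2.iloc[:n_high], "low": order2.iloc[n_high:]}
    pools: list[PoolSpec] = []
    layout = {("high", "high"): 1, ("high", "low"): 2,
              ("low", "high"): 3, ("low", "low"): 4}
    for t2_level, sub in strata.items():
        if len(sub) < 2 * n_per_pool:
            raise ValueError(
                f"trait2-{t2_level} stratum has {len(sub)} individuals; "
                f"need {2 * n_per_pool} to fill two disjoint pools"
            )
        order1 = sub.sort_values(["trait1", "id"], ascending=[False, True],
                                 kind="stable")
        top = order1.iloc[:n_per_pool]["id"].tolist()
        bottom = order1.iloc[-n_per_pool:]["id"].tolist()
        pools.append(PoolSpec(layout[("high", t2_level)], "high", t2_level, top))
        pools.append(PoolSpec(layout[("low", t2_level)], "low", t2_level, bottom))
    pools.sort(key=lambda p: p.pool_id)
    return pools


def simulate_pool_counts(
    pools: Sequence[PoolSpec],
    cohort: Cohort,
    genome: GenomeModel,
    qtl: QtlModel,
    depth_mean: float = 40.0,
    error_rate: float = 0.0,
    seed: int | None = None,
    return_freqs: bool = False,
):
    """Pooled sequencing counts at every diagnostic SNP, in sync layout.

    Inside the suppressed block containing the QTL the donor-allele
    frequency of a pool is (carriers in pool x donor_dosage_fraction) /
    pool size — constant across all block SNPs (zero recombination).
    Elsewhere each individual carries the donor allele with probability 1/2
    independently per SNP (free recombination between SNP blocks), so the
    pool frequency is Binomial(pool size, 1/2) x dosage / size.  Read
    counts are binomial at a Poisson(``depth_mean``) simulated depth; a
    fraction ``error_rate`` of reads is redistributed uniformly to the
    other nucleotides.

    Returns the list of :class:`~poolqtl.pool_io.SyncRecord` (and, with
    ``return_freqs``, a frame of the pre-read-sampling donor frequencies).
    """
    if depth_mean <= 0:
        raise ValueError("depth_mean must be positive")
    if not (0.0 <= error_rate < 0.05):
        raise ValueError("error_rate must be in [0, 0.05)")
    qchrom, qpos = qtl.locus
    if qpos not in genome.snp_positions.get(qchrom, np.empty(0)):
        raise ValueError(f"QTL locus {qchrom}:{qpos} not among snp_positions")

    rng = np.random.default_rng(seed)
    carrier_by_id = cohort.carriers()
    n_carriers = np.array(
        [int(carrier_by_id.loc[p.member_ids].sum()) for p in pools]
    )
    sizes = np.array([len(p.member_ids) for p in pools])
    ddf = qtl.donor_dosage_fraction
    n_pools = len(pools)

    records: list[SyncRecord] = []
    freq_rows: list[pd.DataFrame] = []
    for chrom, _length in genome.chromosomes:
        pos = genome.snp_positions.get(chrom)
        if pos is None or pos.size == 0:
            continue
        s = pos.size
        ref_idx = rng.integers(0, 4, size=s)
        alt_idx = (ref_idx + rng.integers(1, 4, size=s)) % 4
        block = np.asarray(genome.in_block(chrom, pos))

        freqs = np.empty((s, n_pools))
        for p in range(n_pools):
            linked = n_carriers[p] * ddf / sizes[p]
            free = rng.binomial(sizes[p], 0.5, size=s) * ddf / sizes[p]
            freqs[:, p] = np.where(block, linked, free)

        depth = rng.poisson(depth_mean, size=(s, n_pools))
        donor = rng.binomial(depth, freqs)
        ref_reads = depth - donor

        counts = np.zeros((s, n_pools, 6), dtype=np.int64)
        for j in range(s):
            counts[j, :, NUC_INDEX[_NUCS[ref_idx[j]]]] += ref_reads[j]
            counts[j, :, NUC_INDEX[_NUCS[alt_idx[j]]]] += donor[j]

        if error_rate > 0:
            n_err = rng.binomial(depth, error_rate)
            for j, p in zip(*np.nonzero(n_err)):
                _apply_errors(counts[j, p], int(n_err[j, p]), rng)

        for j in range(s):
            records.append(
                SyncRecord(chrom, int(pos[j]), _NUCS[ref_idx[j]], counts[j])
            )
        if return_freqs:
            freq_rows.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": np.repeat(pos, n_pools),
                        "pool_id": np.tile([p.pool_id for p in pools], s),
                        "freq": freqs.ravel(),
                    }
                )
            )
    if return_freqs:
        return records, pd.concat(freq_rows, ignore_index=True)
    return records


def _apply_errors(counts6: np.ndarray, n_err: int, rng: np.random.Generator) -> None:
    """Reassign ``n_err`` reads, drawn without replacement from the existing
    nucleotide counts, uniformly to one of the three other nucleotides
    (in place; operates on the four nucleotide columns of the sync row)."""
    take = rng.multivariate_hypergeometric(counts6[:4], n_err)
    counts6[:4] -= take
    for src in range(4):
        for _ in range(int(take[src])):
            dest = (src + int(rng.integers(1, 4))) % 4
            counts6[dest] += 1


def simulate_ase_counts(
    genome: GenomeModel,
    carriers: Sequence[bool],
    n_genes: int,
    bias: float = 0.5,
    depth_mean: float = 200.0,
    error_rate: float = 0.0,
    seed: int | None = None,
    gene_length: int = 5_000,
) -> tuple[pd.DataFrame, list[pd.DataFrame]]:
    """Gene-level allele-of-origin expression counts along the block chromosome.

    Genes are spaced evenly along the chromosome bearing the suppressed
    block.  In carrier samples, genes inside the introgression express the
    donor allele with proportion ``bias`` (0.5 = unbiased heterozygote);
    non-carrier samples, and genes outside the introgression, see donor
    reads only at ``error_rate``.  Returns the gene table and one profile
    frame per entry of ``carriers``.
    """
    if not (0.0 <= bias <= 1.0):
        raise ValueError("bias must be in [0, 1]")
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    rng = np.random.default_rng(seed)
    chrom = genome.suppressed_block[0]
    length = genome.chrom_length(chrom)
    starts = (np.round(np.arange(n_genes) * length / max(n_genes, 1))
              .astype(np.int64) + 1)
    ends = np.minimum(starts + gene_length - 1, length)
    genes = pd.DataFrame(
        {
            "gene_id": [f"gene{i + 1:04d}" for i in range(n_genes)],
            "chrom": chrom,
            "start": starts,
            "end": ends,
        }
    )
    mid = (starts + ends) // 2
    inside = np.asarray(genome.in_block(chrom, mid), dtype=bool)

    profiles = []
    for is_carrier in carriers:
        depth = rng.poisson(depth_mean, size=n_genes)
        p_donor = np.where(inside & is_carrier, bias, error_rate)
        count_b = rng.binomial(depth, p_donor)
        recs = [
            AseGeneRecord(
                gene_id=genes["gene_id"].iloc[i],
                chrom=chrom,
                start=int(starts[i]),
                end=int(ends[i]),
                count_a=int(depth[i] - count_b[i]),
                count_b=int(count_b[i]),
                count_ambiguous=0,
                n_sites=1,
            )
            for i in range(n_genes)
        ]
        profiles.append(genes_to_frame(recs))
    return genes, profiles


def simulate_metabolite_table(
    n_features: int,
    n_per_group: int,
    effect_features: Mapping[int, float] | None = None,
    cv: float = 0.2,
    seed: int | None = None,
    base_log_mean: float = 9.0,
    base_log_sd: float = 1.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Log-normal feature areas with planted fold changes in the (+) group.

    Per-sample areas are log-normal around a per-feature base area with
    coefficient of variation ``cv`` (mean-preserving); features listed in
    ``effect_features`` are multiplied by their fold change in the (+)
    group.  Returns (feature x sample frame, sample->group labels).
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if cv <= 0:
        raise ValueError("cv must be positive")
    effect_features = dict(effect_features or {})
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(cv * cv))
    base = np.exp(rng.normal(base_log_mean, base_log_sd, size=n_features))
    noise = np.exp(
        rng.normal(-0.5 * sigma * sigma, sigma, size=(n_features, 2 * n_per_group))
    )
    areas = base[:, None] * noise
    fold = np.ones(n_features)
    for idx, fc in effect_features.items():
        fold[idx] = fc
    areas[:, :n_per_group] *= fold[:, None]
    cols = [f"plus_{i + 1:03d}" for i in range(n_per_group)] + [
        f"minus_{i + 1:03d}" for i in range(n_per_group)
    ]
    table = pd.DataFrame(
        areas, index=[f"feat{i + 1:04d}" for i in range(n_features)], columns=cols
    )
    groups = pd.Series(
        ["plus"] * n_per_group + ["minus"] * n_per_group, index=cols
    )
    return table, groups


# ---------------------------------------------------------------------------
# file output and study orchestration

def write_cohort(cohort: Cohort, path: str | Path) -> None:
    cohort.individuals.to_csv(path, sep="\t", index=False)


def write_design(pools: Sequence[PoolSpec], path: str | Path) -> None:
    """Design TSV: pool id, trait1 stratum, trait2 stratum, member ids."""
    df = pd.DataFrame(
        {
            "pool_id": [p.pool_id for p in pools],
            "trait1": [p.trait1 for p in pools],
            "trait2": [p.trait2 for p in pools],
            "members": [",".join(p.member_ids) for p in pools],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def simulate_study(
    config: dict | None = None,
    seed: int | None = None,
    outdir: str | Path | None = None,
):
    """Run the default study simulation: cohort -> pools -> sync counts.

    ``config`` keys (all optional): n_chrom, chrom_length, snps_per_chrom,
    block_start, block_end, qtl_pos, effect, dosage_fraction, n, n_per_pool,
    depth_mean, error_rate.  With ``outdir`` set, writes pools.sync,
    cohort.tsv and design.tsv there.
    """
    cfg = dict(config or {})
    genome = GenomeModel.regular(
        n_chrom=cfg.get("n_chrom", 29),
        chrom_length=cfg.get("chrom_length", 25_000_000),
        snps_per_chrom=cfg.get("snps_per_chrom", 200),
        block=("chr26", cfg.get("block_start", 1), cfg.get("block_end", 10_000_000)),
    )
    qtl = QtlModel(
        locus=("chr26", genome.nearest_snp("chr26", cfg.get("qtl_pos", 7_600_000))),
        effect=cfg.get("effect", 250.0),
        donor_dosage_fraction=cfg.get("dosage_fraction", 0.25),
    )
    rng = np.random.default_rng(seed)
    cohort = simulate_cohort(genome, qtl, n=cfg.get("n", 200),
                             rng=rng)
    pools = construct_pools(cohort, n_per_pool=cfg.get("n_per_pool", 20))
    records = simulate_pool_counts(
        pools, cohort, genome, qtl,
        depth_mean=cfg.get("depth_mean", 40.0),
        error_rate=cfg.get("error_rate", 0.0),
        seed=int(rng.integers(2**31)),
    )
    if outdir is not None:
        from .pool_io import write_sync

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_sync(records, outdir / "pools.sync")
        write_cohort(cohort, outdir / "cohort.tsv")
        write_design(pools, outdir / "design.tsv")
    return genome, qtl, cohort, pools, records
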