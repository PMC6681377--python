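"""Cohort, pool, pooled-count, expression and metabolite generators."""

import numpy as np
import pandas as pd
import pytest

from poolqtl.pool_io import write_sync
from poolqtl.synthetic_data import (
    GenomeModel,
    QtlModel,
    TraitParams,
    construct_pools,
    simulate_ase_counts,
    simulate_cohort,
    simulate_metabolite_table,
    simulate_pool_counts,
)

# printed pool phenotype summaries used as the preset calibration check:
# (focal-trait mean, SD) per pool of the published 2x2 design
TABLE3 = {
    1: (385.9, 59.5),
    2: (433.55, 57.1),
    3: (100.15, 41.12),
    4: (87.25, 24.56),
}
TABLE3_FW = {1: (96.6, 10.85), 2: (56.6, 13.51), 3: (95.65, 15.13), 4: (59.85, 15.04)}


class TestSimulateCohort:
    def test_null_effect_uncorrelated(self, small_genome, small_qtl):
        qtl = QtlModel(locus=small_qtl.locus, effect=0.0)
        cohort = simulate_cohort(small_genome, qtl, n=2000, seed=0)
        df = cohort.individuals
        r = np.corrcoef(df["carrier"].astype(float), df["trait1"])[0, 1]
        assert abs(r) < 0.1

    def test_effect_recovered_at_large_n(self, small_genome, small_qtl):
        params = TraitParams(trait1_sd=50.0, family_sd=0.0)
        cohort = simulate_cohort(
            small_genome, small_qtl, n=2000, seed=1, params=params
        )
        df = cohort.individuals
        diff = (
            df.loc[df.carrier, "trait1"].mean()
            - df.loc[~df.carrier, "trait1"].mean()
        )
        assert diff == pytest.approx(250.0, abs=5.0)

    def test_trait2_independent_of_carrier(self, small_genome, small_qtl):
        cohort = simulate_cohort(small_genome, small_qtl, n=1500, seed=2)
        df = cohort.individuals
        r = np.corrcoef(df["carrier"].astype(float), df["trait2"])[0, 1]
        assert abs(r) < 0.1

    def test_default_preset_reproduces_published_pool_means(
        self, small_genome, small_qtl
    ):
        """Generated pool phenotype means fall within 2 printed SDs of the
        published pool summaries under the default trait preset."""
        cohort = simulate_cohort(small_genome, small_qtl, n=200, seed=3)
        pools = construct_pools(cohort, n_per_pool=20)
        by_id = cohort.individuals.set_index("id")
        for pool in pools:
            mean1 = by_id.loc[pool.member_ids, "trait1"].mean()
            mean2 = by_id.loc[pool.member_ids, "trait2"].mean()
            m, sd = TABLE3[pool.pool_id]
            assert abs(mean1 - m) < 2 * sd, f"pool {pool.pool_id} focal trait"
            m2, sd2 = TABLE3_FW[pool.pool_id]
            assert abs(mean2 - m2) < 2 * sd2, f"pool {pool.pool_id} second trait"

    def test_parameter_validation(self, small_genome, small_qtl):
        with pytest.raises(ValueError, match="n must"):
            simulate_cohort(small_genome, small_qtl, n=2, seed=0)
        with pytest.raises(ValueError, match="trait1_sd"):
            TraitParams(trait1_sd=-1.0)

    def test_locus_must_be_a_snp(self, small_genome):
        qtl = QtlModel(locus=("chr1", 123))
        with pytest.raises(ValueError, match="not among"):
            simulate_cohort(small_genome, qtl, n=10, seed=0)


class TestConstructPools:
    def test_four_disjoint_pools_of_twenty(self, small_genome, small_qtl):
        cohort = simulate_cohort(small_genome, small_qtl, n=200, seed=4)
        pools = construct_pools(cohort, n_per_pool=20)
        assert len(pools) == 4
        members = [m for p in pools for m in p.member_ids]
        assert len(members) == 80 and len(set(members)) == 80
        assert {(p.trait1, p.trait2) for p in pools} == {
            ("high", "high"), ("high", "low"), ("low", "high"), ("low", "low")
        }

    def test_exhaustive_allocation_of_four(self, small_genome, small_qtl):
        cohort = simulate_cohort(small_genome, small_qtl, n=4, seed=5)
        pools = construct_pools(cohort, n_per_pool=1)
        members = sorted(m for p in pools for m in p.member_ids)
        assert members == sorted(cohort.individuals["id"])

    def test_strong_effect_pools_are_pure(self, small_genome):
        qtl = QtlModel(locus=("chr1", GenomeModel.regular(
            n_chrom=2, chrom_length=2_000_000, snps_per_chrom=20,
            block=("chr1", 1, 800_000)).nearest_snp("chr1", 500_000)),
            effect=250.0)
        params = TraitParams(trait1_sd=10.0, family_sd=0.0)
        cohort = simulate_cohort(small_genome, qtl, n=200, seed=6, params=params)
        pools = construct_pools(cohort, n_per_pool=20)
        carriers = cohort.carriers()
        for p in pools:
            frac = carriers.loc[p.member_ids].mean()
            assert frac == (1.0 if p.trait1 == "high" else 0.0)

    def test_rank_selection_oracle(self, small_genome, small_qtl):
        """Pool membership equals an independent rank-based reselection."""
        cohort = simulate_cohort(small_genome, small_qtl, n=100, seed=7)
        pools = {(p.trait1, p.trait2): set(p.member_ids)
                 for p in construct_pools(cohort, n_per_pool=10)}
        df = cohort.individuals.sort_values(["trait2", "id"],
                                            ascending=[False, True])
        high2, low2 = df.iloc[:50], df.iloc[50:]
        for stratum, name in ((high2, "high"), (low2, "low")):
            ranked = stratum.sort_values(["trait1", "id"], ascending=[False, True])
            assert set(ranked.iloc[:10]["id"]) == pools[("high", name)]
            assert set(ranked.iloc[-10:]["id"]) == pools[("low", name)]

    def test_insufficient_stratum_reported(self, small_genome, small_qtl):
        cohort = simulate_cohort(small_genome, small_qtl, n=30, seed=8)
        with pytest.raises(ValueError, match="stratum"):
            construct_pools(cohort, n_per_pool=10)


class TestSimulatePoolCounts:
    def make_study(self, small_genome, small_qtl, seed=9, **kwargs):
        params = TraitParams(trait1_sd=10.0, family_sd=0.0)
        cohort = simulate_cohort(small_genome, small_qtl, n=200, seed=seed,
                                 params=params)
        pools = construct_pools(cohort, n_per_pool=20)
        return cohort, pools

    def test_carrier_pool_frequency_quarter_at_high_depth(
        self, small_genome, small_qtl
    ):
        """All-carrier bulk, dosage 1/4, error 0: donor fraction 0.25."""
        cohort, pools = self.make_study(small_genome, small_qtl)
        records = simulate_pool_counts(
            pools, cohort, small_genome, small_qtl,
            depth_mean=1e6, error_rate=0.0, seed=10,
        )
        carriers = cohort.carriers()
        qpos = small_qtl.locus[1]
        (rec,) = [r for r in records if r.chrom == "chr1" and r.pos == qpos]
        for i, pool in enumerate(pools):
            depth = rec.pools[i].sum()
            ref_count = rec.pools[i][
                ["A", "T", "C", "G", "N", "del"].index(rec.ref)
            ]
            donor_frac = (depth - ref_count) / depth
            if carriers.loc[pool.member_ids].all():
                assert donor_frac == pytest.approx(0.25, abs=1e-3)
            elif not carriers.loc[pool.member_ids].any():
                assert donor_frac == 0.0

    def test_noncarrier_pool_zero_donor_in_block(self, small_genome, small_qtl):
        cohort, pools = self.make_study(small_genome, small_qtl)
        records, freqs = simulate_pool_counts(
            pools, cohort, small_genome, small_qtl, seed=11, return_freqs=True,
        )
        carriers = cohort.carriers()
        noncarrier_ids = [p.pool_id for p in pools
                          if not carriers.loc[p.member_ids].any()]
        block = freqs["chrom"].eq("chr1") & freqs["pos"].le(800_000)
        sub = freqs[block & freqs["pool_id"].isin(noncarrier_ids)]
        assert (sub["freq"] == 0.0).all()

    def test_linkage_block_frequency_constant(self, small_genome, small_qtl):
        """Pre-sampling donor frequency is constant across block SNPs."""
        cohort, pools = self.make_study(small_genome, small_qtl)
        _, freqs = simulate_pool_counts(
            pools, cohort, small_genome, small_qtl, seed=12, return_freqs=True,
        )
        block = freqs["chrom"].eq("chr1") & freqs["pos"].le(800_000)
        per_pool = freqs[block].groupby("pool_id")["freq"].nunique()
        assert (per_pool == 1).all()

    def test_seed_determinism_byte_identical(
        self, small_genome, small_qtl, tmp_path
    ):
        cohort, pools = self.make_study(small_genome, small_qtl)
        texts = []
        for run in range(2):
            records = simulate_pool_counts(
                pools, cohort, small_genome, small_qtl,
                error_rate=0.01, seed=13,
            )
            path = tmp_path / f"run{run}.sync"
            write_sync(records, path)
            texts.append(path.read_text())
        assert texts[0] == texts[1]

    def test_counts_conserved_under_errors(self, small_genome, small_qtl):
        """Base errors move reads between nucleotides, never create or
        destroy them: depths are Poisson-distributed around the mean."""
        cohort, pools = self.make_study(small_genome, small_qtl)
        records = simulate_pool_counts(
            pools, cohort, small_genome, small_qtl,
            depth_mean=40, error_rate=0.04, seed=14,
        )
        depths = np.array([r.depths() for r in records], dtype=float)
        assert depths.mean() == pytest.approx(40.0, rel=0.05)
        assert (depths.sum(axis=1) >= 0).all()

    def test_qtl_off_grid_rejected(self, small_genome, small_qtl):
        cohort, pools = self.make_study(small_genome, small_qtl)
        bad = QtlModel(locus=("chr1", 999))
        with pytest.raises(ValueError, match="not among"):
            simulate_pool_counts(pools, cohort, small_genome, bad, seed=0)


class TestSimulateAseCounts:
    def test_noncarrier_zero_donor(self, small_genome):
        _, (profile,) = simulate_ase_counts(
            small_genome, carriers=[False], n_genes=50, error_rate=0.0, seed=0
        )
        assert (profile["proportion_b"] == 0.0).all()

    def test_carrier_block_proportion_half(self, small_genome):
        _, (profile,) = simulate_ase_counts(
            small_genome, carriers=[True], n_genes=50, bias=0.5,
            depth_mean=1e5, seed=1,
        )
        inside = profile["start"] < 800_000 - 5_000
        assert np.allclose(profile.loc[inside, "proportion_b"], 0.5, atol=0.01)

    def test_step_at_introgression_boundary(self, small_genome):
        _, (profile,) = simulate_ase_counts(
            small_genome, carriers=[True], n_genes=100, bias=0.5,
            depth_mean=100, seed=2,
        )
        mid = (profile["start"] + profile["end"]) // 2
        inside = mid <= 800_000
        step = (profile.loc[inside, "proportion_b"].mean()
                - profile.loc[~inside, "proportion_b"].mean())
        assert step > 0.3

    def test_no_genes_is_empty_not_error(self, small_genome):
        genes, (profile,) = simulate_ase_counts(
            small_genome, carriers=[True], n_genes=0, seed=3
        )
        assert len(genes) == 0 and len(profile) == 0


class TestMetaboliteTable:
    def test_unit_fold_centres_ratio_at_one(self):
        table, groups = simulate_metabolite_table(50, 30, cv=0.2, seed=0)
        plus = table.loc[:, groups == "plus"].mean(axis=1)
        minus = table.loc[:, groups == "minus"].mean(axis=1)
        log_ratios = np.log(plus / minus)
        assert abs(log_ratios.mean()) < 0.05

    def test_planted_fold_recovered(self):
        table, groups = simulate_metabolite_table(
            10, 65, effect_features={3: 6.36}, cv=0.2, seed=1
        )
        plus = table.iloc[3][groups == "plus"].mean()
        minus = table.iloc[3][groups == "minus"].mean()
        assert plus / minus == pytest.approx(6.36, rel=0.2)

    def test_seed_reproducibility(self):
        t1, _ = simulate_metabolite_table(5, 4, cv=0.3, seed=7)
        t2, _ = simulate_metabolite_table(5, 4, cv=0.3, seed=7)
        pd.testing.assert_frame_equal(t1, t2)

    def test_invalid_cv_rejected(self):
        with pytest.raises(ValueError, match="cv"):
            simulate_metabolite_table(5, 4, cv=0.0, seed=0)
        with pytest.raises(ValueError):
            simulate_metabolite_table(5, 1, cv=0.2, seed=0)
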