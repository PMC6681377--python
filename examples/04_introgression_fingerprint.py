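"""Fingerprint the donor introgression from allelic expression proportions.

Gene-level expression counts are split by species of origin at homeo-SNPs;
the donor proportion steps from ~0.5 (heterozygous carriers) to ~0 at the
introgression boundary, and stays ~0 everywhere in non-carriers.
"""

from poolqtl.ase import detect_introgression
from poolqtl.synthetic_data import GenomeModel, simulate_ase_counts

genome = GenomeModel.regular()  # suppressed block chr26:1-10,000,000
genes, (carrier, non_carrier) = simulate_ase_counts(
    genome, carriers=[True, False], n_genes=100, bias=0.5,
    depth_mean=200.0, error_rate=0.0, seed=0,
)

inside = carrier["end"] <= 10_000_000
print(f"carrier donor proportion: {carrier.loc[inside, 'proportion_b'].mean():.3f} "
      f"inside the block, {carrier.loc[~inside, 'proportion_b'].mean():.3f} outside")
print(f"non-carrier donor proportion (max): "
      f"{non_carrier['proportion_b'].max():.3f}")

intervals = detect_introgression(carrier, non_carrier,
                                 tau_absent=0.02, tau_present=0.2, min_genes=5)
for iv in intervals.itertuples(index=False):
    print(f"donor introgression: {iv.chrom}:{iv.start}-{iv.end} "
          f"({iv.n_genes} genes)")
print("The recovered boundary sits within one inter-gene gap (250 kb) of")
print("the true 10-Mbp block edge — the expression-level fingerprint of a")
print("recombination-suppressed donor segment.")
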