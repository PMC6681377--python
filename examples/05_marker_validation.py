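"""Validate a co-dominant marker: two-way ANOVA and recombinant detection.

Trait value is modelled on marker dosage (donor-allele copies, entered
first) plus family; the sequential decomposition reports the share of
variance each term explains and the additive allele effect.
"""

import numpy as np
import pandas as pd

from poolqtl.downstream_stats import detect_recombinants, two_way_anova

rng = np.random.default_rng(0)
n = 196
dosage = rng.integers(0, 2, n)
family = np.array(["AI247", "AJ247"])[rng.integers(0, 2, n)]
fam_shift = {"AI247": 0.0, "AJ247": 60.0}
trait = (95 + 250.0 * dosage
         + np.array([fam_shift[f] for f in family])
         + rng.normal(0, 55.0, n))
table = pd.DataFrame({
    "individual": [f"v{j:03d}" for j in range(n)],
    "dosage": dosage, "family": family, "trait": trait,
})
# plant one genotyping/recombination error
table.loc[17, "dosage"] = 1 - table.loc[17, "dosage"]

fit = two_way_anova(table)
print(fit.terms.round(3).to_string())
print(f"\nallele effect: +{fit.effect:.1f} trait units per donor copy")
recs = detect_recombinants(table, fit, z_cut=2.5)
print(f"putative recombinants: {len(recs)}/{n}: {recs}")
print("Dosage explains the bulk of the variance; the planted mislabel is")
print("recovered as a residual outlier lying in the opposite marker class.")
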