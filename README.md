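# poolqtl

Pooled-sequencing QTL discovery for segregating hybrid populations:
replicated Cochran–Mantel–Haenszel (CMH) association scans over
phenotype-selected pools, QTL-seq bulked-segregant analysis (BSA) with
simulation-derived thresholds — including a tetraploid backcross
population model (`BC4x`) — homeo-SNP allele-of-origin fingerprinting of
donor introgressions, and the downstream marker-validation and
metabolite-contrast statistics. A synthetic-data module generates cohorts,
pools, sync-format pooled counts, allelic expression profiles and
metabolite tables with the structure these methods assume, so the whole
pipeline is testable without sequencing data.

The package is aimed at plant geneticists mapping large-effect loci in
crosses where individual genotyping is impractical (polyploid, highly
heterozygous hybrids): phenotypic extremes are pooled, sequenced, and
allele frequencies do the mapping.

## The statistics

**CMH pool scan.** Four pools form a 2x2 design of the focal trait crossed
with an orthogonal trait. At each biallelic site, K stratified 2x2
allele-count tables (high vs low focal-trait pool, within each level of the
orthogonal trait) are combined as

```
chi2 = ( |Σ_k (a_k − r1_k c1_k / n_k)| )² / Σ_k r1_k r2_k c1_k c2_k / (n_k² (n_k − 1))
```

with 1 df, the Mantel–Haenszel common odds ratio
`(Σ a_k d_k / n_k)/(Σ b_k c_k / n_k)` as effect size, and genome-wide
Benjamini–Hochberg adjustment.

**QTL-seq BSA.** Per bulk, the SNP-index is `alt/(ref+alt)`;
Δ(SNP-index) = high − low bulk is tricube-smoothed in 1-Mbp windows and
compared against a simulated null (genotype sampling of bulk members, then
binomial read sampling at the observed depth). Under `BC4x` — a dominant
donor haplotype on one of four homologues segregating 1:1 — a carrier bulk
expects donor-allele frequency 0.25 and a non-carrier bulk 0. Intervals
are called at BH FDR < 0.001.

**Introgression fingerprint.** Expression counts split by species of
origin at fixed interspecific SNPs give per-gene donor proportions; a
recombination-suppressed donor block shows proportions near 0.5 in
carriers and near 0 in non-carriers, with a sharp step at its boundary.

**Validation statistics.** Two-way sequential ANOVA of trait on marker
dosage + family (variance shares, additive allele effect, residual-based
recombinant detection) and metabolite group contrasts (ratio of group
means, log2 fold change, Welch t-test).

See `docs/methods.md` for assumptions, defaults and numerical choices.

## Worked example

`examples/` contains one short script per capability. Simulating the
default study (29 chromosomes x 200 diagnostic SNPs, 4 pools of 20 at
depth 40, a dominant 250-unit QTL inside the suppressed block
chr26:1–10 Mbp) and scanning it:

```python
from poolqtl.cmh_scan import PoolDesign, scan
from poolqtl.synthetic_data import simulate_study

genome, qtl, cohort, pools, records = simulate_study(seed=0)
res = scan(records, PoolDesign.standard())
print(res.loc[res.p_adj.idxmin()])
```

Running `python examples/02_cmh_scan.py` prints:

```
scanned 5800 sites
strongest association: chr26:6592040 chi2=39.2 p_adj=2.27e-06 OR_MH=0.000
sites with p_adj < 0.001: 52 (52 inside the suppressed block chr26:1-10Mb)
orthogonal-trait contrast: min p_adj = 0.042 (no significant association, ...)
```

The strongest association and every FDR<0.001 site sit inside the
suppressed block carrying the QTL; the common odds ratio of 0 reflects a
donor allele entirely absent from the low pools; the orthogonal
(fruit-weight) contrast finds nothing. The companion BSA scan
(`examples/03_bsa_scan.py`) localises the same region from both
independent bulk pairings:

```
bulk pairing pools 1 vs 3:
  QTL interval chr26:124378-10074627 (81 SNPs, peak delta 0.34 at 2611940)
bulk pairing pools 2 vs 4:
  QTL interval chr26:124378-9950249 (80 SNPs, peak delta 0.28 at 4726368)
```

with peak Δ(SNP-index) near the 0.25 carrier-bulk expectation of the
`BC4x` model.

A thin CLI mirrors the library (`poolqtl simulate | filter | resample |
cmh | bsa | ase | validate-marker | metab`); run `poolqtl --help`.

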