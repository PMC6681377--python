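# Methods

`poolqtl` implements the statistical stack for discovering a dominant
major QTL by pooled sequencing of phenotypic extremes in a hybrid
population, together with a synthetic-data generator that reproduces the
structure those statistics assume. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic data
does and does not emulate.

## Study design and population model

The design crosses two traits. A focal quantitative trait (ascorbic acid
semantics, mg/100 g fresh weight) segregates bimodally because a dominant
major QTL rides on a donor-species haplotype; a second trait (fruit
weight) varies independently. Four pools of 20 individuals each occupy the
cells of the 2x2 high/low design, giving two replicated strata for each
trait's association scan and two independent bulk pairings for
bulked-segregant analysis.

The mapping population is a tetraploid backcross, modelled as `BC4x`: a
carrier bears the donor haplotype on one of four homologues, carriers
segregate 1:1, and selection on the dominant phenotype is assumed perfect.
An all-carrier bulk therefore has expected donor-allele frequency exactly
0.25 at a perfectly linked site and a non-carrier bulk exactly 0; at an
unlinked (null) site, each bulk member is a carrier with probability 1/2
and contributes dosage 0.25, so the null bulk frequency is
`Binomial(n, 1/2) x 0.25 / n`. Tetraploid meiosis is not simulated
mechanistically: carrier status plus the dosage fraction is the contract.
Textbook `F2` (1:2:1 dosage {0, 1/2, 1}) and `RIL` (1:1 dosage {0, 1})
models are provided for comparison.

## Synthetic data generator

* **Genome.** 29 chromosomes of 25 Mbp with 200 evenly spaced
  donor-diagnostic SNPs each (only fixed interspecific differences are
  emitted, mirroring upstream filtering to diagnostic variants). A
  terminal block, chr26:1–10,000,000 by default, is inherited as one unit
  (zero recombination inside, free recombination elsewhere). The
  observation this models is qualitative — suppressed recombination with
  no published rate — so the 0/free dichotomy is the simplest structure
  exhibiting the observed behaviour.
* **Traits.** Normal within genotype class. Defaults: non-carrier focal
  trait mean 94, SD 33, QTL effect +250 (so carriers centre near 344);
  second trait mean 76, SD 22; between-family shifts SD 15 over 11
  families. These values were chosen so that rank-selected pools of 20
  from a 200-individual cohort reproduce the published pool phenotype
  summaries (means within two printed SDs).
* **Pooled counts.** Per site and pool, depth is Poisson(40) — the
  coverage the scans are normalised to — donor reads are binomial at the
  pool's genotype-determined donor frequency, and an optional error rate
  moves a binomial fraction of reads uniformly onto the other nucleotides
  (conserving depth). Pools are treated as exactly equimolar; within-pool
  DNA normalisation noise is not modelled (no published estimate exists).
* **Expression counts.** Genes evenly spaced along the block chromosome;
  in carriers, genes inside the introgression draw donor reads with
  proportion `bias` (default 0.5, an unbiased heterozygote; the true
  allelic bias is unquantified and left as a free parameter), all other
  gene/sample combinations only at the error rate.
* **Metabolite table.** Mean-preserving log-normal areas around per-feature
  base areas with coefficient of variation `cv`; planted features are
  multiplied by their fold change in the carrier group.

What passing tests on these data show: that the statistics recover the
planted structure under idealised sampling (perfect phenotype selection,
equimolar pools, exchangeable reads, diagnostic sites only). What they do
not show: robustness to alignment artefacts, reference bias, contamination,
overdispersed coverage, mis-phenotyping, or segregation distortion — none
of which the generator emulates.

## Site conditioning

Sync-format counts are filtered with the standard pooled-sequencing rules:
at least two alleles must each reach `min_count` (default 6) summed over
all pools, and every pool's depth must lie in
`[min_coverage, max_coverage]` (defaults 4 and 120; a per-pool list is
accepted because published pipelines sometimes bound pools differently,
e.g. 120 and 200). `N` and deletion columns count toward depth but never
form the tested allele pair, since the association tests operate on
biallelic nucleotide contrasts. To compare association strength across
sites of unequal coverage, each pool can be resampled with replacement to
a fixed target depth (default 40) by a multinomial draw proportional to
its counts, which preserves allele frequencies in expectation.

## CMH association scan

At each site the two most frequent nucleotides (ties broken A<C<G<T) form
the tested pair, and K=2 stratified 2x2 tables contrast the high- vs
low-focal-trait pool within each level of the orthogonal trait (the
converse orientation scans the orthogonal trait). The CMH statistic uses
hypergeometric conditional moments,

    chi2 = (|sum_k (a_k - r1_k c1_k / n_k)| - cc)^2
           / sum_k r1_k r2_k c1_k c2_k / (n_k^2 (n_k - 1)),

referred to chi-square with 1 df; the continuity correction `cc` is off by
default (matching the pooled-sequencing tooling this mirrors). Degenerate
sites (zero conditional variance in every stratum) report p = 1. Effect
size is the Mantel–Haenszel common odds ratio
`(sum a_k d_k / n_k) / (sum b_k c_k / n_k)`, reported as NaN when the
denominator vanishes rather than fabricated. P-values are
Benjamini–Hochberg adjusted genome-wide across all retained sites (not per
chromosome); "significant" in scan summaries means adjusted p < 0.001, the
FDR cut-off the genome scans are drawn against.

Note a deliberate property of the simulation: at null sites the four pools
genuinely differ in genotype-sampled allele frequency, so the CMH statistic
on full study simulations is mildly overdispersed relative to its
calibration under the equal-frequency null (which the type-I checks use).
This mirrors real pool-seq data, where finite-pool genotype sampling adds
variance beyond binomial read sampling.

## QTL-seq bulked-segregant scan

Per site, the SNP-index of each bulk is `alt/(ref+alt)` and delta is the
high- minus low-bulk index. The statistic is tricube-smoothed at each SNP
position over a 1-Mbp window: weights `w(u) = (1-|u|^3)^3` with
`u = distance/(window/2)`, evaluated at SNP positions rather than fixed
tiles (the convention of the cited QTL-seq implementations).

Null thresholds are simulated (default 10,000 replicates per depth):
genotype sampling of each bulk followed by binomial read sampling, exactly
the two-stage process the data-generating model assumes. Because the
smoothed statistic averages several sites, its null is simulated as the
mean of `n_eff` independent site deltas, where
`n_eff = (sum w)^2 / sum w^2` is the kernel's effective sample size and
the depth is the weighted mean depth, rounded to the nearest simulated
depth (with a warning when absent from the table). Per-SNP two-sided
p-values use the empirical tail `(count+1)/(reps+1)` while at least 10
null draws are as extreme; beyond the resolution of the simulation the
tail is extended with a normal fit to the same null sample (the null is a
standardised sum of binomial variates and near-Gaussian in its far tail).
Without this extension, an empirical p floor of ~2e-4 could never survive
BH adjustment at FDR 0.001 across a genome of thousands of sites.

Calls are made at BH-adjusted p < 0.001; runs of consecutive significant
SNPs merge into intervals, and an interval requires at least 2 SNPs as a
guard against isolated exceedances. Two resolution limits are inherent:
interval edges can overhang a true block boundary by up to half a window
(the kernel sees block SNPs from outside), and with a strong true signal
inflating the BH threshold, occasional ~4-sigma null excursions can reach
significance. Both are properties of the published procedure, not of this
implementation.

## Allele-of-origin analysis

Homeo-SNPs (fixed interspecific differences) split per-site nucleotide
counts into recipient (`count_a`), donor (`count_b`) and ambiguous (any
other nucleotide, or sites absent from the index). Assignment operates on
per-site counts rather than reads — a deliberate divergence from read-level
assignment tools, with identical expectations at the count level. Gene
proportions sum informative counts over contained sites; genes without
informative counts are flagged, never given a fabricated proportion.

Introgression detection reports maximal runs of at least `min_genes`
(default 5) consecutive informative genes with donor proportion >=
`tau_present` (default 0.2) in the carrier group and <= `tau_absent`
(default 0.02) in the non-carrier group. The defaults separate error-rate
leakage from genuine heterozygous expression: donor proportion near 0.5
signals a carried donor allele, while sequencing error leaks well below
2%. Detection uses proportions only, so it is invariant to per-gene depth
rescaling. A naive library-size-normalised log2 ratio is exposed for
exploratory output only and is explicitly non-inferential; differential
expression testing is out of scope.

## Marker validation and metabolite contrasts

The marker model is `trait ~ dosage + family` with dosage (donor-allele
copies, 0/1/2) as a numeric covariate. Variance shares are sequential
(type-I) sums of squares with dosage entered first — matching the order in
which shares are conventionally reported — computed from nested
least-squares fits (the formula machinery reorders categorical terms, so
entry order is imposed explicitly); an option reverses the entry order.
The allele effect is the fitted trait change per donor copy. A confounded
design (dosage constant within every family) is rejected with an error
naming the confound, and a zero-variance trait returns a flagged degenerate
result. Recombinant detection — no canonical rule exists, so the rule here
is this package's explicit choice — flags individuals whose externally
studentised residual exceeds `z_cut` (default 2.5) **and** whose trait
value lies inside the observed range of another dosage class, i.e. looks
like a member of the opposite marker class rather than a mere outlier.

Metabolite contrasts use arithmetic group means of raw areas; the ratio is
the ratio of group means (not the mean of per-sample ratios, matching how
such tables are printed), the log2 fold change is `log2(ratio)`, and the
p-value is a two-sided Welch t-test on log areas. Printed values round
half away from zero at two decimals. The same function covers simple
two-group trait comparisons (e.g. leaf-tissue contrasts between marker
classes).

## Problem sizes and determinism

Default analyses run at desk scale: 29 x 200 = 5,800 sites, pools of 20 at
depth 40, 10,000 null replicates per depth, 100–200 genes for expression
profiles, 200-replicate Monte-Carlo checks. These sizes keep the full test
suite and the reproduction script to a few minutes on one CPU while
leaving every statistic in its asymptotically valid regime. All
randomness flows through `numpy.random.default_rng` seeds; identical
inputs and seed give byte-identical sync output.

## Known limitations

* Perfect phenotype selection: bulk misclassification is not modelled
  (the BC4x carrier bulk has zero genotype-sampling variance at linked
  sites by construction).
* The BSA smoothed-null approximation treats window sites as exchangeable
  at the rounded effective depth; heterogeneous depths within a window are
  summarised by their weighted mean.
* Within-pool DNA quantity variation, reference/alignment bias and
  overdispersed (non-Poisson) coverage are not simulated.
* The introgression caller assumes a single contiguous donor block per
  run of genes and does not model partial (mosaic) carrier groups.
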