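# Methods

## Data model

All statistics operate on a dense `GenotypeMatrix`: samples × variants
alternate-allele dosages in {0, 1, 2, missing}, with 1-based positions
strictly increasing within each chromosome and one group label per sample.
Only biallelic SNPs enter the model; multiallelic rows, indels and symbolic
alleles are dropped at VCF read time rather than split, and half-calls
(`./1`) are conservatively treated as missing.

## Simulation model

Group structure follows the Balding–Nichols model: each variant draws an
ancestral frequency *p* ~ Beta(0.8, 0.8) (clipped away from fixation), and
each group *g* with drift parameter *F<sub>g</sub>* ∈ (0,1) draws its
frequency from Beta(p(1−F)/F, (1−p)(1−F)/F). Under this model the expected
pairwise Weir–Cockerham *F*<sub>ST</sub> between groups with drifts
*F₁*, *F₂* is approximately (F₁+F₂)/2, which gives every differentiation
statistic a closed-form recovery target. Variants whose *expected* pooled
minor-allele frequency (mean of group frequencies, folded) is below 0.01
are redrawn at the frequency stage, so the number of SNPs surviving the
downstream MAF filter is predictable; the resampling uses expectations, not
realized genotypes, and is fully determined by the seed.

Genotypes are Binomial(2, p<sub>g</sub>) per sample (HWE within groups).
An admixed sample draws, independently for each allele at each variant, a
group of origin from its admixture proportions and then the allele from
that group's frequency; in the sample sheet an admixed sample is labelled
with its majority-ancestry group, since downstream group statistics need a
single assignment. Clone pairs are exact dosage copies made **before**
missingness is applied, so their relatedness matches a duplicated accession
rather than a resequenced one. Missingness is i.i.d. per call.

The planted sweep replaces every non-missing call of the swept group inside
the interval with a homozygote for that group's major allele, leaving the
missingness pattern and all other groups untouched — the interval is
exactly monomorphic in the swept group (windowed π = 0) and strongly
differentiated from the other groups, the signature the composite scan is
designed to recover.

The optional LD-block mode gives each seed variant *k* satellite copies at
random sorted offsets within a span (default 4 copies over 50 kb); each
copy derives from the previous one by redrawing a fraction ε (default 0.05)
of samples from their group frequency, so r² decays geometrically with the
number of chain steps and hence with distance. Offsets are random rather
than a regular grid so that every distance bin below the span receives
pairs. Loci are otherwise unlinked and positions uniform: there is no
coalescent, recombination-map or mutation-model realism, so haplotype-based
statistics (iHS, Tajima's D, EM-phased r²) would be meaningless on this
output, and absolute π levels are set by the ancestral-frequency
distribution, not by a mutation rate. Passing tests demonstrate estimator
correctness and signal recovery under the stated generative model, not
robustness to demography, background selection, or call-rate artefacts of
real resequencing data.

## Filters

MAF is computed over non-missing calls and folded to ≤ 0.5 (standard
PLINK/VCFtools behaviour); a variant is kept iff MAF > 0.05 **and** missing
fraction < 0.20, both strict, so boundary values are removed. The
`FilterReport` conserves counts by construction (input = non-biallelic +
MAF-removed + missing-removed + retained); a variant failing both rules is
attributed to the MAF removal. The filter is idempotent.

## Windowed statistics

Windows start at 1, 1+step, … while the start lies on the chromosome
(defaults 100 kb size, 10 kb step); terminal windows are clipped and
flagged, and the scan consumes full-size windows only, so that window
values are comparable.

Per-site diversity uses the unbiased estimator
π<sub>site</sub> = (2k/(2k−1))·2p̂(1−p̂) for k non-missing diploid calls,
which equals the mean pairwise difference among the 2k sampled alleles
(sites with k < 2 contribute 0). Window π is the per-site sum divided by
the **full window length in bp**, monomorphic positions included — the
VCFtools `--window-pi` convention, and the only one consistent with per-bp
values far below per-SNP heterozygosity.

*F*<sub>ST</sub> uses the Weir–Cockerham (1984) two-population moment
estimator: per-site variance components a (among populations), b (among
individuals within populations) and c (within individuals) from sample
sizes, allele frequencies and observed heterozygote fractions, with sites
skipped when either group has fewer than 2 calls. The window estimate is
the ratio of sums Σa/Σ(a+b+c) ("weighted" estimator, matching VCFtools'
windowed output); a per-site mean-of-ratios variant is available behind a
flag. Raw window estimates may be negative by sampling variance; truncation
to zero happens **per window, before** genome-wide averaging, and
genome-wide means are unweighted over defined windows. Multi-population θ
is deliberately not implemented — the scan consumes all pairwise
comparisons instead.

Both estimators are verified against fully independent oracles in the test
suite (mean-pairwise-difference enumeration for π; a scalar
variance-component implementation written directly from the component
definitions for *F*<sub>ST</sub>) to 1e-9 on random sites with missingness.

## Structure and relatedness

- **LD pruning** replicates PLINK `--indep-pairwise` semantics on genotype
  dosage correlation (not haplotype EM): a 50-SNP window advancing 5 SNPs;
  while any surviving pair has r² above 0.2, the lower-MAF member of the
  worst pair is removed (tie → larger position), and removals persist.
- **Distances**: allele-sharing distance, mean |dosage difference|/2 over
  mutually non-missing variants — simple, missing-tolerant, and bounded in
  [0,1]. The metric is a package choice and is configurable in the sense
  that any `DistanceMatrix` can be fed to the tree builder.
- **Neighbor joining** is the Saitou–Nei algorithm with the Q-criterion;
  ties are broken on the lexicographically smallest leaf-name pair for
  determinism, and negative branch lengths are clamped to zero with the
  deficit moved to the sister branch (preserving the pair's summed length).
  On additive inputs the patristic distances of the output reproduce the
  input exactly (tested to 1e-9 against random additive trees, with
  scikit-bio used to re-read the Newick and compute path lengths).
- **PCA** standardizes each variant by its mean dosage and sqrt(2p̂(1−p̂))
  (EIGENSTRAT convention; unit variance under HWE), mean-imputes missing
  calls after centering, and eigendecomposes the sample covariance;
  percent variance is eigenvalue/trace × 100. Eigenvector signs are fixed
  by making the largest-magnitude loading positive.
- **Kinship** is the GCTA-style GRM,
  G(i,j) = (1/M<sub>ij</sub>) Σ (x<sub>im</sub>−2p<sub>m</sub>)(x<sub>jm</sub>−2p<sub>m</sub>)/(2p<sub>m</sub>(1−p<sub>m</sub>)),
  with per-pair marker counts under missingness and monomorphic markers
  excluded. In-sample allele frequencies force the mean off-diagonal to
  ≈ −1/(n−1); clone pairs appear with off-diagonals near 1, matching the
  long upper tail seen in germplasm panels with duplicated accessions.
  High-kinship pruning flags pairs above a threshold (default 0.45,
  ≈ first-degree on the GRM scale; a package default, as no standard value
  exists) and greedily drops the sample in the most flagged pairs
  (tie → lexicographically larger ID).

## LD decay

r² is the squared Pearson correlation of dosage vectors over mutually
non-missing samples within a group (the composite, unphased measure PLINK
reports), for all same-chromosome pairs within 1,000 kb; zero-variance
pairs are skipped. Decay curves bin pairs by distance (default 10 kb bins)
and report mean r² and pair counts per bin; on unlinked loci the null
expectation is E[r²] ≈ 1/n for n samples, which the tests verify.

## Composite scan

For each included window (defined π for ≥ 2 groups and ≥ 1 defined pairwise
*F*<sub>ST</sub>): log2(π<sub>max</sub>/π<sub>min</sub>) across groups, and
*F*<sub>ST max</sub> over the truncated pairwise values, standardized as
Z = (F<sub>ST max</sub> − mean)/sd over included windows (a degenerate scan
with zero sd is an error). Thresholds are the empirical top-1% of each
metric, taken as an order statistic (the "higher" quantile method) so they
are always actual data values; a window is a candidate iff **both** metrics
are ≥ their thresholds (≥, so exactly-at-quantile windows are included).

A window whose least diverse group is monomorphic (π<sub>min</sub> = 0 <
π<sub>max</sub>) carries +∞ as its ratio and ranks above every finite
value. This replaces a pseudocount: any ε would make the top-1% threshold
depend on an arbitrary constant, whereas the order-statistic threshold with
an infinity marker is parameter-free. When every group is monomorphic
(π<sub>max</sub> = π<sub>min</sub> = 0) the ratio is 0. Thresholds are
computed after excluding undefined windows, and the count of exclusions is
reported in the output header.

Adjacent candidate windows merge while the next start is ≤ current end + 1
(overlapping or bookended); with 100 kb windows at 10 kb step, consecutive
candidates always overlap, so ten consecutive candidate windows merge into
a single interval spanning exactly 0.19 Mb. Intervals report their member
count, per-group π ranges, the maximum pairwise *F*<sub>ST</sub> with its
pair label, and the maximum Z(F<sub>ST max</sub>) (used to rank intervals).

## Pipeline and reproducibility

The pipeline derives each stage's seed by hashing the global seed with the
stage name, so adding a stage never perturbs another stage's draws; a rerun
with identical config and seed is bit-identical (checksummed in the run
manifest). Simulated VCFs are plain VCFv4.2 text with GT-only FORMAT,
deterministic field formatting, and contig header lines carrying
chromosome lengths.

## Problem sizes

Default verification runs use panels the package can analyse in seconds:
parameter recovery at 2 groups × 50 samples with 20,000 unlinked SNPs on a
20 Mb chromosome; sweep recovery at 185 samples in 4 groups
(F = 0.02, 0.02, 0.02, 0.08) with 50,000 SNPs over five 10 Mb chromosomes
and one 200 kb sweep (≈ 4,955 full windows); structure checks at 80
samples × 10,000 SNPs. These sizes give each 100 kb window roughly 100
SNPs, enough that window-level estimator noise is small relative to the
drift parameters being recovered.

## Known limitations

- Two-population *F*<sub>ST</sub> only; no multi-population θ, no
  haplotype statistics, no demography-aware sweep tests.
- The simulator's unlinked-loci default means LD-based analyses are only
  meaningful in LD-block mode, which is a caricature of real haplotype
  structure.
- The NJ tie-break and branch-clamping rules are deterministic choices;
  other NJ implementations may output different but equally valid
  resolutions of near-ties.
- Gene annotation and enrichment of candidate intervals are out of scope;
  the scan ends at coordinate intervals.
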