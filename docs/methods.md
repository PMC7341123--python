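# Methods

## Scope and model

`bulkseg` analyses a four-sample bulk-segregant design: two fully
homozygous inbred parents (P1 carries the restorer alleles, P2 is the
CMS/maintainer line) and two extreme-phenotype bulks (FR = fertility
restored, SM = sterility maintained) drawn from a segregating
population.  The package has two halves: the analysis pipeline
(variant-table reading, SNP-index statistics, windowed scan, Monte-Carlo
bands, region calling, segregation arithmetic) and a simulator of the
whole design used for calibration and testing.

## The simulator

**Genetics.**  Meiosis follows the Haldane model: crossover counts per
chromosome are Poisson with mean equal to the genetic length in Morgans,
positions uniform, no interference.  The default map rate is 1 cM/Mb, a
standard round figure for maize-scale genomes.  An F2 plant receives two
independent F1 gametes; a backcross plant one F1-derived gamete plus one
intact recurrent-parent chromosome.  Haplotypes are stored as
parental-origin mosaics (breakpoint lists), so genotype queries at any
position are exact and O(log k).

**Phenotype.**  Fertility is graded I–V (I–II sterile, III–V fertile,
V fully fertile).  The restoration model has two loci: a dominant
restorer (`rf4` analog) and a parallel restorer QTL (`Q`).  Each joint
genotype class maps to a probability distribution over grades — the
penetrance table, which is configuration, not code.  Defaults:

| class            | grades                                | rationale                                   |
|------------------|---------------------------------------|---------------------------------------------|
| `Rf4_`           | V 0.997, IV 0.002, III 0.001          | the dominant restorer is near-complete      |
| `rf4rf4:qq`      | I 0.2, II 0.8                         | no restoration system active → sterile      |
| `rf4rf4:Qq`/`QQ` | V 0.8, IV 0.1, III 0.1                | dominant QTL with incomplete (0.8) penetrance |

With these defaults an F2 is ~1/16 sterile, the sterile bulk is fixed
for `q`, and the fertile `rf4rf4` bulk has restorer-allele frequency 2/3
at the QTL — so the expected peak Δ(SNP-index) is ≈ 0.65 rather than 1,
a realistic magnitude for a dominant QTL under one-sided selection.

**Default study conditions.**  Two 150-Mb chromosomes with one
informative SNP per 10 kb (a ten-chromosome maize-sized genome is
available via `maize_genome()`); `rf4` at chr1:10 Mb and the QTL at
chr1:130 Mb (both loci on one chromosome, the second chromosome a
QTL-free negative control); F2 of 1000 plants, enough that the 30-plant
sterile bulk is essentially never short; bulks of 30 + 30; Poisson read
depths with means 10× (parents) and 30× (bulks); symmetric per-read
allele-flip error 0.002.  These scaled sizes keep a full simulated scan
near one second while preserving the statistical structure of the
design; they are the conditions under which the calibration and recovery
properties below are stated.

**Reads.**  Per site and bulk, the restorer-allele read count is
Binomial(depth, p′) with p′ = p(1−e) + (1−p)e, where p is the realised
allele frequency among the bulk's 2n chromosomes.  Parents are emitted
as homozygous opposite calls with their own Poisson depths.  Output is
VCF v4.2 (samples P1, P2, FR, SM; GT/DP/AD; REF/ALT orientation
alternating site by site so both encodings are exercised) or a flat TSV;
the master seed is recorded in the file header.  All stochastic stages
draw from named substreams of one master seed (CRC32 of the stage name),
so outputs are byte-reproducible and stages independently replayable.

**What the simulator does not emulate:** alignment and calling artifacts
(mapping bias, paralog collapse), depth heterogeneity beyond Poisson,
linked-read correlations in error, segregation distortion, multi-allelic
sites, cytoplasm variation.  Passing tests therefore demonstrate the
statistical machinery is correct under the declared model, not that real
data are free of upstream artifacts.

## Site selection and filters

Informative sites require both parents called homozygous for different
alleles, each with depth strictly greater than 5 reads, applied per
parent.  Sites are then oriented so counts always refer to the
restorer-parent allele; swapping REF/ALT in the input cannot change any
downstream number.  The per-locus filters drop a site when either bulk's
depth is < 7, or when both bulks' indices are < 0.3 or both > 0.7 — the
both-extreme rule removes monomorphic/mis-called loci while keeping
contrasting sites, which are the signal.  The depth rule runs first, so
indices are always defined (no zero-depth division).  Every discard is
counted by reason and the accounting identity (input = retained + sum of
discards) is tested.

## Windows, bands, regions

Windows of 5 Mb advance in 10-kb steps, anchored at 0-based multiples of
the step; a site at 1-based position p belongs to window [s, s+W) iff
s ≤ p−1 < s+W.  Empty windows are omitted rather than interpolated.
Window means are unweighted arithmetic means of member-site values.

Null bands: for bulk size n (F2 design), bulk frequency p = B/(2n) with
B ~ Binomial(2n, ½); observed index at depth d is Binomial(d, p)/d; the
band at a confidence level is the pair of empirical quantiles of
simulated Δ replicates (default 10,000 per depth, tabulated at depths
7–100 plus 120/150/200, clamped outside).  Because the index at finite
depth is discrete (a lattice of step 1/d), bands taken directly from the
discrete replicates are conservative: the strict exceedance probability
of an empirical quantile is below nominal (measured ~4.5% at 10–30×
for a nominal 5%).  The replicates therefore receive a per-bulk uniform
continuity correction of width 1/d before the quantiles are taken, and
the calibration diagnostic `band_exceedance` applies the same correction
to the observed per-SNP deltas — the standard randomized-test device for
discrete statistics.  With it, the measured null exceedance is 5.0% at
all depths.  Window means aggregate hundreds of sites and are compared
to the bands directly, without dithering.

Each site's band is evaluated at its effective depth — by default the
smaller of its two bulk depths, the conservative choice (wider band);
linear interpolation between tabulated depths.  A window's band is the
mean of its member-site bounds, mirroring how the window statistic
itself is a mean.  Region calling merges windows exceeding the band
(upper tail by default; the lower tail is symmetric and available) when
they overlap or are separated by at most one step; regions shorter than
1 Mb are discarded to suppress single-window false calls.  The reported
peak is the member window with the largest |mean Δ|.

Called regions on simulated data are wide — tens of Mb around a strong
QTL — for two reasons inherent to the method: the 5-Mb window smears any
signal by a window width, and one-sided selection of bulk members drags
allele frequencies over a long flank of the causal locus.  The region is
a localisation interval, not a fine-mapping interval.

## Segregation arithmetic

Goodness-of-fit uses the Pearson χ² without continuity correction
(`scipy.stats.chisquare` behind the package's interface; an exact
rational-arithmetic oracle in the tests): expected counts are
total · wᵢ/Σw for ratio weights w, df = classes − 1.  The
continuity-corrected statistic would visibly disagree with the packaged
tables (2.30 vs 2.44 for 254:220 against 1:1), which pins the
convention.  Ratios and percentages are rounded half-up to two decimals
for report parity; full-precision values stay available.  The packaged
count tables (maize CMS-C cross CHuangzaosi × A619) ship as plain TSV
under `bulkseg/data/`; the BC2F1 table stores fertile/sterile/grade-V
counts only, because a finer grade split is not available for it.

## Numerical and interface choices

- Coordinates are 1-based inclusive internally and in TSVs (VCF
  convention), 0-based half-open in BED output.
- SNP-only analysis by default; biallelic InDels admissible by flag.
  Upstream QC beyond the caller's FILTER column (respected by default,
  configurable off) is out of scope.
- The restorer parent is named by configuration (`sample_map`), never
  inferred from the data.
- Monte-Carlo reproducibility: a fixed seed gives byte-identical variant
  tables, null-CI tables and region BEDs; floats in output files are
  written with fixed formatting.
- Degenerate inputs fail loudly and specifically: loci outside the
  genome, empty bulks, bulk shortfalls (naming the bulk), unsorted
  variant tables (naming the first offending position), zero retained
  sites (with the full filter accounting).

## Calibration and recovery properties

The test suite verifies, under the default study conditions: the
closed-form null index variance (¼ − 1/(8n))/d + 1/(8n) (= 0.02875 at
n = 30, d = 10) against a 10⁶-replicate simulation; 5% ± 0.5% exceedance
of the 95% band on null per-SNP deltas; 1:2:1 / 1:1 single-locus
segregation and the 3:1, 15:1-style phenotype ratios by enumeration;
and a 50-seed end-to-end experiment in which the called P < 0.05 region
contains the simulated causal locus and the QTL-free chromosome stays
clean in ≥ 90% of seeds each (observed: 100% and ~96%).

## Known limitations

- The no-QTL band assumes an F2 (or BC1) bulk of unrelated plants; other
  designs need their own frequency law.
- Window-level exceedances are strongly correlated along a chromosome;
  only the per-SNP rate is calibrated exactly, and region calling is
  assessed empirically by the recovery experiment.
- The simulator's error model is a symmetric allele flip; systematic
  reference bias is not modelled.
- Bands are tabulated for equal-depth bulks and applied at the per-site
  minimum depth; strongly asymmetric bulk depths make the bands
  conservative rather than exact.
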