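# bulkseg

QTL-seq (bulked-segregant) analysis for restorer-of-fertility genetics,
with a built-in cross-and-sequencing simulator.

## The problem

Cytoplasmic male sterility (CMS) in maize is rescued by nuclear
restorer-of-fertility genes; for the C-type cytoplasm the dominant gene
*Rf4* on chromosome 8 is the main restorer.  Crosses between CMS lines
and a strong restorer such as A619 can show fertile:sterile ratios (for
example ~37:1 in an F2) that fit neither a one-gene nor a two-gene model,
pointing at additional restoration systems segregating in parallel.
QTL-seq finds those hidden loci: pool the most extreme plants — here 30
fully fertile and 30 sterile *rf4rf4* plants — sequence the two bulks
plus both parents, and scan the genome for regions where the bulks
inherit the two parental genomes unequally.

`bulkseg` implements that workflow end to end for people who want a
tested, scriptable version of it: the per-SNP statistics, the filters,
the windowed genome scan with Monte-Carlo significance bands, candidate
region extraction, the Mendelian segregation arithmetic used to
characterize such crosses — and a simulator of the whole experimental
design, so every part can be exercised and calibrated without any
sequencing data.

## The statistics

For one site with parental alleles fixed oppositely in the two inbred
parents, the **SNP-index** of a bulk is the fraction of its reads
carrying the restorer-parent allele,

    SNP-index = n_restorer / (n_restorer + n_other),

0.5 at loci unlinked to the trait, and

    Δ(SNP-index) = SNP-index(FR bulk) − SNP-index(SM bulk),

which drifts toward +1 near a restorer locus.  Sites pass the standard
QTL-seq filters: both parents homozygous for different alleles with read
depth > 5×, bulk depth ≥ 7×, and removal of sites whose index is < 0.3
or > 0.7 in *both* bulks.  Per-SNP values are averaged in 5-Mb windows
advanced in 10-kb steps.  Significance comes from simulation: under the
no-QTL null the bulk allele frequency is Binomial(2n, ½)/2n for bulk
size n and the observed index at depth d is Binomial(d, p)/d; quantiles
of simulated Δ replicates give depth-dependent 95%/99% bands, and runs
of windows whose mean Δ exceeds the band are merged into candidate
regions.  A Pearson goodness-of-fit χ² (no continuity correction)
against 1:2:1 / 1:1 marker ratios covers the segregation-genetics side.

## Worked example

`examples/` holds one short script per capability.  Segregation
arithmetic on the packaged fertility-grade tables from a maize CMS-C
restorer cross (CHuangzaosi × A619 F2 and BC1F1, two environments):

```
$ python examples/04_segregation_tables.py
population environment  I  II  III  IV    V  fertile  sterile  total observed_ratio
        F2     Chengdu  5  28   29  10 1174     1213       33   1246        36.76:1
        F2    Jinghong 11  58   38  25 2475     2538       69   2607        36.78:1
     BC1F1     Chengdu 45  97   34  14  284      332      142    474         2.34:1
     BC1F1    Jinghong 24  46    7   3  158      168       70    238         2.40:1

F2 Chengdu: marker fits 1:2:1 (chi2 = 2.16, P = 0.34)
...
F2: 79.62% of rf4rf4 plants fully fertile (758/952)
BC1F1: 17.99% of rf4rf4 plants fully fertile (59/328)
```

The ratios far above 3:1 with a perfectly Mendelian marker, and the
fully-fertile share of *rf4rf4* plants collapsing from ~80% (F2) to ~18%
(BC1), are the signature of extra restorer QTL diluted out by
backcrossing.

A full scan on simulated data (F2 of 1000 plants, causal locus at
chr1:130 Mb, bulks of 30 at ~30×, the second chromosome QTL-free):

```
$ python examples/02_qtlseq_scan.py
sites: 26049 informative of 30000 (low parent depth: 3951)
locus filters kept 20659: both-low 5329, both-high 61, low depth 0
windows: 28476

candidate region chr1:83.82-154.99 Mb peak delta 0.657 at 152.49 Mb (6618 windows above the P<0.05 band)
```

One region is called, on the causal chromosome, containing the simulated
locus; the peak Δ ≈ 0.65 matches the expected bulk composition (restorer
allele frequency ~2/3 in the fertile bulk, 0 in the sterile bulk).  The
many sites removed as "both-low" sit around the *rf4* locus itself,
where both bulks are fixed for the maintainer allele — exactly what the
both-extreme filter is for.

The same pipeline is available from the shell:

```bash
bulkseg simulate --out sim.tsv --seed 1
bulkseg qtlseq sim.tsv --outdir out --seed 1
bulkseg segregation
bulkseg null-ci --out ci.tsv
```

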