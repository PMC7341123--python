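"""Simulate a restorer-line x CMS-line cross and inspect its segregation.

Builds an F2 population under the default two-locus restoration model
(dominant restorer Rf4 plus a parallel restorer QTL), tabulates fertility
grades by marker genotype, and constructs the two extreme bulks.
"""

import bulkseg as bs

genome = bs.default_genome()  # 2 chromosomes x 150 Mb, one SNP per 10 kb
model = bs.default_restoration_model()  # rf4 at chr1:10 Mb, QTL at chr1:130 Mb

pop = bs.simulate_f2(genome, model, n_plants=1000, seed=1)
table = bs.tabulate_population(pop, genome, model)
print(table.with_margins().to_string(index=False))
print()
summary = bs.genotype_fertility_summary(table)
print(summary.to_string(index=False))
print()
# rf4rf4 plants segregate for the second restorer: ~3/4 of them are
# fertile, so the fertile:sterile ratio sits far above the 3:1 of a
# single dominant gene.

fr, sm = bs.build_bulks(pop, genome, model, seed=1)
print(f"FR bulk: {len(fr)} fully fertile rf4rf4 plants (grade V)")
print(f"SM bulk: {len(sm)} sterile rf4rf4 plants (grades I/II)")

reads = bs.simulate_reads({"FR": fr, "SM": sm}, genome, bs.ReadModel(), seed=1)
bs.write_tsv(reads, "sim_variants.tsv", seed=1)
print(f"wrote sim_variants.tsv with {len(reads)} sites "
      "(parents ~10x, bulks ~30x Poisson depth)")
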