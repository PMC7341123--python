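"""Synthetic biparental cross and bulk-sequencing simulator.

Emulates the study design behind a QTL-seq experiment for cytoplasmic male
sterility (CMS) restorer genetics in maize: two fully homozygous inbred
parents (P1, the restorer-carrying line; P2, the CMS line), an F1 selfed to
an F2 (or backcrossed), fertility grades I-V drawn from a configurable
two-locus restoration model, extreme-phenotype bulks, and short-read
allele-depth sampling at the parental SNPs.

Genetics model
--------------
Meiosis uses the Haldane map function: crossovers per chromosome are
Poisson with mean equal to the genetic length in Morgans (derived from a
cM/Mb rate), placed uniformly, with no interference.  All simulated plants
implicitly carry the sterile cytoplasm, so fertility is decided purely by
the nuclear genotype at the dominant restorer locus (*Rf4*-like) and a
parallel restorer QTL (*Q*): grade distributions per joint genotype class
are free penetrance parameters.

Read model
----------
Per site and sample, depth ~ Poisson(mean depth); the restorer-allele read
count is Binomial(depth, p') where p' is the bulk restorer-allele
frequency perturbed by a symmetric per-read error rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import BulkShortfallError, ConfigError, DataError
from .rng import substream

__all__ = [
    "GRADES",
    "STERILE_GRADES",
    "GenomeModel",
    "RestorationModel",
    "Individual",
    "BulkSpec",
    "ReadModel",
    "default_genome",
    "maize_genome",
    "default_restoration_model",
    "simulate_f2",
    "simulate_backcross",
    "build_bulks",
    "simulate_reads",
    "write_tsv",
    "write_vcf",
    "simulate_dataset",
]

GRADES = ("I", "II", "III", "IV", "V")
STERILE_GRADES = frozenset({"I", "II"})

# haplotype origin codes
RESTORER = 0  # P1 / A619-analog chromosome
OTHER = 1  # P2 / CMS-line chromosome


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome lengths, informative-SNP spacing and recombination rate.

    `snp_spacing` places one informative parental SNP every so many bp,
    starting at `snp_spacing` (1-based).  `cm_per_mb` converts physical to
    genetic distance under the Haldane model.
    """

    chromosomes: tuple[tuple[str, int], ...]
    snp_spacing: int = 10_000
    cm_per_mb: float = 1.0

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ConfigError("genome needs at least one chromosome")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ConfigError(f"chromosome {name!r} has non-positive length {length}")
        if self.snp_spacing <= 0:
            raise ConfigError(f"snp_spacing must be > 0, got {self.snp_spacing}")
        if self.cm_per_mb <= 0:
            raise ConfigError(f"cm_per_mb must be > 0, got {self.cm_per_mb}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.chromosomes)

    def length(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise ConfigError(f"unknown chromosome {chrom!r}")

    def index(self, chrom: str) -> int:
        try:
            return self.names.index(chrom)
        except ValueError:
            raise ConfigError(f"unknown chromosome {chrom!r}") from None

    def snp_positions(self, chrom: str) -> np.ndarray:
        """1-based positions of informative SNPs on `chrom`."""
        length = self.length(chrom)
        return np.arange(self.snp_spacing, length + 1, self.snp_spacing, dtype=np.int64)

    def morgans(self, chrom: str) -> float:
        """Genetic length of `chrom` in Morgans."""
        return self.length(chrom) / 1e6 * self.cm_per_mb / 100.0

    def validate_locus(self, locus: tuple[str, int]) -> None:
        chrom, pos = locus
        if not 1 <= pos <= self.length(chrom):
            raise ConfigError(f"locus {chrom}:{pos} outside chromosome bounds")


def default_genome(snp_spacing: int = 10_000) -> GenomeModel:
    """Scaled two-chromosome genome (2 x 150 Mb) used for desk-size runs."""
    return GenomeModel((("chr1", 150_000_000), ("chr2", 150_000_000)), snp_spacing=snp_spacing)


def maize_genome(snp_spacing: int = 10_000) -> GenomeModel:
    """Ten chromosomes with approximate maize (B73) lengths."""
    lengths = [307, 244, 235, 246, 223, 174, 182, 181, 159, 150]
    chroms = tuple((f"chr{i + 1}", mb * 1_000_000) for i, mb in enumerate(lengths))
    return GenomeModel(chroms, snp_spacing=snp_spacing)


#: Joint genotype classes of the restoration model: the dominant restorer
#: masks everything, so rf4rf4 plants are split by restorer-QTL dosage.
GENOTYPE_CLASSES = ("Rf4_", "rf4rf4:qq", "rf4rf4:Qq", "rf4rf4:QQ")


@dataclass(frozen=True)
class RestorationModel:
    """Two-locus fertility restoration model.

    `penetrance` maps each joint genotype class to a probability
    distribution over fertility grades I-V.
    """

    rf4_locus: tuple[str, int]
    q_locus: tuple[str, int]
    penetrance: Mapping[str, Mapping[str, float]]

    def __post_init__(self) -> None:
        missing = set(GENOTYPE_CLASSES) - set(self.penetrance)
        if missing:
            raise ConfigError(f"penetrance table missing classes: {sorted(missing)}")
        for cls, dist in self.penetrance.items():
            if cls not in GENOTYPE_CLASSES:
                raise ConfigError(f"unknown genotype class {cls!r}")
            unknown = set(dist) - set(GRADES)
            if unknown:
                raise ConfigError(f"unknown grades {sorted(unknown)} in class {cls!r}")
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"grade distribution for {cls!r} sums to {total}, not 1")
            if any(p < 0 for p in dist.values()):
                raise ConfigError(f"negative penetrance in class {cls!r}")

    def genotype_class(self, rf4_dosage: int, q_dosage: int) -> str:
        if rf4_dosage > 0:
            return "Rf4_"
        return ("rf4rf4:qq", "rf4rf4:Qq", "rf4rf4:QQ")[q_dosage]

    def draw_grade(self, rf4_dosage: int, q_dosage: int, rng: np.random.Generator) -> str:
        dist = self.penetrance[self.genotype_class(rf4_dosage, q_dosage)]
        grades = list(dist)
        probs = np.fromiter(dist.values(), dtype=float)
        return grades[rng.choice(len(grades), p=probs / probs.sum())]


def default_restoration_model(
    rf4_locus: tuple[str, int] = ("chr1", 10_000_000),
    q_locus: tuple[str, int] = ("chr1", 130_000_000),
    q_fertile_penetrance: float = 0.8,
) -> RestorationModel:
    """Default penetrance: a fully dominant near-complete restorer plus a
    parallel dominant QTL that restores rf4rf4 plants with ~0.8 penetrance
    to full fertility (grade V); rf4rf4 qq plants are sterile (grades I/II).
    """
    rest = 1.0 - q_fertile_penetrance
    fertile_q = {"V": q_fertile_penetrance, "IV": rest / 2, "III": rest / 2}
    return RestorationModel(
        rf4_locus=rf4_locus,
        q_locus=q_locus,
        penetrance={
            "Rf4_": {"V": 0.997, "IV": 0.002, "III": 0.001},
            "rf4rf4:qq": {"I": 0.2, "II": 0.8},
            "rf4rf4:Qq": dict(fertile_q),
            "rf4rf4:QQ": dict(fertile_q),
        },
    )


# A haplotype is a parental-origin mosaic per chromosome: (start_origin,
# sorted breakpoint array in bp); origin flips at each breakpoint.
Haplotype = tuple[tuple[int, np.ndarray], ...]


def _origin_at(hap_chrom: tuple[int, np.ndarray], pos) -> np.ndarray:
    start, breaks = hap_chrom
    k = np.searchsorted(breaks, np.asarray(pos), side="right")
    return (start + k) % 2


@dataclass
class Individual:
    """One simulated plant: two parental-origin mosaics per chromosome,
    a population label and a fertility grade."""

    population: str
    haplotypes: tuple[Haplotype, Haplotype]
    grade: str = ""

    def dosage(self, genome: GenomeModel, chrom: str, pos) -> np.ndarray:
        """Restorer-parent allele count (0/1/2) at position(s) `pos`."""
        ci = genome.index(chrom)
        d = np.zeros_like(np.asarray(pos), dtype=np.int64)
        for hap in self.haplotypes:
            d += _origin_at(hap[ci], pos) == RESTORER
        return d

    def genotype_at(self, genome: GenomeModel, chrom: str, pos: int) -> str:
        return {0: "BB", 1: "AB", 2: "AA"}[int(self.dosage(genome, chrom, pos))]


def _founder_haplotype(genome: GenomeModel, origin: int) -> Haplotype:
    empty = np.empty(0, dtype=np.int64)
    return tuple((origin, empty) for _ in genome.chromosomes)


def _meiose(genome: GenomeModel, hap1: Haplotype, hap2: Haplotype, rng: np.random.Generator) -> Haplotype:
    """One recombinant gamete from an individual's two homologs."""
    out = []
    for ci, (name, length) in enumerate(genome.chromosomes):
        n_x = rng.poisson(genome.morgans(name))
        xpos = np.sort(rng.integers(1, length + 1, size=n_x))
        which = int(rng.integers(2))  # homolog transmitted at position 1
        homs = (hap1[ci], hap2[ci])
        # candidate change points: crossovers plus underlying breakpoints
        cand = np.unique(np.concatenate([xpos, homs[0][1], homs[1][1]]))
        if cand.size == 0:
            out.append((int(homs[which][0]), np.empty(0, dtype=np.int64)))
            continue
        # a change point takes effect at its own position (side="right"
        # convention), so probe the origin at pos 1 and at each point
        probes = np.concatenate([[1], cand])
        active = (which + np.searchsorted(xpos, probes, side="right")) % 2
        origins = np.array(
            [int(_origin_at(homs[a], p)) for a, p in zip(active, probes)], dtype=np.int64
        )
        flips = cand[origins[1:] != origins[:-1]]
        out.append((int(origins[0]), flips.astype(np.int64)))
    return tuple(out)


def _assign_grade(ind: Individual, genome: GenomeModel, model: RestorationModel, rng: np.random.Generator) -> None:
    rf4 = int(ind.dosage(genome, *model.rf4_locus))
    q = int(ind.dosage(genome, *model.q_locus))
    ind.grade = model.draw_grade(rf4, q, rng)


def simulate_f2(
    genome: GenomeModel,
    model: RestorationModel,
    n_plants: int,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> list[Individual]:
    """Self an F1 (restorer line x CMS line) to produce `n_plants` F2 plants.

    Each plant receives two independent recombinant F1 gametes; genotype
    frequencies at any single locus converge to 1:2:1.  Fertility grades
    are drawn from the restoration model's penetrance table.
    """
    if n_plants < 1:
        raise ConfigError(f"n_plants must be >= 1, got {n_plants}")
    model_loci_check(genome, model)
    rng = rng if rng is not None else substream(seed, "f2")
    hap_a = _founder_haplotype(genome, RESTORER)
    hap_b = _founder_haplotype(genome, OTHER)
    plants = []
    for _ in range(n_plants):
        gametes = (_meiose(genome, hap_a, hap_b, rng), _meiose(genome, hap_a, hap_b, rng))
        ind = Individual(population="F2", haplotypes=gametes)
        _assign_grade(ind, genome, model, rng)
        plants.append(ind)
    return plants


def model_loci_check(genome: GenomeModel, model: RestorationModel) -> None:
    genome.validate_locus(model.rf4_locus)
    genome.validate_locus(model.q_locus)


def simulate_backcross(
    parent_pop: Sequence[Individual],
    genome: GenomeModel,
    model: RestorationModel,
    n_plants: int,
    recurrent: str = "P2",
    seed: int = 0,
    rng: np.random.Generator | None = None,
    label: str | None = None,
) -> list[Individual]:
    """Backcross plants from `parent_pop` to a recurrent founder parent.

    Each offspring receives one recombinant gamete from a uniformly chosen
    `parent_pop` plant and one non-recombinant founder gamete.  With the F1
    as parent population, single-locus genotype ratios converge to 1:1.
    """
    if not parent_pop:
        raise DataError("backcross parent population is empty")
    if recurrent not in ("P1", "P2"):
        raise ConfigError(f"recurrent parent must be 'P1' or 'P2', got {recurrent!r}")
    if n_plants < 1:
        raise ConfigError(f"n_plants must be >= 1, got {n_plants}")
    model_loci_check(genome, model)
    rng = rng if rng is not None else substream(seed, "backcross")
    rec_hap = _founder_haplotype(genome, RESTORER if recurrent == "P1" else OTHER)
    if label is None:
        src = parent_pop[0].population
        label = "BC1" if src == "F1" else f"BC+{src}"
    plants = []
    for _ in range(n_plants):
        parent = parent_pop[int(rng.integers(len(parent_pop)))]
        gamete = _meiose(genome, parent.haplotypes[0], parent.haplotypes[1], rng)
        ind = Individual(population=label, haplotypes=(gamete, rec_hap))
        _assign_grade(ind, genome, model, rng)
        plants.append(ind)
    return plants


def f1_individual(genome: GenomeModel) -> Individual:
    """The (non-segregating) F1 hybrid, convenient as a backcross parent."""
    return Individual(
        population="F1",
        haplotypes=(_founder_haplotype(genome, RESTORER), _founder_haplotype(genome, OTHER)),
        grade="V",
    )


@dataclass(frozen=True)
class BulkSpec:
    """Selection rule for one extreme-phenotype bulk.

    `marker_genotype` restricts on the dominant-restorer marker class
    ('rf4rf4', 'Rf4rf4', 'Rf4Rf4', 'Rf4_', or None for no restriction);
    `grades` is the required fertility-grade set; `n` the bulk size.
    """

    name: str
    marker_genotype: str | None
    grades: frozenset[str]
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigError(f"bulk {self.name!r}: size must be >= 1, got {self.n}")
        bad = set(self.grades) - set(GRADES)
        if bad:
            raise ConfigError(f"bulk {self.name!r}: unknown grades {sorted(bad)}")
        if self.marker_genotype not in (None, "rf4rf4", "Rf4rf4", "Rf4Rf4", "Rf4_"):
            raise ConfigError(f"bulk {self.name!r}: unknown marker genotype {self.marker_genotype!r}")

    def qualifies(self, ind: Individual, genome: GenomeModel, model: RestorationModel) -> bool:
        if ind.grade not in self.grades:
            return False
        if self.marker_genotype is None:
            return True
        dosage = int(ind.dosage(genome, *model.rf4_locus))
        if self.marker_genotype == "Rf4_":
            return dosage > 0
        return dosage == {"rf4rf4": 0, "Rf4rf4": 1, "Rf4Rf4": 2}[self.marker_genotype]


#: Study-design bulks: 30 fully fertile (grade V) and 30 sterile (grade I/II)
#: plants, all lacking the dominant restorer.
DEFAULT_FR_SPEC = BulkSpec("FR", "rf4rf4", frozenset({"V"}), 30)
DEFAULT_SM_SPEC = BulkSpec("SM", "rf4rf4", frozenset({"I", "II"}), 30)


def build_bulks(
    pop: Sequence[Individual],
    genome: GenomeModel,
    model: RestorationModel,
    fr_spec: BulkSpec = DEFAULT_FR_SPEC,
    sm_spec: BulkSpec = DEFAULT_SM_SPEC,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[list[Individual], list[Individual]]:
    """Sample the two extreme bulks uniformly without replacement.

    Returns disjoint (FR, SM) member lists; raises BulkShortfallError
    naming the bulk when qualifiers are insufficient.
    """
    rng = rng if rng is not None else substream(seed, "bulks")
    chosen: set[int] = set()
    out = []
    for spec in (fr_spec, sm_spec):
        qualifiers = [
            i
            for i, ind in enumerate(pop)
            if i not in chosen and spec.qualifies(ind, genome, model)
        ]
        if len(qualifiers) < spec.n:
            raise BulkShortfallError(
                f"bulk {spec.name!r} requires {spec.n} plants but only "
                f"{len(qualifiers)} qualify (marker {spec.marker_genotype}, "
                f"grades {sorted(spec.grades)})"
            )
        picked = rng.choice(len(qualifiers), size=spec.n, replace=False)
        idx = [qualifiers[int(i)] for i in picked]
        chosen.update(idx)
        out.append([pop[i] for i in sorted(idx)])
    return out[0], out[1]


@dataclass(frozen=True)
class ReadModel:
    """Short-read sampling model: Poisson depths, symmetric allele-flip
    error.  Depths mirror the study design: ~10x parents, ~30x bulks."""

    parent_depth: float = 10.0
    bulk_depth: float = 30.0
    error_rate: float = 0.002
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.parent_depth < 0 or self.bulk_depth < 0:
            raise ConfigError("mean depths must be >= 0")
        if not 0 <= self.error_rate < 0.5:
            raise ConfigError(f"error rate must be in [0, 0.5), got {self.error_rate}")


_BASES = np.array(list("ACGT"))


def _bulk_restorer_freq(bulk: Sequence[Individual], genome: GenomeModel, chrom: str, positions: np.ndarray) -> np.ndarray:
    """Restorer-allele frequency among the bulk's 2n chromosomes."""
    count = np.zeros(positions.size, dtype=np.int64)
    ci = genome.index(chrom)
    for ind in bulk:
        for hap in ind.haplotypes:
            count += _origin_at(hap[ci], positions) == RESTORER
    return count / (2 * len(bulk))


def simulate_reads(
    bulks: Mapping[str, Sequence[Individual]],
    genome: GenomeModel,
    read_model: ReadModel = ReadModel(),
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Sample per-site allele depths for parents and bulks.

    `bulks` maps 'FR' and 'SM' to their member lists.  Returns the oriented
    variant table with columns chrom, pos, restorer_allele, other_allele,
    p1_depth, p2_depth, fr_restorer, fr_other, sm_restorer, sm_other.
    Sites with zero sampled depth in a sample simply carry zero counts
    there; downstream filters deal with them.
    """
    for name in ("FR", "SM"):
        if name not in bulks or len(bulks[name]) == 0:
            raise ConfigError(f"bulk {name!r} is missing or empty")
    rng = rng if rng is not None else substream(
        seed if read_model.seed is None else read_model.seed, "reads"
    )
    err = read_model.error_rate
    frames = []
    for chrom, _length in genome.chromosomes:
        pos = genome.snp_positions(chrom)
        m = pos.size
        alleles = rng.integers(0, 4, size=m)
        shift = rng.integers(1, 4, size=m)
        restorer_allele = _BASES[alleles]
        other_allele = _BASES[(alleles + shift) % 4]

        cols: dict[str, np.ndarray] = {
            "chrom": np.repeat(chrom, m),
            "pos": pos,
            "restorer_allele": restorer_allele,
            "other_allele": other_allele,
        }
        # parents: truly homozygous; depth is what matters downstream
        cols["p1_depth"] = rng.poisson(read_model.parent_depth, size=m)
        cols["p2_depth"] = rng.poisson(read_model.parent_depth, size=m)
        for name in ("FR", "SM"):
            p = _bulk_restorer_freq(bulks[name], genome, chrom, pos)
            p_obs = p * (1 - err) + (1 - p) * err
            depth = rng.poisson(read_model.bulk_depth, size=m)
            restorer = rng.binomial(depth, p_obs)
            cols[f"{name.lower()}_restorer"] = restorer
            cols[f"{name.lower()}_other"] = depth - restorer
        frames.append(pd.DataFrame(cols))
    return pd.concat(frames, ignore_index=True)


TSV_COLUMNS = [
    "chrom",
    "pos",
    "p1_allele",
    "p2_allele",
    "p1_depth",
    "p2_depth",
    "fr_restorer_depth",
    "fr_other_depth",
    "sm_restorer_depth",
    "sm_other_depth",
]


def write_tsv(table: pd.DataFrame, path, seed: int | None = None) -> None:
    """Write the oriented variant table in the flat TSV dialect.

    p1_allele is the restorer-parent allele; parents are homozygous by
    construction, so only their depths are carried.
    """
    out = pd.DataFrame(
        {
            "chrom": table["chrom"],
            "pos": table["pos"],
            "p1_allele": table["restorer_allele"],
            "p2_allele": table["other_allele"],
            "p1_depth": table["p1_depth"],
            "p2_depth": table["p2_depth"],
            "fr_restorer_depth": table["fr_restorer"],
            "fr_other_depth": table["fr_other"],
            "sm_restorer_depth": table["sm_restorer"],
            "sm_other_depth": table["sm_other"],
        }
    )
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# bulkseg simulation seed={seed}\n")
        out.to_csv(fh, sep="\t", index=False)


def write_vcf(table: pd.DataFrame, path, genome: GenomeModel, seed: int | None = None) -> None:
    """Write the table as VCF v4.2 with samples P1, P2, FR, SM (GT:DP:AD).

    REF/ALT orientation alternates site by site so both encodings of the
    restorer allele are exercised; parents are emitted as opposite
    homozygous calls.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if seed is not None:
            fh.write(f"##bulkseg_simulation_seed={seed}\n")
        fh.write("##source=bulkseg-simulate\n")
        for chrom, length in genome.chromosomes:
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths for the ref and alt alleles">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tP1\tP2\tFR\tSM\n")
        for i, row in enumerate(table.itertuples(index=False)):
            restorer_is_ref = i % 2 == 0
            ref = row.restorer_allele if restorer_is_ref else row.other_allele
            alt = row.other_allele if restorer_is_ref else row.restorer_allele
            if restorer_is_ref:
                p1_gt, p2_gt = "0/0", "1/1"
                p1_ad = f"{row.p1_depth},0"
                p2_ad = f"0,{row.p2_depth}"
                fr_ad = f"{row.fr_restorer},{row.fr_other}"
                sm_ad = f"{row.sm_restorer},{row.sm_other}"
            else:
                p1_gt, p2_gt = "1/1", "0/0"
                p1_ad = f"0,{row.p1_depth}"
                p2_ad = f"{row.p2_depth},0"
                fr_ad = f"{row.fr_other},{row.fr_restorer}"
                sm_ad = f"{row.sm_other},{row.sm_restorer}"
            fr_dp = row.fr_restorer + row.fr_other
            sm_dp = row.sm_restorer + row.sm_other
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT:DP:AD\t"
                f"{p1_gt}:{row.p1_depth}:{p1_ad}\t{p2_gt}:{row.p2_depth}:{p2_ad}\t"
                f"./.:{fr_dp}:{fr_ad}\t./.:{sm_dp}:{sm_ad}\n"
            )


def simulate_dataset(
    out_path,
    fmt: str = "tsv",
    genome: GenomeModel | None = None,
    model: RestorationModel | None = None,
    n_plants: int = 1000,
    fr_spec: BulkSpec = DEFAULT_FR_SPEC,
    sm_spec: BulkSpec = DEFAULT_SM_SPEC,
    read_model: ReadModel = ReadModel(),
    seed: int = 0,
) -> pd.DataFrame:
    """Full study emulation: F2, bulks, reads; write a variant table.

    Returns the oriented table that was written.
    """
    genome = genome if genome is not None else default_genome()
    model = model if model is not None else default_restoration_model()
    pop = simulate_f2(genome, model, n_plants, rng=substream(seed, "f2"))
    fr, sm = build_bulks(pop, genome, model, fr_spec, sm_spec, rng=substream(seed, "bulks"))
    table = simulate_reads({"FR": fr, "SM": sm}, genome, read_model, rng=substream(seed, "reads"))
    if fmt == "tsv":
        write_tsv(table, out_path, seed=seed)
    elif fmt == "vcf":
        write_vcf(table, out_path, genome, seed=seed)
    else:
        raise ConfigError(f"unknown output format {fmt!r} (expected 'tsv' or 'vcf')")
    return table
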