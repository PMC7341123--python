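import numpy as np
import pandas as pd
import pytest

import bulkseg as bs


@pytest.fixture(scope="session")
def small_genome():
    """Two 30-Mb chromosomes, one SNP per 100 kb: 300 sites per chromosome."""
    return bs.GenomeModel((("chr1", 30_000_000), ("chr2", 30_000_000)), snp_spacing=100_000)


@pytest.fixture(scope="session")
def small_model():
    """Both loci on chr1, far enough apart to be nearly unlinked."""
    return bs.default_restoration_model(
        rf4_locus=("chr1", 2_000_000), q_locus=("chr1", 26_000_000)
    )


@pytest.fixture(scope="session")
def null_model():
    """Fertility independent of genotype: a no-QTL phenotype model."""
    dist = {"V": 0.5, "I": 0.5}
    return bs.RestorationModel(
        rf4_locus=("chr1", 2_000_000),
        q_locus=("chr1", 26_000_000),
        penetrance={c: dict(dist) for c in ("Rf4_", "rf4rf4:qq", "rf4rf4:Qq", "rf4rf4:QQ")},
    )


@pytest.fixture(scope="session")
def sim_tables(small_genome, small_model):
    """One simulated dataset (population, bulks, oriented variant table)."""
    pop = bs.simulate_f2(small_genome, small_model, 1500, seed=11)
    fr, sm = bs.build_bulks(pop, small_genome, small_model, seed=11)
    table = bs.simulate_reads({"FR": fr, "SM": sm}, small_genome, bs.ReadModel(), seed=11)
    return {"pop": pop, "fr": fr, "sm": sm, "table": table}


def make_records(chrom, pos, fr_index, sm_index, fr_depth=30, sm_depth=30):
    """Indexed-record table straight from per-site indices (unit-test helper)."""
    pos = np.asarray(pos)
    fr_index = np.asarray(fr_index, dtype=float)
    sm_index = np.asarray(sm_index, dtype=float)
    n = pos.size
    fr_depth = np.broadcast_to(np.asarray(fr_depth), (n,)).astype(int)
    sm_depth = np.broadcast_to(np.asarray(sm_depth), (n,)).astype(int)
    return pd.DataFrame(
        {
            "chrom": np.broadcast_to(chrom, (n,)) if isinstance(chrom, str) else chrom,
            "pos": pos,
            "fr_depth": fr_depth,
            "sm_depth": sm_depth,
            "fr_index": fr_index,
            "sm_index": sm_index,
            "delta": fr_index - sm_index,
        }
    )
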