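import numpy as np
import pytest

import cfcomp as c


@pytest.fixture(scope="session")
def small_genome():
    """1 Mb all-normal chromosome."""
    return c.generate_genome(1_000_000)


@pytest.fixture(scope="session")
def labeled_genome():
    """2 Mb chromosome with centromere/difficult/gap intervals and retention bias."""
    return c.generate_genome(
        2_000_000,
        [
            (900_000, 1_000_000, "centromere"),
            (1_000_000, 1_060_000, "difficult"),
            (1_500_000, 1_520_000, "gap"),
        ],
        bias={
            "centromere": {"short_insert": 0.05, "long_insert": 0.30},
            "difficult": {"short_insert": 0.60, "long_insert": 0.85},
            "gap": {"short_insert": 0.0, "long_insert": 0.0},
        },
    )


@pytest.fixture(scope="session")
def cohort(small_genome):
    """200 individuals x 2000 variants, single ancestry group."""
    return c.generate_cohort(200, 2000, seed=42, genome=small_genome)


@pytest.fixture(scope="session")
def observed_pair(cohort, small_genome):
    """Two observed matrices from the same truth, error-only (e=0.01)."""
    obs = c.ObservationModel(
        short=c.KindObservation(error_rate=0.01, missing_rate=0.0, dropout=0.0),
        long=c.KindObservation(error_rate=0.01, missing_rate=0.0, dropout=0.0),
    )
    a = c.observe_genotypes(cohort, obs, small_genome, "short_insert", seed=7)
    b = c.observe_genotypes(cohort, obs, small_genome, "long_insert", seed=8)
    return a, b


def toy_matrix(dosages, positions=None, vclass=None, refs=None, alts=None, samples=None):
    """Build a small GenotypeMatrix from an (n_samples, n_variants) array."""
    import pandas as pd

    d = np.asarray(dosages, dtype=np.int8)
    n_s, n_v = d.shape
    pos = positions if positions is not None else list(range(100, 100 + n_v))
    variants = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": pos,
            "ref": refs if refs is not None else ["A"] * n_v,
            "alt": alts if alts is not None else ["G"] * n_v,
            "vclass": vclass if vclass is not None else ["SNP"] * n_v,
            "multiallelic": [False] * n_v,
        }
    )
    return c.GenotypeMatrix(
        samples=samples if samples is not None else [f"S{i:04d}" for i in range(n_s)],
        variants=variants,
        dosages=d,
    )
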