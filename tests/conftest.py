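import numpy as np
import pandas as pd
import pytest

from prsport import simulate as sim
from prsport.io import GenotypeMatrix


def make_gm(dosages, chrom="1", pos_start=1, spacing=5000, prefix="S"):
    """Wrap a raw dosage array in a GenotypeMatrix with synthetic metadata."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    variants = pd.DataFrame(
        {
            "chrom": [chrom] * m,
            "pos": pos_start + spacing * np.arange(m),
            "id": [f"v{j}" for j in range(m)],
            "ref": ["A"] * m,
            "alt": ["G"] * m,
        }
    )
    return GenotypeMatrix(dosages, [f"{prefix}{i}" for i in range(n)], variants)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240830)


@pytest.fixture(scope="session")
def small_cohort():
    """One-population cohort with LD blocks, reused across read-only tests."""
    spec = sim.PopulationSpec(fst=(0.0,), sample_sizes=(600,))
    freqs = sim.simulate_population_frequencies(spec, 300, 11, block_length=5)
    geno, pops, variants = sim.simulate_genotypes(
        freqs, spec.sample_sizes, sim.LDBlockSpec(5, 0.6), 12
    )
    cohort, truth = sim.simulate_phenotypes(
        geno, variants, sim.TraitArchitecture(n_causal=20, h2_snp=0.3,
                                              clinical_frac=0.25), 13
    )
    gm = GenotypeMatrix(
        geno, [f"S{i}" for i in range(geno.shape[0])],
        variants[["chrom", "pos", "id", "ref", "alt"]],
    )
    return gm, cohort, truth
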