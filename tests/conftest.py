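import numpy as np
import pytest

from balscan.simulate import GroupSpec, SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A compact two-chromosome dataset with one planted region per chromosome."""
    config = SimConfig(
        n_chromosomes=2,
        chrom_length=2_000_000,
        groups=[
            GroupSpec("selfing", n_populations=2, n_individuals_per_pop=4, inbreeding_f=0.9),
            GroupSpec("outcrossing", n_populations=4, n_individuals_per_pop=4, inbreeding_f=0.0),
        ],
        seed=42,
    )
    return simulate_dataset(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_locus_calls(rng, n_individuals, n_haplotypes=4, length=6, p_missing=0.2):
    """Random calls at one locus: pairs drawn from a small haplotype alphabet."""
    bases = np.array(list("ACGT"))
    haps = ["".join(bases[rng.integers(0, 4, size=length)]) for _ in range(n_haplotypes)]
    calls = []
    for _ in range(n_individuals):
        if rng.random() < p_missing:
            calls.append(None)
        else:
            a, b = rng.choice(haps), rng.choice(haps)
            calls.append((a, b) if a <= b else (b, a))
    return calls
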