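import numpy as np
import pytest

import genomesurvey as gs


def random_dna(rng: np.random.Generator, n: int, with_n: float = 0.0) -> str:
    alphabet = "ACGTN" if with_n > 0 else "ACGT"
    if with_n > 0:
        codes = rng.choice(5, size=n, p=[(1 - with_n) / 4] * 4 + [with_n])
    else:
        codes = rng.integers(0, 4, size=n)
    return "".join(alphabet[c] for c in codes)


@pytest.fixture(scope="session")
def small_sim():
    """A modest diploid simulation with repeats, SNPs and sequencing errors."""
    spec = gs.SimulationSpec(
        genome_length=60_000,
        het_rate=0.002,
        repeat_fraction=0.10,
        repeat_unit_length=1000,
        coverage=20.0,
        base_error_rate=0.001,
        seed=11,
    )
    truth = gs.simulate_diploid_genome(spec)
    pairs = gs.simulate_reads(truth, spec)
    return spec, truth, pairs
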