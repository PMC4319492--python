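import numpy as np
import pytest

from plastasm.simulate import GenomeSpec, build_plastome, simulate_ccs_reads


@pytest.fixture
def small_plastome():
    """6 kb quadripartite genome: LSC 3.5 kb, SSC 1 kb, IR 750 bp."""
    return build_plastome(GenomeSpec(lsc_len=3500, ssc_len=1000,
                                     ir_len=750, seed=42))


@pytest.fixture
def small_reads(small_plastome):
    """Error-free 30x reads (mean 400 bp) from the 6 kb genome."""
    return simulate_ccs_reads(small_plastome, coverage=30, mean_len=400,
                              len_sd=120, max_len=800, error_rate=0.0,
                              seed=7)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[c] for c in rng.integers(0, 4, size=n))
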