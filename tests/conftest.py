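import numpy as np
import pytest

from atacqc.formats_io import AlignedPair, ChromSizes
from atacqc.read_processing import EndSet, useful_ends
from atacqc.synthetic import SimulationConfig, simulate_genome, simulate_pairs


@pytest.fixture(scope="session")
def small_sizes():
    return ChromSizes({"chr1": 1_000_000, "chr2": 500_000, "chrM": 20_000})


@pytest.fixture(scope="session")
def sim_library():
    """One seeded synthetic library shared across tests (read-only)."""
    cfg = SimulationConfig(seed=11, n_pairs=8000)
    sizes, peaks, tss = simulate_genome(cfg)
    pairs, truth = simulate_pairs(cfg, sizes, peaks)
    return {"config": cfg, "sizes": sizes, "peaks": peaks, "tss": tss,
            "pairs": pairs, "truth": truth}


def make_pair(chrom="chr1", start_plus=100, end_plus=150,
              start_minus=200, end_minus=250, mapq=60):
    return AlignedPair(chrom=chrom, start_plus=start_plus, end_plus=end_plus,
                       start_minus=start_minus, end_minus=end_minus, mapq=mapq)


def endset_from_centers(centers, sizes, chrom="chr1", ext=75,
                        mode="pseudoSE", include_mito=False):
    """EndSet of pseudo-SE-style fragments centred at given positions."""
    centers = np.asarray(centers, dtype=np.int64)
    length = sizes[chrom]
    starts = np.maximum(centers - ext, 0)
    ends = np.minimum(centers + ext, length)
    return EndSet(mode=mode, sizes=sizes, include_mito=include_mito,
                  chroms=np.asarray([chrom] * len(centers), dtype=object),
                  starts=starts, ends=ends, centers=centers,
                  strands=np.asarray(["+"] * len(centers), dtype=object))
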