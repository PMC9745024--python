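import numpy as np
import pytest

from aidnipt.genome import GenomeBuild, make_bins
from aidnipt.simulate import toy_genome


@pytest.fixture(scope="session")
def tiny_genome() -> GenomeBuild:
    """Hand-built 3-chromosome genome with known flag outcomes.

    chr1: 10 Mb, one centromeric mask overlapping bins 2 and 3, one bin
    with boundary mappability (80) and one with boundary GC values.
    chr2: 5.5 Mb (short terminal tail dropped).  chr21: 3 Mb, clean.
    """
    gc1 = np.array([40, 40, 40, 40, 40, 50.0, 30.0, 50.1, 40, 40])
    mp1 = np.array([95, 95, 95, 95, 80.0, 95, 95, 95, 80.1, 95])
    return GenomeBuild(
        chrom_names=["chr1", "chr2", "chr21"],
        chrom_lengths={"chr1": 10_000_000, "chr2": 5_500_000, "chr21": 3_000_000},
        mask_intervals={"chr1": [(2_500_000, 3_200_000)]},
        gc_track={"chr1": gc1, "chr2": np.full(5, 42.0), "chr21": np.full(3, 41.0)},
        map_track={"chr1": mp1, "chr2": np.full(5, 92.0), "chr21": np.full(3, 93.0)},
    )


@pytest.fixture(scope="session")
def tiny_bins(tiny_genome):
    return make_bins(tiny_genome)


@pytest.fixture(scope="session")
def study_genome() -> GenomeBuild:
    """The half-scale human-like simulator genome."""
    return toy_genome()


@pytest.fixture(scope="session")
def study_bins(study_genome):
    return make_bins(study_genome)
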