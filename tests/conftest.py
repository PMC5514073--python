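import numpy as np
import pandas as pd
import pytest

from mutdna import (
    GenomeBins,
    call_variants,
    default_scenario,
    make_genome,
    simulate_cohort,
)


def uniform_genome(n_bins: int = 100, n_chrom: int = 1, gc: float = 0.45) -> GenomeBins:
    """A flat bin frame (constant GC, perfect mappability, no blacklist)."""
    rows = []
    for c in range(1, n_chrom + 1):
        starts = np.arange(n_bins, dtype=np.int64) * 1_000_000
        rows.append(
            pd.DataFrame(
                {
                    "chrom": f"chr{c}",
                    "start": starts,
                    "end": starts + 1_000_000,
                    "gc": gc,
                    "mappability": 1.0,
                    "blacklisted": False,
                }
            )
        )
    return GenomeBins(pd.concat(rows, ignore_index=True))


@pytest.fixture(scope="session")
def genome22():
    return make_genome(22, 1_000_000, 50, seed=0)


@pytest.fixture(scope="session")
def cohort():
    """The default 17-patient synthetic cohort at a fixed seed."""
    return simulate_cohort(default_scenario(11))


@pytest.fixture(scope="session")
def called_cohort(cohort):
    return call_variants(cohort.variants)
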