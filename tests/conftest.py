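import numpy as np
import pandas as pd
import pytest

import arraycnv as ac
from arraycnv.core import centromere_table


@pytest.fixture(scope="session")
def one_chrom_map():
    """2,000 markers on one 50 Mb chromosome."""
    return ac.generate_marker_map(2000, {"1": 50_000_000}, seed=11)


@pytest.fixture(scope="session")
def centromeres_15():
    return centromere_table({"15": (39_000_000, 41_000_000)})


@pytest.fixture(scope="session")
def chrom15_map(centromeres_15):
    """4,000 markers on a 102 Mb chromosome with a centromere gap."""
    return ac.generate_marker_map(4000, {"15": 102_000_000},
                                  centromeres=centromeres_15, seed=7)


@pytest.fixture(scope="session")
def quiet_cohort(one_chrom_map):
    """20 event-free samples with default noise."""
    return ac.simulate_cohort(one_chrom_map, 10, 10, seed=23)


def make_uniform_map(n, spacing_bp=10_000, chrom="1", start=1_000_000, pfb=0.5):
    """Evenly spaced markers with constant PFB, for constructed fixtures."""
    pos = start + spacing_bp * np.arange(n)
    return ac.MarkerMap(pd.DataFrame({
        "marker_id": [f"s{i}" for i in range(n)],
        "chromosome": chrom,
        "position_bp": pos,
        "pfb": pfb,
        "gc_frac": 0.5,
        "is_stable": True,
    }))
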