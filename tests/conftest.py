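import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import clonekit as ck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_dataset() -> ck.SimulatedDataset:
    """One simulated data set under the reference conditions, shared across
    tests (clone structure: 1 triploid clone, 8 diploid sibs, 1 pentaploid
    clone, plus duplicate libraries)."""
    return ck.simulate_dataset(ck.SimConfig(seed=2026))


@pytest.fixture(scope="session")
def dataset_paths(default_dataset, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("simdata")
    return ck.write_dataset(default_dataset, outdir)


def depth_table_from_counts(ref: np.ndarray, alt: np.ndarray,
                            sample_id: str = "S") -> ck.DepthTable:
    """Build a one-sample DepthTable from per-locus ref/alt counts."""
    m = len(ref)
    loci = [f"L{j:05d}" for j in range(m)]
    frame = pd.DataFrame(
        {
            "sample_id": sample_id,
            "locus_id": loci * 2,
            "allele": [1] * m + [2] * m,
            "count": np.concatenate([ref, alt]),
        }
    )
    return ck.DepthTable(frame[frame["count"] > 0])
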