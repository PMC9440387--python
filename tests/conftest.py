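import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from maternalome.datasets import DEFAULT_STAGES, ProteomeDataset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_dataset() -> ProteomeDataset:
    """4 proteins x 6 stages x 3 replicates with a few missing cells."""
    rng = np.random.default_rng(42)
    abund = np.exp2(rng.normal(24, 1, (4, 6, 3)))
    abund[0, 2, 1] = np.nan
    abund[3, :, :] = np.nan
    abund[3, 0, :] = 100.0
    return ProteomeDataset(
        dataset_id="TEST",
        proteins=["Ooep", "Nlrp5", "Tle6", "Rare1"],
        stages=DEFAULT_STAGES,
        n_replicates=3,
        abundances=abund,
    )


def random_detection(rng: np.random.Generator, n: int = 50, s: int = 6, k: int = 3, p: float = 0.5):
    from maternalome.datasets import DetectionTable

    return DetectionTable(
        dataset_id="RAND",
        proteins=[f"p{i}" for i in range(n)],
        stages=tuple(f"S{j}" for j in range(s)),
        n_replicates=k,
        detected=rng.random((n, s, k)) < p,
    )
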