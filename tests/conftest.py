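import numpy as np
import pandas as pd
import pytest

from minet import PipelineConfig, SampleMatrix, analyze, default_planted_spec, generate_planted


@pytest.fixture(scope="session")
def small_planted():
    """A small planted dataset (n=150) with its truth matrix."""
    spec = default_planted_spec(n_observations=150, seed=11)
    data, truth = generate_planted(spec)
    return spec, data, truth


@pytest.fixture(scope="session")
def small_pipeline_result(small_planted):
    """One cheap end-to-end run shared by the tests that only inspect artifacts."""
    _, data, _ = small_planted
    cfg = PipelineConfig(seed=5, n_pairs=15, n_permutations=40)
    return analyze(data, cfg)


@pytest.fixture()
def gaussian_matrix():
    """Standardized i.i.d. Gaussian matrix: 6 inputs + 2 outputs, n=200."""
    rng = np.random.default_rng(42)
    names = [f"P{i:02d}" for i in range(6)] + ["C0", "C1"]
    frame = pd.DataFrame(rng.standard_normal((200, 8)), columns=names)
    roles = {c: ("input" if c.startswith("P") else "output") for c in names}
    return SampleMatrix(values=frame, roles=roles, dataset_label="gauss")
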