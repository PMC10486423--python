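import numpy as np
import pytest

from lesionselect import FeatureBlock, LabelVector, SyntheticSpec, generate


@pytest.fixture()
def rng():
    return np.random.default_rng(1)


@pytest.fixture()
def small_blocks(rng):
    """Four named blocks with the benchmark names at desk-scale widths."""
    widths = {"FV1": 2, "FV2": 16, "FV3": 10, "FV4": 20}
    return [
        FeatureBlock(name=n, values=rng.normal(size=(12, w)), source_tag=f"emulated/{n}")
        for n, w in widths.items()
    ]


@pytest.fixture()
def binary_labels():
    return LabelVector(labels=("benign",) * 9 + ("melanoma",) * 3)


@pytest.fixture(scope="session")
def default_synthetic():
    """Default synthetic dataset (200 samples, 448 fused columns, seed 1)."""
    return generate(SyntheticSpec(seed=1))


@pytest.fixture(scope="session")
def tiny_synthetic():
    """Small, fast dataset for selector and harness tests."""
    spec = SyntheticSpec(
        n_samples=60,
        block_widths=(2, 16, 10, 20),
        n_informative=(0, 3, 2, 3),
        n_redundant=(0, 2, 1, 2),
        effect_size=3.0,
        seed=7,
    )
    return generate(spec)
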