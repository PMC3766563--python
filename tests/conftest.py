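import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from antioxseq import features, seqio, synth

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def separable_ds() -> seqio.LabeledDataset:
    """Tiny trivially separable dataset (10 pos / 10 neg)."""
    return synth.generate(synth.separable_spec(n_per_class=10, seed=11))


@pytest.fixture(scope="session")
def separable_fm(separable_ds) -> features.FeatureMatrix:
    return features.encode_dataset(separable_ds)


@pytest.fixture(scope="session")
def biased_ds() -> seqio.LabeledDataset:
    """Default study conditions: injected residue + dipeptide signal."""
    return synth.generate(synth.SynthSpec(seed=7))


@pytest.fixture(scope="session")
def biased_fm(biased_ds) -> features.FeatureMatrix:
    return features.encode_dataset(biased_ds)


@pytest.fixture(scope="session")
def null_ds() -> seqio.LabeledDataset:
    """No-signal dataset: both classes share the background composition."""
    return synth.generate(synth.null_spec(n_per_class=100, seed=13))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def random_sequences(rng: np.random.Generator, n: int, lo=2, hi=60):
    """n random standard-alphabet sequences with lengths in [lo, hi]."""
    aa = np.array(list(features.AMINO_ACIDS))
    out = []
    for _ in range(n):
        length = int(rng.integers(lo, hi + 1))
        out.append("".join(aa[rng.integers(0, 20, size=length)]))
    return out
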