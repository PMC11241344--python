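import warnings

import numpy as np
import pytest

import cppmine as cm

warnings.filterwarnings("ignore", category=FutureWarning)

BENCHMARK_SEED = 40


def random_peptides(n: int, seed: int, min_len: int = 5, max_len: int = 61) -> list[str]:
    """Uniform-composition random peptides for oracle comparisons."""
    rng = np.random.default_rng(seed)
    letters = np.array(list(cm.sequence_io.AMINO_ACIDS))
    lengths = rng.integers(min_len, max_len + 1, size=n)
    return ["".join(rng.choice(letters, size=L)) for L in lengths]


@pytest.fixture(scope="session")
def benchmark_set() -> cm.SequenceSet:
    """The synthetic benchmark: 500 CPP-like + 500 background, full signal."""
    return cm.generate_labeled_set(
        cm.GeneratorConfig(n_per_class=500, seed=BENCHMARK_SEED, signal_strength=1.0)
    )


@pytest.fixture(scope="session")
def benchmark_results(benchmark_set) -> cm.EnsembleResults:
    """Fitted stacked ensemble on the selected benchmark features."""
    features = cm.featurize(benchmark_set)
    selected, _report = cm.select_features(features, seed=BENCHMARK_SEED)
    return cm.CPPEnsemble(selected, cm.EnsembleConfig(seed=BENCHMARK_SEED)).fit()


@pytest.fixture(scope="session")
def small_labeled_set() -> cm.SequenceSet:
    """A light 60/class set for unit-level model tests."""
    return cm.generate_labeled_set(
        cm.GeneratorConfig(n_per_class=60, seed=7, signal_strength=1.0, length_range=(5, 25))
    )
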