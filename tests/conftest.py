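import numpy as np
import pytest

from kgrex import CorpusSpec, KGSpec, LabelScheme, generate_corpus, generate_kg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def planted_kg():
    """Noise-free planted-translation KG: 3 relations x 20 triples, k=8."""
    spec = KGSpec(n_drugs=20, n_relations=3, triples_per_relation=20, k_true=8, rng_seed=1)
    return generate_kg(spec)


@pytest.fixture(scope="session")
def tiny_corpus():
    """Small multiclass corpus with full lexical signal."""
    spec = CorpusSpec(
        n_instances=12,
        vocab_size=50,
        scheme=LabelScheme.multiclass(),
        signal_strength=1.0,
        rng_seed=42,
    )
    return generate_corpus(spec)


def finite_difference(f, arr, analytic, eps=1e-6, stride=1):
    """Worst relative error between ``analytic`` and central differences of
    the scalar function ``f`` with respect to entries of ``arr``."""
    worst = 0.0
    for idx in list(np.ndindex(arr.shape))[::stride]:
        orig = arr[idx]
        arr[idx] = orig + eps
        fp = f()
        arr[idx] = orig - eps
        fm = f()
        arr[idx] = orig
        num = (fp - fm) / (2 * eps)
        ana = analytic[idx]
        denom = abs(ana) + abs(num)
        if denom > 1e-10:
            worst = max(worst, abs(ana - num) / denom)
    return worst
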