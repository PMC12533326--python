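import numpy as np
import pytest

from gpcca.data import MultiModalDataset


def random_dataset(rng, dims=(3, 4, 5), n=30, miss=0.2, blockwise=False,
                   latent=2, noise=0.7):
    """Small dataset drawn from a random factor model, with either
    entrywise or modality-wise missingness."""
    m = sum(dims)
    W = rng.standard_normal((m, latent))
    mu = rng.standard_normal(m)
    X = W @ rng.standard_normal((latent, n)) + mu[:, None]
    X += noise * rng.standard_normal((m, n))
    off = np.concatenate([[0], np.cumsum(dims)])
    if miss == 0:
        mask = np.ones((m, n), dtype=bool)
    elif blockwise:
        mask = np.ones((m, n), dtype=bool)
        for r in range(len(dims)):
            drop = rng.random(n) < miss
            mask[off[r]: off[r + 1], drop] = False
        dead = ~mask.any(axis=0)
        mask[:, dead] = True
    else:
        mask = rng.random((m, n)) > miss
        for j in range(n):
            if not mask[:, j].any():
                mask[0, j] = True
    Xn = np.where(mask, X, np.nan)
    return MultiModalDataset([Xn[off[r]: off[r + 1]] for r in range(len(dims))])


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_missing_dataset(rng):
    return random_dataset(rng, dims=(3, 4, 5), n=24, miss=0.25)


@pytest.fixture
def small_complete_dataset(rng):
    return random_dataset(rng, dims=(3, 4, 5), n=24, miss=0.0)
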