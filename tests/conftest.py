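import numpy as np
import pytest

from xtalselect import obscore, parcrys, seqfeat, synth


@pytest.fixture(scope="session")
def labelled_features():
    """Small labelled synthetic dataset shared across model tests."""
    records, labels = synth.generate_labelled_dataset(150, 150, seed=11)
    feats = [seqfeat.extract_features(r) for r in records]
    return records, feats, labels["label"].to_numpy()


@pytest.fixture(scope="session")
def parzen_model(labelled_features):
    _, feats, labels = labelled_features
    return parcrys.fit_parzen([f for f, l in zip(feats, labels) if l == 1])


@pytest.fixture(scope="session")
def zscore_matrix(labelled_features):
    _, feats, labels = labelled_features
    pos = [f for f, l in zip(feats, labels) if l == 1]
    bg = [f for f, l in zip(feats, labels) if l == 0]
    return obscore.build_zscore_matrix(pos, bg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_sequence(rng, min_len=30, max_len=200):
    letters = list(seqfeat.STANDARD_AA)
    length = int(rng.integers(min_len, max_len + 1))
    return "".join(rng.choice(letters, size=length))
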