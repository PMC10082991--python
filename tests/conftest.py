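import numpy as np
import pytest

from moltriage.discriminator import DiscConfig, DiscTrainConfig, Discriminator
from moltriage.fixtures import (
    FixtureSpec,
    make_fixture_corpora,
    make_toy_enumerable_world,
)
from moltriage.generator import GenConfig, Generator
from moltriage.tokenizer import build_vocabulary, encode_smiles, tokenize


@pytest.fixture(scope="session")
def toy_world():
    """Fixed enumerable generator/discriminator pair (oracle bed)."""
    return make_toy_enumerable_world()


@pytest.fixture(scope="session")
def corpora():
    """Small separable corpora shared across tests."""
    return make_fixture_corpora(FixtureSpec(n_pos=220, n_neg=220, n_pretrain=400, seed=42))


@pytest.fixture(scope="session")
def vocab_and_len(corpora):
    all_sm = corpora["pretrain"] + corpora["pos"] + corpora["neg"]
    vocab = build_vocabulary(all_sm)
    max_len = max(len(tokenize(s)) for s in all_sm) + 2
    return vocab, max_len


@pytest.fixture(scope="session")
def encoded(corpora, vocab_and_len):
    vocab, max_len = vocab_and_len
    enc = lambda lst: [encode_smiles(s, vocab, max_len) for s in lst]
    return {k: enc(v) for k, v in corpora.items()}


@pytest.fixture(scope="session")
def trained_disc(encoded, vocab_and_len):
    """Discriminator trained once on the separable fixture task."""
    vocab, max_len = vocab_and_len
    disc = Discriminator(
        vocab,
        DiscConfig(emb_size=12, window_sizes=(1, 2, 3, 4), n_filters=12, max_len=max_len),
        seed=0,
        dtype=np.float32,
    )
    report = disc.train_initial(
        encoded["pos"], encoded["neg"], DiscTrainConfig(max_epochs=80), seed=1
    )
    return disc, report


@pytest.fixture()
def small_generator(vocab_and_len):
    vocab, max_len = vocab_and_len
    return Generator(
        vocab,
        GenConfig(emb_size=8, hidden_size=12, n_layers=2, dropout=0.0, max_len=max_len),
        seed=3,
    )
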