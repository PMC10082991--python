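import numpy as np
import pytest

from moltriage.discriminator import DiscConfig, DiscTrainConfig, Discriminator
from moltriage.tokenizer import SPECIALS, TokenSequence, TokenVocabulary


@pytest.fixture()
def tiny_vocab():
    return TokenVocabulary(list(SPECIALS) + ["C", "O"])


def test_embed_rows(tiny_vocab):
    disc = Discriminator(tiny_vocab, DiscConfig(emb_size=4, window_sizes=(1, 2), n_filters=2, max_len=6))
    seq = TokenSequence((1, 3, 4, 3, 2, 0))
    M = disc.embed(seq)
    assert M.shape == (6, 4)
    assert np.array_equal(M[1], M[3])  # shared token, shared row
    assert np.array_equal(M[5], disc.params["emb"][0])  # pad row


def test_feature_maps_shapes_and_zero_kernel(tiny_vocab):
    disc = Discriminator(tiny_vocab, DiscConfig(emb_size=3, window_sizes=(2, 4), n_filters=2, max_len=4))
    M = disc.embed(TokenSequence((1, 3, 4, 2)))
    assert disc.feature_maps(M, 4).shape == (1, 2)  # l = T: one window
    assert disc.feature_maps(M, 2).shape == (3, 2)
    disc.params["conv2_K"][:] = 0.0
    disc.params["conv2_b"][:] = 0.0
    assert np.all(disc.feature_maps(M, 2) == 0.0)
    with pytest.raises(ValueError):
        disc.feature_maps(M, 5)


def test_feature_maps_hand_computed():
    """2-filter window-2 convolution on a 3x2 embedding, checked against
    manual arithmetic."""
    vocab = TokenVocabulary(list(SPECIALS) + ["A", "B", "C"])
    disc = Discriminator(vocab, DiscConfig(emb_size=2, window_sizes=(2,), n_filters=1, max_len=4))
    E = np.array([[1.0, 2.0], [0.5, -1.0], [3.0, 0.0]])
    # kernel rows stacked per window offset: ω ∈ R^{2x2} flattened to 4x1
    disc.params["conv2_K"] = np.array([[1.0], [0.0], [2.0], [-1.0]])
    disc.params["conv2_b"] = np.array([0.5])
    out = disc.feature_maps(E, 2)
    # window 1: 1*1 + 2*0 + 0.5*2 + (-1)*(-1) + 0.5 = 3.5
    # window 2: 0.5*1 + (-1)*0 + 3*2 + 0*(-1) + 0.5 = 7.0
    np.testing.assert_allclose(out[:, 0], [3.5, 7.0])


def test_predict_in_open_interval_and_deterministic(toy_world):
    _, _, _, disc = toy_world
    ids = np.array([[1, 3, 4, 2, 0], [1, 4, 4, 4, 2]])
    p = disc.predict(ids)
    assert np.all((p > 0) & (p < 1))
    assert np.array_equal(p, disc.predict(ids))


def test_predict_pad_invariance(toy_world):
    _, _, _, disc = toy_world
    short = np.array([[1, 3, 4, 2]])
    padded = np.array([[1, 3, 4, 2, 0, 0, 0, 0]])
    assert disc.predict(short)[0] == pytest.approx(disc.predict(padded)[0], abs=1e-12)


def test_window_order_permutation_invariant(tiny_vocab):
    d1 = Discriminator(tiny_vocab, DiscConfig(emb_size=4, window_sizes=(1, 2, 3), n_filters=2, max_len=6), seed=7)
    d2 = Discriminator(tiny_vocab, DiscConfig(emb_size=4, window_sizes=(3, 1, 2), n_filters=2, max_len=6), seed=7)
    ids = np.array([[1, 3, 4, 3, 2, 0]])
    assert d1.predict(ids)[0] == d2.predict(ids)[0]


def test_gradients_match_finite_differences(tiny_vocab):
    disc = Discriminator(tiny_vocab, DiscConfig(emb_size=3, window_sizes=(1, 2, 3), n_filters=2, max_len=5))
    ids = np.array([[1, 3, 4, 3, 2], [1, 4, 2, 0, 0]])
    labels = np.array([1.0, 0.0])
    _, grads = disc.loss_and_grads(ids, labels)
    h = 1e-6
    rng = np.random.default_rng(3)
    for k, g in grads.items():
        flat = disc.params[k].reshape(-1)
        gf = np.asarray(g).reshape(-1)
        for i in rng.choice(flat.size, size=min(8, flat.size), replace=False):
            orig = flat[i]
            flat[i] = orig + h
            lp, _ = disc.loss_and_grads(ids, labels)
            flat[i] = orig - h
            lm, _ = disc.loss_and_grads(ids, labels)
            flat[i] = orig
            assert gf[i] == pytest.approx((lp - lm) / (2 * h), rel=1e-4, abs=1e-8), k


def test_split_proportions_double_invariant():
    a, b = Discriminator.config_split_points(100, (0.8, 0.1, 0.1))
    a2, b2 = Discriminator.config_split_points(200, (0.8, 0.1, 0.1))
    assert (a2, b2) == (2 * a, 2 * b)


def test_train_initial_validates_inputs(tiny_vocab):
    disc = Discriminator(tiny_vocab, DiscConfig(emb_size=4, window_sizes=(1,), n_filters=2, max_len=6))
    with pytest.raises(ValueError):
        disc.train_initial([], [TokenSequence((1, 3, 2))], DiscTrainConfig())
    with pytest.raises(ValueError):
        DiscTrainConfig(split=(0.5, 0.2, 0.2))


def test_train_initial_separates_fixture_grammars(trained_disc):
    """The separable-by-construction task is learned to high AUC."""
    _, report = trained_disc
    assert report["test_auc"] >= 0.95
    assert report["n_train"] > report["n_val"] >= report["n_test"] - 2


def test_train_initial_no_signal_control(encoded, vocab_and_len):
    """With both classes drawn from the same grammar the internal-test
    AUC stays near chance."""
    vocab, max_len = vocab_and_len
    disc = Discriminator(
        vocab,
        DiscConfig(emb_size=8, window_sizes=(1, 2, 3), n_filters=8, max_len=max_len),
        seed=5,
        dtype=np.float32,
    )
    pool = encoded["pretrain"]
    report = disc.train_initial(pool[:150], pool[150:300], DiscTrainConfig(max_epochs=8), seed=6)
    assert abs(report["test_auc"] - 0.5) <= 0.2


def test_trained_scores_separate_classes(trained_disc, encoded):
    disc, _ = trained_disc
    pos_scores = disc.predict(encoded["pos"][:100])
    neg_scores = disc.predict(encoded["neg"][:100])
    assert pos_scores.mean() > neg_scores.mean() + 0.1


def test_checkpoint_roundtrip(tmp_path, toy_world):
    _, _, _, disc = toy_world
    path = tmp_path / "disc.npz"
    disc.save(path)
    disc2 = Discriminator(disc.vocab).load(path)
    ids = np.array([[1, 3, 4, 2, 0]])
    assert disc2.predict(ids)[0] == disc.predict(ids)[0]
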