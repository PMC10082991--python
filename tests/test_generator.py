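import numpy as np
import pytest

from moltriage.fixtures import enumerate_sequences
from moltriage.generator import GenConfig, GenTrainConfig, Generator, target_mask
from moltriage.tokenizer import SPECIALS, TokenSequence, TokenVocabulary


@pytest.fixture()
def tiny_vocab():
    return TokenVocabulary(list(SPECIALS) + ["C", "O"])


def _uniform_policy(gen):
    gen.params["M"][:] = 0.0
    gen.params["c"][:] = 0.0
    return gen


def test_step_distribution_normalizes(toy_world):
    _, _, gen, _ = toy_world
    hidden = gen.init_hidden(4)
    _, probs = gen.step(hidden, np.array([1, 3, 4, 2]))
    assert probs.shape == (4, len(gen.vocab))
    assert np.all(probs >= 0)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)


def test_step_uniform_for_zero_output_layer(tiny_vocab):
    gen = _uniform_policy(Generator(tiny_vocab, GenConfig(emb_size=4, hidden_size=5, max_len=6)))
    _, probs = gen.step(gen.init_hidden(1), np.array([1]))
    np.testing.assert_allclose(probs, 1.0 / len(tiny_vocab), atol=1e-12)


def test_step_deterministic(toy_world):
    _, _, gen, _ = toy_world
    h = gen.init_hidden(2)
    _, p1 = gen.step(h, np.array([3, 4]))
    _, p2 = gen.step(h, np.array([3, 4]))
    assert np.array_equal(p1, p2)


def test_sample_contracts(toy_world):
    _, max_len, gen, _ = toy_world
    assert len(gen.sample(0)) == 0
    a = gen.sample(50, rng=np.random.default_rng(5))
    b = gen.sample(50, rng=np.random.default_rng(5))
    assert np.array_equal(a, b)
    assert np.all(a[:, 0] == gen.vocab.start_id)
    # at most one end token, terminal if present: after the first end,
    # everything is pad
    for row in a:
        ends = np.nonzero(row == gen.vocab.end_id)[0]
        if len(ends):
            assert np.all(row[ends[0] + 1 :] == gen.vocab.pad_id)


def test_forced_termination(tiny_vocab):
    gen = Generator(tiny_vocab, GenConfig(emb_size=4, hidden_size=5, max_len=6))
    gen.params["M"][:] = 0.0
    gen.params["c"][:] = 0.0
    gen.params["c"][tiny_vocab.end_id] = 1e3  # p(end | anything) = 1
    ids = gen.sample(10, rng=np.random.default_rng(0))
    assert np.all(ids[:, 1] == tiny_vocab.end_id)
    assert np.all(ids[:, 2:] == tiny_vocab.pad_id)


def test_log_prob_uniform_closed_form(tiny_vocab):
    gen = _uniform_policy(Generator(tiny_vocab, GenConfig(emb_size=4, hidden_size=5, max_len=8)))
    V = len(tiny_vocab)
    seq = TokenSequence((1, 3, 4, 3, 2))  # 3 body tokens + end
    assert gen.sequence_log_prob(seq) == pytest.approx(4 * np.log(1 / V), rel=1e-9)


def test_log_prob_padding_invariant(toy_world):
    _, _, gen, _ = toy_world
    assert gen.sequence_log_prob(TokenSequence((1, 3, 2))) == pytest.approx(
        gen.sequence_log_prob(TokenSequence((1, 3, 2, 0, 0))), abs=1e-12
    )


def test_log_prob_matches_enumeration(toy_world):
    """Chain-rule likelihoods agree with exhaustively enumerated path
    probabilities, and the enumerated measure is a distribution."""
    _, _, gen, _ = toy_world
    ids, probs = enumerate_sequences(gen)
    assert probs.sum() == pytest.approx(1.0, abs=1e-9)
    sel = np.random.default_rng(0).choice(len(ids), size=25, replace=False)
    for i in sel:
        lp = gen.sequence_log_prob(TokenSequence(tuple(ids[i])))
        assert np.exp(lp) == pytest.approx(probs[i], rel=1e-9)


def test_sample_frequencies_match_enumeration(toy_world):
    """Empirical sampling frequencies agree with enumerated sequence
    probabilities within 3σ multinomial error (50,000 draws)."""
    _, max_len, gen, _ = toy_world
    ids, probs = enumerate_sequences(gen)
    n = 50_000
    draws = gen.sample(n, rng=np.random.default_rng(123))
    counts = {}
    for row in draws:
        counts[tuple(row)] = counts.get(tuple(row), 0) + 1
    # ~340 simultaneous comparisons: allow the ~1 expected chance
    # excursion beyond 3σ, but nothing beyond 5σ
    excursions = 0
    for row, p in zip(ids, probs):
        if p < 5e-4:
            continue
        obs = counts.get(tuple(row), 0) / n
        sigma = np.sqrt(p * (1 - p) / n)
        assert abs(obs - p) <= 5 * sigma + 1e-12
        if abs(obs - p) > 3 * sigma:
            excursions += 1
    assert excursions <= 2


def test_target_mask_semantics():
    # pads after the first end are padding; an emitted pad before the
    # end is a realized action; rows without end count in full
    targets = np.array([[3, 2, 0, 0], [0, 3, 2, 0], [3, 3, 3, 3]])
    m = target_mask(targets, end_id=2)
    assert m.tolist() == [
        [True, True, False, False],
        [True, True, True, False],
        [True, True, True, True],
    ]


def test_nll_gradients_match_finite_differences(tiny_vocab):
    gen = Generator(
        tiny_vocab, GenConfig(emb_size=3, hidden_size=4, n_layers=2, dropout=0.0, max_len=5)
    )
    ids = np.array([[1, 3, 4, 3, 2], [1, 4, 2, 0, 0]])
    _, grads = gen.weighted_nll_and_grads(ids)
    h = 1e-6
    rng = np.random.default_rng(0)
    for k, g in grads.items():
        flat = gen.params[k].reshape(-1)
        gf = g.reshape(-1)
        for i in rng.choice(flat.size, size=min(8, flat.size), replace=False):
            orig = flat[i]
            flat[i] = orig + h
            lp, _ = gen.weighted_nll_and_grads(ids)
            flat[i] = orig - h
            lm, _ = gen.weighted_nll_and_grads(ids)
            flat[i] = orig
            num = (lp - lm) / (2 * h)
            assert gf[i] == pytest.approx(num, rel=1e-4, abs=1e-8), k


def test_mle_step_contracts(tiny_vocab):
    gen = Generator(tiny_vocab, GenConfig(emb_size=4, hidden_size=6, max_len=6), seed=1)
    batch = [TokenSequence((1, 3, 4, 3, 2))] * 4
    before = {k: v.copy() for k, v in gen.params.items()}
    gen.mle_step(batch, lr=0.0)
    for k in before:
        assert np.array_equal(gen.params[k], before[k])
    # descent: repeated steps on one batch reduce its NLL
    losses = [gen.mle_step(batch, lr=0.01) for _ in range(10)]
    assert losses[-1] < losses[0]
    assert gen.mean_nll(batch) < losses[0]


def test_mle_overfit_single_sequence(tiny_vocab):
    """Training on one repeated sequence drives its per-token NLL
    toward zero within a few epochs."""
    gen = Generator(tiny_vocab, GenConfig(emb_size=8, hidden_size=16, n_layers=1, max_len=6), seed=2)
    seq = [TokenSequence((1, 3, 4, 3, 2))] * 8
    for _ in range(60):
        gen.mle_step(seq, lr=0.02)
    assert gen.mean_nll(seq) < 0.1


def test_mle_pretrain_early_stopping_and_grammar_separation(
    encoded, vocab_and_len, corpora
):
    vocab, max_len = vocab_and_len
    gen = Generator(
        vocab,
        GenConfig(emb_size=12, hidden_size=32, n_layers=1, dropout=0.0, max_len=max_len),
        seed=0,
        dtype=np.float32,
    )
    train, val = encoded["pretrain"][:320], encoded["pretrain"][320:]
    init_val = gen.mean_nll(val)
    hist = gen.mle_pretrain(
        train, GenTrainConfig(batch_size=64, learning_rate=2e-3, max_epochs=8), val, seed=1
    )
    assert hist["best_val_loss"] <= init_val
    assert gen.mean_nll(val) == pytest.approx(hist["best_val_loss"], rel=1e-5)
    # in-grammar strings become more likely than out-of-grammar ones
    in_lp = np.mean([gen.sequence_log_prob(s) for s in encoded["neg"][:40]])
    out_lp = np.mean([gen.sequence_log_prob(s) for s in encoded["pos"][:40]])
    assert in_lp > out_lp


def test_pretrain_requires_validation(tiny_vocab):
    gen = Generator(tiny_vocab, GenConfig(emb_size=4, hidden_size=5, max_len=6))
    with pytest.raises(ValueError):
        gen.mle_pretrain([TokenSequence((1, 3, 2))], GenTrainConfig(), [])


def test_checkpoint_roundtrip(tmp_path, toy_world):
    _, _, gen, _ = toy_world
    path = tmp_path / "gen.npz"
    gen.save(path)
    gen2 = Generator.load(path)
    seq = TokenSequence((1, 3, 4, 2))
    assert gen2.sequence_log_prob(seq) == gen.sequence_log_prob(seq)
    assert np.array_equal(
        gen2.sample(20, rng=np.random.default_rng(1)),
        gen.sample(20, rng=np.random.default_rng(1)),
    )
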