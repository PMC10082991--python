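import numpy as np
import pytest

from moltriage.adversarial import (
    AdvTrainConfig,
    RolloutConfig,
    adversarial_train,
    discriminator_loss_and_grads,
    discriminator_step,
    estimate_policy_gradient,
    history_to_csv,
    mc_rollout,
    policy_gradient_step,
    q_value,
)
from moltriage.discriminator import DiscConfig, Discriminator
from moltriage.fixtures import exact_policy_gradient, exact_q, make_toy_enumerable_world
from moltriage.generator import Generator
from moltriage.nn import Adam
from moltriage.tokenizer import SPECIALS, TokenSequence, TokenVocabulary


def _constant_half_disc(vocab, max_len):
    """Discriminator pinned at exactly 0.5 for every input."""
    disc = Discriminator(vocab, DiscConfig(emb_size=3, window_sizes=(1, 2), n_filters=2, max_len=max_len))
    disc.params["head_W"][:] = 0.0
    disc.params["head_b"] = np.zeros(())
    return disc


def _token_presence_disc(max_len):
    """Hand-built near-perfect classifier: probability ≈ 1 iff the
    sequence contains the token 'C' (id 3)."""
    vocab = TokenVocabulary(list(SPECIALS) + ["C", "O"])
    disc = Discriminator(vocab, DiscConfig(emb_size=1, window_sizes=(1,), n_filters=1, max_len=max_len))
    disc.params["emb"][:] = 0.0
    disc.params["emb"][3, 0] = 1.0
    disc.params["conv1_K"] = np.array([[50.0]])
    disc.params["conv1_b"] = np.array([0.0])
    disc.params["head_W"] = np.array([1.0])
    disc.params["head_b"] = np.asarray(-25.0)
    return disc


def test_mc_rollout_full_prefix_returns_copies(toy_world):
    _, max_len, gen, _ = toy_world
    prefix = TokenSequence((1, 3, 4, 3, 4))  # fills max_len
    outs = mc_rollout(prefix, gen, RolloutConfig(n_rollouts=5), seed=0)
    assert len(outs) == 5
    assert all(o.ids == prefix.ids for o in outs)
    # a prefix already ending in the end token is also complete
    done = TokenSequence((1, 3, 2))
    outs = mc_rollout(done, gen, RolloutConfig(n_rollouts=3), seed=0)
    assert all(o.ids[:3] == (1, 3, 2) for o in outs)


def test_mc_rollout_deterministic_policy(toy_world):
    vocab, max_len, gen, _ = make_toy_enumerable_world()
    gen.params["M"][:] = 0.0
    gen.params["c"][:] = 0.0
    gen.params["c"][3] = 1e3  # always emit 'C'
    outs = mc_rollout(TokenSequence((1, 4)), gen, RolloutConfig(n_rollouts=4), seed=1)
    assert len({o.ids for o in outs}) == 1
    assert outs[0].ids == (1, 4, 3, 3, 3)


def test_mc_rollout_keeps_prefix_and_seeds(toy_world):
    _, _, gen, _ = toy_world
    prefix = TokenSequence((1, 3))
    a = mc_rollout(prefix, gen, RolloutConfig(n_rollouts=8), seed=3)
    b = mc_rollout(prefix, gen, RolloutConfig(n_rollouts=8), seed=3)
    assert [o.ids for o in a] == [o.ids for o in b]
    assert all(o.ids[:2] == (1, 3) for o in a)


def test_q_value_terminal_is_exact(toy_world):
    _, max_len, gen, disc = toy_world
    prefix = TokenSequence((1, 3, 4))
    est = q_value(prefix, gen.vocab.end_id, gen, disc, RolloutConfig(n_rollouts=16), seed=0)
    full = np.zeros((1, max_len), dtype=np.int64)
    full[0, :4] = [1, 3, 4, 2]
    assert est.value == float(disc.predict(full)[0])  # bitwise
    assert est.n_rollouts == 0


def test_q_value_constant_disc(toy_world):
    vocab, max_len, gen, _ = toy_world
    disc = _constant_half_disc(vocab, max_len)
    for action in range(len(vocab)):
        est = q_value(TokenSequence((1, 3)), action, gen, disc, RolloutConfig(n_rollouts=8), seed=0)
        assert est.value == pytest.approx(0.5, abs=1e-12)
        assert 0.0 <= est.value <= 1.0


def test_q_value_matches_enumeration(toy_world):
    """MC action values agree with the exactly enumerated expectation
    within 3σ (moderate N; the N=10,000 sweep runs in acceptance)."""
    _, _, gen, disc = toy_world
    N = 2000
    for action in (0, 3, 4):
        mu, var = exact_q(gen, disc, [1, 3], action)
        est = q_value(TokenSequence((1, 3)), action, gen, disc, RolloutConfig(n_rollouts=N), seed=7)
        assert abs(est.value - mu) <= 3 * np.sqrt(var / N) + 1e-12


def test_policy_gradient_zero_lr_keeps_params(toy_world):
    _, _, gen, disc = toy_world
    before = {k: v.copy() for k, v in gen.params.items()}
    policy_gradient_step(
        gen, disc, AdvTrainConfig(gen_lr=0.0, gen_batch=8), RolloutConfig(n_rollouts=2),
        np.random.default_rng(0), Adam(lr=0.0),
    )
    for k in before:
        assert np.array_equal(gen.params[k], before[k])


def test_policy_gradient_direction_matches_enumeration(toy_world):
    """Mean REINFORCE estimate aligns with the exact enumerated ∇J
    (light version of the 5,000-draw acceptance check)."""
    _, _, gen, disc = toy_world
    exact = exact_policy_gradient(gen, disc)
    rng = np.random.default_rng(11)
    acc = None
    for _ in range(4):
        grads, _ = estimate_policy_gradient(gen, disc, 250, RolloutConfig(n_rollouts=8), rng)
        acc = grads if acc is None else {k: acc[k] + grads[k] for k in acc}
    a = np.concatenate([(-acc[k]).ravel() for k in sorted(acc)])
    b = np.concatenate([exact[k].ravel() for k in sorted(exact)])
    assert a @ b / (np.linalg.norm(a) * np.linalg.norm(b)) >= 0.9


def test_discriminator_loss_closed_forms(toy_world):
    vocab, max_len, gen, _ = toy_world
    real = np.array([[1, 3, 3, 2, 0], [1, 3, 4, 3, 2]])  # contain 'C'
    fake = np.array([[1, 4, 4, 2, 0], [1, 4, 2, 0, 0]])  # only 'O'
    half = _constant_half_disc(vocab, max_len)
    loss, _ = discriminator_loss_and_grads(half, real, fake)
    assert loss == pytest.approx(2 * np.log(2), abs=1e-9)
    perfect = _token_presence_disc(max_len)
    loss, _ = discriminator_loss_and_grads(perfect, real, fake)
    assert loss <= 1e-6


def test_discriminator_step_descends(toy_world):
    vocab, max_len, gen, disc_fixed = toy_world
    disc = Discriminator(vocab, DiscConfig(emb_size=4, window_sizes=(1, 2), n_filters=3, max_len=max_len), seed=9)
    real = np.array([[1, 3, 3, 2, 0]] * 8)
    fake = np.array([[1, 4, 4, 2, 0]] * 8)
    l0, _ = discriminator_loss_and_grads(disc, real, fake)
    discriminator_step(disc, fake, real, lr=0.05)
    l1, _ = discriminator_loss_and_grads(disc, real, fake)
    assert l1 < l0


def test_adversarial_zero_steps_is_noop(toy_world):
    vocab, max_len, gen, disc = make_toy_enumerable_world()
    g0 = {k: v.copy() for k, v in gen.params.items()}
    d0 = {k: np.copy(v) for k, v in disc.params.items()}
    real = np.array([[1, 3, 3, 2, 0]] * 10)
    gen, disc, history = adversarial_train(
        gen, disc, real, AdvTrainConfig(max_steps=0), RolloutConfig(n_rollouts=2), seed=0
    )
    assert history["step"] == []
    for k in g0:
        assert np.array_equal(gen.params[k], g0[k])
    for k in d0:
        assert np.array_equal(disc.params[k], d0[k])


def test_adversarial_history_and_checkpoints(tmp_path, toy_world):
    vocab, max_len, gen, disc = make_toy_enumerable_world()
    real = np.array([[1, 3, 3, 2, 0], [1, 3, 4, 3, 2]] * 5)
    out = tmp_path / "run"
    gen, disc, history = adversarial_train(
        gen, disc, real,
        AdvTrainConfig(max_steps=6, gen_batch=8, disc_batch=8, burn_in=10**9, window=3),
        RolloutConfig(n_rollouts=2), seed=5, out_dir=str(out),
    )
    assert len(history["step"]) == 6
    assert all(len(history[k]) == 6 for k in history)
    assert all(0.0 <= q <= 1.0 for q in history["mean_q"])
    from moltriage.discriminator import Discriminator as D
    from moltriage.generator import Generator as G
    g2 = G.load(out / "gen_step6.npz")
    d2 = D.load(out / "disc_step6.npz")
    ids = np.array([[1, 3, 4, 2, 0]])
    assert d2.predict(ids)[0] == disc.predict(ids)[0]
    assert g2.sequence_log_prob(TokenSequence((1, 3, 2))) == gen.sequence_log_prob(
        TokenSequence((1, 3, 2))
    )
    path = tmp_path / "h.csv"
    history_to_csv(history, path)
    lines = path.read_text().splitlines()
    assert lines[0].startswith("step,") and len(lines) == 7


def test_disc_batch_must_be_even():
    with pytest.raises(ValueError):
        AdvTrainConfig(disc_batch=63)
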