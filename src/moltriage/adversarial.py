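"""Adversarial training of the SMILES policy against the discriminator.

The generator is treated as a reinforcement-learning agent whose reward
for a finished sequence W_{1:T} is the discriminator probability
D_φ(W_{1:T}).  The action value of an intermediate token choice,

    Q(W_{1:t}, a) = mean over N Monte-Carlo rollouts of D_φ(completion),

uses the policy itself to complete the prefix; at the final step the
reward needs no rollout and is D_φ of the finished sequence exactly.
The policy ascends the REINFORCE estimate of ∇J (score function ×
action value, averaged over batch and steps) with Adam; the
discriminator descends  −E_real[log D] − E_fake[log(1−D)]  on balanced
real/fake batches.  Progressive augmentation interleaves one
maximum-likelihood step on real (drug-like) samples after every policy
update, steadily pulling the "fake" pool toward harder negatives.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import nn
from .discriminator import Discriminator
from .generator import Generator, _as_array, target_mask
from .tokenizer import TokenSequence

__all__ = [
    "RolloutConfig",
    "QEstimate",
    "AdvTrainConfig",
    "mc_rollout",
    "q_value",
    "estimate_policy_gradient",
    "policy_gradient_step",
    "discriminator_loss_and_grads",
    "discriminator_step",
    "adversarial_train",
    "history_to_csv",
]


@dataclass
class RolloutConfig:
    n_rollouts: int = 16
    max_len: Optional[int] = None  # defaults to the policy's max_len

    def __post_init__(self):
        if self.n_rollouts < 1:
            raise ValueError("need at least one rollout")

    def resolve_len(self, policy: Generator) -> int:
        return self.max_len or policy.config.max_len


@dataclass(frozen=True)
class QEstimate:
    prefix: TokenSequence
    action: int
    value: float
    n_rollouts: int


@dataclass
class AdvTrainConfig:
    gen_lr: float = 1e-4
    disc_lr: float = 1e-4
    mle_lr: Optional[float] = None  # progressive-augmentation rate; defaults to gen_lr
    gen_batch: int = 64
    disc_batch: int = 128  # 64 fake + 64 real
    max_steps: int = 1000
    burn_in: int = 100  # steps before early-stop monitoring ("stabilization")
    window: int = 20  # epoch-sized smoothing window for the disc loss
    stop_patience: int = 1  # windows without improvement before stopping

    def __post_init__(self):
        if self.disc_batch % 2 != 0:
            raise ValueError("disc_batch must split 50/50 into real and fake")


# ---------------------------------------------------------------------- #
# rollouts and action values
# ---------------------------------------------------------------------- #


def _strip_pads(prefix: TokenSequence, pad_id: int) -> np.ndarray:
    ids = np.asarray(prefix.ids, dtype=np.int64)
    keep = np.nonzero(ids != pad_id)[0]
    return ids[: keep[-1] + 1] if len(keep) else ids[:0]


def _prefix_hidden(policy: Generator, prefix_ids: np.ndarray, n: int):
    """Hidden state after teacher-forcing a prefix, replicated n times."""
    hidden = policy.init_hidden(1)
    for tok in prefix_ids:
        hidden, _ = policy.step(hidden, np.array([tok]))
    return [[np.repeat(h, n, axis=0), np.repeat(c, n, axis=0)] for h, c in hidden]


def _rollout_ids(
    policy: Generator, ids: np.ndarray, n: int, max_len: int, rng
) -> np.ndarray:
    """N policy completions of an explicit (unpadded) id prefix."""
    if len(ids) >= max_len or (len(ids) and ids[-1] == policy.vocab.end_id):
        full = np.zeros((n, max_len), dtype=np.int64)
        full[:, : len(ids)] = ids
        return full
    hidden = _prefix_hidden(policy, ids, n)
    prefix_rep = np.repeat(ids[None, :], n, axis=0)
    return policy.sample(
        n, max_len=max_len, rng=rng, hidden=hidden, prefix_ids=prefix_rep
    )


def mc_rollout(
    prefix: TokenSequence,
    policy: Generator,
    cfg: RolloutConfig,
    seed: int = 0,
) -> list[TokenSequence]:
    """N Monte-Carlo completions of a prefix under the current policy.

    The prefix tokens are kept fixed; the remainder is sampled
    ancestrally.  A prefix that is already complete (ends in the end
    token or fills max_len) is returned N times unchanged.
    """
    max_len = cfg.resolve_len(policy)
    ids = _strip_pads(prefix, policy.vocab.pad_id)
    rng = np.random.default_rng(seed)
    out = _rollout_ids(policy, ids, cfg.n_rollouts, max_len, rng)
    return policy.to_sequences(out)


def q_value(
    prefix: TokenSequence,
    action: int,
    policy: Generator,
    disc: Discriminator,
    cfg: RolloutConfig,
    seed: int = 0,
) -> QEstimate:
    """Action value Q(W_{1:t}, a).

    For a terminal action (end token, or the prefix+action filling
    max_len) the value is D_φ of the completed sequence exactly — no
    rollout and no Monte-Carlo error.  Otherwise it is the mean
    discriminator score of ``cfg.n_rollouts`` policy completions.
    """
    max_len = cfg.resolve_len(policy)
    ids = _strip_pads(prefix, policy.vocab.pad_id)
    extended = np.concatenate([ids, [action]]).astype(np.int64)
    terminal = action == policy.vocab.end_id or len(extended) >= max_len
    if terminal:
        full = np.zeros((1, max_len), dtype=np.int64)
        full[0, : len(extended)] = extended
        value = float(disc.predict(full)[0])
        return QEstimate(prefix, action, value, 0)
    rng = np.random.default_rng(seed)
    completions = _rollout_ids(policy, extended, cfg.n_rollouts, max_len, rng)
    scores = disc.predict(completions)
    return QEstimate(prefix, action, float(scores.mean()), cfg.n_rollouts)


def _q_matrix(
    policy: Generator,
    disc: Discriminator,
    ids: np.ndarray,
    states: list,
    cfg: RolloutConfig,
    rng: np.random.Generator,
):
    """Action values for every realized (prefix, action) of a sampled
    batch, reusing the hidden states cached during sampling.

    ``states[j]`` is the hidden state after consuming position ``j``.
    Returns (q, mask, d_full): q aligned with the shifted targets
    ids[:, 1:], and d_full the terminal discriminator scores.
    """
    B, L = ids.shape
    end = policy.vocab.end_id
    N = cfg.n_rollouts
    q = np.zeros((B, L - 1), dtype=policy.dtype)
    mask = target_mask(ids[:, 1:], end)
    d_full = disc.predict(ids)
    # terminal actions (end token or the last possible position) take
    # the exact discriminator score of the finished sequence
    terminal = mask & ((ids[:, 1:] == end) | (np.arange(1, L)[None, :] == L - 1))
    q[terminal] = np.broadcast_to(d_full[:, None], terminal.shape)[terminal]

    pending: list[tuple[int, np.ndarray]] = []
    batches = []
    for t in range(L - 2):
        rows = np.nonzero(mask[:, t] & ~terminal[:, t])[0]
        if len(rows) == 0:
            continue
        hidden = [
            [np.repeat(h[rows], N, axis=0), np.repeat(c[rows], N, axis=0)]
            for h, c in states[t + 1]
        ]
        prefix = np.zeros((len(rows) * N, L), dtype=np.int64)
        prefix[:, : t + 2] = np.repeat(ids[rows, : t + 2], N, axis=0)
        comp = policy.sample(
            len(rows) * N,
            max_len=L,
            rng=rng,
            hidden=hidden,
            prefix_ids=prefix[:, : t + 2],
        )
        pending.append((t, rows))
        batches.append(comp)
    if batches:
        scores = disc.predict(np.concatenate(batches))
        offset = 0
        for (t, rows), comp in zip(pending, batches):
            s = scores[offset : offset + len(comp)].reshape(len(rows), N)
            q[rows, t] = s.mean(axis=1)
            offset += len(comp)
    return q, mask, d_full


# ---------------------------------------------------------------------- #
# policy gradient
# ---------------------------------------------------------------------- #


def estimate_policy_gradient(
    policy: Generator,
    disc: Discriminator,
    n_sequences: int,
    cfg: RolloutConfig,
    rng: np.random.Generator,
):
    """REINFORCE estimate over a freshly sampled batch.

    Returns (grads, diagnostics) where ``grads`` is the gradient of the
    surrogate loss  −(1/(B·T_max)) Σ_{b,t} Q·log G_θ(a|s) , i.e. the
    *descent* direction on −J.  Normalization uses the constant T_max so
    the estimator stays exactly proportional to ∇J for variable-length
    sequences.
    """
    max_len = cfg.resolve_len(policy)
    ids, states = policy.sample(
        n_sequences, max_len=max_len, rng=rng, keep_states=True
    )
    q, mask, d_full = _q_matrix(policy, disc, ids, states, cfg, rng)
    weights = q * mask / (n_sequences * max_len)
    loss, grads = policy.weighted_nll_and_grads(ids, weights=weights)
    diag = {
        "mean_reward": float(d_full.mean()),
        "mean_q": float(q[mask].mean()) if mask.any() else 0.0,
        "surrogate_loss": loss,
        "mean_length": float(mask.sum(axis=1).mean()),
    }
    return grads, diag


def policy_gradient_step(
    policy: Generator,
    disc: Discriminator,
    cfg: "AdvTrainConfig",
    rollout_cfg: RolloutConfig,
    rng: np.random.Generator,
    optimizer: Optional[nn.Adam] = None,
) -> dict:
    """One REINFORCE ascent step on the policy; returns diagnostics."""
    if optimizer is None:
        optimizer = nn.Adam(lr=cfg.gen_lr)
    grads, diag = estimate_policy_gradient(
        policy, disc, cfg.gen_batch, rollout_cfg, rng
    )
    nn.clip_grads(grads, policy.config.grad_clip)
    optimizer.step(policy.params, grads)
    return diag


# ---------------------------------------------------------------------- #
# discriminator update
# ---------------------------------------------------------------------- #


def discriminator_loss_and_grads(
    disc: Discriminator, real_ids: np.ndarray, fake_ids: np.ndarray
):
    """Loss  −E_real[log D] − E_fake[log(1−D)]  and its φ-gradient.

    A discriminator stuck at 0.5 scores 2·log 2; a perfect one scores 0.
    """
    loss_r, grads_r = disc.loss_and_grads(real_ids, np.ones(len(real_ids)))
    loss_f, grads_f = disc.loss_and_grads(fake_ids, np.zeros(len(fake_ids)))
    grads = {k: grads_r[k] + grads_f[k] for k in grads_r}
    return loss_r + loss_f, grads


def discriminator_step(
    disc: Discriminator,
    fake_batch,
    real_batch,
    lr: float = 1e-4,
    optimizer: Optional[nn.Adam] = None,
) -> float:
    """One Adam step on the adversarial discriminator objective."""
    if optimizer is None:
        optimizer = nn.Adam(lr=lr)
    real_ids = _as_array(real_batch, disc.config.max_len)
    fake_ids = _as_array(fake_batch, disc.config.max_len)
    loss, grads = discriminator_loss_and_grads(disc, real_ids, fake_ids)
    nn.clip_grads(grads, disc.config.grad_clip)
    optimizer.step(disc.params, grads)
    return loss


# ---------------------------------------------------------------------- #
# the alternating loop
# ---------------------------------------------------------------------- #


def adversarial_train(
    gen: Generator,
    disc: Discriminator,
    real_pool,
    cfg: AdvTrainConfig,
    rollout_cfg: RolloutConfig,
    seed: int = 0,
    out_dir: Optional[str] = None,
    verbose: bool = False,
):
    """Alternate policy-gradient, progressive-augmentation and
    discriminator updates.

    Each step: (1) REINFORCE update of the generator on ``gen_batch``
    sampled sequences; (2) one MLE fine-tune step on ``disc_batch/2``
    real samples (progressive augmentation); (3) one discriminator step
    on a balanced fresh-fake/real batch.  Training stops early when the
    window-smoothed discriminator loss stops decreasing after the
    burn-in, or at ``max_steps``.  Returns (gen, disc, history).
    """
    rng = np.random.default_rng(seed)
    real_ids = _as_array(real_pool, gen.config.max_len)
    half = cfg.disc_batch // 2
    gen_opt = nn.Adam(lr=cfg.gen_lr)
    mle_opt = nn.Adam(lr=cfg.mle_lr if cfg.mle_lr is not None else cfg.gen_lr)
    disc_opt = nn.Adam(lr=cfg.disc_lr)
    history = {
        "step": [],
        "gen_reward": [],
        "mean_q": [],
        "mle_loss": [],
        "disc_loss": [],
    }
    best_smoothed = np.inf
    bad_windows = 0
    for step in range(cfg.max_steps):
        diag = policy_gradient_step(gen, disc, cfg, rollout_cfg, rng, gen_opt)
        aug = real_ids[rng.integers(0, len(real_ids), half)]
        mle_loss = gen.mle_step(aug, optimizer=mle_opt)
        fake = gen.sample(half, max_len=gen.config.max_len, rng=rng)
        real = real_ids[rng.integers(0, len(real_ids), half)]
        disc_loss = discriminator_step(disc, fake, real, optimizer=disc_opt)
        history["step"].append(step)
        history["gen_reward"].append(diag["mean_reward"])
        history["mean_q"].append(diag["mean_q"])
        history["mle_loss"].append(mle_loss)
        history["disc_loss"].append(disc_loss)
        if verbose and step % 10 == 0:
            print(
                f"step {step}: reward {diag['mean_reward']:.4f} "
                f"disc loss {disc_loss:.4f}"
            )
        if out_dir and (step + 1) % cfg.window == 0:
            os.makedirs(out_dir, exist_ok=True)
            gen.save(os.path.join(out_dir, f"gen_step{step + 1}.npz"))
            disc.save(os.path.join(out_dir, f"disc_step{step + 1}.npz"))
        # early stopping on the smoothed discriminator loss, monitored
        # only after the burn-in ("stabilization") period
        if step + 1 >= cfg.burn_in and (step + 1) % cfg.window == 0:
            smoothed = float(np.mean(history["disc_loss"][-cfg.window :]))
            if smoothed < best_smoothed:
                best_smoothed = smoothed
                bad_windows = 0
            else:
                bad_windows += 1
                if bad_windows >= cfg.stop_patience:
                    break
    return gen, disc, history


def history_to_csv(history: dict, path) -> None:
    """Write the training history as CSV (step, gen_reward, mean_q,
    mle_loss, disc_loss) with full float precision."""
    keys = ["step", "gen_reward", "mean_q", "mle_loss", "disc_loss"]
    with open(path, "w") as fh:
        fh.write(",".join(keys) + "\n")
        for i in range(len(history["step"])):
            row = [history[k][i] for k in keys]
            fh.write(
                ",".join(
                    str(v) if isinstance(v, int) else repr(float(v)) for v in row
                )
                + "\n"
            )
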