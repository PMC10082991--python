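"""Autoregressive SMILES policy.

The generator is a token-level language model: an embedding table, a
stack of LSTM layers (three by default) implementing the recurrent state
update h_t = f(h_{t-1}, x_t), and a linear+softmax output head giving
p(w_{t+1} | w_1..w_t).  Generation is ancestral sampling from the start
token until the end token (or the length cap); the same machinery
doubles as the policy of the adversarial loop, where per-step
distributions and hidden states are needed for Monte-Carlo rollouts.

Training is maximum likelihood (mean negative log-likelihood per
non-pad token) with Adam and patience-based early stopping on a
validation split.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

from . import nn
from .tokenizer import TokenSequence, TokenVocabulary

__all__ = ["GenConfig", "GenTrainConfig", "Generator"]


@dataclass
class GenConfig:
    """Architecture of the policy network.

    Sizes are desk-scale defaults, not normative: the contracts
    (normalized per-step distributions, exact likelihoods, seeded
    sampling) hold at any width.
    """

    emb_size: int = 128
    hidden_size: int = 512
    n_layers: int = 3
    dropout: float = 0.1
    max_len: int = 100
    grad_clip: float = 5.0


@dataclass
class GenTrainConfig:
    batch_size: int = 512
    learning_rate: float = 1e-4
    patience: int = 1
    max_epochs: int = 100

    def __post_init__(self):
        if self.batch_size <= 0 or self.learning_rate < 0 or self.patience < 1:
            raise ValueError("invalid training configuration")


def target_mask(targets: np.ndarray, end_id: int) -> np.ndarray:
    """Boolean mask of realized emissions among shifted targets.

    Positions up to and including the first end token count (the policy
    may emit any vocabulary token, pad included, before terminating);
    only positions after termination are padding.  A row without an end
    token is a truncated sequence and counts in full.
    """
    is_end = targets == end_id
    return (np.cumsum(is_end, axis=1) - is_end) == 0


def _as_array(seqs, max_len: int) -> np.ndarray:
    """Stack TokenSequences (or id tuples) into a (B, max_len) int array."""
    if isinstance(seqs, np.ndarray):
        return seqs
    out = np.zeros((len(seqs), max_len), dtype=np.int64)
    for i, s in enumerate(seqs):
        ids = s.ids if isinstance(s, TokenSequence) else tuple(s)
        if len(ids) > max_len:
            raise ValueError("sequence longer than max_len")
        out[i, : len(ids)] = ids
    return out


class Generator:
    """θ-parameterized SMILES policy G_θ."""

    def __init__(
        self,
        vocab: TokenVocabulary,
        config: Optional[GenConfig] = None,
        seed: int = 0,
        dtype=np.float64,
    ):
        self.vocab = vocab
        self.config = config or GenConfig()
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        V, e, H = len(vocab), self.config.emb_size, self.config.hidden_size
        params = {"emb": (rng.standard_normal((V, e)) * 0.1).astype(self.dtype)}
        d_in = e
        for i in range(self.config.n_layers):
            layer = nn.init_lstm_params(d_in, H, rng, self.dtype)
            for k, v in layer.items():
                params[f"lstm{i}_{k}"] = v
            d_in = H
        sm = np.sqrt(6.0 / (H + V))
        params["M"] = rng.uniform(-sm, sm, (H, V)).astype(self.dtype)
        params["c"] = np.zeros(V, dtype=self.dtype)
        self.params = params
        self._mle_opt: Optional[nn.Adam] = None

    # ------------------------------------------------------------------ #
    # forward passes
    # ------------------------------------------------------------------ #

    def _layer_params(self, i: int) -> dict:
        return {
            "W": self.params[f"lstm{i}_W"],
            "U": self.params[f"lstm{i}_U"],
            "b": self.params[f"lstm{i}_b"],
        }

    def _forward_hidden(self, ids_in: np.ndarray, train: bool, rng=None):
        """Top-layer hidden states for teacher-forced input (B, L)."""
        x = self.params["emb"][ids_in]
        caches = []
        masks = []
        p = self.config.dropout if train else 0.0
        for i in range(self.config.n_layers):
            hs, _, cache = nn.lstm_forward(x, self._layer_params(i))
            if p > 0:
                mask = (rng.random(hs.shape) >= p).astype(self.dtype) / (1 - p)
                hs = hs * mask
            else:
                mask = None
            caches.append(cache)
            masks.append(mask)
            x = hs
        return x, caches, masks

    def init_hidden(self, batch: int):
        H = self.config.hidden_size
        return [
            [np.zeros((batch, H), dtype=self.dtype), np.zeros((batch, H), dtype=self.dtype)]
            for _ in range(self.config.n_layers)
        ]

    def step(self, hidden, token_ids: np.ndarray):
        """One decoding step: feed ``token_ids`` (B,), return the updated
        hidden state and the next-token distribution (B, |V|)."""
        x = self.params["emb"][token_ids]
        new_hidden = []
        for i in range(self.config.n_layers):
            p = self._layer_params(i)
            h, c, _ = nn.lstm_step(x, hidden[i][0], hidden[i][1], p["W"], p["U"], p["b"])
            new_hidden.append([h, c])
            x = h
        logits = x @ self.params["M"] + self.params["c"]
        return new_hidden, nn.softmax(logits)

    # ------------------------------------------------------------------ #
    # likelihood and gradients
    # ------------------------------------------------------------------ #

    def weighted_nll_and_grads(
        self,
        ids: np.ndarray,
        weights: Optional[np.ndarray] = None,
        train: bool = False,
        rng=None,
    ):
        """Loss Σ w_{b,t} · (−log p(target_{b,t})) and its θ-gradient.

        ``weights`` has shape (B, L−1) aligned with the shifted targets
        and must already include any normalization and masking; when
        None, the mean NLL per non-pad token is used (the MLE loss).
        """
        ids_in, targets = ids[:, :-1], ids[:, 1:]
        mask = target_mask(targets, self.vocab.end_id).astype(self.dtype)
        if weights is None:
            weights = mask / max(mask.sum(), 1.0)
        else:
            weights = weights * mask
        hs, caches, masks = self._forward_hidden(ids_in, train, rng)
        logits = hs @ self.params["M"] + self.params["c"]
        probs = nn.softmax(logits)
        B, Lm1 = targets.shape
        bi, ti = np.meshgrid(np.arange(B), np.arange(Lm1), indexing="ij")
        logp = np.log(np.maximum(probs[bi, ti, targets], 1e-300))
        loss = float(-(weights * logp).sum())

        dlogits = probs * weights[:, :, None]
        dlogits[bi, ti, targets] -= weights
        grads = {
            "M": np.einsum("blh,blv->hv", hs, dlogits),
            "c": dlogits.sum(axis=(0, 1)),
        }
        dhs = dlogits @ self.params["M"].T
        demb = np.zeros_like(self.params["emb"])
        for i in range(self.config.n_layers - 1, -1, -1):
            if masks[i] is not None:
                dhs = dhs * masks[i]
            dx, g = nn.lstm_backward(dhs, caches[i], self._layer_params(i))
            for k, v in g.items():
                grads[f"lstm{i}_{k}"] = v
            dhs = dx
        np.add.at(demb, ids_in, dhs)
        grads["emb"] = demb
        return loss, grads

    def mean_nll(self, seqs) -> float:
        """Mean negative log-likelihood per non-pad token."""
        ids = _as_array(seqs, self.config.max_len)
        ids_in, targets = ids[:, :-1], ids[:, 1:]
        mask = target_mask(targets, self.vocab.end_id)
        hs, _, _ = self._forward_hidden(ids_in, train=False)
        probs = nn.softmax(hs @ self.params["M"] + self.params["c"])
        B, Lm1 = targets.shape
        bi, ti = np.meshgrid(np.arange(B), np.arange(Lm1), indexing="ij")
        logp = np.log(np.maximum(probs[bi, ti, targets], 1e-300))
        return float(-(logp * mask).sum() / max(mask.sum(), 1))

    def sequence_log_prob(self, seq) -> float:
        """log G_θ(W) summed over body tokens and the end token; pads
        contribute nothing, so the value is padding-invariant."""
        ids = _as_array([seq], self.config.max_len)
        targets = ids[:, 1:]
        mask = target_mask(targets, self.vocab.end_id)
        hs, _, _ = self._forward_hidden(ids[:, :-1], train=False)
        probs = nn.softmax(hs @ self.params["M"] + self.params["c"])
        logp = np.log(np.maximum(probs[0, np.arange(targets.shape[1]), targets[0]], 1e-300))
        return float((logp * mask[0]).sum())

    # ------------------------------------------------------------------ #
    # sampling
    # ------------------------------------------------------------------ #

    @staticmethod
    def _categorical(probs: np.ndarray, u: np.ndarray) -> np.ndarray:
        cdf = np.cumsum(probs, axis=1)
        return np.minimum((cdf < u[:, None]).sum(axis=1), probs.shape[1] - 1)

    def sample(
        self,
        n: int,
        max_len: Optional[int] = None,
        rng: Optional[np.random.Generator] = None,
        keep_states: bool = False,
        hidden=None,
        prefix_ids: Optional[np.ndarray] = None,
    ):
        """Ancestral sampling of ``n`` sequences.

        Each row is [start, tokens.., end, pad..]; a sequence that never
        emits end truncates at ``max_len``.  With ``keep_states`` the
        per-position hidden states are returned for rollout restarts.
        When ``hidden``/``prefix_ids`` are given, sampling continues the
        provided prefixes instead of starting fresh.
        """
        max_len = max_len or self.config.max_len
        if rng is None:
            rng = np.random.default_rng(0)
        ids = np.zeros((n, max_len), dtype=np.int64)
        if n == 0:
            return (ids, []) if keep_states else ids
        if prefix_ids is None:
            ids[:, 0] = self.vocab.start_id
            pos0 = 1
            hidden = self.init_hidden(n)
            last = ids[:, 0]
        else:
            pl = prefix_ids.shape[1]
            ids[:, :pl] = prefix_ids
            pos0 = pl
            last = ids[:, pl - 1]
        alive = np.ones(n, dtype=bool)
        if prefix_ids is not None:
            alive &= last != self.vocab.end_id
        states = []
        for pos in range(pos0, max_len):
            hidden, probs = self.step(hidden, last)
            if keep_states:
                states.append([[h.copy(), c.copy()] for h, c in hidden])
            u = rng.random(n)
            tok = self._categorical(probs, u)
            tok = np.where(alive, tok, self.vocab.pad_id)
            ids[:, pos] = tok
            alive = alive & (tok != self.vocab.end_id)
            last = ids[:, pos]
            if not alive.any() and not keep_states:
                break
        return (ids, states) if keep_states else ids

    def to_sequences(self, ids: np.ndarray) -> list[TokenSequence]:
        return [TokenSequence(tuple(int(t) for t in row)) for row in ids]

    # ------------------------------------------------------------------ #
    # training
    # ------------------------------------------------------------------ #

    def mle_step(self, batch, lr: Optional[float] = None, optimizer: Optional[nn.Adam] = None):
        """One Adam step on the batch's mean NLL (used standalone and as
        the progressive-augmentation fine-tune inside the adversarial
        loop).  Returns the pre-step loss."""
        if optimizer is None:
            if self._mle_opt is None or (lr is not None and self._mle_opt.lr != lr):
                self._mle_opt = nn.Adam(lr=lr if lr is not None else 1e-4)
            optimizer = self._mle_opt
        ids = _as_array(batch, self.config.max_len)
        loss, grads = self.weighted_nll_and_grads(ids)
        nn.clip_grads(grads, self.config.grad_clip)
        optimizer.step(self.params, grads)
        return loss

    def mle_pretrain(
        self,
        corpus,
        cfg: GenTrainConfig,
        validation,
        seed: int = 0,
        verbose: bool = False,
    ) -> dict:
        """Maximum-likelihood pretraining with early stopping.

        Stops when the validation mean loss has not decreased for
        ``cfg.patience`` consecutive epochs and restores the
        best-validation parameters.  Returns the training history.
        """
        if validation is None or len(validation) == 0:
            raise ValueError("a non-empty validation set is required")
        ids = _as_array(corpus, self.config.max_len)
        val = _as_array(validation, self.config.max_len)
        rng = np.random.default_rng(seed)
        opt = nn.Adam(lr=cfg.learning_rate)
        best_val = self.mean_nll(val)
        best_params = copy.deepcopy(self.params)
        history = {"train_loss": [], "val_loss": [best_val]}
        bad_epochs = 0
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(len(ids))
            epoch_losses = []
            for s in range(0, len(ids), cfg.batch_size):
                batch = ids[order[s : s + cfg.batch_size]]
                loss, grads = self.weighted_nll_and_grads(
                    batch, train=self.config.dropout > 0, rng=rng
                )
                nn.clip_grads(grads, self.config.grad_clip)
                opt.step(self.params, grads)
                epoch_losses.append(loss)
            val_loss = self.mean_nll(val)
            history["train_loss"].append(float(np.mean(epoch_losses)))
            history["val_loss"].append(val_loss)
            if verbose:
                print(f"epoch {epoch}: train {history['train_loss'][-1]:.4f} val {val_loss:.4f}")
            if val_loss < best_val:
                best_val = val_loss
                best_params = copy.deepcopy(self.params)
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs >= cfg.patience:
                    break
        self.params = best_params
        history["best_val_loss"] = best_val
        return history

    # ------------------------------------------------------------------ #
    # persistence
    # ------------------------------------------------------------------ #

    def save(self, path) -> None:
        meta = json.dumps(
            {"config": asdict(self.config), "vocab": list(self.vocab.tokens),
             "dtype": self.dtype.name}
        )
        np.savez(path, __meta__=np.array(meta), **self.params)

    @classmethod
    def load(cls, path) -> "Generator":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["__meta__"]))
        vocab = TokenVocabulary(meta["vocab"])
        gen = cls(vocab, GenConfig(**meta["config"]), dtype=np.dtype(meta["dtype"]))
        gen.params = {k: data[k] for k in data.files if k != "__meta__"}
        return gen
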