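"""Convolutional discriminator over token sequences.

A sequence is embedded into a T×k matrix; a bank of kernels with
window sizes l (one kernel matrix ω ∈ R^{l×k} per filter) slides over
it producing feature maps c_i = ρ(ω ⊗ ε_{i:i+l-1} + b); each map is
max-pooled, the pooled features are concatenated across window sizes,
and a linear head with logistic squashing outputs the probability that
the molecule belongs to the positive (drug/bioactive-like) set.

Windows that overlap trailing padding are excluded from pooling, so the
score is invariant to how far a sequence is padded.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from . import nn
from .tokenizer import TokenSequence, TokenVocabulary

__all__ = ["DiscConfig", "DiscTrainConfig", "Discriminator"]

_NEG = -1e30  # pool sentinel for invalid windows


@dataclass
class DiscConfig:
    emb_size: int = 128
    window_sizes: tuple = tuple(range(1, 11))
    n_filters: int = 100
    max_len: int = 100
    grad_clip: float = 5.0

    def __post_init__(self):
        # concatenation order is fixed by sorting, so permuting the
        # configured windows cannot change the model
        self.window_sizes = tuple(sorted(set(self.window_sizes)))
        if max(self.window_sizes) > self.max_len:
            raise ValueError("window size exceeds max sequence length")


@dataclass
class DiscTrainConfig:
    batch_size: int = 128
    learning_rate: float = 1e-4
    split: tuple = (0.8, 0.1, 0.1)
    patience: int = 1
    max_epochs: int = 100

    def __post_init__(self):
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def _as_array(seqs, max_len: int) -> np.ndarray:
    if isinstance(seqs, np.ndarray):
        return seqs
    out = np.zeros((len(seqs), max_len), dtype=np.int64)
    for i, s in enumerate(seqs):
        ids = s.ids if isinstance(s, TokenSequence) else tuple(s)
        out[i, : len(ids)] = ids
    return out


class Discriminator:
    """φ-parameterized classifier D_φ mapping token sequences to (0,1)."""

    def __init__(
        self,
        vocab: TokenVocabulary,
        config: Optional[DiscConfig] = None,
        seed: int = 0,
        dtype=np.float64,
    ):
        self.vocab = vocab
        self.config = config or DiscConfig()
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        V, k, F = len(vocab), self.config.emb_size, self.config.n_filters
        params = {"emb": (rng.standard_normal((V, k)) * 0.1).astype(self.dtype)}
        for l in self.config.window_sizes:
            s = np.sqrt(6.0 / (l * k + F))
            params[f"conv{l}_K"] = rng.uniform(-s, s, (l * k, F)).astype(self.dtype)
            params[f"conv{l}_b"] = np.zeros(F, dtype=self.dtype)
        n_feat = F * len(self.config.window_sizes)
        sh = np.sqrt(6.0 / (n_feat + 1))
        params["head_W"] = rng.uniform(-sh, sh, n_feat).astype(self.dtype)
        params["head_b"] = np.zeros((), dtype=self.dtype)
        self.params = params

    # ------------------------------------------------------------------ #

    def embed(self, seq) -> np.ndarray:
        """T×k embedding matrix of one sequence (row t = embedding of w_t)."""
        ids = np.asarray(seq.ids if isinstance(seq, TokenSequence) else seq)
        return self.params["emb"][ids]

    def feature_maps(self, matrix: np.ndarray, window: int) -> np.ndarray:
        """Feature maps c_i for one window size on a T×k matrix; length
        T−l+1 per filter (no pad masking: caller controls the matrix)."""
        T = matrix.shape[0]
        if window > T:
            raise ValueError(f"window {window} exceeds sequence length {T}")
        K = self.params[f"conv{window}_K"]
        b = self.params[f"conv{window}_b"]
        cols = np.stack(
            [matrix[i : i + window].reshape(-1) for i in range(T - window + 1)]
        )
        return np.maximum(cols @ K + b, 0.0)

    # ------------------------------------------------------------------ #

    def _forward(self, ids: np.ndarray):
        lengths = (ids != self.vocab.pad_id).sum(axis=1)
        # shared trailing padding carries no signal; trim it up front
        T_eff = max(int(lengths.max()), min(self.config.window_sizes))
        ids = ids[:, :T_eff]
        B, T = ids.shape
        X = self.params["emb"][ids]
        feats = []
        cache_w = []
        for l in self.config.window_sizes:
            P = T - l + 1
            if P <= 0:
                feats.append(np.zeros((B, self.config.n_filters), dtype=self.dtype))
                cache_w.append(None)
                continue
            # convolution as a sum of per-offset matmuls on views of X
            # (equivalent to an im2col product, without the big copy)
            k = X.shape[2]
            K = self.params[f"conv{l}_K"]
            A = X[:, :P] @ K[:k]
            for j in range(1, l):
                A += X[:, j : j + P] @ K[j * k : (j + 1) * k]
            A += self.params[f"conv{l}_b"]
            R = np.maximum(A, 0.0)
            valid = np.arange(P)[None, :] <= (lengths[:, None] - l)
            R[~valid] = _NEG
            arg = R.argmax(axis=1)
            pooled = np.take_along_axis(R, arg[:, None, :], axis=1)[:, 0, :]
            has_valid = valid.any(axis=1)
            pooled = np.where(has_valid[:, None], pooled, 0.0)
            feats.append(pooled)
            cache_w.append((A, arg, has_valid, P))
        feat = np.concatenate(feats, axis=1)
        logit = feat @ self.params["head_W"] + self.params["head_b"]
        prob = nn.sigmoid(logit)
        return prob, (ids, X, feat, cache_w)

    def predict(self, seqs) -> np.ndarray:
        """Probability that each sequence is from the positive set."""
        ids = _as_array(seqs, self.config.max_len)
        prob, _ = self._forward(ids)
        return prob

    def predict_one(self, seq) -> float:
        return float(self.predict([seq])[0])

    # ------------------------------------------------------------------ #

    def loss_and_grads(self, ids: np.ndarray, labels: np.ndarray):
        """Mean binary cross-entropy  −y·log D − (1−y)·log(1−D)  and its
        φ-gradient (the adversarial objective in supervised form)."""
        prob, (ids, X, feat, cache_w) = self._forward(ids)
        B = len(labels)
        p = np.clip(prob, 1e-12, 1 - 1e-12)
        loss = float(-(labels * np.log(p) + (1 - labels) * np.log(1 - p)).mean())
        dlogit = (prob - labels) / B
        grads = {
            "head_W": feat.T @ dlogit,
            "head_b": np.asarray(dlogit.sum()),
        }
        dfeat = np.outer(dlogit, self.params["head_W"])
        dX = np.zeros_like(X)
        F = self.config.n_filters
        for wi, l in enumerate(self.config.window_sizes):
            dpooled = dfeat[:, wi * F : (wi + 1) * F]
            if cache_w[wi] is None:
                grads[f"conv{l}_K"] = np.zeros_like(self.params[f"conv{l}_K"])
                grads[f"conv{l}_b"] = np.zeros_like(self.params[f"conv{l}_b"])
                continue
            A, arg, has_valid, P = cache_w[wi]
            dpooled = dpooled * has_valid[:, None]
            dA = np.zeros_like(A)
            np.put_along_axis(dA, arg[:, None, :], dpooled[:, None, :], axis=1)
            dA *= A > 0
            k = X.shape[2]
            K = self.params[f"conv{l}_K"]
            dK = np.empty_like(K)
            db = dA.sum(axis=(0, 1))
            for j in range(l):
                dK[j * k : (j + 1) * k] = np.einsum(
                    "bpk,bpf->kf", X[:, j : j + P], dA
                )
                dX[:, j : j + P] += dA @ K[j * k : (j + 1) * k].T
            grads[f"conv{l}_K"] = dK
            grads[f"conv{l}_b"] = db
        demb = np.zeros_like(self.params["emb"])
        np.add.at(demb, ids, dX)
        grads["emb"] = demb
        return loss, grads

    def train_step(self, ids: np.ndarray, labels: np.ndarray, optimizer: nn.Adam):
        loss, grads = self.loss_and_grads(ids, labels)
        nn.clip_grads(grads, self.config.grad_clip)
        optimizer.step(self.params, grads)
        return loss

    # ------------------------------------------------------------------ #

    def train_initial(
        self,
        positives,
        negatives,
        cfg: DiscTrainConfig,
        seed: int = 0,
        verbose: bool = False,
    ) -> dict:
        """Supervised pretraining on labeled corpora.

        The two classes are merged and split (stratified) into
        train/validation/internal-test at ``cfg.split``; training
        minimizes binary cross-entropy with Adam and early-stops on the
        validation mean loss.  Returns a report with the internal-test
        accuracy and AUC of the restored best model.
        """
        if len(positives) == 0 or len(negatives) == 0:
            raise ValueError("both classes must be non-empty")
        rng = np.random.default_rng(seed)
        pos = _as_array(positives, self.config.max_len)
        neg = _as_array(negatives, self.config.max_len)

        def split(arr):
            order = rng.permutation(len(arr))
            a, b = self.config_split_points(len(arr), cfg.split)
            return arr[order[:a]], arr[order[a:b]], arr[order[b:]]

        ptr, pva, pte = split(pos)
        ntr, nva, nte = split(neg)
        Xtr = np.concatenate([ptr, ntr])
        ytr = np.concatenate([np.ones(len(ptr)), np.zeros(len(ntr))])
        Xva = np.concatenate([pva, nva])
        yva = np.concatenate([np.ones(len(pva)), np.zeros(len(nva))])
        Xte = np.concatenate([pte, nte])
        yte = np.concatenate([np.ones(len(pte)), np.zeros(len(nte))])

        opt = nn.Adam(lr=cfg.learning_rate)
        best_val = self._mean_loss(Xva, yva)
        best_params = copy.deepcopy(self.params)
        history = {"train_loss": [], "val_loss": [best_val]}
        bad = 0
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(len(Xtr))
            losses = []
            for s in range(0, len(Xtr), cfg.batch_size):
                idx = order[s : s + cfg.batch_size]
                losses.append(self.train_step(Xtr[idx], ytr[idx], opt))
            val = self._mean_loss(Xva, yva)
            history["train_loss"].append(float(np.mean(losses)))
            history["val_loss"].append(val)
            if verbose:
                print(f"epoch {epoch}: train {history['train_loss'][-1]:.4f} val {val:.4f}")
            if val < best_val:
                best_val, best_params, bad = val, copy.deepcopy(self.params), 0
            else:
                bad += 1
                if bad >= cfg.patience:
                    break
        self.params = best_params
        p_te = self.predict(Xte)
        return {
            "history": history,
            "best_val_loss": best_val,
            "test_accuracy": float(((p_te >= 0.5) == yte).mean()),
            "test_auc": float(roc_auc_score(yte, p_te)),
            "n_train": len(Xtr),
            "n_val": len(Xva),
            "n_test": len(Xte),
        }

    @staticmethod
    def config_split_points(n: int, split) -> tuple[int, int]:
        a = int(round(n * split[0]))
        b = int(round(n * (split[0] + split[1])))
        return a, b

    def _mean_loss(self, X, y) -> float:
        p = np.clip(self.predict(X), 1e-12, 1 - 1e-12)
        return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())

    # ------------------------------------------------------------------ #

    def save(self, path) -> None:
        meta = json.dumps(
            {"config": asdict(self.config), "vocab": list(self.vocab.tokens),
             "dtype": self.dtype.name}
        )
        np.savez(path, __meta__=np.array(meta), **self.params)

    @classmethod
    def load(cls, path) -> "Discriminator":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["__meta__"]))
        cfg = meta["config"]
        cfg["window_sizes"] = tuple(cfg["window_sizes"])
        disc = cls(
            TokenVocabulary(meta["vocab"]),
            DiscConfig(**cfg),
            dtype=np.dtype(meta["dtype"]),
        )
        disc.params = {k: data[k] for k in data.files if k != "__meta__"}
        return disc
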