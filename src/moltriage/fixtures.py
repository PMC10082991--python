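"""Deterministic synthetic SMILES corpora and an enumerable toy world.

Two hand-written stochastic grammars provide structurally separable
molecule populations with known ground truth and no downloads:

* the *negative* grammar emits acyclic alkane/ether/amine chains using
  only the tokens {C, O, N, (, )} — a stand-in for catalog-like,
  low-interest chemistry;
* the *positive* grammar decorates aromatic cores with amide or
  sulfonamide linkers, stereocenters and halogens — a stand-in for
  drug/bioactive-like chemistry (tokens c, =, [C@H], [C@@H], L, R, ...).

Every emitted molecule is chemically valid, unique within its list, and
survives the preprocessing pipeline by construction.  The grammars do
not imitate real drug property distributions; they only guarantee a
learnable, separable task.

The toy world is a tiny fixed generator/discriminator pair over a
five-token vocabulary whose every sequence, probability, action value
and exact policy gradient can be computed by exhaustive enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .discriminator import DiscConfig, Discriminator
from .generator import GenConfig, Generator
from .prep import RawRecord, clean_record
from .tokenizer import SPECIALS, TokenVocabulary

__all__ = [
    "FixtureSpec",
    "make_negative_grammar",
    "make_positive_grammar",
    "make_fixture_corpora",
    "make_toy_enumerable_world",
    "enumerate_sequences",
    "exact_objective",
    "exact_policy_gradient",
    "exact_q",
]


@dataclass
class FixtureSpec:
    n_pos: int = 500
    n_neg: int = 500
    n_pretrain: int = 2000
    seed: int = 0
    max_heavy_atoms: int = 28

    def __post_init__(self):
        if min(self.n_pos, self.n_neg, self.n_pretrain) <= 0:
            raise ValueError("fixture counts must be positive")


def _canonical_if_clean(smiles: str):
    """Canonical SMILES if the molecule passes preprocessing, else None.
    Grammars dedupe on the canonical form so emitted lists survive the
    pipeline (including duplicate removal) in full."""
    rec = clean_record(RawRecord(smiles))
    return rec.canonical_smiles if rec.accepted else None


def make_negative_grammar(n: int, seed: int = 0) -> list[str]:
    """Acyclic alkane/ether/amine chains; tokens only {C, O, N, (, )}.

    Carbon segments (1–4 C, occasionally with a methyl branch) alternate
    with O/N separators, so no aliphatic chain run can exceed four and
    every molecule has 10–17 heavy atoms.  Deterministic per seed;
    molecules are unique within the returned list.
    """
    rng = np.random.default_rng(seed)
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        n_seg = int(rng.integers(3, 6))
        parts = []
        heavy = 0
        for s in range(n_seg):
            k = int(rng.integers(1, 5))
            seg = "C" * k
            if k >= 3 and rng.random() < 0.3:
                # branch inside the segment keeps its carbon count <= 4
                cut = int(rng.integers(1, k - 1))
                seg = "C" * cut + "(C)" + "C" * (k - cut - 1)
            parts.append(seg)
            heavy += k
            if s < n_seg - 1:
                sep = "O" if rng.random() < 0.6 else "N"
                parts.append(sep)
                heavy += 1
        smiles = "".join(parts)
        if heavy < 10 or heavy > 17:
            continue
        canonical = _canonical_if_clean(smiles)
        if canonical is not None and canonical not in seen:
            seen.add(canonical)
            out.append(smiles)
    return out


_CORES = ["c1ccc({})cc1", "c1ccc({})nc1"]
_SUBS = ["", "Cl", "Br", "F", "O", "C", "N"]
_LINKERS = ["C(=O)N", "S(=O)(=O)N", "C(=O)O", "NC(=O)", "CN", "OC"]
_STEREO = ["[C@H](C)", "[C@@H](C)", "[C@H](O)", "[C@@H](N)", ""]
_TAILS = [
    "c2ccccc2",
    "c2ccncc2",
    "c2ccc(Cl)cc2",
    "c2ccc(F)cc2",
    "CC",
    "CCO",
    "CCN",
    "C(C)C",
]
# optional chain extension on the tail's last atom; multiplies the
# grammar's combination space so large unique corpora stay reachable,
# and the halogenated variants widen the molecular-weight range of the
# positive population relative to the plain-chain negatives
_EXTRAS = ["", "C", "CC", "O", "CO", "N", "CN", "OC", "CCl", "CBr", "C(Br)Br"]


def make_positive_grammar(n: int, seed: int = 0, max_tokens: int = 28) -> list[str]:
    """Drug-motif molecules: aromatic cores + amide/sulfonamide linkers
    + stereocenters + halogens.  Deterministic per seed; all survive
    preprocessing; unique within the list.  ``max_tokens`` bounds the
    tokenized length so sequence models stay desk-scale."""
    from .tokenizer import tokenize

    rng = np.random.default_rng(seed)
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        sub = _SUBS[int(rng.integers(0, len(_SUBS)))]
        core = _CORES[0] if rng.random() < 0.8 else _CORES[1]
        linker = _LINKERS[int(rng.integers(0, len(_LINKERS)))]
        stereo = _STEREO[int(rng.integers(0, len(_STEREO)))]
        tail = _TAILS[int(rng.integers(0, len(_TAILS)))]
        extra = _EXTRAS[int(rng.integers(0, len(_EXTRAS)))]
        smiles = sub + core.format(linker + stereo + tail + extra)
        if len(tokenize(smiles)) > max_tokens:
            continue
        canonical = _canonical_if_clean(smiles)
        if canonical is not None and canonical not in seen:
            seen.add(canonical)
            out.append(smiles)
    return out


def make_fixture_corpora(spec: FixtureSpec) -> dict:
    """Pretraining corpus (negative-grammar chemistry), positive and
    negative labeled sets, each from an independent seed stream."""
    return {
        "pretrain": make_negative_grammar(spec.n_pretrain, spec.seed),
        "pos": make_positive_grammar(spec.n_pos, spec.seed + 1),
        "neg": make_negative_grammar(spec.n_neg, spec.seed + 2),
    }


# ---------------------------------------------------------------------- #
# enumerable toy world
# ---------------------------------------------------------------------- #

TOY_MAX_LEN = 5


def make_toy_enumerable_world(seed: int = 12345):
    """A fixed tiny generator/discriminator pair over specials + {C, O}.

    With max_len 5 (start + at most four emitted tokens) the whole
    sequence space is enumerable, so exact probabilities, action values
    and policy gradients are available as oracles.
    Returns (vocab, max_len, generator, discriminator).
    """
    vocab = TokenVocabulary(list(SPECIALS) + ["C", "O"])
    gen = Generator(
        vocab,
        GenConfig(emb_size=4, hidden_size=6, n_layers=1, dropout=0.0,
                  max_len=TOY_MAX_LEN, grad_clip=0.0),
        seed=seed,
    )
    rng = np.random.default_rng(seed + 1)
    # spread the output distribution away from uniform
    gen.params["M"] = gen.params["M"] + rng.standard_normal(gen.params["M"].shape)
    gen.params["c"] = rng.standard_normal(len(vocab)) * 0.5
    disc = Discriminator(
        vocab,
        DiscConfig(emb_size=4, window_sizes=(1, 2), n_filters=3,
                   max_len=TOY_MAX_LEN, grad_clip=0.0),
        seed=seed + 2,
    )
    # widen and center the score range so rewards are informative:
    # scale the head, then shift its bias so the policy's expected
    # logit is zero (scores straddle 0.5 instead of saturating)
    disc.params["head_W"] = disc.params["head_W"] * 20.0
    ids, p = enumerate_sequences(gen)
    scores = disc.predict(ids)
    mean_logit = float(np.log(scores / (1 - scores)) @ p)
    disc.params["head_b"] = np.asarray(disc.params["head_b"] - mean_logit)
    return vocab, TOY_MAX_LEN, gen, disc


def enumerate_sequences(gen: Generator, max_len: int | None = None):
    """All sampleable sequences with their exact probabilities.

    Mirrors :meth:`Generator.sample` exactly: any token (including
    specials) may be emitted; the end token terminates; a sequence that
    reaches max_len truncates.  Probabilities sum to 1.
    Returns (ids array (n, max_len), probs array (n,)).
    """
    max_len = max_len or gen.config.max_len
    V = len(gen.vocab)
    rows, probs = [], []

    def walk(prefix, hidden, logp, last):
        pos = len(prefix)
        if pos == max_len or last == gen.vocab.end_id:
            row = np.zeros(max_len, dtype=np.int64)
            row[: len(prefix)] = prefix
            rows.append(row)
            probs.append(np.exp(logp))
            return
        new_hidden, p = gen.step(hidden, np.array([last]))
        for a in range(V):
            walk(prefix + [a], new_hidden, logp + np.log(p[0, a]), a)

    walk([gen.vocab.start_id], gen.init_hidden(1), 0.0, gen.vocab.start_id)
    return np.stack(rows), np.array(probs)


def exact_objective(gen: Generator, disc: Discriminator) -> float:
    """J(θ) = E_{W∼G_θ}[D_φ(W)] by exhaustive enumeration."""
    ids, p = enumerate_sequences(gen)
    return float(np.dot(p, disc.predict(ids)))


def exact_policy_gradient(gen: Generator, disc: Discriminator) -> dict:
    """∇_θ J by enumeration: Σ_W p(W)·D(W)·∇log p(W)."""
    ids, p = enumerate_sequences(gen)
    rewards = disc.predict(ids)
    weights = np.repeat((p * rewards)[:, None], ids.shape[1] - 1, axis=1)
    _, grads = gen.weighted_nll_and_grads(ids, weights=weights)
    return {k: -v for k, v in grads.items()}  # nll grads descend −J


def exact_q(
    gen: Generator, disc: Discriminator, prefix_ids, action: int
) -> tuple[float, float]:
    """Exact action value E[D(completion)] and its variance, by
    enumerating every completion of prefix+action."""
    max_len = gen.config.max_len
    ids = list(prefix_ids) + [action]
    if action == gen.vocab.end_id or len(ids) >= max_len:
        row = np.zeros((1, max_len), dtype=np.int64)
        row[0, : len(ids)] = ids
        return float(disc.predict(row)[0]), 0.0
    hidden = gen.init_hidden(1)
    for tok in ids:
        hidden, _ = gen.step(hidden, np.array([tok]))
    vals, ps = [], []

    def walk(body, hid, logp, last):
        if len(ids) + len(body) == max_len or last == gen.vocab.end_id:
            row = np.zeros(max_len, dtype=np.int64)
            full = ids + body
            row[: len(full)] = full
            vals.append(float(disc.predict(row[None, :])[0]))
            ps.append(np.exp(logp))
            return
        new_hid, p = gen.step(hid, np.array([last]))
        for a in range(len(gen.vocab)):
            walk(body + [a], new_hid, logp + np.log(p[0, a]), a)

    walk([], hidden, 0.0, ids[-1])
    vals, ps = np.array(vals), np.array(ps)
    mu = float(np.dot(ps, vals))
    var = float(np.dot(ps, (vals - mu) ** 2))
    return mu, var
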