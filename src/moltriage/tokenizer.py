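"""SMILES tokenization and the closed token vocabulary.

A molecule is handled everywhere in this package as a sequence of tokens
drawn from a fixed vocabulary.  Tokenization is greedy left-to-right:

* the eight multi-character bracket atoms ``[C@H] [C@@H] [nH] [C@@] [C@]
  [S@] [S@@] [H]`` are single tokens (they denote one atom each, and
  splitting them produces strings an autoregressive model can rarely
  close correctly);
* two-letter halogens are rewritten to single letters, ``Cl``->``L`` and
  ``Br``->``R``, so that every remaining atom symbol is one character;
* ``%nn`` ring-closure labels (two-digit ring bonds) are one token;
* every other character is its own token.

Any other bracket expression (``[Se]``, ``[N+]``, ...) is rejected as
out-of-vocabulary rather than split into characters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "BRACKET_ATOMS",
    "OutOfVocabularyError",
    "TokenVocabulary",
    "TokenSequence",
    "tokenize",
    "detokenize",
    "build_vocabulary",
    "encode",
    "decode",
]

#: Multi-character atoms kept atomic during tokenization.
BRACKET_ATOMS = frozenset(
    ["[C@H]", "[C@@H]", "[nH]", "[C@@]", "[C@]", "[S@]", "[S@@]", "[H]"]
)

START = "<start>"
END = "<end>"
PAD = "<pad>"
SPECIALS = (PAD, START, END)


class OutOfVocabularyError(ValueError):
    """A span of a SMILES string cannot be mapped to a known token."""

    def __init__(self, span: str, position: int | None = None):
        self.span = span
        self.position = position
        where = f" at position {position}" if position is not None else ""
        super().__init__(f"out-of-vocabulary span {span!r}{where}")


def tokenize(smiles: str) -> list[str]:
    """Split a SMILES string into tokens (greedy, left to right).

    Raises :class:`OutOfVocabularyError` for bracket atoms outside the
    supported eight.  The result always satisfies
    ``detokenize(tokenize(s)) == s``.
    """
    if not smiles:
        raise ValueError("empty SMILES string")
    tokens: list[str] = []
    i = 0
    n = len(smiles)
    while i < n:
        ch = smiles[i]
        if ch == "[":
            j = smiles.find("]", i)
            if j < 0:
                raise OutOfVocabularyError(smiles[i:], i)
            span = smiles[i : j + 1]
            if span not in BRACKET_ATOMS:
                raise OutOfVocabularyError(span, i)
            tokens.append(span)
            i = j + 1
        elif smiles.startswith("Cl", i):
            tokens.append("L")
            i += 2
        elif smiles.startswith("Br", i):
            tokens.append("R")
            i += 2
        elif ch == "%":
            span = smiles[i : i + 3]
            if len(span) < 3 or not span[1:].isdigit():
                raise OutOfVocabularyError(span, i)
            tokens.append(span)
            i += 3
        else:
            tokens.append(ch)
            i += 1
    return tokens


def detokenize(tokens: Iterable[str]) -> str:
    """Inverse of :func:`tokenize`; special tokens are skipped."""
    out: list[str] = []
    for tok in tokens:
        if tok in SPECIALS:
            continue
        if tok == "L":
            out.append("Cl")
        elif tok == "R":
            out.append("Br")
        else:
            out.append(tok)
    return "".join(out)


@dataclass(frozen=True)
class TokenVocabulary:
    """Closed token set with dense integer ids.

    Ids are ``0 .. len(vocab)-1``; the three special tokens (pad, start,
    end) come first and are never produced by :func:`tokenize`.
    """

    tokens: tuple[str, ...]
    token_to_id: dict[str, int] = field(repr=False)

    def __init__(self, tokens: Sequence[str]):
        tokens = tuple(tokens)
        if tokens[:3] != SPECIALS:
            raise ValueError(f"vocabulary must start with specials {SPECIALS}")
        if len(set(tokens)) != len(tokens):
            raise ValueError("duplicate tokens in vocabulary")
        object.__setattr__(self, "tokens", tokens)
        object.__setattr__(
            self, "token_to_id", {t: i for i, t in enumerate(tokens)}
        )

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_id

    @property
    def pad_id(self) -> int:
        return 0

    @property
    def start_id(self) -> int:
        return 1

    @property
    def end_id(self) -> int:
        return 2

    def id_of(self, token: str) -> int:
        try:
            return self.token_to_id[token]
        except KeyError:
            raise OutOfVocabularyError(token) from None

    def contains_all(self, tokens: Iterable[str]) -> bool:
        return all(t in self.token_to_id for t in tokens)

    def to_json(self) -> str:
        return json.dumps({"tokens": list(self.tokens)})

    @classmethod
    def from_json(cls, text: str) -> "TokenVocabulary":
        return cls(json.loads(text)["tokens"])

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "TokenVocabulary":
        with open(path) as fh:
            return cls.from_json(fh.read())


@dataclass(frozen=True)
class TokenSequence:
    """One molecule as a padded id sequence ``[start, w_1.. w_T, end, pad..]``."""

    ids: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.ids)


def build_vocabulary(corpus: Iterable[str]) -> TokenVocabulary:
    """Collect every token observed in ``corpus`` into a vocabulary.

    Ordering is deterministic (specials first, then lexicographic), so
    the same corpus in any order yields an identical vocabulary.
    """
    observed: set[str] = set()
    empty = True
    for smiles in corpus:
        empty = False
        observed.update(tokenize(smiles))
    if empty:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    return TokenVocabulary(list(SPECIALS) + sorted(observed))


def encode(
    tokens: Sequence[str], vocab: TokenVocabulary, max_len: int
) -> TokenSequence:
    """Map tokens to ids, adding start/end and padding to ``max_len``."""
    if len(tokens) + 2 > max_len:
        raise ValueError(
            f"sequence of {len(tokens)} tokens does not fit in max_len={max_len}"
        )
    ids = [vocab.start_id]
    ids.extend(vocab.id_of(t) for t in tokens)
    ids.append(vocab.end_id)
    ids.extend([vocab.pad_id] * (max_len - len(ids)))
    return TokenSequence(tuple(ids))


def decode(seq: TokenSequence, vocab: TokenVocabulary) -> str:
    """Strip specials from an encoded sequence and rebuild the SMILES."""
    toks = []
    for i in seq.ids:
        if i == vocab.end_id:
            break
        if i in (vocab.pad_id, vocab.start_id):
            continue
        toks.append(vocab.tokens[i])
    return detokenize(toks)


def encode_smiles(
    smiles: str, vocab: TokenVocabulary, max_len: int
) -> TokenSequence:
    """Convenience: tokenize then encode."""
    return encode(tokenize(smiles), vocab, max_len)
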