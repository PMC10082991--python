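"""Molecule triage with a trained discriminator.

The user-facing purpose of the package: score a list of SMILES by the
discriminator probability that each molecule is drug/bioactive-like,
then rank and select.  Unscorable entries (unparseable, rejected by the
cleaning rules, too long, or containing out-of-vocabulary tokens) keep
their position with a null score and an explicit reason — never a
silent drop.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .discriminator import Discriminator
from .prep import RawRecord, Rejection, clean_record
from .tokenizer import OutOfVocabularyError, encode, tokenize

__all__ = ["ScoredMolecule", "score_molecules", "rank_and_select", "scored_to_frame"]


@dataclass(frozen=True)
class ScoredMolecule:
    input_smiles: str
    canonical_smiles: Optional[str]
    score: Optional[float]
    reason: str = "none"

    @property
    def scored(self) -> bool:
        return self.score is not None


def score_molecules(
    smiles: Sequence[str],
    disc: Discriminator,
    prep_first: bool = True,
) -> list[ScoredMolecule]:
    """Score each molecule with the discriminator.

    With ``prep_first`` (default) every record passes the per-record
    cleaning rules first, so scoring sees the same distribution the
    model was trained on.  Duplicates are still scored — selection, not
    deduplication, is this function's job.
    """
    vocab = disc.vocab
    max_len = disc.config.max_len
    out: list[ScoredMolecule] = []
    to_score: list[tuple[int, object]] = []
    for s in smiles:
        if prep_first:
            rec = clean_record(RawRecord(s))
            if rec.rejection_reason not in (Rejection.NONE,):
                out.append(ScoredMolecule(s, None, None, rec.rejection_reason.value))
                continue
            canonical = rec.canonical_smiles
        else:
            canonical = s
        try:
            seq = encode(tokenize(canonical), vocab, max_len)
        except OutOfVocabularyError:
            out.append(ScoredMolecule(s, canonical, None, "oov"))
            continue
        except ValueError:
            out.append(ScoredMolecule(s, canonical, None, "too_long"))
            continue
        out.append(ScoredMolecule(s, canonical, None, "pending"))
        to_score.append((len(out) - 1, seq))
    if to_score:
        probs = disc.predict([seq for _, seq in to_score])
        for (idx, _), p in zip(to_score, probs):
            rec = out[idx]
            out[idx] = ScoredMolecule(
                rec.input_smiles, rec.canonical_smiles, float(p), "none"
            )
    return out


def rank_and_select(
    scored: Sequence[ScoredMolecule],
    top_k: Optional[int] = None,
    threshold: Optional[float] = None,
) -> list[ScoredMolecule]:
    """Stable descending sort by score, then take the top k or everything
    at or above the threshold.  Exactly one criterion must be given;
    unscored records never enter the selection."""
    if (top_k is None) == (threshold is None):
        raise ValueError("give exactly one of top_k or threshold")
    if len(scored) == 0:
        raise ValueError("nothing to rank")
    ranked = sorted(
        (r for r in scored if r.scored),
        key=lambda r: -r.score,  # stable: ties keep input order
    )
    if top_k is not None:
        return ranked[:top_k]
    return [r for r in ranked if r.score >= threshold]


def scored_to_frame(scored: Sequence[ScoredMolecule]) -> pd.DataFrame:
    """CSV-ready table: input_smiles, canonical_smiles, score, rank,
    reason.  Ranks (1-based, descending score, stable ties) only for
    scored records."""
    df = pd.DataFrame(
        {
            "input_smiles": [r.input_smiles for r in scored],
            "canonical_smiles": [r.canonical_smiles for r in scored],
            "score": [r.score for r in scored],
            "reason": [r.reason for r in scored],
        }
    )
    order = (
        df[df["score"].notna()]
        .sort_values("score", ascending=False, kind="stable")
        .index
    )
    df["rank"] = pd.Series(range(1, len(order) + 1), index=order, dtype="Int64")
    return df[["input_smiles", "canonical_smiles", "score", "rank", "reason"]]
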