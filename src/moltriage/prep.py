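"""Corpus cleaning pipeline applied to every raw SMILES collection.

Six checks run in a fixed order on each record; the first one that fails
determines the rejection reason:

1. element  — only H, C, N, O, F, P, S, Cl, Br, I are allowed
2. isotope  — explicit isotope labels are rejected
3. duplicate — duplicates (by canonical SMILES) keep the first occurrence
4. size rules — long aliphatic chains (> 4 consecutive acyclic carbons),
   polyhydroxyl (> 10 hydroxyl groups), MW > 750 Da, or fewer than 10
   atoms
5. canonicalization with stereo descriptors retained
6. oov — when a vocabulary is supplied, molecules whose token stream
   leaves it are rejected

Parse failures are recorded as their own reason: real corpora contain
malformed lines and silently dropping them would break the ledger.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

from .tokenizer import OutOfVocabularyError, TokenVocabulary, tokenize

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "ALLOWED_ELEMENTS",
    "RawRecord",
    "CleanRecord",
    "Rejection",
    "PrepReport",
    "check_elements",
    "check_isotopes",
    "check_size_rules",
    "canonicalize",
    "clean_record",
    "preprocess_corpus",
    "read_smiles_file",
    "write_smiles_file",
]

ALLOWED_ELEMENTS = frozenset(
    ["H", "C", "N", "O", "F", "P", "S", "Cl", "Br", "I"]
)

MAX_CHAIN = 4
MAX_HYDROXYL = 10
MAX_MW = 750.0
MIN_ATOMS = 10

_HYDROXYL = Chem.MolFromSmarts("[OX2H1]")


class Rejection(str, Enum):
    NONE = "none"
    PARSE = "parse"
    ELEMENT = "element"
    ISOTOPE = "isotope"
    DUPLICATE = "duplicate"
    CHAIN = "chain"
    HYDROXYL = "hydroxyl"
    MW = "mw"
    ATOMS = "atoms"
    OOV = "oov"


@dataclass(frozen=True)
class RawRecord:
    smiles: str
    source_id: Optional[str] = None

    def __post_init__(self):
        if not self.smiles:
            raise ValueError("empty SMILES in RawRecord")


@dataclass(frozen=True)
class CleanRecord:
    input_smiles: str
    canonical_smiles: Optional[str]
    mol_weight: float
    heavy_atom_count: int
    rejection_reason: Rejection
    source_id: Optional[str] = None

    @property
    def accepted(self) -> bool:
        return self.rejection_reason is Rejection.NONE


@dataclass
class PrepReport:
    """Per-reason rejection counts; conserves the input size."""

    n_input: int = 0
    n_output: int = 0
    rejections: Counter = field(default_factory=Counter)

    def record(self, reason: Rejection) -> None:
        self.n_input += 1
        if reason is Rejection.NONE:
            self.n_output += 1
        else:
            self.rejections[reason.value] += 1

    @property
    def conserved(self) -> bool:
        return self.n_output + sum(self.rejections.values()) == self.n_input

    def as_dict(self) -> dict:
        return {
            "input": self.n_input,
            "survivors": self.n_output,
            "rejections": dict(self.rejections),
        }


def _parse(smiles: str):
    return Chem.MolFromSmiles(smiles)


def check_elements(mol: Chem.Mol) -> bool:
    """True iff every atom's element is in the allowed set."""
    return all(a.GetSymbol() in ALLOWED_ELEMENTS for a in mol.GetAtoms())


def check_isotopes(mol: Chem.Mol) -> bool:
    """True iff no atom carries an explicit isotope label."""
    return all(a.GetIsotope() == 0 for a in mol.GetAtoms())


def _longest_aliphatic_chain(mol: Chem.Mol) -> int:
    """Longest path of consecutive acyclic non-aromatic carbons whose
    neighbors are only carbon or hydrogen ("greasy tail" length)."""
    qualifies = []
    for a in mol.GetAtoms():
        ok = (
            a.GetSymbol() == "C"
            and not a.GetIsAromatic()
            and not a.IsInRing()
            and all(n.GetSymbol() in ("C", "H") for n in a.GetNeighbors())
        )
        qualifies.append(ok)
    idx = {a.GetIdx() for a in mol.GetAtoms() if qualifies[a.GetIdx()]}
    if not idx:
        return 0
    adj = {i: [] for i in idx}
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i in idx and j in idx:
            adj[i].append(j)
            adj[j].append(i)

    # qualifying atoms are acyclic, so components are trees: two sweeps
    # of depth-first search give the longest path per component
    def farthest(start):
        seen = {start}
        best = (1, start)
        stack = [(start, 1)]
        while stack:
            node, d = stack.pop()
            if d > best[0]:
                best = (d, node)
            for nb in adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append((nb, d + 1))
        return best

    longest = 0
    visited = set()
    for i in idx:
        if i in visited:
            continue
        comp = {i}
        stack = [i]
        while stack:
            n = stack.pop()
            for nb in adj[n]:
                if nb not in comp:
                    comp.add(nb)
                    stack.append(nb)
        visited |= comp
        _, far = farthest(i)
        depth, _ = farthest(far)
        longest = max(longest, depth)
    return longest


def _hydroxyl_count(mol: Chem.Mol) -> int:
    return len(mol.GetSubstructMatches(_HYDROXYL))


def check_size_rules(mol: Chem.Mol, count_hydrogens: bool = False) -> Rejection:
    """First triggered size rule among chain/hydroxyl/mw/atoms, else NONE.

    ``count_hydrogens`` switches the "atom numbers < 10" rule from heavy
    atoms (default; hydrogens are implicit in SMILES) to all atoms.
    """
    if _longest_aliphatic_chain(mol) > MAX_CHAIN:
        return Rejection.CHAIN
    if _hydroxyl_count(mol) > MAX_HYDROXYL:
        return Rejection.HYDROXYL
    if Descriptors.MolWt(mol) > MAX_MW:
        return Rejection.MW
    n_atoms = (
        Chem.AddHs(mol).GetNumAtoms() if count_hydrogens else mol.GetNumHeavyAtoms()
    )
    if n_atoms < MIN_ATOMS:
        return Rejection.ATOMS
    return Rejection.NONE


def canonicalize(smiles: str) -> Optional[str]:
    """Canonical SMILES with stereo descriptors, or None on parse failure.

    Idempotent: re-canonicalizing the output returns it unchanged.
    """
    mol = _parse(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def clean_record(
    record: RawRecord,
    vocab: Optional[TokenVocabulary] = None,
    count_hydrogens: bool = False,
) -> CleanRecord:
    """Run the per-record checks (everything except duplicate removal)."""
    mol = _parse(record.smiles)
    if mol is None:
        return CleanRecord(record.smiles, None, 0.0, 0, Rejection.PARSE, record.source_id)
    mw = Descriptors.MolWt(mol)
    heavy = mol.GetNumHeavyAtoms()

    def rejected(reason):
        return CleanRecord(record.smiles, None, mw, heavy, reason, record.source_id)

    if not check_elements(mol):
        return rejected(Rejection.ELEMENT)
    if not check_isotopes(mol):
        return rejected(Rejection.ISOTOPE)
    reason = check_size_rules(mol, count_hydrogens=count_hydrogens)
    if reason is not Rejection.NONE:
        return rejected(reason)
    canonical = Chem.MolToSmiles(mol)
    if vocab is not None:
        try:
            tokens = tokenize(canonical)
        except OutOfVocabularyError:
            return rejected(Rejection.OOV)
        if not vocab.contains_all(tokens):
            return rejected(Rejection.OOV)
    return CleanRecord(
        record.smiles, canonical, mw, heavy, Rejection.NONE, record.source_id
    )


def preprocess_corpus(
    records: Iterable[RawRecord],
    vocab: Optional[TokenVocabulary] = None,
    count_hydrogens: bool = False,
) -> tuple[list[CleanRecord], PrepReport]:
    """Apply the full pipeline to a corpus.

    Survivors keep input order; duplicates (same canonical SMILES) keep
    the first occurrence.  The report conserves counts:
    survivors + Σ rejections = inputs.  Per-record failures are recorded,
    never raised.
    """
    report = PrepReport()
    out: list[CleanRecord] = []
    seen: set[str] = set()
    for rec in records:
        cleaned = clean_record(rec, vocab=vocab, count_hydrogens=count_hydrogens)
        if cleaned.accepted:
            if cleaned.canonical_smiles in seen:
                cleaned = CleanRecord(
                    cleaned.input_smiles,
                    None,
                    cleaned.mol_weight,
                    cleaned.heavy_atom_count,
                    Rejection.DUPLICATE,
                    cleaned.source_id,
                )
            else:
                seen.add(cleaned.canonical_smiles)
        report.record(cleaned.rejection_reason)
        if cleaned.accepted:
            out.append(cleaned)
    return out, report


def read_smiles_file(path) -> list[RawRecord]:
    """One SMILES per line; optional whitespace-separated id column."""
    records = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            records.append(RawRecord(parts[0], parts[1] if len(parts) > 1 else None))
    return records


def write_smiles_file(path, smiles: Sequence[str]) -> None:
    with open(path, "w") as fh:
        for s in smiles:
            fh.write(s + "\n")
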