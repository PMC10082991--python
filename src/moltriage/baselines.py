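"""Classical comparator metrics for molecule triage.

A property panel (MW, logP, hydrogen-bond donors/acceptors, rotatable
bonds, Fsp3), Lipinski rule-of-five violation counts, and wrappers for
QED and the synthetic-accessibility score.  All descriptors come from
RDKit's published implementations; Fsp3 is the fraction of carbon atoms
that are sp3-hybridized.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, asdict
from typing import Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, QED, RDConfig

sys.path.append(RDConfig.RDContribDir + "/SA_Score")
import sascorer  # noqa: E402  (RDKit contrib module)

__all__ = ["PropertyPanel", "property_panel", "ro5_violations", "qed", "sa_score", "metrics_table"]


@dataclass(frozen=True)
class PropertyPanel:
    mw: float
    logp: float
    hbd: int
    hba: int
    rotatable_bonds: int
    fsp3: float


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return mol


def property_panel(smiles: str) -> PropertyPanel:
    mol = _mol(smiles)
    return PropertyPanel(
        mw=Descriptors.MolWt(mol),
        logp=Descriptors.MolLogP(mol),
        hbd=Descriptors.NumHDonors(mol),
        hba=Descriptors.NumHAcceptors(mol),
        rotatable_bonds=Descriptors.NumRotatableBonds(mol),
        fsp3=Descriptors.FractionCSP3(mol),
    )


def ro5_violations(panel: PropertyPanel) -> int:
    """Number of Lipinski rules breached (0–4): MW > 500, logP > 5,
    donors > 5, acceptors > 10.  Boundaries themselves do not violate."""
    return sum(
        [panel.mw > 500, panel.logp > 5, panel.hbd > 5, panel.hba > 10]
    )


def qed(smiles: str) -> float:
    """Quantitative estimate of drug-likeness, in [0, 1] (larger better)."""
    return float(QED.qed(_mol(smiles)))


def sa_score(smiles: str) -> float:
    """Synthetic-accessibility score, 1 (easy) to 10 (hard)."""
    return float(sascorer.calculateScore(_mol(smiles)))


def metrics_table(smiles: Sequence[str]) -> pd.DataFrame:
    """Panel + RO5 violations + QED + SA for a list of molecules;
    unparseable entries keep their row with null metrics."""
    rows = []
    for s in smiles:
        try:
            panel = property_panel(s)
            rows.append(
                {"smiles": s, **asdict(panel),
                 "ro5_violations": ro5_violations(panel),
                 "qed": qed(s), "sa": sa_score(s)}
            )
        except ValueError:
            rows.append({"smiles": s})
    return pd.DataFrame(rows)
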