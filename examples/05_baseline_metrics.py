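"""Classical triage metrics for comparison with the learned score.

Computes the property panel (MW, logP, H-bond donors/acceptors,
rotatable bonds, Fsp3), Lipinski rule-of-five violations, QED and the
synthetic-accessibility score for a few familiar molecules.
"""

from moltriage.baselines import metrics_table

molecules = {
    "aspirin": "CC(=O)Oc1ccccc1C(=O)O",
    "caffeine": "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "cyclohexane": "C1CCCCC1",
    "a greasy amine": "CCCCCCCCCCCCN",
}

df = metrics_table(list(molecules.values()))
df.insert(0, "name", list(molecules.keys()))
print(df.round(2).to_string(index=False))
# Drug-like molecules show 0 rule-of-five violations and mid-range QED;
# the long alkylamine passes RO5 too — exactly the kind of false
# negative/positive behaviour that motivates a learned triage score.
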