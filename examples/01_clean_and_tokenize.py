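"""Clean a raw SMILES list and tokenize the survivors.

Builds a tiny corpus containing a few rule violations, runs the
six-step cleaning pipeline, and shows the per-reason ledger plus the
token stream of one survivor.
"""

from moltriage import RawRecord, preprocess_corpus, tokenize
from moltriage.fixtures import make_positive_grammar

raw = make_positive_grammar(8, seed=1) + [
    "C[Si](C)C",   # disallowed element (Si)
    "[13CH4]",     # isotope label
    "CO",          # fewer than 10 atoms
    "not_a_smiles",
]

records = [RawRecord(s) for s in raw]
survivors, report = preprocess_corpus(records)

print("ledger:", report.as_dict())
print("first survivor:", survivors[0].canonical_smiles)
print("tokens:", tokenize(survivors[0].canonical_smiles))
# The ledger counts every input exactly once: survivors + rejections
# equals the corpus size, and each rejection names the rule that fired.
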