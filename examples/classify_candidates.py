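"""Classify candidate peptidase sequences by diagnostic residues.

Builds a synthetic reference profile per family, then classifies three
candidates: the reference itself, a DPP 10-like mutant whose catalytic
Ser is replaced by Gly, and a candidate with a deletion over an anchor.
"""

from pspkit import Peptide, classify, gen_reference_profile
from pspkit.annotate import classification_table

families = ["S9A", "S9B", "S28", "M24B", "M17", "M20"]
profiles = [gen_reference_profile(f, length=80, seed=1)[0] for f in families]

s9b, positions = gen_reference_profile("S9B", length=80, seed=1)
ref_seq = s9b.reference_seq.seq

gly = list(ref_seq)
gly[positions[0] - 1] = "G"           # catalytic Ser -> Gly
deleted = ref_seq[:positions[2] - 4] + ref_seq[positions[2] + 3:]

candidates = [
    Peptide("reference_itself", ref_seq),
    Peptide("ser_to_gly_mutant", "".join(gly)),
    Peptide("anchor_deleted", deleted),
]
reports = [classify(c, profiles) for c in candidates]
print(classification_table(reports).to_string(index=False))

# active: all key anchors intact; inactive_homolog: the DPP 10 pattern
# (dead catalytic Ser, rest intact); incomplete: an anchor is missing.
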