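"""Codon-preference statistics on a toy gene: RSCU, ECD, CAI, Fop, E.

The gene uses TTT for every Phe while the reference set prefers TTC,
so the gene looks biased (high E) but poorly adapted to the reference
(low CAI/Fop).
"""

from nifcast.codon_features import DEGENERATE_CODONS, ReferenceSet, cai, e_metric, ecd, fop, rscu
from nifcast.records import CodingSequence

gene = CodingSequence(id="toy|nifD_1", gene="nifd", nucleotides="TTT" * 10 + "GGTGGC" * 5)

# reference preferring TTC over TTT, neutral elsewhere
w = {c: 1.0 for c in DEGENERATE_CODONS}
w["TTT"] = 0.25
ref = ReferenceSet(w=w)

profile = rscu(gene)
print(f"RSCU(TTT) = {profile.values['TTT']:.2f}   (2.0 = all Phe mass on one codon)")
print(f"RSCU(TTC) = {profile.values['TTC']:.2f}")
print(f"ECD       = {ecd(profile):.4f}  (distance of the RSCU vector from all-ones)")
print(f"E         = {e_metric(gene):.4f}  (within-family deviation from uniform usage)")
print(f"CAI       = {cai(gene, ref):.4f}  (geometric-mean adaptiveness to the reference)")
print(f"Fop       = {fop(gene, ref):.4f}  (fraction of reference-optimal codons)")
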