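"""Label a chain's residues as domain / boundary / hinge from its domain
annotation.

A 60-residue chain with one domain spanning residues 11-50: residues
outside the domain and the two segment termini are boundary (1); 2R-residue
hinge windows (R=3 here for readability) straddle each terminus (2); the
rest is domain (0).
"""

import hingecrf as hc

ann = hc.DomainAnnotation("demo", length=60, domains=(((11, 50),),))
labels2 = hc.assign_two_state_labels(ann)
labels3 = hc.assign_hinge_labels(labels2, ann, hc.HingeConfig(R=3))

print("two-state :", labels2.to_text())
print("three-state:", labels3.to_text())
n_b = int((labels2.codes == 1).sum())
n_h = int((labels3.codes == 2).sum())
print(f"{n_b} boundary residues; {n_h} hinge residues "
      f"(= 2 termini x 2R = {2 * 2 * 3}, untruncated)")
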