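"""Additive relationships from a small pedigree.

Builds a five-animal pedigree containing a full-sib mating, then prints
the tabular relationship matrix A, the inbreeding coefficients F and the
sparse inverse of A.  The offspring of the full-sib pair is inbred
(F = 0.25), so its diagonal element of A is 1.25.
"""

import numpy as np

from pedreml import Pedigree, build_A, build_A_inverse

ped = Pedigree.from_records(
    [
        ("sire", None, None),
        ("dam", None, None),
        ("son", "sire", "dam"),
        ("daughter", "sire", "dam"),
        ("inbred_calf", "son", "daughter"),
    ]
)

rel = build_A(ped)
print("animals:", ped.ids)
print("A (numerator relationship matrix):")
print(np.round(rel.A, 3))
print("inbreeding F:", np.round(rel.F, 3))

sparse_rel = build_A_inverse(ped)
print("A^-1 (from Henderson's rules, at most 9 entries per animal):")
print(np.round(sparse_rel.A_inv.toarray(), 3))
print("max |A^-1 A - I| =", np.abs(sparse_rel.A_inv @ rel.A - np.eye(5)).max())
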