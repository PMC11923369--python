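"""Weak-interaction detection on a constructed all-atom fragment.

Builds a small frame containing a salt bridge, a hydrogen bond and a pair of
stacked aromatic rings, then catalogues the unique (type, residue pair)
occurrences the way medoid frames are catalogued in a full study.
"""

import numpy as np

from pincermd import Topology, catalog_to_table, unique_contact_catalog

atoms = [
    # Lys18 NZ ... Glu55 OE1 at 3.2 A: salt bridge (and H-bond geometry)
    (18, "LYS", "NZ", (0.0, 0.0, 0.0)),
    (55, "GLU", "OE1", (3.2, 0.0, 0.0)),
    # backbone N-H...O at 2.9 A
    (30, "GLY", "N", (10.0, 0.0, 0.0)),
    (62, "GLY", "O", (12.9, 0.0, 0.0)),
]
# two parallel Phe rings 4 A apart (pi-stacking)
for resid, z in ((70, 0.0), (90, 4.0)):
    for i, name in enumerate(("CG", "CD1", "CD2", "CE1", "CE2", "CZ")):
        angle = 2 * np.pi * i / 6
        atoms.append((resid, "PHE", name,
                      (20 + 1.4 * np.cos(angle), 1.4 * np.sin(angle), z)))

coords = np.array([a[3] for a in atoms])
top = Topology(serials=np.arange(1, len(atoms) + 1),
               names=tuple(a[2] for a in atoms),
               resids=np.array([a[0] for a in atoms]),
               resnames=tuple(a[1] for a in atoms),
               masses=np.ones(len(atoms)),
               elements=tuple(a[2][0] for a in atoms))

catalog = unique_contact_catalog([coords], top)
print(catalog_to_table(catalog).to_string(index=False))
print("\nhbsb/hbss = side-chain hydrogen bonds, sb = salt bridge,")
print("ps = pi-stacking; each row is one unique residue-pair interaction.")
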