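"""Structure-derived features from coordinates: geometric helix assignment,
K+E-helix ratio, and intra-chain disulfide detection."""

import numpy as np

import binderqc as b

# Geometric SS assignment on synthetic CA traces
helix = b.ideal_helix_coords(20)
ext = b.extended_chain_coords(10)
coords = np.vstack([helix, ext + [0.0, 20.0, 0.0]])
ss = b.assign_ss_from_ca(coords)
print(f"SS of a 20-residue ideal helix + 10-residue extended tail: {ss}")
print(f"helix fraction: {b.helix_fraction(ss):.2f}")

seq = "KE" * 10 + "A" * 10
print(f"K+E-helix ratio of {seq[:12]}...: {b.ke_helix_ratio(seq, ss):.2f}")

# Disulfide counting on constructed cysteine geometry: two SG pairs at
# bonding distance (2.0 A), one stray cysteine.
sg = np.array([[0, 0, 0], [2.0, 0, 0], [20, 0, 0], [22.0, 0, 0], [40, 0, 0]], float)
rec = b.StructureRecord(
    "demo", residue_names=["CYS"] * 5,
    ca=np.arange(15, dtype=float).reshape(5, 3), sg=sg,
)
print(f"intra-chain disulfides: {b.count_intra_chain_disulfides(rec)}")
# The distance rule pairs each cysteine at most once, so the five cysteines
# yield exactly two disulfides.
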