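"""Structure-derived features: helix content, K+E-helix ratio, disulfides.

Structures are consumed, never predicted: the package reads PDB/mmCIF files
(e.g. from Boltz-1/ESMFold/Chai-1) or precomputed secondary-structure
strings. When only CA coordinates are available, helices are assigned with a
P-SEA-style geometric rule on CA(i)-CA(i+3) and CA(i)-CA(i+4) distances.
Precomputed SS strings take precedence over coordinate-based assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

# Geometric helix criterion on CA distances (Angstrom). An ideal alpha helix
# has d(i,i+3) ~ 5.0-5.1 and d(i,i+4) ~ 6.2; the windows below tolerate the
# distortion seen in predicted structures.
HELIX_D13 = (4.9, 5.6)
HELIX_D14 = (5.9, 6.7)
MIN_HELIX_RUN = 5

# Conventional disulfide distance criteria.
SG_SG_CUTOFF = 2.5
CB_CB_CUTOFF = 4.5


@dataclass
class StructureRecord:
    """Per-residue geometry of one binder chain.

    Either coordinates (CA required; CB/SG optional, NaN when absent) or a
    precomputed SS string must be present. Rows follow chain order.
    """

    design_id: str
    chain: str = "A"
    residue_names: list[str] = field(default_factory=list)
    ca: np.ndarray | None = None  # (n, 3)
    cb: np.ndarray | None = None  # (n, 3), NaN rows where missing
    sg: np.ndarray | None = None  # (n, 3), NaN rows where missing
    ss: str | None = None

    def __post_init__(self) -> None:
        for name in ("ca", "cb", "sg"):
            arr = getattr(self, name)
            if arr is not None:
                setattr(self, name, np.asarray(arr, dtype=float))
        if self.ca is not None and np.isinf(self.ca).any():
            raise ValueError("non-finite CA coordinates")

    @property
    def n_residues(self) -> int:
        if self.ca is not None:
            return len(self.ca)
        return len(self.ss or "")

    def secondary_structure(self) -> str:
        """SS string, preferring a supplied annotation over geometry."""
        if self.ss is not None:
            return self.ss
        if self.ca is None:
            raise ValueError(f"{self.design_id}: neither SS nor coordinates")
        return assign_ss_from_ca(self.ca)


def read_structure(path: str | Path, design_id: str | None = None, chain: str = "A") -> StructureRecord:
    """Read one chain from a PDB or mmCIF file (first model, altloc 'A' preferred)."""
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    st.remove_alternative_conformations()
    model = st[0]
    chains = {ch.name: ch for ch in model}
    if chain not in chains:
        raise ValueError(f"chain {chain!r} not found in {path} (have {sorted(chains)})")
    names, ca, cb, sg = [], [], [], []
    for res in chains[chain]:
        info = gemmi.find_tabulated_residue(res.name)
        if info is not None and not info.is_amino_acid():
            continue
        atom_ca = res.find_atom("CA", "*")
        if atom_ca is None:
            warnings.warn(f"{path}: residue {res.seqid} lacks CA; labeled coil")
        names.append(res.name)
        nan3 = [np.nan] * 3
        ca.append(list(atom_ca.pos.tolist()) if atom_ca else nan3)
        atom_cb = res.find_atom("CB", "*")
        cb.append(list(atom_cb.pos.tolist()) if atom_cb else nan3)
        atom_sg = res.find_atom("SG", "*")
        sg.append(list(atom_sg.pos.tolist()) if atom_sg else nan3)
    return StructureRecord(
        design_id=design_id or Path(path).stem,
        chain=chain,
        residue_names=names,
        ca=np.array(ca, dtype=float),
        cb=np.array(cb, dtype=float),
        sg=np.array(sg, dtype=float),
    )


def assign_ss_from_ca(coords: np.ndarray) -> str:
    """Assign H/C labels from CA coordinates (P-SEA-style distance rule).

    Residue i is a helix candidate when d(i,i+3) falls in ``HELIX_D13`` and
    d(i,i+4) in ``HELIX_D14``; candidates are kept only in runs of at least
    ``MIN_HELIX_RUN`` consecutive residues (then extended to cover the i+4
    window of the run). Residues with missing CA are labeled C. Strands are
    not assigned; everything non-helical is C.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n < MIN_HELIX_RUN:
        return "C" * n
    valid = ~np.isnan(coords).any(axis=1)

    def dist(i: int, j: int) -> float:
        if not (valid[i] and valid[j]):
            return np.nan
        return float(np.linalg.norm(coords[i] - coords[j]))

    candidate = np.zeros(n, dtype=bool)
    for i in range(n - 4):
        d13 = dist(i, i + 3)
        d14 = dist(i, i + 4)
        if np.isnan(d13) or np.isnan(d14):
            continue
        candidate[i] = (
            HELIX_D13[0] <= d13 <= HELIX_D13[1]
            and HELIX_D14[0] <= d14 <= HELIX_D14[1]
        )

    labels = np.full(n, "C", dtype="<U1")
    i = 0
    while i < n:
        if candidate[i]:
            j = i
            while j < n and candidate[j]:
                j += 1
            run = j - i
            if run >= MIN_HELIX_RUN:
                # candidates certify the window [i, j+4); label it helical
                labels[i : min(n, j + 4)] = "H"
            i = j
        else:
            i += 1
    return "".join(labels)


def helix_fraction(ss: str) -> float:
    """Fraction of residues labeled H."""
    if not ss:
        raise ValueError("empty SS string")
    return ss.count("H") / len(ss)


def ke_helix_ratio(aa_seq: str, ss: str) -> float:
    """Fraction of all residues that are lysine or glutamate AND helical.

    This parameter-free definition ("(K or E) and H, over chain length") is
    the headline recovery predictor; see :func:`ke_helix_ratio_helixlevel`
    for the helix-level alternative.
    """
    if len(aa_seq) != len(ss):
        raise ValueError(
            f"sequence length {len(aa_seq)} != SS length {len(ss)}"
        )
    return sum(1 for aa, s in zip(aa_seq, ss) if s == "H" and aa in "KE") / len(ss)


def ke_helix_ratio_helixlevel(aa_seq: str, ss: str, ke_cutoff: float = 0.5) -> float:
    """Alternative definition: fraction of residues in helices whose own
    K+E content is at least ``ke_cutoff`` ("helices that are mostly K/E")."""
    if len(aa_seq) != len(ss):
        raise ValueError("sequence/SS length mismatch")
    n = len(ss)
    total = 0
    i = 0
    while i < n:
        if ss[i] == "H":
            j = i
            while j < n and ss[j] == "H":
                j += 1
            seg = aa_seq[i:j]
            ke = sum(1 for aa in seg if aa in "KE") / len(seg)
            if ke >= ke_cutoff:
                total += len(seg)
            i = j
        else:
            i += 1
    return total / n


def count_intra_chain_disulfides(
    structure: StructureRecord,
    sg_cutoff: float = SG_SG_CUTOFF,
    cb_cutoff: float = CB_CB_CUTOFF,
) -> int:
    """Count disulfide pairs among cysteines of the binder chain.

    Pairs are formed greedily nearest-first on SG-SG distance (<= sg_cutoff);
    cysteines without SG coordinates fall back to CB-CB (<= cb_cutoff). Each
    cysteine joins at most one pair, so the count never exceeds #Cys // 2.
    """
    cys_idx = [i for i, name in enumerate(structure.residue_names) if name.upper() in ("CYS", "C")]
    if len(cys_idx) < 2:
        return 0

    def coord(i: int) -> tuple[np.ndarray | None, bool]:
        if structure.sg is not None and not np.isnan(structure.sg[i]).any():
            return structure.sg[i], True
        if structure.cb is not None and not np.isnan(structure.cb[i]).any():
            return structure.cb[i], False
        return None, False

    pairs = []
    for a_pos, i in enumerate(cys_idx):
        ci, i_sg = coord(i)
        if ci is None:
            continue
        for j in cys_idx[a_pos + 1 :]:
            cj, j_sg = coord(j)
            if cj is None:
                continue
            d = float(np.linalg.norm(ci - cj))
            cutoff = sg_cutoff if (i_sg and j_sg) else cb_cutoff
            if d <= cutoff:
                pairs.append((d, i, j))
    pairs.sort()
    used: set[int] = set()
    n_bonds = 0
    for _, i, j in pairs:
        if i in used or j in used:
            continue
        used.update((i, j))
        n_bonds += 1
    return n_bonds


def ideal_helix_coords(
    n_residues: int,
    rise: float = 1.5,
    twist_deg: float = 100.0,
    radius: float = 2.3,
) -> np.ndarray:
    """CA trace of an ideal alpha helix (defaults: 1.5 A rise, 100 deg twist,
    2.3 A radius -> d(i,i+3) ~ 5.05 A, d(i,i+4) ~ 6.20 A). Test/fixture helper."""
    i = np.arange(n_residues)
    theta = np.deg2rad(twist_deg) * i
    return np.column_stack([radius * np.cos(theta), radius * np.sin(theta), rise * i])


def extended_chain_coords(n_residues: int, spacing: float = 3.8) -> np.ndarray:
    """Straight CA trace with the trans CA-CA spacing; never helical."""
    i = np.arange(n_residues)
    return np.column_stack([spacing * i, np.zeros_like(i, dtype=float), np.zeros_like(i, dtype=float)])


def structure_feature_table(structures, sequences=None):
    """Per-structure features: helix_fraction, ke_helix_ratio, n_disulfides.

    ``sequences`` maps design_id -> protein sequence; when absent, one-letter
    codes are derived from residue names.
    """
    import pandas as pd
    from Bio.Data.IUPACData import protein_letters_3to1

    rows = []
    for st in structures:
        ss = st.secondary_structure()
        if sequences and st.design_id in sequences:
            seq = sequences[st.design_id]
        else:
            seq = "".join(
                protein_letters_3to1.get(name.capitalize(), "X") if len(name) == 3 else name
                for name in st.residue_names
            )
        rows.append(
            {
                "design_id": st.design_id,
                "helix_fraction": helix_fraction(ss),
                "ke_helix_ratio": ke_helix_ratio(seq, ss),
                "n_disulfides": count_intra_chain_disulfides(st),
            }
        )
    return pd.DataFrame(rows, columns=["design_id", "helix_fraction", "ke_helix_ratio", "n_disulfides"])
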