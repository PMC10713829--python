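"""Interface contacts and a simplified steric clash score.

The clash score counts heavy-atom van der Waals overlaps >= 0.4 Å per 1000
heavy atoms.  It is an intentionally simplified stand-in for MolProbity's
probe-based all-atom score: no hydrogens are placed and bonded exclusions
use residue adjacency rather than an explicit bond graph.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .model import StructureModel

__all__ = ["contact_residues", "clash_score", "VDW_RADII"]

# Bondi (1964) van der Waals radii, Å
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "SE": 1.90, "FE": 2.00, "ZN": 1.39, "MG": 1.73, "NA": 2.27,
    "MN": 2.00, "K": 2.75, "CA": 2.31,
}

_BACKBONE_LINK_PREV = frozenset({"C", "O", "CA"})
_BACKBONE_LINK_NEXT = frozenset({"N", "CA", "CB"})


def contact_residues(m: StructureModel, peptide_chain: str,
                     receptor_chain: str, cutoff: float = 3.5) -> list[tuple]:
    """Receptor residues with any heavy atom within ``cutoff`` Å of any
    peptide heavy atom.

    Returns (chain, res_number, icode, res_name) tuples in residue order.
    """
    heavy = m.elements != "H"
    pep = heavy & (m.chain_ids == peptide_chain)
    rec = heavy & (m.chain_ids == receptor_chain)
    if not pep.any():
        raise KeyError(f"chain {peptide_chain!r} not present (or has no heavy atoms)")
    if not rec.any():
        raise KeyError(f"chain {receptor_chain!r} not present (or has no heavy atoms)")
    tree = cKDTree(m.xyz[pep])
    rec_idx = np.flatnonzero(rec)
    dmin, _ = tree.query(m.xyz[rec_idx], k=1)
    close = rec_idx[dmin <= cutoff]
    seen: dict[tuple, None] = {}
    for i in close:
        seen.setdefault((m.chain_ids[i], int(m.res_numbers[i]),
                         m.icodes[i], m.res_names[i]))
    # stable residue order as encountered in the model
    order = {k: j for j, k in enumerate(m.residue_keys())}
    return sorted(seen, key=lambda k: order.get(k, len(order)))


def _excluded(m: StructureModel, i: int, j: int) -> bool:
    """Bonded-neighborhood exclusion: same residue, or backbone-linked
    atoms of chain-adjacent residues (within ~3 bonds of the peptide bond)."""
    same_res = (m.chain_ids[i] == m.chain_ids[j]
                and m.res_numbers[i] == m.res_numbers[j]
                and m.icodes[i] == m.icodes[j])
    if same_res:
        return True
    if m.chain_ids[i] != m.chain_ids[j]:
        return False
    delta = int(m.res_numbers[j]) - int(m.res_numbers[i])
    if abs(delta) != 1:
        return False
    lo, hi = (i, j) if delta == 1 else (j, i)
    return (m.atom_names[lo] in _BACKBONE_LINK_PREV
            and m.atom_names[hi] in _BACKBONE_LINK_NEXT)


def clash_score(m: StructureModel, overlap_threshold: float = 0.4,
                return_pairs: bool = False):
    """Heavy-atom vdW overlaps >= threshold, normalized per 1000 heavy atoms.

    A pair clashes when r_vdw(i) + r_vdw(j) - d(i,j) >= threshold and the
    pair is not excluded as bonded neighborhood.
    """
    heavy_idx = np.flatnonzero(m.elements != "H")
    if heavy_idx.size == 0:
        raise ValueError("no heavy atoms")
    radii = np.empty(heavy_idx.size)
    for k, i in enumerate(heavy_idx):
        el = str(m.elements[i]).upper()
        if el not in VDW_RADII:
            raise KeyError(
                f"unknown element {el!r} for atom {m.chain_ids[i]}/"
                f"{m.res_numbers[i]}/{m.atom_names[i]}"
            )
        radii[k] = VDW_RADII[el]
    xyz = m.xyz[heavy_idx]
    rmax = radii.max()
    tree = cKDTree(xyz)
    pairs = tree.query_pairs(r=2 * rmax - overlap_threshold + 1e-9,
                             output_type="ndarray")
    clashes = []
    for a, b in pairs:
        d = float(np.linalg.norm(xyz[a] - xyz[b]))
        overlap = radii[a] + radii[b] - d
        # inclusive boundary within float tolerance
        if overlap >= overlap_threshold - 1e-9 and not _excluded(
                m, int(heavy_idx[a]), int(heavy_idx[b])):
            clashes.append((int(heavy_idx[a]), int(heavy_idx[b]), overlap))
    score = 1000.0 * len(clashes) / heavy_idx.size
    if return_pairs:
        return score, clashes
    return score
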