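"""Torsion angles: phi/psi/chi1 extraction with the IUPAC sign convention."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import Ensemble, StructureModel

__all__ = ["DihedralSeries", "dihedral_angle", "wrap_angle",
           "backbone_dihedrals", "chi1_dihedrals", "ensemble_dihedrals"]

# chi1 is N-CA-CB-<gamma atom>; GLY and ALA have none
_CHI1_GAMMA = {
    "ARG": "CG", "ASN": "CG", "ASP": "CG", "GLN": "CG", "GLU": "CG",
    "HIS": "CG", "LEU": "CG", "LYS": "CG", "MET": "CG", "PHE": "CG",
    "PRO": "CG", "TRP": "CG", "TYR": "CG",
    "ILE": "CG1", "VAL": "CG1",
    "SER": "OG", "THR": "OG1", "CYS": "SG",
}


@dataclass
class DihedralSeries:
    """One named torsion of one residue, one value per model/frame (degrees)."""

    chain: str
    res_number: int
    icode: str
    res_name: str
    angle_name: str  # 'phi' | 'psi' | 'chi1'
    values: np.ndarray  # degrees in (-180, 180]; NaN marks absent

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def wrap_angle(deg) -> np.ndarray | float:
    """Wrap degrees into the principal interval (-180, 180]."""
    a = np.asarray(deg, dtype=float)
    wrapped = -(np.mod(-a + 180.0, 360.0) - 180.0)
    if np.ndim(deg) == 0:
        return float(wrapped)
    return wrapped


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed torsion (degrees) about the p1-p2 axis, IUPAC convention:
    0 for cis/eclipsed, positive clockwise looking from p1 to p2."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def _residue_atoms(m: StructureModel, chain: str):
    """Per-residue {atom_name: index} maps for one chain, in residue order."""
    order: dict[tuple, dict[str, int]] = {}
    for i in range(m.n_atoms):
        if m.chain_ids[i] != chain:
            continue
        rk = (m.res_numbers[i], m.icodes[i], m.res_names[i])
        order.setdefault(rk, {})[m.atom_names[i]] = i
    return order


def backbone_dihedrals(m: StructureModel, chain: str) -> list[DihedralSeries]:
    """phi/psi for every residue of ``chain`` in one model.

    Terminal residues yield only the defined angle; residues with missing
    backbone atoms get NaN (absent), never a fabricated value.
    """
    residues = _residue_atoms(m, chain)
    if not residues:
        raise KeyError(f"chain {chain!r} not present")
    keys = list(residues)
    out: list[DihedralSeries] = []
    for j, rk in enumerate(keys):
        resnum, icode, resname = rk
        atoms = residues[rk]
        prev_atoms = residues[keys[j - 1]] if j > 0 else None
        next_atoms = residues[keys[j + 1]] if j + 1 < len(keys) else None
        if prev_atoms is not None:
            phi = np.nan
            need = ("C",), ("N", "CA", "C")
            if "C" in prev_atoms and all(a in atoms for a in need[1]):
                phi = dihedral_angle(m.xyz[prev_atoms["C"]], m.xyz[atoms["N"]],
                                     m.xyz[atoms["CA"]], m.xyz[atoms["C"]])
            out.append(DihedralSeries(chain, resnum, icode, resname, "phi",
                                      np.array([phi])))
        if next_atoms is not None:
            psi = np.nan
            if "N" in next_atoms and all(a in atoms for a in ("N", "CA", "C")):
                psi = dihedral_angle(m.xyz[atoms["N"]], m.xyz[atoms["CA"]],
                                     m.xyz[atoms["C"]], m.xyz[next_atoms["N"]])
            out.append(DihedralSeries(chain, resnum, icode, resname, "psi",
                                      np.array([psi])))
    return out


def chi1_dihedrals(m: StructureModel, chain: str) -> list[DihedralSeries]:
    """chi1 (N-CA-CB-gamma) for residues that define one."""
    residues = _residue_atoms(m, chain)
    if not residues:
        raise KeyError(f"chain {chain!r} not present")
    out: list[DihedralSeries] = []
    for (resnum, icode, resname), atoms in residues.items():
        gamma = _CHI1_GAMMA.get(resname)
        if gamma is None:
            continue
        val = np.nan
        if all(a in atoms for a in ("N", "CA", "CB")) and gamma in atoms:
            val = dihedral_angle(m.xyz[atoms["N"]], m.xyz[atoms["CA"]],
                                 m.xyz[atoms["CB"]], m.xyz[atoms[gamma]])
        out.append(DihedralSeries(chain, resnum, icode, resname, "chi1",
                                  np.array([val])))
    return out


def ensemble_dihedrals(e: Ensemble, chain: str,
                       angles: tuple[str, ...] = ("phi", "psi"),
                       ) -> list[DihedralSeries]:
    """Stack per-model torsions into per-residue series across an ensemble."""
    per_model: list[dict[tuple, float]] = []
    meta: dict[tuple, tuple] = {}
    for m in e:
        vals: dict[tuple, float] = {}
        series: list[DihedralSeries] = []
        if "phi" in angles or "psi" in angles:
            series += backbone_dihedrals(m, chain)
        if "chi1" in angles:
            series += chi1_dihedrals(m, chain)
        for s in series:
            if s.angle_name not in angles:
                continue
            key = (s.chain, s.res_number, s.icode, s.angle_name)
            vals[key] = float(s.values[0])
            meta[key] = (s.res_name,)
        per_model.append(vals)
    keys = sorted(meta, key=lambda k: (k[1], k[2], k[3]))
    out = []
    for key in keys:
        chain_id, resnum, icode, angle = key
        values = np.array([pm.get(key, np.nan) for pm in per_model])
        out.append(DihedralSeries(chain_id, resnum, icode, meta[key][0],
                                  angle, values))
    return out
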