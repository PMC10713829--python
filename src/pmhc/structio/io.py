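"""Reading and writing coordinate files.

Multi-model PDB and single-model mmCIF are read through Biopython's parsers
and converted to the flat array model.  Writing targets PDB only.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
from Bio.PDB import FastMMCIFParser, PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

from .model import Ensemble, StructureModel

__all__ = ["read_model_ensemble", "write_pdb"]


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    if len(stripped) >= 2 and stripped[:2].upper() in ("CL", "BR", "FE", "ZN",
                                                       "MG", "NA", "MN", "SE"):
        return stripped[:2].upper()
    return stripped[0].upper()


def _biopdb_to_model(bio_model, model_id: int) -> StructureModel:
    chains, resnums, icodes, resnames, names, elements, coords = \
        [], [], [], [], [], [], []
    for chain in bio_model:
        for residue in chain:
            hetflag, resseq, icode = residue.id
            for atom in residue:
                chains.append(chain.id)
                resnums.append(int(resseq))
                icodes.append(icode.strip())
                resnames.append(residue.resname.strip())
                names.append(atom.get_name())
                elem = (atom.element or "").strip().upper()
                elements.append(elem or _guess_element(atom.get_name()))
                coords.append(atom.coord)
    return StructureModel(
        model_id=model_id,
        chain_ids=np.array(chains, dtype=object),
        res_numbers=np.array(resnums, dtype=int),
        icodes=np.array(icodes, dtype=object),
        res_names=np.array(resnames, dtype=object),
        atom_names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        xyz=np.array(coords, dtype=float),
    )


def read_model_ensemble(path: str | Path,
                        shared_topology: bool = False) -> Ensemble:
    """Read a (possibly multi-model) PDB or mmCIF file into an :class:`Ensemble`.

    Model order and atom order are preserved.  Single-model files yield an
    ensemble of length 1.  With ``shared_topology=True``, mismatched atom
    identity lists across models raise ``ValueError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        if suffix in (".cif", ".mmcif"):
            parser = FastMMCIFParser(QUIET=True)
        else:
            parser = PDBParser(QUIET=True)
        structure = parser.get_structure(path.stem, str(path))
    models = [_biopdb_to_model(bm, i) for i, bm in enumerate(structure)]
    if not models:
        raise ValueError(f"no models found in {path}")
    return Ensemble(models=models, shared_topology=shared_topology)


def _format_atom_name(name: str, element: str) -> str:
    # PDB columns 13-16: 1-char elements start at column 14
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1 and len(name) < 4:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(ensemble_or_model, path: str | Path) -> None:
    """Write models as standard PDB with MODEL/ENDMDL delimiters."""
    if isinstance(ensemble_or_model, StructureModel):
        models = [ensemble_or_model]
    else:
        models = list(ensemble_or_model)
    multi = len(models) > 1
    lines: list[str] = []
    for idx, m in enumerate(models, start=1):
        if multi:
            lines.append(f"MODEL     {idx:4d}")
        serial = 0
        for i in range(m.n_atoms):
            serial += 1
            name = _format_atom_name(str(m.atom_names[i]), str(m.elements[i]))
            x, y, z = m.xyz[i]
            lines.append(
                f"ATOM  {serial:5d} {name}{'':1s}{str(m.res_names[i]):>3s} "
                f"{str(m.chain_ids[i]):1s}{int(m.res_numbers[i]):4d}"
                f"{str(m.icodes[i]) or ' ':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {str(m.elements[i]):>2s}"
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
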