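"""Parsers for the AtomPair/BOUNDED restraint dialect and decoy score tables.

Pseudo-atom expansion is name-based (the dialect carries no residue type):
the shipped table covers the common methyl (M*) and methylene/degenerate-pair
(Q*) pseudo-atoms of the standard amino acids.  Names are matched verbatim.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .model import AtomRef, DecoyScores, NoeRestraint, RestraintTable

__all__ = ["PSEUDO_ATOMS", "expand_pseudo_atom", "read_restraints",
           "read_score_table"]

# pseudo-atom name -> constituent proton names
PSEUDO_ATOMS: dict[str, tuple[str, ...]] = {
    # methyls
    "MB": ("HB1", "HB2", "HB3"),          # Ala beta
    "MG": ("HG1", "HG2", "HG3"),
    "MG1": ("HG11", "HG12", "HG13"),      # Val/Ile gamma1
    "MG2": ("HG21", "HG22", "HG23"),      # Val/Ile/Thr gamma2
    "MD": ("HD1", "HD2", "HD3"),
    "MD1": ("HD11", "HD12", "HD13"),      # Leu/Ile delta1
    "MD2": ("HD21", "HD22", "HD23"),      # Leu delta2
    "ME": ("HE1", "HE2", "HE3"),          # Met epsilon
    # degenerate methylene / aromatic pairs
    "QA": ("HA2", "HA3"),
    "QB": ("HB2", "HB3"),
    "QG": ("HG2", "HG3"),
    "QD": ("HD2", "HD3"),
    "QE": ("HE2", "HE3"),
    "QZ": ("HZ2", "HZ3"),
    # both methyls of Leu/Val
    "QQD": ("HD11", "HD12", "HD13", "HD21", "HD22", "HD23"),
    "QQG": ("HG11", "HG12", "HG13", "HG21", "HG22", "HG23"),
}


def expand_pseudo_atom(atom_name: str, res_number: int,
                       chain: str | None = None) -> tuple[AtomRef, ...]:
    """Expand one restraint atom field into concrete AtomRefs."""
    name = atom_name.upper()
    if name in PSEUDO_ATOMS:
        return tuple(AtomRef(res_number, a, chain)
                     for a in PSEUDO_ATOMS[name])
    # Q-prefixed names are always pseudo-atoms in this dialect; an
    # unrecognized one is an error rather than a silent literal match.
    if name.startswith("Q") and len(name) > 1:
        raise KeyError(f"unknown pseudo-atom name {atom_name!r}")
    return (AtomRef(res_number, atom_name, chain),)


def read_restraints(path: str | Path) -> RestraintTable:
    """Parse `AtomPair <a1> <r1> <a2> <r2> BOUNDED <lb> <ub> <sd> [tag]` lines.

    Blank lines and lines starting with '#' are ignored.  Untagged lines
    get a positional label ``noe<N>``.  Malformed lines raise with their
    line number.
    """
    path = Path(path)
    restraints: list[NoeRestraint] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        try:
            if fields[0] != "AtomPair":
                raise ValueError(f"expected AtomPair, got {fields[0]!r}")
            a1, r1, a2, r2 = fields[1], int(fields[2]), fields[3], int(fields[4])
            if fields[5].upper() != "BOUNDED":
                raise ValueError(f"expected BOUNDED, got {fields[5]!r}")
            lb, ub, sd = float(fields[6]), float(fields[7]), float(fields[8])
            label = fields[9] if len(fields) > 9 else f"noe{len(restraints) + 1}"
        except (IndexError, ValueError) as exc:
            raise ValueError(
                f"{path.name}:{lineno}: malformed restraint line ({exc})"
            ) from exc
        restraints.append(NoeRestraint(
            group_a=expand_pseudo_atom(a1, r1),
            group_b=expand_pseudo_atom(a2, r2),
            lower_bound=lb,
            upper_bound=ub,
            width=sd,
            label=label,
        ))
    return RestraintTable(restraints=restraints, provenance=str(path))


def read_score_table(path: str | Path, energy_col: str = "total_score",
                     tag_col: str = "description") -> DecoyScores:
    """Read a whitespace-delimited score table with a header line.

    Rosetta-style `SCORE:` prefixes are tolerated and stripped.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    rows = []
    header: list[str] | None = None
    for ln in lines:
        fields = ln.split()
        if fields[0] == "SCORE:":
            fields = fields[1:]
        if header is None:
            if energy_col in fields:
                header = fields
            continue
        if len(fields) == len(header):
            rows.append(fields)
    if header is None:
        raise ValueError(f"{path.name}: no header naming column "
                         f"{energy_col!r} found")
    df = pd.DataFrame(rows, columns=header)
    if tag_col not in df.columns:
        raise ValueError(f"{path.name}: missing tag column {tag_col!r}")
    return DecoyScores(
        tags=df[tag_col].tolist(),
        energies=[float(v) for v in df[energy_col]],
        source=str(path),
    )
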