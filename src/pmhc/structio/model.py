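"""Coordinate data model: single models, ensembles, and atom selections.

Atoms are stored as parallel arrays (structure-of-arrays) so selections are
cheap boolean masks and coordinate math stays vectorized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "StructureModel",
    "Ensemble",
    "AtomSelection",
    "ATOM_CLASSES",
    "parse_selection",
]

# atom-name classes usable in selections; "backbone" aliases backbone-no-O
ATOM_CLASSES = (
    "all-heavy",
    "backbone-no-O",
    "backbone-with-O",
    "CA",
    "side-chain-heavy",
    "named-list",
    "all",
)

_BB_NO_O = frozenset({"N", "CA", "C"})
_BB_WITH_O = frozenset({"N", "CA", "C", "O"})


@dataclass
class StructureModel:
    """One conformation: atom identities plus Cartesian coordinates in Å."""

    model_id: int
    chain_ids: np.ndarray  # dtype=object, per-atom chain id
    res_numbers: np.ndarray  # int, author numbering
    icodes: np.ndarray  # object, insertion codes ('' when absent)
    res_names: np.ndarray  # object, 3-letter residue codes
    atom_names: np.ndarray  # object
    elements: np.ndarray  # object, upper-case element symbols
    xyz: np.ndarray  # (n_atoms, 3) float64, Å

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must have shape (n_atoms, 3)")
        n = self.xyz.shape[0]
        for name in ("chain_ids", "res_numbers", "icodes", "res_names",
                     "atom_names", "elements"):
            arr = np.asarray(getattr(self, name), dtype=object)
            if name == "res_numbers":
                arr = np.asarray(getattr(self, name), dtype=int)
            if arr.shape != (n,):
                raise ValueError(f"{name} length {arr.shape} != atom count {n}")
            setattr(self, name, arr)
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("coordinates must be finite")
        keys = self.atom_keys()
        if len(set(keys)) != n:
            seen, dupes = set(), []
            for k in keys:
                if k in seen:
                    dupes.append(k)
                seen.add(k)
            raise ValueError(f"duplicate atom identities: {dupes[:5]}")

    @property
    def n_atoms(self) -> int:
        return self.xyz.shape[0]

    def atom_keys(self) -> list[tuple]:
        """(chain, resnum, icode, atom_name) identity tuples, in atom order."""
        return list(
            zip(self.chain_ids, self.res_numbers.tolist(), self.icodes,
                self.atom_names)
        )

    def residue_keys(self) -> list[tuple]:
        """Unique (chain, resnum, icode, resname) in first-appearance order."""
        seen: dict[tuple, None] = {}
        for c, r, i, rn in zip(self.chain_ids, self.res_numbers.tolist(),
                               self.icodes, self.res_names):
            seen.setdefault((c, r, i, rn))
        return list(seen)

    def subset(self, mask: np.ndarray) -> "StructureModel":
        mask = np.asarray(mask)
        return StructureModel(
            model_id=self.model_id,
            chain_ids=self.chain_ids[mask],
            res_numbers=self.res_numbers[mask],
            icodes=self.icodes[mask],
            res_names=self.res_names[mask],
            atom_names=self.atom_names[mask],
            elements=self.elements[mask],
            xyz=self.xyz[mask],
        )

    def with_xyz(self, xyz: np.ndarray) -> "StructureModel":
        return StructureModel(
            model_id=self.model_id,
            chain_ids=self.chain_ids,
            res_numbers=self.res_numbers,
            icodes=self.icodes,
            res_names=self.res_names,
            atom_names=self.atom_names,
            elements=self.elements,
            xyz=np.asarray(xyz, dtype=float),
        )

    def find_atom(self, chain: str, res_number: int, atom_name: str,
                  icode: str = "") -> int:
        """Index of one atom; raises KeyError naming the atom if absent."""
        hit = np.flatnonzero(
            (self.chain_ids == chain)
            & (self.res_numbers == res_number)
            & (self.icodes == icode)
            & (self.atom_names == atom_name)
        )
        if hit.size == 0:
            raise KeyError(
                f"atom not found: chain={chain!r} res={res_number}{icode} "
                f"name={atom_name!r}"
            )
        return int(hit[0])


@dataclass
class Ensemble:
    """Ordered collection of models, optionally with shared atom identity."""

    models: list[StructureModel]
    shared_topology: bool = False

    def __post_init__(self) -> None:
        if self.shared_topology and len(self.models) > 1:
            ref = self.models[0].atom_keys()
            for m in self.models[1:]:
                if m.atom_keys() != ref:
                    raise ValueError(
                        f"model {m.model_id} atom identities differ from "
                        f"model {self.models[0].model_id} "
                        "(shared_topology demanded)"
                    )

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return Ensemble(self.models[i], shared_topology=self.shared_topology)
        return self.models[i]

    def coords(self) -> np.ndarray:
        """Stack coordinates as (n_models, n_atoms, 3); needs shared topology."""
        if not self.shared_topology:
            raise ValueError("coords() requires shared_topology")
        return np.stack([m.xyz for m in self.models])


@dataclass(frozen=True)
class AtomSelection:
    """Declarative atom predicate.

    Fields left as None place no constraint.  ``atom_class`` picks one of
    the standard atom-name classes; ``atom_names`` supplies an explicit
    named-list (implies atom_class='named-list').
    """

    chain: str | None = None
    res_min: int | None = None
    res_max: int | None = None
    res_names: frozenset[str] | None = None
    atom_class: str = "all"
    atom_names: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.atom_class not in ATOM_CLASSES:
            raise ValueError(f"unknown atom class {self.atom_class!r}; "
                             f"one of {ATOM_CLASSES}")
        if self.atom_class == "named-list" and not self.atom_names:
            raise ValueError("named-list selection requires atom_names")

    def mask(self, m: StructureModel) -> np.ndarray:
        keep = np.ones(m.n_atoms, dtype=bool)
        if self.chain is not None:
            keep &= m.chain_ids == self.chain
        if self.res_min is not None:
            keep &= m.res_numbers >= self.res_min
        if self.res_max is not None:
            keep &= m.res_numbers <= self.res_max
        if self.res_names is not None:
            keep &= np.isin(m.res_names, list(self.res_names))
        keep &= self._name_mask(m)
        return keep

    def _name_mask(self, m: StructureModel) -> np.ndarray:
        cls = self.atom_class
        if cls == "all":
            return np.ones(m.n_atoms, dtype=bool)
        heavy = m.elements != "H"
        if cls == "all-heavy":
            return heavy
        if cls == "backbone-no-O":
            return np.isin(m.atom_names, list(_BB_NO_O))
        if cls == "backbone-with-O":
            return np.isin(m.atom_names, list(_BB_WITH_O))
        if cls == "CA":
            return m.atom_names == "CA"
        if cls == "side-chain-heavy":
            return heavy & ~np.isin(m.atom_names,
                                    list(_BB_WITH_O | {"OXT"}))
        # named-list
        return np.isin(m.atom_names, list(self.atom_names))

    def indices(self, m: StructureModel) -> np.ndarray:
        return np.flatnonzero(self.mask(m))


_CLASS_ALIASES = {
    "all": "all",
    "all-heavy": "all-heavy",
    "heavy": "all-heavy",
    "backbone": "backbone-no-O",
    "backbone-no-o": "backbone-no-O",
    "backbone-with-o": "backbone-with-O",
    "ca": "CA",
    "calpha": "CA",
    "sidechain": "side-chain-heavy",
    "side-chain-heavy": "side-chain-heavy",
}


def parse_selection(text: str) -> AtomSelection:
    """Parse compact CLI selection syntax.

    ``CHAIN[:RANGE][:CLASS]`` where RANGE is ``start-end`` or a single
    residue number and CLASS one of the atom-class aliases, e.g.
    ``"A:backbone"``, ``"C:all-heavy"``, ``"A:150-155"``,
    ``"C:55-64:sidechain"``, ``"*:ca"``.
    """
    parts = [p.strip() for p in text.split(":")]
    chain: str | None = None
    res_min = res_max = None
    atom_class = "all"

    if parts and parts[0]:
        chain = None if parts[0] == "*" else parts[0]
    rest = parts[1:]
    for token in rest:
        if not token:
            continue
        low = token.lower()
        if low in _CLASS_ALIASES:
            atom_class = _CLASS_ALIASES[low]
        else:
            rng = token.split("-")
            try:
                if len(rng) == 1:
                    res_min = res_max = int(rng[0])
                elif len(rng) == 2:
                    res_min, res_max = int(rng[0]), int(rng[1])
                else:
                    raise ValueError
            except ValueError:
                raise ValueError(
                    f"cannot parse selection token {token!r} in {text!r}"
                ) from None
    return AtomSelection(chain=chain, res_min=res_min, res_max=res_max,
                         atom_class=atom_class)
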