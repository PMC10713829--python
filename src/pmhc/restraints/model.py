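"""Restraint, score-table, and clustering parameter containers."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from ..structio.model import AtomSelection

__all__ = ["AtomRef", "NoeRestraint", "RestraintTable", "DecoyScores",
           "RestraintViolation", "ViolationReport", "ClusterParams"]


@dataclass(frozen=True)
class AtomRef:
    """One concrete atom in a restraint group; chain=None means 'any chain,
    resolved by residue number' (the AtomPair dialect carries no chain)."""

    res_number: int
    atom_name: str
    chain: str | None = None


@dataclass
class NoeRestraint:
    """Ambiguous flat-bottom distance bound between two atom groups."""

    group_a: tuple[AtomRef, ...]
    group_b: tuple[AtomRef, ...]
    lower_bound: float
    upper_bound: float
    width: float  # BOUNDED sd / padding column
    label: str

    def __post_init__(self) -> None:
        if not self.group_a or not self.group_b:
            raise ValueError(f"restraint {self.label!r}: empty atom group")
        if not (0.0 <= self.lower_bound <= self.upper_bound):
            raise ValueError(
                f"restraint {self.label!r}: need 0 <= lb <= ub, got "
                f"{self.lower_bound}..{self.upper_bound}"
            )


@dataclass
class RestraintTable:
    restraints: list[NoeRestraint]
    provenance: str = ""

    def __post_init__(self) -> None:
        labels = [r.label for r in self.restraints]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate restraint labels: {dupes}")

    def __len__(self) -> int:
        return len(self.restraints)

    def __iter__(self):
        return iter(self.restraints)


@dataclass
class DecoyScores:
    """Per-decoy total energies (Rosetta energy units), tag-keyed."""

    tags: list[str]
    energies: list[float]
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.tags) != len(self.energies):
            raise ValueError("tags and energies must align")
        if len(set(self.tags)) != len(self.tags):
            raise ValueError("decoy tags must be unique")
        if any(not math.isfinite(e) for e in self.energies):
            raise ValueError("non-finite decoy energy")

    def __len__(self) -> int:
        return len(self.tags)

    def energy_of(self, tag: str) -> float:
        return self.energies[self.tags.index(tag)]


@dataclass
class RestraintViolation:
    label: str
    effective_distance: float
    excess: float  # Å beyond the tolerated bound; > 0 iff violated
    violated: bool
    kind: str = "upper"  # 'upper' | 'lower'


@dataclass
class ViolationReport:
    tag: str
    records: list[RestraintViolation]

    @property
    def n_violated(self) -> int:
        return sum(r.violated for r in self.records)


@dataclass
class ClusterParams:
    radius: float = 2.3
    top_n: int = 500
    max_clusters: int = 5
    max_cluster_size: int = 10
    selection: AtomSelection = field(
        default_factory=lambda: AtomSelection(atom_class="backbone-no-O"))
    # superpose each pair over this selection before measuring RMSD;
    # None keeps the decoys' common (receptor) frame so rigid peptide
    # displacement is not erased by the fit
    fit_selection: AtomSelection | None = None

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        for name in ("top_n", "max_clusters", "max_cluster_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
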