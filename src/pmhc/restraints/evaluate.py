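"""Effective distances, violation reports, decoy filtering, and landscapes."""

from __future__ import annotations

import logging

import numpy as np

from ..structio.model import AtomSelection, Ensemble, StructureModel
from ..structio.superpose import rmsd, superpose
from .model import (AtomRef, DecoyScores, NoeRestraint, RestraintTable,
                    RestraintViolation, ViolationReport)

__all__ = ["effective_distance", "evaluate_violations", "filter_decoys",
           "energy_landscape"]

log = logging.getLogger(__name__)


def _resolve(m: StructureModel, ref: AtomRef) -> np.ndarray:
    mask = (m.res_numbers == ref.res_number) & (m.atom_names == ref.atom_name)
    if ref.chain is not None:
        mask &= m.chain_ids == ref.chain
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise KeyError(
            f"atom not found in model {m.model_id}: res {ref.res_number} "
            f"atom {ref.atom_name!r}"
            + (f" chain {ref.chain!r}" if ref.chain else "")
        )
    return m.xyz[idx[0]]


def effective_distance(m: StructureModel, r: NoeRestraint,
                       mode: str = "r6") -> float:
    """Ambiguous group distance in Å.

    ``r6`` (default): d_eff = (sum_ab d_ab^-6)^(-1/6) — standard NOE
    averaging; reduces to the plain distance for 1x1 groups.  ``min``:
    closest pair instead (`--group-min`).
    """
    xa = np.array([_resolve(m, a) for a in r.group_a])
    xb = np.array([_resolve(m, b) for b in r.group_b])
    d = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=2).ravel()
    if np.any(d <= 0):
        raise ValueError(f"coincident atoms in restraint {r.label!r}")
    if mode == "min":
        return float(d.min())
    if mode != "r6":
        raise ValueError(f"unknown averaging mode {mode!r}")
    return float(np.sum(d ** -6.0) ** (-1.0 / 6.0))


def _evaluate_model(m: StructureModel, t: RestraintTable, tolerance: float,
                    mode: str, tag: str) -> ViolationReport:
    records = []
    for r in t:
        d = effective_distance(m, r, mode=mode)
        excess_up = d - (r.upper_bound + tolerance)
        excess_lo = (r.lower_bound - tolerance) - d
        if excess_up > 0:
            records.append(RestraintViolation(r.label, d, excess_up, True,
                                              "upper"))
        elif excess_lo > 0:
            records.append(RestraintViolation(r.label, d, excess_lo, True,
                                              "lower"))
        else:
            records.append(RestraintViolation(r.label, d, 0.0, False))
    return ViolationReport(tag=tag, records=records)


def evaluate_violations(models, t: RestraintTable, tolerance: float = 0.5,
                        mode: str = "r6", tags: list[str] | None = None):
    """Violation report(s) for one model or every model of an ensemble.

    A restraint is violated iff d_eff > ub + tolerance (or d_eff <
    lb - tolerance); the excess beyond the tolerated bound is recorded.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    if isinstance(models, StructureModel):
        tag = tags[0] if tags else f"model{models.model_id}"
        return _evaluate_model(models, t, tolerance, mode, tag)
    reports = []
    for i, m in enumerate(models):
        tag = tags[i] if tags else f"model{m.model_id}"
        reports.append(_evaluate_model(m, t, tolerance, mode, tag))
    return reports


def filter_decoys(scores: DecoyScores,
                  reports: dict[str, ViolationReport] | list[ViolationReport],
                  ) -> DecoyScores:
    """Drop decoys with any violated restraint; sort survivors by energy."""
    if not isinstance(reports, dict):
        reports = {r.tag: r for r in reports}
    missing = [t for t in scores.tags if t not in reports]
    if missing:
        raise KeyError(f"no violation report for decoys: {missing[:5]}")
    keep = [(tag, e) for tag, e in zip(scores.tags, scores.energies)
            if reports[tag].n_violated == 0]
    keep.sort(key=lambda te: te[1])
    return DecoyScores(tags=[t for t, _ in keep],
                       energies=[e for _, e in keep],
                       source=scores.source)


def energy_landscape(scores: DecoyScores, decoys: Ensemble,
                     fit: AtomSelection, report: AtomSelection,
                     ) -> list[tuple[str, float, float]]:
    """(tag, RMSD-to-lowest-energy-decoy, energy) per decoy.

    The reference is the minimum-energy decoy (ties broken by tag order,
    logged); its own point is (0.0, E_min).
    """
    if len(scores) != len(decoys):
        raise ValueError("scores must cover all decoys")
    energies = np.asarray(scores.energies)
    emin = energies.min()
    candidates = np.flatnonzero(energies == emin)
    if candidates.size > 1:
        log.info("energy tie at %.3f REU among %d decoys; using first tag",
                 emin, candidates.size)
    ref_idx = int(candidates[0])
    ref = decoys[ref_idx]
    out = []
    for i, (tag, e) in enumerate(zip(scores.tags, scores.energies)):
        if i == ref_idx:
            out.append((tag, 0.0, float(e)))
            continue
        out.append((tag, rmsd(decoys[i], ref, report, prefit=True,
                              fit_sel=fit), float(e)))
    return out
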