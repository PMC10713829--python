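"""Greedy quality-threshold clustering of docking decoys.

Mirrors the post-docking protocol of clustering the top-N lowest-energy
decoys at a fixed RMSD radius with caps on cluster count and size.  The
exact upstream algorithm is unspecified, so a documented greedy scheme is
used: repeatedly seed a cluster at the unassigned decoy with the most
unassigned neighbors within the radius (ties -> lower energy, then input
order), truncate it to the size cap keeping the lowest-energy members.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ..structio.model import Ensemble
from ..structio.superpose import rmsd
from .model import ClusterParams, DecoyScores

__all__ = ["DecoyCluster", "cluster_decoys", "pairwise_rmsd_matrix"]

log = logging.getLogger(__name__)


@dataclass
class DecoyCluster:
    center_tag: str
    member_tags: list[str]  # includes the center; lowest-energy first
    representative_tag: str  # lowest-energy member


def pairwise_rmsd_matrix(decoys: Ensemble, selection,
                         fit_selection=None) -> np.ndarray:
    n = len(decoys)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = rmsd(
                decoys[i], decoys[j], selection,
                prefit=fit_selection is not None, fit_sel=fit_selection)
    return mat


def cluster_decoys(scores: DecoyScores, decoys: Ensemble,
                   p: ClusterParams) -> list[DecoyCluster]:
    """Cluster the ``p.top_n`` lowest-energy decoys; see module docstring."""
    if len(scores) != len(decoys):
        raise ValueError("scores must cover all decoys")
    order = np.argsort(scores.energies, kind="stable")
    if p.top_n < len(order):
        order = order[: p.top_n]
    else:
        log.info("top_n=%d >= decoy count %d; using all", p.top_n, len(order))
    sub = Ensemble([decoys[int(i)] for i in order],
                   shared_topology=decoys.shared_topology)
    tags = [scores.tags[int(i)] for i in order]
    energies = np.array([scores.energies[int(i)] for i in order])

    dmat = pairwise_rmsd_matrix(sub, p.selection, p.fit_selection)
    within = dmat <= p.radius
    n = len(tags)
    unassigned = np.ones(n, dtype=bool)
    clusters: list[DecoyCluster] = []
    while unassigned.any() and len(clusters) < p.max_clusters:
        counts = (within & unassigned[None, :]).sum(axis=1)
        counts[~unassigned] = -1
        best = counts.max()
        # tie-break: lower energy, then input (energy-sorted tag) order
        cand = np.flatnonzero(counts == best)
        center = int(cand[np.argmin(energies[cand])])
        members = np.flatnonzero(within[center] & unassigned)
        # keep lowest energies when truncating to the size cap
        members = members[np.argsort(energies[members], kind="stable")]
        members = members[: p.max_cluster_size]
        unassigned[members] = False
        member_tags = [tags[int(i)] for i in members]
        clusters.append(DecoyCluster(
            center_tag=tags[center],
            member_tags=member_tags,
            representative_tag=member_tags[0],
        ))
    return clusters
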