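"""Rigid-body superposition, RMSD, ensemble summaries, and RMSF."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import AtomSelection, Ensemble, StructureModel

__all__ = [
    "RigidTransform",
    "FluctProfile",
    "superpose",
    "kabsch",
    "rmsd",
    "ensemble_rmsd_summary",
    "per_atom_rmsf",
]


@dataclass(frozen=True)
class RigidTransform:
    """x -> rotation @ (x - mobile_center) + target_center."""

    rotation: np.ndarray  # (3, 3), proper rotation (det +1)
    mobile_center: np.ndarray
    target_center: np.ndarray

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return (np.asarray(xyz) - self.mobile_center) @ self.rotation.T \
            + self.target_center


@dataclass
class FluctProfile:
    """Per-atom (and per-residue) RMSF in Å."""

    atom_keys: list[tuple]
    rmsf: np.ndarray
    residue_keys: list[tuple]
    residue_rmsf: np.ndarray
    fit_selection: AtomSelection | None = None
    report_selection: AtomSelection | None = None


def kabsch(mobile: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform taking ``mobile`` onto ``target``.

    Closed-form SVD solution with reflection correction so the rotation is
    always proper (determinant +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("need at least 3 atom pairs to superpose")
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    p = mobile - mc
    q = target - tc
    # collinearity check: rank of the centered cloud
    if np.linalg.matrix_rank(p, tol=1e-8) < 2 or \
       np.linalg.matrix_rank(q, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) selection; cannot superpose")
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    return RigidTransform(rotation=rot, mobile_center=mc, target_center=tc)


def _pair_coords(mobile: StructureModel, reference: StructureModel,
                 sel: AtomSelection) -> tuple[np.ndarray, np.ndarray]:
    im = sel.indices(mobile)
    ir = sel.indices(reference)
    if im.size != ir.size:
        raise ValueError(
            f"selection sizes differ: {im.size} (mobile) vs {ir.size} (reference)"
        )
    if im.size == 0:
        raise ValueError("empty selection")
    km = [mobile.atom_keys()[i] for i in im]
    kr = [reference.atom_keys()[i] for i in ir]
    if km != kr:
        raise ValueError("selected atom identities do not correspond")
    return mobile.xyz[im], reference.xyz[ir]


def superpose(mobile: StructureModel, reference: StructureModel,
              fit: AtomSelection) -> tuple[RigidTransform, float]:
    """Optimal rigid fit of ``mobile`` onto ``reference`` over ``fit``.

    Returns the transform and the post-fit RMSD (Å) over the fit selection.
    """
    xm, xr = _pair_coords(mobile, reference, fit)
    tr = kabsch(xm, xr)
    fitted = tr.apply(xm)
    return tr, float(np.sqrt(np.mean(np.sum((fitted - xr) ** 2, axis=1))))


def rmsd(a: StructureModel, b: StructureModel, sel: AtomSelection,
         prefit: bool = False,
         fit_sel: AtomSelection | None = None) -> float:
    """RMSD in Å over ``sel``; with ``prefit`` the models are first superposed
    (over ``fit_sel`` if given, else over ``sel``)."""
    xa, xb = _pair_coords(a, b, sel)
    if prefit:
        tr, _ = superpose(a, b, fit_sel if fit_sel is not None else sel)
        xa = tr.apply(xa)
    return float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))


def ensemble_rmsd_summary(
    e: Ensemble,
    fit: AtomSelection,
    report_backbone: AtomSelection,
    report_heavy: AtomSelection,
    mode: str = "to-reference",
) -> tuple[float, float]:
    """Mean (backbone, all-atom) RMSD characterizing ensemble spread.

    ``to-reference`` (default): every non-reference model is superposed on
    the first model over ``fit``, RMSDs over the two report selections are
    averaged over the other models.  ``pairwise``: mean over all unordered
    model pairs instead.
    """
    if len(e) < 2:
        raise ValueError("ensemble summary needs at least 2 models")
    if mode not in ("to-reference", "pairwise"):
        raise ValueError(f"unknown mode {mode!r}")

    def _one(mob: StructureModel, ref: StructureModel) -> tuple[float, float]:
        tr, _ = superpose(mob, ref, fit)
        fitted = mob.with_xyz(tr.apply(mob.xyz))
        return (rmsd(fitted, ref, report_backbone),
                rmsd(fitted, ref, report_heavy))

    pairs: list[tuple[StructureModel, StructureModel]]
    if mode == "to-reference":
        ref = e[0]
        pairs = [(m, ref) for m in e.models[1:]]
    else:
        pairs = [(e.models[j], e.models[i])
                 for i in range(len(e)) for j in range(i + 1, len(e))]
    vals = np.array([_one(m, r) for m, r in pairs])
    return float(vals[:, 0].mean()), float(vals[:, 1].mean())


def per_atom_rmsf(e: Ensemble, fit: AtomSelection,
                  report: AtomSelection) -> FluctProfile:
    """RMSF about the ensemble-mean position, after one fit iteration.

    Each model is superposed (over ``fit``) on the coordinate mean, the mean
    is recomputed once, and RMSF_i = sqrt(mean_t |x_i(t) - <x_i>|^2) is
    reported over ``report`` atoms.  Per-residue values are means over each
    residue's selected atoms.
    """
    if len(e) < 2:
        raise ValueError("RMSF needs at least 2 models")
    if not e.shared_topology:
        e = Ensemble(e.models, shared_topology=True)
    ref = e[0]
    ifit = fit.indices(ref)
    irep = report.indices(ref)
    if irep.size == 0:
        raise ValueError("empty report selection")
    if ifit.size < 3:
        raise ValueError("fit selection needs >= 3 atoms")

    coords = e.coords()  # (T, N, 3)
    # reference frame chosen order-invariantly: closest to the raw mean
    raw_mean = coords[:, ifit, :].mean(axis=0)
    dev = ((coords[:, ifit, :] - raw_mean) ** 2).sum(axis=(1, 2))
    t0 = int(np.argmin(dev))
    aligned = np.empty_like(coords)
    ref_fit = coords[t0, ifit]
    for t in range(coords.shape[0]):
        tr = kabsch(coords[t, ifit], ref_fit)
        aligned[t] = tr.apply(coords[t])
    mean1 = aligned.mean(axis=0)
    for t in range(coords.shape[0]):
        tr = kabsch(coords[t, ifit], mean1[ifit])
        aligned[t] = tr.apply(coords[t])
    mean2 = aligned.mean(axis=0)

    dev2 = np.sum((aligned - mean2) ** 2, axis=2)  # (T, N)
    rmsf_all = np.sqrt(dev2.mean(axis=0))  # (N,)
    rmsf_rep = rmsf_all[irep]

    keys = ref.atom_keys()
    rep_keys = [keys[i] for i in irep]
    res_of = [(k[0], k[1], k[2]) for k in rep_keys]
    res_order: dict[tuple, list[int]] = {}
    for j, rk in enumerate(res_of):
        res_order.setdefault(rk, []).append(j)
    res_keys = list(res_order)
    res_vals = np.array([rmsf_rep[idx].mean()
                         for idx in res_order.values()])
    return FluctProfile(
        atom_keys=rep_keys,
        rmsf=rmsf_rep,
        residue_keys=res_keys,
        residue_rmsf=res_vals,
        fit_selection=fit,
        report_selection=report,
    )
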