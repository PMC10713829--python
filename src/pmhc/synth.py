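"""Seeded generators with recorded ground truth for every pipeline stage.

Every generator is a pure function of (seed, parameters): repeated calls
are bit-identical.  Where a target proportion must be achieved exactly
(violation counts, cluster occupancies, voxel occupancies), allocation is
deterministic by count rather than sampled, so count-based tests are sharp.

Synthetic structures use a minimal poly-alanine-like topology (N, CA, C, O,
CB per residue) sufficient for selections and RMSD work; no stereochemical
realism is claimed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .dynamics import FrameEnsemble
from .hdx import DEFAULT_TIMEPOINTS, HdxFragmentSeries
from .nmr import (AnisotropySeries, AssayConstants, DecaySeries, MeltCurve,
                  MethylPeak, competition_model, ic50_from_kd)
from .restraints.model import (AtomRef, DecoyScores, NoeRestraint,
                               RestraintTable)
from .structio.model import Ensemble, StructureModel

__all__ = [
    "GroundTruth", "make_chain", "make_complex", "gen_decoy_set",
    "gen_trajectory", "gen_hdx_dataset", "gen_two_state_peaks",
    "gen_decay", "gen_melt", "gen_competition", "gen_waters",
    "DEUTERON_MASS_SHIFT",
]

DEUTERON_MASS_SHIFT = 1.00628  # Da per exchanged deuteron


@dataclass
class GroundTruth:
    """Latent parameters recorded alongside every generated dataset."""

    generator: str
    seed: int
    params: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2,
                                         default=_json_default) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(**d)


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


# ------------------------------------------------------------- structures

# idealized per-residue heavy-atom template, Å (local frame)
_RES_TEMPLATE = (
    ("N", "N", (0.000, 0.000, 0.000)),
    ("CA", "C", (1.458, 0.000, 0.000)),
    ("CB", "C", (1.988, -0.773, 1.205)),
    ("C", "C", (2.009, 1.420, 0.000)),
    ("O", "O", (1.401, 2.440, 0.200)),
)
_RES_SPACING = 3.8  # Å advance along the chain axis


def make_chain(chain_id: str, n_res: int, start_res: int = 1,
               origin=(0.0, 0.0, 0.0), res_name: str = "ALA",
               model_id: int = 0) -> StructureModel:
    """Idealized extended chain of identical residues."""
    chains, nums, icodes, rnames, anames, elems, xyz = \
        [], [], [], [], [], [], []
    origin = np.asarray(origin, dtype=float)
    for i in range(n_res):
        base = origin + np.array([i * _RES_SPACING, 0.6 * (i % 2), 0.0])
        for name, elem, rel in _RES_TEMPLATE:
            chains.append(chain_id)
            nums.append(start_res + i)
            icodes.append("")
            rnames.append(res_name)
            anames.append(name)
            elems.append(elem)
            xyz.append(base + np.asarray(rel))
    return StructureModel(
        model_id=model_id,
        chain_ids=np.array(chains, dtype=object),
        res_numbers=np.array(nums, dtype=int),
        icodes=np.array(icodes, dtype=object),
        res_names=np.array(rnames, dtype=object),
        atom_names=np.array(anames, dtype=object),
        elements=np.array(elems, dtype=object),
        xyz=np.array(xyz, dtype=float),
    )


def _concat_models(models: list[StructureModel],
                   model_id: int = 0) -> StructureModel:
    return StructureModel(
        model_id=model_id,
        chain_ids=np.concatenate([m.chain_ids for m in models]),
        res_numbers=np.concatenate([m.res_numbers for m in models]),
        icodes=np.concatenate([m.icodes for m in models]),
        res_names=np.concatenate([m.res_names for m in models]),
        atom_names=np.concatenate([m.atom_names for m in models]),
        elements=np.concatenate([m.elements for m in models]),
        xyz=np.vstack([m.xyz for m in models]),
    )


def make_complex(receptor_res: int = 12, peptide_res: int = 10,
                 peptide_start: int = 55) -> StructureModel:
    """Minimal receptor (chain A) + peptide (chain C) complex; the peptide
    runs parallel to the receptor 4.5 Å away."""
    receptor = make_chain("A", receptor_res, start_res=1)
    peptide = make_chain("C", peptide_res, start_res=peptide_start,
                         origin=(2.0, 4.5, 1.0))
    return _concat_models([receptor, peptide])


def _peptide_mask(m: StructureModel, chain: str = "C") -> np.ndarray:
    return m.chain_ids == chain


# ------------------------------------------------------------- decoy sets

def gen_decoy_set(seed: int, n: int = 100, funnel_slope: float = 10.0,
                  violation_fraction: float = 0.0,
                  reference: StructureModel | None = None,
                  energy_noise: float = 2.0,
                  ) -> tuple[Ensemble, DecoyScores, RestraintTable,
                             GroundTruth]:
    """Funnel-shaped decoy population with an exact count of injected
    restraint violators.

    Non-violators keep the restrained peptide atom near the receptor;
    violators have the whole peptide displaced 10 Å so the shipped
    restraint breaks.  Pseudo-energy = slope * peptide RMSD + noise.
    """
    if n < 10:
        raise ValueError("need n >= 10 decoys")
    if not (0.0 <= violation_fraction <= 1.0):
        raise ValueError("violation_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    ref = reference if reference is not None else make_complex()
    pep = _peptide_mask(ref)
    n_viol = round(n * violation_fraction)
    violators = np.zeros(n, dtype=bool)
    violators[:n_viol] = True
    rng.shuffle(violators)

    pep_res = sorted(set(ref.res_numbers[pep].tolist()))
    rec_res = sorted(set(ref.res_numbers[~pep].tolist()))
    # restraint between mid-peptide CB and the facing receptor CB
    r_pep = pep_res[len(pep_res) // 2]
    r_rec = rec_res[min(len(rec_res) - 1, r_pep - pep_res[0])]
    i_pep = ref.find_atom("C", r_pep, "CB")
    i_rec = ref.find_atom("A", r_rec, "CB")
    d0 = float(np.linalg.norm(ref.xyz[i_pep] - ref.xyz[i_rec]))
    restraint = NoeRestraint(
        group_a=(AtomRef(r_rec, "CB", "A"),),
        group_b=(AtomRef(r_pep, "CB", "C"),),
        lower_bound=1.5, upper_bound=d0 + 2.0, width=0.5, label="noe1",
    )

    models, tags, energies, true_rmsd = [], [], [], []
    for i in range(n):
        xyz = ref.xyz.copy()
        jitter_scale = rng.uniform(0.05, 1.5)
        xyz[pep] += rng.normal(0.0, jitter_scale, size=(pep.sum(), 3))
        # pin the restrained atom near its reference position so only the
        # programmed violators can break the restraint (counts stay exact)
        xyz[i_pep] = ref.xyz[i_pep] + rng.normal(0.0, 0.1, size=3)
        if violators[i]:
            xyz[pep] += np.array([0.0, 0.0, 10.0])
        rms = float(np.sqrt(np.mean(
            np.sum((xyz[pep] - ref.xyz[pep]) ** 2, axis=1))))
        m = ref.with_xyz(xyz)
        m.model_id = i
        models.append(m)
        tags.append(f"decoy_{i:04d}")
        energies.append(funnel_slope * rms + rng.normal(0.0, energy_noise))
        true_rmsd.append(rms)
    truth = GroundTruth("gen_decoy_set", seed, {
        "n": n, "funnel_slope": funnel_slope,
        "violation_fraction": violation_fraction,
        "n_violators": int(n_viol),
        "violator_tags": [t for t, v in zip(tags, violators) if v],
        "true_rmsd": true_rmsd,
    })
    return (Ensemble(models, shared_topology=True),
            DecoyScores(tags=tags, energies=energies, source="gen_decoy_set"),
            RestraintTable([restraint], provenance="gen_decoy_set"),
            truth)


# ------------------------------------------------------------ trajectories

def gen_trajectory(seed: int, n_frames: int = 100,
                   backbone_proportions: tuple[float, ...] = (0.7, 0.3),
                   rotamer_states: int = 1,
                   thermal_sigma: float = 0.1,
                   state_separation: float = 3.0,
                   rotamer_separation: float = 3.0,
                   n_replicates: int = 1,
                   ) -> tuple[FrameEnsemble, GroundTruth]:
    """Switching trajectory over programmed backbone (and nested rotamer)
    states plus isotropic Gaussian jitter.

    Backbone states are rigid peptide translations ``state_separation``
    apart; rotamer states displace the peptide CB atoms.  State counts are
    allocated exactly per proportion, then the frame order is shuffled by
    the seeded generator; the true per-frame state sequence is recorded.
    """
    props = np.asarray(backbone_proportions, dtype=float)
    if not np.isclose(props.sum(), 1.0):
        raise ValueError("backbone proportions must sum to 1")
    if min(state_separation, rotamer_separation) < 3.0 * thermal_sigma:
        warnings.warn("state separation < 3x jitter: cluster recovery not "
                      "guaranteed", stacklevel=2)
    rng = np.random.default_rng(seed)
    ref = make_complex()
    pep = _peptide_mask(ref)
    cb = pep & (ref.atom_names == "CB")

    counts = _exact_counts(props, n_frames)
    base_states = np.repeat(np.arange(props.size), counts)

    models, reps, bb_seq, rot_seq = [], [], [], []
    frame_id = 0
    for rep in range(n_replicates):
        states = base_states.copy()
        rng.shuffle(states)
        rot = np.zeros(n_frames, dtype=int)
        if rotamer_states > 1:
            # even rotamer split within each backbone state, exact by count
            for s in range(props.size):
                idx = np.flatnonzero(states == s)
                rcounts = _exact_counts(
                    np.full(rotamer_states, 1.0 / rotamer_states), idx.size)
                labels = np.repeat(np.arange(rotamer_states), rcounts)
                rng.shuffle(labels)
                rot[idx] = labels
        for t in range(n_frames):
            xyz = ref.xyz.copy()
            xyz[pep] += np.array([0.0, states[t] * state_separation, 0.0])
            xyz[cb] += np.array([0.0, 0.0, rot[t] * rotamer_separation])
            xyz[pep] += rng.normal(0.0, thermal_sigma, size=(pep.sum(), 3))
            m = ref.with_xyz(xyz)
            m.model_id = frame_id
            frame_id += 1
            models.append(m)
            reps.append(f"rep{rep + 1}")
        bb_seq.extend(states.tolist())
        rot_seq.extend(rot.tolist())
    truth = GroundTruth("gen_trajectory", seed, {
        "n_frames": n_frames, "n_replicates": n_replicates,
        "backbone_proportions": props.tolist(),
        "rotamer_states": rotamer_states,
        "thermal_sigma": thermal_sigma,
        "state_separation": state_separation,
        "rotamer_separation": rotamer_separation,
        "backbone_state_sequence": bb_seq,
        "rotamer_state_sequence": rot_seq,
    })
    fe = FrameEnsemble(frames=Ensemble(models, shared_topology=True),
                       replicate_ids=reps)
    return fe, truth


def _exact_counts(props: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder allocation of ``total`` items to proportions."""
    raw = props * total
    counts = np.floor(raw).astype(int)
    short = total - counts.sum()
    if short:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


# -------------------------------------------------------------------- HDX

def gen_hdx_dataset(seed: int, protein_length: int = 30,
                    fragments: tuple[tuple[int, int], ...] | None = None,
                    base_rate: float = 0.02,
                    protected_span: tuple[int, int] | None = (11, 20),
                    protection_factor: float = 100.0,
                    d_frac: float = 0.8,
                    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS,
                    noise_sd: float = 0.0, n_replicates: int = 3,
                    protein: str = "prot",
                    ) -> tuple[list[HdxFragmentSeries], GroundTruth]:
    """Per-residue exchange forward model.

    u_i(t) = d_frac * (1 - exp(-k_i t)), k_i = base_rate except inside the
    protected span where k_i = base_rate / protection_factor.  Fragment
    centroid = m0 + sum_i u_i(t) * Dm + replicate noise; the all-D
    reference is m0 + d_frac * n_res * Dm, so span-corrected uptake
    saturates at 100%.
    """
    if fragments is None:
        fragments = tuple((s, min(s + 9, protein_length))
                          for s in range(1, protein_length, 5))
    if not fragments:
        raise ValueError("empty fragment tiling")
    rng = np.random.default_rng(seed)
    k = np.full(protein_length, base_rate)
    if protected_span is not None:
        lo, hi = protected_span
        k[lo - 1:hi] = base_rate / protection_factor
    frags = []
    for start, end in fragments:
        if not (1 <= start <= end <= protein_length):
            raise ValueError(f"fragment {start}-{end} outside protein")
        n_res = end - start + 1
        m0 = 800.0 + 110.0 * n_res  # arbitrary but plausible centroid
        m100 = m0 + d_frac * n_res * DEUTERON_MASS_SHIFT
        obs = []
        for t in timepoints:
            if t == 0:
                continue
            uptake = float(np.sum(
                d_frac * (1.0 - np.exp(-k[start - 1:end] * t))))
            for r in range(n_replicates):
                noisy = m0 + uptake * DEUTERON_MASS_SHIFT + (
                    rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                obs.append((float(t), f"rep{r + 1}", float(noisy)))
        frags.append(HdxFragmentSeries(
            protein=protein, start=start, end=end,
            sequence="A" * n_res, m0=m0, m100=m100, observations=obs))
    truth = GroundTruth("gen_hdx_dataset", seed, {
        "protein_length": protein_length,
        "fragments": [list(f) for f in fragments],
        "base_rate": base_rate,
        "protected_span": list(protected_span) if protected_span else None,
        "protection_factor": protection_factor,
        "d_frac": d_frac, "noise_sd": noise_sd,
        "rates": k.tolist(),
    })
    return frags, truth


# -------------------------------------------------------------- NMR peaks

def gen_two_state_peaks(seed: int, n_probes: int = 10,
                        outliers: dict[str, float] | None = None,
                        broadened: dict[str, float] | None = None,
                        background_csp: float = 0.01,
                        noise: float = 0.0,
                        ) -> tuple[list[MethylPeak], list[MethylPeak],
                                   GroundTruth]:
    """Free/bound peak lists with programmed CSP outliers and broadened
    probes.  ``outliers`` maps probe name -> injected 1H shift change (ppm);
    ``broadened`` maps probe name -> intensity ratio drop factor."""
    outliers = outliers or {}
    broadened = broadened or {}
    overlap = set(outliers) & set(broadened)
    if overlap:
        raise ValueError(f"outlier and broadened sets overlap: {overlap}")
    rng = np.random.default_rng(seed)
    probes = [f"M{i + 1}" for i in range(n_probes)]
    unknown = (set(outliers) | set(broadened)) - set(probes)
    if unknown:
        raise ValueError(f"programmed probes not in the set: {unknown}")
    free, bound = [], []
    for p in probes:
        dh0 = float(rng.uniform(0.5, 1.5))
        dc0 = float(rng.uniform(10.0, 25.0))
        dh_shift = outliers.get(p, background_csp) + (
            rng.normal(0.0, noise) if noise > 0 else 0.0)
        # broadened probes lose intensity in the first (empty/free) state,
        # dropping the free/bound intensity ratio below the flagging line
        i_free = 1.0 / broadened[p] if p in broadened else 1.0
        i_bound = 1.0
        free.append(MethylPeak(probe=p, delta_h=dh0, delta_c=dc0,
                               intensity=i_free, state="free"))
        bound.append(MethylPeak(probe=p, delta_h=dh0 + dh_shift,
                                delta_c=dc0, intensity=i_bound,
                                state="bound"))
    truth = GroundTruth("gen_two_state_peaks", seed, {
        "n_probes": n_probes, "outliers": dict(outliers),
        "broadened": dict(broadened), "background_csp": background_csp,
        "noise": noise,
    })
    return free, bound, truth


# ----------------------------------------------------- decay / melt / IC50

def gen_decay(seed: int, t_half: float = 3.7, i0: float = 1.0,
              plateau: float = 0.1, t_max: float = 9.0, dt: float = 1.0,
              noise: float = 0.0, probe: str = "K61",
              ) -> tuple[DecaySeries, GroundTruth]:
    """Single-phase decay sampled on a regular grid (default 0..9 h)."""
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, t_max + dt / 2.0, dt)
    k = np.log(2.0) / t_half
    y = plateau + (i0 - plateau) * np.exp(-k * t)
    if noise > 0:
        y = y + rng.normal(0.0, noise * (i0 - plateau), size=y.shape)
    truth = GroundTruth("gen_decay", seed, {
        "t_half": t_half, "i0": i0, "plateau": plateau, "noise": noise,
    })
    return DecaySeries(times=t, intensities=y, probe=probe), truth


def gen_melt(seed: int, t_m: float = 53.0, slope: float = 2.5,
             f_min: float = 0.05, f_max: float = 1.0,
             t_range: tuple[float, float] = (25.0, 95.0), dt: float = 1.0,
             noise: float = 0.0, label: str = "",
             ) -> tuple[MeltCurve, GroundTruth]:
    """Boltzmann sigmoid melt curve over the scanned range."""
    rng = np.random.default_rng(seed)
    t = np.arange(t_range[0], t_range[1] + dt / 2.0, dt)
    y = f_min + (f_max - f_min) / (1.0 + np.exp((t_m - t) / slope))
    if noise > 0:
        y = y + rng.normal(0.0, noise * (f_max - f_min), size=y.shape)
    truth = GroundTruth("gen_melt", seed, {
        "t_m": t_m, "slope": slope, "f_min": f_min, "f_max": f_max,
        "noise": noise,
    })
    return MeltCurve(temperatures=t, fluorescence=y, label=label), truth


def gen_competition(seed: int, ic50: float = 0.26,
                    concentrations: tuple[float, ...] = (0.0, 0.25, 4.0, 25.0),
                    r_max: float = 0.20, r_min: float = 0.05,
                    n_replicates: int = 1, noise: float = 0.0,
                    constants: AssayConstants | None = None,
                    ) -> tuple[AnisotropySeries, GroundTruth]:
    """Competitive-anisotropy titration whose true IC50 is programmed.

    The competitor Kd is numerically inverted from the requested IC50
    under the one-site two-ligand equilibrium, then anisotropy is forward
    modeled (optionally with replicate noise).  Concentrations in uM.
    """
    from scipy.optimize import brentq

    constants = constants or AssayConstants()
    rng = np.random.default_rng(seed)

    def ic50_err(log_kd):
        return ic50_from_kd(np.exp(log_kd), constants) - ic50

    log_kd = brentq(ic50_err, np.log(1e-6), np.log(1e4), xtol=1e-13)
    kd_c = float(np.exp(log_kd))
    fb0 = competition_model(constants.receptor_total, constants.tracer_total,
                            0.0, constants.tracer_kd, kd_c)
    conc_out, r_out = [], []
    for c in concentrations:
        fb = competition_model(constants.receptor_total,
                               constants.tracer_total, float(c),
                               constants.tracer_kd, kd_c)
        r = r_min + (r_max - r_min) * fb / fb0
        for _ in range(n_replicates):
            val = r + (rng.normal(0.0, noise * (r_max - r_min))
                       if noise > 0 else 0.0)
            conc_out.append(float(c))
            r_out.append(float(val))
    truth = GroundTruth("gen_competition", seed, {
        "ic50": ic50, "competitor_kd": kd_c, "r_max": r_max, "r_min": r_min,
        "noise": noise, "concentrations": list(concentrations),
        "constants": asdict(constants),
    })
    order = np.argsort(conc_out, kind="stable")
    return AnisotropySeries(
        concentrations=np.asarray(conc_out)[order],
        anisotropy=np.asarray(r_out)[order]), truth


# ------------------------------------------------------------------ waters

def gen_waters(seed: int, occupancies: dict[tuple[int, int, int], float],
               n_frames: int = 10, spacing: float = 1.0,
               ) -> tuple[FrameEnsemble, GroundTruth]:
    """Frames whose water oxygens realize the target voxel occupancies
    exactly by count.

    ``occupancies`` maps integer voxel indices (relative to the receptor
    neighborhood grid) to target fractions; each water sits exactly at its
    voxel center for round(occ * n_frames) evenly spread frames.  When the
    exact allocation is impossible the nearest achievable fraction is used
    and reported in the ground truth.
    """
    receptor = make_chain("A", 6, start_res=150)
    achieved: dict[str, float] = {}
    frame_waters: list[list[np.ndarray]] = [[] for _ in range(n_frames)]
    # voxel (i,j,k) center in the grid anchored at the padded receptor corner
    pad = 5.0 + 1.0
    lo = receptor.xyz.min(axis=0) - pad
    origin = np.floor(lo / spacing) * spacing
    for (i, j, k), occ in sorted(occupancies.items()):
        if not (0.0 <= occ <= 1.0):
            raise ValueError(f"occupancy out of range for voxel {(i, j, k)}")
        n_present = round(occ * n_frames)
        achieved[f"{i},{j},{k}"] = n_present / n_frames
        center = origin + spacing * (np.array([i, j, k], dtype=float) + 0.5)
        # evenly spread presence across frames (deterministic)
        present = np.unique(
            np.floor(np.arange(n_present) * n_frames / max(n_present, 1))
            .astype(int)) if n_present else np.array([], dtype=int)
        for t in present:
            frame_waters[t].append(center)
    models = []
    # at least one (parked) water so solvent topology is always present
    max_waters = max(max((len(w) for w in frame_waters), default=0), 1)
    for t in range(n_frames):
        waters = frame_waters[t]
        # park unused waters far away so topology is shared across frames
        coords = list(waters) + [
            np.array([500.0 + 10.0 * q, 500.0, 500.0])
            for q in range(max_waters - len(waters))
        ]
        parts = [receptor]
        if coords:
            parts.append(StructureModel(
                model_id=t,
                chain_ids=np.array(["W"] * len(coords), dtype=object),
                res_numbers=np.arange(1, len(coords) + 1),
                icodes=np.array([""] * len(coords), dtype=object),
                res_names=np.array(["HOH"] * len(coords), dtype=object),
                atom_names=np.array(["O"] * len(coords), dtype=object),
                elements=np.array(["O"] * len(coords), dtype=object),
                xyz=np.array(coords, dtype=float),
            ))
        m = _concat_models(parts, model_id=t)
        models.append(m)
    truth = GroundTruth("gen_waters", seed, {
        "n_frames": n_frames, "spacing": spacing,
        "target": {f"{i},{j},{k}": v for (i, j, k), v in occupancies.items()},
        "achieved": achieved,
        "grid_origin": origin.tolist(),
    })
    return FrameEnsemble(frames=Ensemble(models, shared_topology=True)), truth
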