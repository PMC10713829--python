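"""Ramachandran classification against shipped 2-degree region masks.

The favored/allowed regions are coarse polygonal approximations of the
Top500 empirical contours of Lovell et al. (2003) *Proteins* 50:437-450,
rasterized onto a 2 x 2 degree grid per residue class.  They reproduce the
standard alpha / beta / left-handed-alpha (and polyproline) regions but are
NOT a bit-exact copy of any validation server's tables; treat labels as
approximate.  Classification is deterministic and periodic in both angles.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .model import StructureModel
from .dihedrals import backbone_dihedrals, wrap_angle

__all__ = ["ramachandran_classify", "RESIDUE_CLASSES", "residue_class_of",
           "ramachandran_table"]

RESIDUE_CLASSES = ("general", "glycine", "proline", "pre-proline")

_GRID_STEP = 2.0  # degrees
_NBINS = int(360 / _GRID_STEP)

# Polygons as (phi, psi) vertex lists, degrees. Favored is checked first;
# allowed polygons may overlap favored ones.
_FAVORED: dict[str, list[list[tuple[float, float]]]] = {
    "general": [
        # beta / extended
        [(-180, 80), (-50, 80), (-50, 180), (-180, 180)],
        [(-180, -180), (-50, -180), (-50, -170), (-180, -170)],
        # right-handed alpha
        [(-160, -70), (-45, -70), (-45, -10), (-160, -10)],
        # left-handed alpha
        [(45, 0), (65, 0), (65, 65), (45, 65)],
    ],
    "glycine": [
        [(-180, 110), (-40, 110), (-40, 180), (-180, 180)],
        [(40, -180), (180, -180), (180, -110), (40, -110)],
        [(-140, -70), (-40, -70), (-40, 20), (-140, 20)],
        [(40, -20), (140, -20), (140, 70), (40, 70)],
        [(-180, -180), (-40, -180), (-40, -170), (-180, -170)],
        [(40, 170), (180, 170), (180, 180), (40, 180)],
    ],
    "proline": [
        [(-95, 100), (-40, 100), (-40, 180), (-95, 180)],
        [(-95, -65), (-40, -65), (-40, -5), (-95, -5)],
    ],
    "pre-proline": [
        [(-180, 80), (-50, 80), (-50, 180), (-180, 180)],
        [(-160, -70), (-45, -70), (-45, -10), (-160, -10)],
        [(45, 0), (65, 0), (65, 65), (45, 65)],
    ],
}

_ALLOWED: dict[str, list[list[tuple[float, float]]]] = {
    "general": [
        [(-180, 45), (-40, 45), (-40, 180), (-180, 180)],
        [(-180, -180), (-40, -180), (-40, -150), (-180, -150)],
        [(-180, -90), (-35, -90), (-35, 10), (-180, 10)],
        [(30, -20), (90, -20), (90, 90), (30, 90)],
        [(-180, 180), (-180, 180)],  # degenerate, keeps shape list non-empty
    ],
    "glycine": [
        [(-180, 90), (-30, 90), (-30, 180), (-180, 180)],
        [(30, -180), (180, -180), (180, -90), (30, -90)],
        [(-180, -90), (-30, -90), (-30, 40), (-180, 40)],
        [(30, -40), (180, -40), (180, 90), (30, 90)],
        [(-180, -180), (-30, -180), (-30, -150), (-180, -150)],
        [(30, 150), (180, 150), (180, 180), (30, 180)],
    ],
    "proline": [
        [(-110, 80), (-35, 80), (-35, 180), (-110, 180)],
        [(-110, -80), (-35, -80), (-35, 15), (-110, 15)],
        [(-110, -180), (-35, -180), (-35, -160), (-110, -160)],
    ],
    "pre-proline": [
        [(-180, 45), (-40, 45), (-40, 180), (-180, 180)],
        [(-180, -90), (-35, -90), (-35, 10), (-180, 10)],
        [(30, -20), (90, -20), (90, 90), (30, 90)],
        [(-180, -180), (-40, -180), (-40, -150), (-180, -150)],
    ],
}


def _point_in_polygon(x: float, y: float,
                      poly: list[tuple[float, float]]) -> bool:
    """Even-odd rule; boundary points count as inside on lower/left edges."""
    n = len(poly)
    inside = False
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xcross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xcross:
                inside = not inside
    return inside


def _hits(x: float, y: float, polys: list[list[tuple[float, float]]]) -> bool:
    # periodic images so polygons touching the seam behave on the torus
    for dx in (-360.0, 0.0, 360.0):
        for dy in (-360.0, 0.0, 360.0):
            if any(_point_in_polygon(x + dx, y + dy, p) for p in polys):
                return True
    return False


@lru_cache(maxsize=None)
def _mask_for(residue_class: str) -> np.ndarray:
    """Rasterized labels: 2 favored, 1 allowed, 0 outlier; shape (180, 180)."""
    if residue_class not in RESIDUE_CLASSES:
        raise ValueError(f"unknown residue class {residue_class!r}")
    fav = _FAVORED[residue_class]
    allow = _ALLOWED[residue_class]
    grid = np.zeros((_NBINS, _NBINS), dtype=np.int8)
    centers = -180.0 + _GRID_STEP * (np.arange(_NBINS) + 0.5)
    for i, phi in enumerate(centers):
        for j, psi in enumerate(centers):
            if _hits(phi, psi, fav):
                grid[i, j] = 2
            elif _hits(phi, psi, allow):
                grid[i, j] = 1
    return grid


_LABELS = {2: "favored", 1: "allowed", 0: "outlier"}


def ramachandran_classify(phi: float, psi: float,
                          residue_class: str = "general") -> str:
    """Classify a (phi, psi) pair as favored / allowed / outlier."""
    grid = _mask_for(residue_class)
    p = wrap_angle(phi)
    s = wrap_angle(psi)
    # wrap_angle gives (-180, 180]; fold 180 onto the -180 bin edge
    i = int(np.floor((p + 180.0) / _GRID_STEP)) % _NBINS
    j = int(np.floor((s + 180.0) / _GRID_STEP)) % _NBINS
    return _LABELS[int(grid[i, j])]


def residue_class_of(res_name: str, next_res_name: str | None = None) -> str:
    if res_name == "GLY":
        return "glycine"
    if res_name == "PRO":
        return "proline"
    if next_res_name == "PRO":
        return "pre-proline"
    return "general"


def ramachandran_table(m: StructureModel, chain: str) -> list[dict]:
    """phi/psi pairs and labels for every residue with both angles defined."""
    series = backbone_dihedrals(m, chain)
    by_res: dict[tuple, dict] = {}
    for s in series:
        rec = by_res.setdefault((s.res_number, s.icode), {
            "chain": s.chain, "res_number": s.res_number,
            "icode": s.icode, "res_name": s.res_name,
        })
        rec[s.angle_name] = float(s.values[0])
    order = sorted(by_res)
    out = []
    for idx, key in enumerate(order):
        rec = by_res[key]
        if "phi" not in rec or "psi" not in rec:
            continue
        if np.isnan(rec["phi"]) or np.isnan(rec["psi"]):
            continue
        nxt = by_res[order[idx + 1]]["res_name"] if idx + 1 < len(order) else None
        cls = residue_class_of(rec["res_name"], nxt)
        rec["residue_class"] = cls
        rec["label"] = ramachandran_classify(rec["phi"], rec["psi"], cls)
        out.append(rec)
    return out
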