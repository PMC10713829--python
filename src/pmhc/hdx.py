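"""HDX-MS uptake analysis: back-exchange-corrected percent uptake, kinetic
curves, residue-resolved maps from overlapping fragments, and
heteroscedastic between-state tests (Welch and Brown-Forsythe one-way ANOVA).

Back-exchange correction supports two readings of the centroid-mass
denominator:

* ``span`` (default): (m_t - m0) / (m100 - m0).  The all-D reference
  centroid already embodies both the labeling D fraction and back-exchange,
  so the plain span is the self-consistent denominator.
* ``d-scaled``: (m_t - m0) / (m100 - D_frac * m0), the literal printed
  form; kept selectable because the source expression is typographically
  ambiguous.

The variant in force is recorded in every output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HdxFragmentSeries", "HdxConfig", "UptakeCurve", "ResidueUptakeMap",
    "AnovaResult", "percent_uptake", "build_uptake_curves",
    "residue_resolve", "compare_states", "welch_anova",
    "brown_forsythe_anova", "read_fragment_table", "write_uptake_curves",
    "write_residue_map", "DEFAULT_TIMEPOINTS", "dilution_fraction",
]

DEFAULT_TIMEPOINTS = (0.0, 20.0, 60.0, 180.0, 600.0)


def dilution_fraction(protiated_volume_ul: float,
                      deuterated_volume_ul: float) -> float:
    """Deuterium mole fraction of the labeling reaction's exchangeable
    solvent: deuterated volume over total mixed volume."""
    if protiated_volume_ul < 0 or deuterated_volume_ul <= 0:
        raise ValueError("volumes must be positive")
    return deuterated_volume_ul / (protiated_volume_ul
                                   + deuterated_volume_ul)


@dataclass
class HdxFragmentSeries:
    """One peptic fragment: reference centroids plus timed observations."""

    protein: str
    start: int  # 1-based, inclusive
    end: int
    sequence: str
    m0: float  # Da, all-H centroid
    m100: float  # Da, all-D centroid
    observations: list[tuple[float, str, float]]  # (time_s, replicate, m_t)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.protein} {self.start}-{self.end}: "
                             "start must be <= end")
        if self.sequence and len(self.sequence) != self.end - self.start + 1:
            raise ValueError(
                f"{self.protein} {self.start}-{self.end}: sequence length "
                f"{len(self.sequence)} != span {self.end - self.start + 1}"
            )
        if self.m100 < self.m0:
            raise ValueError(f"{self.protein} {self.start}-{self.end}: "
                             "all-D centroid below all-H centroid")

    @property
    def span_id(self) -> str:
        return f"{self.protein}:{self.start}-{self.end}"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class HdxConfig:
    d_frac: float = 0.8
    correction_variant: str = "span"  # 'span' | 'd-scaled'
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS

    def __post_init__(self) -> None:
        if not (0.0 < self.d_frac <= 1.0):
            raise ValueError("d_frac must be in (0, 1]")
        if self.correction_variant not in ("span", "d-scaled"):
            raise ValueError(
                f"unknown correction variant {self.correction_variant!r}")


@dataclass
class UptakeCurve:
    fragment: str  # span id
    times: np.ndarray  # s, sorted
    mean_uptake: np.ndarray  # %
    sd_uptake: np.ndarray  # sample SD (n-1)
    n_replicates: np.ndarray
    variant: str = "span"

    def at_time(self, t: float) -> float:
        idx = np.flatnonzero(self.times == t)
        if idx.size == 0:
            raise KeyError(f"{self.fragment}: no timepoint {t}")
        return float(self.mean_uptake[idx[0]])


@dataclass
class ResidueUptakeMap:
    time: float
    values: np.ndarray  # % per residue (1-based -> index 0), NaN = uncovered
    coverage: np.ndarray  # fragment count per residue
    variant: str = "span"

    @property
    def covered(self) -> np.ndarray:
        return self.coverage >= 1


def percent_uptake(m_t: float, m0: float, m100: float,
                   cfg: HdxConfig | None = None) -> float:
    """Back-exchange-corrected deuterium uptake in percent."""
    cfg = cfg or HdxConfig()
    if cfg.correction_variant == "span":
        denom = m100 - m0
        if denom <= 0:
            raise ValueError("m100 must exceed m0 for the span variant")
    else:
        denom = m100 - cfg.d_frac * m0
        if denom <= 0:
            raise ValueError("non-positive d-scaled denominator")
    return 100.0 * (m_t - m0) / denom


def build_uptake_curves(frags: list[HdxFragmentSeries],
                        cfg: HdxConfig | None = None) -> list[UptakeCurve]:
    """Per-fragment mean +/- SD corrected uptake over replicates.

    Time 0 is forced to 0% by definition (no labeling has occurred).
    """
    cfg = cfg or HdxConfig()
    curves = []
    for f in frags:
        by_time: dict[float, list[float]] = {}
        for time_s, _rep, m_t in f.observations:
            by_time.setdefault(float(time_s), []).append(
                percent_uptake(m_t, f.m0, f.m100, cfg))
        times = np.array(sorted(set(by_time) | {0.0}))
        means, sds, ns = [], [], []
        for t in times:
            if t == 0.0:
                vals = by_time.get(0.0, [0.0])
                means.append(0.0)
                sds.append(0.0)
                ns.append(len(vals))
                continue
            vals = np.array(by_time[t])
            means.append(float(vals.mean()))
            sds.append(float(vals.std(ddof=1)) if vals.size > 1 else 0.0)
            ns.append(vals.size)
        curves.append(UptakeCurve(
            fragment=f.span_id, times=times,
            mean_uptake=np.array(means), sd_uptake=np.array(sds),
            n_replicates=np.array(ns), variant=cfg.correction_variant,
        ))
    return curves


def residue_resolve(frags: list[HdxFragmentSeries],
                    curves: list[UptakeCurve], time: float,
                    protein_length: int, weighted: bool = False,
                    exclude_fast: bool = False) -> ResidueUptakeMap:
    """Average fragment uptake onto residues by uniform redistribution.

    Each covered residue gets the (optionally 1/length-weighted) mean of
    the uptake of every fragment whose span covers it.  Uncovered residues
    are NaN, never interpolated.  ``exclude_fast`` drops each fragment's
    first residue and prolines from its coverage (fast-exchanging amides).
    """
    by_id = {c.fragment: c for c in curves}
    num = np.zeros(protein_length)
    wsum = np.zeros(protein_length)
    count = np.zeros(protein_length, dtype=int)
    variant = curves[0].variant if curves else "span"
    for f in frags:
        if f.end > protein_length or f.start < 1:
            raise ValueError(f"{f.span_id}: span outside protein "
                             f"length {protein_length}")
        curve = by_id.get(f.span_id)
        if curve is None:
            continue
        uptake = curve.at_time(time)
        weight = 1.0 / f.length if weighted else 1.0
        for res in range(f.start, f.end + 1):
            if exclude_fast:
                if res == f.start:
                    continue
                if f.sequence and f.sequence[res - f.start] == "P":
                    continue
            num[res - 1] += weight * uptake
            wsum[res - 1] += weight
            count[res - 1] += 1
    values = np.full(protein_length, np.nan)
    covered = wsum > 0
    values[covered] = num[covered] / wsum[covered]
    return ResidueUptakeMap(time=time, values=values, coverage=count,
                            variant=variant)


# ----------------------------------------------------------- statistics

@dataclass
class AnovaResult:
    welch_f: float
    welch_df1: float
    welch_df2: float
    welch_p: float
    bf_f: float
    bf_df1: float
    bf_df2: float
    bf_p: float


def welch_anova(groups: list[np.ndarray]) -> tuple[float, float, float, float]:
    """Welch (1951) heteroscedastic one-way ANOVA: (F, df1, df2, p)."""
    k = len(groups)
    n = np.array([len(g) for g in groups], dtype=float)
    means = np.array([np.mean(g) for g in groups])
    var = np.array([np.var(g, ddof=1) for g in groups])
    if np.all(var == 0):
        equal = np.all(means == means[0])
        return (0.0, k - 1.0, math.inf, 1.0) if equal else \
            (math.inf, k - 1.0, math.inf, 0.0)
    w = n / var
    ws = w.sum()
    grand = float((w * means).sum() / ws)
    a = float((w * (means - grand) ** 2).sum() / (k - 1))
    lam = float((((1.0 - w / ws) ** 2) / (n - 1.0)).sum())
    b = 1.0 + 2.0 * (k - 2.0) / (k * k - 1.0) * lam
    f = a / b
    df1 = k - 1.0
    df2 = (k * k - 1.0) / (3.0 * lam)
    p = float(stats.f.sf(f, df1, df2))
    return float(f), df1, float(df2), p


def brown_forsythe_anova(groups: list[np.ndarray],
                         ) -> tuple[float, float, float, float]:
    """Brown-Forsythe (1974) adjusted-F one-way ANOVA for means:
    F* = sum n_i (m_i - m)^2 / sum (1 - n_i/N) s_i^2, Satterthwaite df2."""
    k = len(groups)
    n = np.array([len(g) for g in groups], dtype=float)
    total = n.sum()
    means = np.array([np.mean(g) for g in groups])
    var = np.array([np.var(g, ddof=1) for g in groups])
    if np.all(var == 0):
        equal = np.all(means == means[0])
        return (0.0, k - 1.0, math.inf, 1.0) if equal else \
            (math.inf, k - 1.0, math.inf, 0.0)
    grand = float((n * means).sum() / total)
    numer = float((n * (means - grand) ** 2).sum())
    terms = (1.0 - n / total) * var
    denom = float(terms.sum())
    f = numer / denom
    c = terms / denom
    df2 = 1.0 / float((c * c / (n - 1.0)).sum())
    df1 = k - 1.0
    p = float(stats.f.sf(f, df1, df2))
    return float(f), df1, df2, p


def compare_states(groups: list[np.ndarray]) -> AnovaResult:
    """Welch and Brown-Forsythe tests across per-state replicate uptakes."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs >= 2 replicates")
    wf, wdf1, wdf2, wp = welch_anova(groups)
    bf, bdf1, bdf2, bp = brown_forsythe_anova(groups)
    return AnovaResult(wf, wdf1, wdf2, wp, bf, bdf1, bdf2, bp)


# ----------------------------------------------------------------- file IO

def read_fragment_table(path: str | Path) -> list[HdxFragmentSeries]:
    """Read a fragment CSV.

    Columns: protein, start, end, sequence, replicate, time_s,
    centroid_mass.  Reference rows carry ``allH`` / ``allD`` in ``time_s``;
    multiple reference rows per fragment are averaged.
    """
    df = pd.read_csv(path, dtype={"time_s": str})
    required = {"protein", "start", "end", "sequence", "replicate",
                "time_s", "centroid_mass"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"fragment table missing columns: {sorted(missing)}")
    frags = []
    for (protein, start, end), grp in df.groupby(
            ["protein", "start", "end"], sort=True):
        seqs = grp["sequence"].dropna().unique()
        sequence = str(seqs[0]) if len(seqs) else ""
        kind = grp["time_s"].str.strip()
        m0_rows = grp.loc[kind.str.lower() == "allh", "centroid_mass"]
        m100_rows = grp.loc[kind.str.lower() == "alld", "centroid_mass"]
        if m0_rows.empty or m100_rows.empty:
            raise ValueError(
                f"{protein}:{start}-{end}: missing allH/allD reference rows")
        obs_rows = grp.loc[~kind.str.lower().isin(["allh", "alld"])]
        observations = [
            (float(row.time_s), str(row.replicate), float(row.centroid_mass))
            for row in obs_rows.itertuples()
        ]
        frags.append(HdxFragmentSeries(
            protein=str(protein), start=int(start), end=int(end),
            sequence=sequence, m0=float(m0_rows.mean()),
            m100=float(m100_rows.mean()), observations=observations,
        ))
    return frags


def write_uptake_curves(curves: list[UptakeCurve], path: str | Path) -> None:
    rows = []
    for c in curves:
        for t, m, s, n in zip(c.times, c.mean_uptake, c.sd_uptake,
                              c.n_replicates):
            rows.append({"fragment": c.fragment, "time_s": t,
                         "mean_uptake_pct": m, "sd_uptake_pct": s,
                         "n": int(n), "variant": c.variant})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_residue_map(rmap: ResidueUptakeMap, path: str | Path) -> None:
    """TSV with one row per residue; the value column doubles as a
    B-factor paint source for structure coloring."""
    df = pd.DataFrame({
        "residue": np.arange(1, rmap.values.size + 1),
        "uptake_pct": rmap.values,
        "coverage": rmap.coverage,
        "covered": rmap.covered.astype(int),
    })
    df.insert(0, "time_s", rmap.time)
    df["variant"] = rmap.variant
    df.to_csv(path, sep="\t", index=False)
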