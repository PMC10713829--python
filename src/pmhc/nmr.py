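"""Solution-observable analysis: methyl CSPs, intensity-ratio flagging,
association kinetics, thermal-melt fitting, and competitive-anisotropy IC50s.

All fits are deterministic least squares started from analytic initial
guesses (no random restarts), so results are reproducible bit-for-bit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, least_squares

__all__ = [
    "MethylPeak", "CspRecord", "DecaySeries", "DecayFit",
    "MeltCurve", "MeltCurveFit", "AnisotropySeries", "AssayConstants",
    "CompetitionFit",
    "methyl_csp", "flag_perturbed", "fit_decay", "percent_empty", "fit_tm",
    "competition_model", "fit_ic50", "cheng_prusoff_kd",
]


# ---------------------------------------------------------------- CSP layer

@dataclass
class MethylPeak:
    """One methyl resonance in one state."""

    probe: str  # e.g. 'I23-CD1'
    delta_h: float  # ppm
    delta_c: float  # ppm
    intensity: float = 1.0
    state: str = ""

    def __post_init__(self) -> None:
        if not (math.isfinite(self.delta_h) and math.isfinite(self.delta_c)):
            raise ValueError(f"{self.probe}: non-finite chemical shift")
        if self.intensity < 0:
            raise ValueError(f"{self.probe}: negative intensity")


@dataclass
class CspRecord:
    probe: str
    csp: float  # ppm, combined 1H/13C shift change
    intensity_ratio: float | None = None  # I_empty / I_bound
    csp_outlier: bool = False
    broadened: bool = False
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        if self.csp < 0:
            raise ValueError("csp must be >= 0")
        if self.excluded and not self.exclusion_reason:
            raise ValueError("excluded records must carry a reason")


def methyl_csp(free: MethylPeak, bound: MethylPeak) -> float:
    """Combined methyl chemical-shift perturbation in ppm.

    delta = sqrt((dH^2 + dC^2/4) / 2), the carbon term scaled by 1/4
    inside the root.
    """
    if free.probe != bound.probe:
        raise ValueError(f"probe mismatch: {free.probe!r} vs {bound.probe!r}")
    dh = bound.delta_h - free.delta_h
    dc = bound.delta_c - free.delta_c
    return math.sqrt(0.5 * (dh * dh + dc * dc / 4.0))


def flag_perturbed(records: list[CspRecord]) -> list[CspRecord]:
    """Flag CSP outliers (> mean + 1 SD) and broadened probes
    (ratio < mean - 1 SD), excluding pre-excluded records from the
    thresholds.  Returns new records; input order preserved.
    """
    live = [r for r in records if not r.excluded]
    if len(live) < 2:
        raise ValueError("need >= 2 non-excluded records")
    csps = np.array([r.csp for r in live])
    csp_thr = csps.mean() + csps.std(ddof=1)
    ratios = np.array([r.intensity_ratio for r in live
                       if r.intensity_ratio is not None])
    ratio_thr = (ratios.mean() - ratios.std(ddof=1)) if ratios.size >= 2 \
        else None
    out = []
    for r in records:
        flagged_csp = (not r.excluded) and r.csp > csp_thr
        flagged_broad = (not r.excluded and ratio_thr is not None
                         and r.intensity_ratio is not None
                         and r.intensity_ratio < ratio_thr)
        out.append(CspRecord(
            probe=r.probe, csp=r.csp, intensity_ratio=r.intensity_ratio,
            csp_outlier=flagged_csp, broadened=flagged_broad,
            excluded=r.excluded, exclusion_reason=r.exclusion_reason,
        ))
    return out


# ------------------------------------------------------------- decay fits

@dataclass
class DecaySeries:
    times: np.ndarray  # hours, strictly increasing
    intensities: np.ndarray
    probe: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ValueError("times/intensities must align")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.times.size < 4:
            raise ValueError("need >= 4 points for fitting")


@dataclass
class DecayFit:
    i0: float
    plateau: float
    rate: float  # 1/h, >= 0
    t_half: float  # hours; inf when rate == 0
    rss: float
    stderr: dict[str, float] = field(default_factory=dict)
    warning: str = ""


def _decay_model(t, i0, plateau, k):
    return plateau + (i0 - plateau) * np.exp(-k * t)


def fit_decay(s: DecaySeries) -> DecayFit:
    """Single-phase exponential decay fit; t_half = ln2 / k."""
    t, y = s.times, s.intensities
    span = y[0] - y[-1]
    if abs(span) < 1e-12 * max(1.0, abs(y[0])):
        return DecayFit(i0=float(y.mean()), plateau=float(y.mean()),
                        rate=0.0, t_half=math.inf,
                        rss=float(np.sum((y - y.mean()) ** 2)),
                        warning="non-decaying data; rate pinned at 0")
    # analytic start: plateau ~ last point, k from the half-way crossing
    plateau0 = y[-1]
    i00 = y[0]
    target = plateau0 + span * 0.5
    crossing = t[np.argmin(np.abs(y - target))]
    k0 = math.log(2.0) / max(float(crossing), float(t[1]) or 1e-3)

    def resid(p):
        return _decay_model(t, *p) - y

    sol = least_squares(resid, x0=[i00, plateau0, max(k0, 1e-6)],
                        bounds=([-np.inf, -np.inf, 0.0],
                                [np.inf, np.inf, np.inf]))
    i0, plateau, k = sol.x
    rss = float(np.sum(sol.fun ** 2))
    stderr = _stderr_from_jac(sol, ("i0", "plateau", "rate"))
    warning = ""
    if k <= 1e-12:
        warning = "fit pinned rate at 0 (non-decaying data)"
        t_half = math.inf
    else:
        t_half = math.log(2.0) / k
    return DecayFit(i0=float(i0), plateau=float(plateau), rate=float(k),
                    t_half=float(t_half), rss=rss, stderr=stderr,
                    warning=warning)


def _stderr_from_jac(sol, names) -> dict[str, float]:
    m, n = sol.jac.shape
    if m <= n:
        return {}
    dof = m - n
    s2 = float(np.sum(sol.fun ** 2)) / dof
    try:
        cov = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
    except np.linalg.LinAlgError:
        return {}
    diag = np.diag(cov)
    return {nm: float(np.sqrt(v)) if v > 0 else float("nan")
            for nm, v in zip(names, diag)}


# ---------------------------------------------------------------- DSF layer

@dataclass
class MeltCurve:
    temperatures: np.ndarray  # deg C, increasing
    fluorescence: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperatures.shape != self.fluorescence.shape:
            raise ValueError("temperatures/fluorescence must align")


@dataclass
class MeltCurveFit:
    f_min: float
    f_max: float
    t_m: float  # deg C
    slope: float  # deg C, > 0
    rss: float
    stderr: dict[str, float] = field(default_factory=dict)

    def predict(self, temp) -> np.ndarray:
        temp = np.asarray(temp, dtype=float)
        return self.f_min + (self.f_max - self.f_min) / (
            1.0 + np.exp((self.t_m - temp) / self.slope))


def percent_empty(sample: MeltCurve, reference_empty: MeltCurve,
                  at_temperature: float = 25.0) -> float:
    """100 x F_sample(at_temperature) / max F of the empty reference."""
    fmax = float(reference_empty.fluorescence.max())
    if fmax <= 0:
        raise ValueError("reference curve has non-positive maximum")
    for curve, name in ((sample, "sample"), (reference_empty, "reference")):
        tmin, tmax = curve.temperatures.min(), curve.temperatures.max()
        if not (tmin <= at_temperature <= tmax):
            raise ValueError(f"{name} curve does not cover "
                             f"{at_temperature} deg C")
    fs = float(np.interp(at_temperature, sample.temperatures,
                         sample.fluorescence))
    return 100.0 * fs / fmax


def fit_tm(c: MeltCurve) -> MeltCurveFit:
    """Boltzmann sigmoid fit F(T) = Fmin + (Fmax-Fmin)/(1+exp((Tm-T)/slope))."""
    t, y = c.temperatures, c.fluorescence
    if np.ptp(y) <= 0:
        raise ValueError("flat melt curve; nothing to fit")
    fmin0, fmax0 = float(y.min()), float(y.max())
    mid = fmin0 + 0.5 * (fmax0 - fmin0)
    tm0 = float(t[np.argmin(np.abs(y - mid))])
    slope0 = max(np.ptp(t) / 20.0, 0.5)

    def resid(p):
        fmin, fmax, tm, slope = p
        return fmin + (fmax - fmin) / (1.0 + np.exp((tm - t) / slope)) - y

    sol = least_squares(resid, x0=[fmin0, fmax0, tm0, slope0],
                        bounds=([-np.inf, -np.inf, t.min() - 50.0, 1e-3],
                                [np.inf, np.inf, t.max() + 50.0, np.inf]))
    fmin, fmax, tm, slope = sol.x
    if not (t.min() <= tm <= t.max()):
        warnings.warn("fitted T_m outside the scanned range", stacklevel=2)
    return MeltCurveFit(f_min=float(fmin), f_max=float(fmax), t_m=float(tm),
                        slope=float(slope),
                        rss=float(np.sum(sol.fun ** 2)),
                        stderr=_stderr_from_jac(
                            sol, ("f_min", "f_max", "t_m", "slope")))


# ------------------------------------------------ competition anisotropy

@dataclass(frozen=True)
class AssayConstants:
    """Fixed assay composition for the competition model (uM units)."""

    receptor_total: float = 0.1
    tracer_total: float = 0.025
    tracer_kd: float = 0.1

    def __post_init__(self) -> None:
        for name in ("receptor_total", "tracer_total", "tracer_kd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class AnisotropySeries:
    concentrations: np.ndarray  # competitor, uM, >= 0, includes 0
    anisotropy: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.anisotropy = np.asarray(self.anisotropy, dtype=float)
        if self.concentrations.shape != self.anisotropy.shape:
            raise ValueError("concentrations/anisotropy must align")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be >= 0")
        if np.unique(self.concentrations).size < 4:
            raise ValueError("need >= 4 distinct competitor concentrations")
        if not np.any(self.concentrations == 0):
            raise ValueError("series must include the zero-competitor point")


@dataclass
class CompetitionFit:
    ic50: float  # same units as the concentration axis
    r_max: float
    r_min: float
    competitor_kd: float
    rss: float
    constants: AssayConstants = field(default_factory=AssayConstants)


def competition_model(r_tot: float, l_tot: float, c_tot: float,
                      kd_l: float, kd_c: float) -> float:
    """Bound fraction of the labeled tracer at one-site two-ligand
    equilibrium, solved to 1e-10 on the receptor mass balance."""
    if min(r_tot, l_tot, kd_l, kd_c) <= 0 or c_tot < 0:
        raise ValueError("non-physical inputs")

    def balance(r_free: float) -> float:
        l_free = l_tot / (1.0 + r_free / kd_l)
        c_free = c_tot / (1.0 + r_free / kd_c)
        return r_free * (1.0 + l_free / kd_l + c_free / kd_c) - r_tot

    r_free = brentq(balance, 0.0, r_tot, xtol=1e-14, rtol=1e-15,
                    maxiter=300)
    return (r_free / kd_l) / (1.0 + r_free / kd_l)


def _bound_fraction_curve(conc, constants: AssayConstants,
                          kd_c: float) -> np.ndarray:
    return np.array([
        competition_model(constants.receptor_total, constants.tracer_total,
                          float(c), constants.tracer_kd, kd_c)
        for c in conc
    ])


def ic50_from_kd(kd_c: float, constants: AssayConstants,
                 bracket: tuple[float, float] = (1e-6, 1e6)) -> float:
    """Competitor concentration at half-maximal displacement of the tracer."""
    fb0 = competition_model(constants.receptor_total, constants.tracer_total,
                            0.0, constants.tracer_kd, kd_c)

    def half(c):
        return competition_model(constants.receptor_total,
                                 constants.tracer_total, c,
                                 constants.tracer_kd, kd_c) - fb0 / 2.0

    return brentq(half, *bracket, xtol=1e-12, rtol=1e-12, maxiter=300)


def fit_ic50(s: AnisotropySeries,
             constants: AssayConstants | None = None) -> CompetitionFit:
    """Fit the competitive one-site model to an anisotropy titration.

    The anisotropy is mapped linearly onto the tracer bound fraction
    between r_max (no competitor) and r_min (full displacement); IC50 is
    the concentration at half-maximal anisotropy change, computed from the
    fitted model rather than read off the grid.
    """
    constants = constants or AssayConstants()
    conc, r = s.concentrations, s.anisotropy
    r_max0 = float(r[conc == 0].mean())
    r_min0 = float(r[conc == conc.max()].mean())
    kd0 = max(float(np.median(conc[conc > 0])) / 10.0, 1e-4)

    def resid(p):
        log_kd, r_max, r_min = p
        fb = _bound_fraction_curve(conc, constants, math.exp(log_kd))
        fb0 = competition_model(constants.receptor_total,
                                constants.tracer_total, 0.0,
                                constants.tracer_kd, math.exp(log_kd))
        return r_min + (r_max - r_min) * fb / fb0 - r

    sol = least_squares(resid, x0=[math.log(kd0), r_max0, r_min0],
                        method="lm" if conc.size >= 3 else "trf")
    log_kd, r_max, r_min = sol.x
    kd_c = math.exp(log_kd)
    ic50 = ic50_from_kd(kd_c, constants)
    return CompetitionFit(ic50=float(ic50), r_max=float(r_max),
                          r_min=float(r_min), competitor_kd=float(kd_c),
                          rss=float(np.sum(sol.fun ** 2)),
                          constants=constants)


def cheng_prusoff_kd(ic50: float, constants: AssayConstants) -> float:
    """Approximate competitor Kd from IC50 (derived quantity, not a fit)."""
    return ic50 / (1.0 + constants.tracer_total / constants.tracer_kd)
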