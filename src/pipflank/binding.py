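"""Binding-model fitting: SPR steady state, single-cycle kinetics, and ITC.

Three bespoke models cover the affinity measurements:

* SPR steady state with stoichiometry:  Rss = KA*c*Rmax / (KA*c*n + 1).
* Single-cycle 1:1 Langmuir kinetics: piecewise-analytic solution of
  dR/dt = kon*c*(Rmax - R) - koff*R across sequential injections with no
  surface regeneration (contact 90 s, dissociation 225 s by default).
* Reverse-titration ITC with one set of sites: the titrant (a trimeric
  clamp with ``n`` identical sites) is injected into the cell peptide;
  injections dilute the cell by the exact stepwise displaced-volume
  recursion and each heat is the enthalpy of newly formed complex plus a
  per-mole-of-injectant dilution offset.

Thermodynamic bookkeeping: dG = R*T*ln(KD), -TdS = dG - dH (J/mol).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from lmfit import Parameters, minimize

from .errors import FitConvergenceError, TooFastKineticsWarning, UnreliableFitWarning

R_GAS = 8.314  # J/(mol K)


# --------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class Injection:
    """One analyte injection: [t_start, t_end) at constant concentration."""

    t_start: float
    t_end: float
    conc: float  # M

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("injection must have positive duration")
        if self.conc < 0:
            raise ValueError("concentration must be >= 0")


@dataclass
class SPRSeries:
    """Either steady-state (conc, response) pairs or a time course.

    Steady-state mode: ``conc``/``response`` set, ``time`` None.
    Kinetic mode: ``time``/``response`` set plus an injection ``schedule``
    (non-overlapping, increasing); concentration is 0 outside injections.
    """

    conc: np.ndarray | None = None
    response: np.ndarray | None = None
    time: np.ndarray | None = None
    schedule: tuple[Injection, ...] = ()
    rmax0: float | None = None  # capture-level proxy

    def __post_init__(self) -> None:
        if self.time is None:
            if self.conc is None or self.response is None:
                raise ValueError("steady-state series needs conc and response")
            self.conc = np.asarray(self.conc, dtype=float)
            self.response = np.asarray(self.response, dtype=float)
            if (self.conc <= 0).any():
                raise ValueError("concentrations must be positive")
        else:
            self.time = np.asarray(self.time, dtype=float)
            self.response = np.asarray(self.response, dtype=float)
            prev_end = -np.inf
            for inj in self.schedule:
                if inj.t_start < prev_end:
                    raise ValueError("schedule intervals must be increasing")
                prev_end = inj.t_end

    @property
    def is_kinetic(self) -> bool:
        return self.time is not None


@dataclass
class ITCExperiment:
    """Integrated-heat titration with instrument bookkeeping.

    ``cell_conc`` is the cell species (peptide, M), ``syringe_conc`` the
    titrant (clamp trimer, M); ``heats`` in J per injection.
    """

    v0: float                 # cell volume, L
    cell_conc: float          # M
    syringe_conc: float       # M
    inj_volumes: np.ndarray   # L
    heats: np.ndarray         # J
    temp_K: float = 298.15

    def __post_init__(self) -> None:
        self.inj_volumes = np.asarray(self.inj_volumes, dtype=float)
        self.heats = np.asarray(self.heats, dtype=float)
        if min(self.v0, self.cell_conc, self.syringe_conc) <= 0:
            raise ValueError("volumes and concentrations must be positive")
        if (self.inj_volumes <= 0).any():
            raise ValueError("injection volumes must be positive")
        if not np.isfinite(self.heats).all():
            raise ValueError("heats must be finite")
        if len(self.heats) != len(self.inj_volumes):
            raise ValueError("heats and injection volumes differ in length")


@dataclass
class AffinityRecord:
    """KD and thermodynamics for one ligand/method pair."""

    ligand_id: str
    method: str               # SPR_steady | SPR_kinetic | ITC
    kd: float                 # M
    kd_err: float | None = None
    kon: float | None = None  # 1/(M s)
    koff: float | None = None  # 1/s
    dH: float | None = None   # J/mol
    dG: float | None = None   # J/mol
    minus_TdS: float | None = None
    n: float | None = None
    temp_K: float = 298.15
    ph: float | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def ka(self) -> float:
        return 1.0 / self.kd

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("KD must be positive")
        if self.kon is not None and self.koff is not None:
            if abs(self.kd - self.koff / self.kon) > 1e-9 * self.kd:
                raise ValueError("KD must equal koff/kon for kinetic records")


def thermodynamics(kd: float, dh: float, temp_K: float = 298.15) -> tuple[float, float]:
    """(dG, -TdS) in J/mol from KD (M) and dH (J/mol)."""
    if kd <= 0 or temp_K <= 0:
        raise ValueError("KD and T must be positive")
    dg = R_GAS * temp_K * np.log(kd)
    return float(dg), float(dg - dh)


# --------------------------------------------------------------------------
# SPR steady state


def spr_steady_state_model(
    c: np.ndarray | float, ka: float, rmax: float, n: float = 1.0
) -> np.ndarray | float:
    """Equilibrium response at analyte concentration ``c``."""
    c = np.asarray(c, dtype=float)
    out = ka * c * rmax / (ka * c * n + 1.0)
    return float(out) if out.ndim == 0 else out


def spr_steady_state_fit(
    series: SPRSeries,
    n: float = 1.0,
    fit_n: bool = False,
    ligand_id: str = "",
    ph: float | None = None,
) -> tuple[AffinityRecord, float]:
    """Nonlinear least squares of the steady-state model; returns (record, Rmax).

    Parameterised in log(KA) for conditioning; the asymptotic standard error
    is propagated to the KD scale.  Emits :class:`UnreliableFitWarning` when
    the fitted KD lies outside [c_min/100, 100*c_max] or the responses carry
    no concentration dependence.
    """
    c = series.conc
    r = series.response
    if c is None or len(c) < 4:
        raise ValueError("steady-state fit needs >= 4 concentration points")
    if c.max() / c.min() < 4.0:
        raise ValueError("concentrations must span at least 4-fold")
    warns: list[str] = []
    if np.ptp(r) < 1e-12 * max(1.0, abs(r).max()):
        warns.append("responses carry no concentration dependence")
        warnings.warn(warns[-1], UnreliableFitWarning)

    params = Parameters()
    params.add("log_ka", value=np.log(1.0 / np.median(c)))
    params.add("rmax", value=max(r.max(), 1e-9) * n * 1.5, min=0.0)
    if fit_n:
        params.add("n", value=n, min=1e-6)
    else:
        params.add("n", value=n, vary=False)

    def resid(p):
        return spr_steady_state_model(c, np.exp(p["log_ka"]), p["rmax"], p["n"]) - r

    res = minimize(resid, params)
    if not res.success:
        raise FitConvergenceError("steady-state fit did not converge")
    ka = float(np.exp(res.params["log_ka"].value))
    kd = 1.0 / ka
    stderr = res.params["log_ka"].stderr
    kd_err = kd * stderr if stderr is not None else None
    if not (c.min() / 100.0 <= kd <= 100.0 * c.max()):
        warns.append(f"fitted KD {kd:.3g} M outside supported range")
        warnings.warn(warns[-1], UnreliableFitWarning)
    rec = AffinityRecord(
        ligand_id=ligand_id, method="SPR_steady", kd=kd, kd_err=kd_err,
        n=float(res.params["n"].value), ph=ph, warnings=warns,
    )
    return rec, float(res.params["rmax"].value)


# --------------------------------------------------------------------------
# SPR single-cycle kinetics


def spr_kinetic_model(
    t: np.ndarray,
    schedule: tuple[Injection, ...],
    kon: float,
    koff: float,
    rmax: float,
    r0: float = 0.0,
) -> np.ndarray:
    """Piecewise-analytic 1:1 Langmuir response over a single-cycle schedule.

    On each constant-concentration segment,
    R(t) = Req + (R_seg - Req) * exp(-(kon*c + koff)*(t - t_seg)) with
    Req = kon*c*rmax / (kon*c + koff); the solution is continuous across
    segment boundaries (no regeneration between injections).
    """
    t = np.asarray(t, dtype=float)
    # build breakpoints: alternating dissociation / injection segments
    edges: list[tuple[float, float]] = []  # (start, conc)
    t0 = float(t.min())
    cursor = t0
    for inj in schedule:
        if inj.t_start > cursor:
            edges.append((cursor, 0.0))
        edges.append((inj.t_start, inj.conc))
        cursor = inj.t_end
    edges.append((cursor, 0.0))

    out = np.empty_like(t)
    r_seg = r0
    for k, (start, c) in enumerate(edges):
        end = edges[k + 1][0] if k + 1 < len(edges) else np.inf
        mask = (t >= start) & (t < end) if np.isfinite(end) else (t >= start)
        rate = kon * c + koff
        req = kon * c * rmax / rate if rate > 0 else 0.0
        if mask.any():
            out[mask] = req + (r_seg - req) * np.exp(-rate * (t[mask] - start))
        if np.isfinite(end):
            r_seg = req + (r_seg - req) * np.exp(-rate * (end - start))
    return out


def spr_kinetic_fit(
    series: SPRSeries,
    ligand_id: str = "",
    ph: float | None = None,
) -> AffinityRecord:
    """Global fit of (kon, koff, Rmax) to a single-cycle sensorgram.

    Rates are fitted in log space; a flat baseline offset absorbs the
    reference subtraction.  Warns :class:`TooFastKineticsWarning` when the
    fitted koff exceeds 1/s (beyond what the schedule resolves) and raises
    :class:`FitConvergenceError` for structureless traces.
    """
    if not series.is_kinetic:
        raise ValueError("kinetic fit needs a time course")
    if len(series.schedule) < 2:
        raise ValueError("kinetic fit needs >= 2 injection cycles")
    t, r = series.time, series.response
    scale = np.ptp(r)
    if scale < 1e-9:
        raise FitConvergenceError("flat trace: nothing to fit")

    params = Parameters()
    params.add("log_kon", value=np.log(1e5), min=np.log(1e1), max=np.log(1e10))
    params.add("log_koff", value=np.log(1e-2), min=np.log(1e-6), max=np.log(1e3))
    params.add("rmax", value=float(r.max() * 1.5), min=1e-9)
    params.add("offset", value=float(np.median(r[: max(3, len(r) // 50)])))

    def resid(p):
        model = spr_kinetic_model(
            t, series.schedule, np.exp(p["log_kon"]), np.exp(p["log_koff"]),
            p["rmax"],
        )
        return model + p["offset"] - r

    res = minimize(resid, params)
    model = resid(res.params) + r
    ss_res = float(np.sum((model - r) ** 2))
    ss_tot = float(np.sum((r - r.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    if not res.success or r2 < 0.5:
        raise FitConvergenceError(
            f"kinetic fit unreliable (R^2 = {r2:.2f}); rates may be too fast "
            "for the schedule — consider the steady-state route"
        )
    kon = float(np.exp(res.params["log_kon"].value))
    koff = float(np.exp(res.params["log_koff"].value))
    warns: list[str] = []
    if koff > 1.0:
        warns.append("koff > 1/s: beyond reliable instrument resolution")
        warnings.warn(warns[-1], TooFastKineticsWarning)
    kd = koff / kon
    err = None
    if res.params["log_kon"].stderr and res.params["log_koff"].stderr:
        err = kd * float(
            np.hypot(res.params["log_kon"].stderr, res.params["log_koff"].stderr)
        )
    return AffinityRecord(
        ligand_id=ligand_id, method="SPR_kinetic", kd=kd, kd_err=err,
        kon=kon, koff=koff, ph=ph, warnings=warns,
    )


# --------------------------------------------------------------------------
# ITC one set of sites (reverse titration)


def bound_complex(p_tot: float, s_tot: float, kd: float) -> float:
    """Equilibrium complex concentration for P + S <-> PS.

    Solves B^2 - B*(P + S + KD) + P*S = 0 on the physical branch;
    ``p_tot`` is total peptide, ``s_tot`` total sites.
    """
    b = p_tot + s_tot + kd
    disc = b * b - 4.0 * p_tot * s_tot
    if disc < 0:
        raise FloatingPointError("negative discriminant: invalid inputs")
    # cancellation-free branch of the quadratic
    return 2.0 * p_tot * s_tot / (b + np.sqrt(disc))


def itc_one_site_model(
    exp: ITCExperiment,
    n: float,
    ka: float,
    dh: float,
    q_dil: float = 0.0,
) -> np.ndarray:
    """Predicted heat (J) per injection under the one-set-of-sites model.

    Cell totals follow the exact stepwise displaced-volume recursion
    (factor 1 - dV/V0 per injection); sites are n * [titrant in cell]; the
    per-injection heat is dh * V0 * (complex formed during the injection,
    net of complex expelled) plus ``q_dil`` joules per mole of injectant.
    """
    if min(n, ka) <= 0:
        raise ValueError("n and KA must be positive")
    kd = 1.0 / ka
    p = exp.cell_conc     # total peptide in cell, M
    x = 0.0               # total titrant (trimer) in cell, M
    b_prev = 0.0
    heats = np.empty(len(exp.inj_volumes))
    for i, dv in enumerate(exp.inj_volumes):
        f = 1.0 - dv / exp.v0
        if f <= 0:
            raise ValueError("injection volume exceeds cell volume")
        p *= f
        x = x * f + exp.syringe_conc * dv / exp.v0
        b = bound_complex(p, n * x, kd)
        heats[i] = dh * exp.v0 * (b - b_prev * f) + q_dil * exp.syringe_conc * dv
        b_prev = b
    return heats


def itc_saturation(exp: ITCExperiment, n: float, ka: float) -> float:
    """Fraction of the limiting species bound after the final injection."""
    kd = 1.0 / ka
    p = exp.cell_conc
    x = 0.0
    for dv in exp.inj_volumes:
        f = 1.0 - dv / exp.v0
        p *= f
        x = x * f + exp.syringe_conc * dv / exp.v0
    b = bound_complex(p, n * x, kd)
    return b / min(p, n * x)


def itc_fit(
    exp: ITCExperiment,
    fix_n: float | None = None,
    ligand_id: str = "",
    ph: float | None = None,
    discard_first: bool = False,
    baseline_k: int = 3,
    subtract_baseline: bool = False,
    saturation_heat_ratio: float = 0.1,
) -> AffinityRecord:
    """Least-squares fit of (n, KA, dH, q_dil) to an integrated isotherm.

    ``fix_n`` pins the stoichiometry (the route the weakest variants need);
    with ``subtract_baseline`` the dilution heat is instead taken as the
    mean of the last ``baseline_k`` injections and removed before fitting
    (only valid once saturation is reached), otherwise ``q_dil`` is a free
    parameter.  When the titration visibly never saturates — the final
    ``baseline_k`` heats still exceed ``saturation_heat_ratio`` of the
    largest heat — the stoichiometry is unidentifiable and a free-n fit
    raises :class:`FitConvergenceError` recommending ``fix_n``.
    """
    if len(exp.heats) < 8:
        raise ValueError("ITC fit needs >= 8 injections")
    work = exp
    if discard_first:
        work = ITCExperiment(
            v0=exp.v0, cell_conc=exp.cell_conc, syringe_conc=exp.syringe_conc,
            inj_volumes=exp.inj_volumes[1:], heats=exp.heats[1:],
            temp_K=exp.temp_K,
        )
    heats = work.heats.copy()
    baseline = 0.0
    if subtract_baseline:
        baseline = float(heats[-baseline_k:].mean())
        heats = heats - baseline

    dh0 = float(heats[: max(2, len(heats) // 4)].sum()
                / (work.v0 * work.cell_conc)) or -1e4

    params = Parameters()
    params.add("log_ka", value=np.log(1e7), min=np.log(1e2), max=np.log(1e13))
    params.add("dh", value=dh0)
    if fix_n is None:
        params.add("n", value=3.0, min=1e-3)
    else:
        params.add("n", value=fix_n, vary=False)
    params.add("q_dil", value=0.0, vary=not subtract_baseline)

    def resid(p):
        model = itc_one_site_model(
            work, p["n"].value, np.exp(p["log_ka"].value),
            p["dh"].value, p["q_dil"].value,
        )
        return model - heats

    res = minimize(resid, params)
    if not res.success:
        raise FitConvergenceError("ITC fit did not converge")
    n_fit = float(res.params["n"].value)
    ka = float(np.exp(res.params["log_ka"].value))
    dh_fit = float(res.params["dh"].value)
    # binding-only heats of the fitted model (dilution offset removed):
    # a titration whose tail still releases substantial binding heat never
    # saturated, so a free n is unidentifiable
    binding = itc_one_site_model(work, n_fit, ka, dh_fit)
    tail = float(np.abs(binding[-baseline_k:]).mean())
    if fix_n is None and tail > saturation_heat_ratio * np.abs(binding).max():
        raise FitConvergenceError(
            "saturation not reached by the final injections: stoichiometry "
            "is unidentifiable — re-fit with fix_n (e.g. fix_n=3)"
        )
    kd = 1.0 / ka
    stderr = res.params["log_ka"].stderr
    dg, mtds = thermodynamics(kd, dh_fit, work.temp_K)
    return AffinityRecord(
        ligand_id=ligand_id, method="ITC", kd=kd,
        kd_err=kd * stderr if stderr is not None else None,
        dH=dh_fit, dG=dg, minus_TdS=mtds, n=n_fit,
        temp_K=work.temp_K, ph=ph,
    )
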