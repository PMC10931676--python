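"""Whole-body perfusion-limited PBPK model with a compartmental absorption
and transit (CAT) oral module.

Structure
---------
Blood circulates lung -> arterial -> organs -> venous -> lung.  Every organ
is perfusion-limited: the blood leaving tissue *t* is in equilibrium with the
tissue, ``C_out = C_t * Rb:p / Kp_t``.  The liver receives the hepatic artery
plus the portal outflow of gut and spleen and is the (default) site of
elimination; its intrinsic blood clearance is back-calculated from the
requested systemic plasma clearance through the well-stirred relation
``CLint_b = Qh * CLb / (Qh - CLb)`` so that a simulated IV dose returns
exactly the input clearance (``CLb = CLp / Rb:p``).  A kidney elimination
hook exists via ``renal_fraction``.

Oral dosing enters a 7-compartment lumen chain: solid drug dissolves with a
first-order rate (proportional to the cyclodextrin solubilization factor),
dissolved drug is absorbed with a first-order rate derived from the Caco-2
permeability, and both phases transit with rate ``n/T_si``.  Absorbed drug
enters the liver through the portal route after losing the fraction
``1 - Fg`` to gut-wall metabolism; lumen contents leaving the last
compartment are feces.  All rate constants are first order, so the model is
strictly dose-linear and obeys superposition.

All state variables are amounts in mg; concentrations are reported in ng/mL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .datasets import TISSUES, CompoundProperties, SpeciesPhysiology
from .errors import ConfigurationError, E0703PKError, PhysiologyValidationError
from .partition import KpSet

N_TRANSIT = 7

#: Effective absorptive surface-to-volume factor (1/cm): 2/R for a cylindrical
#: small intestine of radius 1.25 cm times a 10x mucosal surface amplification.
#: Treated as a compound/formulation-level constant across species; species
#: differences in absorption come from the transit time.
ABSORPTION_SURFACE_FACTOR = 16.0

#: Base first-order dissolution rate (1/h) per unit solubilization factor for
#: the micronized tablet; the cyclodextrin complex multiplies it.
DISSOLUTION_RATE_BASE = 1.0


@dataclass(frozen=True)
class AbsorptionParameters:
    """First-order rate constants of the oral absorption chain (all 1/h)."""

    ka: float          # lumen -> portal absorption rate
    kt: float          # transit rate through each of the 7 compartments
    kd: float          # solid -> dissolved rate
    fg: float = 1.0    # fraction escaping gut-wall metabolism

    def __post_init__(self) -> None:
        if min(self.ka, self.kt, self.kd) < 0:
            raise ConfigurationError("absorption rates must be non-negative")
        if not 0 <= self.fg <= 1:
            raise ConfigurationError("Fg must lie in [0, 1]")


def absorption_for(
    compound: CompoundProperties, physiology: SpeciesPhysiology, fg: float = 1.0
) -> AbsorptionParameters:
    """Default absorption parameters: ``ka`` from the Caco-2 permeability,
    ``kt`` from the species small-intestine transit time, ``kd`` from the
    formulation solubilization factor."""
    if physiology.si_transit_h is None:
        raise ConfigurationError(
            f"no small-intestine transit time for {physiology.species}"
        )
    ka = compound.papp_cm_s * 3600.0 * ABSORPTION_SURFACE_FACTOR
    kt = N_TRANSIT / physiology.si_transit_h
    kd = DISSOLUTION_RATE_BASE * compound.solubilization_factor
    return AbsorptionParameters(ka=ka, kt=kt, kd=kd, fg=fg)


def fraction_absorbed(a: AbsorptionParameters) -> float:
    """Closed-form fraction of an oral dose absorbed from the lumen chain
    (before gut-wall and hepatic first pass)."""
    if a.ka == 0:
        return 0.0
    if a.kt == 0:
        return 1.0
    # time integrals of solid and dissolved amounts per unit dose
    s = np.empty(N_TRANSIT)
    d = np.empty(N_TRANSIT)
    s[0] = 1.0 / (a.kd + a.kt)
    for i in range(1, N_TRANSIT):
        s[i] = a.kt * s[i - 1] / (a.kd + a.kt)
    d[0] = a.kd * s[0] / (a.ka + a.kt)
    for i in range(1, N_TRANSIT):
        d[i] = (a.kd * s[i] + a.kt * d[i - 1]) / (a.ka + a.kt)
    return float(a.ka * d.sum())


@dataclass(frozen=True)
class DosingRegimen:
    """Dosing events: (time h, amount mg, route)."""

    events: tuple[tuple[float, float, str], ...]

    def __post_init__(self) -> None:
        if not self.events:
            raise ConfigurationError("regimen needs at least one event")
        last = -math.inf
        for t, amt, route in self.events:
            if t < 0 or t < last:
                raise ConfigurationError("event times must be sorted and >= 0")
            if amt <= 0:
                raise ConfigurationError("dose amounts must be positive")
            if route not in ("oral", "iv_bolus"):
                raise ConfigurationError("route must be oral or iv_bolus")
            last = t

    @classmethod
    def single(cls, amount_mg: float, route: str, time_h: float = 0.0) -> "DosingRegimen":
        return cls(events=((time_h, amount_mg, route),))

    @classmethod
    def repeated(
        cls, amount_mg: float, route: str, n_doses: int, interval_h: float
    ) -> "DosingRegimen":
        return cls(events=tuple(
            (i * interval_h, amount_mg, route) for i in range(n_doses)
        ))

    @property
    def total_dose(self) -> float:
        return sum(amt for _, amt, _ in self.events)


@dataclass
class PBPKModel:
    """Assembled whole-body model (use :func:`build_model`)."""

    compound: CompoundProperties
    physiology: SpeciesPhysiology
    kps: KpSet
    clearance_l_h: float
    absorption: AbsorptionParameters
    renal_fraction: float = 0.0
    clint_hepatic_blood: float = 0.0   # derived
    clint_renal_blood: float = 0.0     # derived

    @property
    def vss_l(self) -> float:
        """Plasma-referenced steady-state volume implied by the Kp set."""
        phys = self.physiology
        return phys.v_blood * self.compound.blood_plasma_ratio + sum(
            kp * phys.volumes[t] for t, kp in self.kps.values.items()
        )

    @property
    def hepatic_escape(self) -> float:
        """Fraction of portally absorbed drug escaping hepatic first pass."""
        qh = self.physiology.qh_l_h
        return qh / (qh + self.clint_hepatic_blood)

    def with_clearance(self, clearance_l_h: float) -> "PBPKModel":
        return build_model(
            self.compound, self.physiology, self.kps, clearance_l_h,
            self.absorption, self.renal_fraction,
        )


def build_model(
    compound: CompoundProperties,
    physiology: SpeciesPhysiology,
    kps: KpSet,
    clearance_l_h: float,
    absorption: AbsorptionParameters | None = None,
    renal_fraction: float = 0.0,
) -> PBPKModel:
    """Validate inputs and back-calculate the elimination rate constants.

    ``clearance_l_h`` is the systemic plasma clearance the IV simulation must
    reproduce; ``renal_fraction`` routes that share of it through the kidney.
    """
    if not physiology.has_full_body():
        raise ConfigurationError(
            f"{physiology.species} physiology lacks whole-body tables"
        )
    try:
        physiology.validate_closure()
    except ValueError as exc:
        raise PhysiologyValidationError(str(exc)) from exc
    missing = [t for t in TISSUES if t not in kps.values]
    if missing:
        raise ConfigurationError(f"Kp set lacks tissues {missing}")
    if clearance_l_h < 0:
        raise ConfigurationError("clearance must be non-negative")
    if not 0 <= renal_fraction <= 1:
        raise ConfigurationError("renal_fraction must lie in [0, 1]")
    if absorption is None:
        absorption = absorption_for(compound, physiology)

    rbp = compound.blood_plasma_ratio
    cl_b = clearance_l_h / rbp
    cl_hep_b = (1.0 - renal_fraction) * cl_b
    cl_ren_b = renal_fraction * cl_b
    qh = physiology.qh_l_h
    qk = physiology.flows["kidney"]
    if cl_hep_b >= qh:
        raise ConfigurationError(
            f"hepatic blood clearance {cl_hep_b:.3g} L/h exceeds hepatic blood "
            f"flow {qh:.3g} L/h; the well-stirred model cannot reach it"
        )
    if cl_ren_b >= qk:
        raise ConfigurationError("renal blood clearance exceeds kidney blood flow")
    clint_h = qh * cl_hep_b / (qh - cl_hep_b) if cl_hep_b > 0 else 0.0
    clint_r = qk * cl_ren_b / (qk - cl_ren_b) if cl_ren_b > 0 else 0.0
    return PBPKModel(
        compound=compound, physiology=physiology, kps=kps,
        clearance_l_h=clearance_l_h, absorption=absorption,
        renal_fraction=renal_fraction,
        clint_hepatic_blood=clint_h, clint_renal_blood=clint_r,
    )


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

_ORGAN_ORDER = tuple(t for t in TISSUES if t != "lung")
_TO_VENOUS = tuple(
    t for t in _ORGAN_ORDER if t not in ("gut", "spleen")
)  # liver included: its outflow is hepatic venous


@dataclass
class SimulationResult:
    """Dense per-compartment trajectories of one simulation.

    ``plasma`` is venous plasma concentration (ng/mL); ``tissues`` are total
    tissue concentrations (ng/mL); ``ledger`` tracks cumulative amounts (mg)
    for mass-balance accounting.
    """

    times: np.ndarray
    plasma: np.ndarray
    tissues: dict[str, np.ndarray]
    ledger: dict[str, np.ndarray]
    dosed: np.ndarray               # cumulative dose administered by each time
    model: PBPKModel
    regimen: DosingRegimen

    def sample(self, times: np.ndarray) -> np.ndarray:
        """Plasma concentration interpolated at arbitrary times."""
        return np.interp(np.asarray(times, dtype=float), self.times, self.plasma)

    def mass_balance_error(self) -> float:
        """Max relative deviation of (in-system + eliminated + unabsorbed)
        from the administered dose, over times after the first dose."""
        total = sum(self.ledger.values())
        mask = self.dosed > 0
        return float(np.max(np.abs(total[mask] - self.dosed[mask]) / self.dosed[mask]))

    def to_frame(self):
        import pandas as pd

        data = {"time_h": self.times, "plasma": self.plasma}
        data.update({t: c for t, c in self.tissues.items()})
        return pd.DataFrame(data)


def _rhs_factory(model: PBPKModel):
    phys = model.physiology
    rbp = model.compound.blood_plasma_ratio
    a = model.absorption

    n_org = len(_ORGAN_ORDER)
    i_lung, i_art, i_ven = 0, 1, 2
    org0 = 3
    sol0 = org0 + n_org
    dis0 = sol0 + N_TRANSIT
    i_hep = dis0 + N_TRANSIT
    i_ren = i_hep + 1
    i_gut_fp = i_ren + 1
    i_feces = i_gut_fp + 1
    n_states = i_feces + 1

    v_org = np.array([phys.volumes[t] for t in _ORGAN_ORDER])
    q_org = np.array([phys.flows[t] for t in _ORGAN_ORDER])
    kp_org = np.array([model.kps.values[t] for t in _ORGAN_ORDER])
    v_lung, kp_lung = phys.volumes["lung"], model.kps.values["lung"]
    v_art, v_ven = phys.v_arterial, phys.v_venous
    co = phys.cardiac_output_l_h
    idx = {t: i for i, t in enumerate(_ORGAN_ORDER)}
    i_liv, i_kid, i_gut, i_spl = idx["liver"], idx["kidney"], idx["gut"], idx["spleen"]
    to_ven = np.array([idx[t] for t in _TO_VENOUS])
    # arterial inflow per organ: liver receives only the hepatic artery
    q_in = q_org.copy()
    q_ha = q_org[i_liv] - q_org[i_gut] - q_org[i_spl]
    q_in[i_liv] = q_ha

    clint_h, clint_r = model.clint_hepatic_blood, model.clint_renal_blood
    ka, kt, kd, fg = a.ka, a.kt, a.kd, a.fg

    def rhs(t, y):
        dy = np.zeros_like(y)
        c_art = y[i_art] / v_art
        c_ven = y[i_ven] / v_ven
        c_lung_out = y[i_lung] / v_lung * rbp / kp_lung
        c_out = y[org0:org0 + n_org] / v_org * rbp / kp_org

        solid = y[sol0:sol0 + N_TRANSIT]
        dissolved = y[dis0:dis0 + N_TRANSIT]
        absorbed_flux = ka * dissolved.sum()

        dy[i_lung] = co * (c_ven - c_lung_out)
        dy[i_art] = co * c_lung_out - co * c_art
        d_org = q_in * c_art - q_org * c_out
        d_org[i_liv] += (
            q_org[i_gut] * c_out[i_gut]
            + q_org[i_spl] * c_out[i_spl]
            + fg * absorbed_flux
            - clint_h * c_out[i_liv]
        )
        d_org[i_kid] -= clint_r * c_out[i_kid]
        dy[org0:org0 + n_org] = d_org
        dy[i_ven] = float(q_org[to_ven] @ c_out[to_ven]) - co * c_ven

        d_solid = -(kd + kt) * solid
        d_solid[1:] += kt * solid[:-1]
        d_dis = kd * solid - (ka + kt) * dissolved
        d_dis[1:] += kt * dissolved[:-1]
        dy[sol0:sol0 + N_TRANSIT] = d_solid
        dy[dis0:dis0 + N_TRANSIT] = d_dis

        dy[i_hep] = clint_h * c_out[i_liv]
        dy[i_ren] = clint_r * c_out[i_kid]
        dy[i_gut_fp] = (1.0 - fg) * absorbed_flux
        dy[i_feces] = kt * (solid[-1] + dissolved[-1])
        return dy

    layout = {
        "n_states": n_states, "i_lung": i_lung, "i_art": i_art, "i_ven": i_ven,
        "org0": org0, "sol0": sol0, "dis0": dis0, "i_hep": i_hep,
        "i_ren": i_ren, "i_gut_fp": i_gut_fp, "i_feces": i_feces,
        "v_org": v_org, "v_art": v_art, "v_ven": v_ven, "v_lung": v_lung,
    }
    return rhs, layout


def simulate(
    model: PBPKModel,
    regimen: DosingRegimen,
    t_end: float,
    grid_dt: float = 0.05,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> SimulationResult:
    """Integrate the model under a dosing regimen up to ``t_end`` hours.

    Dosing events are applied as state jumps between integration segments of
    one continuous solve (stiff LSODA, dense fixed output grid).  The result
    is deterministic for fixed inputs and tolerances.
    """
    if t_end <= max(t for t, _, _ in regimen.events):
        raise ConfigurationError("t_end must lie beyond the last dose")
    rhs, layout = _rhs_factory(model)
    n = layout["n_states"]
    grid = np.arange(0.0, t_end + grid_dt / 2, grid_dt)
    # refine the output grid just after each dose so the fast venous-mixing
    # transient of a bolus is resolved by trapezoidal post-processing
    refine = [grid]
    for t_ev, _, route in regimen.events:
        if route == "iv_bolus":
            refine.append(t_ev + np.geomspace(1e-5, 1.0, 80))
    grid = np.unique(np.concatenate(refine))
    grid = grid[grid <= t_end]

    event_times = sorted({t for t, _, _ in regimen.events})
    boundaries = event_times + [t_end]
    y = np.zeros(n)
    times_out: list[np.ndarray] = []
    states_out: list[np.ndarray] = []
    t_prev = 0.0
    if boundaries[0] > 0.0:
        boundaries = [0.0] + boundaries
    for seg_i in range(len(boundaries) - 1):
        t0, t1 = boundaries[seg_i], boundaries[seg_i + 1]
        for t_ev, amt, route in regimen.events:
            if t_ev == t0:
                if route == "iv_bolus":
                    y[layout["i_ven"]] += amt
                else:
                    y[layout["sol0"]] += amt
        t_eval = grid[(grid >= t0) & (grid <= t1)]
        if t_eval.size == 0 or t_eval[0] > t0:
            t_eval = np.concatenate([[t0], t_eval])
        if t_eval[-1] < t1:
            t_eval = np.concatenate([t_eval, [t1]])
        sol = solve_ivp(
            rhs, (t0, t1), y, method="LSODA", t_eval=t_eval,
            rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise E0703PKError(
                f"integrator failed on [{t0}, {t1}]: {sol.message}; "
                "consider loosening rtol/atol"
            )
        y = sol.y[:, -1].copy()
        # at dose boundaries keep the post-dose state (next segment's first
        # sample), so the ledger at an event time includes the new dose
        last = seg_i == len(boundaries) - 2
        keep = slice(None) if last else slice(None, -1)
        times_out.append(sol.t[keep])
        states_out.append(sol.y[:, keep])

    times = np.concatenate(times_out)
    states = np.concatenate(states_out, axis=1)

    neg = states.min()
    if neg < -1e-6 * regimen.total_dose:
        raise E0703PKError(f"negative state amount beyond tolerance: {neg:.3g} mg")
    states = np.clip(states, 0.0, None)

    rbp = model.compound.blood_plasma_ratio
    plasma = states[layout["i_ven"]] / layout["v_ven"] / rbp * 1000.0
    tissues = {"lung": states[layout["i_lung"]] / layout["v_lung"] * 1000.0}
    for i, t in enumerate(_ORGAN_ORDER):
        tissues[t] = states[layout["org0"] + i] / layout["v_org"][i] * 1000.0

    in_system = states[: layout["sol0"] + 2 * N_TRANSIT].sum(axis=0)
    ledger = {
        "in_system": in_system,
        "eliminated_hepatic": states[layout["i_hep"]],
        "eliminated_renal": states[layout["i_ren"]],
        "eliminated_gut_first_pass": states[layout["i_gut_fp"]],
        "feces": states[layout["i_feces"]],
    }
    dosed = np.array([
        sum(amt for t_ev, amt, _ in regimen.events if t_ev <= t) for t in times
    ])
    return SimulationResult(
        times=times, plasma=plasma, tissues=tissues, ledger=ledger,
        dosed=dosed, model=model, regimen=regimen,
    )


def simulate_oral(
    model: PBPKModel, regimen: DosingRegimen, t_end: float, **kwargs
) -> SimulationResult:
    """Oral-route simulation; oral bioavailability F = Fa*Fg*Fh emerges from
    the absorption chain and hepatic first pass."""
    if any(route != "oral" for _, _, route in regimen.events):
        raise ConfigurationError("simulate_oral expects an all-oral regimen")
    if model.absorption.ka == 0:
        raise ConfigurationError("absorption parameters not set (ka = 0)")
    return simulate(model, regimen, t_end, **kwargs)


def oral_bioavailability(model: PBPKModel) -> float:
    """Closed-form F = Fa * Fg * Fh for the model's absorption chain."""
    fa = fraction_absorbed(model.absorption)
    return fa * model.absorption.fg * model.hepatic_escape


def tissue_exposure(
    result: SimulationResult, tissues: list[str]
) -> dict[str, dict[str, float]]:
    """Per-tissue Cmax, Tmax and grid AUC (ng/mL, h, ng*h/mL) from simulated
    curves; ``"plasma"`` is accepted alongside tissue names."""
    out: dict[str, dict[str, float]] = {}
    for name in tissues:
        if name == "plasma":
            curve = result.plasma
        elif name in result.tissues:
            curve = result.tissues[name]
        else:
            raise ConfigurationError(
                f"unknown tissue {name!r}; available: "
                f"{['plasma'] + sorted(result.tissues)}"
            )
        imax = int(curve.argmax())
        out[name] = {
            "cmax": float(curve[imax]),
            "tmax": float(result.times[imax]),
            "auc": float(np.trapezoid(curve, result.times)),
        }
    return out


def iv_moments(result: SimulationResult) -> tuple[float, float, float]:
    """(AUC0-inf, AUMC0-inf, MRT) of the plasma curve with exponential tail
    extrapolation from the final 10% of the grid."""
    t, c = result.times, result.plasma
    tail = (t >= 0.9 * t[-1]) & (c > 0)
    slope = np.polyfit(t[tail], np.log(c[tail]), 1)[0]
    lam = -slope
    if lam <= 0:
        raise E0703PKError("plasma curve not in terminal decline at t_end")
    auc = float(np.trapezoid(c, t)) + c[-1] / lam
    aumc = float(np.trapezoid(c * t, t)) + c[-1] * t[-1] / lam + c[-1] / lam**2
    return auc, aumc, aumc / auc


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def calibrate_fg(
    model: PBPKModel,
    dose_mg: float,
    target_auc_inf: float,
) -> PBPKModel:
    """Set the gut first-pass factor Fg so the oral AUC0-inf matches a target.

    The model is dose-linear, so ``AUC0-inf = Fa*Fg*Fh*Dose/CL`` exactly and
    Fg solves in closed form; it is clipped to (0, 1].
    """
    if target_auc_inf <= 0 or dose_mg <= 0:
        raise ConfigurationError("dose and target AUC must be positive")
    fa = fraction_absorbed(model.absorption)
    fh = model.hepatic_escape
    if fa * fh == 0:
        raise ConfigurationError("no absorption route (Fa*Fh = 0)")
    # target in ng*h/mL = ug*h/L; dose mg -> ug
    fg = target_auc_inf * model.clearance_l_h / (dose_mg * 1000.0 * fa * fh)
    fg = min(fg, 1.0)
    absorption = replace(model.absorption, fg=fg)
    return build_model(
        model.compound, model.physiology, model.kps, model.clearance_l_h,
        absorption, model.renal_fraction,
    )


def calibrate_disposition(
    times_h: np.ndarray,
    conc_ng_ml: np.ndarray,
    dose_mg: float,
    template: PBPKModel,
    seed: int = 20240306,
    n_starts: int = 3,
    grid_dt: float = 0.1,
) -> tuple[PBPKModel, dict[str, float]]:
    """Fit systemic clearance and a uniform Kp scale to an oral profile.

    This is the top-down step of the workflow: absorption (ka, kt, kd, Fg)
    stays fixed at the template's values and (CL, Vss) are estimated by
    bounded multi-start least squares on log concentrations.  Returns the
    refitted model and ``{"cl_l_h", "vss_l", "kp_scale", "loss"}``.
    """
    times_h = np.asarray(times_h, dtype=float)
    conc = np.asarray(conc_ng_ml, dtype=float)
    mask = (times_h > 0) & np.isfinite(conc) & (conc > 0)
    if mask.sum() < 4:
        raise ConfigurationError("need >= 4 positive observations to calibrate")
    t_obs, c_obs = times_h[mask], conc[mask]
    t_end = float(t_obs[-1]) + grid_dt
    regimen = DosingRegimen.single(dose_mg, "oral")
    qh = template.physiology.qh_l_h
    rbp = template.compound.blood_plasma_ratio
    log_c_obs = np.log(c_obs)

    def build(theta):
        cl = math.exp(theta[0])
        scale = math.exp(theta[1])
        return build_model(
            template.compound, template.physiology,
            template.kps.scaled(scale),
            cl, template.absorption, template.renal_fraction,
        )

    def residuals(theta):
        try:
            sim = simulate(build(theta), regimen, t_end,
                           grid_dt=grid_dt, rtol=1e-6, atol=1e-10)
        except E0703PKError:
            return np.full_like(log_c_obs, 1e3)
        pred = np.clip(sim.sample(t_obs), 1e-9, None)
        return np.log(pred) - log_c_obs

    rng = np.random.default_rng(seed)
    # starting guess: apparent CL from the trapezoidal AUC at a nominal F
    cl0 = max(dose_mg * 1000.0 * 0.003 / max(np.trapezoid(c_obs, t_obs), 1e-9), 1e-5)
    cl0 = min(cl0, 0.5 * qh * rbp)
    hi_cl = math.log(0.95 * qh * rbp)
    best = None
    for k in range(n_starts):
        jitter = rng.normal(0, 0.7, size=2) if k else np.zeros(2)
        x0 = np.clip(np.array([math.log(cl0), 0.0]) + jitter,
                     [-20.0, -10.0], [hi_cl - 1e-6, 10.0])
        res = least_squares(
            residuals, x0, bounds=([-20.0, -10.0], [hi_cl, 10.0]),
            method="trf", diff_step=1e-4, xtol=1e-8, ftol=1e-10,
        )
        if best is None or res.cost < best.cost:
            best = res
    fitted = build(best.x)
    return fitted, {
        "cl_l_h": fitted.clearance_l_h,
        "vss_l": fitted.vss_l,
        "kp_scale": math.exp(best.x[1]),
        "loss": 2.0 * float(best.cost),
    }
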