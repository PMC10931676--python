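"""Synthetic concentration-time data with the study's statistical structure.

Ground truth comes either from a closed-form one-compartment model (fast, for
NCA round-trip checks) or from a PBPK simulation.  Observations are
``truth * lognormal proportional error + additive assay floor``, truncated at
zero — concentrations span three orders of magnitude across doses, so a
multiplicative error model is the realistic choice, with the additive floor
standing in for quantification noise near the LLOQ.

Sampling schedules for the mouse, monkey (oral and IV) and human studies ship
as presets (see :data:`e0703pk.datasets.SCHEDULES`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .nca import ConcentrationTimeProfile
from .pbpk import DosingRegimen, PBPKModel, simulate


@dataclass(frozen=True)
class ErrorModel:
    """Residual-error model for synthetic observations.

    ``proportional_cv`` is the coefficient of variation of the log-normal
    multiplicative error; ``additive_sd`` (ng/mL) is a Gaussian assay floor.
    """

    proportional_cv: float = 0.20
    additive_sd: float = 0.01
    seed: int = 0
    n_subjects: int = 6

    def __post_init__(self) -> None:
        if self.proportional_cv < 0 or self.additive_sd < 0:
            raise ConfigurationError("error magnitudes must be non-negative")
        if self.n_subjects < 1:
            raise ConfigurationError("need at least one subject")


@dataclass(frozen=True)
class OneCompartmentPK:
    """Closed-form one-compartment disposition with first-order absorption.

    For oral dosing ``C(t) = F*D*ka/(V*(ka-ke)) * (e^-ke t - e^-ka t)``; for
    IV bolus ``C(t) = D/V * e^-ke t`` with ``ke = CL/V``.  Doses in mg,
    volumes in L, output in ng/mL.
    """

    cl_l_h: float
    v_l: float
    ka_per_h: float = 1.0
    f: float = 1.0

    @property
    def ke(self) -> float:
        return self.cl_l_h / self.v_l

    def concentration(
        self, times_h: np.ndarray, dose_mg: float, route: str
    ) -> np.ndarray:
        t = np.asarray(times_h, dtype=float)
        ke = self.ke
        if route == "intravenous" or route == "iv_bolus":
            c_mg_l = dose_mg / self.v_l * np.exp(-ke * t)
        elif route == "oral":
            ka = self.ka_per_h
            if abs(ka - ke) < 1e-12:
                c_mg_l = self.f * dose_mg * ka * t / self.v_l * np.exp(-ke * t)
            else:
                c_mg_l = (
                    self.f * dose_mg * ka / (self.v_l * (ka - ke))
                    * (np.exp(-ke * t) - np.exp(-ka * t))
                )
        else:
            raise ConfigurationError(f"unknown route {route!r}")
        return c_mg_l * 1000.0  # mg/L -> ng/mL


def _truth_curve(
    model, regimen: DosingRegimen, schedule: np.ndarray
) -> np.ndarray:
    if isinstance(model, OneCompartmentPK):
        if len(regimen.events) != 1:
            raise ConfigurationError(
                "closed-form truth supports single-dose regimens only"
            )
        _, amt, route = regimen.events[0]
        return model.concentration(schedule, amt, route)
    if isinstance(model, PBPKModel):
        t_end = float(schedule[-1]) + 0.05
        sim = simulate(model, regimen, t_end)
        return sim.sample(schedule)
    raise ConfigurationError("model must be OneCompartmentPK or PBPKModel")


def generate_profiles(
    model,
    regimen: DosingRegimen,
    schedule,
    error: ErrorModel,
    species: str = "",
    body_weight: float | None = None,
    label: str = "",
) -> list[ConcentrationTimeProfile]:
    """Per-subject serial-sampling profiles from a generating model.

    Deterministic given ``error.seed``; with ``cv = sd = 0`` the profiles
    equal the truth exactly.
    """
    schedule = np.asarray(schedule, dtype=float)
    if schedule.size == 0:
        raise ConfigurationError("empty sampling schedule")
    truth = _truth_curve(model, regimen, schedule)
    rng = np.random.default_rng(error.seed)
    route = "intravenous" if all(
        r == "iv_bolus" for _, _, r in regimen.events
    ) else "oral"
    dose = regimen.total_dose
    profiles = []
    for subj in range(error.n_subjects):
        if error.proportional_cv > 0:
            sigma = math.sqrt(math.log(1.0 + error.proportional_cv**2))
            mult = rng.lognormal(-0.5 * sigma**2, sigma, size=schedule.size)
        else:
            mult = np.ones(schedule.size)
        add = (
            rng.normal(0.0, error.additive_sd, size=schedule.size)
            if error.additive_sd > 0 else 0.0
        )
        obs = np.clip(truth * mult + add, 0.0, None)
        profiles.append(ConcentrationTimeProfile(
            times=schedule.copy(), concentrations=obs,
            dose_amount=dose, route=route, species=species,
            body_weight=body_weight,
            label=label or f"subject {subj + 1}",
        ))
    return profiles


def mean_profile(profiles: list[ConcentrationTimeProfile]) -> ConcentrationTimeProfile:
    """Arithmetic-mean group profile on the common schedule (the study reports
    group means of six/five animals per time point)."""
    if not profiles:
        raise ConfigurationError("no profiles to average")
    t0 = profiles[0].times
    stack = []
    for p in profiles:
        if p.times.shape != t0.shape or not np.allclose(p.times, t0):
            raise ConfigurationError("profiles must share a sampling schedule")
        stack.append(p.concentrations)
    ref = profiles[0]
    return ConcentrationTimeProfile(
        times=t0.copy(), concentrations=np.mean(stack, axis=0),
        dose_amount=ref.dose_amount, route=ref.route, species=ref.species,
        body_weight=ref.body_weight, label="group mean",
    )


def dose_proportional_family(
    base_model,
    doses_mg: list[float],
    schedule,
    error: ErrorModel,
    route: str = "oral",
    **profile_kwargs,
) -> dict[float, list[ConcentrationTimeProfile]]:
    """Datasets at several dose levels from one linear generating model.

    With zero noise, Cmax and AUC scale exactly with dose (the models carry
    no saturable terms).
    """
    if not doses_mg:
        raise ConfigurationError("need at least one dose")
    out = {}
    for i, dose in enumerate(doses_mg):
        regimen = DosingRegimen.single(
            dose, "iv_bolus" if route in ("intravenous", "iv_bolus") else "oral"
        )
        err = ErrorModel(
            proportional_cv=error.proportional_cv,
            additive_sd=error.additive_sd,
            seed=error.seed + i, n_subjects=error.n_subjects,
        )
        out[dose] = generate_profiles(
            base_model, regimen, schedule, err, **profile_kwargs
        )
    return out
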