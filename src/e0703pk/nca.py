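"""Non-compartmental analysis of concentration-time profiles.

Implements the standard NCA chain: trapezoidal AUC (linear or linear-up /
log-down), terminal slope selection by best adjusted R-squared, extrapolation
to infinity, moment analysis (AUMC, MRT) and the dose-normalized disposition
parameters CL/F and Vss/F.  Apparent oral parameters and intravenous CL/Vss
share one result type: for the IV route F = 1 and the same fields are the true
clearance and steady-state volume.

Conventions (these reproduce the arithmetic of the study's printed tables):

* AUC in ng*h/mL, doses in mg (total) or mg/kg, so
  ``CL/F [L/h/kg] = 1000 * dose[mg/kg] / AUC0-inf [ng*h/mL]``.
* ``Vss/F = (CL/F) * MRT`` with MRT taken from the oral curve, i.e. including
  mean absorption time for extravascular dosing.
* Below-limit-of-quantification values are entered as NaN and dropped; a
  leading zero at t=0 is kept for oral profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InvalidProfileError, NotEstimableError

LN2 = math.log(2.0)

ROUTES = ("oral", "intravenous")


@dataclass
class ConcentrationTimeProfile:
    """One subject's (or group mean) sampled plasma concentrations.

    ``dose_amount`` is a total dose in mg unless ``dose_per_kg`` is set, in
    which case it is mg/kg.  NaN concentrations (below the quantification
    limit) are dropped on construction; mid-profile zeros are treated the same
    way, while a zero at t=0 is kept for oral routes (pre-dose sample).
    """

    times: np.ndarray
    concentrations: np.ndarray
    dose_amount: float
    route: str
    species: str = ""
    body_weight: float | None = None
    dose_per_kg: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.shape != c.shape or t.ndim != 1:
            raise InvalidProfileError("times and concentrations must be 1-D and equal length")
        keep = np.isfinite(c)
        # zeros after the curve has risen are below-quantification -> missing;
        # baseline zeros (pre-absorption, or an all-zero profile) are kept
        seen_positive = np.cumsum((c > 0) & keep) > 0
        keep &= (c > 0) | ~seen_positive
        t, c = t[keep], c[keep]
        if t.size < 2:
            raise InvalidProfileError("a profile needs at least two quantifiable points")
        if np.any(np.diff(t) <= 0):
            raise InvalidProfileError("times must be strictly increasing")
        if np.any(c < 0) or not np.all(np.isfinite(c)):
            raise InvalidProfileError("concentrations must be finite and non-negative")
        if self.route not in ROUTES:
            raise InvalidProfileError(f"route must be one of {ROUTES}")
        if not self.dose_amount > 0:
            raise InvalidProfileError("dose_amount must be positive")
        if self.body_weight is not None and not self.body_weight > 0:
            raise InvalidProfileError("body_weight must be positive")
        self.times = t
        self.concentrations = c

    @property
    def dose_mg_per_kg(self) -> float:
        if self.dose_per_kg:
            return self.dose_amount
        if self.body_weight is None:
            raise ConfigurationError(
                "body weight required to normalize a total dose to mg/kg"
            )
        return self.dose_amount / self.body_weight

    @property
    def cmax(self) -> float:
        return float(self.concentrations.max())

    @property
    def tmax(self) -> float:
        return float(self.times[int(self.concentrations.argmax())])


@dataclass
class NCAResult:
    """Exposure metrics derived from one profile.

    Extrapolated fields (``auc_0_inf``, ``t_half``, ``mrt`` and the
    dose-normalized parameters) are NaN when the terminal slope could not be
    estimated.
    """

    cmax: float
    tmax: float
    lambda_z: float
    t_half: float
    auc_0_t: float
    auc_0_inf: float
    aumc_0_inf: float
    mrt: float
    cl_over_f_per_kg: float
    vss_over_f_per_kg: float
    n_lambda_points: int
    r2_adj_lambda: float
    label: str = ""
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def _segment_auc_aumc(t0, t1, c0, c1, method: str) -> tuple[float, float]:
    dt = t1 - t0
    log_down = (
        method == "linear_up_log_down" and c0 > 0 and c1 > 0 and c1 < c0
    )
    if log_down:
        k = math.log(c0 / c1) / dt
        auc = (c0 - c1) / k
        # exact first moment of the exponential interpolant
        aumc = (t0 * c0 - t1 * c1) / k + (c0 - c1) / k ** 2
    else:
        auc = 0.5 * (c0 + c1) * dt
        aumc = 0.5 * (t0 * c0 + t1 * c1) * dt
    return auc, aumc


def compute_auc(profile: ConcentrationTimeProfile, method: str = "linear") -> float:
    """AUC from the first to the last quantifiable sample (ng*h/mL).

    ``linear`` is the plain trapezoid; ``linear_up_log_down`` switches to the
    log-trapezoid on segments where both endpoint concentrations are positive
    and declining.
    """
    if method not in ("linear", "linear_up_log_down"):
        raise ValueError(f"unknown AUC method {method!r}")
    t, c = profile.times, profile.concentrations
    total = 0.0
    for i in range(t.size - 1):
        auc, _ = _segment_auc_aumc(t[i], t[i + 1], c[i], c[i + 1], method)
        total += auc
    return total


def _aumc_0_t(profile: ConcentrationTimeProfile, method: str) -> float:
    t, c = profile.times, profile.concentrations
    total = 0.0
    for i in range(t.size - 1):
        _, aumc = _segment_auc_aumc(t[i], t[i + 1], c[i], c[i + 1], method)
        total += aumc
    return total


# ---------------------------------------------------------------------------
# Terminal slope
# ---------------------------------------------------------------------------

def estimate_lambda_z(
    profile: ConcentrationTimeProfile,
) -> tuple[float, int, float]:
    """Terminal elimination rate constant by best-adjusted-R2 suffix selection.

    Candidate point sets are suffixes (>= 3 points, positive concentrations)
    of the samples after Tmax; the Cmax sample itself is excluded for
    extravascular profiles.  Among candidates with a negative log-linear
    slope, the fit maximizing adjusted R-squared wins; ties within 1e-4 go to
    the fit using more points.  Returns ``(lambda_z, n_points, r2_adj)``.
    """
    t, c = profile.times, profile.concentrations
    imax = int(c.argmax())
    start = imax + 1 if profile.route == "oral" else imax
    idx = [i for i in range(start, t.size) if c[i] > 0]
    if len(idx) < 3:
        raise NotEstimableError("fewer than 3 positive post-Tmax concentrations")

    best: tuple[float, int, float] | None = None
    for j in range(len(idx) - 2):
        sub = idx[j:]
        n = len(sub)
        x = t[sub]
        y = np.log(c[sub])
        slope, intercept = np.polyfit(x, y, 1)
        if slope >= 0:
            continue
        yhat = slope * x + intercept
        ss_res = float(np.sum((y - yhat) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
        r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        if (
            best is None
            or r2_adj > best[2] + 1e-4
            or (abs(r2_adj - best[2]) <= 1e-4 and n > best[1])
        ):
            best = (-slope, n, r2_adj)
    if best is None:
        raise NotEstimableError("no declining terminal subset found")
    return best


# ---------------------------------------------------------------------------
# Summary
# ---------------------------------------------------------------------------

def nca_summary(
    profile: ConcentrationTimeProfile, method: str = "linear"
) -> NCAResult:
    """Full non-compartmental summary of one profile.

    ``AUC0-inf = AUC0-t + Clast/lambda_z``; ``MRT = AUMC0-inf/AUC0-inf`` (all
    doses are bolus or oral, so no infusion correction applies);
    ``Vss/F = (CL/F) * MRT``.  For the intravenous route the same fields are
    CL and Vss proper (F = 1).
    """
    auc_t = compute_auc(profile, method)
    cmax, tmax = profile.cmax, profile.tmax
    try:
        lam, n_lam, r2 = estimate_lambda_z(profile)
    except NotEstimableError:
        return NCAResult(
            cmax=cmax, tmax=tmax, lambda_z=math.nan, t_half=math.nan,
            auc_0_t=auc_t, auc_0_inf=math.nan, aumc_0_inf=math.nan,
            mrt=math.nan, cl_over_f_per_kg=math.nan,
            vss_over_f_per_kg=math.nan, n_lambda_points=0,
            r2_adj_lambda=math.nan, label=profile.label,
        )

    t_last = float(profile.times[-1])
    c_last = float(profile.concentrations[-1])
    auc_inf = auc_t + c_last / lam
    aumc_inf = (
        _aumc_0_t(profile, method)
        + c_last * t_last / lam
        + c_last / lam ** 2
    )
    mrt = aumc_inf / auc_inf
    cl_f = clearance_per_kg(profile.dose_mg_per_kg, auc_inf)
    vss_f = cl_f * mrt
    return NCAResult(
        cmax=cmax, tmax=tmax, lambda_z=lam, t_half=LN2 / lam,
        auc_0_t=auc_t, auc_0_inf=auc_inf, aumc_0_inf=aumc_inf, mrt=mrt,
        cl_over_f_per_kg=cl_f, vss_over_f_per_kg=vss_f,
        n_lambda_points=n_lam, r2_adj_lambda=r2, label=profile.label,
    )


# ---------------------------------------------------------------------------
# Identities on printed aggregates
# ---------------------------------------------------------------------------

def clearance_per_kg(dose_mg_per_kg: float, auc_0_inf: float) -> float:
    """CL/F in L/h/kg from a per-kg dose and AUC0-inf in ng*h/mL."""
    if not auc_0_inf > 0:
        raise NotEstimableError("AUC0-inf must be positive")
    return 1000.0 * dose_mg_per_kg / auc_0_inf


def clearance_total(dose_mg: float, auc_0_inf: float) -> float:
    """CL (or CL/F) in L/h from a total dose in mg and AUC0-inf in ng*h/mL."""
    if not auc_0_inf > 0:
        raise NotEstimableError("AUC0-inf must be positive")
    return 1000.0 * dose_mg / auc_0_inf


def vss_from_cl_mrt(cl: float, mrt: float) -> float:
    """Vss (or Vss/F) as clearance times mean residence time."""
    return cl * mrt


def bioavailability(
    auc_oral: float, dose_oral: float, auc_iv: float, dose_iv: float
) -> float:
    """Absolute oral bioavailability in percent:
    ``F% = 100 * (AUC_oral/Dose_oral) / (AUC_iv/Dose_iv)``.
    Doses must share units (both mg or both mg/kg)."""
    if not (np.isfinite(auc_oral) and np.isfinite(auc_iv)) or auc_iv <= 0:
        raise NotEstimableError("both AUC0-inf values are required")
    if dose_oral <= 0 or dose_iv <= 0:
        raise ConfigurationError("doses must be positive")
    return 100.0 * (auc_oral / dose_oral) / (auc_iv / dose_iv)
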