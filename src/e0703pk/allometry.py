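"""Interspecies clearance scaling.

Four predictors of human clearance are provided:

* **SA** — simple allometry, ``CL = a * BW^b`` fitted by log-log ordinary
  least squares across species.
* **SSS** — single-species scaling from one animal with the fixed exponent
  0.75: ``CL_human = CL_animal * (BW_human/BW_animal)^0.75``.
* **TS** — two-species (rat + monkey) scaling: the coefficient alpha comes
  from a conventional two-point allometric fit and the prediction uses the
  fixed exponent 0.650.
* **IVIVE** — in vitro-to-in vivo extrapolation: the well-stirred hepatic
  clearance per kg converted to whole-body units, ``CL = CLh * BW * 0.06``.

Fits are stored in base-10 (``a = 10^intercept``); natural-log fitting gives
identical parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

SSS_EXPONENT = 0.75
TS_EXPONENT = 0.650


@dataclass
class AllometricFit:
    """Power-law clearance model ``CL = a * BW^b`` (CL in L/h, BW in kg)."""

    coefficient_a: float
    exponent_b: float
    species_points: list[tuple[str, float, float]] = field(default_factory=list)
    r2: float = float("nan")

    def predict(self, body_weight: float) -> float:
        if body_weight <= 0:
            raise ConfigurationError("body weight must be positive")
        return self.coefficient_a * body_weight ** self.exponent_b


def fit_simple_allometry(
    points: list[tuple[float, float]] | list[tuple[str, float, float]],
) -> AllometricFit:
    """Log10-log10 OLS fit of clearance against body weight.

    Accepts ``(bw, cl)`` or ``(species, bw, cl)`` tuples; needs >= 2 points
    with distinct positive weights and positive clearances.
    """
    labelled = [p if len(p) == 3 else ("", p[0], p[1]) for p in points]
    bw = np.array([p[1] for p in labelled], dtype=float)
    cl = np.array([p[2] for p in labelled], dtype=float)
    if bw.size < 2:
        raise ConfigurationError("need at least two species points")
    if np.any(bw <= 0) or np.any(cl <= 0):
        raise ConfigurationError("body weights and clearances must be positive")
    if np.unique(bw).size < 2:
        raise ConfigurationError("body weights must be distinct (singular fit)")
    x, y = np.log10(bw), np.log10(cl)
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return AllometricFit(
        coefficient_a=10.0 ** intercept,
        exponent_b=float(slope),
        species_points=[(s, float(w), float(c)) for s, w, c in labelled],
        r2=r2,
    )


def predict_sa(fit: AllometricFit, body_weight: float) -> float:
    """Clearance at ``body_weight`` from a simple-allometry fit (L/h)."""
    return fit.predict(body_weight)


def predict_sss(cl_animal: float, bw_animal: float, bw_human: float) -> float:
    """Single-species scaling with the fixed exponent 0.75 (L/h)."""
    if min(cl_animal, bw_animal, bw_human) <= 0:
        raise ConfigurationError("all inputs must be positive")
    return cl_animal * (bw_human / bw_animal) ** SSS_EXPONENT


def predict_ts(
    cl_rat: float, bw_rat: float, cl_monkey: float, bw_monkey: float,
    bw_human: float,
) -> float:
    """Two-species (rat-monkey) scaling with the fixed exponent 0.650 (L/h).

    The coefficient alpha is the intercept of the conventional two-point
    log-log fit; only alpha is retained, the fit's own exponent is replaced
    by 0.650 for the human prediction.
    """
    if min(cl_rat, bw_rat, cl_monkey, bw_monkey, bw_human) <= 0:
        raise ConfigurationError("all inputs must be positive")
    fit = fit_simple_allometry([(bw_rat, cl_rat), (bw_monkey, cl_monkey)])
    return fit.coefficient_a * bw_human ** TS_EXPONENT


def predict_ivive(clh_ml_min_kg: float, bw_human: float) -> float:
    """Whole-body clearance (L/h) from per-kg hepatic clearance (mL/min/kg)."""
    if clh_ml_min_kg < 0 or bw_human <= 0:
        raise ConfigurationError("inputs must be non-negative / positive")
    return clh_ml_min_kg * bw_human * 60.0 / 1000.0
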