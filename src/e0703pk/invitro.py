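"""In vitro ADME parameter derivation.

Covers the four assay families feeding the PBPK chain:

* Caco-2 monolayer transport: apparent permeability
  ``Papp = (dCr/dt) * Vr / (A * C0)``, efflux ratio, and mass-balance
  recovery.
* Equilibrium dialysis: fraction unbound ``fu = C_buffer / C_plasma``.
* Microsomal depletion: first-order rate from the log-linear remaining
  fraction, ``T1/2 = 0.693/k``, scaled to intrinsic clearance per kg body
  weight and to hepatic clearance by the well-stirred liver model
  ``CLh = Qh * CLint / (Qh + CLint)``.
* Recombinant-CYP reaction phenotyping by the total-normalized-rate (TNR)
  method: per-isoform rate x hepatic abundance as a percent of the sum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .datasets import SpeciesPhysiology
from .errors import ConfigurationError, InvalidAssayError

LN2 = math.log(2.0)


# ---------------------------------------------------------------------------
# Caco-2
# ---------------------------------------------------------------------------

@dataclass
class CacoAssay:
    """One directional Caco-2 transport experiment.

    Receiver-series times are in seconds and concentrations in uM;
    chamber volumes in mL, monolayer area in cm^2.  Default geometry is the
    96-well insert system used in the study: apical volume 0.1 mL,
    basolateral 0.25 mL, area 0.0804 cm^2, donor concentration 10 uM.
    """

    c0_donor: float
    receiver_series: np.ndarray          # shape (n, 2): time_s, conc_um
    direction: str = "A_to_B"
    v_receiver: float = 0.1
    v_donor: float = 0.1
    area: float = 0.0804
    final_donor_conc: float | None = None
    final_receiver_conc: float | None = None
    cell_lysate_conc: float | None = None
    v_cell: float = 0.1

    def __post_init__(self) -> None:
        if self.c0_donor <= 0:
            raise InvalidAssayError("donor concentration must be positive")
        if min(self.v_receiver, self.v_donor, self.area) <= 0:
            raise InvalidAssayError("volumes and area must be positive")
        if self.direction not in ("A_to_B", "B_to_A"):
            raise InvalidAssayError("direction must be A_to_B or B_to_A")
        series = np.asarray(self.receiver_series, dtype=float)
        if series.ndim != 2 or series.shape[1] != 2 or series.shape[0] < 2:
            raise InvalidAssayError("receiver_series needs >= 2 (time, conc) rows")
        if np.any(np.diff(series[:, 0]) <= 0):
            raise InvalidAssayError("receiver-series times must be increasing")
        self.receiver_series = series


def apparent_permeability(assay: CacoAssay) -> float:
    """Apparent permeability coefficient in cm/s.

    ``dCr/dt`` is estimated by ordinary least squares over the full receiver
    series (uM/s); a negative slope is clipped to zero with a warning.
    """
    t = assay.receiver_series[:, 0]
    c = assay.receiver_series[:, 1]
    if np.ptp(t) == 0:
        raise InvalidAssayError("receiver times are identical; slope is singular")
    slope = float(np.polyfit(t, c, 1)[0])
    if slope < 0:
        warnings.warn("negative receiver slope; Papp clipped to 0", stacklevel=2)
        slope = 0.0
    return slope * assay.v_receiver / (assay.area * assay.c0_donor)


def efflux_ratio(papp_ab: float, papp_ba: float) -> float:
    """``Papp(B->A) / Papp(A->B)``; values > 2 suggest active efflux."""
    if papp_ab <= 0:
        raise InvalidAssayError("A->B permeability must be positive for the ratio")
    if papp_ba < 0:
        raise InvalidAssayError("permeabilities must be non-negative")
    return papp_ba / papp_ab


def recovery(assay: CacoAssay) -> tuple[float, float]:
    """Percent mass recovery and total recovery (including the cell fraction).

    ``%Recovery = 100 * (Vr*Cr + Vd*Cd) / (Vd*C0)``; total recovery adds
    ``Vc*Cc``.  Total recovery is NaN when no lysate measurement exists.
    """
    if assay.final_donor_conc is None or assay.final_receiver_conc is None:
        raise ConfigurationError("final donor and receiver concentrations required")
    dosed = assay.v_donor * assay.c0_donor
    recovered = (
        assay.v_receiver * assay.final_receiver_conc
        + assay.v_donor * assay.final_donor_conc
    )
    rec = 100.0 * recovered / dosed
    if assay.cell_lysate_conc is None:
        return rec, math.nan
    total = 100.0 * (recovered + assay.v_cell * assay.cell_lysate_conc) / dosed
    return rec, total


# ---------------------------------------------------------------------------
# Plasma protein binding
# ---------------------------------------------------------------------------

@dataclass
class BindingAssay:
    """Single-read equilibrium dialysis endpoint (5 h, 37 C)."""

    donor_conc_end: float      # plasma side
    receiver_conc_end: float   # buffer side
    species: str = ""

    def __post_init__(self) -> None:
        if self.donor_conc_end < 0 or self.receiver_conc_end < 0:
            raise InvalidAssayError("concentrations must be non-negative")


def fraction_unbound(assay: BindingAssay) -> float:
    """``fu = C_buffer / C_plasma`` at equilibrium, clipped to [0, 1].

    No volume-shift correction is applied (single-read design)."""
    if assay.donor_conc_end <= 0:
        raise InvalidAssayError("plasma-side concentration must be positive")
    return float(np.clip(assay.receiver_conc_end / assay.donor_conc_end, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Microsomal depletion and hepatic clearance
# ---------------------------------------------------------------------------

@dataclass
class MicrosomeAssay:
    """Remaining-fraction series from a microsomal stability incubation."""

    remaining_fraction_series: np.ndarray   # shape (n, 2): time_min, fraction
    species: str = ""
    protein_conc_mg_ml: float = 0.5

    def __post_init__(self) -> None:
        series = np.asarray(self.remaining_fraction_series, dtype=float)
        if series.ndim != 2 or series.shape[1] != 2 or series.shape[0] < 3:
            raise InvalidAssayError("need >= 3 (time, fraction) rows")
        if np.any(np.diff(series[:, 0]) <= 0):
            raise InvalidAssayError("times must be increasing")
        f0 = series[series[:, 0] == series[0, 0], 1]
        if series[0, 0] == 0 and abs(f0[0] - 1.0) > 0.05:
            raise InvalidAssayError("fraction at t=0 must be ~1")
        if np.any(series[:, 1] > 1.2) or np.any(series[:, 1] < 0):
            raise InvalidAssayError("fractions must lie in (0, 1.2]")
        self.remaining_fraction_series = series


def depletion_half_life(assay: MicrosomeAssay) -> tuple[float, float]:
    """First-order depletion rate ``kappa`` (1/min) and ``T1/2 = 0.693/kappa``.

    ``kappa`` is minus the least-squares slope of ln(remaining fraction)
    against time.  A non-depleting series returns ``(0, inf)`` — the
    stable-compound flag."""
    series = assay.remaining_fraction_series
    pos = series[:, 1] > 0
    if pos.sum() < 3:
        raise InvalidAssayError("need >= 3 positive fractions")
    t = series[pos, 0]
    y = np.log(series[pos, 1])
    slope = float(np.polyfit(t, y, 1)[0])
    kappa = -slope
    if kappa <= 0:
        return 0.0, math.inf
    return kappa, LN2 / kappa


def scale_clint(
    t_half_min: float, species: str, physiology: SpeciesPhysiology
) -> float:
    """Microsomal intrinsic clearance in mL/min/kg body weight.

    ``CLint = (0.693/T1/2) * (incubation mL / mg protein)
              * (mg microsomal protein / g liver) * (g liver / kg BW)``.
    """
    if not t_half_min > 0:
        raise ConfigurationError("depletion half-life must be positive")
    if math.isinf(t_half_min):
        return 0.0
    for attr in ("incubation_ml_per_mg", "microsomal_mg_per_g_liver", "liver_g_per_kg"):
        if not getattr(physiology, attr, 0) > 0:
            raise ConfigurationError(f"physiology for {species} lacks {attr}")
    return (
        LN2 / t_half_min
        * physiology.incubation_ml_per_mg
        * physiology.microsomal_mg_per_g_liver
        * physiology.liver_g_per_kg
    )


def well_stirred_clh(clint: float, qh: float) -> float:
    """Hepatic clearance from the well-stirred liver model (same units as
    inputs, conventionally mL/min/kg): ``CLh = Qh*CLint/(Qh + CLint)``.

    Bounded above by hepatic blood flow; reduces to CLint when CLint << Qh.
    """
    if qh <= 0:
        raise ConfigurationError("hepatic blood flow must be positive")
    if clint < 0:
        raise ConfigurationError("intrinsic clearance must be non-negative")
    return qh * clint / (qh + clint)


def hepatic_extraction(clh: float, qh: float) -> float:
    """Hepatic extraction ratio in percent, ``100 * CLh/Qh``."""
    if not 0 <= clh < qh:
        raise ConfigurationError("need 0 <= CLh < Qh")
    return 100.0 * clh / qh


# ---------------------------------------------------------------------------
# CYP reaction phenotyping
# ---------------------------------------------------------------------------

@dataclass
class CypPanel:
    """Recombinant-CYP rates with hepatic abundances.

    ``records`` maps isoform name -> (rate pmol/min/pmol rCYP,
    abundance pmol CYP/mg microsomal protein).  Feeding pre-normalized rates
    with unit abundance is supported (used when the normalized rates
    themselves are the authoritative measurements).
    """

    records: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.records:
            raise InvalidAssayError("panel needs at least one isoform")
        for iso, (rate, abundance) in self.records.items():
            if rate < 0:
                raise InvalidAssayError(f"negative rate for {iso}")
            if abundance <= 0:
                raise InvalidAssayError(f"non-positive abundance for {iso}")

    def normalized_rates(self) -> dict[str, float]:
        """Per-isoform rate x abundance (pmol/min/mg microsomal protein)."""
        return {iso: r * a for iso, (r, a) in self.records.items()}


def tnr_phenotyping(panel: CypPanel) -> dict[str, float]:
    """Percent contribution of each isoform by the total-normalized-rate
    method; contributions sum to 100."""
    norm = panel.normalized_rates()
    total = sum(norm.values())
    if total <= 0:
        raise InvalidAssayError("all rates are zero; phenotype undefined")
    return {iso: 100.0 * v / total for iso, v in norm.items()}
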