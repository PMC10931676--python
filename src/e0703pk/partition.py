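"""Tissue-to-plasma partition coefficient (Kp) prediction and whole-body Vss.

Four tissue-composition methods are implemented:

* ``poulin_theil`` — solubility-weighted water/lipid partitioning with the
  unbound-fraction ratio ``fu_p/fu_t`` applied to the whole tissue:plasma
  quotient; ``fu_t`` assumes interstitial binding at half plasma strength.
* ``berezhkovskiy`` — the same composition terms with the unbound fractions
  moved inside the aqueous terms (the two methods coincide when ``fu_p = 1``).
* ``rodgers_rowland`` — unbound partition coefficient ``Kpu`` built from
  extra/intracellular water, neutral lipid and phospholipid partitioning plus
  ionic or protein binding terms, then ``Kp = Kpu * fu_p``.  Ionized species
  associate with acidic phospholipids (bases) or extracellular proteins
  (acids/neutrals); the protein association constant is back-calculated from
  plasma binding and floored at zero.
* ``rodgers_single`` — the single unified equation covering all compound
  classes; for a neutral compound it reduces to the same expression as
  ``rodgers_rowland``, so the two columns coincide exactly (as they should
  for a non-ionized steroid).

Neutral-lipid partitioning uses the octanol:water coefficient, except in
adipose where the vegetable-oil:water coefficient
``log Pvow = 1.115 logP - 1.35`` is substituted.

``Vss = V_blood * Rb:p + sum_t Kp_t * V_t`` referenced to plasma
concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .datasets import (
    PLASMA_COMPOSITION,
    TISSUE_COMPOSITION,
    CompoundProperties,
    SpeciesPhysiology,
    TissueComposition,
)
from .errors import ConfigurationError

KP_METHODS = ("poulin_theil", "berezhkovskiy", "rodgers_rowland", "rodgers_single")

PH_PLASMA = 7.4
PH_INTRACELLULAR = 7.0


@dataclass
class KpSet:
    """Per-tissue partition coefficients from one prediction method."""

    values: dict[str, float]
    method: str
    fu_plasma: float = float("nan")

    def __post_init__(self) -> None:
        bad = {t: k for t, k in self.values.items() if not k > 0}
        if bad:
            raise ConfigurationError(f"non-positive Kp values: {bad}")

    def scaled(self, factor: float) -> "KpSet":
        """Uniformly rescaled copy (used for observed/predicted Vss correction)."""
        if factor <= 0:
            raise ConfigurationError("scale factor must be positive")
        return KpSet(
            values={t: k * factor for t, k in self.values.items()},
            method=self.method, fu_plasma=self.fu_plasma,
        )


def _pvow(logp: float) -> float:
    """Vegetable-oil:water partition coefficient from logP (neutral species)."""
    return 10.0 ** (1.115 * logp - 1.35)


def _ionized_fraction_terms(
    compound: CompoundProperties, ph: float
) -> tuple[float, float, float]:
    """Henderson-Hasselbalch terms at ``ph``: (X, acid_part, base_part) where
    ``X = 1 + acid_part + base_part`` and parts are zero for a neutral."""
    acid = 10.0 ** (ph - compound.pka_acid) if compound.pka_acid is not None else 0.0
    base = 10.0 ** (compound.pka_base - ph) if compound.pka_base is not None else 0.0
    return 1.0 + acid + base, acid, base


def _lipid_term(p: float, comp: TissueComposition) -> float:
    return p * comp.f_nl + (0.3 * p + 0.7) * comp.f_pl


def _kp_poulin_theil(
    compound: CompoundProperties, fu_p: float,
    tissue: TissueComposition, plasma: TissueComposition, is_adipose: bool,
) -> float:
    p = _pvow(compound.logp) if is_adipose else 10.0 ** compound.logp
    num = p * (tissue.f_nl + 0.3 * tissue.f_pl) + (tissue.f_water + 0.7 * tissue.f_pl)
    den = p * (plasma.f_nl + 0.3 * plasma.f_pl) + (plasma.f_water + 0.7 * plasma.f_pl)
    fu_t = 1.0 if is_adipose else 1.0 / (1.0 + 0.5 * (1.0 - fu_p) / fu_p)
    return num / den * fu_p / fu_t


def _kp_berezhkovskiy(
    compound: CompoundProperties, fu_p: float,
    tissue: TissueComposition, plasma: TissueComposition, is_adipose: bool,
) -> float:
    p = _pvow(compound.logp) if is_adipose else 10.0 ** compound.logp
    fu_t = 1.0 if is_adipose else 1.0 / (1.0 + 0.5 * (1.0 - fu_p) / fu_p)
    num = p * (tissue.f_nl + 0.3 * tissue.f_pl) + (tissue.f_water + 0.7 * tissue.f_pl) / fu_t
    den = p * (plasma.f_nl + 0.3 * plasma.f_pl) + (plasma.f_water + 0.7 * plasma.f_pl) / fu_p
    return num / den


def _kp_rodgers(
    compound: CompoundProperties, fu_p: float,
    tissue: TissueComposition, plasma: TissueComposition, is_adipose: bool,
) -> float:
    """Unified Rodgers-family unbound Kp times fu_p.

    Moderately-to-strongly lipophilic neutrals are assigned lipoprotein
    binding, hydrophilic neutrals and acids albumin binding; strong bases
    (pKa > 7) bind acidic phospholipids through the blood-cell-derived
    association constant route (untriggered for a neutral compound).
    """
    p = _pvow(compound.logp) if is_adipose else 10.0 ** compound.logp
    x_p, _, base_p = _ionized_fraction_terms(compound, PH_PLASMA)
    x_iw, _, base_iw = _ionized_fraction_terms(compound, PH_INTRACELLULAR)

    lipid_t = _lipid_term(p, tissue)
    lipid_p = _lipid_term(10.0 ** compound.logp, plasma)

    strong_base = compound.pka_base is not None and compound.pka_base > 7.0
    kpu = tissue.f_ew + (x_iw / x_p) * tissue.f_iw + lipid_t / x_p
    if strong_base:
        # acidic-phospholipid association, scaled from plasma binding residue
        ka_ap = max(
            0.0,
            (1.0 / fu_p - 1.0 - lipid_p / x_p) * x_p / (base_p * plasma.ap_mg_g),
        ) if plasma.ap_mg_g > 0 else 0.0
        kpu += ka_ap * tissue.ap_mg_g * base_iw / x_p
    else:
        # extracellular protein binding: lipoprotein for lipophilic neutrals,
        # albumin otherwise; association back-calculated from measured fu_p
        ratio = (
            tissue.lipoprotein_ratio
            if (compound.pka_base is None and compound.pka_acid is None
                and compound.logp >= 3.0)
            else tissue.albumin_ratio
        )
        ka_pr = max(0.0, 1.0 / fu_p - 1.0 - lipid_p / x_p)
        kpu += ka_pr * ratio
    return kpu * fu_p


def predict_kp(
    compound: CompoundProperties,
    species: str,
    method: str,
    tissues: dict[str, TissueComposition] | None = None,
    plasma: TissueComposition | None = None,
    fu_override: float | None = None,
) -> KpSet:
    """Predict Kp for every tissue in ``tissues`` (defaults to the packaged
    composition table) by the chosen method."""
    if method not in KP_METHODS:
        raise ConfigurationError(f"method must be one of {KP_METHODS}")
    tissues = TISSUE_COMPOSITION if tissues is None else tissues
    plasma = PLASMA_COMPOSITION if plasma is None else plasma
    fu_p = compound.fu(species) if fu_override is None else fu_override
    if not 0 < fu_p <= 1:
        raise ConfigurationError("fraction unbound must lie in (0, 1]")

    fn = {
        "poulin_theil": _kp_poulin_theil,
        "berezhkovskiy": _kp_berezhkovskiy,
        "rodgers_rowland": _kp_rodgers,
        "rodgers_single": _kp_rodgers,
    }[method]
    values = {
        name: fn(compound, fu_p, comp, plasma, name == "adipose")
        for name, comp in tissues.items()
    }
    return KpSet(values=values, method=method, fu_plasma=fu_p)


def vss_from_kp(
    kps: KpSet,
    physiology: SpeciesPhysiology,
    blood_plasma_ratio: float = 1.0,
) -> float:
    """Plasma-referenced steady-state volume (L):
    ``Vss = V_blood * Rb:p + sum_t Kp_t * V_t``."""
    missing = [t for t in kps.values if t not in physiology.volumes]
    if missing:
        raise ConfigurationError(
            f"physiology for {physiology.species} lacks volumes for {missing}"
        )
    return physiology.v_blood * blood_plasma_ratio + sum(
        kp * physiology.volumes[t] for t, kp in kps.values.items()
    )


def kpset_scaled_to_vss(
    kps: KpSet,
    physiology: SpeciesPhysiology,
    target_vss: float,
    blood_plasma_ratio: float = 1.0,
) -> KpSet:
    """Uniformly rescale a Kp set so the implied Vss hits ``target_vss`` (L).

    Used both for the observed/predicted ratio correction (scale the whole
    set by the ratio established in the reference species) and for building
    models with a prescribed distribution volume.
    """
    blood_term = physiology.v_blood * blood_plasma_ratio
    if target_vss <= blood_term:
        raise ConfigurationError(
            f"target Vss {target_vss:.3g} L does not exceed the blood space "
            f"{blood_term:.3g} L"
        )
    tissue_sum = sum(kp * physiology.volumes[t] for t, kp in kps.values.items())
    return kps.scaled((target_vss - blood_term) / tissue_sum)


def ratio_corrected_vss(
    observed_animal: float, predicted_animal: float, predicted_target: float
) -> float:
    """Scale a target-species Vss prediction by the observed/predicted ratio
    established in the reference animal."""
    if min(observed_animal, predicted_animal, predicted_target) <= 0:
        raise ConfigurationError("all volumes must be positive")
    return predicted_target * observed_animal / predicted_animal
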