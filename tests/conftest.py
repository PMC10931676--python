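"""Shared fixtures: reference models and a degenerate one-compartment rig."""

from __future__ import annotations

import numpy as np
import pytest

import e0703pk as pk
from e0703pk import pipeline
from e0703pk.datasets import TISSUES, SpeciesPhysiology
from e0703pk.pbpk import AbsorptionParameters


@pytest.fixture(scope="session")
def monkey_anchor():
    """Monkey PBPK model with ratio-corrected Kp and calibrated Fg, plus the
    calibration provenance dict."""
    return pipeline.build_monkey_models()


@pytest.fixture(scope="session")
def human_sa_model(monkey_anchor):
    """Human model under the published simple-allometry clearance."""
    monkey_model, info = monkey_anchor
    return pipeline.build_human_model(pk.CL_SA_PUBLISHED, monkey_model, info)


@pytest.fixture(scope="session")
def probe_compound():
    """A neutral probe with unit blood:plasma ratio and full availability,
    convenient for symmetry checks."""
    return pk.CompoundProperties(
        name="probe", mw=300.0, logp=2.0, solubility_mg_ml=1.0,
        papp_cm_s=1e-5, fu_plasma={"human": 1.0, "monkey": 1.0},
        blood_plasma_ratio=1.0,
    )


@pytest.fixture(scope="session")
def one_compartment_rig(probe_compound):
    """Degenerate physiology: one large tissue, fast-equilibrating
    micro-tissues, unit Kp — behaves as a single well-mixed volume."""
    vols = {t: 1e-3 for t in TISSUES}
    vols["rest"] = 1.0
    flows = {t: 2.0 for t in TISSUES}
    flows.update(rest=500.0, liver=100.0, gut=1.0, spleen=1.0)
    co = sum(q for t, q in flows.items() if t not in ("lung", "gut", "spleen"))
    flows["lung"] = co
    phys = SpeciesPhysiology(
        "human", body_weight=1.0, qh_ml_min_kg=100.0 * 1000 / 60,
        liver_g_per_kg=25.7, cardiac_output_l_h=co,
        volumes=vols, flows=flows, v_arterial=0.005, v_venous=0.005,
    )
    phys.validate_closure()
    kps = pk.KpSet(values={t: 1.0 for t in TISSUES}, method="rodgers_single")
    absorption = AbsorptionParameters(ka=0.1, kt=2.0, kd=6.0)

    def build(clearance, renal_fraction=0.0, absorption_=absorption):
        return pk.build_model(
            probe_compound, phys, kps, clearance, absorption_, renal_fraction
        )

    v_total = sum(vols.values()) + 0.01  # incl. blood
    return build, v_total


@pytest.fixture()
def rng():
    return np.random.default_rng(20240306)
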