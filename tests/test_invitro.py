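"""In vitro ADME: Caco-2, binding, microsomal clearance chain, CYP phenotyping."""

import math

import numpy as np
import pytest

from e0703pk import (
    BindingAssay,
    CacoAssay,
    CypPanel,
    InvalidAssayError,
    MicrosomeAssay,
    apparent_permeability,
    depletion_half_life,
    efflux_ratio,
    fraction_unbound,
    hepatic_extraction,
    recovery,
    scale_clint,
    tnr_phenotyping,
    well_stirred_clh,
)
from e0703pk.datasets import MICROSOME_T_HALF_MIN, default_physiology


def caco(slope_um_s, c0=10.0, vr=0.1, **kw):
    t = np.arange(0, 7200, 1200.0)
    return CacoAssay(
        c0_donor=c0, receiver_series=np.column_stack([t, slope_um_s * t]),
        v_receiver=vr, **kw,
    )


class TestCaco2:
    def test_flat_receiver_series_gives_zero(self):
        assert apparent_permeability(caco(0.0)) == 0.0

    def test_formula(self):
        # slope chosen so the standard geometry yields the compound's A->B value
        papp = apparent_permeability(caco(1.35e-5))
        assert papp == pytest.approx(1.35e-5 * 0.1 / (0.0804 * 10.0))
        assert papp == pytest.approx(1.68e-6, rel=0.01)

    def test_linearity_in_donor_concentration(self):
        assert apparent_permeability(caco(1e-5, c0=20.0)) == pytest.approx(
            apparent_permeability(caco(1e-5, c0=10.0)) / 2
        )

    def test_negative_slope_clipped_with_warning(self):
        with pytest.warns(UserWarning):
            assert apparent_permeability(caco(-1e-6)) == 0.0

    @pytest.mark.parametrize(
        "ab, ba, expected",
        [(1.68e-6, 3.74e-6, 2.22), (0.65e-6, 14.64e-6, 22.48)],
    )
    def test_efflux_ratio_printed_pairs(self, ab, ba, expected):
        assert efflux_ratio(ab, ba) == pytest.approx(expected, rel=0.01)

    def test_efflux_symmetry_and_zero_denominator(self):
        assert efflux_ratio(2e-6, 2e-6) == 1.0
        with pytest.raises(InvalidAssayError):
            efflux_ratio(0.0, 1e-6)

    def test_recovery_nothing_moved(self):
        a = caco(0.0, final_donor_conc=10.0, final_receiver_conc=0.0,
                 cell_lysate_conc=0.0)
        assert recovery(a) == (pytest.approx(100.0), pytest.approx(100.0))

    def test_recovery_hand_example(self):
        a = CacoAssay(
            c0_donor=10.0, receiver_series=[[0, 0], [100, 0.1]],
            v_donor=0.1, v_receiver=0.25, v_cell=0.1,
            final_donor_conc=2.0, final_receiver_conc=0.3, cell_lysate_conc=1.0,
        )
        rec, total = recovery(a)
        assert rec == pytest.approx(27.5)
        assert total == pytest.approx(37.5)

    def test_recovery_scale_invariance_and_ordering(self):
        a = caco(1e-5, final_donor_conc=4.0, final_receiver_conc=1.0,
                 cell_lysate_conc=0.5)
        b = caco(1e-5, c0=100.0, final_donor_conc=40.0,
                 final_receiver_conc=10.0, cell_lysate_conc=5.0)
        assert recovery(a) == pytest.approx(recovery(b))
        rec, total = recovery(a)
        assert total > rec


class TestBinding:
    @pytest.mark.parametrize(
        "donor, receiver, fu",
        [(1.0, 1.0, 1.0), (1.0, 0.009, 0.009), (1.0, 0.0, 0.0)],
    )
    def test_fraction_unbound(self, donor, receiver, fu):
        assert fraction_unbound(
            BindingAssay(donor_conc_end=donor, receiver_conc_end=receiver)
        ) == pytest.approx(fu)

    def test_zero_donor(self):
        with pytest.raises(InvalidAssayError):
            fraction_unbound(BindingAssay(donor_conc_end=0.0, receiver_conc_end=0.0))


def microsome(kappa, t_max=60.0, n=7):
    t = np.linspace(0, t_max, n)
    return MicrosomeAssay(np.column_stack([t, np.exp(-kappa * t)]))


class TestMicrosomes:
    @pytest.mark.parametrize("kappa, t_half", [(0.0066, 105.0), (0.01, 69.3)])
    def test_depletion_half_life_closed_form(self, kappa, t_half):
        k, th = depletion_half_life(microsome(kappa))
        assert k == pytest.approx(kappa, rel=1e-6)
        assert th == pytest.approx(t_half, rel=1e-3)

    def test_stable_compound_flag(self):
        k, th = depletion_half_life(microsome(0.0))
        assert k == 0.0 and math.isinf(th)

    @pytest.mark.parametrize(
        "species, clint", [("human", 15.3), ("mouse", 78.8),
                           ("monkey", 22.4), ("beagle", 12.7)],
    )
    def test_clint_scaling_reproduces_all_species(self, species, clint):
        got = scale_clint(
            MICROSOME_T_HALF_MIN[species], species, default_physiology(species)
        )
        assert got == pytest.approx(clint, rel=0.01)

    def test_infinite_half_life_gives_zero_clint(self):
        assert scale_clint(math.inf, "human", default_physiology("human")) == 0.0


class TestWellStirred:
    @pytest.mark.parametrize(
        "clint, qh, clh", [(15.3, 20.7, 8.8), (78.8, 90.0, 42.0)],
    )
    def test_printed_values(self, clint, qh, clh):
        assert well_stirred_clh(clint, qh) == pytest.approx(clh, rel=0.01)

    def test_flow_limited_ceiling_and_restrictive_limit(self):
        qh = 20.7
        assert well_stirred_clh(1e9, qh) == pytest.approx(qh, rel=1e-6)
        assert well_stirred_clh(0.01, qh) == pytest.approx(0.01, rel=1e-3)

    def test_bounded_and_monotone(self, rng):
        qh = 50.0
        clints = np.sort(rng.uniform(0, 500, 30))
        clhs = [well_stirred_clh(c, qh) for c in clints]
        assert all(0 <= v < qh for v in clhs)
        assert all(b >= a for a, b in zip(clhs, clhs[1:]))

    @pytest.mark.parametrize(
        "clh, qh, pct", [(8.8, 20.7, 42.5), (42.0, 90.0, 46.67), (0.0, 20.7, 0.0)],
    )
    def test_hepatic_extraction(self, clh, qh, pct):
        assert hepatic_extraction(clh, qh) == pytest.approx(pct, abs=0.1)


class TestPhenotyping:
    NORMALIZED = {
        "CYP1A2": 25.95, "CYP2C9": 5.33, "CYP2C19": 1.71,
        "CYP2A6": 4.08, "CYP2D6": 8.30, "CYP3A4": 162.33,
    }

    def test_printed_contributions(self):
        panel = CypPanel({iso: (v, 1.0) for iso, v in self.NORMALIZED.items()})
        pct = tnr_phenotyping(panel)
        assert pct["CYP3A4"] == pytest.approx(78.15, abs=0.02)
        assert pct["CYP1A2"] == pytest.approx(12.49, abs=0.02)
        assert sum(pct.values()) == pytest.approx(100.0, abs=0.1)

    def test_rate_times_abundance(self):
        panel = CypPanel({"A": (2.0, 10.0), "B": (1.0, 20.0)})
        pct = tnr_phenotyping(panel)
        assert pct == {"A": pytest.approx(50.0), "B": pytest.approx(50.0)}

    def test_single_isoform_is_100(self):
        assert tnr_phenotyping(CypPanel({"X": (0.5, 3.0)}))["X"] == 100.0

    def test_all_zero_rates_undefined(self):
        with pytest.raises(InvalidAssayError):
            tnr_phenotyping(CypPanel({"X": (0.0, 3.0)}))
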