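"""Capacity readouts: titrations, load ramps, contributions, scaling."""

import numpy as np
import pytest

from myoflux.capacity import (
    FASTED,
    POSTPRANDIAL,
    PlasmaProfile,
    RampConfig,
    TitrationConfig,
    atp_load_scan,
    individualized_scan,
    merge_profile,
    substrate_capacity,
    substrate_contributions,
    whole_heart_capacity,
)
from myoflux.network import (
    SteadyState,
    build_reference_model,
    solve_steady_state,
    total_atp_production,
)


class TestPlasmaProfiles:
    def test_builtin_fasted_values(self):
        assert (
            FASTED.glucose,
            FASTED.fatty_acids,
            FASTED.lactate,
            FASTED.valine,
            FASTED.leucine,
            FASTED.isoleucine,
            FASTED.bhb,
            FASTED.acac,
            FASTED.insulin,
            FASTED.catecholamines,
        ) == (5.8, 0.5, 0.8, 0.2, 0.15, 0.06, 0.08, 0.04, 100.0, 0.75)

    def test_builtin_postprandial_values(self):
        assert (
            POSTPRANDIAL.glucose,
            POSTPRANDIAL.fatty_acids,
            POSTPRANDIAL.lactate,
            POSTPRANDIAL.valine,
            POSTPRANDIAL.leucine,
            POSTPRANDIAL.isoleucine,
            POSTPRANDIAL.bhb,
            POSTPRANDIAL.acac,
            POSTPRANDIAL.insulin,
        ) == (7.8, 0.1, 2.0, 0.4, 0.4, 0.2, 0.0, 0.0, 600.0)

    def test_negative_field_rejected(self):
        with pytest.raises(ValueError):
            PlasmaProfile(
                glucose=-1, fatty_acids=0, lactate=0, valine=0, leucine=0,
                isoleucine=0, bhb=0, acac=0, insulin=0,
            )


def single_transporter_doc(vmax=0.05, km=1.0):
    """Glucose-only toy: transporter -> full oxidation lump -> demand.

    As the titration saturates the transporter, uptake capacity -> vmax.
    """
    return {
        "name": "toy-glc",
        "resting_demand": 0.3,
        "demand_reaction": "dem",
        "metabolites": [
            {"id": "glc_p", "compartment": "plasma", "conc0": 5.0},
            {"id": "o2", "compartment": "mitochondria", "conc0": 1.0, "boundary": True},
            {"id": "x", "compartment": "cytosol", "conc0": 0.1},
            {"id": "atp", "compartment": "cytosol", "conc0": 4.0},
            {"id": "adp", "compartment": "cytosol", "conc0": 1.0},
        ],
        "pools": [{"name": "adenine", "members": ["atp", "adp"], "total": 5.0}],
        "reactions": [
            {
                "id": "up",
                "pathway": "glycolysis",
                "stoichiometry": {"glc_p": -1, "x": 1},
                "proteins": ["T1"],
                "law": {"form": "facilitated-transport", "vmax": vmax, "km": {"glc_p": km}},
            },
            {
                "id": "oxi",
                "pathway": "oxphos",
                "stoichiometry": {"x": -1, "o2": -6, "adp": -30, "atp": 30},
                "proteins": ["O1"],
                "law": {"form": "irreversible-MM", "vmax": 5.0, "km": {"x": 0.05, "adp": 0.1}},
            },
            {
                "id": "dem",
                "pathway": "atp-demand",
                "stoichiometry": {"atp": -1, "adp": 1},
                "law": {"form": "load-hyperbolic", "vmax": 0.1, "km": {"atp": 0.5}},
            },
        ],
        "substrate_classes": {"glucose": {"species": ["glc_p"], "reactions": ["up"]}},
    }


class TestSubstrateCapacity:
    def test_zero_substrate_zero_capacity(self, model):
        prof = FASTED.with_boundary(glc_p=0.0)
        cap = substrate_capacity(
            model, "glucose", prof, TitrationConfig(zero_base_max=0.0)
        )
        assert cap == pytest.approx(0.0, abs=1e-9)

    def test_mm_transporter_limit(self):
        m = build_reference_model(single_transporter_doc(vmax=0.05, km=1.0))
        prof = FASTED
        cap = substrate_capacity(m, "glucose", prof)
        # grid reaches 50x5 mM = 250 mM >> km: saturation within ~1%
        assert cap == pytest.approx(0.05, rel=0.02)

    def test_unknown_class_rejected(self, model):
        with pytest.raises(ValueError):
            substrate_capacity(model, "caffeine", FASTED)

    def test_glycolysis_halving_halves_glucose_capacity(self, model):
        """Halving the glycolytic lump roughly halves the glucose capacity;
        NAD freed to competing pathways softens strict proportionality."""
        base = substrate_capacity(model, "glucose", FASTED)
        half = model.scale_vmax({"glut": 0.5, "glyc": 0.5})
        cap = substrate_capacity(half, "glucose", FASTED)
        assert 0.40 <= cap / base <= 0.68

    def test_capacity_homogeneity(self, model):
        alpha = 0.6
        scaled = model.scale_vmax(
            {r.id: alpha for r in model.reactions if r.proteins}
        )
        for substrate in ("glucose", "ffa"):
            c1 = substrate_capacity(model, substrate, FASTED)
            c2 = substrate_capacity(scaled, substrate, FASTED)
            assert c2 / c1 == pytest.approx(alpha, rel=1e-3)


class TestLoadScan:
    def test_zero_initial_load_zero_production(self, model):
        scan = atp_load_scan(model, FASTED, RampConfig(initial_load=0.0))
        assert scan.atp_production[0] == pytest.approx(0.0, abs=1e-9)

    def test_single_substrate_uptake_limited_bound(self):
        m = build_reference_model(single_transporter_doc(vmax=0.02, km=1.0))
        scan = atp_load_scan(m, FASTED, RampConfig(initial_load=0.01))
        # yield: 30 ATP per molecule (derived at build); fasted glucose 5.8 mM
        assert m.atp_yield["glc_p"] == pytest.approx(30.0)
        bound = 30.0 * 0.02 * 5.8 / 6.8
        assert scan.max_atp == pytest.approx(bound, rel=0.02)

    def test_ramp_monotone_and_converged(self, model):
        scan = atp_load_scan(model, FASTED)
        assert np.all(np.diff(scan.atp_production) >= -1e-6)
        assert np.isfinite(scan.converged_at)

    def test_shares_normalized_at_every_load(self, model):
        scan = atp_load_scan(model, FASTED)
        for total, contrib in zip(scan.atp_production, scan.contributions):
            if total > 1e-9:
                assert sum(contrib.values()) == pytest.approx(total, rel=1e-6)

    def test_atp_o2_below_stoichiometric_ceiling(self, model):
        for prof in (FASTED, POSTPRANDIAL):
            scan = atp_load_scan(model, prof)
            assert 0 < scan.atp_o2_at_max <= model.atp_o2_max + 1e-9

    def test_capacity_homogeneity_via_ramp(self, model):
        alpha = 0.7
        scaled = model.scale_vmax(
            {r.id: alpha for r in model.reactions if r.proteins}
        )
        c1 = atp_load_scan(model, FASTED).max_atp
        c2 = atp_load_scan(scaled, FASTED).max_atp
        assert c2 / c1 == pytest.approx(alpha, rel=1e-3)

    def test_metabolic_reserve(self, model):
        scan = atp_load_scan(model, FASTED)
        assert scan.max_atp / model.resting_demand >= 3.0


class TestContributions:
    def test_glucose_only_share_one(self):
        m = build_reference_model(single_transporter_doc())
        st = solve_steady_state(m, load=0.5)
        contrib = substrate_contributions(st, m)
        total = total_atp_production(m, st)
        assert contrib["glucose"] == pytest.approx(total, rel=1e-9)

    def test_zero_ketone_uptake_zero_contribution(self, model):
        st = solve_steady_state(model, POSTPRANDIAL, load=1.0)
        contrib = substrate_contributions(st, model)
        assert contrib["ketones"] == pytest.approx(0.0, abs=1e-6)

    def test_hand_set_fluxes_flux_weighted_yields(self, model):
        st = SteadyState(
            conc={m.id: m.conc0 for m in model.metabolites},
            flux={r.id: 0.0 for r in model.reactions},
            residual=0.0,
            converged=True,
        )
        st.flux["glut"] = 0.002
        st.flux["fat"] = 0.010
        contrib = substrate_contributions(st, model)
        assert contrib["glucose"] == pytest.approx(0.002 * 34.0)
        assert contrib["ffa"] == pytest.approx(0.010 * 103.5)


class TestWholeHeart:
    def test_unit_conversion(self):
        assert whole_heart_capacity(10.0, 200.0) == pytest.approx(2.0)

    def test_zero_capacity(self):
        assert whole_heart_capacity(0.0, 150.0) == 0.0

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            whole_heart_capacity(1.0, 0.0)

    def test_heart_mass_scales_linearly(self):
        assert whole_heart_capacity(5.0, 210.0) == pytest.approx(
            1.4 * whole_heart_capacity(5.0, 150.0)
        )


class TestIndividualized:
    def test_panel_identical_to_defaults_is_identity(self, model):
        base = atp_load_scan(model, FASTED)
        merged = individualized_scan(
            model,
            {
                "glucose": FASTED.glucose,
                "nefa": FASTED.fatty_acids,
                "lactate": FASTED.lactate,
                "bhb": FASTED.bhb,
            },
            FASTED,
        )
        np.testing.assert_array_equal(base.atp_production, merged.atp_production)
        assert base.max_atp == merged.max_atp

    def test_doubling_bhb_changes_capacity_little(self, model):
        base = atp_load_scan(model, FASTED)
        merged = individualized_scan(model, {"bhb": 2 * FASTED.bhb}, FASTED)
        assert abs(merged.max_atp - base.max_atp) / base.max_atp < 0.02

    def test_empty_panel_uses_defaults(self, model, caplog):
        base = atp_load_scan(model, FASTED)
        merged = individualized_scan(model, {}, FASTED)
        assert merged.max_atp == base.max_atp

    def test_tg_ignored_negative_rejected(self):
        prof = merge_profile({"tg": 3.0}, FASTED)
        assert prof.boundary_map() == FASTED.boundary_map()
        with pytest.raises(ValueError):
            merge_profile({"bhb": -0.1}, FASTED)
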