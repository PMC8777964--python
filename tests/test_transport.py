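import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdisim.aerosol import (
    AirProperties,
    DropletPopulation,
    SizeDistributionSpec,
    SourceConfig,
    droplet_mass,
    make_population,
)
from mdisim.breathing import LPM_TO_M3S, flow_at
from mdisim.jet import relaxation_time, schiller_naumann
from mdisim.transport import (
    TransportConfig,
    back_throat_stokes,
    count_sensitivity,
    impaction_probability,
    records_to_fates,
    sedimentation_probability,
    simulate_scenario,
)

from conftest import scenario_at

AIR = AirProperties()


def monodisperse(d_um, n=4000, seed=5):
    pop = make_population(
        SourceConfig(n_droplets=n, rng_seed=seed),
        SizeDistributionSpec(dv50=d_um, gsd=1.0, d_min=d_um / 2, d_max=d_um * 2),
    )
    return pop


class TestImpactionProbability:
    def test_zero_stokes(self):
        assert impaction_probability(0.0, 35.0) == 0.0

    def test_saturation(self):
        assert impaction_probability(1e3, 35.0) > 0.99

    def test_bounds(self):
        p = impaction_probability(np.logspace(-3, 3, 50), 35.0)
        assert np.all((p >= 0.0) & (p <= 1.0))

    @given(stk=st.floats(min_value=0.0, max_value=100.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_stokes(self, stk):
        assert impaction_probability(2.0 * stk, 35.0) >= impaction_probability(stk, 35.0)

    @given(
        stk=st.floats(min_value=1e-3, max_value=10.0),
        a1=st.floats(min_value=0.0, max_value=89.0),
        a2=st.floats(min_value=0.0, max_value=89.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_angle(self, stk, a1, a2):
        lo, hi = sorted((a1, a2))
        assert impaction_probability(stk, hi) >= impaction_probability(stk, lo)

    def test_negative_stokes_rejected(self):
        with pytest.raises(ValueError):
            impaction_probability(-1.0, 35.0)


class TestSedimentationProbability:
    def test_zero_terminal_velocity(self):
        assert sedimentation_probability(0.0, 1.0, 0.01, 90.0) == 0.0

    def test_complete_settling_horizontal(self):
        # settling distance >= diameter in a horizontal tube
        assert sedimentation_probability(0.01, 2.0, 0.01, 90.0) == 1.0

    def test_vertical_tube_no_cross_settling(self):
        assert sedimentation_probability(0.01, 2.0, 0.01, 0.0) == 0.0

    def test_monotone_in_residence_time(self):
        # halving residence time never increases the probability
        times = np.linspace(0.0, 5.0, 30)
        p = sedimentation_probability(1e-3, times, 0.01, 60.0)
        assert np.all(np.diff(p) >= 0.0)
        for t in times:
            assert sedimentation_probability(1e-3, t / 2, 0.01, 60.0) <= sedimentation_probability(
                1e-3, t, 0.01, 60.0
            )

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            sedimentation_probability(-1e-3, 1.0, 0.01, 90.0)


class TestSimulateScenario:
    def test_empty_population(self, tree, control_scenario):
        empty = DropletPopulation(
            ids=np.empty(0, dtype=int),
            diameters_um=np.empty(0),
            masses_kg=np.empty(0),
            release_times_s=np.empty(0),
            directions=np.empty((0, 3)),
            speeds=np.empty(0),
        )
        records = simulate_scenario(empty, tree, control_scenario)
        assert len(records) == 0

    def test_fate_partition_and_mass_conservation(self, tree, small_population, control_scenario):
        records = simulate_scenario(small_population, tree, control_scenario)
        assert len(records) == len(small_population)
        assert set(records["status"].unique()) <= {"deposited", "exited", "airborne"}
        assert records["droplet_id"].is_unique
        assert records["mass_kg"].sum() == pytest.approx(small_population.total_mass, rel=1e-12)

    def test_fate_times_within_delivery(self, tree, small_population, control_scenario):
        records = simulate_scenario(small_population, tree, control_scenario)
        assert (records["fate_time_s"] >= 0.0).all()
        assert (records["fate_time_s"] <= 6.0 + 1e-12).all()

    def test_deterministic_under_seed(self, tree, small_population, control_scenario):
        a = simulate_scenario(small_population, tree, control_scenario)
        b = simulate_scenario(small_population, tree, control_scenario)
        pd.testing.assert_frame_equal(a, b)

    def test_submicron_droplets_mostly_exit(self, tree, control_scenario):
        # d -> 0 turns impaction/sedimentation probabilities off
        pop = monodisperse(0.5)
        records = simulate_scenario(pop, tree, control_scenario)
        assert (records["status"] == "exited").mean() >= 0.99

    def test_back_throat_fraction_matches_closure_oracle(self, tree, control_scenario):
        # Monodisperse 35 um at 40 m/s: the back-throat deposit fraction must
        # match the bend-impaction closure evaluated analytically per droplet.
        pop = monodisperse(35.0, n=20_000)
        cfg = TransportConfig()
        records = simulate_scenario(pop, tree, control_scenario, cfg)

        ext = tree.extrathoracic_ids()
        seg_mp, seg_mouth = tree.segments[ext[0]], tree.segments[ext[1]]
        l_path = seg_mp.length_m + seg_mouth.length_m
        # lateral cone hits are excluded from the bend draw
        sin_phi = np.sqrt(1.0 - pop.directions[:, 0] ** 2)
        re = AIR.density * 40.0 * 35e-6 / AIR.viscosity
        tau_eff = relaxation_time(35.0) / schiller_naumann(re)
        r_reach = 40.0 * sin_phi * tau_eff
        s_hit = (seg_mp.diameter_m / 2.0) / np.maximum(sin_phi, 1e-12)
        lateral = (r_reach >= seg_mp.diameter_m / 2.0) & (s_hit <= seg_mp.length_m)

        t_rel = 0.63 + pop.release_times_s
        u_bg = flow_at(control_scenario.profile, t_rel) * LPM_TO_M3S / seg_mouth.area_m2
        u_char = cfg.jet_decay_constant * 40.0 * cfg.orifice_diameter_mm * 1e-3 / l_path + u_bg
        stk = back_throat_stokes(35.0, u_char, 1000.0, cfg.bt_char_diameter_m)
        p = impaction_probability(stk, cfg.bt_bend_angle_deg, cfg.impaction_coeff)
        expected = p[~lateral].mean()

        is_bt = (
            (records["region"] == "MOUTH")
            & records["patch_id"].str.endswith(":9")
            & (records["fate_time_s"] < t_rel + 0.05)
        )
        observed = is_bt.sum() / (~lateral).sum()
        sigma = np.sqrt(expected * (1 - expected) / (~lateral).sum())
        assert observed == pytest.approx(expected, abs=4 * sigma)

    def test_df_invariant_to_uniform_density_rescale(self, tree, control_scenario):
        # A uniform density rescale multiplies every droplet mass by the same
        # factor, which cancels in the mass-based DF.
        from mdisim.dosimetry import deposition_fraction

        base = make_population(SourceConfig(n_droplets=3000, rng_seed=3))
        rec = simulate_scenario(base, tree, control_scenario)
        rescaled = rec.copy()
        rescaled["mass_kg"] = rescaled["mass_kg"] * 7.5
        for region in ("MOUTH", "PHARYNX", "LARYNX", "TB"):
            assert deposition_fraction(rescaled, region) == pytest.approx(
                deposition_fraction(rec, region), rel=1e-12
            )

    def test_size_ordering_throat_vs_exited(self, tree, small_population, control_scenario):
        records = simulate_scenario(small_population, tree, control_scenario)
        throat = records[
            (records["status"] == "deposited")
            & records["region"].isin(["MOUTH", "PHARYNX", "LARYNX"])
        ]
        exited = records[records["status"] == "exited"]
        mw = lambda df: np.average(df["diameter_um"], weights=df["mass_kg"])
        assert mw(throat) >= mw(exited)

    def test_lower_lobe_preference(self, tree, small_population, control_scenario):
        records = simulate_scenario(small_population, tree, control_scenario)
        dep = records[records["status"] == "deposited"]
        lower = dep.loc[dep["lobe"].isin(["LL", "RL"]), "mass_kg"].sum()
        upper = dep.loc[dep["lobe"].isin(["LU", "RU"]), "mass_kg"].sum()
        assert lower >= upper

    def test_exited_droplets_carry_outlets_and_lobes(self, tree, small_population, control_scenario):
        records = simulate_scenario(small_population, tree, control_scenario)
        exited = records[records["status"] == "exited"]
        assert (exited["outlet_id"] >= 0).all()
        outlet_set = set(tree.outlet_ids)
        assert set(exited["outlet_id"]).issubset(outlet_set)
        assert set(exited["lobe"]).issubset({"LU", "LL", "RU", "RM", "RL"})

    def test_fixed_lobar_fractions_routing(self, tree, small_population, control_scenario):
        cfg = TransportConfig(lobar_fractions={"LU": 0.8, "LL": 0.05, "RU": 0.05, "RM": 0.05, "RL": 0.05})
        records = simulate_scenario(small_population, tree, control_scenario, cfg)
        exited = records[records["status"] == "exited"]
        assert (exited["lobe"] == "LU").mean() > 0.5

    def test_records_to_fates_round_trip(self, tree, control_scenario):
        pop = make_population(SourceConfig(n_droplets=50, rng_seed=1))
        records = simulate_scenario(pop, tree, control_scenario)
        fates = records_to_fates(records)
        assert len(fates) == 50
        assert {f.status for f in fates} <= {"deposited", "exited", "airborne"}

    def test_dispersion_toggle_increases_mouth_dose(self, tree, small_population, control_scenario):
        from mdisim.dosimetry import deposition_fraction

        off = simulate_scenario(small_population, tree, control_scenario, TransportConfig(dispersion=False))
        on = simulate_scenario(small_population, tree, control_scenario, TransportConfig(dispersion=True))
        assert deposition_fraction(on, "MOUTH") >= deposition_fraction(off, "MOUTH")

    def test_breath_hold_toggle(self, tree, control_scenario):
        # With settling disabled, droplets stranded without flow stay airborne.
        pop = monodisperse(20.0, n=2000, seed=9)
        late = scenario_at(2.5, seed=3)
        with_settling = simulate_scenario(pop, tree, late, TransportConfig(breath_hold_settling=True))
        without = simulate_scenario(pop, tree, late, TransportConfig(breath_hold_settling=False))
        assert (without["status"] == "airborne").sum() >= (with_settling["status"] == "airborne").sum()


@pytest.fixture(scope="module")
def reports(tree):
    from mdisim.dosimetry import build_report

    pop = make_population(SourceConfig(n_droplets=10_000, rng_seed=1))
    out = {}
    for t_act in (0.0, 0.63, 1.5, 2.5):
        records = simulate_scenario(pop, tree, scenario_at(t_act, seed=42))
        out[t_act] = build_report(records)
    return out


class TestTimingEffects:
    def test_delayed_actuation_raises_mouth_df(self, reports):
        control = reports[0.63].regional_df["MOUTH"]
        assert reports[1.5].regional_df["MOUTH"] >= control
        assert reports[2.5].regional_df["MOUTH"] >= control

    def test_early_actuation_raises_device_df(self, reports):
        control = reports[0.63].regional_df["MDI_MOUTHPIECE"]
        assert reports[0.0].regional_df["MDI_MOUTHPIECE"] >= control

    def test_conservation_across_scenarios(self, reports):
        for rep in reports.values():
            total = (
                sum(rep.regional_df.values()) + rep.exited_fraction + rep.airborne_fraction
            )
            assert total == pytest.approx(1.0, abs=1e-12)


class TestCountSensitivity:
    def test_paper_count_grid_default(self):
        import inspect

        from mdisim.transport import count_sensitivity as cs

        default_counts = inspect.signature(cs).parameters["counts"].default
        assert tuple(default_counts) == (20_000, 30_000, 45_000, 60_000, 75_000, 100_000, 150_000)

    def test_determinism_and_structure(self, tree, control_scenario):
        table = count_sensitivity(
            tree, control_scenario, counts=(500, 1000), repeats=2, base_seed=0
        )
        assert set(table["count"].unique()) == {500, 1000}
        assert {"df_mean", "df_std"} <= set(table.columns)
        again = count_sensitivity(
            tree, control_scenario, counts=(500, 1000), repeats=2, base_seed=0
        )
        pd.testing.assert_frame_equal(table, again)

    def test_monte_carlo_spread_shrinks(self, tree, control_scenario):
        # DF standard error across repeats shrinks roughly like 1/sqrt(n).
        table = count_sensitivity(
            tree, control_scenario, counts=(1000, 16_000), repeats=6, base_seed=1
        )
        mouth = table[table["region"] == "MOUTH"].drop_duplicates("count").set_index("count")
        ratio = mouth.loc[1000, "df_std"] / mouth.loc[16_000, "df_std"]
        assert 1.3 <= ratio <= 13.0  # 4x expected, generous band

    def test_empty_counts_rejected(self, tree, control_scenario):
        with pytest.raises(ValueError):
            count_sensitivity(tree, control_scenario, counts=())
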