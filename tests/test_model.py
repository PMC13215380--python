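"""Mass-balance model: rates, integration, closed-form oracle, conservation."""

import numpy as np
import pytest

from pbtampon import (
    ModelParams,
    ReleaseSchedule,
    analytic_trajectory,
    derive_rates,
    fate_summary,
    mass_balance_residual,
    simulate,
)

SCHEDULES = [
    ReleaseSchedule(tampon_content=264, fraction_released=1.0, release_duration=4.0),
    ReleaseSchedule(tampon_content=264, fraction_released=1.0, release_duration=0.25),
    ReleaseSchedule(tampon_content=264, fraction_released=0.5, release_duration=0.25),
]


class TestDerivedRates:
    def test_baseline_rates(self, baseline_params, baseline_schedule):
        r = derive_rates(baseline_params, baseline_schedule)
        assert r.k_out == pytest.approx(2.0)
        assert r.k_tissue == pytest.approx(0.018144)
        assert r.release_rate == pytest.approx(66.0)

    def test_split_fractions_sum_to_one(self, baseline_params, baseline_schedule):
        r = derive_rates(baseline_params, baseline_schedule)
        assert r.f_plasma + r.f_rbc == pytest.approx(1.0)
        assert r.f_rbc / r.f_plasma == pytest.approx(
            baseline_params.k_rbc_plasma
        )

    @pytest.mark.parametrize(
        "field,value",
        [("v_menses", -1.0), ("q_abs", 0.0), ("f_unbound", 1.5), ("papp", -1e-6)],
    )
    def test_invalid_parameters_rejected(self, field, value):
        with pytest.raises(ValueError):
            ModelParams(**{field: value})


class TestSimulation:
    def test_baseline_end_of_wear_masses(self, baseline_params, baseline_schedule):
        traj = simulate(baseline_params, baseline_schedule)
        assert traj.a_tissue[-1] == pytest.approx(0.58, abs=0.005)
        assert traj.a_plasma[-1] == pytest.approx(9.08, abs=0.01)
        assert traj.a_rbc[-1] == pytest.approx(23.83, abs=0.01)

    def test_zero_release_gives_identically_zero_state(self, baseline_params):
        schedule = ReleaseSchedule(tampon_content=0.0)
        traj = simulate(baseline_params, schedule)
        for arr in (traj.a_plasma, traj.a_rbc, traj.a_tissue, traj.a_tampon):
            assert np.all(arr == 0.0)
        assert mass_balance_residual(traj) == 0.0

    def test_cumulative_compartments_non_decreasing(self, baseline_params):
        schedule = SCHEDULES[1].replace(sim_end=4.0)
        traj = simulate(baseline_params, schedule)
        assert np.all(np.diff(traj.a_tissue) >= -1e-12)
        assert np.all(np.diff(traj.a_tampon) >= -1e-12)
        assert np.all(traj.a_plasma >= -1e-12)

    @pytest.mark.parametrize("schedule", SCHEDULES)
    def test_mass_conservation(self, baseline_params, schedule):
        traj = simulate(baseline_params, schedule)
        assert mass_balance_residual(traj) <= 1e-6 * schedule.released_mass

    def test_linearity_in_released_amount(self, baseline_params, baseline_schedule):
        base = fate_summary(simulate(baseline_params, baseline_schedule))
        scaled_schedule = baseline_schedule.replace(tampon_content=3 * 264.0)
        scaled = fate_summary(simulate(baseline_params, scaled_schedule))
        for attr in ("plasma_ng", "rbc_ng", "tissue_ng", "tampon_ng"):
            assert getattr(scaled, attr) == pytest.approx(
                3 * getattr(base, attr), rel=1e-8
            )
        for attr in ("pct_plasma", "pct_rbc", "pct_tissue", "pct_tampon"):
            assert getattr(scaled, attr) == pytest.approx(
                getattr(base, attr), rel=1e-8
            )

    @pytest.mark.parametrize(
        "field,increases_uptake",
        [
            ("papp", True),
            ("area", True),
            ("f_unbound", True),
            ("q_abs", False),
            ("k_rbc_plasma", False),
        ],
    )
    def test_monotone_response_over_tenfold_grid(
        self, baseline_params, baseline_schedule, field, increases_uptake
    ):
        factors = [0.1, 0.3, 1.0, 3.0, 10.0]
        if field == "f_unbound":  # bounded above by 1 (0.12 x 10 is illegal)
            factors = [0.1, 0.3, 1.0, 3.0, 8.0]
        uptakes = []
        for f in factors:
            p = baseline_params.replace(**{field: getattr(baseline_params, field) * f})
            uptakes.append(simulate(p, baseline_schedule).a_tissue[-1])
        diffs = np.diff(uptakes)
        assert np.all(diffs > 0) if increases_uptake else np.all(diffs < 0)

    def test_release_rate_scales_uptake(self, baseline_params, baseline_schedule):
        doubled = baseline_schedule.replace(tampon_content=528.0)
        up1 = simulate(baseline_params, baseline_schedule).a_tissue[-1]
        up2 = simulate(baseline_params, doubled).a_tissue[-1]
        assert up2 == pytest.approx(2 * up1, rel=1e-9)

    def test_integration_failure_raises(self, baseline_params):
        with pytest.raises(ValueError):
            ReleaseSchedule(release_duration=8.0, sim_end=4.0)


class TestAnalyticOracle:
    @pytest.mark.parametrize("schedule", SCHEDULES)
    def test_numeric_matches_closed_form_at_checkpoints(
        self, baseline_params, schedule
    ):
        times = np.linspace(0, schedule.sim_end, 100)
        num = simulate(baseline_params, schedule, n_points=100)
        ana = analytic_trajectory(baseline_params, schedule, times=num.times)
        for a, b in (
            (num.a_plasma, ana.a_plasma),
            (num.a_rbc, ana.a_rbc),
            (num.a_tissue, ana.a_tissue),
            (num.a_tampon, ana.a_tampon),
        ):
            scale = np.maximum(np.abs(b), 1e-9 * schedule.released_mass)
            assert np.max(np.abs(a - b) / scale) < 1e-6
        assert times.size == 100  # checkpoints requested

    def test_closed_form_conserves_mass_exactly(self, baseline_params):
        for schedule in SCHEDULES:
            traj = analytic_trajectory(baseline_params, schedule)
            assert mass_balance_residual(traj) <= 1e-9 * schedule.released_mass

    def test_plasma_pool_during_release_formula(self, baseline_params,
                                                baseline_schedule):
        r = derive_rates(baseline_params, baseline_schedule)
        k_p = r.k_out + r.k_tissue
        expected = r.release_rate * r.f_plasma / k_p * (1 - np.exp(-k_p * 4.0))
        traj = analytic_trajectory(baseline_params, baseline_schedule,
                                   times=[4.0])
        assert traj.a_plasma[0] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(9.08, abs=0.01)

    def test_infinite_time_limit(self, baseline_params):
        """Fluid pools drain; tissue approaches its closed-form asymptote."""
        schedule = ReleaseSchedule(sim_end=500.0)
        r = derive_rates(baseline_params, schedule)
        traj = analytic_trajectory(baseline_params, schedule, times=[500.0])
        tissue_inf = (
            schedule.released_mass * r.f_plasma * r.k_tissue / (r.k_out + r.k_tissue)
        )
        assert traj.a_plasma[0] == pytest.approx(0.0, abs=1e-9)
        assert traj.a_rbc[0] == pytest.approx(0.0, abs=1e-9)
        assert traj.a_tissue[0] == pytest.approx(tissue_inf, rel=1e-9)

    def test_steady_state_during_long_release(self, baseline_params):
        schedule = ReleaseSchedule(tampon_content=66.0 * 400, release_duration=400.0,
                                   wear_time=400.0)
        r = derive_rates(baseline_params, schedule)
        traj = analytic_trajectory(baseline_params, schedule, times=[400.0])
        assert traj.a_plasma[0] == pytest.approx(
            r.release_rate * r.f_plasma / (r.k_out + r.k_tissue), rel=1e-6
        )
        assert traj.a_rbc[0] == pytest.approx(
            r.release_rate * r.f_rbc / r.k_out, rel=1e-6
        )


class TestFateSummary:
    def test_percentages_sum_to_100(self, baseline_params, baseline_schedule):
        s = fate_summary(simulate(baseline_params, baseline_schedule))
        total = s.pct_plasma + s.pct_rbc + s.pct_tissue + s.pct_tampon
        assert total == pytest.approx(100.0, abs=0.01)

    def test_full_release_tampon_percentages_coincide(
        self, baseline_params, baseline_schedule
    ):
        s = fate_summary(simulate(baseline_params, baseline_schedule))
        assert s.pct_tampon == pytest.approx(s.pct_tampon_of_content, rel=1e-12)

    def test_partial_release_uses_content_denominator(self, baseline_params):
        s = fate_summary(simulate(baseline_params, SCHEDULES[2].replace(sim_end=4.0)))
        # half the content never leaves the tampon, so the content-based
        # percentage must exceed the released-based one
        assert s.pct_tampon_of_content > s.pct_tampon

    def test_mass_balance_violation_rejected(self, baseline_params,
                                             baseline_schedule):
        traj = simulate(baseline_params, baseline_schedule)
        traj.a_tampon = traj.a_tampon + 1.0  # corrupt conservation
        with pytest.raises(ValueError, match="mass balance"):
            fate_summary(traj, baseline_schedule)
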