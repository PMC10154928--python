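"""Isotope-washout metabolic power estimation and selection filters."""

import numpy as np
import pytest

from flightpower.exceptions import FitQualityError, InsufficientDataError, InvalidInputError
from flightpower.metabolic import (
    GLYCOGEN,
    MIXED_FUEL,
    BreathTrace,
    FlightEvent,
    MetabolicResult,
    bmr_from_respirometry,
    filter_flights,
    fit_washout,
    flight_vco2,
    power_from_vco2,
    pool_from_dose,
)
from flightpower.synth import gen_washout_trace


class TestWashoutFit:
    def test_noiseless_exponential_recovered_exactly(self):
        trace, _, truth = gen_washout_trace(noise_sd=0.0, seed=0)
        fit = fit_washout(trace, "washout_pre")
        assert fit.decay_rate == pytest.approx(
            truth.params["decay_rate_rest"], rel=1e-8)
        assert fit.amplitude == pytest.approx(
            truth.params["equilibrium_enrichment"], rel=1e-6)
        assert fit.baseline == pytest.approx(0.0, abs=1e-6)

    def test_noisy_decay_rate_within_three_percent(self):
        errs = []
        for r in range(60):
            trace, _, truth = gen_washout_trace(noise_sd=0.02, seed=100 + r)
            fit = fit_washout(trace, "washout_pre")
            errs.append(abs(fit.decay_rate / truth.params["decay_rate_rest"] - 1))
        assert np.median(errs) < 0.03

    def test_constant_trace_rejected(self):
        n = 50
        trace = BreathTrace(time=np.arange(n, dtype=float),
                            enrichment=np.full(n, 5.0),
                            co2_production=np.full(n, 0.2),
                            phase=np.array(["washout_pre"] * n, dtype=object))
        with pytest.raises(FitQualityError):
            fit_washout(trace, "washout_pre")

    def test_short_phase_rejected(self):
        trace = BreathTrace(time=np.arange(5, dtype=float),
                            enrichment=np.exp(-np.arange(5.0)),
                            co2_production=np.full(5, 0.2),
                            phase=np.array(["washout_pre"] * 5, dtype=object))
        with pytest.raises(InsufficientDataError):
            fit_washout(trace, "washout_pre")


class TestFlightVco2:
    @staticmethod
    def estimate(trace, event, truth):
        pre = fit_washout(trace, "washout_pre")
        post = fit_washout(trace, "washout_post")
        return flight_vco2(trace, event, pre, post,
                           pool_ml_co2=truth.params["pool_ml_co2"])

    def test_all_landing_event_returns_resting_rate(self):
        trace, event, truth = gen_washout_trace(noise_sd=0.0, seed=1)
        grounded = FlightEvent(start=event.start, end=event.end,
                               landings=((event.start, event.end),))
        got = self.estimate(trace, grounded, truth)
        assert got == pytest.approx(truth.params["resting_vco2"], rel=1e-6)

    def test_step_increase_recovered(self):
        """A 3x resting step during a ~1 min flight is recovered within 5%."""
        trace, event, truth = gen_washout_trace(
            resting_vco2=0.23, flight_vco2=0.69, flight_duration=60.0,
            landings=(), noise_sd=0.0, seed=2)
        got = self.estimate(trace, event, truth)
        assert got == pytest.approx(0.69, rel=0.05)

    def test_noiseless_recovery_tight(self):
        trace, event, truth = gen_washout_trace(noise_sd=0.0, seed=3)
        got = self.estimate(trace, event, truth)
        assert got == pytest.approx(truth.params["flight_vco2"], rel=1e-6)

    def test_halving_flight_fraction_doubles_excess(self):
        """At a fixed isotope deficit the inferred in-flight excess rate is
        inversely proportional to the time attributed to flight."""
        trace, event, truth = gen_washout_trace(noise_sd=0.0, seed=4)
        pre = fit_washout(trace, "washout_pre")
        post = fit_washout(trace, "washout_post")
        pool = truth.params["pool_ml_co2"]
        rest = truth.params["resting_vco2"]
        full = FlightEvent(start=event.start, end=event.end)
        dur = event.end - event.start
        half = FlightEvent(start=event.start, end=event.end,
                           landings=((event.start, event.start + dur / 2),))
        v_full = flight_vco2(trace, full, pre, post, pool_ml_co2=pool)
        v_half = flight_vco2(trace, half, pre, post, pool_ml_co2=pool)
        assert (v_half - rest) == pytest.approx(2 * (v_full - rest), rel=1e-6)

    def test_inconsistent_pre_post_rates_rejected(self):
        trace, event, truth = gen_washout_trace(noise_sd=0.0, seed=5)
        pre = fit_washout(trace, "washout_pre")
        bad_post = type(pre)(amplitude=pre.amplitude, decay_rate=5 * pre.decay_rate,
                             baseline=pre.baseline, t_ref=pre.t_ref,
                             residual_sd=pre.residual_sd)
        with pytest.raises(FitQualityError):
            flight_vco2(trace, event, pre, bad_post,
                        pool_ml_co2=truth.params["pool_ml_co2"])

    def test_parameter_recovery_across_conditions(self):
        """Median P_met error < 5% across VCO2 1-4 ml/min, fractions 0.6-1."""
        rng = np.random.default_rng(99)
        errs = []
        for r in range(60):
            vco2 = float(rng.uniform(1.0, 4.0))
            frac = float(rng.uniform(0.6, 1.0))
            dur = 66.0
            landings = (() if frac >= 0.999 else
                        ((730.0, 730.0 + (1 - frac) * dur),))
            trace, event, truth = gen_washout_trace(
                flight_vco2=vco2, flight_duration=dur, landings=landings,
                noise_sd=0.02, seed=600 + r)
            got = self.estimate(trace, event, truth)
            errs.append(abs(power_from_vco2(got) / power_from_vco2(vco2) - 1))
        assert np.median(errs) < 0.05


class TestFuelConversion:
    def test_glycogen_factor_gives_one_watt(self):
        assert power_from_vco2(2.84, GLYCOGEN) == pytest.approx(1.0, abs=2e-3)

    def test_fuel_switch_is_exact_factor_ratio(self):
        v = 2.5
        ratio = power_from_vco2(v, MIXED_FUEL) / power_from_vco2(v, GLYCOGEN)
        assert ratio == pytest.approx(23.7 / 21.1, rel=1e-12)

    def test_zero_is_zero(self):
        assert power_from_vco2(0.0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(InvalidInputError):
            power_from_vco2(-1.0)

    def test_pool_from_dose(self):
        assert pool_from_dose(20.0, 20.0) == pytest.approx(1.0)
        with pytest.raises(InvalidInputError):
            pool_from_dose(0.0, 20.0)


class TestFilters:
    @staticmethod
    def res(p, frac=0.9, ind="a", speed=6.0):
        return MetabolicResult(vco2_flight=p * 60 / 21.1, p_met=p,
                               flight_fraction=frac, individual_id=ind,
                               speed=speed)

    def test_flight_fraction_boundary(self):
        low = self.res(1.0, frac=0.59)
        ok = self.res(1.0, frac=0.60)
        kept = filter_flights([low] + [ok] * 4, min_flights=1)
        assert low not in kept and ok in kept

    def test_z_score_hand_computed(self):
        group = [self.res(1.0) for _ in range(3)] + [self.res(2.0)]
        kept = filter_flights(group, min_flights=1)
        assert len(kept) == 4  # Z(2.0) = 1.73, retained
        assert kept[-1].z_score == pytest.approx(1.732, abs=1e-3)

    def test_z_exactly_two_retained(self):
        """Only Z strictly exceeding 2 is an outlier."""
        group = [self.res(1.0) for _ in range(4)] + [self.res(3.0)]
        kept = filter_flights(group, min_flights=1)
        assert len(kept) == 5
        assert kept[-1].z_score == pytest.approx(2.0, abs=1e-9)

    def test_clear_outlier_dropped(self):
        group = [self.res(1.0 + 0.01 * i) for i in range(6)] + [self.res(3.0)]
        kept = filter_flights(group, min_flights=1)
        assert all(r.p_met < 2.0 for r in kept)

    def test_individual_with_three_flights_excluded(self):
        few = [self.res(1.0, ind="few", speed=5 + i) for i in range(3)]
        many = [self.res(1.0, ind="many", speed=5 + i % 3) for i in range(5)]
        kept = filter_flights(few + many)
        assert {r.individual_id for r in kept} == {"many"}

    def test_singleton_speed_group_retained(self):
        lone = self.res(5.0, speed=9.0)
        kept = filter_flights([lone], min_flights=1)
        assert kept == [lone]
        assert np.isnan(lone.z_score)

    def test_filters_fill_bookkeeping_fields(self):
        group = [self.res(1.0) for _ in range(4)]
        filter_flights(group)
        assert all(r.retained for r in group)


class TestBmr:
    def test_oxygen_mode_reference_value(self):
        assert bmr_from_respirometry(0.239, "o2") == pytest.approx(0.080, abs=5e-4)

    def test_zero_flow(self):
        assert bmr_from_respirometry(0.0) == 0.0

    def test_thermoneutral_warning(self):
        with pytest.warns(UserWarning):
            bmr_from_respirometry(0.2, "o2", temperature_c=20.0)

    def test_synthetic_cohort_mean_near_target(self, rng):
        """Ten individuals generated around 0.08 W recover the cohort mean."""
        target = 0.08
        vo2 = target * 60 / 20.1 * (1 + rng.normal(0, 0.05, 10))
        powers = [bmr_from_respirometry(float(v), "o2") for v in vo2]
        sem = np.std(powers, ddof=1) / np.sqrt(len(powers))
        assert abs(np.mean(powers) - target) <= max(sem, 1e-3)
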