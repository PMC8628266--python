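import math

import numpy as np
import pytest

from ritpipe.biodist import TimeActivityCurve
from ritpipe.dosimetry import (
    DoseEstimate,
    InjectionSpec,
    TimeIntegratedActivity,
    absorbed_dose,
    dose_table,
    dose_table_wide,
    read_dose_table,
    surrogate_substitution_check,
    time_integrated_activity,
    write_dose_table,
)
from ritpipe.errors import ConfigError, MissingConstantError, ValidationError
from ritpipe.nuclides import Nuclide, builtin_nuclide

Y90 = builtin_nuclide("Y-90")
DELTA = 1.495e-13
LAMBDA_S = math.log(2) / (64.1 * 3600.0)
STABLE = Nuclide("stable", half_life_h=math.inf)


def curve(times, values, organ="tumor", group="saline"):
    n = len(times)
    return TimeActivityCurve(organ, group, times, values, [0.0] * n, [5] * n)


def brute_force_integral_s(times_h, values, lam_per_s, n_grid=100_000):
    """Independent oracle: fine-grid trapezoid of f(t)·e^(−λt) over the window."""
    t_s = np.asarray(times_h, dtype=float) * 3600.0
    grid = np.union1d(np.linspace(0.0, t_s[-1], n_grid), t_s)
    f = np.interp(grid, t_s, np.asarray(values, dtype=float))
    return float(np.trapezoid(f * np.exp(-lam_per_s * grid), grid))


class TestTimeIntegratedActivity:
    def test_constant_curve_closed_form(self):
        # f ≡ 100 %ID/g from t=0, physical-decay tail: Ã = A₀·1000/λ
        c = curve([0.0, 168.0], [100.0, 100.0])
        tia = time_integrated_activity(c, InjectionSpec(1e6, Y90), tail_mode="physical")
        expected = 1e6 * 1000.0 / LAMBDA_S
        assert tia.value == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(3.329e14, rel=1e-3)

    def test_stable_nuclide_triangle(self):
        # λ = 0, f rising linearly 0 -> 100 over one second, truncated tail:
        # triangle area 50 %ID/g·s, Ã = A₀ × 10 × 50
        c = curve([1.0 / 3600.0], [100.0])
        tia = time_integrated_activity(
            c, InjectionSpec(2e6, STABLE), tail_mode="truncate", t0_mode="zero"
        )
        assert tia.value == pytest.approx(2e6 * 10.0 * 50.0, rel=1e-12)

    def test_zero_curve(self):
        c = curve([1.0, 6.0], [0.0, 0.0])
        tia = time_integrated_activity(c, InjectionSpec(1e6, Y90))
        assert tia.value == 0.0

    def test_matches_brute_force(self):
        times = [1.0, 6.0, 24.0, 48.0, 96.0, 168.0]
        values = [3.2, 15.0, 30.0, 37.8, 36.0, 25.0]
        c = curve(times, values)
        tia = time_integrated_activity(
            c, InjectionSpec(1.0, Y90), tail_mode="truncate", t0_mode="zero"
        )
        oracle = brute_force_integral_s([0.0] + times, [0.0] + values, LAMBDA_S)
        assert tia.value == pytest.approx(10.0 * oracle, rel=1e-6)

    def test_trapezoid_method_agrees(self):
        times = [1.0, 6.0, 24.0, 48.0, 96.0, 168.0]
        values = [3.2, 15.0, 30.0, 37.8, 36.0, 25.0]
        c = curve(times, values)
        spec = InjectionSpec(1e6, Y90)
        analytic = time_integrated_activity(c, spec, method="analytic")
        numeric = time_integrated_activity(c, spec, method="trapezoid")
        assert numeric.value == pytest.approx(analytic.value, rel=1e-3)

    def test_hold_first_exceeds_zero_ramp(self):
        c = curve([6.0, 24.0], [10.0, 5.0], organ="blood")
        spec = InjectionSpec(1e6, Y90)
        hold = time_integrated_activity(c, spec, t0_mode="hold_first")
        ramp = time_integrated_activity(c, spec, t0_mode="zero")
        auto = time_integrated_activity(c, spec, t0_mode="auto")
        assert hold.value > ramp.value
        assert auto.value == hold.value  # blood holds its first value

    def test_auto_is_zero_ramp_for_non_blood(self):
        c = curve([6.0, 24.0], [10.0, 5.0], organ="liver")
        spec = InjectionSpec(1e6, Y90)
        assert (
            time_integrated_activity(c, spec, t0_mode="auto").value
            == time_integrated_activity(c, spec, t0_mode="zero").value
        )

    def test_tail_mode_ordering(self):
        # physical ≥ truncated; terminal_slope ≤ physical for a falling tail
        c = curve([24.0, 96.0, 168.0], [30.0, 20.0, 10.0])
        spec = InjectionSpec(1e6, Y90)
        phys = time_integrated_activity(c, spec, tail_mode="physical").value
        term = time_integrated_activity(c, spec, tail_mode="terminal_slope").value
        trunc = time_integrated_activity(c, spec, tail_mode="truncate").value
        assert phys >= trunc
        assert term <= phys
        assert term >= trunc

    def test_unknown_tail_mode(self):
        c = curve([1.0], [1.0])
        with pytest.raises(ConfigError):
            time_integrated_activity(c, InjectionSpec(1e6, Y90), tail_mode="bogus")

    def test_unknown_t0_mode(self):
        c = curve([1.0], [1.0])
        with pytest.raises(ConfigError):
            time_integrated_activity(c, InjectionSpec(1e6, Y90), t0_mode="bogus")

    def test_longer_half_life_larger_dose(self):
        c = curve([1.0, 48.0, 168.0], [5.0, 30.0, 20.0])
        longer = Nuclide("L", half_life_h=100.0, mean_energy_per_transition=DELTA)
        shorter = Nuclide("S", half_life_h=50.0, mean_energy_per_transition=DELTA)
        d_long = absorbed_dose(
            time_integrated_activity(c, InjectionSpec(1e6, longer)), longer
        )
        d_short = absorbed_dose(
            time_integrated_activity(c, InjectionSpec(1e6, shorter)), shorter
        )
        assert d_long.absorbed_dose_gy > d_short.absorbed_dose_gy


class TestOracleEquivalence:
    def test_random_piecewise_linear_curves(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n_pts = int(rng.integers(2, 9))
            times = np.sort(rng.uniform(0.5, 200.0, size=n_pts))
            times += np.arange(n_pts) * 1e-3  # enforce strict increase
            values = rng.uniform(0.0, 50.0, size=n_pts)
            c = curve(times.tolist(), values.tolist())
            tia = time_integrated_activity(
                c, InjectionSpec(1.0, Y90), tail_mode="truncate", t0_mode="zero"
            )
            oracle = brute_force_integral_s(
                [0.0] + times.tolist(), [0.0] + values.tolist(), LAMBDA_S
            )
            assert tia.value == pytest.approx(10.0 * oracle, rel=1e-6)


class TestAbsorbedDose:
    def test_unit_scaling_by_delta(self):
        tia = TimeIntegratedActivity("tumor", 1.0, 168.0, "physical", "saline", 1e6)
        assert absorbed_dose(tia, Y90).absorbed_dose_gy == pytest.approx(1.495e-13)

    def test_continues_constant_curve_example(self):
        tia = TimeIntegratedActivity("tumor", 3.329e14, 168.0, "physical", "saline", 1e6)
        assert absorbed_dose(tia, Y90).absorbed_dose_gy == pytest.approx(49.77, abs=0.05)

    def test_zero_tia_zero_dose(self):
        tia = TimeIntegratedActivity("tumor", 0.0, 168.0, "physical")
        assert absorbed_dose(tia, Y90).absorbed_dose_gy == 0.0

    def test_missing_delta_rejected(self, in111):
        tia = TimeIntegratedActivity("tumor", 1.0, 168.0, "physical")
        with pytest.raises(MissingConstantError):
            absorbed_dose(tia, in111)


class TestDoseTable:
    def _curves(self):
        return [
            curve([1, 24, 168], [3.0, 30.0, 20.0], organ="tumor"),
            curve([1, 24, 168], [10.0, 5.0, 1.0], organ="liver"),
        ]

    def test_printed_linearity_pattern(self):
        # doubling 0.925 -> 1.85 MBq doubles the dose (10.9 -> 21.8 pattern)
        estimates = dose_table(self._curves(), [0.925e6, 1.85e6], Y90)
        by_act = {e.activity_bq: e for e in estimates if e.organ == "tumor"}
        assert by_act[1.85e6].absorbed_dose_gy == 2.0 * by_act[0.925e6].absorbed_dose_gy

    def test_exact_linearity_bit_for_bit(self):
        estimates = dose_table(self._curves(), [1e6, 2e6, 4e6], Y90)
        tumor = sorted(
            (e for e in estimates if e.organ == "tumor"), key=lambda e: e.activity_bq
        )
        assert tumor[1].absorbed_dose_gy == 2.0 * tumor[0].absorbed_dose_gy
        assert tumor[2].absorbed_dose_gy == 4.0 * tumor[0].absorbed_dose_gy

    def test_empty_activities_rejected(self):
        with pytest.raises(ValidationError):
            dose_table(self._curves(), [], Y90)

    def test_nonpositive_activity_rejected(self):
        with pytest.raises(ValidationError):
            dose_table(self._curves(), [1e6, -1.0], Y90)

    def test_one_estimate_per_cell(self):
        estimates = dose_table(self._curves(), [1e6, 2e6], Y90)
        assert len(estimates) == 4

    def test_serialization_roundtrip_full_precision(self, tmp_path):
        estimates = dose_table(self._curves(), [0.925e6, 1.85e6, 3.7e6], Y90)
        long_path = tmp_path / "long.csv"
        wide_path = tmp_path / "wide.csv"
        write_dose_table(estimates, long_path, wide_path)
        back = read_dose_table(long_path)
        assert len(back) == len(estimates)
        orig = {(e.group, e.organ, e.activity_bq): e.absorbed_dose_gy for e in estimates}
        for e in back:
            assert e.absorbed_dose_gy == pytest.approx(
                orig[(e.group, e.organ, e.activity_bq)], rel=1e-12
            )

    def test_wide_report_rounded_to_tenth_gy(self):
        estimates = [
            DoseEstimate("tumor", "saline", 0.925e6, 10.8749),
            DoseEstimate("tumor", "saline", 1.85e6, 21.7498),
        ]
        wide = dose_table_wide(estimates, rounding_gy=0.1)
        assert wide.loc["tumor"].tolist() == [10.9, 21.7]


class TestSubstitutionCheck:
    def test_in111_for_y90_no_warning(self, in111, y90):
        report = surrogate_substitution_check(in111, y90)
        assert report.half_life_ratio == pytest.approx(67.4 / 64.1, rel=1e-12)
        assert report.half_life_ratio == pytest.approx(1.051, abs=5e-4)
        assert not report.warn

    def test_short_lived_imaging_warns(self, y90):
        fake = Nuclide("X", half_life_h=6.0)
        assert surrogate_substitution_check(fake, y90).warn

    def test_identity_zero_discrepancy(self, y90):
        report = surrogate_substitution_check(y90, y90)
        assert report.half_life_ratio == 1.0
        assert report.max_decay_weight_discrepancy == 0.0
        assert not report.warn
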