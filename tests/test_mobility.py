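"""CCS calibration round trips and the arrival-time compaction metric."""

import numpy as np
import pandas as pd
import pytest

from znbind.mobility import (ArrivalTimeDistribution, compaction_fraction,
                             corrected_drift_time, drift_to_ccs,
                             ensemble_average_ccs, fit_powerlaw_calibration,
                             reduced_ccs)
from znbind.scenario import simulate_atds


def synthetic_calibrants(a=390.0, b=0.55, edc=1.35, n=8):
    """Calibrant rows generated exactly from a known power law."""
    rng = np.random.default_rng(11)
    rows = []
    for i in range(n):
        mass = rng.uniform(8000, 17000)
        charge = int(rng.integers(7, 20))
        tprime = rng.uniform(3.0, 9.0)
        ccs_red = a * tprime ** b
        mu = mass * 28.006 / (mass + 28.006)
        ccs = ccs_red * charge / np.sqrt(mu)
        mz = (mass + charge * 1.00728) / charge
        arrival = tprime + edc * np.sqrt(mz) / 1000.0
        rows.append((f"cal{i}", mass, charge, ccs, arrival))
    return pd.DataFrame(rows, columns=["species", "mass_da", "charge",
                                       "ccs_a2", "arrival_ms"])


def two_gaussian_atd(w_compact, centers=(5.5, 8.5), sigma=(0.3, 0.3),
                     n=2001):
    t = np.linspace(3.0, 11.0, n)
    i = (w_compact / (sigma[0] * np.sqrt(2 * np.pi)) * np.exp(
            -0.5 * ((t - centers[0]) / sigma[0]) ** 2)
         + (1 - w_compact) / (sigma[1] * np.sqrt(2 * np.pi)) * np.exp(
            -0.5 * ((t - centers[1]) / sigma[1]) ** 2))
    return ArrivalTimeDistribution(time=t, intensity=i, charge=8)


class TestDriftCorrection:
    def test_zero_edc_is_identity(self):
        assert corrected_drift_time(8.0, 1600.0, 0.0) == 8.0

    def test_hand_arithmetic(self):
        assert corrected_drift_time(8.0, 1600.0, 1.35) == pytest.approx(
            8.0 - 1.35 * 40.0 / 1000.0)

    def test_strictly_increasing_in_arrival(self):
        t1 = corrected_drift_time(6.0, 1600.0, 1.35)
        t2 = corrected_drift_time(6.1, 1600.0, 1.35)
        assert t2 - t1 == pytest.approx(0.1)

    def test_inconsistent_edc_rejected(self):
        with pytest.raises(ValueError, match="EDC"):
            corrected_drift_time(0.05, 1600.0, 10.0)


class TestReducedCcs:
    def test_heavy_ion_limit(self):
        lim = reduced_ccs(1000.0, 1, 1e12)
        assert lim == pytest.approx(1000.0 * np.sqrt(28.006), rel=1e-9)

    def test_doubling_charge_halves(self):
        assert reduced_ccs(3000.0, 10, 12358.0) == pytest.approx(
            reduced_ccs(3000.0, 5, 12358.0) / 2)

    def test_hand_arithmetic(self):
        mu = 12358.0 * 28.006 / (12358.0 + 28.006)
        assert reduced_ccs(3000.0, 15, 12358.0) == pytest.approx(
            3000.0 * np.sqrt(mu) / 15)


class TestCalibration:
    def test_round_trip_recovers_power_law(self):
        cal = fit_powerlaw_calibration(synthetic_calibrants(), 1.35)
        assert cal.fit_a == pytest.approx(390.0, rel=1e-10)
        assert cal.fit_b == pytest.approx(0.55, rel=1e-10)
        assert cal.r_squared == pytest.approx(1.0, abs=1e-12)
        assert 0 < cal.fit_b < 1

    def test_round_trip_identity_on_calibrant_points(self):
        table = synthetic_calibrants()
        cal = fit_powerlaw_calibration(table, 1.35)
        for _, row in table.iterrows():
            mz = (row["mass_da"] + row["charge"] * 1.00728) / row["charge"]
            ccs = drift_to_ccs(row["arrival_ms"], mz, int(row["charge"]),
                               row["mass_da"], cal)
            assert ccs == pytest.approx(row["ccs_a2"], rel=1e-8)

    def test_two_calibrants_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            fit_powerlaw_calibration(synthetic_calibrants(n=2), 1.35)

    def test_degenerate_drift_times_rejected(self):
        t = synthetic_calibrants(n=4)
        mz = (t["mass_da"] + t["charge"] * 1.00728) / t["charge"]
        t["arrival_ms"] = 5.0 + 1.35 * np.sqrt(mz) / 1000.0
        with pytest.raises(ValueError, match="degenerate"):
            fit_powerlaw_calibration(t, 1.35)

    def test_ccs_monotone_and_linear_in_a(self):
        cal = fit_powerlaw_calibration(synthetic_calibrants(), 1.35)
        c1 = drift_to_ccs(6.0, 1800.0, 8, 14502.0, cal)
        c2 = drift_to_ccs(7.0, 1800.0, 8, 14502.0, cal)
        assert c2 > c1
        import dataclasses
        cal2 = dataclasses.replace(cal, fit_a=2 * cal.fit_a)
        assert drift_to_ccs(6.0, 1800.0, 8, 14502.0, cal2) == pytest.approx(
            2 * c1)


class TestCompactionFraction:
    def test_uniform_intensity_splits_by_window_length(self):
        t = np.linspace(3.0, 11.0, 1601)
        atd = ArrivalTimeDistribution(time=t, intensity=np.ones_like(t),
                                      charge=8)
        assert compaction_fraction(atd) == pytest.approx(50.0, abs=1e-9)

    def test_all_compact(self):
        atd = two_gaussian_atd(1.0)
        assert compaction_fraction(atd) == pytest.approx(100.0, abs=1e-3)

    def test_symmetric_two_gaussians_give_fifty_percent(self):
        assert compaction_fraction(two_gaussian_atd(0.5)) == pytest.approx(
            50.0, abs=1e-6)

    def test_scaling_and_grid_refinement_invariance(self):
        coarse = two_gaussian_atd(0.37, n=500)
        fine = two_gaussian_atd(0.37, n=5000)
        f_coarse = compaction_fraction(coarse)
        f_fine = compaction_fraction(fine)
        assert abs(f_coarse - f_fine) < 0.1
        scaled = ArrivalTimeDistribution(
            time=coarse.time, intensity=coarse.intensity * 123.0, charge=8)
        assert compaction_fraction(scaled) == pytest.approx(f_coarse,
                                                            rel=1e-12)

    def test_compact_plus_extended_sum_to_100(self):
        atd = two_gaussian_atd(0.3)
        extended = 100.0 - compaction_fraction(atd)
        swapped = compaction_fraction(
            atd, compact_window=(7.0, 10.0), extended_window=(4.0, 7.0))
        assert swapped == pytest.approx(extended, abs=1e-9)

    def test_empty_windows_error(self):
        t = np.linspace(3.0, 11.0, 801)
        i = np.where(t < 3.5, 1.0, 0.0)
        with pytest.raises(ValueError, match="no intensity"):
            compaction_fraction(ArrivalTimeDistribution(
                time=t, intensity=i, charge=8))

    def test_short_grid_rejected(self):
        t = np.linspace(4.5, 9.0, 200)
        with pytest.raises(ValueError, match="cover"):
            compaction_fraction(ArrivalTimeDistribution(
                time=t, intensity=np.ones_like(t), charge=8))


class TestEnsembleAverage:
    def test_delta_like_atd_maps_to_its_ccs(self):
        cal = fit_powerlaw_calibration(synthetic_calibrants(), 1.35)
        t = np.linspace(3.0, 11.0, 4001)
        i = np.zeros_like(t)
        idx = np.argmin(np.abs(t - 6.2))
        i[idx] = 1.0
        atd = ArrivalTimeDistribution(time=t, intensity=i, charge=8)
        got = ensemble_average_ccs([atd], cal, {8: 1814.0}, 14502.0)
        assert got == pytest.approx(
            drift_to_ccs(t[idx], 1814.0, 8, 14502.0, cal), rel=1e-12)

    def test_equal_weights_average(self):
        cal = fit_powerlaw_calibration(synthetic_calibrants(), 1.35)
        t = np.linspace(3.0, 11.0, 4001)

        def delta(at):
            i = np.zeros_like(t)
            i[np.argmin(np.abs(t - at))] = 1.0
            return ArrivalTimeDistribution(time=t, intensity=i, charge=8)

        a1, a2 = delta(5.0), delta(9.0)
        got = ensemble_average_ccs([a1, a2], cal, {8: 1814.0}, 14502.0)
        c1 = ensemble_average_ccs([a1], cal, {8: 1814.0}, 14502.0)
        c2 = ensemble_average_ccs([a2], cal, {8: 1814.0}, 14502.0)
        assert got == pytest.approx((c1 + c2) / 2, rel=1e-12)

    def test_generator_average_ccs_decreases_with_dose(self, noiseless_truth):
        cal = fit_powerlaw_calibration(synthetic_calibrants(), 1.35)
        atds = simulate_atds(noiseless_truth, charge=8)
        mz = {8: (noiseless_truth.protein_avg_mass + 8 * 1.00728) / 8}
        ccs = [ensemble_average_ccs([a], cal, mz,
                                    noiseless_truth.protein_avg_mass)
               for a in atds]
        assert (np.diff(ccs) < 1e-9).all()
        assert ccs[-1] < ccs[0]

    def test_empty_input_rejected(self):
        cal = fit_powerlaw_calibration(synthetic_calibrants(), 1.35)
        with pytest.raises(ValueError):
            ensemble_average_ccs([], cal, {}, 14502.0)
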