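"""Scenario generator: determinism, noiseless closure, monotone linkage."""

import dataclasses

import numpy as np
import pytest

from znbind.binding import fit_kds
from znbind.kinetics import blank_correct, extract_t50, normalize_trace
from znbind.mobility import compaction_fraction
from znbind.scenario import (ScenarioTruth, scenario_paper_mimic,
                             simulate_atds, simulate_hsqc, simulate_tht,
                             simulate_titration_spectra)
from znbind.spectra import assign_adduct_series, extract_peak_areas


class TestDefaults:
    def test_thirteen_point_titration(self, truth):
        assert len(truth.ligand_concs) == 13
        assert truth.ligand_concs[0] == 0.0
        assert truth.ligand_concs[-1] == pytest.approx(800e-6)

    def test_equivalents_start(self, truth):
        np.testing.assert_allclose(truth.equivalents[:7],
                                   [0, 0.1, 0.5, 1, 2, 3, 5])

    def test_two_calls_identical(self):
        assert scenario_paper_mimic() == scenario_paper_mimic()

    def test_five_sites_per_charge(self, truth):
        assert all(len(k) == 5 for k in truth.kds_per_charge.values())
        assert truth.kds_per_charge[7][0] == pytest.approx(58e-6)
        assert truth.kds_per_charge[12][0] == pytest.approx(27e-6)

    def test_t50_dose_response_shape(self, truth):
        # baseline at x=0, plateau in the limit, midpoint at x=K
        assert truth.t50_true(0.0) == truth.t50_baseline
        assert truth.t50_true(1e9) == pytest.approx(truth.t50_plateau,
                                                    rel=1e-6)
        k = truth.t50_halfsat_equivalents
        assert truth.t50_true(k) == pytest.approx(
            (truth.t50_baseline + truth.t50_plateau) / 2)

    def test_json_round_trip(self, truth, tmp_path):
        path = tmp_path / "scenario.json"
        truth.to_json(path)
        assert ScenarioTruth.from_json(path) == truth

    def test_invalid_scenarios_rejected(self, truth):
        with pytest.raises(ValueError, match="t50"):
            dataclasses.replace(truth, t50_plateau=40.0)
        with pytest.raises(ValueError, match="compaction"):
            dataclasses.replace(truth, compaction_link_slope=2.0)


class TestDeterminism:
    def test_spectra_bit_identical(self, truth):
        s1 = simulate_titration_spectra(truth, charges=[8])
        s2 = simulate_titration_spectra(truth, charges=[8])
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_all_modalities_reproducible(self, truth):
        a1 = simulate_atds(truth)
        a2 = simulate_atds(truth)
        for x, y in zip(a1, a2):
            np.testing.assert_array_equal(x.intensity, y.intensity)
        t1 = simulate_tht(truth)
        t2 = simulate_tht(truth)
        for x, y in zip(t1, t2):
            np.testing.assert_array_equal(x.fluorescence, y.fluorescence)
        h1 = simulate_hsqc(truth)
        h2 = simulate_hsqc(truth)
        for x, y in zip(h1, h2):
            np.testing.assert_array_equal(x["delta_h_ppm"], y["delta_h_ppm"])

    def test_different_seed_changes_noise(self, truth):
        other = dataclasses.replace(truth, seed=truth.seed + 1)
        s1 = simulate_titration_spectra(truth, charges=[8])[3]
        s2 = simulate_titration_spectra(other, charges=[8])[3]
        assert not np.array_equal(s1.intensity, s2.intensity)


class TestNoiselessClosure:
    def test_occupancy_recovers_truth(self, noiseless_truth):
        specs = simulate_titration_spectra(noiseless_truth, charges=[8])
        assignments = assign_adduct_series(
            noiseless_truth.protein_avg_mass, 8, 5,
            noiseless_truth.adduct_mass_shift)
        from znbind.binding import percent_occupancy
        for point, spec in enumerate(specs):
            table = extract_peak_areas(spec, assignments)
            truth_pct = 100.0 * noiseless_truth.bound_fraction(point)
            if truth_pct == 0.0:
                assert percent_occupancy(table) < 1e-6
            else:
                assert percent_occupancy(table) == pytest.approx(
                    truth_pct, rel=1e-6)

    def test_kd_fit_recovers_truth(self, noiseless_truth):
        specs = simulate_titration_spectra(noiseless_truth, charges=[8])
        assignments = assign_adduct_series(
            noiseless_truth.protein_avg_mass, 8, 5,
            noiseless_truth.adduct_mass_shift)
        import pandas as pd
        areas = pd.concat([extract_peak_areas(s, assignments) for s in specs],
                          ignore_index=True)
        res = fit_kds(areas, noiseless_truth.design, n_sites=5)
        np.testing.assert_allclose(res.kds, noiseless_truth.kds_per_charge[8],
                                   rtol=1e-4)

    def test_compaction_recovers_link(self, noiseless_truth):
        atds = simulate_atds(noiseless_truth, charge=8)
        for point, atd in enumerate(atds):
            expect = 100.0 * noiseless_truth.compact_weight(point)
            # Gaussian tails outside the windows bound the residual error
            assert compaction_fraction(atd) == pytest.approx(expect,
                                                             abs=0.05)

    def test_t50_recovers_truth(self, noiseless_truth):
        traces = simulate_tht(noiseless_truth)
        blanks = [t for t in traces if t.is_blank]
        for tr in traces:
            if tr.is_blank:
                continue
            got = extract_t50(normalize_trace(blank_correct([tr],
                                                            blanks)[0]))
            expect = noiseless_truth.t50_true(tr.condition)
            assert got == pytest.approx(expect, rel=1e-3)


class TestMonotoneLinkage:
    def test_occupancy_compactweight_and_t50_all_monotone(self, truth):
        occ = [truth.bound_fraction(p) for p in range(13)]
        w = [truth.compact_weight(p) for p in range(13)]
        drop = [truth.t50_baseline - truth.t50_true(x)
                for x in truth.equivalents]
        for series in (occ, w, drop):
            assert (np.diff(series) >= -1e-12).all()

    def test_atd_compact_weight_increases_zero_to_saturating(self, truth):
        assert truth.compact_weight(12) > truth.compact_weight(0)

    def test_constant_link_gives_constant_fraction(self, noiseless_truth):
        flat = dataclasses.replace(noiseless_truth,
                                   compaction_link_intercept=0.5,
                                   compaction_link_slope=0.0)
        atds = simulate_atds(flat, charge=8)
        for atd in atds:
            assert compaction_fraction(atd) == pytest.approx(50.0, abs=0.05)


class TestSimulatorContracts:
    def test_spectra_reject_bad_inputs(self, truth):
        with pytest.raises(ValueError, match="charges"):
            simulate_titration_spectra(truth, charges=[4])
        with pytest.raises(ValueError, match="width"):
            simulate_titration_spectra(truth, charges=[8], peak_fwhm=0.0)

    def test_atds_reject_short_grid(self, truth):
        with pytest.raises(ValueError, match="cover"):
            simulate_atds(truth, time_grid=np.linspace(4.5, 9.0, 100))

    def test_apo_only_at_zero_ligand(self, noiseless_truth):
        spec = simulate_titration_spectra(noiseless_truth, charges=[8])[0]
        assignments = assign_adduct_series(
            noiseless_truth.protein_avg_mass, 8, 5,
            noiseless_truth.adduct_mass_shift)
        table = extract_peak_areas(spec, assignments)
        areas = table.sort_values("n_bound")["area"].to_numpy()
        assert areas[0] > 0
        assert np.all(areas[1:] / areas[0] < 1e-9)

    def test_hsqc_zero_ligand_zero_csp(self, noiseless_truth):
        tables = simulate_hsqc(noiseless_truth)
        assert np.allclose(tables[0]["delta_h_ppm"], 0.0)

    def test_hsqc_half_saturation_point(self, noiseless_truth):
        # CSP at L = halfsat equals half the per-residue maximum
        assert noiseless_truth.csp_true(
            121, noiseless_truth.csp_halfsat) == pytest.approx(
                0.5 * noiseless_truth.csp_profile[121])

    def test_tht_trace_count_and_blanks(self, truth):
        traces = simulate_tht(truth)
        n_points = len(truth.ligand_concs)
        samples = [t for t in traces if not t.is_blank]
        blanks = [t for t in traces if t.is_blank]
        assert len(samples) == n_points * truth.n_replicates
        assert len(blanks) == n_points
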