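"""Synthetic-data generator: ground-truth contracts, noiseless
equality with the forward models, determinism, and design limits."""

import json

import numpy as np
import pytest

from slowex import simulate, spin
from slowex.cest import estimate_profile_noise
from slowex.types import Topology


class TestMakeScenario:
    def test_single_mutant_scenario_is_two_site(self):
        truth = simulate.make_scenario("S99T-like", 3, seed=1)
        assert truth.exchange.topology is Topology.TWO_SITE_AB
        assert truth.exchange.k_ex_AB == 188.3
        assert truth.exchange.p_B == 0.0122

    def test_triple_mutant_scenario_is_linear_bac(self):
        truth = simulate.make_scenario("triple-like", 2, seed=1)
        ex = truth.exchange
        assert ex.topology is Topology.LINEAR_BAC
        assert (ex.k_ex_AB, ex.p_B) == (265.1, 0.0432)
        assert (ex.k_ex_AC, ex.p_C) == (186.5, 0.0073)

    def test_unknown_scenario_lists_valid_names(self):
        with pytest.raises(ValueError, match="S99T-like"):
            simulate.make_scenario("quadruple", 3)

    def test_zero_residues_gives_empty_truth(self):
        truth = simulate.make_scenario("S99T-like", 0, seed=1)
        assert truth.per_residue == {}
        profs = simulate.generate_cest_dataset(
            truth, simulate.default_cest_schedules("S99T-like",
                                                   spacing_hz=100.0))
        assert profs == []

    def test_every_residue_has_group_and_plausible_parameters(self):
        truth = simulate.make_scenario("triple-like", 3, seed=5)
        assert set(truth.per_residue) == set(truth.group_assignment)
        for rid, s in truth.per_residue.items():
            group = truth.group_assignment[rid]
            assert 1.0 <= s.R1 <= 2.0 and 8.0 <= s.R2 <= 20.0
            if group in ("process1", "both"):
                assert 1.0 <= abs(s.dw_AB) <= 5.0
            else:
                assert s.dw_AB == 0.0
            if group in ("process2", "both"):
                assert 1.0 <= abs(s.dw_AC) <= 5.0

    def test_truth_sidecar_round_trips(self, tmp_path):
        truth = simulate.make_scenario("double-like", 2, seed=9)
        path = tmp_path / "truth.json"
        truth.save(path)
        back = simulate.ScenarioTruth.load(path)
        assert back.to_dict() == truth.to_dict()


class TestCESTGeneration:
    def test_noiseless_dataset_equals_forward_model(self):
        truth = simulate.make_scenario("S99T-like", 2, seed=2, noise_sd=0.0)
        scheds = simulate.default_cest_schedules("S99T-like",
                                                 spacing_hz=80.0)
        profs = simulate.generate_cest_dataset(truth, scheds, seed=0)
        for p in profs:
            expected = spin.cest_forward(truth.exchange,
                                         truth.per_residue[p.residue_id],
                                         p.schedule)
            assert np.array_equal(p.ratios, expected)

    def test_same_seed_reproduces_dataset(self):
        truth = simulate.make_scenario("S99T-like", 2, seed=2)
        scheds = simulate.default_cest_schedules("S99T-like",
                                                 spacing_hz=80.0)
        a = simulate.generate_cest_dataset(truth, scheds, seed=7)
        b = simulate.generate_cest_dataset(truth, scheds, seed=7)
        assert all(np.array_equal(x.ratios, y.ratios)
                   for x, y in zip(a, b))

    def test_default_grid_keeps_enough_baseline_for_noise_estimation(self):
        truth = simulate.make_scenario("S99T-like", 3, seed=2)
        scheds = simulate.default_cest_schedules("S99T-like")
        profs = simulate.generate_cest_dataset(truth, scheds, seed=1)
        # the noise estimator must not fall back to its floor
        sigma = estimate_profile_noise(profs[0])
        assert sigma == pytest.approx(truth.noise_sd, rel=0.5)

    def test_narrow_grid_warns_about_unobservable_dip(self):
        truth = simulate.make_scenario("S99T-like", 1, seed=2)
        rid, sp = next(iter(truth.per_residue.items()))
        sched = simulate.default_cest_schedules("S99T-like",
                                                spacing_hz=60.0)[0]
        import dataclasses

        narrow = dataclasses.replace(
            sched, offsets=np.linspace(sp.shift_ppm - 0.5,
                                       sp.shift_ppm + 0.5, 60))
        with pytest.warns(UserWarning, match="outside the offset grid"):
            simulate.generate_cest_dataset(truth, [narrow], seed=0)


class TestCPMGGeneration:
    def test_flat_profiles_without_exchange(self):
        truth = simulate.make_scenario("S99T-like", 2, seed=2,
                                       noise_sd=0.0)
        truth.noise_sd_r2 = 0.0
        for s in truth.per_residue.values():
            s.dw_AB = 0.0
        profs = simulate.generate_cpmg_dataset(
            truth, [simulate.default_cpmg_schedule()], seed=0)
        for p in profs:
            assert np.allclose(p.R2_eff, truth.per_residue[
                p.residue_id].R2)

    def test_duplicates_generated_independently(self):
        truth = simulate.make_scenario("S99T-like", 1, seed=2)
        profs = simulate.generate_cpmg_dataset(
            truth, [simulate.default_cpmg_schedule()], seed=0)
        p = profs[0]
        dup = p.duplicate_mask()
        assert dup.sum() == 6  # three duplicated frequencies
        for v in (200.0, 800.0, 1000.0):
            vals = p.R2_eff[p.nu_values == v]
            assert vals.size == 2 and vals[0] != vals[1]

    def test_slow_process_rex_grows_with_temperature(self):
        truth = simulate.make_scenario("S99T-like", 3, seed=6,
                                       noise_sd=0.0)
        truth.noise_sd_r2 = 0.0
        scheds = [simulate.default_cpmg_schedule(283.15),
                  simulate.default_cpmg_schedule(288.15)]
        profs = simulate.generate_cpmg_dataset(truth, scheds, seed=0)
        by_res = {}
        for p in profs:
            by_res.setdefault(p.residue_id, {})[
                p.schedule.temperature] = p
        for rid, d in by_res.items():
            rex = {t: p.R2_eff.max() - p.R2_eff.min()
                   for t, p in d.items()}
            assert rex[288.15] > rex[283.15]


class TestTitrationGeneration:
    def test_fractional_shift_at_highest_concentration(self):
        # K_D = 5.4 mM, protein 0.25 mM, ligand 9 mM: solving the
        # single-site quadratic exactly gives a bound fraction of
        # (14.65 - sqrt(14.65^2 - 9)) / 0.5 = 0.62091
        frac = simulate.bound_fraction(9.0, 0.25, 5.4)
        assert frac == pytest.approx(0.62091, abs=1e-4)

    def test_zero_concentration_stays_at_apo(self):
        series = simulate.generate_titration_dataset(
            5.4, {"T1": (0.1, 0.8)}, seed=3, noise_h=0.0, noise_n=0.0)
        s = series[0]
        assert s.ligand_concentrations[0] == 0.0
        d = s.positions - s.positions[0]
        assert np.all(d[0] == 0.0)
        assert np.all(np.abs(d[1:]) > 0)

    def test_infinite_kd_limit_gives_no_shift(self):
        series = simulate.generate_titration_dataset(
            1e9, {"T1": (0.1, 0.8)}, seed=3, noise_h=0.0, noise_n=0.0)
        d = series[0].positions - series[0].positions[0]
        assert np.abs(d).max() < 1e-6


class TestAssayGeneration:
    def test_background_curve_has_background_rate(self):
        curves = simulate.generate_assay_curves(
            0.13e5, 5e-3, [2e-6], seed=0, noise_sd=0.0)
        bg = [c for c in curves if c.enzyme_concentration == 0.0]
        assert len(bg) == 3
        # noiseless single exponential at k0 exactly
        c = bg[0]
        fitted = -np.log((0.60 - c.absorbance) / 0.50) / c.times.clip(1e-9)
        assert np.allclose(fitted[1:], 5e-3, rtol=1e-9)

    def test_design_window_arithmetic(self):
        # k_obs = k0 + (kcat/KM) [E] = 5e-3 + 0.13e5 * 2e-6 = 3.1e-2
        curves = simulate.generate_assay_curves(
            0.13e5, 5e-3, [2e-6], seed=0, noise_sd=0.0)
        cat = [c for c in curves if c.enzyme_concentration > 0]
        k_obs = 5e-3 + 0.13e5 * 2e-6
        assert k_obs / 5e-3 == pytest.approx(6.2)
        c = cat[0]
        expected = 0.10 + 0.50 * (1 - np.exp(-k_obs * c.times))
        assert np.allclose(c.absorbance, expected)

    def test_out_of_window_concentration_warns(self):
        with pytest.warns(UserWarning, match="design window"):
            simulate.generate_assay_curves(0.13e5, 5e-3, [1e-7], seed=0)

    def test_same_seed_same_curves(self):
        a = simulate.generate_assay_curves(0.13e5, 5e-3, [2e-6], seed=4)
        b = simulate.generate_assay_curves(0.13e5, 5e-3, [2e-6], seed=4)
        assert all(np.array_equal(x.absorbance, y.absorbance)
                   for x, y in zip(a, b))
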