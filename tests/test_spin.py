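"""Forward-model physics: Bloch-McConnell propagation, exchange-matrix
structure, Carver-Richards limits, and oracle cross-checks."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.linalg import expm as scipy_expm

from slowex import spin
from slowex._expm import expm_action_batch
from slowex.constants import NITROGEN_FREQ_500, NITROGEN_FREQ_600
from slowex.types import (
    CESTSchedule,
    CPMGSchedule,
    ExchangeParameters,
    ResidueSpinParameters,
    Topology,
    UnsupportedModelError,
)


class TestExchangeRateMatrix:
    def test_two_site_rates_from_kex_and_population(self, s99t_exchange):
        K = spin.exchange_rate_matrix(s99t_exchange)
        # k_A->B = p_B k_ex, k_B->A = p_A k_ex
        assert K[1, 0] == pytest.approx(2.297, abs=5e-4)
        assert K[0, 1] == pytest.approx(186.0, abs=0.05)

    def test_columns_sum_to_zero(self, triple_exchange):
        K = spin.exchange_rate_matrix(triple_exchange)
        assert np.abs(K.sum(axis=0)).max() < 1e-12

    @pytest.mark.parametrize("topology", [Topology.LINEAR_BAC,
                                          Topology.LINEAR_ABC,
                                          Topology.LINEAR_ACB])
    def test_populations_are_stationary(self, topology):
        ex = ExchangeParameters(topology, 265.1, 0.0432, 186.5, 0.0073)
        K = spin.exchange_rate_matrix(ex)
        assert np.abs(K @ ex.populations).max() < 1e-10

    @pytest.mark.parametrize("topology,zero_pair", [
        (Topology.LINEAR_BAC, (1, 2)),   # no direct B<->C coupling
        (Topology.LINEAR_ABC, (0, 2)),   # no direct A<->C coupling
        (Topology.LINEAR_ACB, (0, 1)),   # no direct A<->B coupling
    ])
    def test_linear_chains_have_no_skipped_edge(self, topology, zero_pair):
        ex = ExchangeParameters(topology, 265.1, 0.0432, 186.5, 0.0073)
        K = spin.exchange_rate_matrix(ex)
        i, j = zero_pair
        assert K[i, j] == 0.0 and K[j, i] == 0.0


class TestEvolutionMatrix:
    def test_no_exchange_no_rf_decays_longitudinally(self, spins):
        ex = ExchangeParameters(Topology.TWO_SITE_AB, 0.0, 0.0122)
        em = spin.build_evolution_matrix(ex, spins, B1=0.0, offset=118.0,
                                         carrier_freq=NITROGEN_FREQ_500)
        # z-z entries are -R1; no coupling between z and the transverse
        # plane without RF
        assert em.matrix[2, 2] == pytest.approx(-spins.R1)
        assert em.matrix[5, 5] == pytest.approx(-spins.R1)
        assert em.matrix[1, 2] == 0.0 and em.matrix[2, 1] == 0.0

    def test_z_magnetization_conserved_without_relaxation_or_rf(self):
        ex = ExchangeParameters(Topology.TWO_SITE_AB, 188.3, 0.0122)
        sp = ResidueSpinParameters("x", dw_AB=2.0, R1=1e-12, R2=1e-12,
                                   shift_ppm=118.0)
        em = spin.build_evolution_matrix(ex, sp, B1=0.0, offset=100.0,
                                         carrier_freq=NITROGEN_FREQ_500)
        L = em.matrix.copy()
        # remove the (negligible) relaxation entirely
        L[np.diag_indices_from(L)] -= np.diag(L) * (np.abs(np.diag(L))
                                                    < 1e-9)
        v0 = np.zeros(6)
        v0[2], v0[5] = 0.7, 0.3
        v1 = scipy_expm(L * 0.5) @ v0
        assert v1[2] + v1[5] == pytest.approx(1.0, abs=1e-12)


class TestCESTForward:
    def test_far_offset_ratio_is_pure_r1_decay(self):
        ex = ExchangeParameters(Topology.NONE)
        sp = ResidueSpinParameters("x", R1=1.5, R2=12.0, shift_ppm=118.0)
        sched = CESTSchedule(B1_field=25.0, T_EX=0.5,
                             offsets=np.array([178.0, 190.0]),
                             spectrometer_15N_freq=NITROGEN_FREQ_500)
        ratios = spin.cest_forward(ex, sp, sched)
        assert ratios == pytest.approx(np.exp(-0.75), abs=2e-3)

    def test_zero_b1_profile_is_flat_r1_decay(self, s99t_exchange, spins):
        sched = CESTSchedule(B1_field=0.0, T_EX=0.5,
                             offsets=np.linspace(110, 126, 11),
                             spectrometer_15N_freq=NITROGEN_FREQ_500)
        ratios = spin.cest_forward(s99t_exchange, spins, sched)
        assert np.allclose(ratios, np.exp(-0.75), atol=1e-12)

    def test_agrees_with_independent_ode_integrator(self, s99t_exchange,
                                                    spins, cest_schedule):
        ratios = spin.cest_forward(s99t_exchange, spins, cest_schedule)
        v0 = np.zeros(6)
        v0[2::3] = s99t_exchange.populations
        for k in range(0, cest_schedule.offsets.size, 8):
            L = spin.build_evolution_matrix(
                s99t_exchange, spins, cest_schedule.B1_field,
                cest_schedule.offsets[k],
                cest_schedule.spectrometer_15N_freq).matrix
            sol = solve_ivp(lambda t, y: L @ y, (0.0, cest_schedule.T_EX),
                            v0, method="DOP853", rtol=1e-11, atol=1e-13)
            oracle = sol.y[2, -1] / s99t_exchange.populations[0]
            assert ratios[k] == pytest.approx(oracle, abs=1e-6)

    def test_minor_dip_sits_at_minor_state_shift(self):
        ex = ExchangeParameters(Topology.TWO_SITE_AB, 50.0, 0.05)
        sp = ResidueSpinParameters("x", dw_AB=3.0, R1=1.5, R2=10.0,
                                   shift_ppm=118.0)
        sched = CESTSchedule(B1_field=15.0, T_EX=0.5,
                             offsets=np.linspace(112.0, 124.0, 241),
                             spectrometer_15N_freq=NITROGEN_FREQ_500)
        ratios = spin.cest_forward(ex, sp, sched)
        off = sched.offsets
        minor_region = np.abs(off - 121.0) < 1.5
        dip = off[minor_region][np.argmin(ratios[minor_region])]
        assert abs(dip - 121.0) <= (off[1] - off[0])

    def test_ratios_within_physical_range(self, s99t_exchange, spins,
                                          cest_schedule):
        ratios = spin.cest_forward(s99t_exchange, spins, cest_schedule)
        assert np.all(ratios <= 1.0) and np.all(ratios >= -1.0)


class TestCarverRichards:
    nu_grid = np.arange(100.0, 1001.0, 100.0)

    def test_no_minor_population_reduces_to_r2(self, spins):
        ex = ExchangeParameters(Topology.TWO_SITE_AB, 500.0, 1e-12)
        ex.p_B = 0.0  # exact limit, bypassing the (0,1) constructor check
        out = spin.carver_richards_r2eff(ex, spins, self.nu_grid)
        assert np.allclose(out, spins.R2)

    def test_fast_exchange_luz_meiboom_limit(self):
        ex = ExchangeParameters(Topology.TWO_SITE_AB, 1.0e4, 0.05)
        sp = ResidueSpinParameters("x", dw_AB=1.0, R2=10.0)
        dw = 2 * np.pi * 1.0 * NITROGEN_FREQ_600
        expected_rex = 0.95 * 0.05 * dw ** 2 / 1.0e4
        r2eff = spin.carver_richards_r2eff(ex, sp, 10.0)
        assert r2eff - sp.R2 == pytest.approx(expected_rex, rel=0.01)

    def test_slow_exchange_rex_equals_forward_rate(self, s99t_exchange):
        # deep slow exchange (dw >> k_ex): the low-nu exchange
        # contribution reduces to the major-to-minor conversion rate
        sp = ResidueSpinParameters("x", dw_AB=3.0, R2=12.0)
        r2eff = spin.carver_richards_r2eff(s99t_exchange, sp, 10.0)
        k_forward = 0.0122 * 188.3
        assert r2eff - sp.R2 == pytest.approx(k_forward, rel=0.05)

    def test_three_site_parameters_rejected(self, triple_exchange, spins):
        with pytest.raises(UnsupportedModelError):
            spin.carver_richards_r2eff(triple_exchange, spins, 100.0)

    @pytest.mark.parametrize("regime,draw", [(r, d) for r in ("slow",
                                                              "fast")
                                             for d in range(3)])
    def test_matches_numerical_propagation(self, regime, draw):
        # draws cover the study's parameter regimes: slow processes with
        # k_ex ~ 50-450 s^-1 and p_B up to ~4.5%, and a fast loop-motion
        # regime with k_ex in the 10^3-10^4 s^-1 range
        rng = np.random.default_rng(100 + draw)
        if regime == "slow":
            kex = float(10 ** rng.uniform(1.7, 2.65))
            dw = float(rng.uniform(1.5, 4.5))
        else:
            kex = float(10 ** rng.uniform(3.5, 4.2))
            dw = float(rng.uniform(0.5, 1.5))
        ex = ExchangeParameters(Topology.TWO_SITE_AB, k_ex_AB=kex,
                                p_B=float(rng.uniform(0.003, 0.045)))
        sp = ResidueSpinParameters("x", dw_AB=dw,
                                   R2=float(rng.uniform(8, 20)))
        sched = CPMGSchedule(nu_cpmg=self.nu_grid)
        cr = spin.carver_richards_r2eff(ex, sp, self.nu_grid)
        num = np.array([spin.numerical_cpmg_r2eff(ex, sp, sched, nu)
                        for nu in self.nu_grid])
        assert np.abs(cr - num).max() / np.abs(num).max() < 0.02


class TestNumericalCPMG:
    def test_no_exchange_gives_flat_r2(self, spins):
        ex = ExchangeParameters(Topology.TWO_SITE_AB, 1e-12, 0.0122)
        ex.k_ex_AB = 0.0
        sched = CPMGSchedule(nu_cpmg=np.array([100.0, 500.0, 1000.0]))
        for nu in sched.nu_cpmg:
            assert spin.numerical_cpmg_r2eff(ex, spins, sched, nu) == \
                pytest.approx(spins.R2, rel=1e-9)

    def test_incompatible_nu_rejected(self, s99t_exchange, spins):
        sched = CPMGSchedule(nu_cpmg=np.array([100.0]))
        with pytest.raises(ValueError, match="integer number of echoes"):
            spin.numerical_cpmg_r2eff(s99t_exchange, spins, sched, 333.3)

    def test_three_site_slow_processes_compose_additively(self):
        """For two independent slow processes (B<->A<->C), the exchange
        contribution approximates the sum of the two two-site
        contributions."""
        ex3 = ExchangeParameters(Topology.LINEAR_BAC, 150.0, 0.02,
                                 100.0, 0.01)
        sp = ResidueSpinParameters("x", dw_AB=2.5, dw_AC=-3.0, R2=10.0)
        sched = CPMGSchedule(nu_cpmg=np.array([100.0]))
        r3 = spin.numerical_cpmg_r2eff(ex3, sp, sched, 100.0)
        rex3 = r3 - sp.R2
        rex_sum = 0.0
        for kex, pb, dw in ((150.0, 0.02, 2.5), (100.0, 0.01, -3.0)):
            ex2 = ExchangeParameters(Topology.TWO_SITE_AB, kex, pb)
            sp2 = ResidueSpinParameters("x", dw_AB=dw, R2=10.0)
            rex_sum += spin.numerical_cpmg_r2eff(ex2, sp2, sched,
                                                 100.0) - sp.R2
        assert rex3 == pytest.approx(rex_sum, rel=0.10)


class TestIntensityConversion:
    def test_equal_intensities_give_zero(self):
        assert spin.r2eff_from_intensities(0.8, 0.8, 0.04) == 0.0

    def test_logarithmic_conversion(self):
        assert spin.r2eff_from_intensities(np.exp(-0.4), 1.0, 0.04) == \
            pytest.approx(10.0)

    def test_inverts_numerical_propagation(self, s99t_exchange, spins):
        sched = CPMGSchedule(nu_cpmg=np.array([200.0]))
        r2 = spin.numerical_cpmg_r2eff(s99t_exchange, spins, sched, 200.0)
        intensity = s99t_exchange.populations[0] * np.exp(-r2 * sched.T_cp)
        back = spin.r2eff_from_intensities(
            intensity, s99t_exchange.populations[0], sched.T_cp)
        assert back == pytest.approx(r2, rel=1e-12)

    def test_nonpositive_intensity_flagged(self):
        with pytest.warns(UserWarning, match="below noise"):
            out = spin.r2eff_from_intensities(
                np.array([-0.1, 0.5]), 1.0, 0.04)
        assert np.isnan(out[0]) and np.isfinite(out[1])


class TestExpmKernel:
    @pytest.mark.parametrize("n,scale", [(3, 1.0), (6, 50.0), (9, 2000.0)])
    def test_matches_scipy_expm(self, n, scale):
        # evolution-matrix-like stacks: large skew (precession) part on
        # top of a dissipative (negative-definite symmetric) part
        rng = np.random.default_rng(n)
        G = rng.normal(size=(40, n, n))
        skew = 0.5 * (G - np.swapaxes(G, 1, 2)) * scale
        S = rng.normal(size=(40, n, n))
        decay = -0.1 * scale * np.matmul(S, np.swapaxes(S, 1, 2)) / n
        A = skew + decay
        v = rng.normal(size=n)
        out = expm_action_batch(A, v)
        ref = np.einsum("bij,j->bi", scipy_expm(A), v)
        assert np.abs(out - ref).max() < 1e-9 * max(1.0,
                                                    np.abs(ref).max())
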