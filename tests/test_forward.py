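"""Forward-model tests: Bloch-McConnell generator, propagation, CW equivalence."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from cestpvc.forward import (
    GAMMA_H,
    ConfigurationError,
    Pool,
    PulseTrain,
    SaturationProtocol,
    assemble_generator,
    cw_equivalent_b1,
    simulate_zspectrum,
)
from cestpvc.forward import _assemble_batch

from conftest import random_pool_system


WATER = Pool("water", m0=1.0, kex=0.0, t1=1.3, t2=0.055, dw=0.0)


class TestAssembleGenerator:
    def test_water_only_no_saturation_equilibrium_is_fixed_point(self):
        A, b = assemble_generator([WATER], b1=0.0, offset=0.0)
        m_eq = np.array([0.0, 0.0, 1.0])
        assert np.allclose(A @ m_eq + b, 0.0, atol=1e-14)

    def test_four_pool_system_dimension(self):
        pools = [WATER] + [
            Pool(f"s{i}", 1e-3, 20.0, 1.0, 0.01, d) for i, d in enumerate((3.5, 0.0, -3.5))
        ]
        A, b = assemble_generator(pools, b1=0.55, offset=3.5)
        assert A.shape == (12, 12)
        assert b.shape == (12,)

    def test_two_pool_matrix_matches_hand_written_bloch_mcconnell(self):
        """Element-by-element check against the standard 2-pool BM equations,
        transcribed independently of the implementation."""
        water = Pool("water", m0=1.0, kex=0.0, t1=1.5, t2=0.06, dw=0.0)
        solute = Pool("amide", m0=2e-3, kex=25.0, t1=1.1, t2=0.015, dw=3.5)
        b1, offset, b0, larmor = 1.2, 2.0, 0.05, 127.74

        w1 = GAMMA_H * b1 * 1e-6
        dwa = 2 * math.pi * larmor * (offset - 0.0 - b0)
        dwb = 2 * math.pi * larmor * (offset - 3.5 - b0)
        kb = solute.kex                      # solute -> water
        ka = solute.kex * solute.m0          # water -> solute (detailed balance)
        r1a, r2a = 1 / water.t1, 1 / water.t2
        r1b, r2b = 1 / solute.t1, 1 / solute.t2
        # order (xa, ya, za, xb, yb, zb)
        expected = np.array(
            [
                [-(r2a + ka), -dwa, 0, kb, 0, 0],
                [dwa, -(r2a + ka), w1, 0, kb, 0],
                [0, -w1, -(r1a + ka), 0, 0, kb],
                [ka, 0, 0, -(r2b + kb), -dwb, 0],
                [0, ka, 0, dwb, -(r2b + kb), w1],
                [0, 0, ka, 0, -w1, -(r1b + kb)],
            ]
        )
        expected_b = np.array([0, 0, r1a * water.m0, 0, 0, r1b * solute.m0 * water.m0])
        A, b = assemble_generator([water, solute], b1, offset, b0, larmor)
        np.testing.assert_allclose(A, expected, rtol=1e-12)
        np.testing.assert_allclose(b, expected_b, rtol=1e-12)

    def test_non_water_first_pool_rejected(self):
        shifted = Pool("notwater", 1.0, 0.0, 1.3, 0.05, 3.5)
        with pytest.raises(ConfigurationError):
            assemble_generator([shifted], 0.55, 0.0)

    def test_nonpositive_relaxation_rejected(self):
        with pytest.raises(ValueError):
            Pool("water", 1.0, 0.0, -1.0, 0.05, 0.0)
        with pytest.raises(ValueError):
            Pool("water", 1.0, 0.0, 1.3, 0.0, 0.0)


class TestSimulateZspectrum:
    def test_no_saturation_gives_unit_signal(self, tissue_pools, protocol):
        prot = SaturationProtocol(b1=0.0, t_sat=2.0, offsets=protocol.offsets)
        z = simulate_zspectrum(tissue_pools, prot)
        np.testing.assert_array_equal(z.signal, 1.0)

    def test_far_off_resonance_saturation_negligible(self):
        prot = SaturationProtocol(b1=0.55, t_sat=2.0, offsets=(300.0,))
        z = simulate_zspectrum([WATER], prot)
        assert abs(z.signal[0] - 1.0) < 0.01

    @pytest.mark.parametrize("seed", range(5))
    def test_matrix_exponential_matches_ode_integration(self, seed):
        rng = np.random.default_rng(seed)
        pools = random_pool_system(rng, int(rng.integers(2, 5)), solute_t2=(1e-3, 3e-2))
        offsets = np.linspace(-5, 5, 7)
        prot = SaturationProtocol(b1=rng.uniform(0.3, 2.0), t_sat=2.0, offsets=offsets)
        z = simulate_zspectrum(pools, prot)
        A, b = _assemble_batch(pools, prot.b1, offsets, 0.0, prot.larmor)
        m0 = np.zeros(3 * len(pools))
        m0[2::3] = [p.m0 for p in pools]
        m0[5::3] *= pools[0].m0
        for i in range(offsets.size):
            sol = solve_ivp(
                lambda t, m: A[i] @ m + b, (0.0, prot.t_sat), m0,
                method="DOP853", rtol=1e-10, atol=1e-13,
            )
            assert abs(sol.y[2, -1] / pools[0].m0 - z.signal[i]) < 1e-6

    def test_stiff_semisolid_system_matches_pade_exponential(self):
        """With a 10 us T2 semisolid pool the equations are far too stiff for
        time-stepping oracles; the eigendecomposition propagator is checked
        against the independent Pade scaling-and-squaring matrix exponential
        of the affine-augmented system."""
        from cestpvc.params import default_protocol, default_tissue_pools

        pools = default_tissue_pools()
        prot = default_protocol()
        offsets = np.asarray(prot.offsets)
        z = simulate_zspectrum(pools, prot)
        A, b = _assemble_batch(pools, prot.b1, offsets, 0.0, prot.larmor)
        m0 = np.zeros(12)
        m0[2::3] = [p.m0 for p in pools]
        m0[5::3] *= pools[0].m0
        aug = np.zeros((13, 13))
        m_aug = np.concatenate([m0, [1.0]])
        for i in range(offsets.size):
            aug[:12, :12] = A[i]
            aug[:12, 12] = b
            ref = (expm(aug * prot.t_sat) @ m_aug)[2]
            assert abs(ref - z.signal[i]) < 1e-9

    def test_symmetric_pool_pair_gives_symmetric_spectrum(self, protocol):
        pools = [
            WATER,
            Pool("up", 1e-3, 20.0, 1.0, 0.02, 2.5),
            Pool("down", 1e-3, 20.0, 1.0, 0.02, -2.5),
        ]
        offs = np.linspace(-4.0, 4.0, 17)
        z = simulate_zspectrum(pools, protocol.with_offsets(offs))
        np.testing.assert_allclose(z.signal, z.signal[::-1], atol=1e-10)

    def test_signal_bounded_in_relaxation_dominated_regime(self):
        """Within the tissue-like regime (water T2 well below the saturation
        time) the normalized signal stays in [0, 1]; outside it coherent
        nutation transients can undershoot zero, so that regime is excluded."""
        rng = np.random.default_rng(11)
        for _ in range(10):
            pools = random_pool_system(rng, int(rng.integers(1, 5)))
            water = pools[0]
            t2 = rng.uniform(0.03, 0.08)
            pools[0] = Pool("water", water.m0, 0.0, water.t1, min(t2, water.t1), 0.0)
            prot = SaturationProtocol(
                b1=rng.uniform(0.0, 1.5), t_sat=rng.uniform(2.0, 4.0),
                offsets=np.linspace(-5, 5, 11),
            )
            z = simulate_zspectrum(pools, prot)
            assert np.all(z.signal >= -1e-6)
            assert np.all(z.signal <= 1.0 + 1e-6)

    def test_signal_decreases_with_amide_concentration_and_duration(self, tissue_pools):
        at_amide = SaturationProtocol(b1=0.55, t_sat=2.0, offsets=(3.5,))
        sigs = []
        for m0 in (2e-4, 5e-4, 1e-3, 2e-3):
            pools = [tissue_pools[0], tissue_pools[1].with_m0(m0)] + tissue_pools[2:]
            sigs.append(simulate_zspectrum(pools, at_amide).signal[0])
        assert np.all(np.diff(sigs) < 0)
        durations = [
            simulate_zspectrum(
                tissue_pools, SaturationProtocol(b1=0.55, t_sat=t, offsets=(3.5,))
            ).signal[0]
            for t in (0.5, 1.0, 2.0, 4.0)
        ]
        assert np.all(np.diff(durations) < 0)

    def test_b0_shift_equivalent_to_shifted_offsets(self, tissue_pools, protocol):
        delta = 0.13
        offs = np.linspace(-4, 4, 9)
        shifted_field = simulate_zspectrum(
            tissue_pools, protocol.with_offsets(offs), b0_shift=delta
        )
        shifted_axis = simulate_zspectrum(
            tissue_pools, protocol.with_offsets(offs - delta), b0_shift=0.0
        )
        np.testing.assert_allclose(shifted_field.signal, shifted_axis.signal, atol=1e-12)

    def test_normalized_signal_invariant_to_water_scale(self, tissue_pools, protocol):
        scaled = [tissue_pools[0].with_m0(4.2)] + tissue_pools[1:]
        z1 = simulate_zspectrum(tissue_pools, protocol)
        z2 = simulate_zspectrum(scaled, protocol)
        np.testing.assert_allclose(z1.signal, z2.signal, atol=1e-10)
        assert z2.s0 == pytest.approx(4.2)


class TestCwEquivalentB1:
    def test_zero_flip_angle(self):
        train = PulseTrain(10, 0.0, 0.02, 0.02)
        assert cw_equivalent_b1(train) == 0.0

    def test_rectangular_half_duty_cycle(self):
        # 180 deg over 20 ms -> peak pi/(gamma * 0.02) ~ 0.587 uT; RMS over the
        # 50% duty cycle scales by sqrt(0.5)
        train = PulseTrain(50, 180.0, 0.02, 0.02, shape="rectangular")
        peak = math.pi / (GAMMA_H * 0.02) * 1e6
        assert cw_equivalent_b1(train) == pytest.approx(peak * math.sqrt(0.5), rel=1e-9)
        assert cw_equivalent_b1(train) == pytest.approx(0.415, abs=5e-4)

    def test_continuous_rectangular_is_identity(self):
        train = PulseTrain(1, 90.0, 0.05, 0.0, shape="rectangular")
        peak = math.radians(90.0) / (GAMMA_H * 0.05) * 1e6
        assert cw_equivalent_b1(train) == pytest.approx(peak, rel=1e-12)

    def test_gaussian_requires_truncation(self):
        train = PulseTrain(50, 184.0, 0.02, 0.02, shape="gaussian")
        with pytest.raises(ConfigurationError):
            cw_equivalent_b1(train)

    def test_gaussian_protocol_reaches_nominal_average_power(self):
        train = PulseTrain(50, 184.0, 0.02, 0.02, shape="gaussian", gaussian_truncation=0.01)
        assert cw_equivalent_b1(train) == pytest.approx(0.55, abs=0.01)
        # averaging over the pulse alone concentrates the power
        assert cw_equivalent_b1(train, average_over="pulse") > cw_equivalent_b1(train)

    def test_pulse_train_total_duration(self):
        assert PulseTrain(50, 184.0, 0.02, 0.02).total_duration == pytest.approx(2.0)
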