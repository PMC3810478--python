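"""Fisher-information, F-value and figure-of-merit tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hdimtools.errors import DomainError, SingularModelError
from hdimtools.fisher import (
    ExponentialDecaySignature,
    cost_from_dark_counts,
    f_value_scalar,
    fisher_matrix,
    fisher_scalar,
    marginalize,
    photon_efficiency,
    resolution_and_power,
    separability,
    split_gain,
    technique_fvalue_scan,
    two_gate_f_curve,
    two_gate_optimum,
)
from hdimtools.models import FluorophoreModel, build_hdss, spectrum_fractions


class TestFisherScalar:
    def test_single_channel_carries_no_information(self):
        sig = ExponentialDecaySignature([0.0, 50.0], 50.0)
        assert fisher_scalar(sig, 2.0, N=1000) == pytest.approx(0.0, abs=1e-20)

    def test_fine_partition_approaches_exponential_limit(self):
        # closed form for the full exponential distribution: I = N / tau^2
        tau, N = 2.0, 1234.0
        sig = ExponentialDecaySignature(np.linspace(0, 25 * tau, 257), 25 * tau)
        info = fisher_scalar(sig, tau, N=N)
        assert info == pytest.approx(N / tau**2, rel=5e-3)

    def test_two_gate_algebraic_oracle(self):
        # two adjacent gates with boundary u*tau and T >> tau:
        # I = N u^2 e^-u / (tau^2 (1 - e^-u))
        tau, N, u = 2.0, 500.0, 1.59
        T = 40 * tau
        sig = ExponentialDecaySignature([0.0, u * tau, T], T)
        expected = N * u**2 * np.exp(-u) / (tau**2 * (1 - np.exp(-u)))
        assert fisher_scalar(sig, tau, N=N) == pytest.approx(expected, rel=1e-3)

    @pytest.mark.parametrize("delta", [0.005, 0.01, 0.02])
    def test_finite_difference_step_stability(self, delta):
        sig = ExponentialDecaySignature(np.linspace(0, 12.5, 17), 12.5)
        ref = fisher_scalar(sig, 2.5, delta=0.01)
        assert fisher_scalar(sig, 2.5, delta=delta) == pytest.approx(ref, rel=1e-3)


class TestFValueScalar:
    def test_two_gates_at_optimum(self):
        tau = 2.0
        sig = ExponentialDecaySignature([0.0, 1.59 * tau, 80.0], 80.0)
        assert f_value_scalar(sig, tau) == pytest.approx(1.24, abs=5e-3)

    def test_fine_partition_is_shot_limited(self):
        tau = 2.0
        sig = ExponentialDecaySignature(np.linspace(0, 25 * tau, 257), 25 * tau)
        assert f_value_scalar(sig, tau) == pytest.approx(1.0, abs=0.01)

    def test_independent_of_photon_count(self):
        sig = ExponentialDecaySignature([0.0, 3.0, 50.0], 50.0)
        assert f_value_scalar(sig, 2.0, N=250) == f_value_scalar(sig, 2.0, N=10000)

    def test_information_free_partition_warns_and_is_infinite(self):
        sig = ExponentialDecaySignature([0.0, 50.0], 50.0)
        with pytest.warns(RuntimeWarning):
            assert np.isinf(f_value_scalar(sig, 2.0))


class TestTwoGateCurve:
    def test_printed_optimum(self):
        u_star, f_star = two_gate_optimum()
        assert f_star == pytest.approx(1.24, abs=5e-3)
        assert u_star == pytest.approx(1.59, abs=5e-3)

    def test_direct_evaluation_and_divergence(self):
        assert two_gate_f_curve(1.0) == pytest.approx(np.sqrt(np.e - 1), rel=1e-12)
        assert two_gate_f_curve(1e-4) > 50.0
        assert two_gate_f_curve(40.0) > 1e6
        with pytest.raises(DomainError):
            two_gate_f_curve(0.0)

    def test_curve_agrees_with_fisher_scalar(self):
        tau, T = 1.7, 200.0
        for u in (0.8, 1.59, 2.5):
            sig = ExponentialDecaySignature([0.0, u * tau, T], T)
            assert f_value_scalar(sig, tau) == pytest.approx(
                float(two_gate_f_curve(u)), rel=2e-3
            )


class TestSplitGain:
    def test_trivial_split_gains_nothing(self):
        assert split_gain(100.0, 0.3, 0.0) == 0.0

    def test_quadratic_in_gradient_at_even_split(self):
        for c in (0.1, 0.2, 0.4):
            assert split_gain(7.0, 0.5, c) == pytest.approx(4 * 7.0 * c**2, rel=1e-12)

    def test_matches_direct_information_difference(self):
        # splitting the single gate of an exponential at t = 1.59 tau
        tau, N, T = 2.0, 1000.0, 300.0
        one = ExponentialDecaySignature([0.0, T], T)
        two = ExponentialDecaySignature([0.0, 1.59 * tau, T], T)
        direct = fisher_scalar(two, tau, N=N) - fisher_scalar(one, tau, N=N)

        # partitioning function phi(tau) = fraction of the channel's photons
        # landing in the first sub-gate; same 1% central-difference step as
        # fisher_scalar so the two-channel identity is exact
        def phi(t):
            return 1.0 - np.exp(-1.59 * tau / t)

        h = 0.01 * tau
        dphi = (phi(tau + h) - phi(tau - h)) / (2 * h)
        assert split_gain(N, phi(tau), dphi) == pytest.approx(direct, rel=1e-8)

    def test_degenerate_split_raises(self):
        with pytest.raises(DomainError):
            split_gain(10.0, 1.0, 0.1)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        u=st.floats(0.05, 6.0),
        tau=st.floats(0.5, 5.0),
    )
    def test_gain_formula_equals_eight_sum_difference(self, u, tau):
        """The split-gain formula reproduces the direct two-channel
        information difference for arbitrary single-channel splits."""
        T = 500.0
        N = 1.0
        one = ExponentialDecaySignature([0.0, T], T)
        two = ExponentialDecaySignature([0.0, u * tau, T], T)
        direct = fisher_scalar(two, tau, N=N) - fisher_scalar(one, tau, N=N)

        def phi(t):
            return 1.0 - np.exp(-u * tau / t)

        h = 0.01 * tau
        dphi = (phi(tau + h) - phi(tau - h)) / (2 * h)
        gain = split_gain(N, phi(tau), dphi)
        assert gain == pytest.approx(direct, rel=1e-8, abs=1e-15)


class TestFisherMatrix:
    def test_disjoint_support_is_shot_limited(self):
        # independent Poisson counts per component: exactly F = 1 each
        g_a = np.array([0.5, 0.5, 0.0, 0.0])
        g_b = np.array([0.0, 0.0, 0.25, 0.75])
        res = fisher_matrix([g_a, g_b], [0.5, 0.5], N=1.0)
        np.testing.assert_allclose(res.per_param_F, [1.0, 1.0], rtol=1e-10)
        assert res.combined_F == pytest.approx(1.0, rel=1e-10)

    def test_disjoint_support_at_uneven_mixture(self):
        g_a = np.array([1.0, 0.0])
        g_b = np.array([0.0, 1.0])
        res = fisher_matrix([g_a, g_b], [0.2, 0.8], N=5.0)
        np.testing.assert_allclose(res.per_param_F, [1.0, 1.0], rtol=1e-10)

    def test_duplicated_endmember_is_singular(self, fluor_a, small_grid):
        h = build_hdss(fluor_a, small_grid)
        with pytest.raises(SingularModelError):
            fisher_matrix([h, h], [0.5, 0.5])

    def test_combined_f_independent_of_total_photons(self, fluor_a, fluor_b, small_grid):
        ems = [build_hdss(fluor_a, small_grid), build_hdss(fluor_b, small_grid)]
        f1 = fisher_matrix(ems, [0.5, 0.5], N=250.0).combined_F
        f2 = fisher_matrix(ems, [0.5, 0.5], N=10000.0).combined_F
        assert f1 == pytest.approx(f2, rel=1e-12)

    def test_result_serializes(self, fluor_a, fluor_b, small_grid):
        ems = [build_hdss(fluor_a, small_grid), build_hdss(fluor_b, small_grid)]
        d = fisher_matrix(ems, [0.3, 0.7]).to_dict()
        assert set(d) >= {"information", "covariance", "per_param_F", "combined_F"}


class TestMarginalize:
    def test_identity_when_keeping_all(self, fluor_a, small_grid):
        h = build_hdss(fluor_a, small_grid)
        out = marginalize(h, ("polarization", "wavelength", "time"))
        np.testing.assert_array_equal(out, h.fractions)

    def test_wavelength_marginal_recovers_spectrum(self, fluor_a, paper_grid):
        h = build_hdss(fluor_a, paper_grid)
        out = marginalize(h, ("wavelength",))
        spec = spectrum_fractions(
            paper_grid.wavelength_edges, fluor_a.spectral_peak, fluor_a.spectral_fwhm
        )
        assert out.shape == (16,)
        np.testing.assert_allclose(out, spec, atol=1e-12)

    def test_total_preserved(self, fluor_b, small_grid):
        h = build_hdss(fluor_b, small_grid)
        for dims in [("time",), ("polarization", "time"), ("wavelength",)]:
            assert marginalize(h, dims).sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_keep_dims_rejected(self, fluor_a, small_grid):
        with pytest.raises(DomainError):
            marginalize(build_hdss(fluor_a, small_grid), ())


class TestTechniqueScan:
    def test_identical_fluorophores_are_unresolvable(self, fluor_a, small_grid):
        scan = technique_fvalue_scan(fluor_a, fluor_a, small_grid, [0.5])
        assert np.all(np.isinf(scan["F"]))

    def test_full_grid_dominates_every_marginalization(self, fluor_a, fluor_b, small_grid):
        scan = technique_fvalue_scan(fluor_a, fluor_b, small_grid, [0.3, 0.5, 0.7])
        for a, sub in scan.groupby("abundance"):
            hdim = sub.loc[sub.technique == "HDIM", "F"].iloc[0]
            assert (hdim <= sub["F"] + 1e-9).all()

    @settings(deadline=None, max_examples=15)
    @given(
        tau_a=st.floats(0.8, 5.0),
        tau_b=st.floats(0.8, 5.0),
        r0_a=st.floats(0.0, 0.4),
        r0_b=st.floats(0.0, 0.4),
        shift=st.floats(-20.0, 20.0),
        a=st.floats(0.15, 0.85),
    )
    def test_hdim_dominance_on_random_fluorophore_pairs(
        self, small_grid, tau_a, tau_b, r0_a, r0_b, shift, a
    ):
        """Photon partitioning: the full grid never loses to a binning of it."""
        fa = FluorophoreModel(tau_a, r0_a, 5.0, 500.0 + shift, 50.0)
        fb = FluorophoreModel(tau_b, r0_b, 2.0, 500.0, 50.0)
        try:
            scan = technique_fvalue_scan(fa, fb, small_grid, [a])
        except SingularModelError:
            return  # indistinguishable pair: every technique is singular
        finite = scan[np.isfinite(scan["F"])]
        if (finite.technique == "HDIM").any():
            hdim = finite.loc[finite.technique == "HDIM", "F"].iloc[0]
            assert (hdim <= finite["F"] * (1 + 1e-9)).all()


class TestRefinementMonotonicity:
    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(data=st.data())
    def test_nested_partitions_never_lose_information(self, data):
        """A finer partition of the same decay has >= Fisher information."""
        tau = data.draw(st.floats(0.5, 4.0))
        T = 30.0
        coarse_edges = np.sort(
            np.concatenate(
                [[0.0, T], data.draw(st.lists(st.floats(0.5, T - 0.5), min_size=1, max_size=5, unique=True))]
            )
        )
        # refine by bisecting every channel
        mids = (coarse_edges[:-1] + coarse_edges[1:]) / 2
        fine_edges = np.sort(np.concatenate([coarse_edges, mids]))
        coarse = fisher_scalar(ExponentialDecaySignature(coarse_edges, T), tau)
        fine = fisher_scalar(ExponentialDecaySignature(fine_edges, T), tau)
        assert fine >= coarse - 1e-9 * max(coarse, 1e-300)


class TestScalarFigures:
    def test_photon_efficiency_values(self):
        assert photon_efficiency(1.0) == 1.0
        assert photon_efficiency(2.0) == 0.25
        fs = np.linspace(0.5, 5.0, 20)
        ps = [photon_efficiency(f) for f in fs]
        assert all(p1 > p2 for p1, p2 in zip(ps, ps[1:]))
        with pytest.raises(DomainError):
            photon_efficiency(0.0)

    def test_separability(self):
        assert separability(1.0, 0.1, 1.0, 0.2) == 0.0
        assert separability(2.0, 0.5, 1.0, 0.5) == pytest.approx(1.0 / (0.5 * np.sqrt(2)))
        with pytest.raises(DomainError):
            separability(1.0, 0.0, 2.0, 0.1)

    def test_resolution_and_power(self):
        dx, R = resolution_and_power(1.0, 1.0, 400.0)
        assert dx == pytest.approx(2 * np.sqrt(2) / 20)
        assert R * dx == pytest.approx(1.0, rel=1e-12)
        _, R4 = resolution_and_power(1.0, 1.0, 1600.0)
        assert R4 == pytest.approx(2 * R, rel=1e-12)
        dx_eff, R_eff = resolution_and_power(1.0, 0.5, 400.0)
        assert dx_eff > dx and R_eff < R

    def test_dark_count_cost(self):
        assert cost_from_dark_counts(1e3, 1e6, 100) == pytest.approx(1e-5)
        assert cost_from_dark_counts(0.0, 1e6, 100) == 0.0
        assert cost_from_dark_counts(1e3, 1e6, 1000) == pytest.approx(1e-6)
        with pytest.raises(DomainError):
            cost_from_dark_counts(1e3, 0.0, 100)
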