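"""MVAR fitting, GPDC, and the flow quantifiers.

The GPDC path is checked against an independent, literal element-by-element
evaluation of the spectral transfer matrix and the noise-weighted column
normalization, plus a hand-computable two-channel case.
"""

import numpy as np
import pytest

from soflow.channels import ANALYSIS_CHANNELS
from soflow.connectivity import (MVARModel, default_freq_grid,
                                 fit_mvar, gpdc, non_so_quantifiers,
                                 quantifiers, select_order_aic,
                                 sliding_window_starts, so_epoch_quantifiers,
                                 spectral_radius)
from soflow.simulate import simulate_var


def literal_gpdc(coeffs, sigma, freqs):
    """Independent oracle: element-by-element spectral transfer + GPDC."""
    p, n, _ = coeffs.shape
    out = np.zeros((len(freqs), n, n))
    for fi, f in enumerate(freqs):
        a_f = np.zeros((n, n), dtype=complex)
        for i in range(n):
            for j in range(n):
                a_f[i, j] = (1.0 if i == j else 0.0) - sum(
                    coeffs[k - 1, i, j] * np.exp(-2j * np.pi * f * k)
                    for k in range(1, p + 1))
        for j in range(n):
            denom = np.sqrt(sum(abs(a_f[k, j]) ** 2 / sigma[k, k]
                                for k in range(n)))
            for i in range(n):
                out[fi, i, j] = (abs(a_f[i, j]) / np.sqrt(sigma[i, i])) / denom
    return out


def random_stable_model(rng, n=3, p=3):
    while True:
        coeffs = rng.normal(0, 0.25, (p, n, n))
        if spectral_radius(coeffs) < 0.95:
            break
    d = rng.uniform(0.5, 2.0, n)
    sigma = np.diag(d)
    return MVARModel(order=p, coeffs=coeffs, sigma=sigma, n_obs=1000)


class TestFitMVAR:
    def test_recovers_known_var2_coefficients(self, rng):
        a = np.zeros((2, 2, 2))
        a[0] = [[0.5, 0.1], [0.3, 0.4]]
        a[1] = [[-0.2, 0.0], [0.0, 0.1]]
        x = simulate_var(a, np.eye(2), 20_000, seed=rng)
        for method in ("ols", "vm"):
            model = fit_mvar(x, 2, method=method)
            assert np.abs(model.coeffs - a).max() < 0.02

    def test_white_noise_gives_near_zero_coefficients(self, rng):
        x = rng.standard_normal((2, 10_000))
        model = fit_mvar(x, 3)
        assert np.abs(model.coeffs).max() < 0.05

    def test_insufficient_equations_raises(self):
        x = np.random.default_rng(0).standard_normal((12, 50))
        with pytest.raises(ValueError, match="insufficient equations"):
            fit_mvar(x, 13, method="ols")

    def test_vm_handles_short_paper_size_window(self, rng):
        x = rng.standard_normal((12, 128))
        model = fit_mvar(x, 13, method="vm")
        assert np.all(np.diag(model.sigma) > 0)

    def test_sigma_denominator_matches_residual_count(self, rng):
        x = rng.standard_normal((2, 500))
        model = fit_mvar(x, 2, method="ols")
        assert model.n_obs == 498


class TestOrderSelection:
    def test_recovers_true_order_two(self):
        a = np.zeros((2, 2, 2))
        a[0] = [[0.5, 0.2], [0.1, 0.4]]
        a[1] = [[-0.3, 0.0], [0.1, -0.2]]
        hits = 0
        for seed in range(10):
            x = simulate_var(a, np.eye(2), 5_000, seed=seed)
            if select_order_aic([x], p_max=6) == 2:
                hits += 1
        assert hits >= 8

    def test_white_noise_selects_minimum_order(self):
        hits = 0
        for seed in range(10):
            x = np.random.default_rng(seed).standard_normal((2, 5_000))
            if select_order_aic([x], p_max=5) == 1:
                hits += 1
        assert hits >= 8

    def test_rejects_nonpositive_pmax(self, rng):
        with pytest.raises(ValueError):
            select_order_aic([rng.standard_normal((2, 100))], p_max=0)


class TestGPDC:
    def test_decoupled_channels_have_zero_cross_flow(self):
        coeffs = np.zeros((2, 3, 3))
        coeffs[0] = np.diag([0.5, 0.3, -0.2])
        model = MVARModel(order=2, coeffs=coeffs, sigma=np.eye(3), n_obs=100)
        res = gpdc(model)
        off = ~np.eye(3, dtype=bool)
        assert np.all(res.pi_f[:, off] == 0)

    def test_column_normalization_on_random_models(self, rng):
        for _ in range(20):
            res = gpdc(random_stable_model(rng))
            colnorm = (res.pi_f ** 2).sum(axis=1)
            assert np.abs(colnorm - 1).max() < 1e-8

    def test_hand_computed_two_channel_case(self):
        # VAR(1): a11 = 0.5 and a21 = 0.5 (only off-diagonal), unit noise.
        # At f=0: |A11| = |A21| = 0.5 so |pi_21|^2 = 0.25/(0.25+0.25) = 0.5.
        coeffs = np.zeros((1, 2, 2))
        coeffs[0] = [[0.5, 0.0], [0.5, 0.0]]
        model = MVARModel(order=1, coeffs=coeffs, sigma=np.eye(2), n_obs=100)
        res = gpdc(model, freqs=np.array([0.0]))
        assert res.pi_f[0, 1, 0] ** 2 == pytest.approx(0.5, abs=1e-12)

    def test_matches_literal_oracle(self, rng):
        freqs = default_freq_grid(16)
        for _ in range(20):
            model = random_stable_model(rng)
            res = gpdc(model, freqs)
            oracle = literal_gpdc(model.coeffs, model.sigma, freqs)
            assert np.abs(res.pi_f - oracle).max() < 1e-10

    def test_zero_sigma_diagonal_rejected(self):
        coeffs = np.zeros((1, 2, 2))
        model = MVARModel.__new__(MVARModel)
        model.order, model.coeffs, model.n_obs = 1, coeffs, 10
        model.sigma = np.diag([1.0, 0.0])
        with pytest.raises(ValueError):
            gpdc(model)


class TestFrequencyAverageModes:
    def test_power_average_dominates_magnitude_average(self, rng):
        # sqrt(mean(x^2)) >= mean(x) pointwise (Jensen), both on magnitude scale
        model = random_stable_model(rng)
        mag = gpdc(model, average="magnitude").pi_avg
        power = gpdc(model, average="power").pi_avg
        assert np.all(power >= mag - 1e-12)

    def test_unknown_average_mode_rejected(self, rng):
        with pytest.raises(ValueError):
            gpdc(random_stable_model(rng), average="median")


class TestQuantifiers:
    def test_identity_matrix_has_zero_outflow(self):
        pi = np.eye(12)
        for src in ("Fz", "Cz", "Pz", "POz"):
            outflow, _ = quantifiers(pi, src)
            assert outflow == 0.0

    def test_uniform_column_sums(self):
        # pi(i, Fz) = c for all i: each region receives 3 c^2, outflow 9 c^2
        c = 0.2
        pi = np.zeros((12, 12))
        pi[:, ANALYSIS_CHANNELS.index("Fz")] = c
        outflow, to_region = quantifiers(pi, "Fz")
        assert to_region["C"] == pytest.approx(3 * c * c)
        assert outflow == pytest.approx(9 * c * c)

    def test_outflow_is_sum_over_foreign_regions(self, rng):
        pi = rng.uniform(0, 1, (12, 12))
        outflow, to_region = quantifiers(pi, "Pz")
        foreign = sum(v for r, v in to_region.items() if r != "P")
        assert outflow == pytest.approx(foreign)

    def test_unknown_source_rejected(self):
        with pytest.raises(KeyError):
            quantifiers(np.eye(12), "T7")


class TestSlidingWindows:
    def test_exactly_193_windows_per_so(self):
        starts = sliding_window_starts(512, 128, 2)
        assert len(starts) == 193

    def test_window_centers_span_pm_750_ms(self, rng):
        data = rng.standard_normal((12, 4096))
        series = so_epoch_quantifiers(data, 256.0, 2048, p=3)
        centers = series[0].window_centers
        assert len(centers) == 193
        assert centers[0] == pytest.approx(-0.75)
        assert centers[-1] == pytest.approx(0.75)

    def test_epoch_at_record_edge_rejected(self, rng):
        data = rng.standard_normal((12, 1000))
        with pytest.raises(ValueError, match="edge"):
            so_epoch_quantifiers(data, 256.0, 100, p=3)

    def test_post_trough_coupling_yields_post_peak(self):
        # coupling from Fz active only after the "trough": outflow maximum
        # must land at a positive window center
        rng = np.random.default_rng(5)
        n, fs = 12, 256.0
        total = 4096
        trough = 2048
        j = ANALYSIS_CHANNELS.index("Fz")
        base = np.zeros((1, n, n)); base[0] = np.eye(n) * 0.5
        boost = base.copy()
        for i in range(n):
            if ANALYSIS_CHANNELS[i].startswith(("P", "O")):
                boost[0, i, j] = 0.8
        x = np.zeros((n, total + 200))
        innov = rng.standard_normal((n, total + 200))
        for t in range(1, total + 200):
            a = boost if (200 + trough + 64 <= t <= 200 + trough + 192) else base
            x[:, t] = a[0] @ x[:, t - 1] + innov[:, t]
        series = so_epoch_quantifiers(x[:, 200:], fs, trough, p=3, method="vm")
        fz = next(s for s in series if s.source == "Fz")
        assert fz.window_centers[np.argmax(fz.outflow)] > 0


class TestAmplitudeInvariance:
    def test_common_scaling_leaves_gpdc_unchanged(self, rng):
        x = rng.standard_normal((4, 2_000))
        r1 = gpdc(fit_mvar(x, 3))
        r2 = gpdc(fit_mvar(100.0 * x, 3))
        assert np.abs(r1.pi_avg - r2.pi_avg).max() < 1e-6

    def test_single_channel_rescaling_barely_moves_outflow(self):
        # the noise-variance weighting is the point of GPDC over plain PDC
        rng = np.random.default_rng(9)
        x = rng.standard_normal((12, 20_000))
        base, _ = quantifiers(gpdc(fit_mvar(x, 3, method="ols")).pi_avg, "Fz")
        y = x.copy()
        y[ANALYSIS_CHANNELS.index("Fz")] *= 10
        scaled, _ = quantifiers(gpdc(fit_mvar(y, 3, method="ols")).pi_avg, "Fz")
        assert abs(scaled - base) / base < 0.05


class TestDirectionRecovery:
    def test_planted_direction_dominates_reverse(self):
        # unidirectional 2->1 coupling: flow 2->1 must exceed 1->2 by >= 5x
        a = np.zeros((1, 2, 2))
        a[0] = [[0.5, 0.5], [0.0, 0.5]]
        ratios = []
        for seed in range(50):
            x = simulate_var(a, np.eye(2), 20_000, seed=seed)
            res = gpdc(fit_mvar(x, 1, method="ols"))
            ratios.append(res.pi_avg[0, 1] / res.pi_avg[1, 0])
        assert np.median(ratios) >= 5.0


class TestNonSOWindows:
    def test_duplicate_window_is_deterministic(self, rng):
        data = rng.standard_normal((12, 2_000))
        v1 = non_so_quantifiers(data, 256.0, 1000, "Cz", p=3)
        v2 = non_so_quantifiers(data, 256.0, 1000, "Cz", p=3)
        assert v1[0] == v2[0]

    def test_window_at_edge_rejected(self, rng):
        data = rng.standard_normal((12, 500))
        with pytest.raises(ValueError):
            non_so_quantifiers(data, 256.0, 30, "Cz", p=3)

    def test_decoupled_floor_far_below_planted_coupling(self):
        # with long windows the decoupled noise floor sits >= 10x below
        # outflow under strong planted coupling
        rng = np.random.default_rng(3)
        quiet = rng.standard_normal((12, 20_000))
        floor, _ = quantifiers(gpdc(fit_mvar(quiet, 3, method="ols")).pi_avg, "Fz")
        a = np.zeros((1, 12, 12))
        a[0] = np.eye(12) * 0.5
        j = ANALYSIS_CHANNELS.index("Fz")
        for i, ch in enumerate(ANALYSIS_CHANNELS):
            if ch.startswith(("C", "P", "O")):
                a[0, i, j] = 0.4
        x = simulate_var(a, np.eye(12), 20_000, seed=4)
        strong, _ = quantifiers(gpdc(fit_mvar(x, 3, method="ols")).pi_avg, "Fz")
        assert strong / floor >= 10.0
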