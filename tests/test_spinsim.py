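"""Spin-system simulator: exact transitions and Lorentzian rendering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lfnmr.spinsim import (MAX_COUPLED_SPINS, SpinSystem, compute_transitions,
                           lorentzian, render_spectrum, simulate_mixture)
from lfnmr.types import MixtureSpec, PpmInterval, make_axis


def brute_force_transitions(shifts_ppm, J, freq_mhz):
    """Independent dense reference: product-basis Hamiltonian built by
    explicit bit arithmetic over basis states, no operator algebra shared
    with the implementation."""
    n = len(shifts_ppm)
    dim = 2 ** n
    nu = np.asarray(shifts_ppm) * freq_mhz

    def m_i(state, i):  # +1/2 for bit 0, -1/2 for bit 1
        return 0.5 if not (state >> i) & 1 else -0.5

    H = np.zeros((dim, dim))
    for s in range(dim):
        diag = sum(nu[i] * m_i(s, i) for i in range(n))
        diag += sum(J[i][j] * m_i(s, i) * m_i(s, j)
                    for i in range(n) for j in range(i + 1, n))
        H[s, s] = diag
        # flip-flop terms: J/2 (I+I- + I-I+)
        for i in range(n):
            for j in range(i + 1, n):
                if (s >> i) & 1 != (s >> j) & 1:
                    t = s ^ (1 << i) ^ (1 << j)
                    H[t, s] += J[i][j] / 2.0
    E, V = np.linalg.eigh(H)
    # lowering operator: flips one spin from up (bit 0) to down (bit 1)
    Im = np.zeros((dim, dim))
    for s in range(dim):
        for i in range(n):
            if not (s >> i) & 1:
                Im[s | (1 << i), s] = 1.0
    A = V.T @ Im @ V
    w = A ** 2 / 2 ** (n - 1)
    f_idx, i_idx = np.nonzero(w > 1e-14)
    return E[i_idx] - E[f_idx], w[f_idx, i_idx]


def spectrum_moments(freqs, intens):
    total = intens.sum()
    return total, (freqs * intens).sum() / total


class TestComputeTransitions:
    def test_single_uncoupled_spin_is_one_zeeman_line(self):
        sys = SpinSystem.from_arrays("s", [1.0], np.zeros((1, 1)))
        t = compute_transitions(sys, 80.0)
        assert len(t) == 1
        assert t.frequencies_hz[0] == pytest.approx(80.0)
        assert t.intensities[0] == pytest.approx(1.0)

    def test_weak_coupling_limit_gives_first_order_doublets(self):
        # two spins separated by 10 J: near-ideal AX pattern
        J = 7.0
        dv = 10 * J
        sys = SpinSystem.from_arrays("ax", [1.0, 1.0 + dv / 80.0],
                                     [[0, J], [J, 0]])
        t = compute_transitions(sys, 80.0)
        f = np.sort(t.frequencies_hz)
        centre_a, centre_x = 80.0, 80.0 + dv
        expected = np.sort([centre_a - J / 2, centre_a + J / 2,
                            centre_x - J / 2, centre_x + J / 2])
        # first-order positions correct within 0.1 J
        assert np.allclose(f, expected, atol=0.1 * J)
        # residual roofing follows the exact AB law: 0.5 (1 +- J/q)
        q = np.sqrt(dv ** 2 + J ** 2)
        w = t.intensities[np.argsort(t.frequencies_hz)]
        expected_w = 0.5 * np.array([1 - J / q, 1 + J / q,
                                     1 + J / q, 1 - J / q])
        assert np.allclose(w, expected_w, rtol=1e-9)

    def test_ab_quartet_matches_closed_form(self):
        # AB system at delta-nu = J: positions centre +- (sqrt(2) J +- J)/2,
        # intensity ratio inner:outer = (1 + 1/sqrt2)/(1 - 1/sqrt2)
        J = 5.0
        sys = SpinSystem.from_arrays("ab", [1.0, 1.0 + J / 80.0],
                                     [[0, J], [J, 0]])
        t = compute_transitions(sys, 80.0)
        order = np.argsort(t.frequencies_hz)
        f, w = t.frequencies_hz[order], t.intensities[order]
        centre = 80.0 + J / 2
        exp_pos = centre + np.array([-(np.sqrt(2) + 1), -(np.sqrt(2) - 1),
                                     (np.sqrt(2) - 1), (np.sqrt(2) + 1)]) * J / 2
        assert np.allclose(f, exp_pos, atol=1e-9)
        ratio = w[1] / w[0]
        expected = (1 + 1 / np.sqrt(2)) / (1 - 1 / np.sqrt(2))
        assert ratio == pytest.approx(expected, rel=1e-9)
        assert w[1] == pytest.approx(w[2], rel=1e-9)
        assert w[0] == pytest.approx(w[3], rel=1e-9)

    @settings(derandomize=True, deadline=None, max_examples=20)
    @given(st.data())
    def test_intensity_sum_equals_spin_count_for_random_couplings(self, data):
        n = data.draw(st.integers(2, 5))
        shifts = data.draw(st.lists(
            st.floats(0.5, 5.0, allow_nan=False), min_size=n, max_size=n))
        rng = np.random.default_rng(data.draw(st.integers(0, 2 ** 20)))
        J = rng.uniform(-15, 15, size=(n, n))
        J = np.triu(J, 1)
        J = J + J.T
        sys = SpinSystem.from_arrays("rand", shifts, J)
        t = compute_transitions(sys, 80.0, intensity_floor=0.0)
        assert t.total_intensity == pytest.approx(n, rel=1e-6)

    @pytest.mark.parametrize("n_spins,seed", [(2, 0), (3, 1), (3, 2)])
    def test_matches_brute_force_reference(self, n_spins, seed):
        rng = np.random.default_rng(seed)
        shifts = rng.uniform(1.0, 4.0, n_spins)
        J = rng.uniform(-12, 12, (n_spins, n_spins))
        J = np.triu(J, 1)
        J = J + J.T
        sys = SpinSystem.from_arrays("bf", shifts, J)
        t = compute_transitions(sys, 80.0, intensity_floor=0.0)
        bf_f, bf_w = brute_force_transitions(shifts, J, 80.0)
        # compare total intensity and intensity-weighted mean frequency —
        # invariant under transition-order and degenerate-merge differences
        tot_a, mean_a = spectrum_moments(t.frequencies_hz, t.intensities)
        tot_b, mean_b = spectrum_moments(bf_f, bf_w)
        assert tot_a == pytest.approx(tot_b, rel=1e-8)
        assert mean_a == pytest.approx(mean_b, rel=1e-8)
        # and the rendered spectra agree pointwise
        x = np.linspace(0, 6, 4000)[::-1]
        ya = render_spectrum(
            type(t)(t.frequencies_hz, t.intensities, n_spins, 80.0), x).intensities
        yb = render_spectrum(
            type(t)(bf_f, bf_w, n_spins, 80.0), x).intensities
        assert np.allclose(ya, yb, rtol=1e-8, atol=1e-10 * ya.max())

    def test_doubling_field_doubles_shift_separation_not_j(self):
        J = 7.0
        sys = SpinSystem.from_arrays("ax", [1.0, 2.0], [[0, J], [J, 0]])
        t80 = compute_transitions(sys, 80.0)
        t160 = compute_transitions(sys, 160.0)

        def doublet_centres_and_split(t):
            f = np.sort(t.frequencies_hz)
            return (f[:2].mean(), f[2:].mean(), f[1] - f[0])

        c80a, c80x, s80 = doublet_centres_and_split(t80)
        c160a, c160x, s160 = doublet_centres_and_split(t160)
        # doublet centres sit q = sqrt(dv^2 + J^2) apart; the underlying
        # shift separation dv doubles with the field, J does not
        dv80 = np.sqrt((c80x - c80a) ** 2 - J ** 2)
        dv160 = np.sqrt((c160x - c160a) ** 2 - J ** 2)
        assert dv160 == pytest.approx(2 * dv80, rel=1e-9)
        assert s160 == pytest.approx(s80, rel=1e-9)
        assert s80 == pytest.approx(J, rel=1e-9)

    def test_asymmetric_couplings_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            SpinSystem.from_arrays("bad", [1.0, 2.0], [[0, 5], [4, 0]])

    def test_cluster_cap_raises_capability_error(self):
        n = MAX_COUPLED_SPINS + 1
        J = np.full((n, n), 1.0)
        np.fill_diagonal(J, 0.0)
        sys = SpinSystem.from_arrays("big", [1.0] * n, J)
        with pytest.raises(ValueError, match=str(MAX_COUPLED_SPINS)):
            compute_transitions(sys, 80.0)


class TestRenderSpectrum:
    def test_lorentzian_peak_height_closed_form(self):
        # a single transition of area a and FWHM w peaks at 2a/(pi w)
        x = make_axis(2.0, 0.0, 1e-4)
        y = lorentzian(x, 1.0, 0.01, area=3.0)
        assert y.max() == pytest.approx(2 * 3.0 / (np.pi * 0.01), rel=1e-6)
        # half maximum at centre +- w/2
        idx = np.argmin(np.abs(x - 1.005))
        assert y[idx] == pytest.approx(y.max() / 2, rel=1e-3)

    def test_concentration_linearity_pointwise(self, library):
        lac = library["lactate"][0]
        t = compute_transitions(lac, 80.0)
        x = make_axis(5.0, 0.5)
        y1 = render_spectrum(t, x, concentration=1.0).intensities
        y2 = render_spectrum(t, x, concentration=2.0).intensities
        assert np.allclose(y2, 2 * y1, rtol=1e-12)

    def test_lactate_methyl_doublet_area_is_three_protons(self, library):
        # integrate the CH3 doublet over +-50 linewidths: ~3 x concentration
        lac = library["lactate"][0]
        t = compute_transitions(lac, 80.0)
        w_ppm = 1.0 / 80.0
        x = make_axis(1.33 + 50 * w_ppm, 1.33 - 50 * w_ppm, 1e-4)
        conc = 2.0
        y = render_spectrum(t, x, linewidth=1.0, concentration=conc).intensities
        area = np.trapezoid(y[::-1], x[::-1])
        assert area == pytest.approx(3 * conc, rel=0.02)


class TestSimulateMixture:
    def test_singleton_mixture_equals_single_render(self, library, axis):
        mix = MixtureSpec(species=(("citrate", 0.4),), reference_concentration=0.0)
        sim = simulate_mixture(mix, axis)
        t = compute_transitions(library["citrate"][0], 80.0)
        direct = render_spectrum(t, axis, concentration=0.4).intensities
        assert np.allclose(sim.intensities, direct, rtol=1e-9)

    def test_glucose_expands_to_36_64_anomers(self, library, axis):
        pops = sorted(s.population for s in library["glucose"])
        assert pops == [0.36, 0.64]
        assert sum(pops) == pytest.approx(1.0)
        # effective concentrations 3.6 / 6.4 mmol/L at 10 mmol/L glucose
        mix = MixtureSpec(species=(("glucose", 10.0),), reference_concentration=0.0)
        sim = simulate_mixture(mix, axis)
        total_area = sim.intensities.sum() * abs(axis[1] - axis[0])
        assert total_area == pytest.approx(7 * 10.0, rel=0.02)  # 7 protons

    def test_mixture_additivity(self, axis, mixed_sim):
        parts = np.zeros_like(axis)
        for name, conc in (("glucose", 10.0), ("lactate", 2.0),
                           ("citrate", 0.2), ("tsp", 0.1)):
            mix = MixtureSpec(species=((name, conc),), reference_concentration=0.0)
            parts += simulate_mixture(mix, axis).intensities
        assert np.allclose(mixed_sim.intensities, parts, rtol=1e-9)

    def test_components_sum_to_total(self, mixed_sim):
        total = sum(mixed_sim.components.values())
        assert np.allclose(total, mixed_sim.intensities, rtol=1e-9)

    def test_unknown_species_lists_available(self, axis):
        mix = MixtureSpec(species=(("unobtainium", 1.0),))
        with pytest.raises(KeyError, match="glucose"):
            simulate_mixture(mix, axis)
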