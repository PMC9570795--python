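"""Spectrum generation, filtration, air kerma and energy sampling."""

import numpy as np
import pytest
from scipy import stats

from kfluoro import materials as mat
from kfluoro.spectrum import (
    KERMA_UGY_PER_FLUENCE,
    Spectrum,
    SpectrumError,
    apply_filtration,
    energy_fluence,
    esak,
    generate_w_spectrum,
    load_spectrum,
    photons_for_esak,
    sample_energy,
    save_spectrum,
)


def single_bin(energy=30.0, counts=100.0):
    return Spectrum(np.array([energy]), np.array([counts]))


class TestSpectrumContainer:
    def test_single_bin_e0(self):
        assert single_bin(30.0).e0 == 30.0

    def test_rejects_negative_counts(self):
        with pytest.raises(SpectrumError):
            Spectrum(np.array([10.0, 10.5]), np.array([1.0, -1.0]))

    def test_rejects_nonuniform_grid(self):
        with pytest.raises(SpectrumError):
            Spectrum(np.array([10.0, 10.5, 11.5]), np.ones(3))

    def test_rejects_counts_above_tube_voltage(self):
        with pytest.raises(SpectrumError):
            Spectrum(np.array([39.5, 40.0, 40.5]), np.ones(3), tube_voltage=40.0)


class TestLoadSave:
    def test_round_trip_exact(self, tmp_path):
        s = generate_w_spectrum(40.0)
        path = tmp_path / "s.csv"
        save_spectrum(s, path)
        loaded = load_spectrum(path)
        np.testing.assert_array_equal(loaded.energies, s.energies)
        np.testing.assert_array_equal(loaded.counts, s.counts)

    def test_parse_error_reports_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("energy_keV,photons_per_mm2\n10.0,5\nnot-a-number,3\n")
        with pytest.raises(SpectrumError, match="line 3"):
            load_spectrum(path)

    def test_non_ascending_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("10.0,5\n9.5,3\n")
        with pytest.raises(SpectrumError, match="non-ascending"):
            load_spectrum(path)


class TestGenerateWSpectrum:
    def test_no_counts_above_tube_voltage(self):
        s = generate_w_spectrum(40.0)
        assert s.e0 <= 40.0
        assert np.all(s.counts[s.energies > 40.0] == 0)

    def test_kv_out_of_range(self):
        with pytest.raises(SpectrumError):
            generate_w_spectrum(15.0)
        with pytest.raises(SpectrumError):
            generate_w_spectrum(80.0)

    def test_deterministic_and_scalable(self):
        a = generate_w_spectrum(50.0)
        b = generate_w_spectrum(50.0)
        np.testing.assert_array_equal(a.counts, b.counts)
        np.testing.assert_allclose(a.scaled(2.0).counts, 2 * a.counts)

    def test_50kv_has_larger_above_edge_fraction(self):
        """The 50 kV filtered spectrum carries a strictly larger fluence
        fraction above the iodine K edge than the 40 kV one — the stated
        mechanism of the higher-voltage advantage."""
        al = mat.load_material("aluminum")
        gd = mat.load_material("gadolinium")
        fracs = {}
        for kv in (40.0, 50.0):
            s = generate_w_spectrum(kv, e_min=10.5)
            s = apply_filtration(s, al, 0.16)
            s = apply_filtration(s, gd, 0.03)
            above = s.energies >= mat.IODINE_K_EDGE_KEV
            fracs[kv] = s.counts[above].sum() / s.counts.sum()
        assert fracs[50.0] > fracs[40.0]


class TestFiltration:
    def test_zero_thickness_identity(self, fat):
        s = generate_w_spectrum(40.0, e_min=10.5)
        assert apply_filtration(s, fat, 0.0) is s

    def test_commutes(self):
        al = mat.load_material("aluminum")
        gd = mat.load_material("gadolinium")
        s = generate_w_spectrum(45.0, e_min=10.5)
        ab = apply_filtration(apply_filtration(s, al, 0.16), gd, 0.03)
        ba = apply_filtration(apply_filtration(s, gd, 0.03), al, 0.16)
        np.testing.assert_allclose(ab.counts, ba.counts, rtol=1e-12)

    def test_never_increases_any_bin(self):
        gd = mat.load_material("gadolinium")
        s = generate_w_spectrum(50.0, e_min=10.5)
        f = apply_filtration(s, gd, 0.03)
        assert np.all(f.counts <= s.counts)

    def test_gd_k_edge_depresses_bins_above_edge_more(self):
        """0.3 mm Gd transmits less just above its K edge (~50.24 keV) than
        just below it."""
        gd = mat.load_material("gadolinium")
        s = generate_w_spectrum(55.0, e_min=10.5)
        f = apply_filtration(s, gd, 0.03)
        trans = f.counts / s.counts
        below = trans[np.argmin(np.abs(s.energies - 49.75))]
        above = trans[np.argmin(np.abs(s.energies - 50.75))]
        assert above < below


class TestEnergyFluenceAndKerma:
    def test_empty_spectrum_zero(self):
        s = Spectrum(np.array([20.0, 20.5]), np.zeros(2))
        assert energy_fluence(s) == 0.0

    def test_single_bin_sum(self):
        assert energy_fluence(single_bin(30.0, 100.0)) == pytest.approx(3000.0)

    def test_linear_in_counts(self):
        s = generate_w_spectrum(40.0)
        assert energy_fluence(s.scaled(2.0)) == pytest.approx(
            2 * energy_fluence(s), rel=1e-12
        )

    def test_esak_zero_spectrum(self, air):
        s = Spectrum(np.array([20.0, 20.5]), np.zeros(2))
        assert esak(s, air) == 0.0

    def test_esak_monoenergetic_hand_computation(self, air):
        """One bin at a tabulated air energy reduces to a single product."""
        e, n = 30.0, 100.0
        expected = KERMA_UGY_PER_FLUENCE * n * e * air.mu_en_rho_at(e)
        assert esak(single_bin(e, n), air) == pytest.approx(expected, rel=1e-12)

    def test_esak_halves_with_counts(self, air):
        s = generate_w_spectrum(40.0, e_min=10.5)
        assert esak(s.scaled(0.5), air) == pytest.approx(0.5 * esak(s, air), rel=1e-12)

    def test_kerma_decreases_with_filter_thickness(self, air):
        al = mat.load_material("aluminum")
        s = generate_w_spectrum(40.0, e_min=10.5)
        kermas = [esak(apply_filtration(s, al, t), air) for t in (0.0, 0.1, 0.2)]
        assert kermas[0] > kermas[1] > kermas[2]


class TestPhotonsForEsak:
    def test_identity_target(self, air):
        s = generate_w_spectrum(40.0, e_min=10.5)
        current = esak(s, air)
        n, scaled = photons_for_esak(s, current, air)
        np.testing.assert_allclose(scaled.counts, s.counts, rtol=1e-12)
        assert n == int(round(s.total_counts))

    def test_budget_linear_in_target(self, air):
        s = generate_w_spectrum(40.0, e_min=10.5)
        n1, _ = photons_for_esak(s, 1000.0, air)
        n2, _ = photons_for_esak(s, 2000.0, air)
        assert n2 == pytest.approx(2 * n1, rel=1e-6)

    def test_zero_kerma_rejected(self, air):
        s = Spectrum(np.array([20.0, 20.5]), np.zeros(2))
        with pytest.raises(SpectrumError):
            photons_for_esak(s, 1000.0, air)

    def test_40kv_10mgy_budget_magnitude(self, air):
        """Filtered 40 kV spectrum normalized to 10 mGy needs a photon budget
        on the order of 1.5e8 per mm^2 (absolute scale is spectrum-model
        dependent)."""
        al = mat.load_material("aluminum")
        gd = mat.load_material("gadolinium")
        s = generate_w_spectrum(40.0, e_min=10.5)
        s = apply_filtration(apply_filtration(s, al, 0.16), gd, 0.03)
        n, scaled = photons_for_esak(s, 10_000.0, air)
        assert 5e7 < n < 5e8
        assert esak(scaled, air) == pytest.approx(10_000.0, rel=1e-9)


class TestSampleEnergy:
    def test_single_bin_always_that_energy(self, rng):
        s = single_bin(30.0, 5.0)
        draws = sample_energy(s, rng, size=1000)
        assert np.all(draws == 30.0)

    def test_two_equal_bins_split(self, rng):
        s = Spectrum(np.array([20.0, 30.0]), np.array([1.0, 1.0]))
        draws = sample_energy(s, rng, size=100_000)
        frac = np.mean(draws > 25.0)
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / 100_000)

    def test_chi_square_against_40kv_spectrum(self, rng):
        """1e6 draws from the filtered 40 kV spectrum pass a chi-square
        goodness-of-fit test at alpha = 0.01."""
        al = mat.load_material("aluminum")
        gd = mat.load_material("gadolinium")
        s = generate_w_spectrum(40.0, e_min=10.5)
        s = apply_filtration(apply_filtration(s, al, 0.16), gd, 0.03)
        n = 1_000_000
        draws = sample_energy(s, rng, size=n)
        edges = np.concatenate([
            s.energies - s.bin_width / 2, [s.energies[-1] + s.bin_width / 2]
        ])
        observed, _ = np.histogram(draws, bins=edges)
        expected = s.counts / s.counts.sum() * n
        keep = expected >= 10
        chi2, p = stats.chisquare(observed[keep], expected[keep] *
                                  observed[keep].sum() / expected[keep].sum())
        assert p > 0.01
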