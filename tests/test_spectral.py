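"""Spectral model: attenuation tables, spectra, detector weighting,
material sensitivities and their conditioning."""

import numpy as np
import pytest

from hybridct import spectral as S


@pytest.fixture(scope="module")
def grid():
    return S.EnergyGrid.default()


@pytest.fixture(scope="module")
def tables(grid):
    return S.load_attenuation_tables(
        ["water", "iodine", "barium", "calcium"], grid=grid
    )


class TestAttenuationTables:
    def test_k_edges(self, tables):
        assert tables.k_edge("iodine") == (33.2,)
        assert tables.k_edge("barium") == (37.4,)
        sep = tables.k_edge("barium")[0] - tables.k_edge("iodine")[0]
        assert sep == pytest.approx(4.2, abs=1e-9)

    def test_edge_discontinuity_sampled(self, tables):
        e, mu = tables.sampled("iodine")
        below = mu[np.argmin(np.abs(e - (33.2 - 1e-3)))]
        above = mu[np.argmin(np.abs(e - (33.2 + 1e-3)))]
        assert above / below > 4.0  # K-shell jump

    def test_positive_and_decreasing_away_from_edges(self, tables):
        for mat in ("water", "calcium"):
            mu = tables.mu_rho_on_grid(mat)
            assert np.all(mu > 0)
            assert np.all(np.diff(mu) <= 0)  # no edges in range

    def test_water_matches_reference_points(self, grid, tables):
        # standard tabulated water mass attenuation (cm^2/g)
        ref = {20.0: 0.8096, 30.0: 0.3756, 50.0: 0.2269, 80.0: 0.1837}
        mu = tables.mu_rho_on_grid("water")
        for e_ref, v_ref in ref.items():
            v = mu[np.argmin(np.abs(grid.energies - e_ref))]
            assert v == pytest.approx(v_ref, rel=0.05)

    def test_unknown_material_rejected(self, grid):
        with pytest.raises(KeyError):
            S.load_attenuation_tables(["unobtainium"], grid=grid)


class TestSourceSpectrum:
    def test_cutoff_at_kvp(self, grid):
        sp = S.build_source_spectrum(80.0, (), grid)
        assert np.all(sp.fluence[grid.energies > 80.0] == 0)
        assert sp.fluence[grid.energies < 80.0].sum() > 0

    def test_filtration_attenuates_preferentially_below_30kev(self, grid):
        bare = S.build_source_spectrum(80.0, (), grid)
        filt = S.build_source_spectrum(80.0, [("aluminum", 0.7)], grid)
        pos = bare.fluence > 0
        ratio = filt.fluence[pos] / bare.fluence[pos]
        assert np.all(ratio < 1.0)
        e = grid.energies[pos]
        assert ratio[e < 30].mean() < ratio[e > 30].mean()

    def test_mean_energy_against_direct_summation(self, grid):
        sp = S.build_source_spectrum(80.0, [("aluminum", 0.7), ("pmma", 3.0)], grid)
        # independent oracle: plain Riemann sum on the same samples
        mean_oracle = float(
            np.sum(sp.fluence * grid.energies) / np.sum(sp.fluence)
        )
        mean_trapz = grid.integrate(sp.fluence * grid.energies) / grid.integrate(
            sp.fluence
        )
        assert mean_trapz == pytest.approx(mean_oracle, rel=0.01)
        assert 30.0 < mean_trapz < 55.0  # hardened 80 kVp beam

    def test_kvp_out_of_range(self, grid):
        with pytest.raises(ValueError):
            S.build_source_spectrum(500.0, (), grid)


class TestDetectedSpectra:
    def test_eid_energy_weighting(self, grid):
        flat = S.SpectrumTable(grid, np.ones_like(grid.energies), kvp=80.0)
        resp = S.DetectorResponse("EID", grid, np.ones_like(grid.energies))
        w = S.detected_spectrum_eid(flat, resp)
        assert np.allclose(w / w[0], grid.energies / grid.energies[0])

    def test_eid_zero_spectrum(self, grid):
        zero = S.SpectrumTable(grid, np.zeros_like(grid.energies), kvp=80.0)
        resp = S.DetectorResponse.eid(grid)
        assert np.all(S.detected_spectrum_eid(zero, resp) == 0)

    def test_chain_mismatch_rejected(self, grid):
        sp = S.build_source_spectrum(80.0, (), grid)
        with pytest.raises(ValueError):
            S.detected_spectrum_eid(sp, S.DetectorResponse.pcd(grid))
        with pytest.raises(ValueError):
            S.detected_spectrum_pcd(sp, S.DetectorResponse.eid(grid), 26.0)

    def test_sharp_threshold_is_step(self, grid):
        sp = S.build_source_spectrum(80.0, (), grid)
        resp = S.DetectorResponse.pcd(grid, sigma_esf_kev=0.0)
        w = S.detected_spectrum_pcd(sp, resp, 26.0)
        below = grid.energies < 26.0
        assert np.all(w[below] == 0)
        expected = sp.fluence * resp.sensitivity
        assert np.allclose(w[~below], expected[~below])

    def test_esf_half_weight_at_threshold(self, grid):
        sp = S.SpectrumTable(grid, np.ones_like(grid.energies), kvp=80.0)
        resp = S.DetectorResponse("PCD", grid, np.ones_like(grid.energies), 3.25)
        w = S.detected_spectrum_pcd(sp, resp, 37.0)
        at = np.argmin(np.abs(grid.energies - 37.0))
        assert w[at] == pytest.approx(0.5, abs=1e-6)

    def test_esf_matches_brute_force_convolution(self, grid):
        """The closed-form Gaussian-CDF weight equals a numeric
        convolution of the rect threshold with the spread function."""
        sigma = 3.25
        t = 37.0
        g = np.linspace(-30, 30, 6001)
        gauss = np.exp(-(g**2) / (2 * sigma**2))
        gauss /= np.trapezoid(gauss, g)
        e_chk = np.array([30.0, 34.0, 37.0, 40.0, 45.0])
        for e in e_chk:
            # integrate rect_t(e - g) * G(g) over g
            rect = (e - g) >= t
            oracle = np.trapezoid(rect * gauss, g)
            sp = S.SpectrumTable(grid, np.ones_like(grid.energies), kvp=80.0)
            resp = S.DetectorResponse("PCD", grid, np.ones_like(grid.energies), sigma)
            w = S.detected_spectrum_pcd(sp, resp, t)
            idx = np.argmin(np.abs(grid.energies - e))
            assert w[idx] == pytest.approx(oracle, abs=2e-3)

    def test_negative_esf_rejected(self, grid):
        sp = S.build_source_spectrum(80.0, (), grid)
        resp = S.DetectorResponse.pcd(grid)
        with pytest.raises(ValueError):
            S.detected_spectrum_pcd(sp, resp, 26.0, sigma_esf_kev=-1.0)


class TestSensitivities:
    def test_monoenergetic_weight_recovers_pointwise_mu(self, grid, tables):
        w = np.zeros_like(grid.energies)
        idx = np.argmin(np.abs(grid.energies - 40.0))
        w[idx - 1 : idx + 2] = [0.0, 1.0, 0.0]
        msm = S.effective_sensitivity(tables, [w], ["mono"])
        mu_w40 = tables.mu_on_grid("water")[idx]
        assert msm.mu_water[0] == pytest.approx(mu_w40, rel=1e-6)
        mu_i40 = tables.mu_rho_on_grid("iodine")[idx] * 1e-4
        assert msm.m[0, 2] == pytest.approx(mu_i40, rel=1e-6)

    def test_identical_weights_identical_rows(self, grid, tables):
        sp = S.build_source_spectrum(80.0, S.PCD_FILTRATION, grid)
        resp = S.DetectorResponse.pcd(grid)
        w = S.detected_spectrum_pcd(sp, resp, 30.0)
        msm = S.effective_sensitivity(tables, [w, w.copy()], [30.0, 30.0])
        assert np.allclose(msm.m[0], msm.m[1])

    def test_zero_weight_rejected(self, grid, tables):
        with pytest.raises(ValueError):
            S.effective_sensitivity(tables, [np.zeros_like(grid.energies)], ["z"])

    def test_iodine_kedge_capture_at_34kev_threshold(self):
        """Relative to water, iodine contrast peaks in the channel whose
        threshold sits just above the 33.2 keV K edge, and barium's in
        the 37/39 keV channels (numeric averaging oracle)."""
        msm, *_ = S.default_spectral_model()
        i_rel = msm.m[:, 2] / msm.mu_water
        ba_rel = msm.m[:, 3] / msm.mu_water
        thresholds = list(msm.channels)
        assert thresholds[int(np.argmax(i_rel))] == 34.0
        assert thresholds[int(np.argmax(ba_rel))] in (37.0, 39.0)
        assert i_rel[1] > i_rel[0]

    def test_water_decomposes_to_unit_pe_cs(self):
        msm, *_ = S.default_spectral_model()
        coefs, *_ = np.linalg.lstsq(msm.m, msm.mu_water, rcond=None)
        assert np.allclose(coefs, [1.0, 1.0, 0.0, 0.0], atol=1e-8)

    def test_pe_cs_projection_change_below_3_percent(self):
        msm, *_ = S.default_spectral_model()
        assert msm.projection_rel_change < 0.03

    def test_projection_idempotent_when_in_span(self, grid, tables):
        """PE/CS columns already in span{water, calcium} are unchanged
        (up to the water rescaling)."""
        msm, *_ = S.default_spectral_model(include_eid=False)
        water = msm.mu_water
        ca = msm.calcium[:-1] if msm.calcium.size == 6 else msm.calcium
        refit = S.fit_pe_cs_basis(msm, water, ca[: len(water)])
        # second projection leaves the fitted columns fixed
        assert np.allclose(refit.m[:, 0], msm.m[:, 0], rtol=1e-8)
        assert np.allclose(refit.m[:, 1], msm.m[:, 1], rtol=1e-8)


class TestConditionNumber:
    def test_identity(self):
        assert S.condition_number(np.eye(3), normalize=False) == pytest.approx(1.0)

    def test_diagonal_unnormalized(self):
        assert S.condition_number(np.diag([2.0, 1.0]), normalize=False) == pytest.approx(2.0)

    def test_normalization_removes_column_scaling(self):
        m = np.array([[1.0, 0.0], [0.0, 5.0]])
        assert S.condition_number(m, normalize=True) == pytest.approx(1.0)

    def test_rank_deficient_is_infinite(self):
        m = np.array([[1.0, 2.0], [2.0, 4.0]])
        assert np.isinf(S.condition_number(m))
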