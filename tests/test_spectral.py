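"""Spectral module: spectra, sensing matrices, unmixing, crosstalk, QC."""

import numpy as np
import pytest

from mplexpheno import fixtures, panels, scene, spectral
from mplexpheno.errors import ConfigurationError, LibraryError, UnmixingError


def _cos(a, b):
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


class TestParametricSpectrum:
    def test_peak_position_and_unit_maximum(self):
        s = spectral.parametric_spectrum("Opal480", 480, 30)
        assert s.wavelengths_nm[np.argmax(s.intensities)] == 480
        assert s.intensities.max() == 1.0

    def test_overlapping_pair_more_similar_than_distant_pair(self):
        grid = spectral.default_grid()
        s650 = spectral.parametric_spectrum("Opal650", 650, 40, grid)
        s690 = spectral.parametric_spectrum("Opal690", 690, 40, grid)
        s570 = spectral.parametric_spectrum("Opal570", 570, 40, grid)
        assert _cos(s650.intensities, s690.intensities) > _cos(
            s570.intensities, s690.intensities
        )

    def test_narrow_fwhm_limit_approaches_indicator(self):
        s = spectral.parametric_spectrum("x", 600, 0.5)
        assert s.intensities[s.wavelengths_nm == 600] == 1.0
        off_peak = s.intensities[s.wavelengths_nm != 600]
        assert off_peak.max() < 1e-6

    def test_peak_outside_grid_rejected(self):
        with pytest.raises(ConfigurationError, match="outside grid"):
            spectral.parametric_spectrum("x", 900, 30)

    def test_nonpositive_fwhm_rejected(self):
        with pytest.raises(ConfigurationError):
            spectral.parametric_spectrum("x", 500, 0.0)


class TestSensingMatrix:
    def test_disjoint_band_fluorophore_hits_single_channel(self):
        filters = spectral.FilterSet("toy", {"A": (400, 500), "B": (600, 700)})
        lib = spectral.SpectralLibrary(
            spectra=[spectral.parametric_spectrum("f", 650, 10)],
            autofluorescence=spectral.autofluorescence_spectrum(),
        )
        A = spectral.sensing_matrix(lib, filters)
        col = A[:, 0]
        assert col[1] > 0 and col[0] < 1e-9

    def test_exposure_doubling_doubles_row(self):
        filters = spectral.standard5()
        lib = spectral.synthetic_library(["DAPI", "Opal520"])
        e1 = {c: 50.0 for c in filters.channels}
        e2 = dict(e1, Cy3=100.0)
        A1 = spectral.sensing_matrix(lib, filters, e1)
        A2 = spectral.sensing_matrix(lib, filters, e2)
        i = filters.channels.index("Cy3")
        np.testing.assert_allclose(A2[i], 2 * A1[i])
        np.testing.assert_allclose(np.delete(A2, i, 0), np.delete(A1, i, 0))

    def test_motif_columns_less_collinear_than_overlapping_standard_pair(self):
        # spectrally distant MOTiF dyes under motif-7 vs the Opal650/690
        # pairing sharing the Cy5 band under standard-5
        m7 = spectral.motif7()
        lib7 = spectral.synthetic_library(["Opal570", "Opal690"])
        A7 = spectral.sensing_matrix(lib7, m7)
        s5 = spectral.standard5()
        lib5 = spectral.synthetic_library(["Opal650", "Opal690"])
        A5 = spectral.sensing_matrix(lib5, s5)
        assert _cos(A7[:, 0], A7[:, 1]) < _cos(A5[:, 0], A5[:, 1])

    def test_rank_deficiency_recorded_as_warning(self):
        filters = spectral.FilterSet("one-band", {"A": (400, 800)})
        lib = spectral.synthetic_library(["Opal520", "Opal570"])
        spectral.sensing_matrix(lib, filters)
        assert any("rank-deficient" in w for w in lib.warnings)


@pytest.fixture(scope="module")
def mp1_setup(sparse_mp1, sparse_mp1_truth):
    cfg = sparse_mp1.config
    planes, af = scene.render_truth_planes(sparse_mp1_truth, cfg)
    img = sparse_mp1.image()
    return sparse_mp1, planes, af, img


class TestUnmix:

    def test_noiseless_recovery_matches_truth_planes(self, mp1_setup):
        fx, planes, af, img = mp1_setup
        um = spectral.unmix(img, fx.library, fx.filters)
        for marker, fluor in fx.pairing.items():
            np.testing.assert_allclose(
                um.plane(fluor), planes[marker], atol=1e-6, rtol=0
            )
        np.testing.assert_allclose(um.autofluorescence, af, atol=1e-6, rtol=0)

    def test_matches_pseudoinverse_oracle_when_solution_nonnegative(self, mp1_setup):
        fx, _, _, img = mp1_setup
        A = spectral.sensing_matrix(fx.library, fx.filters, img.exposures_ms)
        Y = img.planes.reshape(img.planes.shape[0], -1).T
        X_oracle = Y @ np.linalg.pinv(A).T
        assert X_oracle.min() > -1e-9  # nonnegative by construction
        um = spectral.unmix(img, fx.library, fx.filters)
        X = np.stack(
            [um.abundances[n].ravel() for n in fx.library.fluorophore_names]
            + [um.autofluorescence.ravel()],
            axis=1,
        )
        assert np.abs(X - np.clip(X_oracle, 0, None)).max() < 1e-6

    def test_all_zero_image_gives_zero_abundances_and_residual(self):
        lib = spectral.synthetic_library(["DAPI", "Opal520"])
        filters = spectral.standard5()
        img = scene.mix_to_channels(
            {"Opal520": np.zeros((8, 8))}, np.zeros((8, 8)), lib, filters,
            {c: 50.0 for c in filters.channels},
        )
        um = spectral.unmix(img, lib, filters)
        assert um.residual.max() == 0.0
        assert all(p.max() == 0.0 for p in um.abundances.values())

    def test_rank_deficient_matrix_raises(self):
        filters = spectral.FilterSet("one-band", {"A": (400, 800)})
        lib = spectral.synthetic_library(["Opal520", "Opal570"])
        from mplexpheno.image import MultichannelImage

        img = MultichannelImage(np.zeros((1, 4, 4)), ["A"], {"A": 50.0})
        with pytest.raises(UnmixingError, match="rank"):
            spectral.unmix(img, lib, filters)

    def test_channel_mismatch_raises(self, mp1_setup):
        fx, _, _, img = mp1_setup
        with pytest.raises(UnmixingError, match="channels"):
            spectral.unmix(img, fx.library, spectral.standard5())


@pytest.fixture(scope="module")
def singleplex_setup():
    """Zero-noise singleplex slides (flat AF) for each MP1 fluorophore."""
    pairing = panels.panel_fluorophores(panels.MP1)
    fluors = sorted(set(pairing.values()), key=list(spectral.NOMINAL_PEAKS_NM).index)
    lib = spectral.synthetic_library(fluors)
    filters = spectral.motif7()
    expos = panels.default_exposures(filters.channels)
    marker_of = {v: k for k, v in pairing.items()}

    def cfg(seed):
        return scene.SceneConfig(
            panel=panels.MP1, shape=(128, 128), n_cells=25, seed=seed,
            min_separation_px=16.0, af_texture_amplitude=0.0,
        )

    def build(noise):
        imgs = {}
        for i, fl in enumerate(fluors):
            mk = marker_of[fl]
            comp = panels.MARKER_COMPARTMENT[mk]
            profs = [
                scene.PhenotypeProfile(
                    mk, {mk: scene.MarkerLevel(comp, 23.0)}, {scene.SPARSE: 1.0}
                )
            ]
            c = cfg(50 + i)
            t = scene.simulate_scene(c, profs)
            pl, afp = scene.render_truth_planes(t, c)
            imgs[fl] = scene.mix_to_channels(
                {mk: pl[mk]}, afp, lib, filters, expos, noise, 50 + i, {mk: fl}
            )
        c = cfg(99)
        t = scene.simulate_scene(c, [scene.PhenotypeProfile("neg", {}, {scene.SPARSE: 1.0})])
        _, afp = scene.render_truth_planes(t, c)
        af_img = scene.mix_to_channels({}, afp, lib, filters, expos, noise, 99, {})
        return imgs, af_img

    return lib, filters, build


class TestLibraryFromSingleplex:
    def test_noiseless_signatures_match_true_sensing_columns(self, singleplex_setup):
        lib, filters, build = singleplex_setup
        imgs, af_img = build(0.0)
        measured = spectral.build_library_from_singleplex(imgs, af_img, filters)
        A_true = spectral.sensing_matrix(lib, filters)
        A_true = A_true / A_true.max(axis=0)  # signatures are unit-max
        A_meas = spectral.sensing_matrix(measured, filters)
        assert np.abs(A_true - A_meas).max() < 1e-6

    def test_autofluorescence_only_image_yields_af_signature(self, singleplex_setup):
        lib, filters, build = singleplex_setup
        imgs, af_img = build(0.0)
        measured = spectral.build_library_from_singleplex(imgs, af_img, filters)
        true_af = spectral.sensing_matrix(lib, filters)[:, -1]
        assert _cos(measured.signatures[spectral.AF_NAME], true_af) > 1 - 1e-9

    def test_noisy_signatures_remain_close_to_truth(self, singleplex_setup):
        lib, filters, build = singleplex_setup
        imgs, af_img = build(0.5)
        measured = spectral.build_library_from_singleplex(imgs, af_img, filters)
        A_true = spectral.sensing_matrix(lib, filters)
        for j, name in enumerate(lib.fluorophore_names):
            assert _cos(measured.signatures[name], A_true[:, j]) > 0.99

    def test_synthetic_and_measured_libraries_unmix_equally(
        self, singleplex_setup, sparse_mp1
    ):
        # a measured library built from noiseless singleplex slides must
        # reproduce the parametric library's unmixing up to its column scale
        lib, filters, build = singleplex_setup
        imgs, af_img = build(0.0)
        measured = spectral.build_library_from_singleplex(imgs, af_img, filters)
        img = sparse_mp1.image()
        um_syn = spectral.unmix(img, lib, filters)
        um_meas = spectral.unmix(img, measured, filters)
        scale = spectral.sensing_matrix(lib, filters).max(axis=0)
        for j, name in enumerate(lib.fluorophore_names):
            np.testing.assert_allclose(
                um_meas.abundances[name], um_syn.abundances[name] * scale[j],
                atol=1e-5 * scale[j], rtol=1e-6,
            )

    def test_degenerate_image_names_fluorophore(self, singleplex_setup):
        lib, filters, build = singleplex_setup
        imgs, af_img = build(0.0)
        from mplexpheno.image import MultichannelImage

        shape = imgs[next(iter(imgs))].planes.shape
        imgs["Opal520"] = MultichannelImage(
            np.zeros(shape), filters.channels, imgs[next(iter(imgs))].exposures_ms
        )
        with pytest.raises(LibraryError, match="Opal520"):
            spectral.build_library_from_singleplex(imgs, af_img, filters)


@pytest.fixture(scope="module")
def overlap():
    return fixtures.make_fixture("overlap-spectra")


class TestCrosstalk:

    def test_noiseless_crosstalk_is_identity(self, overlap):
        scenes = overlap.singleplex_scenes(
            overlap.spaced_pairing, overlap.spaced_library, seed=300, noise_sigma=0.0
        )
        ct = spectral.crosstalk_matrix(scenes, overlap.spaced_library, overlap.filters)
        np.testing.assert_allclose(ct.to_numpy(), np.eye(2), atol=1e-6)

    def test_overlapping_pairing_leaks_more_than_spaced_pairing(self, overlap):
        sc_o = overlap.singleplex_scenes(
            overlap.overlap_pairing, overlap.overlap_library, seed=301, noise_sigma=0.5
        )
        ct_o = spectral.crosstalk_matrix(sc_o, overlap.overlap_library, overlap.filters)
        sc_s = overlap.singleplex_scenes(
            overlap.spaced_pairing, overlap.spaced_library, seed=301, noise_sigma=0.5
        )
        ct_s = spectral.crosstalk_matrix(sc_s, overlap.spaced_library, overlap.filters)
        assert ct_o.loc["Opal650", "Opal690"] > ct_s.loc["Opal570", "Opal690"]

    def test_dropout_scene_row_totals_near_zero(self, overlap):
        # CD20 omitted from staining: its assigned totals sit at noise level
        stained = overlap.singleplex_scenes(
            overlap.spaced_pairing, overlap.spaced_library, seed=302, noise_sigma=0.1
        )
        blank_cfg = scene.SceneConfig(
            panel=panels.MP1, shape=(160, 160), n_cells=40, seed=303,
            min_separation_px=16.0, noise_sigma=0.1,
        )
        t = scene.simulate_scene(
            blank_cfg, [scene.PhenotypeProfile("neg", {}, {scene.SPARSE: 1.0})]
        )
        _, afp = scene.render_truth_planes(t, blank_cfg)
        dropout = scene.mix_to_channels(
            {}, afp, overlap.spaced_library, overlap.filters,
            panels.default_exposures(overlap.filters.channels), 0.1, 303, {},
        )
        scenes = dict(stained, Opal570=dropout)
        totals = spectral.crosstalk_matrix(
            scenes, overlap.spaced_library, overlap.filters, normalize=False
        )
        assert totals.loc["Opal570"].sum() < 0.01 * totals.loc["Opal690"].sum()


class TestQC:
    def test_calibrated_thickness_passes_and_thick_section_fails(self):
        fx = fixtures.make_fixture("thick-section")
        qc_thin = spectral.qc_autofluorescence(fx.thin.unmixed())
        qc_thick = spectral.qc_autofluorescence(fx.thick.unmixed())
        assert qc_thin.passed
        assert not qc_thick.passed
        assert "autofluorescence bound" in qc_thick.reason

    def test_wrong_library_trips_residual_bound(self, sparse_mp1):
        grid = spectral.default_grid()
        shifted = spectral.SpectralLibrary(
            spectra=[
                spectral.parametric_spectrum(
                    n, spectral.NOMINAL_PEAKS_NM[n] + 15, 60 if n == "DAPI" else 40, grid
                )
                for n in sparse_mp1.library.fluorophore_names
            ],
            autofluorescence=spectral.autofluorescence_spectrum(grid),
        )
        um = spectral.unmix(sparse_mp1.image(), shifted, sparse_mp1.filters)
        qc = spectral.qc_autofluorescence(um)
        assert not qc.passed
        assert "residual bound" in qc.reason
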