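import numpy as np
import pytest

from msicelltyper import synthetic_data as sd
from msicelltyper.preprocess import BinGrid, bin_spectrum


class TestPanel:
    def test_default_panel_structure(self, panel):
        assert len(panel) == 79
        mz = panel.mz
        assert np.all((mz >= 600.0) & (mz < 950.0))
        assert np.all(np.diff(mz) > 0)
        by_name = dict(panel.entries)
        assert by_name["PC 34:1"] == pytest.approx(760.585)
        assert by_name["PC 36:1"] == pytest.approx(788.610)

    def test_invalid_panels_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            sd.LipidPanel((("a", 700.0), ("a", 710.0)))
        with pytest.raises(ValueError, match="600"):
            sd.LipidPanel((("a", 599.0),))
        with pytest.raises(ValueError, match="ascending"):
            sd.LipidPanel((("a", 710.0), ("b", 700.0)))


class TestMakeProfiles:
    def test_profiles_normalized_and_subtyped(self, panel):
        profiles = sd.make_profiles(14, panel, separation=1.0, seed=1)
        assert len(profiles) == 14
        for i, p in enumerate(profiles):
            assert p.abundance.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(p.abundance >= 0)
            assert p.subtype == sd.SUBTYPES[i % 3]

    def test_zero_separation_collapses_to_base(self, panel):
        profiles = sd.make_profiles(5, panel, separation=0.0, seed=9)
        for p in profiles[1:]:
            np.testing.assert_array_equal(p.abundance, profiles[0].abundance)

    def test_seeded_determinism_bitwise(self, panel):
        a = sd.make_profiles(14, panel, separation=1.0, seed=1)
        b = sd.make_profiles(14, panel, separation=1.0, seed=1)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.abundance, pb.abundance)

    def test_noiseless_identifiability(self, panel):
        grid = BinGrid()
        profiles = sd.make_profiles(6, panel, separation=0.5, seed=2)
        vecs = [
            bin_spectrum(
                sd.synth_spectrum(p, panel, noise_cv=0.0, seed=0, background=False),
                grid,
            ).values
            for p in profiles
        ]
        for i in range(len(vecs)):
            for j in range(i + 1, len(vecs)):
                assert not np.array_equal(vecs[i], vecs[j])

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError, match="empty panel"):
            sd.make_profiles(3, sd.LipidPanel(()), seed=0)


class TestSynthSpectrum:
    def test_noiseless_proportional_to_abundance(self, panel, profiles):
        s = sd.synth_spectrum(profiles[0], panel, intensity_scale=500.0,
                              noise_cv=0.0, seed=3, background=False)
        np.testing.assert_allclose(s.intensity, 500.0 * profiles[0].abundance, rtol=1e-12)
        np.testing.assert_array_equal(s.mz, panel.mz)

    def test_noise_cv_monte_carlo(self, panel, profiles):
        # empirical CV of one lipid over 1000 draws within 20% of the nominal 0.05
        rng = np.random.default_rng(7)
        vals = np.array([
            sd.synth_spectrum(profiles[0], panel, noise_cv=0.05, rng=rng,
                              background=False).intensity[0]
            for _ in range(1000)
        ])
        cv = vals.std(ddof=1) / vals.mean()
        assert abs(cv - 0.05) < 0.2 * 0.05

    def test_background_peaks_stay_off_panel(self, panel, profiles):
        rng = np.random.default_rng(11)
        for _ in range(20):
            s = sd.synth_spectrum(profiles[1], panel, noise_cv=0.05, rng=rng)
            bg = np.setdiff1d(s.mz, panel.mz)
            assert len(bg) > 0
            dist = np.min(np.abs(bg[:, None] - panel.mz[None, :]), axis=1)
            assert np.all(dist > 0.05)

    def test_invalid_parameters_rejected(self, panel, profiles):
        with pytest.raises(ValueError, match="intensity_scale"):
            sd.synth_spectrum(profiles[0], panel, intensity_scale=0.0)
        with pytest.raises(ValueError, match="noise_cv"):
            sd.synth_spectrum(profiles[0], panel, noise_cv=-0.1)


class TestCellImage:
    def test_empty_request_gives_background_only(self, panel, profiles):
        image, gt = sd.synth_cell_image(profiles[:2], 0, panel, seed=4)
        assert gt.cell_masks == []
        assert np.all(gt.label_image == sd.BACKGROUND)
        assert image.n_pixels == image.shape[0] * image.shape[1]

    def test_masks_disjoint_and_geometry(self, panel, profiles):
        image, gt = sd.synth_cell_image(profiles[:3], 2, panel, seed=4)
        assert len(gt.cell_masks) == 6
        # pairwise disjointness, brute force
        for i in range(6):
            for j in range(i + 1, 6):
                assert not (set(gt.cell_masks[i][1]) & set(gt.cell_masks[j][1]))
        # >= 4 pixels for any cell of >= 20 µm diameter at 5 µm pixels
        for _, pix, label in gt.cell_masks:
            assert len(pix) >= 4
            for p in pix:
                assert gt.label_image[p] == label

    def test_seeded_determinism(self, panel, profiles):
        im1, gt1 = sd.synth_cell_image(profiles[:2], 2, panel, seed=8)
        im2, gt2 = sd.synth_cell_image(profiles[:2], 2, panel, seed=8)
        np.testing.assert_array_equal(gt1.label_image, gt2.label_image)
        for c in im1.coordinates()[:50]:
            np.testing.assert_array_equal(im1.spectra[c].mz, im2.spectra[c].mz)
            np.testing.assert_array_equal(im1.spectra[c].intensity, im2.spectra[c].intensity)

    def test_overflowing_request_reports_placed_count(self, panel, profiles):
        with pytest.raises(ValueError, match="placed"):
            sd.synth_cell_image(
                profiles[:2], 40, panel, diameter_range_um=(140.0, 150.0),
                seed=0, max_tries=3,
            )


class TestTissueImage:
    def test_zero_necrosis_labels_all_tumor_main(self, panel, profiles):
        image, gt = sd.synth_tissue_image(profiles[0], 0.0, panel, size=(16, 16), seed=3)
        measured = set(image.coordinates())
        for coord in measured:
            assert gt.label_image[coord] == profiles[0].label

    def test_necrotic_share_matches_request(self, small_tissue, profiles):
        _, gt = small_tissue
        n_nec = np.sum(gt.label_image == sd.NECROTIC)
        n_tumor = np.sum(gt.label_image == profiles[0].label) + n_nec
        assert abs(n_nec / n_tumor - 0.3) < 0.05

    def test_necrotic_region_contiguous(self, small_tissue):
        _, gt = small_tissue
        nec = {tuple(p) for p in np.argwhere(gt.label_image == sd.NECROTIC)}
        seen = {next(iter(nec))}
        frontier = list(seen)
        while frontier:
            r, c = frontier.pop()
            for q in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                if q in nec and q not in seen:
                    seen.add(q)
                    frontier.append(q)
        assert seen == nec

    def test_seeded_determinism(self, panel, profiles):
        im1, gt1 = sd.synth_tissue_image(profiles[1], 0.2, panel, size=(12, 12), seed=6)
        im2, gt2 = sd.synth_tissue_image(profiles[1], 0.2, panel, size=(12, 12), seed=6)
        np.testing.assert_array_equal(gt1.label_image, gt2.label_image)
        for c in im1.coordinates():
            np.testing.assert_array_equal(im1.spectra[c].intensity, im2.spectra[c].intensity)

    def test_bad_fraction_and_size_rejected(self, panel, profiles):
        with pytest.raises(ValueError, match="necrotic_fraction"):
            sd.synth_tissue_image(profiles[0], 1.5, panel)
        with pytest.raises(ValueError, match="8"):
            sd.synth_tissue_image(profiles[0], 0.1, panel, size=(4, 4))
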