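"""Segmentation, morphometry, colocalization, linescan, quartile binning."""
import numpy as np
import pytest

from chromodyn import presets, structure, synthgen


def _disk(shape, cy, cx, r):
    yy, xx = np.ogrid[0:shape[0], 0:shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2


class TestSegment:
    def test_blank_image_no_labels(self):
        nuc, cc = structure.segment(np.random.default_rng(0).normal(
            40, 2, (128, 128)))
        assert nuc.n_labels == 0 and cc.n_labels == 0

    def test_counts_match_generative_truth(self):
        p = presets.nucleus_preset("gfp_gapmer")
        for s in range(5):
            img, masks, truth = synthgen.make_nucleus_image(p, seed=s)
            nuc, cc = structure.segment(img)
            assert nuc.n_labels == 1
            assert abs(cc.n_labels - truth["n_chromocenters"]) <= 1

    def test_invariance_to_additive_offset(self):
        p = presets.nucleus_preset("gfp_gapmer")
        img, _, _ = synthgen.make_nucleus_image(p, seed=1)
        _, cc_a = structure.segment(img)
        _, cc_b = structure.segment(img + 500.0)
        assert cc_a.n_labels == cc_b.n_labels

    def test_chromocenters_nested_in_nuclei(self):
        p = presets.nucleus_preset("msr_gapmer")
        img, _, _ = synthgen.make_nucleus_image(p, seed=0)
        nuc, cc = structure.segment(img)
        assert np.all(nuc.data[cc.data > 0] > 0)

    def test_count_histogram_shift_between_presets(self):
        counts = {"gfp": [], "msr": []}
        for cond, name in (("gfp", "gfp_gapmer"), ("msr", "msr_gapmer")):
            p = presets.nucleus_preset(name)
            for s in range(12):
                img, _, _ = synthgen.make_nucleus_image(p, seed=s)
                _, cc = structure.segment(img)
                counts[cond].append(cc.n_labels)
        df, p_val = structure.chromocenter_count_histogram(counts)
        assert np.mean(counts["msr"]) > np.mean(counts["gfp"])
        assert p_val < 1e-4

    def test_degenerate_histogram(self):
        df, p_val = structure.chromocenter_count_histogram({"a": [5] * 10})
        hit = df[(df.n_chromocenters == 5)]
        assert hit.pct_nuclei.iloc[0] == 100.0
        assert np.isnan(p_val)


class TestMorphometry:
    def test_disk_geometry(self):
        lab = _disk((64, 64), 32, 32, 10).astype(np.int32)
        df = structure.morphometry(lab, pixel_size_um=1.0)
        assert df.area_px[0] == pytest.approx(np.pi * 100, abs=5)
        assert df.major_axis_um[0] == pytest.approx(20, abs=1)

    def test_ellipse_major_axis_from_moments(self):
        yy, xx = np.ogrid[0:64, 0:64]
        lab = ((((yy - 32) / 10.0) ** 2 + ((xx - 32) / 5.0) ** 2) <= 1
               ).astype(np.int32)
        df = structure.morphometry(lab)
        assert df.major_axis_um[0] == pytest.approx(20, abs=1)
        assert df.minor_axis_um[0] == pytest.approx(10, abs=1)
        assert df.major_axis_um[0] >= df.minor_axis_um[0]

    def test_sphere_mid_section_is_equator(self):
        zz, yy, xx = np.mgrid[0:21, 0:41, 0:41]
        lab = (((zz - 13) ** 2 + (yy - 20) ** 2 + (xx - 20) ** 2) <= 36
               ).astype(np.int32)
        df = structure.morphometry(lab)
        assert df.optimal_z[0] == 13
        assert df.area_px[0] == pytest.approx(np.pi * 36, abs=8)

    def test_intensity_at_foci_uniform_channel(self):
        lab = _disk((64, 64), 32, 32, 8).astype(np.int32)
        chan = np.full((64, 64), 7.5)
        df = structure.intensity_at_foci(chan, lab)
        assert df.mean_intensity[0] == pytest.approx(7.5)

    def test_intensity_identity_on_own_channel(self):
        p = presets.nucleus_preset("gfp_gapmer")
        img, _, _ = synthgen.make_nucleus_image(p, seed=2)
        _, cc = structure.segment(img)
        df = structure.morphometry(cc, intensity_channels={"dapi": img})
        direct = structure.intensity_at_foci(img, cc)
        assert np.allclose(df["mean_dapi"], direct["mean_intensity"])


class TestPearson:
    def test_affine_relation_r_one(self):
        rng = np.random.default_rng(0)
        ch1 = rng.normal(100, 20, (64, 64))
        lab = _disk((64, 64), 32, 32, 10).astype(np.int32)
        df = structure.pearson_colocalization(ch1, 2 * ch1 + 5, lab)
        assert df.pearson_r[0] == pytest.approx(1.0)
        df = structure.pearson_colocalization(ch1, -ch1, lab)
        assert df.pearson_r[0] == pytest.approx(-1.0)

    def test_matches_analytic_correlation_under_noise(self):
        rng = np.random.default_rng(1)
        lab = np.ones((100, 100), dtype=np.int32)
        ch1 = rng.normal(0, 1, (100, 100))
        sigma = 0.5
        ch2 = ch1 + rng.normal(0, sigma, (100, 100))
        rho = 1 / np.sqrt(1 + sigma ** 2)
        df = structure.pearson_colocalization(ch1, ch2, lab)
        assert df.pearson_r[0] == pytest.approx(rho, abs=0.02)

    def test_zero_variance_excluded_with_reason(self):
        lab = _disk((32, 32), 16, 16, 6).astype(np.int32)
        df = structure.pearson_colocalization(np.ones((32, 32)),
                                              np.random.default_rng(0)
                                              .normal(size=(32, 32)), lab)
        assert df.excluded[0] == "zero_variance"
        assert np.isnan(df.pearson_r[0])

    def test_invariance_to_channel_rescaling(self):
        rng = np.random.default_rng(3)
        lab = _disk((64, 64), 32, 32, 12).astype(np.int32)
        a = rng.normal(size=(64, 64))
        b = rng.normal(size=(64, 64)) + 0.5 * a
        r1 = structure.pearson_colocalization(a, b, lab).pearson_r[0]
        r2 = structure.pearson_colocalization(10 * a + 3, 0.1 * b - 7,
                                              lab).pearson_r[0]
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestLinescan:
    def test_symmetric_blob_peak_at_midpoint(self):
        yy, xx = np.mgrid[0:64, 0:64]
        img = np.exp(-((yy - 32) ** 2 + (xx - 32) ** 2) / 50.0)
        df = structure.linescan([img], (32, 8), (32, 56))
        peak = df["ch0"].idxmax()
        assert abs(df["position_um"][peak] - df["position_um"].iloc[-1] / 2) < 2
        assert df["ch0"].max() == 1.0 and df["ch0"].min() == 0.0

    def test_concentric_widths_ordered(self):
        yy, xx = np.mgrid[0:64, 0:64]
        wide = np.exp(-((yy - 32) ** 2 + (xx - 32) ** 2) / 128.0)
        narrow = np.exp(-((yy - 32) ** 2 + (xx - 32) ** 2) / 18.0)
        df = structure.linescan([wide, narrow], (32, 8), (32, 56))
        fwhm = lambda col: (df[col] >= 0.5).sum()
        assert fwhm("ch1") < fwhm("ch0")

    def test_flat_image_returns_zeros_with_warning(self):
        with pytest.warns(UserWarning):
            df = structure.linescan([np.full((32, 32), 5.0)], (10, 2), (10, 30))
        assert np.allclose(df["ch0"], 0.0)

    def test_degenerate_line_rejected(self):
        with pytest.raises(ValueError):
            structure.linescan([np.zeros((16, 16))], (4, 4), (4, 4))


class TestQuartileBin:
    def test_control_against_itself_quarters(self):
        vals = np.arange(1.0, 101.0)
        out = structure.quartile_bin(vals, vals)
        assert np.allclose(out["control_fractions"], 0.25)
        assert np.allclose(out["treatment_fractions"], 0.25)

    def test_large_shift_all_in_top_bin(self):
        rng = np.random.default_rng(0)
        c = rng.normal(0, 1, 200)
        out = structure.quartile_bin(c, c + 100)
        assert out["treatment_fractions"][3] == 1.0
        assert out["p_mannwhitney"] < 1e-10

    def test_half_sd_shift_matches_normal_theory(self):
        from scipy.stats import norm
        rng = np.random.default_rng(42)
        c = rng.normal(0, 1, 5000)
        t = rng.normal(0.5, 1, 5000)
        out = structure.quartile_bin(c, t)
        expected_top = 1 - norm.cdf(norm.ppf(0.75) - 0.5)
        assert out["treatment_fractions"][3] == pytest.approx(expected_top,
                                                              abs=0.03)
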