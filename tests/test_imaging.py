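"""Synthetic fluorescence fields and single-cell quantification."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.spatial import cKDTree

from adiposwitch import InputDomainError, ModelState, NumericalError
from adiposwitch.imaging import (CHANNEL_NAMES, SyntheticFieldSpec,
                                 find_nuclear_centroids, generate_field,
                                 grow_nucleus_mask, load_field,
                                 make_cell_mask, measure_cell, quantify_field,
                                 save_field)


@pytest.fixture(scope="module")
def field_and_truth():
    rng = np.random.default_rng(1)
    states = [ModelState(*np.abs(rng.lognormal(0.5, 0.5, 6))) for _ in range(150)]
    spec = SyntheticFieldSpec(n_cells=150, seed=4)
    channels, truth = generate_field(spec, states)
    return spec, states, channels, truth


class TestGenerateField:
    def test_empty_field_is_pure_background(self):
        spec = SyntheticFieldSpec(n_cells=0, seed=1)
        channels, truth = generate_field(spec, [])
        assert len(truth) == 0
        assert channels["pparg"].mean() == pytest.approx(spec.background, rel=0.05)

    def test_integrated_nuclear_signal_proportional_to_state(self):
        spec = SyntheticFieldSpec(n_cells=1, seed=2, background=0.0,
                                  read_noise_sd=0.0)
        v = 3.0
        channels, truth = generate_field(spec, [ModelState(1, v, 1, 0, 0, 0)])
        # blurring preserves the integral; Poisson noise averages out
        total = channels["pparg"].sum()
        r = truth["radius_px"].iloc[0]
        expect = spec.gain * v * np.pi * r ** 2
        assert total == pytest.approx(expect, rel=0.02)

    def test_identical_seed_identical_pixels(self):
        spec = SyntheticFieldSpec(n_cells=20, seed=9)
        rng = np.random.default_rng(0)
        states = [ModelState(*np.abs(rng.lognormal(0, 0.3, 6))) for _ in range(20)]
        a, _ = generate_field(spec, states)
        b, _ = generate_field(spec, states)
        for ch in CHANNEL_NAMES:
            assert np.array_equal(a[ch], b[ch])

    def test_state_count_mismatch_rejected(self):
        with pytest.raises(InputDomainError):
            generate_field(SyntheticFieldSpec(n_cells=3), [ModelState(1, 1, 1)])


class TestCentroidDetection:
    def test_blank_field_empty(self):
        rng = np.random.default_rng(0)
        img = rng.normal(100, 2, (256, 256))
        assert len(find_nuclear_centroids(img)) == 0

    def test_recall_precision_on_synthetic_field(self, field_and_truth):
        spec, _, channels, truth = field_and_truth
        cents = find_nuclear_centroids(channels["hoechst"])
        tree = cKDTree(truth[["y", "x"]].to_numpy())
        d, _ = tree.query(cents)
        precision = (d < 2.0).mean()
        tree2 = cKDTree(cents)
        d2, _ = tree2.query(truth[["y", "x"]].to_numpy())
        recall = (d2 < 2.0).mean()
        assert recall >= 0.95 and precision >= 0.95

    def test_adjacent_nuclei_merge_to_one_detection(self):
        img = np.full((128, 128), 10.0)
        for cx in (64, 65):
            img[60:70, cx - 3:cx + 3] += 500.0
        img = ndimage.gaussian_filter(img, 2.0)
        cents = find_nuclear_centroids(img, min_separation_px=8)
        assert len(cents) == 1


class TestNucleusMask:
    def test_gaussian_spot_level_set_radius(self):
        img = np.zeros((101, 101))
        img[50, 50] = 1000.0
        img = ndimage.gaussian_filter(img, 5.0)
        mask = grow_nucleus_mask(img, (50, 50), background=0.0)
        r_eq = np.sqrt(mask.sum() / np.pi)
        expect = 5.0 * np.sqrt(2 * np.log(1 / 0.3))
        assert abs(r_eq - expect) <= 1.0

    def test_mask_contains_centroid(self, field_and_truth):
        _, _, channels, truth = field_and_truth
        sm = ndimage.gaussian_filter(channels["hoechst"], 1.0)
        bg = float(np.median(sm))
        for _, row in truth.head(10).iterrows():
            mask = grow_nucleus_mask(sm, (row.y, row.x), background=bg)
            assert mask[int(round(row.y)), int(round(row.x))]

    def test_higher_cutoff_shrinks_mask(self):
        img = np.zeros((101, 101))
        img[50, 50] = 1000.0
        img = ndimage.gaussian_filter(img, 5.0)
        areas = [grow_nucleus_mask(img, (50, 50), cutoff=c, background=0.0).sum()
                 for c in (0.2, 0.3, 0.5, 0.7)]
        assert np.all(np.diff(areas) < 0)

    def test_background_centroid_rejected(self):
        img = np.full((128, 128), 50.0)
        with pytest.raises(NumericalError):
            grow_nucleus_mask(img, (64, 64), background=50.0)


class TestCellMask:
    def test_dilation_radius_from_pixel_size(self):
        nuc = np.zeros((64, 64), bool)
        nuc[32, 32] = True
        cell = make_cell_mask(nuc, pixel_size_um=1.6)  # round(7/1.6) = 4 px
        assert cell[32, 36] and not cell[32, 37]

    def test_degenerate_pixel_size_keeps_nucleus(self):
        nuc = np.zeros((64, 64), bool)
        nuc[30:35, 30:35] = True
        cell = make_cell_mask(nuc, pixel_size_um=20.0)
        assert np.array_equal(cell, nuc)

    def test_cell_mask_contains_nucleus(self, field_and_truth):
        _, _, channels, _ = field_and_truth
        sm = ndimage.gaussian_filter(channels["hoechst"], 1.0)
        cents = find_nuclear_centroids(channels["hoechst"])
        nuc = grow_nucleus_mask(sm, cents[0], background=float(np.median(sm)))
        cell = make_cell_mask(nuc)
        assert cell.sum() >= nuc.sum()
        assert not np.any(nuc & ~cell)


class TestMeasurement:
    def test_uniform_image_measures_zero(self):
        img = np.full((64, 64), 77.0)
        nuc = np.zeros((64, 64), bool)
        nuc[30:34, 30:34] = True
        cell = make_cell_mask(nuc)
        out = measure_cell({"pparg": img, "bodipy": img}, nuc, cell)
        assert out["pparg"] == 0.0 and out["bodipy"] == 0.0

    def test_ground_truth_recovery(self, field_and_truth):
        _, _, channels, truth = field_and_truth
        df = quantify_field(channels)
        tree = cKDTree(truth[["y", "x"]].to_numpy())
        d, idx = tree.query(df[["y", "x"]].to_numpy())
        m = d < 3.0
        for ch in ("pparg", "cebpb", "bodipy", "pakt"):
            r = np.corrcoef(truth.loc[idx[m], f"true_{ch}"], df.loc[m, ch])[0, 1]
            assert r >= 0.95

    def test_linear_gradient_robustness(self, field_and_truth):
        spec, states, channels, truth = field_and_truth
        import dataclasses
        spec_g = dataclasses.replace(spec, background_gradient=(0.10, 0.0))
        channels_g, _ = generate_field(spec_g, states)
        flat = quantify_field(channels).sort_values(["y", "x"])
        grad = quantify_field(channels_g).sort_values(["y", "x"])
        assert len(flat) == len(grad)
        for ch in ("pparg", "bodipy"):
            a, b = flat[ch].to_numpy(), grad[ch].to_numpy()
            ok = a > np.median(a) * 0.3
            rel = np.abs(b[ok] - a[ok]) / a[ok]
            assert np.median(rel) < 0.05

    def test_measurement_linearity(self):
        spec = SyntheticFieldSpec(n_cells=1, seed=3)
        vals = []
        for v in (2.0, 4.0):
            channels, _ = generate_field(spec, [ModelState(1, v, 1, 0, 0, 0)])
            df = quantify_field(channels)
            vals.append(df["pparg"].iloc[0])
        assert vals[1] / vals[0] == pytest.approx(2.0, abs=0.1)


def test_tiff_roundtrip(tmp_path, field_and_truth):
    _, _, channels, _ = field_and_truth
    path = tmp_path / "field.tiff"
    save_field(path, channels)
    loaded = load_field(path)
    for ch in CHANNEL_NAMES:
        assert np.allclose(loaded[ch], np.round(np.clip(channels[ch], 0, 65535)),
                           atol=1.0)
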