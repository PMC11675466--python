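"""Templates, region-curve extraction, structure tables and voxel maps."""

import numpy as np
import pytest

from mese_relaxo.acquisition import (
    MultiEchoStack,
    add_rician_noise,
    generate_phantom,
    simulate_decay,
    three_ring_phantom_spec,
)
from mese_relaxo.optimizer import OptimizerConfig
from mese_relaxo.structures import (
    extract_region_curves,
    invert_structures,
    make_ring_template,
    report,
    tomato_template,
    voxelwise_maps,
)

from conftest import RING_TRUTH


class TestTemplates:
    def test_ring_template_labels_present(self):
        lm = make_ring_template((256, 256), n_rings=3)
        assert sorted(np.unique(lm.labels)) == [0, 1, 2, 3]

    def test_template_matches_phantom_labelmap(self):
        spec = three_ring_phantom_spec(shape=(64, 64))
        _, labels = generate_phantom(spec, n_echo=3)
        lm = make_ring_template((64, 64), n_rings=3)
        np.testing.assert_array_equal(lm.labels, labels.labels)

    def test_rings_disjoint_and_nonempty(self):
        lm = make_ring_template((128, 128), n_rings=3, equal_area=True)
        sizes = [int((lm.labels == k).sum()) for k in (1, 2, 3)]
        assert all(s > 0 for s in sizes)
        # equal-area layout: ring areas within a few % of each other
        assert max(sizes) / min(sizes) < 1.1

    def test_tomato_template_has_six_structures(self):
        lm = tomato_template((128, 128))
        assert set(lm.region_labels()) == {1, 2, 3, 4, 5, 6}
        assert lm.name(2) == "endocarp"


class TestExtractRegionCurves:
    def test_noiseless_ring_curve_equals_generating_decay(self, phantom_small):
        stack, labels = phantom_small
        curves = extract_region_curves(stack, labels)
        for label, (a, t2) in RING_TRUTH.items():
            expected = simulate_decay([(a, t2)], stack.te_grid)
            np.testing.assert_allclose(curves[label].y, expected, rtol=1e-12)

    def test_equal_area_foreground_mean_is_mixture(self, phantom_equal_area_61):
        # the foreground mean of the equal-area phantom is (up to pixelation
        # of the ring areas) the equal-amplitude three-component mixture
        stack, labels = phantom_equal_area_61
        fg = labels.labels > 0
        foreground_mean = stack.data[fg, :].mean(axis=0)
        oracle = np.mean(
            [simulate_decay([RING_TRUTH[k]], stack.te_grid) for k in (1, 2, 3)], axis=0
        )
        np.testing.assert_allclose(foreground_mean, oracle, rtol=0.03)
        # and exactly the size-weighted mixture of the generating decays
        sizes = np.array([(labels.labels == k).sum() for k in (1, 2, 3)], dtype=float)
        weighted = sum(
            w * simulate_decay([RING_TRUTH[k]], stack.te_grid)
            for w, k in zip(sizes / sizes.sum(), (1, 2, 3))
        )
        np.testing.assert_allclose(foreground_mean, weighted, rtol=1e-12)

    def test_single_voxel_region_verbatim(self, rng):
        data = rng.uniform(1, 10, (4, 4, 6))
        stack = MultiEchoStack(data, np.arange(1, 7) * 30.0)
        labels = np.zeros((4, 4), dtype=np.int32)
        labels[2, 3] = 1
        from mese_relaxo.acquisition import LabelMap

        curves = extract_region_curves(stack, LabelMap(labels))
        np.testing.assert_array_equal(curves[1].y, data[2, 3, :])

    def test_bias_correction_recovers_decayed_signal(self, phantom_small):
        # with known sigma the Rayleigh-corrected second moment removes the
        # magnitude floor that a plain mean carries at late echoes
        stack, labels = phantom_small
        noisy = add_rician_noise(stack, 10.0, seed=13)
        corrected = extract_region_curves(noisy, labels, bias_correction=True)
        plain = extract_region_curves(noisy, labels, bias_correction=False)
        truth = simulate_decay([RING_TRUTH[1]], stack.te_grid)
        tail = slice(30, None)  # echoes where the inner ring has decayed to ~0
        err_corr = np.abs(corrected[1].y[tail] - truth[tail]).mean()
        err_plain = np.abs(plain[1].y[tail] - truth[tail]).mean()
        assert err_corr < err_plain

    def test_region_sigma_is_standard_error(self, noisy_phantom_small):
        noisy, labels = noisy_phantom_small
        curves = extract_region_curves(noisy, labels)
        n1 = int((labels.labels == 1).sum())
        assert curves[1].sigma == pytest.approx(10.0 / np.sqrt(n1))


class TestInvertStructures:
    def test_noiseless_rings_recover_printed_t2s(self, phantom_small):
        stack, labels = phantom_small
        curves = extract_region_curves(stack, labels)
        table = invert_structures(
            curves, config=OptimizerConfig(seed=0), es=(1,), names=labels.names
        )
        df = table.to_frame().set_index("label")
        for label, (a, t2) in RING_TRUTH.items():
            assert df.loc[label, "T2_ms"] == pytest.approx(t2, rel=1e-3)
            assert df.loc[label, "A_T2"] == pytest.approx(a, rel=1e-3)

    def test_table_schema_one_row_per_label_and_e(self, phantom_small):
        stack, labels = phantom_small
        curves = extract_region_curves(stack, labels)
        cfg = OptimizerConfig(seed=0, n_particles=20, max_iter=60, n_restarts=1)
        table = invert_structures(curves, config=cfg, es=(1, 3), names=labels.names)
        df = table.to_frame()
        assert len(df) == 6  # 3 labels x 2 component counts
        assert set(df["e"]) == {1, 3}
        assert set(df["label"]) == {1, 2, 3}

    def test_exclusion_never_lowers_r2_on_corrupted_curves(self, phantom_small, rng):
        stack, labels = phantom_small
        noisy = add_rician_noise(stack, 4.0, seed=2)
        curves = extract_region_curves(noisy, labels)
        # corrupt one early echo per curve
        from mese_relaxo.relaxometry import DecayCurve

        corrupted = {}
        for k, c in curves.items():
            y = c.y.copy()
            y[5] *= 6.0
            corrupted[k] = DecayCurve(c.te, y, sigma=c.sigma)
        cfg = OptimizerConfig(seed=0, n_particles=30, max_iter=150, n_restarts=2)
        table = invert_structures(corrupted, config=cfg, es=(1,))
        df = table.to_frame()
        assert np.all(df["r2_exp"] >= df["r2_raw"] - 1e-12)
        assert np.all(df["n_excluded"] >= 1)


class TestVoxelwiseMaps:
    def test_noiseless_maps_piecewise_constant(self, phantom_small):
        stack, labels = phantom_small
        mask = labels.labels > 0
        maps = voxelwise_maps(
            stack, mask, e=1, config=OptimizerConfig.light(seed=0), stride=8
        )
        t2_map = maps.t2_ms[:, :, 0]
        a_map = maps.amplitude[:, :, 0]
        for label, (a, t2) in RING_TRUTH.items():
            sel = (labels.labels == label) & ~np.isnan(t2_map)
            if sel.sum() == 0:
                continue
            np.testing.assert_allclose(t2_map[sel], t2, rtol=5e-3)
            np.testing.assert_allclose(a_map[sel], a, rtol=5e-3)

    def test_masked_out_voxels_never_evaluated(self, phantom_small):
        stack, labels = phantom_small
        mask = labels.labels == 1
        maps = voxelwise_maps(
            stack, mask, e=1, config=OptimizerConfig.light(seed=0), stride=4
        )
        sel = np.zeros_like(mask)
        sel[::4, ::4] = True
        expected_count = int((sel & mask).sum())
        assert maps.n_fitted + maps.n_failed == expected_count
        assert np.all(np.isnan(maps.t2_ms[~mask, 0]))


class TestReport:
    def test_structure_report_roundtrip(self, phantom_small, tmp_path):
        import pandas as pd

        stack, labels = phantom_small
        curves = extract_region_curves(stack, labels)
        cfg = OptimizerConfig(seed=0, n_particles=20, max_iter=60, n_restarts=1)
        table = invert_structures(curves, config=cfg, es=(1, 3), names=labels.names)
        written = report(table, tmp_path)
        df = pd.read_csv(written["csv"])
        assert len(df) == 3 * 2
        # tri rows: proportions sum to one
        tri = df[df["e"] == 3]
        totals = tri[["p_T21", "p_T22", "p_T23"]].sum(axis=1)
        np.testing.assert_allclose(totals, 1.0, atol=1e-9)
        # CSV roundtrip preserves the fitted values
        orig = table.to_frame()
        np.testing.assert_allclose(df["r2_exp"], orig["r2_exp"], rtol=1e-12)

    def test_map_report_writes_tiffs(self, phantom_small, tmp_path):
        stack, labels = phantom_small
        maps = voxelwise_maps(
            stack, labels.labels == 1, e=1, config=OptimizerConfig.light(seed=0), stride=16
        )
        written = report(maps, tmp_path, make_figures=False)
        import tifffile

        arr = tifffile.imread(written["t2_map"])
        assert arr.shape[:2] == (64, 64)
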