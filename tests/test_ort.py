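"""Ordinal-trends CVA: decomposition, AIC selection, permutation, bootstrap."""

import numpy as np
import pandas as pd
import pytest

from betapet import ort
from betapet.roi import ScanVolume
from conftest import ort_phantom


def paired_design(n_subj):
    return np.tile([-1.0, 1.0], n_subj)


class TestBuildMatrix:
    def test_rows_columns_and_order(self):
        scans, _ = ort_phantom(n_subj=9)
        mask = np.ones((16, 16, 16), dtype=bool)
        m = ort.build_ort_matrix(scans, mask)
        assert m.data.shape == (18, 16**3)
        assert m.row_meta["condition"].tolist() == ["F1", "F3"] * 9
        assert list(m.design[:4]) == [-1.0, 1.0, -1.0, 1.0]

    def test_voxel_index_round_trips(self):
        scans, _ = ort_phantom(n_subj=2)
        mask = np.zeros((16, 16, 16), dtype=bool)
        mask[2:9, 3:8, 1:14] = True
        m = ort.build_ort_matrix(scans, mask)
        assert m.data.shape[1] == mask.sum()
        cols = m.coords_to_columns(m.voxel_index)
        assert np.array_equal(cols, np.arange(m.data.shape[1]))

    def test_missing_condition_names_subject(self):
        scans, _ = ort_phantom(n_subj=2)
        with pytest.raises(ValueError, match="S01"):
            ort.build_ort_matrix(scans[:-1], np.ones((16, 16, 16), dtype=bool))


class TestPca:
    def test_rank_one_matrix_recovers_direction(self):
        u = np.array([1.0, -1.0, 2.0, 0.5])
        v = np.array([3.0, 0.0, 4.0]) / 5.0
        data = 2.0 + np.outer(u, v)
        pcs = ort.pca_decompose(data)
        assert pcs.components.shape[0] == 1
        assert np.allclose(np.abs(pcs.components[0]), np.abs(v))
        # expressions proportional to the centered left factor
        e = pcs.expressions[:, 0]
        uc = u - u.mean()
        assert np.allclose(np.abs(e / np.linalg.norm(e)), np.abs(uc / np.linalg.norm(uc)))

    def test_reconstruction_from_all_components(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(6, 40))
        pcs = ort.pca_decompose(data)
        recon = pcs.expressions @ pcs.components + pcs.column_mean
        assert np.allclose(recon, data, atol=1e-8)
        gram = pcs.components @ pcs.components.T
        assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-10)

    def test_expression_variance_matches_singular_values(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(8, 30))
        pcs = ort.pca_decompose(data)
        var = pcs.expressions.var(axis=0, ddof=1)
        assert np.allclose(var, pcs.singular_values**2 / (8 - 1))

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="rank 0"):
            ort.pca_decompose(np.full((4, 10), 3.0))


class TestAicSelection:
    def test_aic_arithmetic(self):
        # n = 4, RSS = 4, k = 1 -> AIC = 4 ln(1) + 2*2 = 4
        n, rss, k = 4, 4.0, 1
        assert n * np.log(rss / n) + 2 * (k + 1) == pytest.approx(4.0)

    def test_collinear_singleton_selected(self):
        rng = np.random.default_rng(2)
        design = paired_design(5)
        # component 2's expressions equal the design exactly
        E = rng.normal(size=(10, 4))
        E[:, 2] = design
        pcs = ort.PcSet(
            components=np.eye(4, 50),
            expressions=E,
            singular_values=np.array([4.0, 3.0, 2.0, 1.0]),
            explained_variance=np.full(4, 0.25),
            column_mean=np.zeros(50),
        )
        pattern = ort.select_pattern_aic(pcs, design, k_max=4)
        assert pattern.selected_pc_indices == [2]

    def test_tie_breaks_prefer_smaller_sets(self):
        sets = ort._candidate_sets(rank=5, k_max=3)
        assert sets == [(0,), (1,), (2,), (0, 1), (0, 1, 2)]

    def test_pattern_weights_unit_norm_and_majority_increasing(self):
        scans, _ = ort_phantom(n_subj=6, seed=3)
        m = ort.build_ort_matrix(scans, np.ones((16, 16, 16), dtype=bool))
        pcs = ort.pca_decompose(m.data)
        pattern = ort.select_pattern_aic(pcs, m.design)
        assert np.linalg.norm(pattern.weights) == pytest.approx(1.0)
        expr = pcs.expressions[:, pattern.selected_pc_indices] @ pattern.coef
        deltas = expr[1::2] - expr[0::2]
        assert (deltas > 0).sum() >= 3


class TestPermutation:
    def test_p_value_bounds(self):
        scans, _ = ort_phantom(n_subj=5, delta=0.0, sigma=0.05, seed=4)
        m = ort.build_ort_matrix(scans, np.ones((16, 16, 16), dtype=bool))
        obs, p, _ = ort.ordinal_trend_permutation(m, n_perm=50, seed=0)
        assert 1.0 / 51.0 <= p <= 1.0

    def test_strong_trend_has_small_p(self):
        scans, _ = ort_phantom(n_subj=9, delta=0.10, seed=5)
        m = ort.build_ort_matrix(scans, np.ones((16, 16, 16), dtype=bool))
        obs, p, _ = ort.ordinal_trend_permutation(m, n_perm=200, seed=1)
        assert obs == 9
        assert p < 0.05

    def test_same_seed_reproducible(self):
        scans, _ = ort_phantom(n_subj=6, seed=6)
        m = ort.build_ort_matrix(scans, np.ones((16, 16, 16), dtype=bool))
        r1 = ort.ordinal_trend_permutation(m, n_perm=100, seed=9)
        r2 = ort.ordinal_trend_permutation(m, n_perm=100, seed=9)
        assert r1[:2] == r2[:2]

    def test_fixed_pattern_mode_runs(self):
        scans, _ = ort_phantom(n_subj=6, seed=7)
        m = ort.build_ort_matrix(scans, np.ones((16, 16, 16), dtype=bool))
        _, p, _ = ort.ordinal_trend_permutation(m, n_perm=100, seed=2, mode="fixed_pattern")
        assert 0.0 < p <= 1.0

    def test_bad_inputs_rejected(self):
        scans, _ = ort_phantom(n_subj=4, seed=8)
        m = ort.build_ort_matrix(scans, np.ones((16, 16, 16), dtype=bool))
        with pytest.raises(ValueError):
            ort.ordinal_trend_permutation(m, n_perm=0)
        with pytest.raises(ValueError):
            ort.ordinal_trend_permutation(m, n_perm=10, mode="bogus")


class TestBootstrap:
    def test_same_seed_identical_z(self):
        scans, _ = ort_phantom(n_subj=6, seed=9)
        m = ort.build_ort_matrix(scans, np.ones((16, 16, 16), dtype=bool))
        pcs = ort.pca_decompose(m.data)
        pattern = ort.select_pattern_aic(pcs, m.design)
        z1, s1 = ort.bootstrap_voxel_weights(m, pattern, n_boot=50, seed=11)
        z2, s2 = ort.bootstrap_voxel_weights(m, pattern, n_boot=50, seed=11)
        assert np.array_equal(z1, z2) and np.array_equal(s1, s2)

    def test_noise_free_block_fully_significant(self):
        scans, block = ort_phantom(n_subj=6, sigma=0.0, delta=0.1, seed=10)
        mask = np.ones((16, 16, 16), dtype=bool)
        m = ort.build_ort_matrix(scans, mask)
        pcs = ort.pca_decompose(m.data)
        pattern = ort.select_pattern_aic(pcs, m.design)
        z, sig = ort.bootstrap_voxel_weights(m, pattern, n_boot=30, seed=12)
        inblock = block.ravel()
        assert sig[inblock].all()
        assert not sig[~inblock].any()
        assert (pattern.weights[inblock] > 0).all()


class TestExpressionChange:
    def test_identical_conditions_give_zero_change(self):
        rng = np.random.default_rng(13)
        grid = (6, 6, 6)
        scans = []
        for i in range(4):
            vol = 1.0 + rng.normal(0, 0.05, grid)
            scans.append(ScanVolume(f"S{i}", "F1", vol, normalized=True))
            scans.append(ScanVolume(f"S{i}", "F3", vol.copy(), normalized=True))
        mask = np.ones(grid, dtype=bool)
        m = ort.build_ort_matrix(scans, mask)
        pattern = ort.Pattern(
            selected_pc_indices=[0],
            weights=np.full(m.data.shape[1], 1.0 / np.sqrt(m.data.shape[1])),
            aic_trace={},
            sign_flipped=False,
        )
        delta, summary = ort.expression_change(pattern, m)
        assert np.allclose(delta["delta_expression"], 0.0, atol=1e-12)

    def test_z_scoring_and_group_summary(self):
        scans, _ = ort_phantom(n_subj=8, seed=14)
        mask = np.ones((16, 16, 16), dtype=bool)
        m = ort.build_ort_matrix(scans, mask)
        pcs = ort.pca_decompose(m.data)
        pattern = ort.select_pattern_aic(pcs, m.design)
        labels = {f"S{i:02d}": ("CON" if i < 4 else "LS") for i in range(8)}
        delta, summary = ort.expression_change(pattern, m, labels=labels)
        raw = m.data @ pattern.weights
        z = (raw - raw.mean()) / raw.std()
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std() == pytest.approx(1.0)
        assert set(summary["groups"]) == {"CON", "LS"}
        # planted increase in every subject: all deltas positive
        assert summary["fraction_increasing"] == 1.0

    def test_mismatched_pattern_rejected(self):
        scans, _ = ort_phantom(n_subj=3, seed=15)
        m = ort.build_ort_matrix(scans, np.ones((16, 16, 16), dtype=bool))
        bad = ort.Pattern([0], np.ones(10), {}, False)
        with pytest.raises(ValueError, match="voxel index"):
            ort.expression_change(bad, m)


def test_flipping_all_conditions_flips_expression_changes():
    scans, _ = ort_phantom(n_subj=6, seed=16)
    flipped = [
        ScanVolume(s.subject_id, {"F1": "F3", "F3": "F1"}[s.session], s.voxels,
                   normalized=True)
        for s in scans
    ]
    mask = np.ones((16, 16, 16), dtype=bool)
    m1 = ort.build_ort_matrix(scans, mask)
    m2 = ort.build_ort_matrix(flipped, mask)
    pcs1 = ort.pca_decompose(m1.data)
    pattern = ort.select_pattern_aic(pcs1, m1.design)
    d1, _ = ort.expression_change(pattern, m1)
    d2, _ = ort.expression_change(pattern, m2)
    merged = d1.merge(d2, on="subject", suffixes=("_a", "_b"))
    assert np.allclose(merged["delta_expression_a"], -merged["delta_expression_b"])
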