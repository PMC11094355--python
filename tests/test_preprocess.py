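"""SNV/MSC scatter correction, SPA/CARS band selection, PCA, Welch masks."""

import numpy as np
import pytest

from seedvigor.preprocess import (
    MscTransformer,
    PcaModel,
    SpectrumMatrix,
    band_significance_mask,
    cars_retention_schedule,
    cars_select,
    msc,
    pca_reduce,
    snv,
    spa_select,
)


def _mat(X, labels=None, wl=None):
    X = np.asarray(X, dtype=float)
    if labels is None:
        labels = np.array(["HV"] * X.shape[0])
    if wl is None:
        wl = np.linspace(400, 1000, X.shape[1])
    return SpectrumMatrix(X, labels, wl)


@pytest.fixture
def affine_family():
    """Rows that are random affine maps of one smooth base curve."""
    rng = np.random.default_rng(0)
    t = np.linspace(0, 1, 50)
    base = 0.4 + 0.3 * np.sin(2 * np.pi * t) + 0.2 * t
    rows = [rng.uniform(0.5, 2.0) * base + rng.uniform(-0.3, 0.3) for _ in range(12)]
    return _mat(np.stack(rows)), base


class TestSnv:
    def test_rows_standardized(self):
        rng = np.random.default_rng(1)
        out = snv(_mat(rng.random((6, 40))))
        np.testing.assert_allclose(out.X.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.X.std(axis=1, ddof=1), 1.0, atol=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        s = rng.random(30)
        out1 = snv(_mat(s[None, :]))
        out2 = snv(_mat((5.0 + 2.5 * s)[None, :]))
        np.testing.assert_allclose(out1.X, out2.X, atol=1e-12)

    def test_idempotent_on_standardized_rows(self):
        rng = np.random.default_rng(3)
        once = snv(_mat(rng.random((4, 25))))
        twice = snv(once)
        np.testing.assert_allclose(once.X, twice.X, atol=1e-12)

    def test_constant_row_names_offender(self):
        X = np.vstack([np.linspace(0, 1, 10), np.full(10, 0.5)])
        with pytest.raises(ValueError, match=r"\[1\]"):
            snv(_mat(X))

    def test_shape_preserved(self):
        out = snv(_mat(np.random.default_rng(4).random((7, 33))))
        assert out.X.shape == (7, 33)


class TestMsc:
    def test_reference_row_unchanged(self, affine_family):
        mat, base = affine_family
        out = msc(mat, reference=base)
        # a row equal to the reference maps to itself
        mat2 = _mat(np.vstack([base, mat.X]))
        out2 = msc(mat2, reference=base)
        np.testing.assert_allclose(out2.X[0], base, atol=1e-10)

    def test_exact_affine_map_recovers_reference(self):
        t = np.linspace(0, 1, 40)
        ref = 0.3 + 0.5 * np.sin(3 * t) ** 2
        row = 2.0 + 3.0 * ref
        out = msc(_mat(row[None, :]), reference=ref)
        np.testing.assert_allclose(out.X[0], ref, atol=1e-12)

    def test_affine_family_collapses(self, affine_family):
        mat, _ = affine_family
        out = msc(mat)
        spread = out.X.max(axis=0) - out.X.min(axis=0)
        assert spread.max() < 1e-10

    def test_fitted_reference_reusable_on_new_data(self, affine_family):
        mat, base = affine_family
        tr = MscTransformer().fit(mat)
        new = _mat((1.7 * base - 0.2)[None, :])
        out = tr.apply(new)
        # collapses onto the same reference as the training rows
        np.testing.assert_allclose(out.X[0], tr.apply(mat).X[0], atol=1e-10)

    def test_degenerate_slope_raises(self):
        ref = np.linspace(0, 1, 20)
        flat = np.full(20, 0.5)  # zero covariance with the reference
        with pytest.raises(ValueError, match="degenerate"):
            msc(_mat(flat[None, :]), reference=ref)

    def test_persistence_round_trip(self, tmp_path, affine_family):
        mat, _ = affine_family
        tr = MscTransformer().fit(mat)
        tr.to_json(tmp_path / "msc.json")
        tr2 = MscTransformer.from_json(tmp_path / "msc.json")
        np.testing.assert_allclose(tr.reference, tr2.reference)


def _brute_force_spa_step(X, selected):
    """Residual norm of every candidate after projecting out the selected span."""
    S = X[:, selected]
    proj = S @ np.linalg.pinv(S)
    residual = X - proj @ X
    norms = np.linalg.norm(residual, axis=0)
    norms[selected] = -1
    return norms


class TestSpa:
    def test_k1_is_max_column_norm(self):
        rng = np.random.default_rng(5)
        X = rng.random((10, 8))
        sel = spa_select(_mat(X), k=1)
        assert sel.indices[0] == np.argmax(np.linalg.norm(X, axis=0))

    def test_second_pick_matches_brute_force(self):
        rng = np.random.default_rng(6)
        X = rng.random((12, 5))
        sel = spa_select(_mat(X), k=2)
        order = sel.diagnostics["order"]
        norms = _brute_force_spa_step(X, [order[0]])
        assert order[1] == int(np.argmax(norms))

    def test_full_greedy_path_matches_brute_force(self):
        rng = np.random.default_rng(7)
        X = rng.random((15, 6))
        sel = spa_select(_mat(X), k=4)
        order = sel.diagnostics["order"]
        for j in range(1, 4):
            norms = _brute_force_spa_step(X, order[:j])
            assert order[j] == int(np.argmax(norms))

    def test_duplicated_band_never_selected_twice(self):
        rng = np.random.default_rng(8)
        X = rng.random((10, 5))
        X[:, 3] = X[:, 1]  # exact twin
        sel = spa_select(_mat(X), k=4)
        assert not {1, 3} <= set(sel.indices)

    def test_nested_selections(self):
        rng = np.random.default_rng(9)
        X = rng.random((20, 12))
        big = spa_select(_mat(X), k=6).diagnostics["order"]
        small = spa_select(_mat(X), k=3).diagnostics["order"]
        assert big[:3] == small

    def test_rank_error(self):
        X = np.ones((4, 5))  # rank 1
        with pytest.raises(ValueError):
            spa_select(_mat(X), k=3)


class TestCars:
    def test_retention_schedule_closed_form(self):
        p, runs = 360, 50
        sched = cars_retention_schedule(p, runs)
        a = (p / 2.0) ** (1.0 / (runs - 1))
        kcoef = np.log(p / 2.0) / (runs - 1)
        expected = np.clip(
            np.round(p * a * np.exp(-kcoef * np.arange(1, runs + 1))), 2, p
        ).astype(int)
        np.testing.assert_array_equal(sched, expected)
        assert sched[0] == p  # run 1 keeps everything
        assert sched[-1] == 2  # final run keeps two bands

    def test_planted_informative_bands_retained(self):
        """Labels driven by 5 bands: CARS keeps them in >= 80% of repeats."""
        planted = [3, 11, 19, 27, 35]
        hits = 0
        n_rep = 20
        for rep in range(n_rep):
            rng = np.random.default_rng(100 + rep)
            X = rng.normal(0.5, 0.1, size=(60, 40))
            signal = X[:, planted].sum(axis=1)
            labels = np.where(signal > np.median(signal), "HV", "NV")
            mat = SpectrumMatrix(X, labels, np.linspace(400, 1000, 40))
            sel = cars_select(mat, runs=25, cv_folds=5, rng_seed=rep)
            if np.mean([b in sel.indices for b in planted]) >= 0.6:
                hits += 1
        assert hits / n_rep >= 0.8

    def test_two_runs_contract(self):
        rng = np.random.default_rng(10)
        X = rng.random((30, 20))
        labels = np.array(["HV"] * 15 + ["NV"] * 15)
        sel = cars_select(_mat(X, labels), runs=2, cv_folds=3, rng_seed=0)
        assert sel.indices.size >= 1
        assert np.all((sel.indices >= 0) & (sel.indices < 20))

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(11)
        X = rng.random((40, 25))
        labels = np.array(["HV", "MV", "LV", "NV"] * 10)
        mat = _mat(X, labels)
        a = cars_select(mat, runs=10, cv_folds=4, rng_seed=5)
        b = cars_select(mat, runs=10, cv_folds=4, rng_seed=5)
        np.testing.assert_array_equal(a.indices, b.indices)

    def test_fold_error(self):
        X = np.random.default_rng(12).random((3, 10))
        labels = np.array(["HV", "NV", "HV"])
        with pytest.raises(ValueError):
            cars_select(_mat(X, labels), runs=5, cv_folds=5)


class TestPcaReduce:
    def test_exact_low_rank_reconstruction(self):
        rng = np.random.default_rng(13)
        basis = rng.random((5, 30))
        crops = [
            (rng.random((8, 8, 5)) @ basis).reshape(8, 8, 30) for _ in range(4)
        ]
        reduced, model = pca_reduce(crops, k=5)
        recon = (
            reduced[0].reshape(-1, 5) @ model.components + model.mean
        ).reshape(8, 8, 30)
        np.testing.assert_allclose(recon, crops[0], atol=1e-8)

    def test_output_shape_46x46x5(self):
        rng = np.random.default_rng(14)
        crops = [rng.random((46, 46, 60)) for _ in range(3)]
        reduced, model = pca_reduce(crops, k=5)
        assert all(r.shape == (46, 46, 5) for r in reduced)

    def test_explained_variance_ratios_non_increasing(self):
        rng = np.random.default_rng(15)
        crops = [rng.random((6, 6, 20)) for _ in range(3)]
        _, model = pca_reduce(crops, k=5)
        assert np.all(np.diff(model.explained_variance_ratio) <= 1e-12)
        assert model.explained_variance_ratio.sum() <= 1.0 + 1e-9

    def test_model_reused_on_heldout_crops(self):
        rng = np.random.default_rng(16)
        train = [rng.random((6, 6, 20)) for _ in range(3)]
        test = [rng.random((6, 6, 20))]
        _, model = pca_reduce(train, k=4)
        red_a, model_b = pca_reduce(test, k=4, model=model)
        assert model_b is model
        np.testing.assert_allclose(red_a[0], model.transform_crop(test[0]))

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(17)
        crops = [rng.random((6, 6, 15)) for _ in range(2)]
        _, model = pca_reduce(crops, k=4)
        np.testing.assert_allclose(
            model.components @ model.components.T, np.eye(4), atol=1e-10
        )

    def test_persistence_round_trip(self, tmp_path):
        rng = np.random.default_rng(18)
        crops = [rng.random((5, 5, 12)) for _ in range(2)]
        _, model = pca_reduce(crops, k=3)
        model.to_json(tmp_path / "pca.json")
        model2 = PcaModel.from_json(tmp_path / "pca.json")
        np.testing.assert_allclose(model.components, model2.components)

    def test_k_exceeding_bands_raises(self):
        with pytest.raises(ValueError):
            pca_reduce([np.zeros((4, 4, 3))], k=5)


class TestBandSignificance:
    def test_identical_groups_all_nonsignificant(self):
        rng = np.random.default_rng(19)
        A = rng.normal(0.5, 0.1, (10, 30))
        mask = band_significance_mask(A, A.copy())
        assert mask.all()

    def test_extreme_separation_detected(self):
        rng = np.random.default_rng(20)
        A = rng.normal(0.0, 0.1, (20, 10))
        B = rng.normal(0.0, 0.1, (20, 10))
        B[:, 4] += 1.0  # 10 pooled SDs at band 4
        mask = band_significance_mask(A, B, alpha=0.01)
        assert not mask[4]

    def test_null_type_one_rate(self):
        """Under the null, ~alpha of bands flag significant."""
        rng = np.random.default_rng(21)
        n_bands, alpha = 2000, 0.01
        A = rng.normal(0.0, 1.0, (40, n_bands))
        B = rng.normal(0.0, 1.0, (40, n_bands))
        frac = 1.0 - band_significance_mask(A, B, alpha=alpha).mean()
        se = np.sqrt(alpha * (1 - alpha) / n_bands)
        assert abs(frac - alpha) <= 3 * se

    def test_single_sample_group_raises(self):
        with pytest.raises(ValueError):
            band_significance_mask(np.zeros((1, 5)), np.zeros((4, 5)))
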