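"""Dataset ingestion, preprocessing rules, and synthetic generators."""

import numpy as np
import pytest

import stnet as st


class TestLoadTabular:
    def test_toy_csv(self, tmp_path):
        p = tmp_path / "toy.csv"
        p.write_text("1.0,2.0,a\n3.0,4.0,b\n5.0,6.0,a\n")
        ds = st.load_tabular(p)
        assert ds.X.shape == (3, 2)
        np.testing.assert_array_equal(ds.y, [0, 1, 0])

    def test_label_column_position_invariance(self, tmp_path):
        last = tmp_path / "last.csv"
        last.write_text("1,2,x\n3,4,y\n")
        first = tmp_path / "first.csv"
        first.write_text("x,1,2\ny,3,4\n")
        a = st.load_tabular(last, label_col=-1)
        b = st.load_tabular(first, label_col=0)
        np.testing.assert_array_equal(a.X, b.X)
        np.testing.assert_array_equal(a.y, b.y)

    def test_iris_shaped_file(self, tmp_path):
        rng = np.random.default_rng(0)
        rows = [",".join(f"{v:.2f}" for v in rng.uniform(0, 8, 4))
                + f",class{i % 3}" for i in range(150)]
        p = tmp_path / "iris_like.csv"
        p.write_text("\n".join(rows) + "\n")
        ds = st.load_tabular(p)
        assert ds.n_samples == 150 and ds.n_features == 4
        assert ds.n_classes == 3

    def test_missing_marker_becomes_nan(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("1,?,a\n2,3,b\n")
        ds = st.load_tabular(p)
        assert np.isnan(ds.X[0, 1])

    def test_non_numeric_feature_names_row(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("1,2,a\n3,oops,b\n")
        with pytest.raises(ValueError, match="row 1"):
            st.load_tabular(p)

    def test_header_detected(self, tmp_path):
        p = tmp_path / "h.csv"
        p.write_text("f1,f2,label\n1,2,a\n3,4,b\n")
        ds = st.load_tabular(p)
        assert ds.n_samples == 2


class TestPreprocessing:
    def test_minmax_basic_and_idempotent(self):
        ds = st.Dataset(X=np.array([[2.0], [4.0], [6.0]]), y=[0, 1, 0])
        norm = st.minmax_normalize(ds)
        np.testing.assert_allclose(norm.X[:, 0], [0, 0.5, 1])
        again = st.minmax_normalize(norm)
        np.testing.assert_allclose(again.X, norm.X)

    def test_minmax_round_trip(self, rng):
        X = rng.uniform(-5, 20, (30, 4))
        ds = st.Dataset(X=X, y=np.zeros(30, dtype=int))
        norm = st.minmax_normalize(ds)
        back = norm.X * (ds.xmax - ds.xmin) + ds.xmin
        np.testing.assert_allclose(back, X, atol=1e-12)

    def test_minmax_constant_feature_warns(self):
        ds = st.Dataset(X=np.array([[1.0, 5.0], [2.0, 5.0]]), y=[0, 1])
        with pytest.warns(UserWarning, match="constant"):
            norm = st.minmax_normalize(ds)
        np.testing.assert_array_equal(norm.X[:, 1], 0.0)

    def test_impute_mean(self):
        X = np.array([[1.0], [np.nan], [3.0]])
        out = st.impute_mean(st.Dataset(X=X, y=[0, 0, 0]))
        assert out.X[1, 0] == 2.0
        # conservation: observed mean preserved
        assert out.X[:, 0].mean() == pytest.approx(2.0)

    def test_impute_no_missing_is_identity(self, rng):
        X = rng.uniform(0, 1, (5, 3))
        out = st.impute_mean(st.Dataset(X=X, y=np.zeros(5, dtype=int)))
        np.testing.assert_array_equal(out.X, X)

    def test_impute_fully_missing_feature_errors(self):
        X = np.array([[np.nan], [np.nan]])
        with pytest.raises(ValueError):
            st.impute_mean(st.Dataset(X=X, y=[0, 1]))

    def test_preprocessing_commutes_with_shuffling(self, rng):
        X = rng.uniform(0, 10, (20, 3))
        X[2, 1] = np.nan
        ds = st.Dataset(X=X, y=np.zeros(20, dtype=int))
        p = rng.permutation(20)
        a = st.minmax_normalize(st.impute_mean(ds)).X[p]
        shuffled = st.Dataset(X=X[p], y=np.zeros(20, dtype=int))
        b = st.minmax_normalize(st.impute_mean(shuffled)).X
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestStatlogBandAverage:
    def test_constant_input(self):
        ds = st.Dataset(X=np.full((2, 36), 7.0), y=[0, 1])
        out = st.statlog_band_average(ds)
        np.testing.assert_array_equal(out.X, np.full((2, 4), 7.0))

    def test_single_band_mean(self):
        X = np.zeros((1, 36))
        X[0, 9:18] = np.arange(1, 10)  # band 1 in band-major layout
        out = st.statlog_band_average(st.Dataset(X=X, y=[0]))
        np.testing.assert_allclose(out.X[0], [0.0, 5.0, 0.0, 0.0])

    def test_pixel_major_layout(self):
        X = np.zeros((1, 36))
        X[0, 1::4] = np.arange(1, 10)  # band 1 in pixel-major layout
        out = st.statlog_band_average(st.Dataset(X=X, y=[0]),
                                      layout="pixel-major")
        np.testing.assert_allclose(out.X[0], [0.0, 5.0, 0.0, 0.0])

    def test_output_width_and_validation(self):
        ds = st.Dataset(X=np.zeros((3, 36)), y=[0, 1, 0])
        assert st.statlog_band_average(ds).n_features == 4
        with pytest.raises(ValueError):
            st.statlog_band_average(st.Dataset(X=np.zeros((1, 35)), y=[0]))


class TestIdx:
    def test_round_trip(self, tmp_path, rng):
        imgs = rng.integers(0, 256, size=(2, 28, 28), dtype=np.uint8)
        labels = np.array([3, 7], dtype=np.uint8)
        ip, lp = tmp_path / "img.idx", tmp_path / "lab.idx"
        st.write_idx(ip, lp, imgs, labels)
        ds = st.read_idx_images(ip, lp)
        assert ds.X.shape == (2, 784)
        np.testing.assert_array_equal(ds.y, [3, 7])
        np.testing.assert_allclose(ds.X, imgs.reshape(2, -1) / 255.0)

    def test_all_zero_image(self, tmp_path):
        st.write_idx(tmp_path / "i", tmp_path / "l",
                     np.zeros((1, 4, 4), dtype=np.uint8),
                     np.array([0], dtype=np.uint8))
        ds = st.read_idx_images(tmp_path / "i", tmp_path / "l")
        np.testing.assert_array_equal(ds.X, 0.0)

    def test_bad_magic_rejected(self, tmp_path):
        (tmp_path / "junk").write_bytes(b"\x00" * 16)
        (tmp_path / "lab").write_bytes(b"\x00" * 8)
        with pytest.raises(ValueError, match="magic"):
            st.read_idx_images(tmp_path / "junk", tmp_path / "lab")


class TestSynthetic:
    def test_deterministic_per_seed(self):
        a = st.make_synthetic("blobs", seed=5)
        b = st.make_synthetic("blobs", seed=5)
        np.testing.assert_array_equal(a.X, b.X)
        np.testing.assert_array_equal(a.y, b.y)
        c = st.make_synthetic("blobs", seed=6)
        assert not np.array_equal(a.X, c.X)

    def test_shapes_and_balance(self):
        ds = st.make_synthetic("blobs", n_per_class=50, n_features=4,
                               n_classes=3, seed=0)
        assert ds.n_samples == 150 and ds.n_features == 4
        np.testing.assert_array_equal(np.bincount(ds.y), [50, 50, 50])

    def test_noiseless_blobs_linearly_separable(self):
        """With tiny noise a nearest-centroid rule is perfect."""
        ds = st.make_synthetic("blobs", n_per_class=30, n_features=2,
                               n_classes=2, noise=1e-3, seed=3)
        centroids = np.array([ds.X[ds.y == c].mean(axis=0) for c in range(2)])
        d = np.linalg.norm(ds.X[:, None] - centroids[None], axis=-1)
        assert np.all(np.argmin(d, axis=1) == ds.y)

    @pytest.mark.parametrize("kind", ["xor", "rings"])
    def test_other_kinds_generate(self, kind):
        ds = st.make_synthetic(kind, n_per_class=20, n_features=2,
                               n_classes=2, noise=0.05, seed=1)
        assert ds.n_features == 2 and ds.n_samples == 40

    def test_csv_round_trip(self, tmp_path):
        ds = st.make_synthetic("blobs", n_per_class=5, seed=2)
        ds.to_csv(tmp_path / "blobs.csv")
        back = st.load_tabular(tmp_path / "blobs.csv")
        np.testing.assert_allclose(back.X, ds.X, atol=1e-12)
        np.testing.assert_array_equal(back.y, ds.y)
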