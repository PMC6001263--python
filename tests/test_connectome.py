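import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brainmass import (
    BoldRun,
    DegenerateSeriesError,
    DisconnectedGraphError,
    FunctionalConnectome,
    MatrixParseError,
    StructuralConnectome,
    fc_from_bold,
    is_connected,
    normalize_sc,
    read_matrix,
    read_sidecar,
    threshold_sc,
    upper_triangle,
    write_matrix,
    write_sidecar,
)
from brainmass.connectome import R_CLIP


def sc_from(w):
    return StructuralConnectome(np.asarray(w, dtype=float))


class TestThreshold:
    def test_removes_weights_below_cutoff(self):
        sc = sc_from([[0, 4, 6], [4, 0, 10], [6, 10, 0]])
        out = threshold_sc(sc, 5)
        expected = np.array([[0, 0, 6], [0, 0, 10], [6, 10, 0]], dtype=float)
        np.testing.assert_array_equal(out.weights, expected)

    def test_zero_cutoff_is_identity(self):
        sc = sc_from([[0, 4, 6], [4, 0, 10], [6, 10, 0]])
        np.testing.assert_array_equal(threshold_sc(sc, 0).weights, sc.weights)

    def test_disconnection_raises(self):
        sc = sc_from([[0, 4], [4, 0]])
        with pytest.raises(DisconnectedGraphError):
            threshold_sc(sc, 5)

    def test_lengths_zeroed_with_weights(self):
        w = np.array([[0, 4, 6], [4, 0, 10], [6, 10, 0]], dtype=float)
        ln = np.where(w > 0, 30.0, 0.0)
        out = threshold_sc(StructuralConnectome(w, ln), 5)
        assert out.lengths[0, 1] == 0.0 and out.lengths[0, 2] == 30.0

    def test_commutes_with_normalization_when_cutoff_rescaled(self, rng):
        # thresholding raw counts at c then dividing by s equals dividing
        # first and thresholding at c/s; with the unscaled cutoff the order
        # matters (everything below s would vanish)
        for _ in range(5):
            n = 12
            w = rng.integers(0, 60_000, size=(n, n)).astype(float)
            w = np.triu(w, 1)
            w = w + w.T
            for i in range(n):  # strong ring so thresholding keeps connectivity
                j = (i + 1) % n
                w[i, j] = w[j, i] = 50_000.0
            sc = StructuralConnectome(w)
            a = normalize_sc(threshold_sc(sc, 5), 75_000.0)
            b = threshold_sc(normalize_sc(sc, 75_000.0), 5 / 75_000.0)
            np.testing.assert_allclose(a.weights, b.weights, atol=1e-15)
            # same cutoff applied after normalization is a different operation:
            # it wipes every link below 5 (all of them are below 1)
            with pytest.raises(DisconnectedGraphError):
                threshold_sc(normalize_sc(sc, 75_000.0), 5)


class TestNormalize:
    def test_divides_by_scalar(self):
        sc = sc_from([[0, 15_000], [15_000, 0]])
        assert normalize_sc(sc, 75_000.0).weights[0, 1] == pytest.approx(0.2)

    def test_scalar_equal_to_max_gives_one(self):
        sc = sc_from([[0, 42.0], [42.0, 0]])
        assert normalize_sc(sc, 42.0).weights.max() == 1.0

    def test_exceeding_scalar_raises(self):
        sc = sc_from([[0, 80_000], [80_000, 0]])
        with pytest.raises(ValueError, match="exceeds"):
            normalize_sc(sc, 75_000.0)


class TestConnectivity:
    def test_two_disjoint_dyads(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 1.0
        assert not is_connected(StructuralConnectome(w))

    def test_path_graph(self):
        w = np.zeros((4, 4))
        for i in range(3):
            w[i, i + 1] = w[i + 1, i] = 1.0
        assert is_connected(StructuralConnectome(w))


class TestFcFromBold:
    def test_perfect_correlation_clipped_finite(self, rng):
        x = rng.standard_normal(200)
        run = BoldRun(np.vstack([x, x]), tr=2.1)
        fc = fc_from_bold(run)
        assert np.isfinite(fc.z_values[0, 1])
        assert fc.z_values[0, 1] == pytest.approx(np.arctanh(R_CLIP))

    def test_orthogonal_series_near_zero(self):
        t = np.linspace(0, 2 * np.pi, 10_000, endpoint=False)
        run = BoldRun(np.vstack([np.sin(t), np.cos(t)]), tr=1.0)
        assert abs(fc_from_bold(run).z_values[0, 1]) < 1e-10

    def test_half_correlation_closed_form(self, rng):
        # construct series with exact sample correlation 0.5
        x = rng.standard_normal(500)
        y = rng.standard_normal(500)
        x = (x - x.mean()) / x.std()
        y = (y - y.mean()) / y.std()
        y -= (y @ x / len(x)) * x  # orthogonalize
        y /= y.std()
        z = 0.5 * x + np.sqrt(1 - 0.25) * y
        fc = fc_from_bold(BoldRun(np.vstack([x, z]), tr=2.0))
        assert fc.z_values[0, 1] == pytest.approx(0.5493, abs=2e-4)

    def test_constant_series_names_region(self):
        series = np.vstack([np.ones(50), np.arange(50.0)])
        with pytest.raises(DegenerateSeriesError, match="region index 0"):
            fc_from_bold(BoldRun(series, tr=2.0))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_symmetric_zero_diag_bounded(self, seed):
        r = np.random.default_rng(seed)
        series = r.standard_normal((4, 30))
        fc = fc_from_bold(BoldRun(series, tr=1.0))
        z = fc.z_values
        assert np.allclose(z, z.T)
        assert np.all(np.diag(z) == 0)
        assert np.all(np.abs(z) <= np.arctanh(R_CLIP) + 1e-12)


class TestUpperTriangle:
    def test_row_major_order(self):
        m = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        np.testing.assert_array_equal(
            upper_triangle(FunctionalConnectome(m)), [1, 2, 3]
        )

    def test_length(self):
        n = 6
        m = np.zeros((n, n))
        assert len(upper_triangle(FunctionalConnectome(m))) == n * (n - 1) // 2

    def test_two_regions(self):
        m = np.array([[0, 0.7], [0.7, 0]])
        np.testing.assert_array_equal(upper_triangle(FunctionalConnectome(m)), [0.7])


class TestMatrixIO:
    def test_roundtrip(self, tmp_path, rng):
        w = rng.random((68, 68))
        w = (w + w.T) / 2
        path = tmp_path / "m.txt"
        write_matrix(w, path)
        np.testing.assert_allclose(read_matrix(path), w, atol=1e-12)

    def test_comma_and_whitespace_dialects(self, tmp_path):
        (tmp_path / "a.txt").write_text("1 2\n3 4\n")
        (tmp_path / "b.txt").write_text("1,2\n3,4\n")
        np.testing.assert_array_equal(
            read_matrix(tmp_path / "a.txt"), read_matrix(tmp_path / "b.txt")
        )

    def test_ragged_raises_with_line(self, tmp_path):
        (tmp_path / "bad.txt").write_text("1 2\n3 4 5\n")
        with pytest.raises(MatrixParseError, match="line 2"):
            read_matrix(tmp_path / "bad.txt")

    def test_non_numeric_raises(self, tmp_path):
        (tmp_path / "bad.txt").write_text("1 2\n3 x\n")
        with pytest.raises(MatrixParseError, match="line 2"):
            read_matrix(tmp_path / "bad.txt")

    def test_sidecar_roundtrip(self, tmp_path):
        meta = {"regions": ["a", "b"], "tr": 2.1, "group": "CON"}
        write_sidecar(meta, tmp_path / "m.json")
        assert read_sidecar(tmp_path / "m.json") == meta


class TestAverageConnectome:
    def test_elementwise_mean(self):
        a = sc_from([[0, 2.0], [2.0, 0]])
        b = sc_from([[0, 4.0], [4.0, 0]])
        from brainmass import average_connectome

        avg = average_connectome([a, b])
        assert avg.weights[0, 1] == pytest.approx(3.0)

    def test_mismatched_regions_rejected(self):
        from brainmass import average_connectome

        a = StructuralConnectome(np.array([[0, 1.0], [1.0, 0]]), region_ids=["a", "b"])
        b = StructuralConnectome(np.array([[0, 1.0], [1.0, 0]]), region_ids=["x", "y"])
        with pytest.raises(ValueError, match="region"):
            average_connectome([a, b])


class TestInvariantEnforcement:
    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            StructuralConnectome(np.array([[0, 1.0], [2.0, 0]]))

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            StructuralConnectome(np.array([[0, -1.0], [-1.0, 0]]))

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            StructuralConnectome(np.array([[1.0, 1.0], [1.0, 0]]))

    def test_bold_run_validation(self):
        with pytest.raises(ValueError):
            BoldRun(np.ones((2, 1)), tr=2.0)
        with pytest.raises(ValueError):
            BoldRun(np.ones((2, 5)), tr=-1.0)
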