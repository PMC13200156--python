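"""Connectome loading/validation and Laplacian decomposition."""

import numpy as np
import pytest

from ndmap import (
    Connectome,
    ConnectomeError,
    build_laplacian,
    load_connectome,
    load_labels,
)
from tests.conftest import random_connected_weights


def _write_study(tmp_path, w, names=None, matrix_text=None):
    n = w.shape[0] if w is not None else len(matrix_text.splitlines())
    names = names or [f"R{i + 1:03d}" for i in range(n)]
    labels = tmp_path / "labels.csv"
    rows = ["index,name,hemisphere,tier"] + [
        f"{i + 1},{nm},{'L' if i % 2 else 'R'},cortical" for i, nm in enumerate(names)
    ]
    labels.write_text("\n".join(rows) + "\n")
    mat = tmp_path / "conn.tsv"
    if matrix_text is None:
        matrix_text = "\n".join("\t".join(f"{v:.12g}" for v in row) for row in w)
    mat.write_text(matrix_text + "\n")
    return mat, labels


class TestLoadConnectome:
    def test_symmetric_matrix_passes_through(self, tmp_path):
        w = np.array([[0, 1, 2], [1, 0, 0.5], [2, 0.5, 0]], dtype=float)
        mat, labels = _write_study(tmp_path, w)
        c = load_connectome(mat, labels)
        assert c.n_regions == 3
        np.testing.assert_allclose(c.weights, w)
        assert c.region_ids == ["R001", "R002", "R003"]

    def test_tiny_asymmetry_averaged(self, tmp_path):
        text = "0\t2\n2.0000000001\t0"
        mat, labels = _write_study(tmp_path, None, names=["a", "b"], matrix_text=text)
        c = load_connectome(mat, labels)
        assert c.weights[0, 1] == pytest.approx(2.00000000005, abs=1e-15)
        assert c.weights[0, 1] == c.weights[1, 0]

    def test_large_asymmetry_rejected(self, tmp_path):
        text = "0\t2\n3\t0"
        mat, labels = _write_study(tmp_path, None, names=["a", "b"], matrix_text=text)
        with pytest.raises(ConnectomeError, match="asymmetry"):
            load_connectome(mat, labels)

    def test_negative_weight_names_cell(self, tmp_path):
        w = np.array([[0, -1.0], [-1.0, 0]])
        mat, labels = _write_study(tmp_path, w)
        with pytest.raises(ConnectomeError, match=r"negative weight .*\(0, 1\)"):
            load_connectome(mat, labels)

    def test_nan_entry_names_cell(self, tmp_path):
        text = "0\t1\n1\tnan"
        mat, labels = _write_study(tmp_path, None, names=["a", "b"], matrix_text=text)
        with pytest.raises(ConnectomeError, match=r"non-finite .*\(1, 1\)"):
            load_connectome(mat, labels)

    def test_dimension_mismatch(self, tmp_path):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[1, 2] = w[2, 1] = 1.0
        mat, labels = _write_study(tmp_path, w, names=["a", "b", "c", "d"][:3])
        extra = tmp_path / "labels4.csv"
        extra.write_text(
            "index,name,hemisphere,tier\n"
            + "\n".join(f"{i + 1},x{i},L,cortical" for i in range(4))
            + "\n"
        )
        with pytest.raises(ConnectomeError, match="labels but matrix"):
            load_connectome(mat, extra)

    def test_self_loops_stripped_with_warning(self, tmp_path):
        w = np.array([[1.0, 2.0], [2.0, 0.0]])
        mat, labels = _write_study(tmp_path, w)
        with pytest.warns(UserWarning, match="self-loop"):
            c = load_connectome(mat, labels)
        assert c.weights[0, 0] == 0.0

    def test_header_variant_roundtrip(self, tmp_path):
        w = np.array([[0, 1.5], [1.5, 0]])
        labels = tmp_path / "labels.csv"
        labels.write_text(
            "index,name,hemisphere,tier\n1,Left_A,L,cortical\n2,Right_A,R,subcortical\n"
        )
        mat = tmp_path / "conn.csv"
        mat.write_text(",Left_A,Right_A\nLeft_A,0,1.5\nRight_A,1.5,0\n")
        c = load_connectome(mat, labels)
        np.testing.assert_allclose(c.weights, w)
        assert list(c.region_meta["tier"]) == ["cortical", "subcortical"]

    def test_atlas_scale_246(self, tmp_path, rng):
        """Full-parcellation scale: 246 regions load with matching labels."""
        w = random_connected_weights(246, rng, density=0.05)
        mat, labels = _write_study(tmp_path, w)
        c = load_connectome(mat, labels)
        assert c.n_regions == 246
        assert len(load_labels(labels)) == 246


class TestBuildLaplacian:
    @pytest.mark.parametrize("weight", [1.0, 0.25, 40.0])
    def test_two_node_normalization_removes_weight(self, weight):
        L = build_laplacian(np.array([[0.0, weight], [weight, 0.0]]))
        np.testing.assert_allclose(L.matrix, [[1, -1], [-1, 1]], atol=1e-12)
        np.testing.assert_allclose(L.eigenvalues, [0.0, 2.0], atol=1e-12)

    def test_complete_triangle_spectrum(self):
        w = np.ones((3, 3)) - np.eye(3)
        L = build_laplacian(w)
        np.testing.assert_allclose(L.eigenvalues, [0.0, 1.5, 1.5], atol=1e-12)

    def test_spectrum_and_nullspace_random_graph(self, rng):
        w = random_connected_weights(10, rng)
        L = build_laplacian(w)
        assert L.eigenvalues[0] == pytest.approx(0.0, abs=1e-8)
        assert np.all(L.eigenvalues >= -1e-8)
        assert np.all(L.eigenvalues <= 2 + 1e-8)
        # nullspace eigenvector proportional to D^{1/2} 1
        v = L.eigenvectors[:, 0]
        expected = np.sqrt(L.degree)
        expected /= np.linalg.norm(expected)
        np.testing.assert_allclose(np.abs(v), expected, atol=1e-8)

    def test_eigensystem_is_consistent(self, small_connectome):
        L = build_laplacian(small_connectome)
        h = L.eigenvectors @ np.diag(L.eigenvalues) @ L.eigenvectors.T
        np.testing.assert_allclose(h, L.matrix, atol=1e-8)
        np.testing.assert_allclose(
            L.eigenvectors.T @ L.eigenvectors, np.eye(10), atol=1e-8
        )
        np.testing.assert_allclose(
            L.matrix @ L.eigenvectors,
            L.eigenvectors * L.eigenvalues,
            atol=1e-8,
        )

    def test_weight_scaling_invariance(self, small_connectome):
        L1 = build_laplacian(small_connectome.weights)
        L2 = build_laplacian(small_connectome.weights * 37.5)
        np.testing.assert_allclose(L1.matrix, L2.matrix, atol=1e-12)

    def test_isolated_region_is_error(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        with pytest.raises(ConnectomeError, match="isolated"):
            build_laplacian(Connectome(weights=w, region_ids=["a", "b", "c"]))

    def test_disconnected_warns_and_proceeds(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 1.0
        with pytest.warns(UserWarning, match="disconnected"):
            L = build_laplacian(w)
        # one zero eigenvalue per component
        assert np.sum(np.abs(L.eigenvalues) < 1e-10) == 2
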