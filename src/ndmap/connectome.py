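"""Structural connectome container, loading/validation, and Laplacian decomposition.

A connectome is a weighted undirected graph over brain parcels (regions):
nodes are atlas regions, edge weights are inter-regional connection
strengths, typically streamline counts or densities from fiber tractography.
Diffusion dynamics on the graph are governed by the symmetric normalized
graph Laplacian

    H = I - D^{-1/2} W D^{-1/2},

where ``W`` is the weight matrix and ``D`` the diagonal matrix of node
strengths (sum of weighted connections per node).  Degree normalization
keeps regions with very different total connectivity comparable.  All
eigenvalues of H lie in [0, 2]; a connected graph has exactly one zero
eigenvalue with eigenvector proportional to ``D^{1/2} 1``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger(__name__)

#: relative tolerance below which asymmetries are silently averaged away;
#: anything larger is treated as a corrupt/transposed file and rejected.
ASYMMETRY_RTOL = 1e-9

LABEL_COLUMNS = ("index", "name", "hemisphere", "tier")


class ConnectomeError(ValueError):
    """Raised for invalid connectivity matrices or label tables."""


@dataclass
class Connectome:
    """Weighted undirected structural brain network.

    Attributes
    ----------
    weights : (N, N) ndarray
        Symmetric nonnegative connection-strength matrix, zero diagonal.
    region_ids : list of str
        Ordered region labels; this order is the single source of truth
        for every regional vector downstream.
    region_meta : pandas.DataFrame
        One row per region with columns ``name``, ``hemisphere`` (L/R/BL)
        and ``tier`` (cortical/subcortical), indexed 0..N-1 in region order.
    """

    weights: np.ndarray
    region_ids: list[str]
    region_meta: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        validate_weights(self.weights)
        if len(self.region_ids) != self.weights.shape[0]:
            raise ConnectomeError(
                f"{len(self.region_ids)} region labels for a "
                f"{self.weights.shape[0]}x{self.weights.shape[1]} matrix"
            )
        if self.region_meta is None:
            self.region_meta = pd.DataFrame(
                {
                    "name": self.region_ids,
                    "hemisphere": "BL",
                    "tier": "cortical",
                }
            )

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    @property
    def degree(self) -> np.ndarray:
        """Node strength: row sums of the weight matrix."""
        return self.weights.sum(axis=1)

    @property
    def tiers(self) -> np.ndarray:
        return self.region_meta["tier"].to_numpy()

    def n_components(self) -> int:
        n, _ = connected_components(self.weights > 0, directed=False)
        return int(n)


def validate_weights(w: np.ndarray) -> None:
    """Check an in-memory weight matrix: square, finite, nonnegative,
    symmetric, zero diagonal.  Raises :class:`ConnectomeError` naming the
    first offending cell."""
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ConnectomeError(f"matrix is not square: shape {w.shape}")
    bad = np.argwhere(~np.isfinite(w))
    if bad.size:
        i, j = bad[0]
        raise ConnectomeError(f"non-finite weight at cell ({i}, {j})")
    neg = np.argwhere(w < 0)
    if neg.size:
        i, j = neg[0]
        raise ConnectomeError(f"negative weight {w[i, j]!r} at cell ({i}, {j})")
    scale = np.abs(w).max() or 1.0
    asym = np.abs(w - w.T)
    if asym.max() > 1e-8 * scale:  # post-loading matrices must be clean
        i, j = np.unravel_index(np.argmax(asym), w.shape)
        raise ConnectomeError(
            f"asymmetric weights at cell ({i}, {j}): {w[i, j]!r} vs {w[j, i]!r}"
        )
    if np.abs(np.diag(w)).max() > 0:
        i = int(np.argmax(np.abs(np.diag(w))))
        raise ConnectomeError(f"nonzero diagonal at region {i}")


def _clean_matrix(w: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Symmetrize tiny asymmetries, strip self-loops; return cleaned matrix
    and a log of modifications.  Larger problems raise."""
    notes: list[str] = []
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ConnectomeError(f"matrix is not square: shape {w.shape}")
    bad = np.argwhere(~np.isfinite(w))
    if bad.size:
        i, j = bad[0]
        raise ConnectomeError(f"non-finite weight at cell ({i}, {j})")
    neg = np.argwhere(w < 0)
    if neg.size:
        i, j = neg[0]
        raise ConnectomeError(f"negative weight {w[i, j]!r} at cell ({i}, {j})")
    scale = np.abs(w).max() or 1.0
    asym = np.abs(w - w.T)
    if asym.max() > ASYMMETRY_RTOL * scale:
        i, j = np.unravel_index(np.argmax(asym), w.shape)
        raise ConnectomeError(
            f"asymmetry {asym[i, j]:.3e} at cell ({i}, {j}) exceeds relative "
            f"tolerance {ASYMMETRY_RTOL:g}; refusing to average (possible "
            "transposed or corrupt file)"
        )
    if asym.max() > 0:
        w = (w + w.T) / 2.0
        notes.append(f"symmetrized asymmetries up to {asym.max():.3e} by averaging")
    d = np.diag(w)
    if np.abs(d).max() > 0:
        k = int(np.count_nonzero(d))
        w = w.copy()
        np.fill_diagonal(w, 0.0)
        msg = f"stripped {k} self-loop(s)"
        notes.append(msg)
        warnings.warn(msg, stacklevel=3)
    return w, notes


def load_labels(path) -> pd.DataFrame:
    """Read an atlas label table (CSV with columns index, name, hemisphere,
    tier).  ``index`` is 1-based per atlas convention; rows are returned in
    index order and re-indexed 0..N-1."""
    df = pd.read_csv(path)
    missing = [c for c in LABEL_COLUMNS if c not in df.columns]
    if missing:
        raise ConnectomeError(f"labels file {path} missing columns {missing}")
    df = df.sort_values("index").reset_index(drop=True)
    bad_h = set(df["hemisphere"].unique()) - {"L", "R", "BL"}
    if bad_h:
        raise ConnectomeError(f"unknown hemisphere codes {sorted(bad_h)}")
    bad_t = set(df["tier"].unique()) - {"cortical", "subcortical"}
    if bad_t:
        raise ConnectomeError(f"unknown tier codes {sorted(bad_t)}")
    return df


def _read_matrix(path, region_names: list[str]) -> np.ndarray:
    """Read a delimited numeric matrix, with or without header row/column."""
    df = pd.read_csv(path, sep=None, engine="python", header=None)
    row0 = df.iloc[0].tolist()
    # header row: any non-numeric string (the top-left corner cell may be empty)
    has_header = any(isinstance(v, str) and not _is_number(v) for v in row0) or (
        pd.isna(row0[0]) and df.shape[1] == len(region_names) + 1
    )
    if has_header:
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
        if list(df.columns) != region_names or list(df.index) != region_names:
            raise ConnectomeError(
                f"matrix header/index in {path} does not match the labels file"
            )
    try:
        return df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ConnectomeError(f"non-numeric entry in {path}: {exc}") from exc


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def load_connectome(path, labels_path) -> Connectome:
    """Load and validate a connectome from a delimited matrix file plus an
    atlas label table.

    Asymmetries within :data:`ASYMMETRY_RTOL` (relative) are averaged,
    self-loops are stripped with a warning, and every modification is
    logged.  Larger defects are hard errors naming the offending cell.
    """
    labels = load_labels(labels_path)
    names = labels["name"].astype(str).tolist()
    w = _read_matrix(path, names)
    if w.shape[0] != len(names):
        raise ConnectomeError(
            f"{len(names)} labels but matrix is {w.shape[0]}x{w.shape[1]}"
        )
    w, notes = _clean_matrix(w)
    for note in notes:
        logger.info("load_connectome(%s): %s", path, note)
    return Connectome(weights=w, region_ids=names, region_meta=labels)


@dataclass
class LaplacianDecomposition:
    """Symmetric normalized graph Laplacian with its full eigensystem.

    ``eigenvalues`` are ascending; ``eigenvectors[:, k]`` pairs with
    ``eigenvalues[k]``.  Modes with small eigenvalues decay slowly under
    diffusion and are the persistent spatial patterns of the network.
    """

    matrix: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    degree: np.ndarray
    region_ids: list[str] | None = None

    @property
    def n_regions(self) -> int:
        return self.matrix.shape[0]


def build_laplacian(c: Connectome | np.ndarray) -> LaplacianDecomposition:
    """Construct H = I - D^{-1/2} W D^{-1/2} and eigendecompose it.

    Parameters
    ----------
    c : Connectome or (N, N) ndarray
        Validated connectome (or a raw symmetric weight matrix).

    Raises
    ------
    ConnectomeError
        If any region is isolated (zero strength) — the normalization is
        undefined there.

    Warns
    -----
    UserWarning
        If the graph is disconnected (extra zero eigenvalues; diffusion
        then conserves mass within each component).  This is tolerated so
        that occasional fragmented rewired null networks do not abort a
        null-distribution run.
    """
    if isinstance(c, Connectome):
        w = c.weights
        region_ids = c.region_ids
    else:
        w = np.asarray(c, dtype=float)
        region_ids = None
    deg = w.sum(axis=1)
    isolated = np.flatnonzero(deg <= 0)
    if isolated.size:
        ids = (
            [region_ids[i] for i in isolated]
            if region_ids is not None
            else isolated.tolist()
        )
        raise ConnectomeError(f"isolated region(s) with zero degree: {ids}")
    ncomp, _ = connected_components(w > 0, directed=False)
    if ncomp > 1:
        warnings.warn(
            f"connectome is disconnected ({ncomp} components); "
            "diffusion conserves mass within each component",
            stacklevel=2,
        )
    inv_sqrt = 1.0 / np.sqrt(deg)
    h = -w * inv_sqrt[:, None] * inv_sqrt[None, :]
    np.fill_diagonal(h, 1.0)
    h = (h + h.T) / 2.0  # enforce exact symmetry for eigh
    evals, evecs = np.linalg.eigh(h)
    return LaplacianDecomposition(
        matrix=h,
        eigenvalues=evals,
        eigenvectors=evecs,
        degree=deg,
        region_ids=region_ids,
    )
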