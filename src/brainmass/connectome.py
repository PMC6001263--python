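"""Connectivity containers, preprocessing, and plain-text I/O.

Structural connectomes are symmetric non-negative region-by-region weight
matrices (streamline-count derived), optionally accompanied by a tract-length
matrix in millimetres.  Functional connectomes store Fisher-z transformed
Pearson correlations between regional BOLD time series.  Matrices travel as
plain whitespace- or comma-delimited text with a JSON sidecar carrying region
labels and acquisition metadata (TR, group label).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "StructuralConnectome",
    "FunctionalConnectome",
    "BoldRun",
    "make_region_table",
    "DisconnectedGraphError",
    "DegenerateSeriesError",
    "MatrixParseError",
    "threshold_sc",
    "average_connectome",
    "normalize_sc",
    "is_connected",
    "fc_from_bold",
    "upper_triangle",
    "read_matrix",
    "write_matrix",
    "read_sidecar",
    "write_sidecar",
]

#: correlations are clipped to +/- this value before the Fisher transform so
#: that degenerate toy inputs (perfectly correlated series) stay finite.
R_CLIP = 1.0 - 1e-7


class DisconnectedGraphError(ValueError):
    """Raised when an operation would leave the connectome disconnected."""


class DegenerateSeriesError(ValueError):
    """Raised when a BOLD series has zero variance and cannot be correlated."""


class MatrixParseError(ValueError):
    """Raised on ragged or non-numeric plain-text matrix files."""


def _default_labels(n: int) -> list[str]:
    return [f"region_{i}" for i in range(n)]


@dataclass(frozen=True)
class StructuralConnectome:
    """Symmetric non-negative coupling matrix over labeled regions.

    ``weights`` is the dimensionless coupling substrate C_ij (zero diagonal);
    ``lengths``, when present, holds mean tract lengths in mm with the same
    sparsity pattern.
    """

    weights: np.ndarray
    lengths: np.ndarray | None = None
    region_ids: Sequence[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1] or w.shape[0] < 2:
            raise ValueError("weights must be a square matrix with n >= 2")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if np.any(np.diag(w) != 0):
            raise ValueError("weights must have a zero diagonal")
        object.__setattr__(self, "weights", w)
        if self.lengths is not None:
            ln = np.asarray(self.lengths, dtype=float)
            if ln.shape != w.shape or np.any(ln < 0):
                raise ValueError("lengths must be non-negative and conformable")
            object.__setattr__(self, "lengths", ln)
        ids = self.region_ids
        ids = _default_labels(w.shape[0]) if ids is None else list(ids)
        if len(ids) != w.shape[0]:
            raise ValueError("region_ids length must match matrix size")
        object.__setattr__(self, "region_ids", ids)

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    def in_strength(self) -> np.ndarray:
        """Sum of incident weights per region, sum_j C_ij."""
        return self.weights.sum(axis=1)


@dataclass(frozen=True)
class FunctionalConnectome:
    """Fisher-z Pearson correlation matrix; diagonal carries no information."""

    z_values: np.ndarray
    region_ids: Sequence[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        z = np.asarray(self.z_values, dtype=float)
        if z.ndim != 2 or z.shape[0] != z.shape[1]:
            raise ValueError("z_values must be square")
        if not np.all(np.isfinite(z)):
            raise ValueError("z_values must be finite")
        if not np.allclose(z, z.T, atol=1e-10):
            raise ValueError("z_values must be symmetric")
        object.__setattr__(self, "z_values", z)
        ids = self.region_ids
        ids = _default_labels(z.shape[0]) if ids is None else list(ids)
        if len(ids) != z.shape[0]:
            raise ValueError("region_ids length must match matrix size")
        object.__setattr__(self, "region_ids", ids)

    @property
    def n_regions(self) -> int:
        return self.z_values.shape[0]


@dataclass(frozen=True)
class BoldRun:
    """Region-by-time BOLD matrix sampled every ``tr`` seconds."""

    series: np.ndarray
    tr: float
    source: str = "simulated"  # "empirical" | "simulated"

    def __post_init__(self):
        s = np.asarray(self.series, dtype=float)
        if s.ndim != 2 or s.shape[1] < 2:
            raise ValueError("series must be n_regions x T with T >= 2")
        if not np.all(np.isfinite(s)):
            raise ValueError("series must contain no missing values")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.source not in ("empirical", "simulated"):
            raise ValueError("source must be 'empirical' or 'simulated'")
        object.__setattr__(self, "series", s)

    @property
    def n_regions(self) -> int:
        return self.series.shape[0]

    @property
    def n_samples(self) -> int:
        return self.series.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples * self.tr


def make_region_table(region_ids, sizes, is_tumor=None):
    """Assemble the per-region metadata table (label, size in voxels, tumor flag).

    Returns a pandas DataFrame with one row per connectome region, in
    connectome order.
    """
    import pandas as pd

    region_ids = list(region_ids)
    sizes = np.asarray(sizes)
    if np.any(sizes <= 0):
        raise ValueError("region sizes must be positive")
    if len(sizes) != len(region_ids):
        raise ValueError("sizes must match region_ids")
    if is_tumor is None:
        is_tumor = np.zeros(len(region_ids), dtype=bool)
    return pd.DataFrame(
        {
            "region_id": region_ids,
            "size": sizes.astype(int),
            "is_tumor": np.asarray(is_tumor, dtype=bool),
        }
    )


# ---------------------------------------------------------------------------
# preprocessing


def threshold_sc(sc: StructuralConnectome, cutoff: float) -> StructuralConnectome:
    """Zero all weights below ``cutoff`` (absolute threshold on streamline counts).

    Tract lengths are zeroed wherever the corresponding weight is removed.
    Raises :class:`DisconnectedGraphError` if the thresholded network falls
    apart — downstream modeling requires a fully connected substrate.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    keep = sc.weights >= cutoff
    w = np.where(keep, sc.weights, 0.0)
    lengths = None if sc.lengths is None else np.where(w > 0, sc.lengths, 0.0)
    out = StructuralConnectome(w, lengths, sc.region_ids)
    if not is_connected(out):
        raise DisconnectedGraphError(
            f"thresholding at {cutoff} disconnects the network"
        )
    return out


def normalize_sc(sc: StructuralConnectome, scalar: float = 75_000.0) -> StructuralConnectome:
    """Divide all weights by a constant so couplings lie in [0, 1].

    The default scalar of 75,000 corresponds to filtered tractograms of
    7.5 million streamlines per subject divided by 100, shared across a cohort
    so that relative weight differences between subjects survive.
    """
    if scalar <= 0:
        raise ValueError("scalar must be positive")
    if sc.weights.max() > scalar:
        raise ValueError(
            f"max weight {sc.weights.max():g} exceeds normalization scalar {scalar:g}"
        )
    return replace(sc, weights=sc.weights / scalar)


def average_connectome(connectomes) -> StructuralConnectome:
    """Element-wise mean of several connectomes (e.g. the control average).

    All inputs must share the region set and order; lengths are averaged over
    the connectomes where the corresponding weight is nonzero.
    """
    connectomes = list(connectomes)
    if not connectomes:
        raise ValueError("need at least one connectome")
    ids = list(connectomes[0].region_ids)
    for sc in connectomes[1:]:
        if list(sc.region_ids) != ids:
            raise ValueError("connectomes cover different region sets")
    w = np.mean([sc.weights for sc in connectomes], axis=0)
    lengths = None
    if all(sc.lengths is not None for sc in connectomes):
        stack = np.array([sc.lengths for sc in connectomes])
        present = np.array([sc.weights > 0 for sc in connectomes])
        with np.errstate(invalid="ignore"):
            lengths = np.where(present.any(axis=0),
                               (stack * present).sum(axis=0)
                               / np.maximum(present.sum(axis=0), 1), 0.0)
    return StructuralConnectome(w, lengths, ids)


def is_connected(sc: StructuralConnectome) -> bool:
    """True iff the binary graph of nonzero weights has a single component."""
    n_comp, _ = connected_components(csr_matrix(sc.weights != 0), directed=False)
    return n_comp == 1


# ---------------------------------------------------------------------------
# functional connectivity


def fc_from_bold(run: BoldRun, region_ids: Sequence[str] | None = None) -> FunctionalConnectome:
    """Fisher-z Pearson correlation between all pairs of regional BOLD series.

    Correlations are clipped to +/-(1 - 1e-7) before ``arctanh`` so that
    perfectly (anti)correlated toy inputs map to a large finite z rather than
    infinity.  The diagonal is set to zero and excluded from all comparisons.
    """
    series = run.series
    sd = series.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise DegenerateSeriesError(
            f"constant BOLD series for region index {bad[0]}"
        )
    r = np.corrcoef(series)
    r = np.clip(r, -R_CLIP, R_CLIP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0  # enforce exact symmetry against float asymmetry
    return FunctionalConnectome(z, region_ids)


def upper_triangle(fc: FunctionalConnectome | np.ndarray) -> np.ndarray:
    """Strictly-upper-triangular entries in row-major order, length n(n-1)/2."""
    m = fc.z_values if isinstance(fc, FunctionalConnectome) else np.asarray(fc)
    if m.shape[0] < 2:
        raise ValueError("need at least 2 regions")
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


# ---------------------------------------------------------------------------
# plain-text I/O


def read_matrix(path) -> np.ndarray:
    """Read a whitespace- or comma-delimited numeric grid.

    Raises :class:`MatrixParseError` with a 1-based line number on ragged rows
    or non-numeric cells.
    """
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            cells = line.replace(",", " ").split()
            try:
                rows.append([float(c) for c in cells])
            except ValueError as exc:
                raise MatrixParseError(f"{path}: non-numeric cell on line {lineno}") from exc
            if len(rows[-1]) != len(rows[0]):
                raise MatrixParseError(
                    f"{path}: ragged row on line {lineno} "
                    f"({len(rows[-1])} cells, expected {len(rows[0])})"
                )
    if not rows:
        raise MatrixParseError(f"{path}: empty matrix file")
    return np.asarray(rows, dtype=float)


def write_matrix(matrix: np.ndarray, path) -> None:
    """Write a matrix as plain text, one row per line, full double precision."""
    np.savetxt(path, np.asarray(matrix, dtype=float), fmt="%.17g")


def read_sidecar(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_sidecar(meta: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=1)
        fh.write("\n")


def sidecar_path(matrix_path) -> Path:
    return Path(matrix_path).with_suffix(".json")
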