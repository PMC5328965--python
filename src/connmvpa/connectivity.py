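"""Pearson connectivity matrices and Fisher-z feature vectors.

A regional time-series matrix (frames x regions) becomes a symmetric
Pearson correlation matrix; its upper triangle, Fisher z-transformed, is
the feature vector used for classification. With the standard 116-region
whole-brain parcellation this yields 116*115/2 = 6670 features.

Edge-indexing convention (used everywhere in this package): row-major
upper triangle with 1-based region IDs, i.e. feature k=1 is edge (1,2),
then (1,3), ..., (1,R), (2,3), ... This single convention keeps consensus
edge lists and region weights unambiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConnectivityMatrix",
    "FeatureVector",
    "correlation_matrix",
    "fisher_z",
    "vectorize_upper",
    "edge_index",
    "pair_index",
    "n_edges",
]

#: correlations with |r| at or beyond this are clipped before artanh
_R_CLIP = 1.0 - 1e-7
_SYM_TOL = 1e-8


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric Pearson correlation matrix over brain regions."""

    values: np.ndarray  # (R, R)
    region_ids: np.ndarray  # (R,), 1-based integer labels

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        ids = np.asarray(self.region_ids, dtype=int)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"correlation matrix must be square, got {v.shape}")
        if ids.shape != (v.shape[0],):
            raise ValueError("region_ids length must match matrix size")
        if not np.allclose(v, v.T, atol=_SYM_TOL):
            raise ValueError("correlation matrix is asymmetric beyond tolerance")
        if not np.allclose(np.diag(v), 1.0, atol=1e-8):
            raise ValueError("correlation matrix diagonal must be 1")
        if np.nanmax(np.abs(v)) > 1 + 1e-12:
            raise ValueError("correlation entries must lie in [-1, 1]")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "region_ids", ids)

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class FeatureVector:
    """Fisher-z upper-triangle feature vector with its edge table.

    ``edges[k]`` gives the (i, j) region-ID pair of feature k (0-based
    position; IDs 1-based, i < j, row-major order).
    """

    z: np.ndarray  # (R(R-1)/2,)
    region_ids: np.ndarray
    edges: np.ndarray = field(repr=False)  # (n_edges, 2) region-ID pairs

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        if not np.all(np.isfinite(z)):
            raise ValueError("feature vector contains non-finite values")
        object.__setattr__(self, "z", z)

    def __len__(self) -> int:
        return self.z.shape[0]


def n_edges(R: int) -> int:
    """Number of region-pair features for R regions: R(R-1)/2."""
    return R * (R - 1) // 2


def correlation_matrix(ts) -> ConnectivityMatrix:
    """Pearson correlation between every pair of regional time series.

    Parameters
    ----------
    ts : RoiTimeSeries
        Preprocessed frames x regions signal.

    Raises
    ------
    ValueError
        Fewer than 3 frames, or a constant-valued region column (its
        correlation is undefined) -- the error names the region.
    """
    x = np.asarray(ts.data, dtype=float)
    if x.shape[0] < 3:
        raise ValueError(f"need >= 3 frames for correlation, got {x.shape[0]}")
    sd = x.std(axis=0)
    if np.any(sd == 0):
        bad = [int(r) for r in np.asarray(ts.region_ids)[sd == 0]]
        raise ValueError(f"constant time series for region(s) {bad}: correlation undefined")
    r = np.corrcoef(x, rowvar=False)
    # corrcoef can exceed |1| by float eps
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    r = (r + r.T) / 2.0
    return ConnectivityMatrix(values=r, region_ids=np.asarray(ts.region_ids, dtype=int))


def fisher_z(r):
    """Fisher z-transform, z = artanh(r), variance-stabilizing a correlation.

    Values with |r| >= 1 - 1e-7 are clipped to that bound before the
    transform (degenerate, perfectly correlated synthetic series would
    otherwise map to infinity); a warning is emitted. |r| > 1 is an error.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1 + 1e-12):
        raise ValueError("correlation magnitude exceeds 1")
    if np.any(np.abs(r) >= _R_CLIP):
        warnings.warn("correlation at |r|~1 clipped before Fisher z", stacklevel=2)
    clipped = np.clip(r, -_R_CLIP, _R_CLIP)
    z = np.arctanh(clipped)
    return z if z.ndim else float(z)


def vectorize_upper(m: ConnectivityMatrix) -> FeatureVector:
    """Fisher-z vector of the row-major upper triangle (i < j).

    For R regions the result has length R(R-1)/2 (6670 at R=116). The
    diagonal is dropped; each off-diagonal correlation appears once.
    """
    R = m.n_regions
    iu, ju = np.triu_indices(R, k=1)  # row-major: (0,1),(0,2),...
    r_upper = m.values[iu, ju]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        z = np.arctanh(np.clip(r_upper, -_R_CLIP, _R_CLIP))
    edges = np.column_stack([m.region_ids[iu], m.region_ids[ju]])
    return FeatureVector(z=z, region_ids=np.asarray(m.region_ids, dtype=int), edges=edges)


def pair_index(i: int, j: int, R: int) -> int:
    """Feature index k (1-based) of region pair (i, j), i < j, under the
    row-major upper-triangle convention."""
    if not (1 <= i < j <= R):
        raise ValueError(f"need 1 <= i < j <= R, got (i={i}, j={j}, R={R})")
    return (i - 1) * (2 * R - i) // 2 + (j - i)


def edge_index(k: int, R: int) -> tuple[int, int]:
    """Region pair (i, j) of feature index k (1-based); inverse of pair_index."""
    m = n_edges(R)
    if not (1 <= k <= m):
        raise ValueError(f"feature index {k} out of range [1, {m}] for R={R}")
    # row i is the largest i with offset(i) < k, offset(i) = (i-1)(2R-i)/2
    i = 1
    while (i) * (2 * R - i - 1) // 2 < k:
        i += 1
    offset = (i - 1) * (2 * R - i) // 2
    j = i + (k - offset)
    return i, j
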