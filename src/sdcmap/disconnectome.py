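"""Lesion-induced structural disconnection.

A streamline is *disconnected* by a lesion when its path intersects any
lesioned voxel.  From the set of disconnected streamlines two summaries
are derived:

* the voxel-wise disconnection **severity map** — for each voxel, the
  percentage of streamlines traversing that voxel that the lesion
  disconnects;
* the **tract-wise** disconnection percentage — per tract, the share of
  its streamlines the lesion disconnects.

Streamline-to-voxel assignment uses exact 3-D digital differential
analysis: each polyline segment is cut at every integer voxel-plane
crossing and each sub-interval's midpoint is floored to a voxel index.
Voxel boxes are half-open ``[v, v + 1)``, so a point lying exactly on a
shared face belongs to the higher-index voxel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from sklearn.base import BaseEstimator, TransformerMixin

from .atlas import TractAtlas
from .grid import ReferenceGrid, VolumeImage

__all__ = [
    "DisconnectionSeverityMap",
    "DisconnectionMapper",
    "streamline_voxels",
    "find_disconnected",
    "disconnection_severity_map",
    "binarize_severity",
    "tract_disconnection",
    "lesion_volume",
]


# ----------------------------------------------------------------- traversal


def _polyline_voxels(u: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """Voxel indices traversed by a polyline given in voxel coordinates.

    Returns an (n, 3) int array ordered by first traversal, restricted
    to the grid.
    """
    u = np.asarray(u, float)
    if np.allclose(u, u[0]):
        warnings.warn("degenerate zero-length streamline; assigning single voxel")
        vox = np.floor(u[:1]).astype(int)
    else:
        chunks = []
        for p0, p1 in zip(u[:-1], u[1:]):
            ts = [0.0, 1.0]
            delta = p1 - p0
            for ax in range(3):
                if delta[ax] == 0.0:
                    continue
                lo, hi = sorted((p0[ax], p1[ax]))
                planes = np.arange(np.ceil(lo), np.floor(hi) + 1.0)
                t = (planes - p0[ax]) / delta[ax]
                ts.extend(t[(t > 0.0) & (t < 1.0)].tolist())
            ts = np.unique(np.asarray(ts))
            mids = (ts[:-1] + ts[1:]) / 2.0
            pts = p0[None, :] + mids[:, None] * delta[None, :]
            # segment endpoints land exactly on faces for axis-aligned input;
            # include them so single-voxel-wide crossings are not missed
            pts = np.vstack([p0[None, :], pts, p1[None, :]])
            chunks.append(np.floor(pts).astype(int))
        vox = np.vstack(chunks)
    inside = np.all((vox >= 0) & (vox < np.asarray(shape)), axis=1)
    vox = vox[inside]
    if vox.size == 0:
        return vox.reshape(0, 3)
    # unique, preserving traversal order
    flat = np.ravel_multi_index(vox.T, shape)
    _, first = np.unique(flat, return_index=True)
    return vox[np.sort(first)]


def streamline_voxels(streamline: np.ndarray, grid: ReferenceGrid) -> np.ndarray:
    """Ordered voxel indices whose boxes a world-mm polyline intersects."""
    pts = np.asarray(streamline, float)
    if not np.all(np.isfinite(pts)):
        raise ValueError("streamline contains non-finite points")
    return _polyline_voxels(grid.world_to_voxel(pts), grid.shape)


def streamline_incidence(
    atlas: TractAtlas, grid: ReferenceGrid
) -> sparse.csr_matrix:
    """Sparse streamline x voxel incidence matrix (flat voxel indexing)."""
    indptr = [0]
    indices: list[np.ndarray] = []
    for sl in atlas.streamlines:
        vox = streamline_voxels(sl, grid)
        flat = (
            np.ravel_multi_index(vox.T, grid.shape)
            if vox.size
            else np.empty(0, int)
        )
        indices.append(np.sort(flat))
        indptr.append(indptr[-1] + flat.size)
    data = np.ones(indptr[-1], dtype=np.uint8)
    return sparse.csr_matrix(
        (data, np.concatenate(indices) if indices else np.empty(0, int), indptr),
        shape=(atlas.n_streamlines, grid.n_voxels),
    )


# ---------------------------------------------------------------- summaries


@dataclass
class DisconnectionSeverityMap:
    """Per-voxel disconnection severity in percent, with denominators.

    ``severity`` is 0 wherever no streamline traverses the voxel
    (``denominator == 0``) and never exceeds 100.
    """

    severity: VolumeImage
    denominator: VolumeImage

    @property
    def grid(self) -> ReferenceGrid:
        return self.severity.grid


def _lesion_flat(lesion, grid: ReferenceGrid | None = None):
    if isinstance(lesion, VolumeImage):
        return np.asarray(lesion.data, bool).ravel(), lesion.grid
    arr = np.asarray(lesion, bool)
    if grid is None:
        raise ValueError("grid required when lesion is a bare array")
    if arr.shape != grid.shape:
        raise ValueError("lesion shape does not match grid")
    return arr.ravel(), grid


def find_disconnected(
    lesion, atlas: TractAtlas, grid: ReferenceGrid | None = None,
    incidence: sparse.csr_matrix | None = None,
) -> np.ndarray:
    """Indices of streamlines whose traversed voxels meet the lesion."""
    flat, grid = _lesion_flat(lesion, grid)
    if incidence is None:
        incidence = streamline_incidence(atlas, grid)
    hits = incidence @ flat.astype(np.int64)
    return np.flatnonzero(hits > 0)


def disconnection_severity_map(
    lesion, atlas: TractAtlas, grid: ReferenceGrid | None = None,
    incidence: sparse.csr_matrix | None = None,
) -> DisconnectionSeverityMap:
    """Voxel-wise percentage of traversing streamlines disconnected."""
    flat, grid = _lesion_flat(lesion, grid)
    if incidence is None:
        incidence = streamline_incidence(atlas, grid)
    disconnected = find_disconnected(flat.reshape(grid.shape), atlas, grid, incidence)
    denom = np.asarray(incidence.sum(axis=0)).ravel().astype(float)
    numer = np.asarray(incidence[disconnected].sum(axis=0)).ravel().astype(float)
    severity = np.zeros(grid.n_voxels)
    np.divide(numer, denom, out=severity, where=denom > 0)
    severity *= 100.0
    return DisconnectionSeverityMap(
        severity=VolumeImage(severity.reshape(grid.shape), grid),
        denominator=VolumeImage(denom.reshape(grid.shape), grid),
    )


def binarize_severity(
    severity_map, threshold_percent: float = 10.0
) -> np.ndarray:
    """Binarize a severity map at an inclusive percent threshold.

    Thresholds of 1, 10 and 20 are the first-class variants; any value
    in (0, 100] is accepted.
    """
    if not 0.0 < threshold_percent <= 100.0:
        raise ValueError("threshold_percent must lie in (0, 100]")
    if isinstance(severity_map, DisconnectionSeverityMap):
        data = severity_map.severity.data
    elif isinstance(severity_map, VolumeImage):
        data = severity_map.data
    else:
        data = np.asarray(severity_map)
    return (data >= threshold_percent).astype(np.uint8)


def tract_disconnection(
    lesion, atlas: TractAtlas, grid: ReferenceGrid | None = None,
    incidence: sparse.csr_matrix | None = None,
) -> np.ndarray:
    """Percent of each tract's streamlines disconnected; shape (n_tracts,)."""
    disconnected = find_disconnected(lesion, atlas, grid, incidence)
    hit = np.zeros(atlas.n_streamlines, bool)
    hit[disconnected] = True
    out = np.zeros(atlas.n_tracts)
    for t in range(1, atlas.n_tracts + 1):
        members = atlas.tract_labels == t
        out[t - 1] = 100.0 * hit[members].sum() / members.sum()
    return out


def lesion_volume(lesion, brain_mask=None, grid: ReferenceGrid | None = None):
    """Lesion volume in cm^3 and as a fraction of the brain mask.

    The brain mask defaults to the full grid.  Lesion voxels outside
    the brain mask are counted with a warning.
    """
    flat, grid = _lesion_flat(lesion, grid)
    if brain_mask is None:
        brain_flat = np.ones(grid.n_voxels, bool)
    else:
        brain_flat, _ = _lesion_flat(brain_mask, grid)
    if brain_flat.sum() == 0:
        raise ValueError("brain mask is empty")
    if np.any(flat & ~brain_flat):
        warnings.warn("lesion voxels fall outside the brain mask; counted anyway")
    n = int(flat.sum())
    volume_cm3 = n * grid.voxel_volume_mm3 / 1000.0
    fraction = n / int(brain_flat.sum())
    return volume_cm3, fraction


# ---------------------------------------------------------------- estimator


class DisconnectionMapper(BaseEstimator, TransformerMixin):
    """Transform binary lesion masks into disconnection severity maps.

    Parameters
    ----------
    atlas : TractAtlas
        The streamline atlas the lesions are embedded into.
    grid : ReferenceGrid
        Common grid of the lesions and the atlas.

    After :meth:`fit`, ``incidence_`` holds the streamline-by-voxel
    sparse incidence matrix and ``denominator_`` the per-voxel
    streamline counts.
    """

    def __init__(self, atlas: TractAtlas = None, grid: ReferenceGrid = None):
        self.atlas = atlas
        self.grid = grid

    def fit(self, X=None, y=None):
        if self.atlas is None or self.grid is None:
            raise ValueError("atlas and grid are required")
        self.incidence_ = streamline_incidence(self.atlas, self.grid)
        self.denominator_ = (
            np.asarray(self.incidence_.sum(axis=0)).ravel().astype(float)
        )
        return self

    def _check_fitted(self):
        if not hasattr(self, "incidence_"):
            self.fit()

    def transform(self, X) -> np.ndarray:
        """Severity maps for a stack of lesions.

        Parameters
        ----------
        X : (n_lesions, nx, ny, nz) boolean array

        Returns
        -------
        (n_lesions, nx, ny, nz) float array of severities in percent.
        """
        self._check_fitted()
        X = np.asarray(X, bool)
        if X.ndim == 3:
            X = X[None]
        n = X.shape[0]
        flat = sparse.csr_matrix(X.reshape(n, -1).astype(np.uint8))
        hit = (self.incidence_ @ flat.T).toarray() > 0  # streamlines x lesions
        numer = (
            sparse.csr_matrix(hit.T.astype(np.int64)) @ self.incidence_
        ).toarray().astype(float)
        severity = np.zeros_like(numer, dtype=float)
        np.divide(
            numer, self.denominator_[None, :], out=severity,
            where=self.denominator_[None, :] > 0,
        )
        severity *= 100.0
        return severity.reshape((n,) + self.grid.shape)

    def severity_map(self, lesion) -> DisconnectionSeverityMap:
        self._check_fitted()
        return disconnection_severity_map(
            lesion, self.atlas, self.grid, incidence=self.incidence_
        )

    def tract_severities(self, X) -> np.ndarray:
        """Tract-wise disconnection percents for a lesion stack; (n, T)."""
        self._check_fitted()
        X = np.asarray(X, bool)
        if X.ndim == 3:
            X = X[None]
        n = X.shape[0]
        flat = sparse.csr_matrix(X.reshape(n, -1).astype(np.uint8))
        hit = (self.incidence_ @ flat.T).toarray() > 0  # S x n
        out = np.zeros((n, self.atlas.n_tracts))
        for t in range(1, self.atlas.n_tracts + 1):
            members = self.atlas.tract_labels == t
            out[:, t - 1] = 100.0 * hit[members].sum(axis=0) / members.sum()
        return out
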