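"""Mass-univariate voxel mapping (VLSM / VDSM).

The same machinery serves voxel-based lesion-symptom mapping (binary
lesion masks as input) and voxel-based disconnection-symptom mapping
(binarized disconnection maps as input): build an inclusion mask of
voxels affected in enough patients, test each included voxel's 2x2
association with the binary outcome using the one-tailed Liebermeister
quasi-exact test, control the family-wise error by the permutation
max-Z distribution, and apply a permutation-derived cluster-extent
threshold at a fixed cluster-forming p.

The Liebermeister test is computed as the exact one-sided
hypergeometric tail of the augmented table (a+1, b, c, d+1) — the
standard quasi-exact formulation used by lesion-mapping toolkits — and
converted to a Z score by the inverse normal CDF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import hypergeom, norm
from sklearn.base import BaseEstimator

from .grid import ReferenceGrid

__all__ = [
    "MappingResult",
    "LesionSymptomMapper",
    "liebermeister_test",
    "liebermeister_z_table",
    "inclusion_mask",
    "min_count_from_fraction",
    "voxelwise_z_map",
    "permutation_fwe_threshold",
    "cluster_extent_threshold",
    "significant_clusters",
    "descriptive_maps",
]

#: Z values are clipped to +/- Z_CAP (the inverse-normal of ~1e-16) so
#: perfectly separating voxels stay finite and representable.
Z_CAP = 8.2


# ------------------------------------------------------------ exact test


def liebermeister_test(a: int, b: int, c: int, d: int, z_cap: float = Z_CAP):
    """One-tailed Liebermeister test on a 2x2 table.

    Table layout: ``a`` affected & outcome=1, ``b`` affected &
    outcome=0, ``c`` unaffected & outcome=1, ``d`` unaffected &
    outcome=0.  The tail is fixed so enrichment of affected status
    among outcome=1 patients yields a small p and a large positive Z.

    Returns
    -------
    (p_value, z_score)
    """
    a, b, c, d = (int(x) for x in (a, b, c, d))
    if min(a, b, c, d) < 0:
        raise ValueError("table cells must be nonnegative")
    n = a + b + c + d
    if n < 1:
        raise ValueError("empty table")
    if a + b == 0 or a + c == 0:
        # degenerate margins: no affected patients or no events
        return 1.0, -z_cap
    # augmented table (a+1, b, c, d+1): total n+2, affected a+b+1, events a+c+1
    p = float(hypergeom.sf(a, n + 2, a + b + 1, a + c + 1))
    p = min(max(p, 0.0), 1.0)
    z = float(np.clip(norm.isf(max(p, 1e-300)), -z_cap, z_cap))
    return p, z


def liebermeister_z_table(
    n_patients: int, n_events: int, z_cap: float = Z_CAP
) -> np.ndarray:
    """Z lookup ``z[k, a]`` for all tables with fixed N and event count.

    ``k`` is the number of affected patients at a voxel and ``a`` the
    number of affected events; entries with impossible ``(k, a)`` are
    NaN.  Label permutations keep both margins fixed, so one table
    serves every permutation of a mapping run.
    """
    N, n1 = int(n_patients), int(n_events)
    k = np.arange(N + 1)[:, None]
    a = np.arange(N + 1)[None, :]
    valid = (a <= k) & (a <= n1) & (k - a <= N - n1)
    with np.errstate(all="ignore"):
        p = hypergeom.sf(a, N + 2, k + 1, n1 + 1)
    p = np.clip(p, 1e-300, 1.0)
    z = np.clip(norm.isf(p), -z_cap, z_cap)
    z = np.where(valid, z, np.nan)
    z[0, :] = np.where(valid[0, :], -z_cap, np.nan)  # degenerate: no affected
    if n1 == 0:
        z[:, 0] = -z_cap
    return z


# ---------------------------------------------------------- inclusion mask


def min_count_from_fraction(fraction: float, n_patients: int) -> int:
    """Convert an inclusion fraction to a minimum patient count (ceil)."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    return int(np.ceil(fraction * n_patients))


def _as_stack(maps) -> np.ndarray:
    X = np.asarray(maps)
    if X.ndim != 4:
        raise ValueError("expected a (n_patients, nx, ny, nz) stack of maps")
    return X.astype(bool)


def inclusion_mask(maps, min_count: int) -> np.ndarray:
    """Voxels affected in at least ``min_count`` patients."""
    X = _as_stack(maps)
    if min_count > X.shape[0]:
        warnings.warn("min_count exceeds the number of patients; empty mask")
    counts = X.sum(axis=0)
    return counts >= min_count


# ------------------------------------------------------------- z map


def _check_outcome(outcome, n) -> np.ndarray:
    y = np.asarray(outcome).astype(int).ravel()
    if y.shape[0] != n:
        raise ValueError("outcome length does not match number of maps")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome has a single class")
    return y


def voxelwise_z_map(maps, outcome, inclusion: np.ndarray, z_cap: float = Z_CAP):
    """Liebermeister Z at every included voxel; NaN elsewhere."""
    X = _as_stack(maps)
    y = _check_outcome(outcome, X.shape[0])
    incl = np.asarray(inclusion, bool)
    flat = X.reshape(X.shape[0], -1)[:, incl.ravel()]
    k = flat.sum(axis=0)
    a = (flat & (y[:, None] > 0)).sum(axis=0)
    lut = liebermeister_z_table(X.shape[0], int(y.sum()), z_cap)
    z = lut[k, a]
    out = np.full(incl.shape, np.nan)
    out[incl] = z
    return out


# ----------------------------------------------------- permutation engine


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError("connectivity must be 6 or 26")


def _max_cluster_size(binary_vol: np.ndarray, structure: np.ndarray) -> int:
    labels, n = ndimage.label(binary_vol, structure=structure)
    if n == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


def _permutation_nulls(
    flat_incl: np.ndarray,
    y: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    lut: np.ndarray,
    incl: np.ndarray,
    z_form: float,
    structure: np.ndarray,
    chunk: int = 256,
):
    """Max-Z and max-cluster-size permutation nulls in one pass.

    Only the outcome labels are permuted; the maps are never modified.
    """
    N = y.shape[0]
    k = flat_incl.sum(axis=0).astype(np.intp)
    Xf = flat_incl.T.astype(np.float32)  # V_incl x N
    max_z = np.empty(n_perm)
    max_cs = np.empty(n_perm, dtype=int)
    flat_idx = np.flatnonzero(incl.ravel())
    vol = np.zeros(incl.shape, dtype=bool)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        P = rng.permuted(np.tile(y, (m, 1)), axis=1).astype(np.float32)  # m x N
        A = np.rint(Xf @ P.T).astype(np.intp)  # V_incl x m
        Z = lut[k[:, None], A]
        max_z[done : done + m] = Z.max(axis=0) if Z.size else -np.inf
        if np.isinf(z_form):
            max_cs[done : done + m] = 0
        else:
            supra = Z >= z_form
            for j in range(m):
                vol.ravel()[flat_idx] = supra[:, j]
                max_cs[done + j] = _max_cluster_size(vol, structure)
                vol.ravel()[flat_idx] = False
        done += m
    return max_z, max_cs


def permutation_fwe_threshold(
    maps, outcome, inclusion, n_perm: int = 10_000, alpha: float = 0.05,
    seed=None, z_cap: float = Z_CAP,
) -> float:
    """FWE Z threshold: (1 - alpha) quantile of the permutation max-Z null."""
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    X = _as_stack(maps)
    y = _check_outcome(outcome, X.shape[0])
    incl = np.asarray(inclusion, bool)
    lut = liebermeister_z_table(X.shape[0], int(y.sum()), z_cap)
    flat = X.reshape(X.shape[0], -1)[:, incl.ravel()]
    rng = np.random.default_rng(seed)
    max_z, _ = _permutation_nulls(
        flat, y, n_perm, rng, lut, incl, np.inf, _connectivity_structure(26)
    )
    return float(np.quantile(max_z, 1.0 - alpha, method="higher"))


def cluster_extent_threshold(
    maps, outcome, inclusion, n_perm: int = 10_000,
    cluster_forming_p: float = 0.001, seed=None, connectivity: int = 26,
    z_cap: float = Z_CAP,
) -> int:
    """Minimal cluster size from the permutation max-cluster-size null.

    Per permutation the Z map is thresholded at the cluster-forming
    Z (= inverse normal of 1 - cluster_forming_p), components labelled,
    and the largest recorded; the threshold is the smallest integer
    exceeding the null's 95th percentile.
    """
    if not 0.0 < cluster_forming_p <= 0.05:
        raise ValueError("cluster_forming_p must lie in (0, 0.05]")
    X = _as_stack(maps)
    y = _check_outcome(outcome, X.shape[0])
    incl = np.asarray(inclusion, bool)
    lut = liebermeister_z_table(X.shape[0], int(y.sum()), z_cap)
    flat = X.reshape(X.shape[0], -1)[:, incl.ravel()]
    rng = np.random.default_rng(seed)
    z_form = float(norm.isf(cluster_forming_p))
    _, max_cs = _permutation_nulls(
        flat, y, n_perm, rng, lut, incl, z_form,
        _connectivity_structure(connectivity),
    )
    return int(np.floor(np.percentile(max_cs, 95.0))) + 1


# ------------------------------------------------------------- clusters


def significant_clusters(
    z_map: np.ndarray, fwe_z_threshold: float, cluster_min_size: int,
    connectivity: int = 26,
):
    """Label suprathreshold voxels into clusters and tabulate them.

    Components smaller than ``cluster_min_size`` are dropped; the table
    is sorted by size descending with ties broken by peak Z.  Returns
    ``(cluster_mask, cluster_table)`` where the mask labels clusters
    1..K in table order.
    """
    if not (np.isfinite(fwe_z_threshold) and np.isfinite(cluster_min_size)):
        raise ValueError("thresholds must be finite")
    z = np.asarray(z_map, float)
    supra = np.nan_to_num(z, nan=-np.inf) >= fwe_z_threshold
    labels, n = ndimage.label(supra, structure=_connectivity_structure(connectivity))
    rows = []
    for lab in range(1, n + 1):
        idx = np.argwhere(labels == lab)
        size = idx.shape[0]
        if size < cluster_min_size:
            continue
        zvals = z[tuple(idx.T)]
        peak = int(np.argmax(zvals))
        rows.append(
            {
                "size": size,
                "peak_z": float(zvals[peak]),
                "peak_voxel": tuple(int(v) for v in idx[peak]),
                "_old_label": lab,
            }
        )
    rows.sort(key=lambda r: (-r["size"], -r["peak_z"]))
    mask = np.zeros(z.shape, dtype=np.int32)
    table_rows = []
    for new_label, row in enumerate(rows, start=1):
        mask[labels == row.pop("_old_label")] = new_label
        table_rows.append({"label": new_label, **row})
    table = pd.DataFrame(
        table_rows, columns=["label", "size", "peak_z", "peak_voxel"]
    )
    return mask, table


def descriptive_maps(maps, outcome):
    """Overlap, per-class prevalence (%) and subtraction maps."""
    X = _as_stack(maps)
    y = _check_outcome(outcome, X.shape[0])
    overlap = X.sum(axis=0)
    prev_pos = 100.0 * X[y == 1].mean(axis=0)
    prev_neg = 100.0 * X[y == 0].mean(axis=0)
    return overlap, prev_pos, prev_neg, prev_pos - prev_neg


# ------------------------------------------------------------- estimator


@dataclass
class MappingResult:
    """Everything a fitted voxel mapping produces."""

    inclusion_mask: np.ndarray
    z_map: np.ndarray
    fwe_z_threshold: float
    cluster_min_size: int
    cluster_mask: np.ndarray
    cluster_table: pd.DataFrame
    n_permutations: int
    seed: object
    alpha: float
    cluster_forming_p: float
    connectivity: int
    min_count: int
    fitted_ids: tuple | None = None
    map_id: str = field(default="")

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_table)

    def significant_z(self) -> np.ndarray:
        """Z values on cluster voxels (all positive by the one-tailed design)."""
        return self.z_map[self.cluster_mask > 0]


class LesionSymptomMapper(BaseEstimator):
    """Mass-univariate voxel mapper (the VLSM/VDSM engine).

    Fit on a stack of binary per-patient maps ``X`` of shape
    ``(n_patients, nx, ny, nz)`` and a binary outcome ``y``.  Fitted
    attributes carry the inclusion mask, the Liebermeister Z map, the
    permutation FWE Z threshold, the permutation cluster-extent
    threshold, and the surviving clusters.

    Parameters
    ----------
    min_count : int
        Minimum number of affected patients for a voxel to enter the
        analysis (ignored when ``min_fraction`` is set).
    min_fraction : float, optional
        Inclusion threshold as a fraction of patients (ceil).
    alpha : float
        Voxel-level FWE level.
    cluster_forming_p : float
        Cluster-forming p for the extent threshold.
    n_permutations : int
        Label permutations for both permutation nulls.
    connectivity : {26, 6}
        Neighbourhood for cluster labelling.
    random_state : int or None
        Seed for the permutation generator.
    """

    def __init__(
        self,
        min_count: int = 5,
        min_fraction: float | None = None,
        alpha: float = 0.05,
        cluster_forming_p: float = 0.001,
        n_permutations: int = 1000,
        connectivity: int = 26,
        z_cap: float = Z_CAP,
        random_state=None,
    ):
        self.min_count = min_count
        self.min_fraction = min_fraction
        self.alpha = alpha
        self.cluster_forming_p = cluster_forming_p
        self.n_permutations = n_permutations
        self.connectivity = connectivity
        self.z_cap = z_cap
        self.random_state = random_state

    def fit(self, X, y, patient_ids=None):
        X = _as_stack(X)
        y = _check_outcome(y, X.shape[0])
        n = X.shape[0]
        min_count = (
            min_count_from_fraction(self.min_fraction, n)
            if self.min_fraction is not None
            else int(self.min_count)
        )
        incl = inclusion_mask(X, min_count)
        self.inclusion_mask_ = incl
        self.z_map_ = voxelwise_z_map(X, y, incl, self.z_cap)

        lut = liebermeister_z_table(n, int(y.sum()), self.z_cap)
        flat = X.reshape(n, -1)[:, incl.ravel()]
        rng = np.random.default_rng(self.random_state)
        z_form = float(norm.isf(self.cluster_forming_p))
        max_z, max_cs = _permutation_nulls(
            flat, y, int(self.n_permutations), rng, lut, incl, z_form,
            _connectivity_structure(self.connectivity),
        )
        self.fwe_z_threshold_ = float(
            np.quantile(max_z, 1.0 - self.alpha, method="higher")
        )
        self.cluster_min_size_ = int(np.floor(np.percentile(max_cs, 95.0))) + 1
        self.cluster_mask_, self.cluster_table_ = significant_clusters(
            self.z_map_, self.fwe_z_threshold_, self.cluster_min_size_,
            self.connectivity,
        )
        self.fitted_ids_ = (
            tuple(patient_ids) if patient_ids is not None else None
        )
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        map_id = (
            f"mapping-n{n}-perm{self.n_permutations}-seed{self.random_state}"
        )
        self.result_ = MappingResult(
            inclusion_mask=incl,
            z_map=self.z_map_,
            fwe_z_threshold=self.fwe_z_threshold_,
            cluster_min_size=self.cluster_min_size_,
            cluster_mask=self.cluster_mask_,
            cluster_table=self.cluster_table_,
            n_permutations=int(self.n_permutations),
            seed=self.random_state,
            alpha=self.alpha,
            cluster_forming_p=self.cluster_forming_p,
            connectivity=self.connectivity,
            min_count=min_count,
            fitted_ids=self.fitted_ids_,
            map_id=map_id,
        )
        return self
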