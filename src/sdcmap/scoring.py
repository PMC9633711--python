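"""Patient-level structural disconnection (SDC) score.

The score collapses a significant VDSM map and a patient's continuous
disconnection severity map into one scalar: the sum over significant
cluster voxels of the voxel Z score weighted by the patient's
disconnection severity at that voxel (severity entered as a fraction,
percent / 100).  The log transform used downstream is ``ln(1 + raw)``
so patients with no overlap (raw = 0) remain defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .mapping import MappingResult

__all__ = ["SDCScore", "SDCScorer", "LeakageError", "sdc_score", "risk_tertiles"]


class LeakageError(RuntimeError):
    """Raised when a patient is scored against a mapping fitted on them."""


@dataclass(frozen=True)
class SDCScore:
    raw: float
    transformed: float
    n_overlap_voxels: int
    source_map_id: str = ""


def sdc_score(
    significant_z: np.ndarray,
    severity: np.ndarray,
    cluster_mask: np.ndarray | None = None,
    source_map_id: str = "",
) -> SDCScore:
    """Weighted sum of significant-voxel Z scores.

    Parameters
    ----------
    significant_z : array
        Either a full Z map (with ``cluster_mask`` selecting the
        significant voxels) or a vector of Z values aligned with the
        mask's nonzero voxels.
    severity : array
        The patient's continuous severity map in percent, same grid.
    cluster_mask : array, optional
        Labelled/binary mask of significant voxels.
    """
    sev = np.asarray(severity, float)
    if cluster_mask is not None:
        mask = np.asarray(cluster_mask) > 0
        zfull = np.asarray(significant_z, float)
        if zfull.shape == mask.shape:
            z = zfull[mask]
        else:
            z = zfull.ravel()
            if z.shape[0] != int(mask.sum()):
                raise ValueError("z vector does not match mask voxel count")
        if sev.shape != mask.shape:
            raise ValueError("severity map grid does not match the mask")
        w = sev[mask] / 100.0
    else:
        z = np.asarray(significant_z, float).ravel()
        w = sev.ravel() / 100.0
        if z.shape != w.shape:
            raise ValueError("z values and severities must align")
    if np.any(z < 0):
        raise ValueError(
            "negative Z inside the significant mask; the mask must be "
            "one-tailed-significant"
        )
    raw = float(np.sum(z * w))
    return SDCScore(
        raw=raw,
        transformed=float(np.log1p(raw)),
        n_overlap_voxels=int(np.count_nonzero(w)),
        source_map_id=source_map_id,
    )


def risk_tertiles(scores) -> np.ndarray:
    """Tertile group labels ('low'/'medium'/'high') for a score vector.

    Cut points at the 1/3 and 2/3 empirical quantiles; ties at a cut
    point go to the lower group.
    """
    s = np.asarray(scores, float)
    if s.shape[0] < 3:
        raise ValueError("at least 3 patients required for tertiles")
    if np.all(s == s[0]):
        warnings.warn("all scores identical; single 'low' risk group")
        return np.full(s.shape, "low", dtype=object)
    q1, q2 = np.quantile(s, [1.0 / 3.0, 2.0 / 3.0])
    out = np.full(s.shape, "high", dtype=object)
    out[s <= q2] = "medium"
    out[s <= q1] = "low"
    return out


class SDCScorer(BaseEstimator, TransformerMixin):
    """Transform continuous severity maps into SDC scores.

    Parameters
    ----------
    mapping : MappingResult or fitted LesionSymptomMapper
        The significance map supplying cluster voxels and Z weights.

    ``transform`` returns the log-transformed scores; ``score_records``
    returns full :class:`SDCScore` objects.  When patient identifiers
    are supplied and the mapping records the identifiers it was fitted
    on, scoring a patient against a mapping fitted on a sample
    containing them raises :class:`LeakageError` — the cross-fit
    discipline of split-half validation is enforced mechanically.
    """

    def __init__(self, mapping=None):
        self.mapping = mapping

    def _result(self) -> MappingResult:
        m = self.mapping
        if m is None:
            raise ValueError("a fitted mapping is required")
        if isinstance(m, MappingResult):
            return m
        if hasattr(m, "result_"):
            return m.result_
        raise TypeError("mapping must be a MappingResult or fitted mapper")

    def fit(self, X=None, y=None):
        res = self._result()
        self.cluster_mask_ = res.cluster_mask > 0
        self.z_values_ = res.z_map[self.cluster_mask_]
        self.source_map_id_ = res.map_id
        self.fitted_ids_ = res.fitted_ids
        return self

    def score_records(self, severity_maps, patient_ids=None) -> list[SDCScore]:
        if not hasattr(self, "cluster_mask_"):
            self.fit()
        X = np.asarray(severity_maps, float)
        if X.ndim == 3:
            X = X[None]
        if patient_ids is not None and self.fitted_ids_ is not None:
            overlap = set(patient_ids) & set(self.fitted_ids_)
            if overlap:
                raise LeakageError(
                    f"patients {sorted(overlap)[:5]} were in the sample the "
                    "mapping was fitted on; cross-fit scoring forbids this"
                )
        return [
            sdc_score(
                self.z_values_,
                sev[self.cluster_mask_],
                source_map_id=self.source_map_id_,
            )
            for sev in X
        ]

    def transform(self, severity_maps, patient_ids=None) -> np.ndarray:
        """Log-transformed SDC scores, one per severity map."""
        records = self.score_records(severity_maps, patient_ids)
        return np.asarray([r.transformed for r in records])
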