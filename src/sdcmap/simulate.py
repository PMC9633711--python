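"""Synthetic study generator.

Produces a fully self-contained study — reference grid, multi-bundle
streamline atlas, spatially clustered lesions, Table-1-style
covariates, and a depression outcome with a *planted* effect of
structural disconnection — so every downstream stage (severity maps,
VDSM, SDC scoring, prediction models) can be exercised and calibrated
without any external data.

The planted outcome model is a convention of this package, not a claim
about any real cohort: depression status is Bernoulli with

    logit p = beta0 + beta_sdc * exposure + beta_cov' * covariates

where *exposure* is the patient's mean disconnection fraction (percent
/ 100) over the designated planted tracts.  The total HDRS-like
symptom score is drawn so that the >= 10 cutoff reproduces the binary
outcome exactly, and 5 of the 14 individual symptom flags are coupled
to disconnection while the other 9 are independent noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.interpolate import CubicSpline
from scipy.special import expit, logit

from .atlas import TractAtlas
from .disconnectome import DisconnectionMapper, streamline_voxels
from .grid import ReferenceGrid, VolumeImage

__all__ = [
    "SimulationConfig",
    "SyntheticStudy",
    "default_grid",
    "generate_atlas",
    "generate_lesions",
    "generate_covariates",
    "simulate_outcomes",
    "simulate_study",
    "write_study",
]

#: Base rate of the outcome: prevalence 27.8% when all slopes are zero.
DEFAULT_BETA0 = float(logit(0.278))

#: Nominal (center, scale) used to standardize covariates inside the
#: outcome model, fixed so the planted effect does not depend on the
#: realized sample.
_COVARIATE_SCALES = {
    "age": (59.0, 10.0),
    "sex_female": (0.0, 1.0),
    "education_years": (9.5, 3.5),
    "nihss": (3.0, 3.0),
    "bi": (80.0, 25.0),
    "moca": (20.0, 4.5),
    "neuroticism": (9.0, 3.5),
    "extraversion": (11.0, 4.0),
}

N_SYMPTOMS = 14


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; fixed seed gives identical output."""

    n_patients: int = 200
    n_tracts: int = 8
    streamlines_per_tract: int = 50
    lesion_radius_range: tuple[float, float] = (6.0, 16.0)  # mm
    planted_tracts: tuple[int, ...] = (1, 2)
    fraction_on_planted: float = 0.5
    beta0: float = DEFAULT_BETA0
    beta_sdc: float = 2.0
    beta_covariates: dict = field(
        default_factory=lambda: {
            "sex_female": 0.4,
            "education_years": -0.2,
            "nihss": 0.3,
            "bi": -0.3,
            "moca": -0.3,
            "neuroticism": 0.35,
            "extraversion": -0.15,
        }
    )
    hdrs_noise: float = 2.0
    bundle_jitter_mm: float = 3.0
    coupled_symptoms: tuple[int, ...] = (1, 2, 8, 10, 13)  # 1-based indices
    symptom_coupling_strength: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 20:
            raise ValueError("n_patients must be at least 20")
        if not self.planted_tracts:
            raise ValueError("planted_tracts must be nonempty")
        if any(t < 1 or t > self.n_tracts for t in self.planted_tracts):
            raise ValueError("planted_tracts must be a subset of tract labels")
        if len(self.coupled_symptoms) > N_SYMPTOMS:
            raise ValueError("too many coupled symptoms")

    # three independent streams so e.g. changing n_patients never
    # perturbs the atlas
    def _streams(self):
        atlas_ss, lesion_ss, outcome_ss = np.random.SeedSequence(
            self.seed
        ).spawn(3)
        return (
            np.random.default_rng(atlas_ss),
            np.random.default_rng(lesion_ss),
            np.random.default_rng(outcome_ss),
        )

    def to_yaml(self, path) -> None:
        d = asdict(self)
        for key in ("lesion_radius_range", "planted_tracts", "coupled_symptoms"):
            d[key] = list(d[key])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("lesion_radius_range", "planted_tracts", "coupled_symptoms"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def default_grid() -> ReferenceGrid:
    """24^3 voxels at 4 mm isotropic — the default study space."""
    return ReferenceGrid(shape=(24, 24, 24), voxel_size=(4.0, 4.0, 4.0))


# ------------------------------------------------------------------- atlas


def generate_atlas(grid: ReferenceGrid, config: SimulationConfig) -> TractAtlas:
    """Bundles of smooth jittered polylines along distinct corridors.

    Each tract runs face-to-face along one grid axis through its own
    interior lane; streamlines are cubic-spline curves through jittered
    control points, clipped to the grid's world bounding box.
    """
    if config.n_tracts < 2:
        raise ValueError("at least 2 tracts required")
    rng = config._streams()[0]
    lanes_per_axis = int(np.ceil(config.n_tracts / 3))
    if lanes_per_axis > min(grid.shape) - 4:
        raise ValueError(
            f"grid too small to route {config.n_tracts} disjoint bundle "
            f"corridors: needs {lanes_per_axis} lanes per axis but the "
            f"minimum interior extent is {min(grid.shape) - 4} voxels"
        )
    lo, hi = grid.world_bounds()
    extent = hi - lo
    eps = 1e-6 * extent.max()
    margin = 0.08 * extent
    n_ctrl = 5
    streamlines: list[np.ndarray] = []
    labels: list[int] = []
    for t in range(1, config.n_tracts + 1):
        axis = (t - 1) % 3
        lane = (t - 1) // 3
        cross = [ax for ax in range(3) if ax != axis]
        # deterministic lane offsets spread over the interior cross-section
        frac = (lane + 1) / (lanes_per_axis + 1)
        base = np.zeros((n_ctrl, 3))
        base[:, axis] = np.linspace(
            lo[axis] + margin[axis], hi[axis] - margin[axis], n_ctrl
        )
        for ci, ax in enumerate(cross):
            center = lo[ax] + (0.25 + 0.5 * frac) * extent[ax] if ci == 0 \
                else lo[ax] + (0.35 + 0.3 * frac) * extent[ax]
            wobble = rng.normal(0.0, 0.10 * extent[ax], n_ctrl)
            base[:, ax] = center + wobble
        s = base[:, axis]
        n_samples = 3 * grid.shape[axis]
        dense = np.linspace(s[0], s[-1], n_samples)
        for _ in range(config.streamlines_per_tract):
            ctrl = base + rng.normal(0.0, config.bundle_jitter_mm, base.shape)
            ctrl[:, axis] = s  # keep the along-axis parameterization monotone
            spline = CubicSpline(s, ctrl, axis=0)
            pts = spline(dense)
            pts = np.clip(pts, lo + eps, hi - eps)
            streamlines.append(pts)
            labels.append(t)
    return TractAtlas(streamlines=streamlines, tract_labels=np.asarray(labels))


# ------------------------------------------------------------------ lesions


def _planted_corridor_mask(
    grid: ReferenceGrid, atlas: TractAtlas, planted: tuple[int, ...]
) -> np.ndarray:
    mask = np.zeros(grid.shape, bool)
    for sl, lab in zip(atlas.streamlines, atlas.tract_labels):
        if lab in planted:
            vox = streamline_voxels(sl, grid)
            if vox.size:
                mask[tuple(vox.T)] = True
    return mask


_WORLD_CENTER_CACHE: dict[ReferenceGrid, np.ndarray] = {}


def _voxel_center_world(grid: ReferenceGrid) -> np.ndarray:
    world = _WORLD_CENTER_CACHE.get(grid)
    if world is None:
        centers = (
            np.stack(
                np.meshgrid(*[np.arange(s) for s in grid.shape], indexing="ij"),
                axis=-1,
            )
            + 0.5
        )
        world = centers * np.asarray(grid.voxel_size) + np.asarray(grid.origin)
        _WORLD_CENTER_CACHE[grid] = world
    return world


def _ellipsoid(grid: ReferenceGrid, center_mm, radii_mm) -> np.ndarray:
    world = _voxel_center_world(grid)
    dist = np.sum(((world - np.asarray(center_mm)) / np.asarray(radii_mm)) ** 2, axis=-1)
    mask = dist <= 1.0
    if not mask.any():  # guarantee a nonempty, single-voxel lesion
        vox = np.clip(
            np.floor(grid.world_to_voxel(center_mm)[0]).astype(int),
            0,
            np.asarray(grid.shape) - 1,
        )
        mask[tuple(vox)] = True
    return mask


def generate_lesions(
    grid: ReferenceGrid, config: SimulationConfig, atlas: TractAtlas | None = None
) -> np.ndarray:
    """Stack of connected ellipsoidal lesion masks, (n, nx, ny, nz) bool.

    A ``fraction_on_planted`` share of lesions is centred on points of
    planted-tract streamlines (guaranteed to intersect the corridor);
    the rest are rejection-sampled to *miss* the planted corridors, so
    ``fraction_on_planted = 0`` yields no planted-tract disconnection.
    """
    r_lo, r_hi = config.lesion_radius_range
    lo, hi = grid.world_bounds()
    if not 0 < r_lo <= r_hi or r_hi >= (hi - lo).min() / 2:
        raise ValueError(
            "lesion_radius_range must lie within (0, min grid extent / 2)"
        )
    rng = config._streams()[1]
    if atlas is None:
        atlas = generate_atlas(grid, config)
    corridor = _planted_corridor_mask(grid, atlas, tuple(config.planted_tracts))
    planted_points = np.vstack(
        [
            sl
            for sl, lab in zip(atlas.streamlines, atlas.tract_labels)
            if lab in config.planted_tracts
        ]
    )
    masks = np.zeros((config.n_patients,) + grid.shape, bool)
    for i in range(config.n_patients):
        on_planted = rng.random() < config.fraction_on_planted
        radii = rng.uniform(r_lo, r_hi, size=3)
        if on_planted:
            center = planted_points[rng.integers(planted_points.shape[0])]
            center = center + rng.normal(0.0, 2.0, 3)
            center = np.clip(center, lo + radii * 0.1, hi - radii * 0.1)
            mask = _ellipsoid(grid, center, radii)
        else:
            mask = None
            for _ in range(500):
                center = rng.uniform(lo + 0.1 * (hi - lo), hi - 0.1 * (hi - lo))
                cand = _ellipsoid(grid, center, radii)
                if not np.any(cand & corridor):
                    mask = cand
                    break
                radii = np.maximum(radii * 0.8, r_lo * 0.5)
            if mask is None:
                raise RuntimeError(
                    "could not place a lesion off the planted corridors"
                )
        masks[i] = mask
    return masks


# --------------------------------------------------------------- covariates


def generate_covariates(
    config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Covariates with realistic marginals; NIHSS and BI negatively coupled."""
    n = config.n_patients
    age = np.clip(np.rint(rng.normal(59, 10, n)), 18, 90)
    sex_female = (rng.random(n) < 0.207).astype(int)
    education = np.clip(np.rint(rng.normal(9.5, 3.5, n)), 0, 20)
    nihss = np.clip(np.rint(rng.lognormal(np.log(3.0), 0.8, n)), 0, 30)
    bi = np.clip(np.rint(100 - 6.0 * nihss + rng.normal(0, 15, n)), 0, 100)
    moca = np.clip(np.rint(rng.normal(20, 4.5, n)), 0, 30)
    neuroticism = np.clip(np.rint(rng.normal(9, 3.5, n)), 0, 24)
    extraversion = np.clip(np.rint(rng.normal(11, 4, n)), 0, 24)
    timing = rng.choice(
        np.arange(1, 8), size=n, p=[0.10, 0.20, 0.30, 0.20, 0.10, 0.06, 0.04]
    )
    return pd.DataFrame(
        {
            "age": age,
            "sex": np.where(sex_female == 1, "female", "male"),
            "education_years": education,
            "nihss": nihss,
            "bi": bi,
            "moca": moca,
            "neuroticism": neuroticism,
            "extraversion": extraversion,
            "timing_of_imaging_days": timing,
        }
    )


def _localization(grid: ReferenceGrid, lesions: np.ndarray) -> list[str]:
    """Lesion localization from geometry: x is left-right, low z infratentorial."""
    nx, _, nz = grid.shape
    out = []
    for mask in lesions:
        idx = np.argwhere(mask)
        zc = idx[:, 2].mean()
        left = idx[:, 0] < nx / 2
        if zc < nz / 4:
            out.append("infratentorial")
        elif left.all():
            out.append("left")
        elif (~left).all():
            out.append("right")
        else:
            out.append("bihemispheric")
    return out


# ----------------------------------------------------------------- outcomes


def simulate_outcomes(
    planted_exposure: np.ndarray,
    covariates: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    symptom_exposures: np.ndarray | None = None,
) -> pd.DataFrame:
    """Draw (hdrs_total, psd, symptom flags) from the planted model.

    ``planted_exposure`` is the per-patient mean disconnection fraction
    of the planted tracts in [0, 1].  ``symptom_exposures`` optionally
    supplies a distinct exposure per coupled symptom (column per
    symptom index), enabling anterior/posterior coupling.
    """
    if rng is None:
        rng = config._streams()[2]
    exposure = np.asarray(planted_exposure, float).ravel()
    n = exposure.shape[0]
    if len(covariates) != n:
        raise ValueError("exposure and covariates must align by patient")
    sex_female = (
        (covariates["sex"] == "female").astype(float)
        if "sex" in covariates
        else covariates["sex_female"].astype(float)
    )
    std = {"sex_female": sex_female.to_numpy()}
    for name in _COVARIATE_SCALES:
        if name in covariates.columns:
            center, scale = _COVARIATE_SCALES[name]
            std[name] = (covariates[name].to_numpy(float) - center) / scale
    eta = config.beta0 + config.beta_sdc * exposure
    for name, beta in config.beta_covariates.items():
        if name not in std:
            raise ValueError(f"unknown covariate in beta_covariates: {name}")
        eta = eta + beta * std[name]
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite logit in the outcome model")
    psd = (rng.random(n) < expit(eta)).astype(int)
    # severity score consistent with the cutoff: >= 10 iff psd
    base = expit(eta)
    noise = rng.normal(0.0, config.hdrs_noise, n)
    hdrs = np.where(
        psd == 1,
        np.clip(np.rint(11 + 8 * base + noise), 10, 52),
        np.clip(np.rint(3 + 5 * base + noise), 0, 9),
    ).astype(int)
    flags = {}
    coupled = set(config.coupled_symptoms)
    for k in range(1, N_SYMPTOMS + 1):
        if k in coupled:
            exp_k = (
                symptom_exposures[:, k - 1]
                if symptom_exposures is not None
                else exposure
            )
            p_k = expit(-1.2 + config.symptom_coupling_strength * exp_k)
        else:
            p_k = np.full(n, 0.2)
        flags[f"symptom_{k}"] = (rng.random(n) < p_k).astype(int)
    return pd.DataFrame({"hdrs_total": hdrs, "psd": psd, **flags})


# -------------------------------------------------------------- full study


@dataclass
class SyntheticStudy:
    """Everything one simulated study comprises, in memory."""

    config: SimulationConfig
    grid: ReferenceGrid
    atlas: TractAtlas
    lesions: np.ndarray             # (n, nx, ny, nz) bool
    severity: np.ndarray            # (n, nx, ny, nz) float percent
    tract_severities: np.ndarray    # (n, n_tracts) percent
    exposure: np.ndarray            # (n,) planted-tract fraction
    cohort: pd.DataFrame

    @property
    def patient_ids(self) -> list[str]:
        return list(self.cohort["patient_id"])


def simulate_study(
    config: SimulationConfig, grid: ReferenceGrid | None = None
) -> SyntheticStudy:
    """Generate atlas, lesions, severity maps, covariates and outcomes."""
    if grid is None:
        grid = default_grid()
    atlas = generate_atlas(grid, config)
    lesions = generate_lesions(grid, config, atlas)
    mapper = DisconnectionMapper(atlas=atlas, grid=grid).fit()
    severity = mapper.transform(lesions)
    tract_sev = mapper.tract_severities(lesions)
    planted_idx = [t - 1 for t in config.planted_tracts]
    exposure = tract_sev[:, planted_idx].mean(axis=1) / 100.0

    _, _, outcome_rng = config._streams()
    covariates = generate_covariates(config, outcome_rng)
    outcomes = simulate_outcomes(exposure, covariates, config, rng=outcome_rng)

    n = config.n_patients
    vox_cm3 = grid.voxel_volume_mm3 / 1000.0
    cohort = pd.concat(
        [
            pd.DataFrame(
                {
                    "patient_id": [f"p{i + 1:04d}" for i in range(n)],
                }
            ),
            covariates,
            pd.DataFrame(
                {
                    "lesion_volume_cm3": lesions.reshape(n, -1).sum(axis=1)
                    * vox_cm3,
                    "lesion_localization": _localization(grid, lesions),
                }
            ),
            outcomes,
        ],
        axis=1,
    )
    return SyntheticStudy(
        config=config,
        grid=grid,
        atlas=atlas,
        lesions=lesions,
        severity=severity,
        tract_severities=tract_sev,
        exposure=exposure,
        cohort=cohort,
    )


def write_study(study: SyntheticStudy, outdir) -> None:
    """Write lesions (NIfTI-1), atlas (TRK + JSON-lines), cohort CSV, config YAML."""
    outdir = Path(outdir)
    lesion_dir = outdir / "lesions"
    lesion_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for pid, mask in zip(study.patient_ids, study.lesions):
        path = lesion_dir / f"{pid}_lesion.nii.gz"
        VolumeImage(mask.astype(np.uint8), study.grid).save(path)
        paths.append(str(path.relative_to(outdir)))
    study.atlas.save_trk(outdir / "atlas.trk", study.grid)
    study.atlas.save_jsonl(outdir / "atlas.jsonl")
    cohort = study.cohort.copy()
    cohort["lesion_ref"] = paths
    cohort.to_csv(outdir / "cohort.csv", index=False)
    study.config.to_yaml(outdir / "config.yaml")
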