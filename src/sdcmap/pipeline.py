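"""End-to-end study orchestration.

Runs the whole analysis on one cohort: descriptive lesion maps and
laterality comparison, voxel-based lesion-symptom mapping (VLSM),
voxel-based disconnection-symptom mapping (VDSM), SDC scoring and
Models 1-3, split-half cross-fitted validation with basic/enhanced
prediction models (AUC, NRI, IDI, dominance analysis), tract-wise
rank-sum comparison with FDR correction, and symptom-level VDSM.

Cross-fit discipline is enforced mechanically: in the split-half
analysis a patient's SDC score is derived only from the mapping fitted
on the *other* half, and the scorer raises if this is violated.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .disconnectome import binarize_severity
from .grid import VolumeImage
from .mapping import LesionSymptomMapper, MappingResult, descriptive_maps
from .models import (
    ModelFit,
    ReclassificationResult,
    chi_square_test,
    compare_models,
    dominance_general,
    fdr_correct,
    fit_logistic,
    model_specs,
    rank_sum_test,
)
from .scoring import SDCScorer, risk_tertiles
from .simulate import N_SYMPTOMS, SimulationConfig, SyntheticStudy, simulate_study

__all__ = [
    "SplitPlan",
    "CrossFitResult",
    "split_half",
    "run_crossfit",
    "run_symptom_vdsm",
    "run_tractwise",
    "run_study",
    "predict_probabilities",
]

logger = logging.getLogger("sdcmap")


# ------------------------------------------------------------- split plan


@dataclass(frozen=True)
class SplitPlan:
    seed: int
    assignment: tuple[str, ...]  # 'dataset1' / 'dataset2' per patient

    @property
    def sizes(self) -> tuple[int, int]:
        a = np.asarray(self.assignment)
        return int((a == "dataset1").sum()), int((a == "dataset2").sum())

    def indices(self, which: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.assignment) == which)


def split_half(n_patients: int, seed: int) -> SplitPlan:
    """Uniform random balanced split; sizes differ by at most one."""
    if n_patients < 6:
        raise ValueError("at least 6 patients required for a split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_patients)
    n1 = int(np.ceil(n_patients / 2))
    assignment = np.full(n_patients, "dataset2", dtype=object)
    assignment[order[:n1]] = "dataset1"
    return SplitPlan(seed=int(seed), assignment=tuple(assignment))


# --------------------------------------------------------------- crossfit


def predict_probabilities(fit: ModelFit, design: pd.DataFrame) -> np.ndarray:
    """Out-of-sample predicted probabilities from a fitted model."""
    eta = fit.intercept + design[fit.names].to_numpy(float) @ (
        fit.coefficients[fit.names].to_numpy()
    )
    return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class CrossFitResult:
    plan: SplitPlan
    mappings: dict[str, MappingResult]
    scores_log: np.ndarray          # pooled, opposite-half provenance
    score_group_test: tuple[float, float]
    tertiles: np.ndarray
    tertile_prevalence_test: tuple[float, float]
    tertile_severity_test: tuple[float, float]
    model_fits: dict                # direction -> {'basic','enhanced'}
    aucs: dict                      # direction -> train/test AUCs
    reclassification: dict          # direction -> {'train','test'} results
    per_half_model3_or: dict
    dominance_mean: pd.Series
    seeds: dict = field(default_factory=dict)


def run_crossfit(
    cohort: pd.DataFrame,
    binary_maps: np.ndarray,
    severity_maps: np.ndarray,
    plan: SplitPlan,
    min_fraction: float = 0.05,
    n_permutations: int = 1000,
    seeds: tuple[int, int] = (11, 12),
) -> CrossFitResult:
    """Split-half cross-fitted validation of the SDC score."""
    y = cohort["psd"].to_numpy(int)
    ids = np.asarray(cohort["patient_id"], dtype=object)
    halves = {"dataset1": plan.indices("dataset1"), "dataset2": plan.indices("dataset2")}
    for name, idx in halves.items():
        if len(np.unique(y[idx])) < 2:
            raise ValueError(f"{name} contains a single outcome class")

    mappings: dict[str, MappingResult] = {}
    for (name, idx), seed in zip(halves.items(), seeds):
        mapper = LesionSymptomMapper(
            min_fraction=min_fraction,
            n_permutations=n_permutations,
            random_state=int(seed),
        ).fit(binary_maps[idx], y[idx], patient_ids=ids[idx])
        mappings[name] = mapper.result_
        logger.info(
            "crossfit %s: FWE Z=%.3f, min cluster=%d, clusters=%d",
            name, mapper.fwe_z_threshold_, mapper.cluster_min_size_,
            mapper.result_.n_clusters,
        )

    # opposite-half scoring with mechanical leakage enforcement
    scores = np.empty(len(cohort))
    opposite = {"dataset1": "dataset2", "dataset2": "dataset1"}
    for name, idx in halves.items():
        scorer = SDCScorer(mapping=mappings[opposite[name]]).fit()
        scores[idx] = scorer.transform(
            severity_maps[idx], patient_ids=ids[idx]
        )

    score_test = rank_sum_test(scores[y == 1], scores[y == 0])
    tertiles = risk_tertiles(scores)
    groups = ["low", "medium", "high"]
    table = np.array(
        [
            [int(((tertiles == g) & (y == v)).sum()) for v in (0, 1)]
            for g in groups
            if (tertiles == g).sum() > 0
        ]
    )
    tert_prev = chi_square_test(table.T) if table.shape[0] >= 2 else (np.nan, np.nan)
    hdrs = cohort["hdrs_total"].to_numpy(float)
    present = [g for g in groups if (tertiles == g).sum() > 0]
    if len(present) >= 2:
        from scipy.stats import kruskal

        sev = kruskal(*[hdrs[tertiles == g] for g in present])
        tert_sev = (float(sev.statistic), float(sev.pvalue))
    else:
        tert_sev = (np.nan, np.nan)

    # per-half fully adjusted model for the SDC score
    per_half_or = {}
    for name, idx in halves.items():
        if np.ptp(scores[idx]) == 0.0:
            # no significant clusters in the opposite half: the score
            # carries no information and cannot enter the model
            per_half_or[name] = {"or": float("nan"), "p": float("nan")}
            continue
        sub = cohort.iloc[idx].reset_index(drop=True)
        specs = model_specs(sub, scores[idx])
        fit3 = fit_logistic(specs["model3"], y[idx], compute_vif=False)
        per_half_or[name] = {
            "or": float(fit3.odds_ratios.loc["sdc_score_log", "or"]),
            "p": float(fit3.p_values["sdc_score_log"]),
        }

    # basic vs enhanced, trained in one half and tested in the other
    model_fits, aucs, reclass = {}, {}, {}
    dominances = []
    from .models import auc as auc_fn

    for train, test in (("dataset1", "dataset2"), ("dataset2", "dataset1")):
        tr, te = halves[train], halves[test]
        specs_tr = model_specs(cohort.iloc[tr].reset_index(drop=True), scores[tr])
        specs_te = model_specs(cohort.iloc[te].reset_index(drop=True), scores[te])
        basic = fit_logistic(specs_tr["basic"], y[tr], compute_vif=True)
        if np.ptp(scores[tr]) == 0.0:
            # degenerate: constant score adds nothing; the enhanced
            # model collapses onto the basic one
            enhanced = basic
        else:
            enhanced = fit_logistic(specs_tr["enhanced"], y[tr], compute_vif=True)
        direction = f"train_{train}"
        model_fits[direction] = {"basic": basic, "enhanced": enhanced}
        p_basic_te = predict_probabilities(basic, specs_te["basic"])
        p_enh_te = predict_probabilities(
            enhanced, specs_te["enhanced" if enhanced is not basic else "basic"]
        )
        aucs[direction] = {
            "basic_train": basic.auc,
            "enhanced_train": enhanced.auc,
            "basic_test": auc_fn(p_basic_te, y[te]),
            "enhanced_test": auc_fn(p_enh_te, y[te]),
        }
        from .models import category_free_nri, idi as idi_fn

        nri_te, nri_ci_te, nri_p_te = category_free_nri(p_basic_te, p_enh_te, y[te])
        idi_te, idi_ci_te, idi_p_te = idi_fn(p_basic_te, p_enh_te, y[te])
        reclass[direction] = {
            "train": compare_models(basic, enhanced, y[tr]),
            "test": ReclassificationResult(
                nri=nri_te, nri_ci=tuple(nri_ci_te), nri_p=nri_p_te,
                idi=idi_te, idi_ci=tuple(idi_ci_te), idi_p=idi_p_te,
            ),
        }
        dom_design = specs_tr["enhanced" if enhanced is not basic else "basic"]
        dominances.append(
            dominance_general(dom_design, y[tr]).general_dominance
        )

    dominance_mean = pd.concat(dominances, axis=1).mean(axis=1)

    return CrossFitResult(
        plan=plan,
        mappings=mappings,
        scores_log=scores,
        score_group_test=score_test,
        tertiles=tertiles,
        tertile_prevalence_test=tert_prev,
        tertile_severity_test=tert_sev,
        model_fits=model_fits,
        aucs=aucs,
        reclassification=reclass,
        per_half_model3_or=per_half_or,
        dominance_mean=dominance_mean,
        seeds={"split": plan.seed, "mappings": list(seeds)},
    )


# ----------------------------------------------------- symptoms and tracts


def run_symptom_vdsm(
    cohort: pd.DataFrame,
    binary_maps: np.ndarray,
    symptom_index: int,
    min_fraction: float = 0.05,
    n_permutations: int = 1000,
    random_state=None,
) -> MappingResult | None:
    """VDSM with one binary symptom flag as the outcome.

    Returns None (with a warning) for single-class symptoms.
    """
    if not 1 <= symptom_index <= N_SYMPTOMS:
        raise ValueError(f"symptom index must lie in 1..{N_SYMPTOMS}")
    flag = cohort[f"symptom_{symptom_index}"].to_numpy(int)
    if flag.min() == flag.max():
        import warnings

        warnings.warn(f"symptom {symptom_index} has a single class; skipped")
        return None
    mapper = LesionSymptomMapper(
        min_fraction=min_fraction,
        n_permutations=n_permutations,
        random_state=random_state,
    ).fit(binary_maps, flag, patient_ids=cohort["patient_id"])
    return mapper.result_


def run_tractwise(outcome, tract_severities: np.ndarray) -> pd.DataFrame:
    """Per-tract rank-sum comparison with BH-FDR across tracts."""
    y = np.asarray(outcome).astype(int).ravel()
    sev = np.asarray(tract_severities, float)
    if sev.shape[0] != y.shape[0]:
        raise ValueError("tract severities not aligned with the cohort")
    stats_, ps = [], []
    for t in range(sev.shape[1]):
        v = sev[:, t]
        if np.all(v == v[0]):
            stats_.append(np.nan)
            ps.append(1.0)
            continue
        s, p = rank_sum_test(v[y == 1], v[y == 0])
        stats_.append(s)
        ps.append(p)
    adj = fdr_correct(ps)
    return pd.DataFrame(
        {
            "tract_label": np.arange(1, sev.shape[1] + 1),
            "statistic": stats_,
            "p_value": ps,
            "p_fdr": adj,
            "significant": adj < 0.05,
        }
    )


# -------------------------------------------------------------- full study


def _reclass_dict(r: ReclassificationResult) -> dict:
    return {
        "nri": r.nri, "nri_ci": list(r.nri_ci), "nri_p": r.nri_p,
        "idi": r.idi, "idi_ci": list(r.idi_ci), "idi_p": r.idi_p,
    }


def _json_safe(obj):
    if isinstance(obj, dict):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_json_safe(v) for v in obj.tolist()]
    if isinstance(obj, pd.Series):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    return obj


def run_study(
    config: SimulationConfig,
    n_permutations: int = 1000,
    min_fraction: float = 0.05,
    vlsm_min_count: int = 5,
    binarize_threshold: float = 10.0,
    outdir=None,
    symptom_level: bool = True,
) -> dict:
    """Simulate a cohort and run the complete analysis; returns the report.

    All permutation and split seeds are derived deterministically from
    ``config.seed``; a fixed configuration yields byte-identical
    reports.
    """
    t0 = time.time()
    seeds = np.random.SeedSequence([config.seed, 2023]).generate_state(24)
    study: SyntheticStudy = simulate_study(config)
    cohort = study.cohort
    y = cohort["psd"].to_numpy(int)
    logger.info("simulated cohort n=%d, PSD prevalence %.1f%%",
                len(cohort), 100 * y.mean())

    report: dict = {
        "config": {"n_patients": config.n_patients, "seed": config.seed,
                   "n_tracts": config.n_tracts,
                   "planted_tracts": list(config.planted_tracts),
                   "beta_sdc": config.beta_sdc},
        "n_permutations": n_permutations,
        "prevalence_percent": float(100 * y.mean()),
        "timings_s": {},
    }

    # descriptive lesion analyses + laterality
    overlap, prev_pos, prev_neg, subtraction = descriptive_maps(study.lesions, y)
    loc = cohort["lesion_localization"].to_numpy()
    lat_mask = np.isin(loc, ["left", "right"])
    lat = {}
    if lat_mask.sum() >= 4:
        table = np.array(
            [
                [int(((loc == h) & (y == v) & lat_mask).sum()) for v in (0, 1)]
                for h in ("left", "right")
            ]
        )
        if table.sum(axis=1).min() > 0:
            stat, p = chi_square_test(table)
            lat = {
                "left_prevalence_percent": 100.0 * table[0, 1] / table[0].sum(),
                "right_prevalence_percent": 100.0 * table[1, 1] / table[1].sum(),
                "chi2": stat, "p": p,
            }
    report["laterality"] = lat
    report["timings_s"]["descriptive"] = round(time.time() - t0, 3)

    # VLSM on raw lesion masks
    t1 = time.time()
    vlsm = LesionSymptomMapper(
        min_count=vlsm_min_count, n_permutations=n_permutations,
        random_state=int(seeds[0]),
    ).fit(study.lesions, y, patient_ids=study.patient_ids)
    report["vlsm"] = {
        "fwe_z_threshold": vlsm.fwe_z_threshold_,
        "cluster_min_size": vlsm.cluster_min_size_,
        "n_clusters": vlsm.result_.n_clusters,
        "n_included_voxels": int(vlsm.inclusion_mask_.sum()),
    }
    report["timings_s"]["vlsm"] = round(time.time() - t1, 3)

    # VDSM on binarized disconnection maps
    t1 = time.time()
    binary = binarize_severity(study.severity, binarize_threshold)
    vdsm = LesionSymptomMapper(
        min_fraction=min_fraction, n_permutations=n_permutations,
        random_state=int(seeds[1]),
    ).fit(binary, y, patient_ids=study.patient_ids)
    report["vdsm"] = {
        "fwe_z_threshold": vdsm.fwe_z_threshold_,
        "cluster_min_size": vdsm.cluster_min_size_,
        "n_clusters": vdsm.result_.n_clusters,
        "n_included_voxels": int(vdsm.inclusion_mask_.sum()),
    }
    report["timings_s"]["vdsm"] = round(time.time() - t1, 3)

    # whole-sample SDC scores and Models 1-3
    t1 = time.time()
    scorer = SDCScorer(mapping=vdsm.result_).fit()
    scores = scorer.transform(study.severity)
    models_report = {}
    if np.ptp(scores) == 0.0:
        # no significant VDSM clusters: the score is uninformative and
        # cannot enter a regression
        models_report = {
            name: {"degenerate": True} for name in ("model1", "model2", "model3")
        }
    else:
        specs = model_specs(cohort, scores)
        for name in ("model1", "model2", "model3"):
            fit = fit_logistic(specs[name], y, compute_vif=(name == "model3"))
            entry = {
                "sdc_or": float(fit.odds_ratios.loc["sdc_score_log", "or"]),
                "sdc_or_ci": [
                    float(fit.odds_ratios.loc["sdc_score_log", "ci_low"]),
                    float(fit.odds_ratios.loc["sdc_score_log", "ci_high"]),
                ],
                "sdc_p": float(fit.p_values["sdc_score_log"]),
                "auc": fit.auc,
                "epv": fit.epv,
            }
            if fit.vifs is not None:
                entry["vif_max"] = float(fit.vifs.max())
            models_report[name] = entry
    report["models"] = models_report
    report["timings_s"]["models"] = round(time.time() - t1, 3)

    # split-half cross-fitted validation
    t1 = time.time()
    plan = split_half(len(cohort), seed=int(seeds[2]))
    crossfit = run_crossfit(
        cohort, binary, study.severity, plan,
        min_fraction=min_fraction, n_permutations=n_permutations,
        seeds=(int(seeds[3]), int(seeds[4])),
    )
    mean_auc = {
        key: float(np.mean([crossfit.aucs[d][key] for d in crossfit.aucs]))
        for key in ("basic_train", "basic_test", "enhanced_train", "enhanced_test")
    }
    report["crossfit"] = {
        "sizes": list(plan.sizes),
        "score_rank_sum_p": crossfit.score_group_test[1],
        "tertile_prevalence_p": crossfit.tertile_prevalence_test[1],
        "tertile_severity_p": crossfit.tertile_severity_test[1],
        "per_half_model3_or": crossfit.per_half_model3_or,
        "mean_auc": mean_auc,
        "reclassification": {
            d: {phase: _reclass_dict(r) for phase, r in res.items()}
            for d, res in crossfit.reclassification.items()
        },
        "dominance_mean": crossfit.dominance_mean.to_dict(),
        "dominance_top": crossfit.dominance_mean.idxmax(),
    }
    report["timings_s"]["crossfit"] = round(time.time() - t1, 3)

    # tract-wise comparison
    t1 = time.time()
    tractwise = run_tractwise(y, study.tract_severities)
    report["tractwise"] = {
        "n_significant": int(tractwise["significant"].sum()),
        "significant_tracts": [
            int(t) for t in tractwise.loc[tractwise["significant"], "tract_label"]
        ],
        "min_p_fdr_tract": int(
            tractwise.loc[tractwise["p_fdr"].idxmin(), "tract_label"]
        ),
    }
    report["timings_s"]["tractwise"] = round(time.time() - t1, 3)

    # symptom-level VDSM
    if symptom_level:
        t1 = time.time()
        symptoms = {}
        for k in range(1, N_SYMPTOMS + 1):
            res = run_symptom_vdsm(
                cohort, binary, k, min_fraction=min_fraction,
                n_permutations=n_permutations, random_state=int(seeds[5 + k]),
            )
            symptoms[f"symptom_{k}"] = (
                {"n_clusters": res.n_clusters} if res is not None
                else {"n_clusters": 0, "skipped": True}
            )
        report["symptom_vdsm"] = symptoms
        report["timings_s"]["symptoms"] = round(time.time() - t1, 3)

    report["timings_s"]["total"] = round(time.time() - t0, 3)
    report = _json_safe(report)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        # volumetric outputs
        grid = study.grid
        VolumeImage(overlap.astype(np.int16), grid).save(outdir / "lesion_overlap.nii.gz")
        VolumeImage(subtraction.astype(np.float32), grid).save(
            outdir / "lesion_subtraction.nii.gz"
        )
        VolumeImage(np.nan_to_num(vdsm.z_map_).astype(np.float32), grid).save(
            outdir / "vdsm_z.nii.gz"
        )
        VolumeImage(vdsm.cluster_mask_.astype(np.int16), grid).save(
            outdir / "vdsm_clusters.nii.gz"
        )
        vdsm.cluster_table_.to_csv(outdir / "vdsm_clusters.tsv", sep="\t", index=False)
        vlsm.cluster_table_.to_csv(outdir / "vlsm_clusters.tsv", sep="\t", index=False)
        tractwise.to_csv(outdir / "tractwise.tsv", sep="\t", index=False)
        scores_df = pd.DataFrame(
            {
                "patient_id": cohort["patient_id"],
                "sdc_score_log": scores,
                "crossfit_score_log": crossfit.scores_log,
                "risk_tertile": crossfit.tertiles,
            }
        )
        scores_df.to_csv(outdir / "scores.csv", index=False)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        with open(outdir / "report.txt", "w") as fh:
            fh.write(format_report(report))
    return report


def format_report(report: dict) -> str:
    """Human-readable one-page summary of a study report."""
    lines = [
        "Structural disconnection study report",
        "=" * 40,
        f"patients: {report['config']['n_patients']}  "
        f"seed: {report['config']['seed']}",
        f"PSD prevalence: {report['prevalence_percent']:.1f}%",
        "",
        f"VLSM: FWE Z >= {report['vlsm']['fwe_z_threshold']:.3f}, "
        f"cluster >= {report['vlsm']['cluster_min_size']} voxels, "
        f"{report['vlsm']['n_clusters']} significant cluster(s)",
        f"VDSM: FWE Z >= {report['vdsm']['fwe_z_threshold']:.3f}, "
        f"cluster >= {report['vdsm']['cluster_min_size']} voxels, "
        f"{report['vdsm']['n_clusters']} significant cluster(s)",
        "",
    ]
    for name, m in report["models"].items():
        if m.get("degenerate"):
            lines.append(f"{name}: score degenerate (no significant clusters)")
            continue
        lines.append(
            f"{name}: SDC OR {m['sdc_or']:.3f} "
            f"({m['sdc_or_ci'][0]:.3f}, {m['sdc_or_ci'][1]:.3f}), "
            f"p = {m['sdc_p']:.4g}"
        )
    cf = report.get("crossfit", {})
    if cf:
        lines += [
            "",
            f"split-half sizes: {cf['sizes']}",
            f"cross-fitted score rank-sum p: {cf['score_rank_sum_p']:.4g}",
            "mean AUC: basic {basic_train:.3f}/{basic_test:.3f} "
            "enhanced {enhanced_train:.3f}/{enhanced_test:.3f} "
            "(train/test)".format(**cf["mean_auc"]),
            f"top predictor by general dominance: {cf['dominance_top']}",
        ]
    tw = report.get("tractwise", {})
    if tw:
        lines.append(
            f"tract-wise: {tw['n_significant']} significant tract(s) "
            f"{tw['significant_tracts']}"
        )
    return "\n".join(lines) + "\n"
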