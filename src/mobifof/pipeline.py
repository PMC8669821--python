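"""End-to-end orchestration: simulate -> detect -> features -> statistics.

The default cohort run uses the timeline fast path (ground-truth events
without raw-signal synthesis); raw-signal synthesis plus full detection
is available for small runs via ``synthesize_signals`` and is validated
separately by the detection-recovery tests.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import detect, lab, stats
from .config import RunConfig, dump_config
from .daily import DayEvents, HOME_FEATURES, build_daily_feature_set
from .lab import LAB_FEATURES, analyze_lab_session, lab_result_from_timeline
from .simulate import GroupEffectConfig, SubjectData, generate_cohort
from .stats import (assign_fof_group, effect_size_r, effect_size_table,
                    loso_classify, paired_lab_home, select_features,
                    split_feature_sets)

#: lab/home parameter pairs compared between settings (Table-5 analog)
LAB_HOME_PAIRS = (
    [("V_TUG_avg", h) for h in ("V_ALL_P50", "V_ALL_P95", "V_mu1", "V_mu2",
                                "V_SWB_P50", "V_SWB_P95", "V_MWB_P50",
                                "V_MWB_P95", "V_LWB_P50", "V_LWB_P95")]
    + [(l, h) for l in ("P_TUG", "P_5xSTS_N", "P_5xSTS_F")
       for h in ("P_H_P50", "P_H_P95")]
    + [(l, h) for l in ("omega_TUG_1", "omega_TUG_2")
       for h in ("omega_H_P50", "omega_H_P95")]
)


def subject_features(sub: SubjectData, seed: int = 0,
                     use_signals: bool = False) -> dict:
    """Covariates plus the 41 mobility parameters for one subject."""
    row = {
        "subject_id": sub.subject_id,
        "fes_i": sub.spec.fes_i,
        "fof_group": assign_fof_group(sub.spec.fes_i),
        "gender": 0 if sub.spec.gender == "male" else 1,
        "updrs_iii": sub.spec.updrs_iii,
        "body_mass": sub.spec.body_mass,
        "height": sub.spec.height,
    }
    if use_signals and sub.lab_recording is not None:
        row.update(analyze_lab_session(sub.lab_recording, sub.spec.body_mass,
                                       sub.spec.height))
    else:
        row.update(lab_result_from_timeline(sub.lab_timeline))

    days = []
    for rec, tl in sub.daily:
        if use_signals and rec is not None:
            frame = detect.resolve_frame(rec)
            days.append(DayEvents(
                wear_hours=rec.duration / 3600.0,
                bouts=detect.detect_walking_bouts(rec, height=sub.spec.height,
                                                  frame=frame),
                sit_to_stands=[t for t in detect.detect_postural_transitions(
                    rec, sub.spec.body_mass, frame=frame)
                    if t.kind == "sit_to_stand"],
                turns=detect.detect_turns(rec, frame=frame)))
        else:
            days.append(DayEvents.from_timeline(tl))
    row.update(build_daily_feature_set(days, seed=seed))
    return row


def cohort_feature_table(subjects: list, seed: int = 0,
                         use_signals: bool = False) -> pd.DataFrame:
    """Subjects x (covariates + 41 features) table, the substrate of the
    statistics layer."""
    rows = [subject_features(s, seed=seed, use_signals=use_signals)
            for s in subjects]
    return pd.DataFrame(rows)


def run_statistics(cohort: pd.DataFrame, seed: int = 0,
                   tree_params: dict | None = None,
                   screen_threshold: float = 0.2,
                   selection_in_folds: bool = False) -> dict:
    """The full statistics layer on a cohort feature table."""
    all_features = LAB_FEATURES + list(HOME_FEATURES)
    usable = [f for f in all_features if cohort[f].notna().all()]
    es = effect_size_table(cohort, usable)

    f1 = select_features(cohort, usable, seed=seed, threshold=screen_threshold,
                         tree_params=tree_params)
    f2, f3 = split_feature_sets(f1)
    reports = {}
    for name, feats in (("F1", f1), ("F2", f2), ("F3", f3)):
        if feats:
            if selection_in_folds and name == "F1":
                reports[name] = _loso_with_inner_selection(
                    cohort, usable, seed, screen_threshold, tree_params)
            else:
                reports[name] = loso_classify(cohort, feats, seed=seed,
                                              feature_set=name,
                                              tree_params=tree_params)

    paired_rows, ratio_rows = [], []
    for lab_f, home_f in LAB_HOME_PAIRS:
        if lab_f not in usable or home_f not in usable:
            continue
        per_group = {}
        for group in ("FOF+", "FOF-"):
            res = paired_lab_home(cohort, lab_f, home_f, group)
            per_group[group] = res
            paired_rows.append({
                "lab": lab_f, "home": home_f, "group": group,
                "signed_rank_p": res.signed_rank_p, "rho": res.rho,
                "rho_band": res.rho_band, "flag": res.flag,
            })
        r = effect_size_r(per_group["FOF+"].ratio_values,
                          per_group["FOF-"].ratio_values)
        ratio_rows.append({
            "lab": lab_f, "home": home_f, "ratio_effect_size_r": r,
            "ratio_median_fof_pos": float(np.median(per_group["FOF+"].ratio_values)),
            "ratio_median_fof_neg": float(np.median(per_group["FOF-"].ratio_values)),
        })

    return {
        "effect_sizes": es,
        "feature_sets": {"F1": f1, "F2": f2, "F3": f3},
        "classification": reports,
        "paired": pd.DataFrame(paired_rows),
        "ratios": pd.DataFrame(ratio_rows),
        "n_tests_run": len(usable) + len(paired_rows) + len(ratio_rows),
    }


def _loso_with_inner_selection(cohort, features, seed, threshold, tree_params):
    """Honest variant: feature selection re-run inside every training fold."""
    from sklearn.metrics import roc_auc_score
    from sklearn.tree import DecisionTreeClassifier

    y = (cohort["fof_group"] == "FOF+").to_numpy(int)
    n = len(y)
    preds, probas = np.empty(n, int), np.empty(n, float)
    for i in range(n):
        train = cohort.drop(index=cohort.index[i])
        feats = select_features(train, features, seed=seed, threshold=threshold,
                                tree_params=tree_params) or features
        clf = DecisionTreeClassifier(random_state=seed,
                                     **dict(stats.DEFAULT_TREE_PARAMS,
                                            **(tree_params or {})))
        clf.fit(train[feats].to_numpy(float), y[np.arange(n) != i])
        Xi = cohort.iloc[i:i + 1][feats].to_numpy(float)
        preds[i] = int(clf.predict(Xi)[0])
        cls = list(clf.classes_)
        probas[i] = float(clf.predict_proba(Xi)[0, cls.index(1)]) if 1 in cls else 0.0
    tp = int(((preds == 1) & (y == 1)).sum()); tn = int(((preds == 0) & (y == 0)).sum())
    fp = int(((preds == 1) & (y == 0)).sum()); fn = int(((preds == 0) & (y == 1)).sum())
    pct = lambda a, b: 100.0 * a / b if b else float("nan")
    return stats.ClassificationReport(
        feature_set="F1(selection-in-folds)", features=list(features),
        sensitivity=pct(tp, tp + fn), specificity=pct(tn, tn + fp),
        precision=pct(tp, tp + fp), accuracy=pct(tp + tn, n),
        auc=float(roc_auc_score(y, probas)), y_true=y, y_pred=preds,
        y_proba=probas)


# ---------------------------------------------------------------------------
# full run with provenance
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    config_yaml: str
    version: str
    digests: dict
    timestamp: str
    warnings: list = field(default_factory=list)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> RunManifest:
    """Execute simulate -> features -> statistics, write every table, and
    emit a manifest with per-file digests (identical digests under an
    identical config and seed)."""
    from . import __version__

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings_log: list[str] = []

    effects = GroupEffectConfig(**cfg.group_effects) if cfg.group_effects \
        else GroupEffectConfig()
    subjects = generate_cohort(cfg.n_fof_pos, cfg.n_fof_neg, effects,
                               seed=cfg.seed, n_days=cfg.n_days,
                               synthesize=cfg.synthesize_signals,
                               wear_hours=cfg.wear_hours)
    cohort = cohort_feature_table(subjects, seed=cfg.seed,
                                  use_signals=cfg.synthesize_signals)
    cohort.to_csv(out / "cohort_features.csv", index=False)

    results = run_statistics(cohort, seed=cfg.seed, tree_params=cfg.tree_params(),
                             screen_threshold=cfg.effect_screen_r,
                             selection_in_folds=cfg.selection_in_folds)
    results["effect_sizes"].to_csv(out / "effect_sizes.csv", index=False)
    results["paired"].to_csv(out / "paired_lab_home.csv", index=False)
    results["ratios"].to_csv(out / "home_lab_ratios.csv", index=False)
    rep_rows = []
    for name, rep in results["classification"].items():
        rep_rows.append({"feature_set": name, "n_features": len(results["feature_sets"][name]),
                         "sensitivity": rep.sensitivity, "specificity": rep.specificity,
                         "precision": rep.precision, "accuracy": rep.accuracy,
                         "auc": rep.auc})
    pd.DataFrame(rep_rows).to_csv(out / "classification_report.csv", index=False)
    (out / "feature_sets.json").write_text(json.dumps(results["feature_sets"], indent=2))

    digests = {p.name: _sha256(p) for p in sorted(out.glob("*.csv")) }
    digests["feature_sets.json"] = _sha256(out / "feature_sets.json")
    manifest = RunManifest(config_yaml=dump_config(cfg), version=__version__,
                           digests=digests,
                           timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
                           warnings=warnings_log)
    (out / "manifest.json").write_text(json.dumps(vars(manifest), indent=2))
    return manifest
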