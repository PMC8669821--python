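"""Recovery evaluation against generator ground truth.

Detected events are matched to true events greedily at a minimum
interval-overlap fraction (default 50% of the shorter event); sensitivity
and precision summarise the match, and parameter errors (speed, peak
angular velocity, peak power) are computed over matched pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import detect
from .core import GroundTruthTimeline, IMURecording


def _seed_of(base: int, k: int) -> int:
    return int((base * 100003 + k) % (2**31 - 1))


def _overlap_fraction(a, b) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    shorter = min(a[1] - a[0], b[1] - b[0])
    return inter / shorter if shorter > 0 else 0.0


def match_events(true_events, detected_events, min_overlap: float = 0.5):
    """Greedy best-overlap matching; returns list of (true, detected) pairs."""
    true_iv = [(t.start, t.end) for t in true_events]
    det_iv = [(d.start, d.end) for d in detected_events]
    pairs = []
    used = set()
    for i, tv in enumerate(true_iv):
        best, best_f = None, min_overlap
        for j, dv in enumerate(det_iv):
            if j in used:
                continue
            f = _overlap_fraction(tv, dv)
            if f >= best_f:
                best, best_f = j, f
        if best is not None:
            used.add(best)
            pairs.append((true_events[i], detected_events[best]))
    return pairs


@dataclass
class RecoveryStats:
    n_true: int = 0
    n_detected: int = 0
    n_matched: int = 0
    rel_errors: list = field(default_factory=list)

    @property
    def sensitivity(self) -> float:
        return self.n_matched / self.n_true if self.n_true else float("nan")

    @property
    def precision(self) -> float:
        return self.n_matched / self.n_detected if self.n_detected else float("nan")

    def add(self, true_events, detected_events, pairs, value_fn=None) -> None:
        self.n_true += len(true_events)
        self.n_detected += len(detected_events)
        self.n_matched += len(pairs)
        if value_fn is not None:
            for t, d in pairs:
                vt, vd = value_fn(t), value_fn(d)
                if vt:
                    self.rel_errors.append((vd - vt) / vt)

    @property
    def max_abs_rel_error(self) -> float:
        return float(np.max(np.abs(self.rel_errors))) if self.rel_errors else float("nan")

    @property
    def mean_abs_rel_error(self) -> float:
        return float(np.mean(np.abs(self.rel_errors))) if self.rel_errors else float("nan")


def evaluate_day(rec: IMURecording, tl: GroundTruthTimeline, *, body_mass: float,
                 height: float, stats: dict | None = None) -> dict:
    """Run all three detectors on one day and accumulate recovery stats.

    ``stats`` maps ``{"bouts": ..., "turns": ..., "sists": ...}`` to
    :class:`RecoveryStats`; per-second speed errors of matched bouts are
    appended to ``stats['bouts'].rel_errors`` as mean-speed relative
    errors.
    """
    if stats is None:
        stats = {"bouts": RecoveryStats(), "turns": RecoveryStats(),
                 "sists": RecoveryStats()}
    frame = detect.resolve_frame(rec)

    bouts = detect.detect_walking_bouts(rec, height=height, frame=frame)
    pairs = match_events(tl.walking_bouts, bouts)
    stats["bouts"].add(tl.walking_bouts, bouts, pairs,
                       value_fn=lambda b: float(np.nanmean(b.per_second_speed)))

    turns = detect.detect_turns(rec, frame=frame)
    pairs = match_events(tl.turns, turns)
    stats["turns"].add(tl.turns, turns, pairs, value_fn=lambda t: t.peak_omega)

    trans = [t for t in detect.detect_postural_transitions(rec, body_mass, frame=frame)
             if t.kind == "sit_to_stand"]
    pairs = match_events(tl.sit_to_stands, trans)
    stats["sists"].add(tl.sit_to_stands, trans, pairs, value_fn=lambda t: t.peak_power)
    return stats


# ---------------------------------------------------------------------------
# study-level validation runs (used by the acceptance checks)
# ---------------------------------------------------------------------------

def detection_recovery_study(n_days: int = 20, seed: int = 0,
                             wear_hours: float = 0.3) -> dict:
    """Detector recovery over seeded synthetic days (short wear windows
    keep the raw-signal volume tractable at unchanged event rates)."""
    from .simulate import default_phenotype, generate_daily_recording

    spec = default_phenotype("FOF-", bouts_per_day_by_class=(3, 2, 1),
                             wear_hours_per_day=wear_hours)
    stats = {"bouts": RecoveryStats(), "turns": RecoveryStats(),
             "sists": RecoveryStats()}
    days = generate_daily_recording(spec, n_days, _seed_of(seed, 1),
                                    synthesize=True, wear_hours=wear_hours)
    for rec, tl in days:
        evaluate_day(rec, tl, body_mass=spec.body_mass, height=spec.height,
                     stats=stats)
    return stats


def mixture_recovery_study(n_seeds: int = 20, n_samples: int = 5000,
                           modes=(0.5, 0.9), sd: float = 0.05,
                           seed: int = 0) -> dict:
    """Bimodal mode recovery on mixtures with known ground truth."""
    from .daily import fit_bimodal_modes

    err1, err2 = [], []
    for k in range(n_seeds):
        rng = np.random.default_rng(_seed_of(seed, 200 + k))
        half = n_samples // 2
        x = np.concatenate([rng.normal(modes[0], sd, half),
                            rng.normal(modes[1], sd, n_samples - half)])
        fit = fit_bimodal_modes(x, seed=_seed_of(seed, 300 + k))
        err1.append(abs(fit.v_mu1 - modes[0]))
        err2.append(abs(fit.v_mu2 - modes[1]))
    return {"max_err_mode1": float(np.max(err1)),
            "max_err_mode2": float(np.max(err2)), "n_seeds": n_seeds}


def logistic_null_calibration(n_replicates: int = 200, n: int = 26,
                              n_pos: int = 9, seed: int = 0) -> dict:
    """Rejection rate of the covariate-adjusted logistic Wald test at
    alpha = 0.05 when the feature is independent of group."""
    from .stats import adjusted_logistic_p

    rng = np.random.default_rng(_seed_of(seed, 2))
    hits = usable = 0
    for _ in range(n_replicates):
        y = np.array([1] * n_pos + [0] * (n - n_pos))
        rng.shuffle(y)
        res = adjusted_logistic_p(rng.normal(0, 1, n), rng.integers(0, 2, n),
                                  rng.normal(25, 6, n),
                                  ["FOF+" if v else "FOF-" for v in y])
        if res.p_value is not None:
            usable += 1
            hits += res.p_value < 0.05
    return {"rejection_rate": hits / usable, "n_usable": usable}


def permuted_label_auc(n_permutations: int = 100, seed: int = 0) -> dict:
    """Mean LOSO AUC of a real synthetic cohort under label permutation."""
    import pandas as pd
    from .pipeline import cohort_feature_table
    from .simulate import generate_cohort
    from .stats import loso_classify

    subs = generate_cohort(9, 17, seed=_seed_of(seed, 3), n_days=2)
    cohort = cohort_feature_table(subs, seed=_seed_of(seed, 3))
    feats = ["T_TUG", "omega_TUG_1", "omega_TUG_2", "V_mu1", "omega_H_P50",
             "Gait_ALL_avg"]
    rng = np.random.default_rng(_seed_of(seed, 4))
    labels = cohort["fof_group"].to_numpy()
    aucs = []
    for k in range(n_permutations):
        perm = cohort.copy()
        perm["fof_group"] = rng.permutation(labels)
        if min((perm["fof_group"] == "FOF+").sum(),
               (perm["fof_group"] == "FOF-").sum()) < 2:
            continue
        aucs.append(loso_classify(perm, feats, seed=k).auc)
    return {"mean_auc": float(np.mean(aucs)), "n_permutations": len(aucs)}


def turn_effect_direction_study(n_seeds: int = 100, seed: int = 0,
                                n_days: int = 2) -> dict:
    """Sign consistency of the rank-sum effect size for turn features on
    cohorts generated with a large turning deficit in the FOF+ group."""
    import pandas as pd
    from .lab import lab_result_from_timeline
    from .simulate import GroupEffectConfig, generate_cohort
    from .stats import effect_size_r

    cfg = GroupEffectConfig(turn_omega_shift=-40.0, omega_between_sd=10.0,
                            home_omega_transfer=0.5, home_omega_between_cv=0.05)
    feats = ["omega_TUG_1", "omega_TUG_2", "omega_H_P50", "omega_H_P95"]
    neg = np.zeros(len(feats))
    for k in range(n_seeds):
        subs = generate_cohort(9, 17, cfg, seed=_seed_of(seed, 500 + k),
                               n_days=n_days)
        rows = []
        for s in subs:
            row = {"group": s.spec.group_label}
            lab = lab_result_from_timeline(s.lab_timeline)
            row["omega_TUG_1"], row["omega_TUG_2"] = lab["omega_TUG_1"], lab["omega_TUG_2"]
            omegas = np.concatenate(
                [[t.peak_omega for t in tl.turns] for _, tl in s.daily])
            row["omega_H_P50"] = float(np.percentile(omegas, 50))
            row["omega_H_P95"] = float(np.percentile(omegas, 95))
            rows.append(row)
        df = pd.DataFrame(rows)
        pos = df["group"] == "FOF+"
        for j, f in enumerate(feats):
            neg[j] += effect_size_r(df.loc[pos, f], df.loc[~pos, f]) < 0
    return {"features": feats,
            "negative_fraction": {f: float(neg[j] / n_seeds)
                                  for j, f in enumerate(feats)},
            "min_negative_fraction": float(neg.min() / n_seeds),
            "n_seeds": n_seeds}


def feature_set_auc_study(n_seeds: int = 50, seed: int = 0,
                          n_days: int = 3) -> dict:
    """AUC of the combined (F1) versus daily-activity-only (F3) feature
    sets over seeded cohorts with the default group-effect pattern."""
    from .pipeline import cohort_feature_table, run_statistics
    from .simulate import generate_cohort

    auc = {"F1": [], "F2": [], "F3": []}
    ge = 0
    for k in range(n_seeds):
        s = _seed_of(seed, 700 + k)
        subs = generate_cohort(9, 17, seed=s, n_days=n_days)
        cohort = cohort_feature_table(subs, seed=s)
        res = run_statistics(cohort, seed=s)
        reps = res["classification"]
        a1 = reps["F1"].auc if "F1" in reps else 0.5
        a3 = reps["F3"].auc if "F3" in reps else 0.5
        ge += a1 >= a3
        for name in auc:
            if name in reps:
                auc[name].append(reps[name].auc)
    return {"frac_f1_ge_f3": ge / n_seeds,
            "mean_auc": {k: float(np.mean(v)) for k, v in auc.items() if v},
            "n_seeds": n_seeds}
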