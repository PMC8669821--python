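"""Group-level statistics: FOF grouping, effect sizes, adjusted logistic
regression, feature selection, leave-one-subject-out classification, and
lab-versus-home comparison.

The effect size ``r`` is the Wilcoxon rank-sum statistic standardised by
the square root of the total sample size (``r = Z / sqrt(N)``, tie-
corrected normal approximation, no continuity correction), signed so that
positive values mean the FOF+ group tends larger.  Bands: |r| ~ 0.1
small, 0.3 medium, 0.5 large.  Every mobility parameter is additionally
adjusted for gender and UPDRS-III in a multivariable logistic regression
of group membership; the reported p-value is the Wald p of the parameter
coefficient.  Classification uses a fixed-hyperparameter decision tree
with leave-one-subject-out (LOSO) cross-validation, pooling fold
predictions for the metrics and the AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sstats
from sklearn.metrics import roc_auc_score
from sklearn.tree import DecisionTreeClassifier

from .daily import HOME_FEATURES
from .lab import LAB_FEATURES

FES_I_FOF_THRESHOLD = 19       # FOF+ iff FES-I total > 19
EFFECT_SIZE_SCREEN = 0.2       # |r| screen for feature selection
EFFECT_BANDS = (0.1, 0.3, 0.5)
RHO_BANDS = (0.5, 0.7)

DEFAULT_TREE_PARAMS = dict(criterion="gini", max_depth=3, min_samples_leaf=2)


def assign_fof_group(fes_i: int) -> str:
    """FES-I total > 19 defines the presence of fear of falling."""
    if fes_i < 0:
        raise ValueError("FES-I score must be >= 0")
    return "FOF+" if fes_i > FES_I_FOF_THRESHOLD else "FOF-"


# ---------------------------------------------------------------------------
# effect size
# ---------------------------------------------------------------------------

def effect_band(r: float) -> str:
    a = abs(r)
    if a >= EFFECT_BANDS[2]:
        return "large"
    if a >= EFFECT_BANDS[1]:
        return "medium"
    return "small"


def effect_size_r(group_pos, group_neg) -> float:
    """Signed rank-sum effect size ``r = Z / sqrt(N)``.

    ``group_pos`` holds the FOF+ values; positive r means FOF+ tends
    larger.  Ties are handled mid-rank with the tie-corrected variance;
    fully tied data return 0 with a warning.
    """
    a = np.asarray(list(group_pos), float)
    b = np.asarray(list(group_neg), float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sstats.rankdata(pooled)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0  # Mann-Whitney U of FOF+
    mean_u = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var_u = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var_u <= 0:
        warnings.warn("all values tied across both groups; effect size set to 0")
        return 0.0
    z = (u - mean_u) / np.sqrt(var_u)
    return float(z / np.sqrt(n))


# ---------------------------------------------------------------------------
# covariate-adjusted logistic regression
# ---------------------------------------------------------------------------

@dataclass
class LogisticResult:
    p_value: float | None
    coef: float | None
    flag: str | None = None  # "separation" | "collinear" | "nonconvergence"


def adjusted_logistic_p(feature, gender, updrs_iii, group_labels) -> LogisticResult:
    """Wald p-value of a mobility parameter in a logistic model of FOF
    group on (gender, UPDRS-III, parameter).

    Gender is coded 0 = male, 1 = female (binary input accepted as-is).
    Complete separation and collinearity are detected and flagged rather
    than reported as a spurious p.
    """
    x = np.asarray(list(feature), float)
    g = np.asarray(list(gender), float)
    u = np.asarray(list(updrs_iii), float)
    labels = list(group_labels)
    y = np.asarray([1.0 if lab in ("FOF+", 1, True) else 0.0 for lab in labels])
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 subjects")
    if np.isnan(x).any() or np.isnan(g).any() or np.isnan(u).any():
        raise ValueError("missing values are not supported")

    X = sm.add_constant(np.column_stack([g, u, x]), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return LogisticResult(None, None, flag="collinear")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception:
            return LogisticResult(None, None, flag="separation")
    if not fit.mle_retvals.get("converged", False):
        return LogisticResult(None, None, flag="nonconvergence")
    if np.abs(fit.params).max() > 50 or np.isnan(fit.bse).any():
        return LogisticResult(None, None, flag="separation")
    return LogisticResult(float(fit.pvalues[-1]), float(fit.params[-1]))


@dataclass
class EffectSizeResult:
    feature: str
    r: float
    band: str
    p_adjusted_logistic: float | None
    logistic_flag: str | None = None


def effect_size_table(cohort: pd.DataFrame, features) -> pd.DataFrame:
    """Effect size and adjusted logistic p for every feature.

    ``cohort`` needs columns ``fof_group`` ('FOF+'/'FOF-'), ``gender``
    (0 male / 1 female), ``updrs_iii`` and the feature columns.
    """
    pos = cohort["fof_group"] == "FOF+"
    rows = []
    for f in features:
        r = effect_size_r(cohort.loc[pos, f], cohort.loc[~pos, f])
        res = adjusted_logistic_p(cohort[f], cohort["gender"], cohort["updrs_iii"],
                                  cohort["fof_group"])
        rows.append(EffectSizeResult(f, r, effect_band(r), res.p_value, res.flag))
    return pd.DataFrame([vars(r) for r in rows])


# ---------------------------------------------------------------------------
# LOSO decision-tree classification
# ---------------------------------------------------------------------------

@dataclass
class ClassificationReport:
    feature_set: str
    features: list
    sensitivity: float  # percent
    specificity: float
    precision: float
    accuracy: float
    auc: float
    y_true: np.ndarray = field(repr=False, default=None)
    y_pred: np.ndarray = field(repr=False, default=None)
    y_proba: np.ndarray = field(repr=False, default=None)
    degenerate_folds: int = 0


def loso_classify(cohort: pd.DataFrame, features, seed: int = 0,
                  feature_set: str = "F1",
                  tree_params: dict | None = None) -> ClassificationReport:
    """Leave-one-subject-out decision-tree classification of FOF group.

    Metrics come from the pooled held-out predictions; the AUC from the
    pooled predicted FOF+ probabilities.
    """
    features = list(features)
    if not features:
        raise ValueError("feature set is empty")
    X = cohort[features].to_numpy(float)
    y = (cohort["fof_group"] == "FOF+").to_numpy(int)
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ValueError("need at least 2 subjects per class")
    params = dict(DEFAULT_TREE_PARAMS, **(tree_params or {}))

    n = len(y)
    preds = np.empty(n, int)
    probas = np.empty(n, float)
    degenerate = 0
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        ytr = y[mask]
        if len(np.unique(ytr)) < 2:
            degenerate += 1
            maj = int(np.bincount(ytr).argmax())
            preds[i], probas[i] = maj, float(maj)
            continue
        clf = DecisionTreeClassifier(random_state=seed, **params)
        clf.fit(X[mask], ytr)
        preds[i] = int(clf.predict(X[i:i + 1])[0])
        probas[i] = float(clf.predict_proba(X[i:i + 1])[0, list(clf.classes_).index(1)])

    tp = int(((preds == 1) & (y == 1)).sum())
    tn = int(((preds == 0) & (y == 0)).sum())
    fp = int(((preds == 1) & (y == 0)).sum())
    fn = int(((preds == 0) & (y == 1)).sum())
    assert tp + tn + fp + fn == n
    pct = lambda num, den: 100.0 * num / den if den else float("nan")
    return ClassificationReport(
        feature_set=feature_set, features=features,
        sensitivity=pct(tp, tp + fn), specificity=pct(tn, tn + fp),
        precision=pct(tp, tp + fp), accuracy=pct(tp + tn, n),
        auc=float(roc_auc_score(y, probas)),
        y_true=y, y_pred=preds, y_proba=probas, degenerate_folds=degenerate)


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------

def screen_features(es_table: pd.DataFrame, threshold: float = EFFECT_SIZE_SCREEN) -> list:
    """Features with |r| strictly above the screen threshold."""
    kept = es_table.loc[es_table["r"].abs() > threshold, "feature"].tolist()
    if not kept:
        warnings.warn("no feature passes the |r| screen")
    return kept


def backward_eliminate(cohort: pd.DataFrame, features, seed: int = 0,
                       tree_params: dict | None = None) -> list:
    """Backward elimination against LOSO accuracy.

    Repeatedly drops the feature whose removal gives the highest LOSO
    accuracy (ties broken by feature name order), as long as that
    accuracy is at least the current one; stops when every removal would
    strictly degrade it, or when one feature remains.
    """
    current = sorted(features)
    if len(current) < 2:
        return list(current)
    acc = loso_classify(cohort, current, seed=seed, tree_params=tree_params).accuracy
    while len(current) > 1:
        candidates = []
        for f in current:
            reduced = [g for g in current if g != f]
            a = loso_classify(cohort, reduced, seed=seed, tree_params=tree_params).accuracy
            candidates.append((a, f))
        # deterministic tie-break: among equal accuracies drop the first by name
        best_acc = max(a for a, _ in candidates)
        best_f = min(f for a, f in candidates if a == best_acc)
        if best_acc >= acc:
            current.remove(best_f)
            acc = best_acc
        else:
            break
    return current


def select_features(cohort: pd.DataFrame, features=None, seed: int = 0,
                    threshold: float = EFFECT_SIZE_SCREEN,
                    tree_params: dict | None = None) -> list:
    """The combined feature set F1: |r| screen then backward elimination."""
    features = list(features) if features is not None else LAB_FEATURES + list(HOME_FEATURES)
    es = effect_size_table(cohort, features)
    screened = screen_features(es, threshold)
    if not screened:
        return []
    return backward_eliminate(cohort, screened, seed=seed, tree_params=tree_params)


def split_feature_sets(f1) -> tuple:
    """Partition F1 into lab-only (F2) and home-only (F3) sets."""
    f2, f3 = [], []
    for f in f1:
        if f in LAB_FEATURES:
            f2.append(f)
        elif f in HOME_FEATURES:
            f3.append(f)
        else:
            raise ValueError(f"feature {f!r} has no lab/home provenance tag")
    if not f3:
        warnings.warn("F1 contains no daily-activity features; F3 is empty")
    if not f2:
        warnings.warn("F1 contains no lab features; F2 is empty")
    return f2, f3


# ---------------------------------------------------------------------------
# lab versus daily activity
# ---------------------------------------------------------------------------

def rho_band(rho: float) -> str:
    a = abs(rho)
    if a > RHO_BANDS[1]:
        return "high"
    if a >= RHO_BANDS[0]:
        return "moderate"
    return "low"


@dataclass
class PairedComparisonResult:
    lab_feature: str
    home_feature: str
    group: str
    signed_rank_p: float | None
    rho: float | None
    rho_band: str | None
    ratio_values: np.ndarray = field(repr=False, default=None)
    flag: str | None = None


def paired_lab_home(cohort: pd.DataFrame, lab_feature: str, home_feature: str,
                    group: str) -> PairedComparisonResult:
    """Paired signed-rank test and Pearson correlation between a lab
    parameter and its daily-life counterpart within one group, plus the
    per-subject home/lab unitless ratios."""
    sub = cohort[cohort["fof_group"] == group]
    a = sub[lab_feature].to_numpy(float)
    b = sub[home_feature].to_numpy(float)
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("both features must be present for every subject in group")
    diffs = b - a
    flag = None
    if np.all(diffs == 0):
        p = None
        flag = "all-differences-zero"
    else:
        mode = "exact" if len(a) <= 25 and not np.any(diffs == 0) else "approx"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = float(sstats.wilcoxon(a, b, mode=mode).pvalue)
    if np.std(a) == 0 or np.std(b) == 0:
        rho, band = None, None
        flag = flag or "constant-feature"
    else:
        rho = float(sstats.pearsonr(a, b)[0])
        band = rho_band(rho)
    ratios = np.array([home_lab_ratio(hb, la) for hb, la in zip(b, a)])
    return PairedComparisonResult(lab_feature, home_feature, group, p, rho, band,
                                  ratios, flag)


def home_lab_ratio(home_value: float, lab_value: float) -> float:
    """Unitless daily-activity / lab parameter ratio."""
    if lab_value <= 0:
        raise ValueError("lab value must be > 0 to form a ratio")
    return home_value / lab_value
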