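"""Leave-one-out cross-validated discrimination with six classifier families.

Models run with their library defaults (only random seeds are pinned).  All
per-fold preprocessing — standardisation, univariate selection when enabled,
PCA when enabled — is fit on the training fold only, so no information from
the held-out unit leaks into the model.  ``cv_unit="subject"`` leaves out all
fragments of one participant together, for split-fragment tables where
sample-level LOOCV would leak subject identity.

If univariate selection leaves no feature in some training fold, that fold
falls back to predicting the training majority class with a chance-level
score: with nothing informative retained, the honest prediction is baseline.

Accuracy is the fraction of correctly predicted held-out units; AUC is
computed from the pooled held-out decision scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .stats import FeatureTable, pca_reduce, univariate_select

__all__ = ["MODEL_NAMES", "CVResult", "loocv", "evaluate_all",
           "compare_conditions"]

MODEL_NAMES = ["logistic_regression", "decision_tree", "svm",
               "random_forest", "naive_bayes", "mlp"]


def _make_model(name: str, seed: int):
    if name == "logistic_regression":
        return LogisticRegression()
    if name == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if name == "svm":
        return SVC()
    if name == "random_forest":
        return RandomForestClassifier(random_state=seed)
    if name == "naive_bayes":
        return GaussianNB()
    if name == "mlp":
        return MLPClassifier(random_state=seed)
    raise ValueError(
        f"unknown model {name!r}; valid models: " + ", ".join(MODEL_NAMES)
    )


@dataclass
class CVResult:
    """LOOCV outcome for one model."""

    model: str
    accuracy: float
    auc: float
    roc_points: np.ndarray          # (n, 2) columns fpr, tpr
    predictions: pd.DataFrame       # per held-out unit: truth, prediction, score
    pca_used: bool | dict = False
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.accuracy <= 1 or not 0 <= self.auc <= 1:
            raise ValueError("accuracy and AUC must lie in [0, 1]")


def _folds(tab: FeatureTable, cv_unit: str):
    if cv_unit == "sample":
        for i in range(len(tab.data)):
            mask = np.zeros(len(tab.data), dtype=bool)
            mask[i] = True
            yield ~mask, mask
    elif cv_unit == "subject":
        subjects = tab.subject_ids.to_numpy()
        for s in pd.unique(subjects):
            mask = subjects == s
            yield ~mask, mask
    else:
        raise ValueError("cv_unit must be 'sample' or 'subject'")


def _score_of(model, X) -> np.ndarray:
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X), dtype=float)
    return np.asarray(model.predict_proba(X)[:, 1], dtype=float)


def loocv(tab: FeatureTable, model: str, cv_unit: str = "sample",
          pca: bool = False, variance_target: float = 0.85,
          select_alpha: float | None = None, seed: int = 0) -> CVResult:
    """Leave-one-unit-out evaluation of one model.

    ``select_alpha`` enables per-fold univariate screening; ``pca`` enables
    per-fold PCA after screening.  The positive class for scores/AUC is the
    lexicographically larger group label (``PE`` when labels are PC/PE).
    """
    if model not in MODEL_NAMES:
        raise ValueError(
            f"unknown model {model!r}; valid models: " + ", ".join(MODEL_NAMES)
        )
    levels = tab.group_levels
    if len(levels) != 2:
        raise ValueError("LOOCV needs exactly 2 groups")
    counts = tab.groups.value_counts()
    if counts.min() < 3:
        raise ValueError("need >= 3 samples per group")
    pos = levels[1]
    y_all = (tab.groups.to_numpy() == pos).astype(int)
    X_all = tab.data.to_numpy(dtype=float)
    feat_names = np.array(tab.feature_names)

    base_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**30))
    truths, preds, scores, ids = [], [], [], []
    for fold_idx, (train, test) in enumerate(_folds(tab, cv_unit)):
        fold_seed = base_seed + fold_idx  # master seed fanned out per fold
        X_tr, y_tr = X_all[train], y_all[train]
        X_te = X_all[test]

        cols = np.arange(X_tr.shape[1])
        if select_alpha is not None:
            sub = FeatureTable(
                pd.DataFrame(X_tr, columns=feat_names),
                tab.groups.to_numpy()[train],
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                kept, _ = univariate_select(sub, alpha=select_alpha)
            cols = np.array([i for i, f in enumerate(feat_names) if f in kept],
                            dtype=int)
        if cols.size == 0:
            # nothing informative retained: training-majority baseline
            majority = int(round(y_tr.mean()))
            for t in np.where(test)[0]:
                truths.append(y_all[t])
                preds.append(majority)
                scores.append(0.5)
                ids.append(tab.data.index[t])
            continue

        X_tr_s, X_te_s = X_tr[:, cols], X_te[:, cols]
        scaler = StandardScaler().fit(X_tr_s)
        X_tr_s = scaler.transform(X_tr_s)
        X_te_s = scaler.transform(X_te_s)
        if pca and X_tr_s.shape[1] >= 2:
            ft = FeatureTable(pd.DataFrame(X_tr_s), tab.groups.to_numpy()[train])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                red = pca_reduce(ft, variance_target)
            info = red.pca_info
            k = info.n_components
            comp = info.loadings.to_numpy()[:, :k]
            X_te_s = ((X_te_s - info.scaler_mean) / info.scaler_scale) @ comp
            X_tr_s = red.data.to_numpy()
        est = _make_model(model, fold_seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            est.fit(X_tr_s, y_tr)
            p = est.predict(X_te_s)
            s = _score_of(est, X_te_s)
        for t, pi, si in zip(np.where(test)[0], p, s):
            truths.append(y_all[t])
            preds.append(int(pi))
            scores.append(float(si))
            ids.append(tab.data.index[t])

    truths = np.array(truths)
    preds = np.array(preds)
    scores = np.array(scores)
    accuracy = float((truths == preds).mean())
    if len(np.unique(truths)) < 2 or np.ptp(scores) == 0:
        auc = 0.5
        roc = np.array([[0.0, 0.0], [1.0, 1.0]])
    else:
        auc = float(roc_auc_score(truths, scores))
        fpr, tpr, _ = roc_curve(truths, scores)
        roc = np.column_stack([fpr, tpr])
    pred_df = pd.DataFrame({"sample_id": ids, "truth": truths,
                            "prediction": preds, "score": scores})
    return CVResult(model=model, accuracy=accuracy, auc=auc, roc_points=roc,
                    predictions=pred_df, pca_used=pca, seed=seed)


def evaluate_all(tab: FeatureTable, cv_unit: str = "sample", seed: int = 0,
                 select_alpha: float | None = None,
                 variance_target: float = 0.85) -> list[CVResult]:
    """All six models, each with and without PCA; per model the better accuracy
    and the better AUC are retained (possibly from different variants)."""
    ss = np.random.SeedSequence(seed)
    model_seeds = [int(s % (2**31)) for s in ss.generate_state(len(MODEL_NAMES))]
    out = []
    for name, mseed in zip(MODEL_NAMES, model_seeds):
        variants = {
            False: loocv(tab, name, cv_unit, pca=False, seed=mseed,
                         select_alpha=select_alpha,
                         variance_target=variance_target),
            True: loocv(tab, name, cv_unit, pca=True, seed=mseed,
                        select_alpha=select_alpha,
                        variance_target=variance_target),
        }
        best_acc = max(variants, key=lambda k: variants[k].accuracy)
        best_auc = max(variants, key=lambda k: variants[k].auc)
        retained = CVResult(
            model=name,
            accuracy=variants[best_acc].accuracy,
            auc=variants[best_auc].auc,
            roc_points=variants[best_auc].roc_points,
            predictions=variants[best_acc].predictions,
            pca_used={"accuracy": best_acc, "auc": best_auc},
            seed=mseed,
        )
        retained.variants = variants
        out.append(retained)
    return out


def compare_conditions(results: dict) -> pd.DataFrame:
    """Long-format accuracy/AUC table across experiment conditions.

    ``results`` maps ``(network_kind, method, band, dataset)`` tuples to lists
    of :class:`CVResult`.
    """
    if not results:
        raise ValueError("no conditions to compare")
    rows = []
    for cond, cvs in results.items():
        kind, method, band, dataset = cond
        for r in cvs:
            rows.append({"network_kind": kind, "method": method, "band": band,
                         "dataset": dataset, "model": r.model,
                         "accuracy": r.accuracy, "auc": r.auc})
    return pd.DataFrame(rows)


def plot_comparison(df: pd.DataFrame, path) -> None:
    """Grouped bar chart of accuracy by condition and model."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = df.copy()
    df["condition"] = (df["network_kind"] + "/" + df["method"] + "/"
                       + df["band"] + "/" + df["dataset"])
    pivot = df.pivot_table(index="condition", columns="model", values="accuracy")
    ax = pivot.plot.bar(figsize=(max(6, 1.2 * len(pivot)), 4))
    ax.set_ylabel("LOOCV accuracy")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=7)
    ax.figure.tight_layout()
    ax.figure.savefig(path, dpi=120)
    plt.close(ax.figure)
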