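"""Univariate group comparison, feature selection, PCA reduction, and the
demographic tests.

Selection mirrors uncorrected univariate screening: per feature, Shapiro-Wilk
normality is assessed in both groups at alpha = 0.05; a two-sample t-test is
used if both groups pass, otherwise the Wilcoxon rank-sum (Mann-Whitney) test;
features with p > alpha are discarded.  No multiple-testing correction is
applied by default (a Benjamini-Hochberg flag is available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

__all__ = [
    "FeatureTable",
    "UnivariateResult",
    "univariate_select",
    "univariate_report",
    "pca_reduce",
    "chi_square_2x2",
    "mann_whitney",
]


@dataclass
class FeatureTable:
    """Samples x named features, with group labels and subject identifiers.

    ``sample_id`` distinguishes rows (fragments of a split record get their
    own ids); ``subject_id`` ties fragments back to the participant they came
    from, for subject-level cross-validation.
    """

    data: pd.DataFrame
    groups: pd.Series
    subject_ids: pd.Series | None = None

    def __post_init__(self):
        self.data = pd.DataFrame(self.data)
        self.groups = pd.Series(np.asarray(self.groups), index=self.data.index)
        if self.subject_ids is None:
            self.subject_ids = pd.Series(self.data.index.astype(str),
                                         index=self.data.index)
        else:
            self.subject_ids = pd.Series(np.asarray(self.subject_ids),
                                         index=self.data.index)
        if self.data.isna().any().any():
            raise ValueError("feature table contains missing values")

    @property
    def feature_names(self) -> list:
        return list(self.data.columns)

    @property
    def group_levels(self) -> list:
        return sorted(self.groups.unique())

    def subset(self, features) -> "FeatureTable":
        return FeatureTable(self.data[list(features)], self.groups, self.subject_ids)

    def rows(self, mask) -> "FeatureTable":
        return FeatureTable(self.data[mask], self.groups[mask],
                            self.subject_ids[mask])


@dataclass
class UnivariateResult:
    feature: str
    test: str  # "t" | "wilcoxon"
    statistic: float
    p: float
    medians: dict = field(default_factory=dict)   # group -> P50
    iqrs: dict = field(default_factory=dict)      # group -> IQR


def _two_groups(tab: FeatureTable):
    levels = tab.group_levels
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 group levels, got {levels}")
    return levels


def univariate_select(tab: FeatureTable, alpha: float = 0.05,
                      normality_alpha: float = 0.05,
                      bh_correct: bool = False):
    """Screen features by two-group univariate tests.

    Returns ``(selected_feature_names, results)``.  A constant feature is
    assigned p = 1 with a warning (no test can rank it).
    """
    g1, g2 = _two_groups(tab)
    results = []
    for feat in tab.feature_names:
        x = tab.data.loc[tab.groups == g1, feat].to_numpy(dtype=float)
        y = tab.data.loc[tab.groups == g2, feat].to_numpy(dtype=float)
        if min(len(x), len(y)) < 2:
            raise ValueError("need >= 2 samples per group")
        med = {g1: float(np.median(x)), g2: float(np.median(y))}
        iqr = {g1: float(np.subtract(*np.percentile(x, [75, 25]))),
               g2: float(np.subtract(*np.percentile(y, [75, 25])))}
        if np.ptp(np.concatenate([x, y])) == 0:
            warnings.warn(f"feature {feat!r} is constant; assigning p = 1",
                          stacklevel=2)
            results.append(UnivariateResult(feat, "wilcoxon", float("nan"),
                                            1.0, med, iqr))
            continue
        normal = True
        for v in (x, y):
            if len(v) < 3 or np.ptp(v) == 0:
                normal = False
                break
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if sst.shapiro(v).pvalue < normality_alpha:
                    normal = False
                    break
        if normal:
            stat, p = sst.ttest_ind(x, y)
            test = "t"
        else:
            res = sst.mannwhitneyu(x, y, alternative="two-sided")
            stat, p = res.statistic, res.pvalue
            test = "wilcoxon"
        results.append(UnivariateResult(feat, test, float(stat), float(p),
                                        med, iqr))
    pvals = np.array([r.p for r in results])
    if bh_correct:
        from statsmodels.stats.multitest import multipletests
        reject, _, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        selected = [r.feature for r, rej in zip(results, reject) if rej]
    else:
        selected = [r.feature for r in results if r.p <= alpha]
    return selected, results


def univariate_report(results, group_order=None) -> pd.DataFrame:
    """One row per feature with the per-group median/IQR and the test outcome."""
    if not results:
        return pd.DataFrame()
    groups = group_order or sorted(results[0].medians)
    rows = []
    for r in results:
        row = {"Item": r.feature}
        for g in groups:
            row[f"P50_{g}"] = r.medians[g]
            row[f"IQR_{g}"] = r.iqrs[g]
        row["W"] = r.statistic
        row["p"] = r.p
        row["test"] = r.test
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class PCAInfo:
    n_components: int
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray


def pca_reduce(tab: FeatureTable, variance_target: float = 0.85) -> FeatureTable:
    """Standardise, then project onto the leading principal components whose
    cumulative explained variance first reaches ``variance_target``.

    The returned table carries a ``pca_info`` attribute with loadings and
    explained-variance fractions for reporting (the scree-map choice).
    """
    if tab.data.shape[1] < 2:
        raise ValueError("PCA needs at least 2 features")
    if tab.data.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    scaler = StandardScaler()
    z = scaler.fit_transform(tab.data.to_numpy(dtype=float))
    pca = PCA()
    scores = pca.fit_transform(z)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    k = min(k, scores.shape[1])
    cols = [f"PC{i + 1}" for i in range(k)]
    out = FeatureTable(
        pd.DataFrame(scores[:, :k], index=tab.data.index, columns=cols),
        tab.groups, tab.subject_ids,
    )
    out.pca_info = PCAInfo(
        n_components=k,
        explained_variance_ratio=pca.explained_variance_ratio_,
        loadings=pd.DataFrame(pca.components_.T, index=tab.feature_names,
                              columns=[f"PC{i + 1}" for i in range(len(cum))]),
        scaler_mean=scaler.mean_,
        scaler_scale=scaler.scale_,
    )
    return out


def chi_square_2x2(counts) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, without continuity correction, df = 1."""
    t = np.asarray(counts, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("chi-square undefined: a row or column margin is zero")
    res = sst.chi2_contingency(t, correction=False)
    return float(res.statistic), float(res.pvalue)


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with tie correction.

    U is the statistic of the first sample (``U_x``); ``U_x + U_y = n_x n_y``.
    Exact p-values are used for small tie-free samples (scipy's automatic
    choice), the normal approximation with tie correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    res = sst.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
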