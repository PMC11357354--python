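"""Clinical-cohort association statistics.

Joins per-sample heterogeneity metrics with clinicopathological labels and
runs the association analysis: dichotomization of TNM stage and grade,
z-normalization of the six heterogeneity features (D and BI of a1, tau_m and
tau2; tau1 fluctuations carry no biological interpretation and are excluded),
Mann-Whitney group comparison, point-biserial correlation, and random-forest
feature attribution via exact tree-Shapley values.

Dichotomization follows the clinical convention for small cohorts:
T1+T2 -> group 0, T3+T4 -> group 1; N0M0 -> 0, any metastasis -> 1;
G1+G2 -> 0, G3 -> 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from ._tree_shap import forest_shapley

__all__ = [
    "ClinicalRecord",
    "AttributionConfig",
    "FeatureAttribution",
    "HETEROGENEITY_FEATURES",
    "dichotomize",
    "znormalize",
    "mann_whitney",
    "point_biserial",
    "normality_report",
    "build_cohort_table",
    "feature_attribution",
    "association_report",
]

#: The six heterogeneity features entering the clinical association analysis.
HETEROGENEITY_FEATURES = ["D_a1", "D_tau_m", "D_tau2", "BI_a1", "BI_tau_m", "BI_tau2"]

_ROMAN = {"I": 1, "II": 2, "III": 3, "IV": 4}


@dataclass
class ClinicalRecord:
    """TNM staging and grade for one tumor sample.

    T in 1..4 (tumor extent), N >= 0 (nodal involvement), M >= 0 (distant
    metastasis), G in 1..3 (differentiation grade).  ``stage_label`` is the
    roman-numeral stage group (I-IV, optionally with a letter suffix, e.g.
    IIIB); when given it must be consistent with the TNM codes.
    """

    sample_id: str
    T: int
    N: int
    M: int
    G: int
    stage_label: str = ""
    pretreated: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.T <= 4:
            raise ValueError(f"T must be in 1..4, got {self.T}")
        if self.N < 0:
            raise ValueError(f"N must be >= 0, got {self.N}")
        if self.M < 0:
            raise ValueError(f"M must be >= 0, got {self.M}")
        if not 1 <= self.G <= 3:
            raise ValueError(f"G must be in 1..3, got {self.G}")
        if self.stage_label:
            root = self._stage_root(self.stage_label)
            if root != self._expected_stage_root():
                raise ValueError(
                    f"stage_label {self.stage_label!r} inconsistent with "
                    f"T{self.T}N{self.N}M{self.M}"
                )

    @staticmethod
    def _stage_root(label: str) -> str:
        core = "".join(c for c in label.upper() if c in "IV")
        if core not in _ROMAN:
            raise ValueError(f"unparseable stage label {label!r}")
        return core

    def _expected_stage_root(self) -> str:
        if self.M > 0:
            return "IV"
        if self.N > 0:
            return "III"
        if self.T >= 3:
            return "II"
        return "I"


def dichotomize(record: ClinicalRecord) -> tuple[int, int, int]:
    """Binary group coding (T_group, NM_group, G_group) of a clinical record."""
    t_group = 0 if record.T in (1, 2) else 1
    nm_group = 0 if (record.N == 0 and record.M == 0) else 1
    g_group = 0 if record.G in (1, 2) else 1
    return t_group, nm_group, g_group


def znormalize(table: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Center and scale the given columns by their sample SD (n-1 denominator)."""
    out = table.copy()
    for col in columns:
        vals = out[col].dropna()
        if len(vals) < 2:
            raise ValueError(f"column {col!r} needs >= 2 non-missing values")
        sd = vals.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"column {col!r} has zero variance")
        out[col] = (out[col] - vals.mean()) / sd
    return out


def mann_whitney(values, groups) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of a binary grouping.

    Returns (U, p) with U counted for group 0.  Uses exact enumeration for
    combined n <= 20 without ties and the tie-corrected normal approximation
    otherwise.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    x0 = values[groups == 0]
    x1 = values[groups == 1]
    if len(x0) == 0 or len(x1) == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(values)) < len(values)
    method = "exact" if (len(values) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x0, x1, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def point_biserial(binary_labels, values) -> float:
    """Point-biserial correlation: Pearson r between a 0/1 label and values."""
    labels = np.asarray(binary_labels, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("both label classes must be present")
    return float(stats.pearsonr(labels, values).statistic)


def normality_report(values) -> tuple[float, float]:
    """Kolmogorov-Smirnov-type normality screen (Lilliefors, estimated moments).

    Reporting utility only — it never switches which group test is run.
    """
    from statsmodels.stats.diagnostic import lilliefors

    stat, p = lilliefors(np.asarray(values, dtype=float), dist="norm")
    return float(stat), float(p)


def build_cohort_table(
    metrics: pd.DataFrame, clinical: list[ClinicalRecord] | pd.DataFrame
) -> pd.DataFrame:
    """Join per-sample metrics with dichotomized clinical groups.

    Adds T_group / NM_group / G_group and z-normalized copies (z_ prefix) of
    the six heterogeneity features.
    """
    if isinstance(clinical, pd.DataFrame):
        records = [
            ClinicalRecord(
                sample_id=str(r.sample_id),
                T=int(r.T),
                N=int(r.N),
                M=int(r.M),
                G=int(r.G),
                stage_label=str(getattr(r, "stage", "") or ""),
            )
            for r in clinical.itertuples()
        ]
    else:
        records = list(clinical)
    rows = []
    for rec in records:
        t, nm, g = dichotomize(rec)
        rows.append(
            {"sample_id": rec.sample_id, "T_group": t, "NM_group": nm, "G_group": g}
        )
    groups = pd.DataFrame(rows)
    table = metrics.merge(groups, on="sample_id", validate="one_to_one")
    zcols = {f: f"z_{f}" for f in HETEROGENEITY_FEATURES}
    znorm = znormalize(table[HETEROGENEITY_FEATURES].copy(), HETEROGENEITY_FEATURES)
    for raw, z in zcols.items():
        table[z] = znorm[raw]
    return table


@dataclass
class AttributionConfig:
    """Random-forest + Shapley attribution settings.

    500 Gini-impurity trees with square-root feature subsampling and no depth
    limit; Shapley values are the exact path-dependent tree values by
    default, with the interventional (background-marginalized) variant behind
    ``shap_mode='interventional'``.
    """

    n_trees: int = 500
    max_features: str | None = "sqrt"
    seed: int = 0
    shap_mode: str = "path"


@dataclass
class FeatureAttribution:
    """Per-feature importance and signed per-sample Shapley attributions."""

    target: str
    features: list[str]
    shap_values: pd.DataFrame
    base_value: np.ndarray
    importances: pd.Series  # mean |shapley|, descending
    gini_importances: pd.Series
    model: RandomForestClassifier

    @property
    def ranking(self) -> list[str]:
        return list(self.importances.index)


def feature_attribution(
    table: pd.DataFrame,
    target_group: str,
    config: AttributionConfig | None = None,
    features: list[str] | None = None,
) -> FeatureAttribution:
    """Fit a random forest on the heterogeneity features and attribute it.

    The forest (Gini splitting) is fitted in-sample — this is an explanatory,
    not predictive, analysis — and each sample-feature pair receives an exact
    Shapley value for the class-1 probability; the global ranking is by mean
    absolute attribution.  The target column is excluded from the features by
    schema, never by filtering.
    """
    config = config or AttributionConfig()
    if features is None:
        zfeats = [f"z_{f}" for f in HETEROGENEITY_FEATURES]
        features = zfeats if all(f in table.columns for f in zfeats) else list(
            HETEROGENEITY_FEATURES
        )
    if len(features) < 6:
        raise ValueError("need at least the six heterogeneity features")
    if target_group in features:
        raise ValueError("target column must not appear among the features")
    y = table[target_group].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError(f"target {target_group!r} has a single class")
    X = table[features].to_numpy(dtype=float)
    model = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=config.max_features,
        criterion="gini",
        random_state=config.seed,
        n_jobs=1,
    )
    model.fit(X, y)
    phi, base = forest_shapley(model, X, mode=config.shap_mode, background=X)
    shap_df = pd.DataFrame(phi, columns=features, index=table["sample_id"])
    importances = shap_df.abs().mean().sort_values(ascending=False, kind="stable")
    gini = pd.Series(model.feature_importances_, index=features).sort_values(
        ascending=False, kind="stable"
    )
    return FeatureAttribution(
        target=target_group,
        features=list(features),
        shap_values=shap_df,
        base_value=base,
        importances=importances,
        gini_importances=gini,
        model=model,
    )


def association_report(
    table: pd.DataFrame,
    target_group: str,
    config: AttributionConfig | None = None,
    holm: bool = False,
) -> pd.DataFrame:
    """Per-feature association summary for one dichotomized clinical variable.

    One row per heterogeneity feature: Mann-Whitney U and two-sided p,
    point-biserial r, and the feature's Shapley importance rank.  Raw
    p-values by default; optional Holm adjustment adds a column.
    """
    attribution = feature_attribution(table, target_group, config)
    rank_of = {f: i + 1 for i, f in enumerate(attribution.ranking)}
    groups = table[target_group].to_numpy()
    rows = []
    for feat in HETEROGENEITY_FEATURES:
        values = table[feat].to_numpy(dtype=float)
        U, p = mann_whitney(values, groups)
        r = point_biserial(groups, values)
        zfeat = f"z_{feat}" if f"z_{feat}" in table.columns else feat
        rows.append(
            {
                "feature": feat,
                "group_variable": target_group,
                "U": U,
                "p_value": p,
                "point_biserial_r": r,
                "shap_rank": rank_of.get(zfeat, rank_of.get(feat)),
                "mean_abs_shap": float(attribution.importances.get(zfeat, np.nan)),
            }
        )
    report = pd.DataFrame(rows)
    if holm:
        from statsmodels.stats.multitest import multipletests

        report["p_holm"] = multipletests(report["p_value"], method="holm")[1]
    return report
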