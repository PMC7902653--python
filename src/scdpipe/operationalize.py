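"""The four SCD operationalization approaches.

Subjects with zero endorsed complaints are healthy controls (HC) under every
approach; the approaches differ in how they partition the complainers:

* **Clinical** — MCI-style subtypes on the *domains* of complaint: amnestic /
  non-amnestic x single / multiple domain.
* **Psychometric** — SCD requires a total complaint count at or above a
  normative percentile cutoff (90th by default).
* **Distribution** — subtypes from the empirical complaint distribution:
  amnestic (memory only), anomic (word-finding only), amnestic+anomic
  (exactly those two), atypical (complaints sparing both), remainder nonSCD.
* **Multivariate** — a data-driven rule: PCA extracts the clinical-severity
  component (the one clustering the ADL measures), a random-forest
  regression ranks the complaints by out-of-bag permutation importance, and
  subjects endorsing any selected complaint form the SCD group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestRegressor

from . import schema
from ._utils import nearest_rank_percentile
from .cohort import CohortTable

logger = logging.getLogger(__name__)

HC = "HC"
NON_SCD = "nonSCD"

CLINICAL_LABELS = (HC, "aSCD_sd", "aSCD_md", "naSCD_sd", "naSCD_md")
PSYCHOMETRIC_LABELS = (HC, NON_SCD, "SCD_90thPC")
DISTRIBUTION_LABELS = (HC, "amSCD", "anSCD", "am_anSCD", "atSCD", NON_SCD)
MULTIVARIATE_LABELS = (HC, NON_SCD, "SCD_multivariate")

#: labels that count as SCD membership, per approach
SCD_LABELS = {
    "clinical": {"aSCD_sd", "aSCD_md", "naSCD_sd", "naSCD_md"},
    "psychometric": {"SCD_90thPC"},
    "distribution": {"amSCD", "anSCD", "am_anSCD", "atSCD"},
    "multivariate": {"SCD_multivariate"},
}


class SelectionError(RuntimeError):
    """No PCA component satisfies the ADL-clustering rule."""


def _complaint_frame(cohort: CohortTable) -> pd.DataFrame:
    df = cohort.df[list(schema.COMPLAINT_COLUMNS)]
    if df.isna().any().any():
        bad = cohort.df.loc[df.isna().any(axis=1), "subject_id"].tolist()
        logger.warning("excluding subjects with missing complaint items: %s", bad)
        df = df.dropna()
    return df.astype(int)


# ---------------------------------------------------------------------------
# Approach 1: Clinical
# ---------------------------------------------------------------------------

def clinical_label(items: dict | pd.Series,
                   domain_map: dict[str, str] | None = None) -> str:
    """Label one subject from their complaint items (keyed by item name)."""
    domain_map = domain_map or schema.DEFAULT_DOMAIN_MAP
    endorsed = {item for item in schema.COMPLAINT_ITEMS if items[item]}
    if not endorsed:
        return HC
    domains = {domain_map[item] for item in endorsed}
    amnestic = "memory" in domains
    single = len(domains) == 1
    if amnestic:
        return "aSCD_sd" if single else "aSCD_md"
    return "naSCD_sd" if single else "naSCD_md"


def classify_clinical(cohort: CohortTable,
                      domain_map: dict[str, str] | None = None) -> pd.Series:
    """MCI-style subtype per subject (indexed like the cohort frame)."""
    comp = _complaint_frame(cohort)
    comp = comp.rename(columns=lambda c: c.removeprefix("c_"))
    return comp.apply(lambda row: clinical_label(row, domain_map), axis=1).rename(
        "clinical")


# ---------------------------------------------------------------------------
# Approach 2: Psychometric
# ---------------------------------------------------------------------------

def classify_psychometric(totals: pd.Series, percentile: float = 90,
                          reference: pd.Series | None = None
                          ) -> tuple[pd.Series, int]:
    """Percentile-cutoff labels from the total complaint count.

    The cutoff is the nearest-rank ``percentile`` of the reference totals
    distribution (default: the totals themselves, i.e. the full sample).
    Returns (labels, cutoff).
    """
    reference = totals if reference is None else reference
    if len(reference) < 10:
        raise ValueError("reference sample too small for a percentile cutoff")
    cutoff = int(nearest_rank_percentile(reference, percentile))
    labels = pd.Series(NON_SCD, index=totals.index, name="psychometric")
    labels[totals == 0] = HC
    if cutoff > 0:
        labels[totals >= cutoff] = "SCD_90thPC"
    return labels, cutoff


# ---------------------------------------------------------------------------
# Approach 3: Distribution
# ---------------------------------------------------------------------------

def classify_distribution(cohort: CohortTable
                          ) -> tuple[pd.Series, tuple[int, int, int]]:
    """Empirical-distribution subtypes plus the quartile cuts of the totals.

    The subtype rules are exact complaint patterns: memory only -> amSCD;
    word-finding only -> anSCD; exactly both -> am_anSCD; complaints sparing
    both -> atSCD; any other complainer -> nonSCD.
    """
    comp = _complaint_frame(cohort)
    totals = comp.sum(axis=1)
    cuts = tuple(int(nearest_rank_percentile(totals, p)) for p in (25, 50, 75))
    mem = comp["c_memory"] == 1
    wf = comp["c_word_finding"] == 1
    labels = pd.Series(NON_SCD, index=comp.index, name="distribution")
    labels[totals == 0] = HC
    labels[mem & (totals == 1)] = "amSCD"
    labels[wf & (totals == 1)] = "anSCD"
    labels[mem & wf & (totals == 2)] = "am_anSCD"
    labels[(totals > 0) & ~mem & ~wf] = "atSCD"
    return labels, cuts


def quartile_assignment(totals: pd.Series,
                        cuts: tuple[int, int, int]) -> pd.Series:
    """Quartile label Q1..Q4 per subject from nearest-rank quartile cuts."""
    c25, c50, c75 = cuts
    q = pd.Series("Q4", index=totals.index)
    q[totals <= c75] = "Q3"
    q[totals <= c50] = "Q2"
    q[totals <= c25] = "Q1"
    return q


def quartile_complaint_crosstab(cohort: CohortTable,
                                items: tuple[str, ...] = ("memory", "word_finding")
                                ) -> pd.DataFrame:
    """Counts of complaint endorsement within each quartile of the totals."""
    comp = _complaint_frame(cohort)
    totals = comp.sum(axis=1)
    _, cuts = classify_distribution(cohort)
    quart = quartile_assignment(totals, cuts)
    table = pd.DataFrame(
        {item: comp.groupby(quart)[f"c_{item}"].sum() for item in items})
    return table.reindex(["Q1", "Q2", "Q3", "Q4"], fill_value=0).astype(int)


# ---------------------------------------------------------------------------
# Approach 4: Multivariate
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """Standardized-variable PCA with the clinical-severity component tagged."""

    loadings: pd.DataFrame            # variables x components, correlation-scaled
    explained_variance_ratio: np.ndarray
    scores: pd.DataFrame              # subjects x components
    component_id: int                 # 0-based index of the severity component
    adl_vars: tuple[str, ...]

    @property
    def severity_scores(self) -> pd.Series:
        """Oriented component scores: lower = worse clinical-cognitive status."""
        return self.scores.iloc[:, self.component_id]


def fit_clinical_severity_pca(cohort: CohortTable, n_components: int = 5,
                              adl_vars: tuple[str, ...] = schema.ADL_COLUMNS
                              ) -> PCAResult:
    """PCA over the cognitive battery plus ADL measures; find the component
    on which every ADL variable attains its maximum absolute loading.

    The severity component is sign-oriented so lower scores mean worse
    status (ADL-burden loadings negative). Several satisfying components are
    disambiguated by the largest summed absolute ADL loading; none at all
    raises :class:`SelectionError`.
    """
    variables = cohort.cognition_columns + list(adl_vars)
    X = cohort.df[variables].astype(float)
    if X.isna().any().any():
        raise ValueError("PCA input must be complete; impute first")
    Xs = (X - X.mean()) / X.std(ddof=1)
    pca = PCA(n_components=n_components)
    raw_scores = pca.fit_transform(Xs.to_numpy())
    # correlation-scaled loadings: component weights x singular scale
    load = pca.components_.T * np.sqrt(pca.explained_variance_)
    loadings = pd.DataFrame(
        load, index=variables,
        columns=[f"PC{i + 1}" for i in range(n_components)])

    adl_load = loadings.loc[list(adl_vars)].abs()
    argmax = adl_load.to_numpy().argmax(axis=1)
    candidates = sorted(set(argmax))
    satisfying = [c for c in candidates if (argmax == c).all()]
    if not satisfying:
        raise SelectionError(
            "no component clusters all ADL measures "
            f"(per-variable maxima on components {sorted(set(argmax + 1))}); "
            "inspect the loadings and choose manually")
    component_id = max(satisfying,
                       key=lambda c: adl_load.iloc[:, c].sum())

    # orient: ADL burden loads negatively (lower score = worse status)
    if loadings.loc[list(adl_vars)].iloc[:, component_id].sum() > 0:
        loadings.iloc[:, component_id] *= -1
        raw_scores[:, component_id] *= -1
    scores = pd.DataFrame(raw_scores, index=cohort.df.index,
                          columns=loadings.columns)
    return PCAResult(loadings, pca.explained_variance_ratio_, scores,
                     component_id, tuple(adl_vars))


@dataclass
class MultivariateRule:
    """The learned complaint-selection rule of the multivariate approach."""

    selected_complaints: tuple[str, ...]
    importance_table: pd.Series       # per-predictor OOB permutation importance
    importance_z: pd.Series           # importance / between-tree SE
    point_biserial: pd.Series         # complaint vs oriented component score
    component_id: int
    model_r2: float
    n_trees: int
    seed: int


def derive_multivariate_rule(cohort: CohortTable, pca_result: PCAResult,
                             n_trees: int = 5000, importance_threshold: float = 0.0,
                             relative_threshold: float = 0.10,
                             z_threshold: float = 2.0,
                             min_samples_leaf: int = 10,
                             seed: int = 0) -> MultivariateRule:
    """Random-forest regression of the severity component on the complaints
    plus age, sex, crystallized intelligence, and depressive symptomatology;
    a complaint is selected when its out-of-bag permutation importance
    clears the threshold, is significantly positive across trees, *and* its
    association points toward worse status (negative point-biserial
    correlation with the oriented component).

    The threshold is ``max(importance_threshold, relative_threshold *
    largest complaint importance)``, and significance means importance
    exceeding ``z_threshold`` between-tree standard errors. Both guards
    exist because permutation importance of a predictor a deep tree fits
    noise with is slightly positive on average; ``min_samples_leaf``
    regularizes the trees for the same reason.
    """
    from .characterize import oob_permutation_importance

    y = pca_result.severity_scores.to_numpy()
    if np.std(y) == 0:
        raise ValueError("component score has zero variance")
    df = cohort.df
    X = pd.DataFrame({
        **{item: df[f"c_{item}"].astype(float) for item in schema.COMPLAINT_ITEMS},
        "age": df["age"].astype(float),
        "sex": df["sex"].map(schema.SEX_CODES).astype(float),
        "wais_info": df["wais_info"].astype(float),
        "dep_z": df["dep_z"].astype(float),
    })
    forest = RandomForestRegressor(
        n_estimators=n_trees, oob_score=True, bootstrap=True,
        min_samples_leaf=min_samples_leaf, random_state=seed, n_jobs=1)
    forest.fit(X.to_numpy(), y)
    imp_mean, imp_se = oob_permutation_importance(
        forest, X.to_numpy(), y, seed=seed, with_se=True)
    importance = pd.Series(imp_mean, index=X.columns, name="importance")
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(imp_se > 0, imp_mean / imp_se, 0.0)
    importance_z = pd.Series(z, index=X.columns, name="importance_z")

    rpb = pd.Series(
        {item: stats.pointbiserialr(df[f"c_{item}"], y)[0]
         if df[f"c_{item}"].nunique() > 1 else 0.0
         for item in schema.COMPLAINT_ITEMS}, name="r_pb")
    top = float(importance[list(schema.COMPLAINT_ITEMS)].max())
    cut = max(importance_threshold, relative_threshold * max(top, 0.0))
    selected = tuple(
        item for item in schema.COMPLAINT_ITEMS
        if importance[item] > cut and importance_z[item] > z_threshold
        and rpb[item] < 0)
    return MultivariateRule(selected, importance, importance_z, rpb,
                            pca_result.component_id, float(forest.oob_score_),
                            n_trees, seed)


def classify_multivariate(cohort: CohortTable,
                          rule: MultivariateRule) -> pd.Series:
    """HC / SCD_multivariate / nonSCD labels from the learned rule.

    Endorsing any selected complaint — alone or with others — puts a
    complainer in the SCD group.
    """
    comp = _complaint_frame(cohort)
    totals = comp.sum(axis=1)
    labels = pd.Series(NON_SCD, index=comp.index, name="multivariate")
    labels[totals == 0] = HC
    if not rule.selected_complaints:
        logger.warning("empty multivariate rule: all complainers labelled nonSCD")
        return labels
    cols = [f"c_{item}" for item in rule.selected_complaints]
    hit = comp[cols].any(axis=1)
    labels[(totals > 0) & hit] = "SCD_multivariate"
    return labels


# ---------------------------------------------------------------------------
# overlap between approaches
# ---------------------------------------------------------------------------

@dataclass
class OverlapReport:
    """SCD membership per approach and their intersections."""

    n_complainers: int
    members: dict[str, frozenset] = field(default_factory=dict)
    pairwise_counts: pd.DataFrame | None = None
    four_way_count: int = 0

    @property
    def percentages(self) -> dict[str, float]:
        return {k: 100.0 * len(v) / self.n_complainers
                for k, v in self.members.items()}


def overlap_analysis(labels: dict[str, pd.Series]) -> OverlapReport:
    """Pairwise and four-way overlap of the SCD membership sets.

    ``labels`` maps approach name -> per-subject label Series (all on the
    same index). Percentages are relative to the complainer count (the
    Clinical approach membership).
    """
    approaches = list(labels)
    index = labels[approaches[0]].index
    for name, ser in labels.items():
        if not ser.index.equals(index):
            raise ValueError(f"label set {name!r} is from a different cohort")
    members = {
        name: frozenset(ser.index[ser.isin(SCD_LABELS[name])])
        for name, ser in labels.items()
    }
    complainers = frozenset(index[labels[approaches[0]] != HC])
    pair = pd.DataFrame(0, index=approaches, columns=approaches, dtype=int)
    for a in approaches:
        for b in approaches:
            pair.loc[a, b] = len(members[a] & members[b])
    four = len(frozenset.intersection(*members.values())) if members else 0
    return OverlapReport(len(complainers), members, pair, four)


def classify_all(cohort: CohortTable, percentile: float = 90,
                 domain_map: dict[str, str] | None = None,
                 n_trees: int = 500, seed: int = 0
                 ) -> tuple[pd.DataFrame, dict]:
    """Run all four approaches; returns (label table, metadata sidecar)."""
    clinical = classify_clinical(cohort, domain_map)
    totals = cohort.complaint_totals
    psychometric, cutoff = classify_psychometric(totals, percentile)
    distribution, cuts = classify_distribution(cohort)
    pca_result = fit_clinical_severity_pca(cohort)
    rule = derive_multivariate_rule(cohort, pca_result, n_trees=n_trees, seed=seed)
    multivariate = classify_multivariate(cohort, rule)
    table = pd.DataFrame({
        "subject_id": cohort.df["subject_id"],
        "clinical": clinical,
        "psychometric": psychometric,
        "distribution": distribution,
        "multivariate": multivariate,
    })
    meta = {
        "psychometric_cutoff": cutoff,
        "quartile_cuts": list(cuts),
        "severity_component": f"PC{pca_result.component_id + 1}",
        "selected_complaints": list(rule.selected_complaints),
        "rf_r2": rule.model_r2,
        "n_trees": n_trees,
        "seed": seed,
    }
    return table, meta
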