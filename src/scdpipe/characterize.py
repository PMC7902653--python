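"""Statistical characterization of SCD groups.

Random-forest classification of each SCD group against controls (out-of-bag
error vs error-by-chance), random-forest regressions of sMRI biomarkers on
the complaints, borderline-performance percentages under a covariate-
adjusted 10th-percentile threshold, group contrasts (ANOVA/ANCOVA,
Kruskal-Wallis, Mann-Whitney, chi-square) with Hochberg-corrected post-hoc
tests, the two-cell equal-proportion chi-square used for subtype size
contrasts, and residual-based partial correlation.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from statsmodels.stats.multitest import multipletests

from . import schema
from ._utils import nearest_rank_percentile
from .cohort import CohortTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# out-of-bag permutation importance
# ---------------------------------------------------------------------------

def _oob_indices(tree, n_samples: int) -> np.ndarray:
    # reproduce the forest's bootstrap draw: each tree samples n_samples
    # indices with replacement from RandomState(tree.random_state)
    sampled = np.random.RandomState(tree.random_state).randint(
        0, n_samples, n_samples)
    mask = np.ones(n_samples, dtype=bool)
    mask[sampled] = False
    return np.flatnonzero(mask)


def oob_permutation_importance(forest, X: np.ndarray, y: np.ndarray,
                               seed: int = 0, with_se: bool = False):
    """Mean out-of-bag increase in loss when one predictor is permuted.

    For each tree, predictions on its out-of-bag subjects are scored before
    and after permuting a single column (MSE for regressors, error rate for
    classifiers); the importance of a predictor is the average increase
    across trees. This is the importance convention of classical
    random-forest software: the relative loss in prediction when a predictor
    is perturbed out of the model. With ``with_se`` the between-tree
    standard error of the increase is returned as well, which supports a
    significance check on the importance.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, m = X.shape
    is_classifier = hasattr(forest, "classes_")
    rng = np.random.default_rng(seed)
    delta = np.zeros((len(forest.estimators_), m))
    for ti, tree in enumerate(forest.estimators_):
        oob = _oob_indices(tree, n)
        if oob.size == 0:
            continue
        Xo, yo = X[oob], y[oob]
        if is_classifier:
            base_pred = forest.classes_[
                np.argmax(tree.predict_proba(Xo), axis=1)]
            base = float(np.mean(base_pred != yo))
        else:
            base = float(np.mean((tree.predict(Xo) - yo) ** 2))
        for j in range(m):
            Xp = Xo.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            if is_classifier:
                pred = forest.classes_[np.argmax(tree.predict_proba(Xp), axis=1)]
                loss = float(np.mean(pred != yo))
            else:
                loss = float(np.mean((tree.predict(Xp) - yo) ** 2))
            delta[ti, j] = loss - base
    if with_se:
        se = delta.std(axis=0, ddof=1) / np.sqrt(delta.shape[0])
        return delta.mean(axis=0), se
    return delta.mean(axis=0)


# ---------------------------------------------------------------------------
# random-forest reports
# ---------------------------------------------------------------------------

def error_by_chance(n_classes: int) -> float:
    """Expected misclassification rate (%) of a uniform random guesser."""
    return 100.0 * (1.0 - 1.0 / n_classes)


@dataclass
class RFClassReport:
    class_errors: dict[str, float]     # per-class OOB error, %
    error_by_chance: float             # %
    top_predictors: list[str]
    importance: pd.Series
    n_per_class: dict[str, int]
    n_trees: int
    seed: int


@dataclass
class RFRegReport:
    outcome: str
    r2: float                          # out-of-bag R^2
    importance: pd.Series              # zero-floored for display
    n_trees: int
    seed: int


def _predictor_frame(cohort: CohortTable, include: str = "all") -> pd.DataFrame:
    df = cohort.df
    cols = {
        **{item: df[f"c_{item}"].astype(float)
           for item in schema.COMPLAINT_ITEMS},
        "age": df["age"].astype(float),
        "sex": df["sex"].map(schema.SEX_CODES).astype(float),
        "wais_info": df["wais_info"].astype(float),
    }
    if "dep_z" in df.columns:
        cols["dep_z"] = df["dep_z"].astype(float)
    if include == "all":
        for c in ("mmse", "faq", "bdrs_total"):
            cols[c] = df[c].astype(float)
        for c in cohort.cognition_columns:
            cols[c] = df[c].astype(float)
    return pd.DataFrame(cols)


def rf_group_vs_hc(cohort: CohortTable, labels: pd.Series,
                   n_trees: int = 5000, seed: int = 0,
                   predictors: pd.DataFrame | None = None) -> RFClassReport:
    """Random-forest classification of the SCD labels across demographic,
    clinical, and cognitive predictors; a usable model must beat
    error-by-chance = 100*(1 - 1/k)."""
    X = predictors if predictors is not None else _predictor_frame(cohort)
    y = labels.to_numpy()
    counts = pd.Series(y).value_counts()
    if (counts < 5).any():
        small = counts[counts < 5].index.tolist()
        raise ValueError(f"classes with < 5 subjects: {small}")
    if len(counts) < 2:
        raise ValueError("need at least two classes")
    forest = RandomForestClassifier(
        n_estimators=n_trees, oob_score=True, random_state=seed, n_jobs=1)
    forest.fit(X.to_numpy(), y)
    oob_pred = forest.classes_[np.argmax(forest.oob_decision_function_, axis=1)]
    class_errors = {
        cls: 100.0 * float(np.mean(oob_pred[y == cls] != cls))
        for cls in counts.index
    }
    imp = pd.Series(
        oob_permutation_importance(forest, X.to_numpy(), y, seed=seed),
        index=X.columns).sort_values(ascending=False)
    return RFClassReport(
        class_errors=class_errors,
        error_by_chance=error_by_chance(len(counts)),
        top_predictors=list(imp.index[:5]),
        importance=imp,
        n_per_class={str(k): int(v) for k, v in counts.items()},
        n_trees=n_trees, seed=seed)


def rf_biomarker_regression(cohort: CohortTable, outcome: str,
                            n_trees: int = 5000, seed: int = 0) -> RFRegReport:
    """Random-forest regression of an sMRI biomarker on the complaints plus
    age, sex, depressive symptomatology and crystallized intelligence.

    Age and ICV enter only the white-matter-lesion (``wmsa``) model: the
    severity index is already adjusted for both during its creation.
    """
    df = cohort.df
    if outcome not in df.columns:
        raise ValueError(f"outcome column {outcome!r} absent")
    y = df[outcome].astype(float)
    if y.std() == 0:
        raise ValueError("outcome has zero variance")
    X = _predictor_frame(cohort, include="complaints")
    if outcome == "wmsa":
        X["icv"] = df["icv"].astype(float)
    else:
        X = X.drop(columns=["age"], errors="ignore")
    forest = RandomForestRegressor(
        n_estimators=n_trees, oob_score=True, random_state=seed, n_jobs=1)
    forest.fit(X.to_numpy(), y.to_numpy())
    imp = pd.Series(
        oob_permutation_importance(forest, X.to_numpy(), y.to_numpy(), seed=seed),
        index=X.columns).sort_values(ascending=False)
    return RFRegReport(outcome=outcome, r2=float(forest.oob_score_),
                       importance=imp.clip(lower=0.0),
                       n_trees=n_trees, seed=seed)


# ---------------------------------------------------------------------------
# borderline performance
# ---------------------------------------------------------------------------

@dataclass
class BorderlineReport:
    percent_below: pd.DataFrame       # groups x components
    thresholds: pd.Series             # per component
    covariates: tuple[str, ...]
    percentile: float
    reference: str


def borderline_performance(scores: pd.DataFrame, covariates: pd.DataFrame,
                           groups: pd.Series, pct: float = 10,
                           reference_mask: pd.Series | None = None
                           ) -> BorderlineReport:
    """Percentage of each group scoring below the covariate-adjusted
    ``pct``-th percentile.

    Each component score is residualized on the covariates by OLS over the
    reference population (default: everyone); the nearest-rank percentile of
    the reference residuals is the threshold, and a subject at or below it
    is flagged.
    """
    ref = (reference_mask if reference_mask is not None
           else pd.Series(True, index=scores.index))
    Xcov = sm.add_constant(covariates.astype(float))
    flags = {}
    thresholds = {}
    for comp in scores.columns:
        fit = sm.OLS(scores.loc[ref, comp].astype(float), Xcov[ref]).fit()
        adjusted = scores[comp].astype(float) - fit.predict(Xcov)
        thr = nearest_rank_percentile(adjusted[ref], pct)
        flags[comp] = adjusted <= thr
        thresholds[comp] = thr
    flag_df = pd.DataFrame(flags)
    out = {}
    for g, idx in groups.groupby(groups).groups.items():
        if len(idx) == 0:
            logger.warning("empty group %r omitted", g)
            continue
        out[g] = 100.0 * flag_df.loc[idx].mean()
    return BorderlineReport(pd.DataFrame(out).T, pd.Series(thresholds),
                            tuple(covariates.columns), pct,
                            "custom" if reference_mask is not None else "full")


# ---------------------------------------------------------------------------
# contrasts
# ---------------------------------------------------------------------------

def equal_proportion_chisq(count_a: int, count_b: int) -> tuple[float, float]:
    """Two-cell goodness-of-fit chi-square against equal expected counts.

    chi2 = (a - b)^2 / (a + b) on 1 df, no continuity correction — the form
    used for subtype size contrasts.
    """
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be non-negative")
    total = count_a + count_b
    if total == 0:
        raise ValueError("both counts zero")
    chi2 = (count_a - count_b) ** 2 / total
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def hochberg_adjust(pvalues) -> np.ndarray:
    """Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="simes-hochberg")[1]


def partial_correlation(x, y, covariates=None) -> tuple[float, float]:
    """Correlation of OLS residuals of x and y on the covariates.

    With no covariates this is the Pearson correlation. The p-value is from
    the t distribution on n - k - 2 degrees of freedom (k covariates).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if covariates is None or (hasattr(covariates, "shape") and
                              np.size(covariates) == 0):
        Z = np.ones((n, 1))
        k = 0
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        k = C.shape[1]
        Z = np.column_stack([np.ones(n), C])
        if np.linalg.matrix_rank(Z) < Z.shape[1]:
            raise ValueError("rank-deficient covariates")
    if n <= k + 2:
        raise ValueError("too few observations for the covariate count")
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    r = float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    dof = n - k - 2
    r_clamped = min(max(r, -1 + 1e-15), 1 - 1e-15)
    tstat = r_clamped * np.sqrt(dof / (1 - r_clamped ** 2))
    p = 2 * stats.t.sf(abs(tstat), dof)
    return r, float(p)


@dataclass
class ContrastRow:
    variable: str
    test: str
    statistic: float
    p: float
    p_adjusted: float | None = None
    groups: tuple[str, ...] = ()
    covariates: tuple[str, ...] = ()


def group_contrasts(df: pd.DataFrame, labels: pd.Series, variables: list[str],
                    family: str = "anova", covariates: list[str] | None = None,
                    pairwise: bool = False) -> pd.DataFrame:
    """Per-variable omnibus group contrast, optionally with Hochberg-adjusted
    pairwise post-hocs (used for the sMRI variables).

    Families: ``anova``, ``ancova`` (OLS with covariates), ``kruskal``,
    ``mannwhitney`` (two groups), ``chisq`` (categorical variable).
    """
    covariates = covariates or []
    rows: list[ContrastRow] = []
    group_names = [g for g in labels.unique()]
    for var in variables:
        data = pd.DataFrame({"y": df[var], "g": labels})
        for c in covariates:
            data[c] = df[c]
        data = data.dropna()
        samples = [data.loc[data["g"] == g, "y"].to_numpy() for g in group_names]
        if family == "anova":
            f, p = stats.f_oneway(*samples)
            rows.append(ContrastRow(var, "anova", float(f), float(p),
                                    groups=tuple(group_names)))
        elif family == "ancova":
            formula = "y ~ C(g)" + "".join(f" + {c}" for c in covariates)
            fit = smf.ols(formula, data=data).fit()
            table = sm.stats.anova_lm(fit, typ=2)
            rows.append(ContrastRow(var, "ancova",
                                    float(table.loc["C(g)", "F"]),
                                    float(table.loc["C(g)", "PR(>F)"]),
                                    groups=tuple(group_names),
                                    covariates=tuple(covariates)))
        elif family == "kruskal":
            h, p = stats.kruskal(*samples)
            rows.append(ContrastRow(var, "kruskal", float(h), float(p),
                                    groups=tuple(group_names)))
        elif family == "mannwhitney":
            if len(samples) != 2:
                raise ValueError("mannwhitney needs exactly two groups")
            u, p = stats.mannwhitneyu(*samples, alternative="two-sided")
            rows.append(ContrastRow(var, "mannwhitney", float(u), float(p),
                                    groups=tuple(group_names)))
        elif family == "chisq":
            table = pd.crosstab(data["g"], data["y"])
            chi2, p, _, _ = stats.chi2_contingency(table)
            rows.append(ContrastRow(var, "chisq", float(chi2), float(p),
                                    groups=tuple(group_names)))
        else:
            raise ValueError(f"unknown contrast family {family!r}")

        if pairwise and family in {"anova", "ancova"}:
            pair_rows = []
            for a, b in itertools.combinations(group_names, 2):
                sub = data[data["g"].isin([a, b])]
                if family == "ancova" and covariates:
                    formula = "y ~ C(g)" + "".join(f" + {c}" for c in covariates)
                    fit = smf.ols(formula, data=sub).fit()
                    tab = sm.stats.anova_lm(fit, typ=2)
                    stat_, p_ = (float(tab.loc["C(g)", "F"]),
                                 float(tab.loc["C(g)", "PR(>F)"]))
                else:
                    stat_, p_ = stats.f_oneway(
                        sub.loc[sub["g"] == a, "y"], sub.loc[sub["g"] == b, "y"])
                pair_rows.append(ContrastRow(
                    var, f"posthoc_{family}", float(stat_), float(p_),
                    groups=(a, b), covariates=tuple(covariates)))
            adj = hochberg_adjust([r.p for r in pair_rows])
            for r, pa in zip(pair_rows, adj):
                r.p_adjusted = float(pa)
            rows.extend(pair_rows)

    out = pd.DataFrame([vars(r) for r in rows])
    return out
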