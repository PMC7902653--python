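"""Structural-MRI disease severity index.

A case/control OPLS model (orthogonal projections to latent structures) is
trained on age/ICV-residualized morphometry from a labelled HC/AD reference
set, and new subjects are projected onto it as unseen data. The predictive
score is regressed onto the 0/1 class coding, so the projected index is ~0
for a control-like atrophy pattern and ~1 for an AD-like pattern (values may
fall slightly outside [0, 1]; no clipping). Model quality is summarized by
R2X (X variance captured by the predictive + orthogonal components), R2Y
(in-sample fit of the class variable) and Q2Y (sevenfold cross-validated
predictive ability; > 0.1 acceptable, > 0.5 good, > 0.9 optimal).

OPLS here is the single-response form: orthogonal components — systematic
X-variation uncorrelated with the class — are peeled off one at a time, and
a single predictive component is fitted to what remains. With zero
orthogonal components it reduces exactly to one-component PLS1.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from ._utils import nearest_rank_percentile

logger = logging.getLogger(__name__)

Q2_BANDS = ((0.9, "optimal"), (0.5, "good"), (0.1, "acceptable"))


def q2_band(q2: float) -> str:
    for cut, name in Q2_BANDS:
        if q2 > cut:
            return name
    return "not significant"


# ---------------------------------------------------------------------------
# age/ICV residualization
# ---------------------------------------------------------------------------

@dataclass
class ResidualizationFit:
    """Per-feature OLS coefficients for the nuisance covariates.

    Thickness features are adjusted for age only; volumetric features for
    age and ICV. Coefficients are estimated once on the declared reference
    population and applied to everyone.
    """

    coef: pd.DataFrame        # features x [intercept, age, icv]; icv NaN for ct_
    reference: str = ""

    def covariates_for(self, feature: str) -> list[str]:
        return ["age"] if feature.startswith("ct_") else ["age", "icv"]


def fit_residualization(df: pd.DataFrame, feature_names: list[str],
                        reference: str = "") -> ResidualizationFit:
    """OLS fit of each sMRI feature on age (thickness) or age + ICV (volumes)."""
    rows = {}
    for feat in feature_names:
        covs = ["age"] if feat.startswith("ct_") else ["age", "icv"]
        sub = df[[feat] + covs].dropna()
        X = np.column_stack([np.ones(len(sub))] + [sub[c].to_numpy() for c in covs])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(f"collinear or constant covariates for {feat!r}")
        beta, *_ = np.linalg.lstsq(X, sub[feat].to_numpy(), rcond=None)
        rows[feat] = {"intercept": beta[0], "age": beta[1],
                      "icv": beta[2] if len(covs) == 2 else np.nan}
    return ResidualizationFit(pd.DataFrame(rows).T, reference)


def residualize(df: pd.DataFrame, fit: ResidualizationFit) -> pd.DataFrame:
    """Adjusted feature = observed - covariate prediction (reference fit)."""
    missing = [f for f in fit.coef.index if f not in df.columns]
    if missing:
        raise ValueError(f"features absent from table: {missing}")
    for cov in ("age", "icv"):
        if fit.coef[cov].notna().any() and cov not in df.columns:
            raise ValueError(f"missing covariate column {cov!r}")
    out = {}
    for feat, row in fit.coef.iterrows():
        pred = row["intercept"] + row["age"] * df["age"].to_numpy()
        if np.isfinite(row["icv"]):
            pred = pred + row["icv"] * df["icv"].to_numpy()
        out[feat] = df[feat].to_numpy() - pred
    return pd.DataFrame(out, index=df.index)


# ---------------------------------------------------------------------------
# OPLS
# ---------------------------------------------------------------------------

@dataclass
class SeverityModel:
    """Fitted OPLS case/control model with its scaling, on HC=0/AD=1 coding."""

    feature_names: list[str]
    x_mean: np.ndarray
    x_sd: np.ndarray
    w: np.ndarray                 # predictive weights, unit norm
    p: np.ndarray                 # predictive X-loadings
    q: float                      # regression of centered y on the score
    y_mean: float
    w_orth: np.ndarray            # (k, n_features)
    p_orth: np.ndarray            # (k, n_features)
    r2x: float
    r2y: float
    q2y: float | None = None
    n_per_class: dict[str, int] = field(default_factory=dict)

    @property
    def n_orthogonal(self) -> int:
        return self.w_orth.shape[0]

    def to_json(self, path: str | Path) -> None:
        doc = asdict(self)
        for key in ("x_mean", "x_sd", "w", "p", "w_orth", "p_orth"):
            doc[key] = np.asarray(doc[key]).tolist()
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SeverityModel":
        doc = json.loads(Path(path).read_text())
        for key in ("x_mean", "x_sd", "w", "p", "w_orth", "p_orth"):
            doc[key] = np.asarray(doc[key], dtype=float)
        doc["w_orth"] = doc["w_orth"].reshape(-1, len(doc["feature_names"]))
        doc["p_orth"] = doc["p_orth"].reshape(-1, len(doc["feature_names"]))
        return cls(**doc)


def _scale(X: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    return (X - mean) / sd


def fit_opls(X: pd.DataFrame | np.ndarray, y: np.ndarray,
             n_orthogonal: int = 0,
             feature_names: list[str] | None = None) -> SeverityModel:
    """Fit the OPLS model: ``n_orthogonal`` orthogonal components followed by
    one predictive component, on unit-variance-scaled X and 0/1 y.

    Orthogonal score vectors are exactly uncorrelated with y by
    construction; with ``n_orthogonal=0`` the predictive component is the
    first PLS1 component.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    elif feature_names is None:
        feature_names = [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(y, dtype=float)
    classes = np.unique(y)
    if not np.array_equal(classes, [0.0, 1.0]):
        raise ValueError("y must contain both classes coded 0/1")
    n, m = X.shape
    if n_orthogonal >= min(n, m):
        raise ValueError("n_orthogonal exceeds the matrix rank budget")

    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0, ddof=1)
    if np.any(x_sd == 0):
        raise ValueError("constant feature; cannot unit-variance scale")
    Xc = _scale(X, x_mean, x_sd)
    X0 = Xc.copy()
    y_mean = float(y.mean())
    yc = y - y_mean

    w_orth, p_orth, ssx_orth = [], [], 0.0
    for _ in range(n_orthogonal):
        w = Xc.T @ yc
        w /= np.linalg.norm(w)
        t = Xc @ w
        p = Xc.T @ t / (t @ t)
        wo = p - (w @ p) * w
        norm = np.linalg.norm(wo)
        if norm < 1e-12:
            raise ValueError("no orthogonal variation left to extract")
        wo /= norm
        to = Xc @ wo
        po = Xc.T @ to / (to @ to)
        Xc = Xc - np.outer(to, po)
        w_orth.append(wo)
        p_orth.append(po)
        ssx_orth += float((to @ to) * (po @ po))

    w = Xc.T @ yc
    w /= np.linalg.norm(w)
    t = Xc @ w
    p = Xc.T @ t / (t @ t)
    q = float(t @ yc / (t @ t))

    ssx_total = float((X0 ** 2).sum())
    ssx_pred = float((t @ t) * (p @ p))
    r2x = (ssx_pred + ssx_orth) / ssx_total
    resid = yc - q * t
    r2y = 1.0 - float(resid @ resid) / float(yc @ yc)

    n_per_class = {"HC": int((y == 0).sum()), "AD": int((y == 1).sum())}
    return SeverityModel(
        feature_names=feature_names, x_mean=x_mean, x_sd=x_sd,
        w=w, p=p, q=q, y_mean=y_mean,
        w_orth=np.array(w_orth).reshape(len(w_orth), m),
        p_orth=np.array(p_orth).reshape(len(p_orth), m),
        r2x=float(r2x), r2y=float(r2y), n_per_class=n_per_class)


def project(model: SeverityModel, X: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Disease severity index for (residualized) feature rows.

    Orthogonal variation is removed from each subject's vector with the
    training loadings; the remaining predictive score is mapped through the
    training regression onto the HC=0 / AD=1 scale.
    """
    if isinstance(X, pd.DataFrame):
        missing = [f for f in model.feature_names if f not in X.columns]
        if missing:
            raise ValueError(f"feature mismatch; missing {missing}")
        X = X[model.feature_names].to_numpy(dtype=float)
    if X.shape[1] != len(model.feature_names):
        raise ValueError("feature count mismatch")
    Xs = _scale(X, model.x_mean, model.x_sd)
    for wo, po in zip(model.w_orth, model.p_orth):
        to = Xs @ wo
        Xs = Xs - np.outer(to, po)
    t = Xs @ model.w
    return model.y_mean + model.q * t


def orthogonal_scores(model: SeverityModel, X: pd.DataFrame | np.ndarray
                      ) -> np.ndarray:
    """Per-component orthogonal scores (n_subjects x k), for diagnostics."""
    if isinstance(X, pd.DataFrame):
        X = X[model.feature_names].to_numpy(dtype=float)
    Xs = _scale(X, model.x_mean, model.x_sd)
    out = []
    for wo, po in zip(model.w_orth, model.p_orth):
        to = Xs @ wo
        out.append(to)
        Xs = Xs - np.outer(to, po)
    return np.array(out).T if out else np.empty((X.shape[0], 0))


def cross_validate_q2(X: pd.DataFrame | np.ndarray, y: np.ndarray,
                      folds: int = 7, n_orthogonal: int = 0,
                      seed: int = 0) -> float:
    """Sevenfold (by default) stratified Q2Y = 1 - PRESS/SS.

    All preprocessing (unit-variance scaling and the OPLS fit) is nested
    inside each training fold; PRESS accumulates over held-out predictions.
    """
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) < folds:
        raise ValueError("fewer subjects than folds")
    counts = np.bincount(y.astype(int))
    if counts.min() < folds:
        raise ValueError("stratification impossible: a class is smaller than "
                         "the fold count")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    press = 0.0
    for train, test in skf.split(X, y):
        model = fit_opls(X[train], y[train], n_orthogonal)
        pred = project(model, X[test])
        press += float(((y[test] - pred) ** 2).sum())
    ss = float(((y - y.mean()) ** 2).sum())
    q2 = 1.0 - press / ss
    logger.info("Q2(Y) = %.3f over %d folds (%s)", q2, folds, q2_band(q2))
    return q2


def select_n_orthogonal(X, y, candidates=range(4), folds: int = 7,
                        seed: int = 0) -> tuple[int, dict[int, float]]:
    """Pick the orthogonal-component count maximizing the sevenfold Q2."""
    scores = {k: cross_validate_q2(X, y, folds=folds, n_orthogonal=k, seed=seed)
              for k in candidates}
    best = max(scores, key=scores.get)
    return best, scores


def fit_severity_model(reference: pd.DataFrame, feature_names: list[str],
                       n_orthogonal: int | None = None, folds: int = 7,
                       seed: int = 0) -> tuple[SeverityModel, ResidualizationFit]:
    """End-to-end fit on a labelled reference table (column ``group``: HC/AD).

    Residualization coefficients are estimated on the HC subjects only and
    applied to everyone; the orthogonal-component count defaults to the Q2
    maximizer over 0..3.
    """
    y = (reference["group"] == "AD").to_numpy(dtype=float)
    res_fit = fit_residualization(reference[reference["group"] == "HC"],
                                  feature_names, reference="HC")
    Xadj = residualize(reference, res_fit)
    if n_orthogonal is None:
        n_orthogonal, _ = select_n_orthogonal(Xadj, y, folds=folds, seed=seed)
    model = fit_opls(Xadj, y, n_orthogonal)
    model.q2y = cross_validate_q2(Xadj, y, folds=folds,
                                  n_orthogonal=n_orthogonal, seed=seed)
    return model, res_fit


# ---------------------------------------------------------------------------
# interpretation helpers
# ---------------------------------------------------------------------------

def rank_model_regions(model: SeverityModel) -> pd.DataFrame:
    """Features by decreasing contribution |w|; negative sign = reduced in AD."""
    table = pd.DataFrame({
        "feature": model.feature_names,
        "weight": model.w * np.sign(model.q),
    })
    table["abs_weight"] = table["weight"].abs()
    table = table.sort_values(["abs_weight", "feature"],
                              ascending=[False, True], ignore_index=True)
    return table.drop(columns="abs_weight")


def dichotomize_index(scores: np.ndarray | pd.Series, percentile: float = 90,
                      reference: np.ndarray | pd.Series | None = None
                      ) -> tuple[np.ndarray, float]:
    """AD-like flags from a nearest-rank percentile threshold.

    ``reference`` defaults to the scores themselves (the projected cohort);
    a score at or above the threshold is flagged AD-like.
    """
    scores = np.asarray(scores, dtype=float)
    ref = scores if reference is None else np.asarray(reference, dtype=float)
    if ref.size < 10:
        raise ValueError("reference sample too small for a percentile threshold")
    threshold = nearest_rank_percentile(ref, percentile)
    if np.ptp(ref) == 0:
        logger.warning("degenerate reference: all scores equal %.4f", threshold)
    return scores >= threshold, threshold
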