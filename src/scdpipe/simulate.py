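"""Synthetic cohorts with the latent structure the analysis pipeline assumes.

The generator emulates a community-based ageing cohort screened for normal
functional status: nine binary cognitive-complaint items with marginal
prevalences dominated by word-finding (~36%) and memory (~27%), a cognitive
battery driven by five latent factors (visual, verbal memory, visual memory,
clinical severity, executive/premotor), floor-heavy ADL scales tied to the
clinical-severity factor, and ~2% missingness in the battery. A companion
generator produces a labelled HC/AD structural-MRI reference set with an
AD-signature atrophy pattern (hippocampus, precuneus, supramarginal,
inferior parietal; enlarged inferior lateral ventricles) plus age and ICV
covariate effects, standing in for the external case/control training data.

Complaint items are Bernoulli draws through a logistic link on the latent
factors; the link intercept is solved numerically (Gauss-Hermite quadrature
+ Brent root finding) so each item hits its target marginal prevalence
regardless of the dependence structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

from . import schema
from .cohort import CohortTable


class SimulationError(RuntimeError):
    """Raised when the requested cohort cannot be calibrated or generated."""


#: The five latent cognitive factors, independent standard normals.
FACTORS: tuple[str, ...] = (
    "visual", "verbal_memory", "visual_memory", "severity", "executive",
)

#: Target marginal prevalence of each complaint item.
DEFAULT_PREVALENCE: dict[str, float] = {
    "orientation": 0.051,
    "memory": 0.27,
    "face_recognition": 0.0595,
    "executive": 0.0425,
    "word_finding": 0.36,
    "reading": 0.034,
    "writing": 0.034,
    "lang_production": 0.051,
    "lang_comprehension": 0.0425,
}

#: Logistic coefficients of each complaint on the latent factors. Negative
#: coefficients mean a *lower* factor score raises the complaint odds. The
#: amnestic cluster (orientation, memory) loads on verbal memory + severity;
#: the anomic cluster (word-finding, other language items) loads on the
#: executive/premotor factor, with word-finding saturating both clusters and
#: writing/production/comprehension carrying the severity link.
DEFAULT_COMPLAINT_LINKS: dict[str, dict[str, float]] = {
    "orientation": {"verbal_memory": -1.275, "severity": -1.02},
    "memory": {"verbal_memory": -3.0, "severity": -1.5},
    "face_recognition": {"visual": -1.275, "visual_memory": -0.765},
    "executive": {"executive": -1.275, "severity": -0.765},
    "word_finding": {"executive": -2.4, "verbal_memory": -2.2},
    "reading": {"executive": -1.275, "severity": -0.765},
    "writing": {"severity": -1.53, "executive": -1.02},
    "lang_production": {"severity": -1.275, "executive": -1.02},
    "lang_comprehension": {"severity": -1.275, "executive": -1.02},
}


@dataclass
class SimulationParams:
    """Knobs of the cohort generator; defaults emulate a community-based
    cohort of ~400 screened adults."""

    n_subjects: int = 399
    complaint_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE))
    complaint_links: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COMPLAINT_LINKS.items()})
    n_cognitive: int = 20
    factor_loading: float = 0.7
    noise_sd: float = 0.714  # residual SD so battery scores have unit variance
    #: cross-loading of alternating verbal-memory battery variables on the
    #: clinical-severity factor (the episodic-memory/fluency mixing that makes
    #: those variables cluster with the ADL measures); 0 = pure factors
    severity_cross_loading: float = 0.45
    age_mean: float = 58.0
    age_sd: float = 11.0
    age_range: tuple[float, float] = (35.0, 90.0)
    prop_female: float = 0.55
    missing_rate: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 10:
            raise SimulationError("n_subjects must be >= 10")
        for item, p in self.complaint_prevalence.items():
            if not 0 < p < 1:
                raise SimulationError(f"prevalence for {item!r} must be in (0,1)")
        for item, links in self.complaint_links.items():
            for f, b in links.items():
                if f not in FACTORS:
                    raise SimulationError(f"unknown factor {f!r} for {item!r}")
                if not np.isfinite(b):
                    raise SimulationError(f"non-finite link for {item!r}")
        if not 1 <= self.n_cognitive <= 67:
            raise SimulationError("n_cognitive must be in [1, 67]")
        if not 0 <= self.missing_rate < 1:
            raise SimulationError("missing_rate must be in [0, 1)")


def calibrate_intercept(target: float, link_scale: float) -> float:
    """Intercept of a logistic item so its marginal prevalence hits ``target``.

    The linear predictor is ``alpha + s*Z`` with ``Z ~ N(0,1)`` and
    ``s = link_scale``; the marginal is computed with 80-node Gauss-Hermite
    quadrature and inverted with Brent's method.
    """
    if link_scale == 0:
        return float(special.logit(target))
    nodes, weights = np.polynomial.hermite_e.hermegauss(80)
    weights = weights / np.sqrt(2 * np.pi)

    def marginal(alpha: float) -> float:
        return float(weights @ special.expit(alpha + link_scale * nodes))

    try:
        return float(optimize.brentq(
            lambda a: marginal(a) - target, -40.0, 40.0, xtol=1e-12))
    except ValueError as exc:  # pragma: no cover - requires absurd parameters
        raise SimulationError(
            f"intercept calibration failed for target {target}") from exc


def _cognition_layout(n_cognitive: int, severity_cross_loading: float = 0.45
                      ) -> list[tuple[str, dict[str, float]]]:
    """Assign each battery variable a primary factor (round-robin) plus the
    severity cross-loadings that make some memory/fluency-style variables
    cluster with the ADL measures."""
    layout = []
    for i in range(n_cognitive):
        primary = FACTORS[i % len(FACTORS)]
        loadings = {primary: 1.0}
        # every other verbal-memory variable also tracks clinical severity
        if (primary == "verbal_memory" and (i // len(FACTORS)) % 2 == 0
                and severity_cross_loading):
            loadings["severity"] = severity_cross_loading
        layout.append((f"cog_{i + 1:02d}", loadings))
    return layout


def planted_language_links() -> dict[str, dict[str, float]]:
    """Link configuration planting the severity signal exclusively on the
    writing / language-production / language-comprehension complaints.

    Every other complaint loads only on factors orthogonal to clinical
    severity, so a correct multivariate rule selects exactly the three
    language items. Pair with ``severity_cross_loading=0`` for pure factors.
    """
    return {
        "orientation": {"verbal_memory": -1.0},
        "memory": {"verbal_memory": -1.6},
        "face_recognition": {"visual": -1.2},
        "executive": {"executive": -1.2},
        "word_finding": {"executive": -1.6},
        "reading": {"executive": -1.0},
        "writing": {"severity": -2.5},
        "lang_production": {"severity": -2.5},
        "lang_comprehension": {"severity": -2.5},
    }


def planted_language_scenario(n_subjects: int = 1000, seed: int = 0
                              ) -> SimulationParams:
    """The planted-truth recovery scenario for the multivariate rule.

    Strong severity links sit exclusively on the three language items
    (see :func:`planted_language_links`), latent factors are pure
    (no severity cross-loading in the battery), and the planted items are
    endorsed by ~10% of subjects so each carries enough endorsements at
    ``n_subjects=1000`` for its effect to be estimable.
    """
    prevalence = dict(DEFAULT_PREVALENCE)
    for item in ("writing", "lang_production", "lang_comprehension"):
        prevalence[item] = 0.10
    return SimulationParams(
        n_subjects=n_subjects, seed=seed,
        complaint_links=planted_language_links(),
        complaint_prevalence=prevalence,
        severity_cross_loading=0.0)


def generate_cohort(params: SimulationParams | None = None) -> CohortTable:
    """Draw a complete synthetic cohort; bit-reproducible from ``params.seed``."""
    params = params or SimulationParams()
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_subjects

    factors = pd.DataFrame(
        rng.standard_normal((n, len(FACTORS))), columns=list(FACTORS))

    age = np.clip(rng.normal(params.age_mean, params.age_sd, n), *params.age_range)
    sex = np.where(rng.random(n) < params.prop_female,
                   schema.SEX_FEMALE, schema.SEX_MALE)
    wais = np.clip(15.5 + 1.8 * factors["severity"] + rng.normal(0, 6.0, n), 0, 28)

    df = pd.DataFrame({
        "subject_id": [f"S{i + 1:04d}" for i in range(n)],
        "age": np.round(age, 1),
        "sex": sex,
        "wais_info": np.round(wais, 0),
    })

    # floor-heavy ADL scales: discretized monotone transforms of (-severity)
    worse = -factors["severity"].to_numpy()
    def adl(coef, noise, cap):
        raw = coef * worse + rng.normal(0, noise, n)
        return np.clip(np.round(raw), 0, cap).astype(int)

    df["faq"] = adl(0.9, 0.6, 30)
    df["bdrs_adl"] = adl(0.8, 0.6, 9)
    df["bdrs_habits"] = adl(0.5, 0.5, 9)
    df["bdrs_personality"] = adl(0.4, 0.5, 9)
    df["bdrs_total"] = df["bdrs_adl"] + df["bdrs_habits"] + df["bdrs_personality"]
    df["mmse"] = 30 - np.clip(
        np.round(0.7 * worse + rng.normal(0, 0.8, n)), 0, 4).astype(int)

    is_bdi = df["age"] < 63
    df["dep_scale"] = np.where(is_bdi, "BDI", "GDS")
    dep = np.where(is_bdi,
                   8 + 1.0 * worse + rng.normal(0, 4.5, n),
                   5 + 0.8 * worse + rng.normal(0, 3.0, n))
    df["dep_raw"] = np.clip(np.round(dep), 0, 40).astype(int)

    # cognitive battery: linear latent-factor model, unit-variance targets
    for name, loadings in _cognition_layout(params.n_cognitive,
                                            params.severity_cross_loading):
        signal = sum(params.factor_loading * w * factors[f]
                     for f, w in loadings.items())
        df[name] = np.round(signal + rng.normal(0, params.noise_sd, n), 4)

    # complaints: logistic on latent factors, intercept calibrated to target
    F = factors.to_numpy()
    for item in schema.COMPLAINT_ITEMS:
        links = params.complaint_links.get(item, {})
        beta = np.array([links.get(f, 0.0) for f in FACTORS])
        alpha = calibrate_intercept(params.complaint_prevalence[item],
                                    float(np.linalg.norm(beta)))
        prob = special.expit(alpha + F @ beta)
        df[f"c_{item}"] = (rng.random(n) < prob).astype(int)

    # retain latent factors for downstream planted-truth checks
    for f in FACTORS:
        df[f"latent_{f}"] = np.round(factors[f], 6)

    # inject missingness into the battery only
    if params.missing_rate > 0:
        cog_cols = [name for name, _ in _cognition_layout(params.n_cognitive,
                                                          params.severity_cross_loading)]
        mask = rng.random((n, len(cog_cols))) < params.missing_rate
        block = df[cog_cols].to_numpy(dtype=float)
        block[mask] = np.nan
        df[cog_cols] = block

    return CohortTable(df, {"source": "synthetic", "seed": params.seed})


# ---------------------------------------------------------------------------
# structural-MRI reference set (HC vs AD) and cohort sMRI attachment
# ---------------------------------------------------------------------------

APARC_REGIONS: tuple[str, ...] = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "fusiform", "inferiorparietal", "inferiortemporal",
    "isthmuscingulate", "lateraloccipital", "lateralorbitofrontal", "lingual",
    "medialorbitofrontal", "middletemporal", "parahippocampal", "paracentral",
    "parsopercularis", "parsorbitalis", "parstriangularis", "pericalcarine",
    "postcentral", "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal", "frontalpole",
    "temporalpole", "transversetemporal", "insula",
)

#: (region, baseline mm^3, between-subject SD) for the 21 aseg structures.
_ASEG_BILATERAL: tuple[tuple[str, float, float], ...] = (
    ("lateral_ventricle", 8000.0, 3000.0),
    ("inf_lat_vent", 400.0, 150.0),
    ("thalamus", 7000.0, 700.0),
    ("caudate", 3500.0, 400.0),
    ("putamen", 5000.0, 500.0),
    ("pallidum", 1800.0, 200.0),
    ("hippocampus", 4000.0, 400.0),
    ("amygdala", 1500.0, 200.0),
    ("accumbens", 600.0, 100.0),
    ("ventraldc", 4000.0, 400.0),
)

THICKNESS_BASELINE = 2.5   # mm
THICKNESS_SD = 0.15

#: Standardized AD-vs-HC mean shifts (Cohen's d in units of the within-group
#: residual SD, i.e. net of the age/ICV variance); negative = reduced in AD.
DEFAULT_ATROPHY_EFFECT: dict[str, float] = {
    "vol_left_hippocampus": -1.8,
    "vol_right_hippocampus": -1.8,
    "vol_left_inf_lat_vent": 1.2,
    "vol_right_inf_lat_vent": 1.2,
    "vol_left_amygdala": -0.8,
    "vol_right_amygdala": -0.8,
    "ct_lh_entorhinal": -1.0,
    "ct_rh_entorhinal": -1.0,
    "ct_lh_precuneus": -1.0,
    "ct_rh_precuneus": -1.0,
    "ct_rh_supramarginal": -0.9,
    "ct_lh_supramarginal": -0.5,
    "ct_lh_inferiorparietal": -0.9,
    "ct_rh_inferiorparietal": -0.9,
    "ct_lh_middletemporal": -0.6,
    "ct_rh_middletemporal": -0.6,
    "ct_lh_fusiform": -0.5,
    "ct_rh_fusiform": -0.5,
}
#: mild global cortical thinning applied to all other thickness features
DEFAULT_GLOBAL_THINNING = -0.3


def smri_feature_names() -> list[str]:
    names = [f"ct_{h}_{r}" for h in ("lh", "rh") for r in APARC_REGIONS]
    names += [f"vol_{side}_{r}" for r, _, _ in _ASEG_BILATERAL
              for side in ("left", "right")]
    names.append("vol_brainstem")
    return names


def _feature_scales() -> dict[str, tuple[float, float]]:
    """feature -> (baseline, between-subject SD)."""
    scales = {f"ct_{h}_{r}": (THICKNESS_BASELINE, THICKNESS_SD)
              for h in ("lh", "rh") for r in APARC_REGIONS}
    for r, base, sd in _ASEG_BILATERAL:
        scales[f"vol_left_{r}"] = (base, sd)
        scales[f"vol_right_{r}"] = (base, sd)
    scales["vol_brainstem"] = (21000.0, 2000.0)
    return scales


@dataclass
class SMRIReferenceParams:
    """HC/AD case-control reference generator; defaults mirror a 69/39 split."""

    n_hc: int = 69
    n_ad: int = 39
    atrophy_effect: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ATROPHY_EFFECT))
    global_thinning: float = DEFAULT_GLOBAL_THINNING
    age_mean: float = 73.0
    age_sd: float = 7.0
    age_slope_thickness: float = -0.008   # mm per year
    age_slope_volume: float = -0.002      # fraction of baseline per year
    ventricle_age_slope: float = 0.010    # ventricles grow with age
    icv_mean: float = 1.5e6
    icv_sd: float = 1.4e5
    seed: int = 0

    def validate(self) -> None:
        if self.n_hc < 5 or self.n_ad < 5:
            raise SimulationError("need at least 5 subjects per group")
        for feat, d in self.atrophy_effect.items():
            if feat.startswith("vol_") and "vent" in feat:
                if d < 0:
                    raise SimulationError(
                        f"ventricular shift must be >= 0 for {feat!r}")
            elif d > 0:
                raise SimulationError(
                    f"AD shift must be <= 0 for non-ventricular {feat!r}")


def _draw_smri_block(rng, n, age, icv, ad_load, params: SMRIReferenceParams
                     ) -> pd.DataFrame:
    """Morphometric features for ``n`` subjects.

    ``ad_load`` is a per-subject multiplier on the standardized atrophy
    pattern: 0/1 group labels for the reference set, a continuous severity
    score when attaching sMRI to a cohort.
    """
    scales = _feature_scales()
    age_c = age - params.age_mean
    icv_c = (icv - params.icv_mean) / params.icv_mean
    out = {}
    for feat in smri_feature_names():
        base, sd = scales[feat]
        if feat.startswith("ct_"):
            shift = params.atrophy_effect.get(feat, params.global_thinning)
            mean = base + params.age_slope_thickness * age_c
        else:
            shift = params.atrophy_effect.get(feat, 0.0)
            slope = (params.ventricle_age_slope if "vent" in feat
                     else params.age_slope_volume)
            mean = base * (1 + slope * age_c / 10.0) + base * 0.8 * icv_c
        values = mean + ad_load * shift * sd + rng.normal(0, sd, n)
        out[feat] = np.maximum(values, base * 0.05)  # physical positivity
    return pd.DataFrame(out)


def generate_smri_reference(params: SMRIReferenceParams | None = None
                            ) -> pd.DataFrame:
    """Labelled HC/AD reference table with `group`, `age`, `icv`, features."""
    params = params or SMRIReferenceParams()
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_hc + params.n_ad
    group = np.array(["HC"] * params.n_hc + ["AD"] * params.n_ad)
    age = np.clip(rng.normal(params.age_mean, params.age_sd, n), 55, 95)
    icv = rng.normal(params.icv_mean, params.icv_sd, n)
    label = (group == "AD").astype(float)
    feats = _draw_smri_block(rng, n, age, icv, label, params)
    wmsa = np.exp(np.log(2500) + 0.035 * (age - params.age_mean)
                  + 0.3 * label + rng.normal(0, 0.5, n))
    df = pd.DataFrame({
        "subject_id": [f"R{i + 1:04d}" for i in range(n)],
        "group": group,
        "age": np.round(age, 1),
        "icv": np.round(icv, 0),
        "wmsa": np.round(wmsa, 1),
    })
    return pd.concat([df, feats.round(4)], axis=1)


def attach_smri_to_cohort(cohort: CohortTable, severity_link: float = 0.15,
                          wmsa_link: float = 0.5, seed: int = 0,
                          smri_params: SMRIReferenceParams | None = None
                          ) -> CohortTable:
    """Give each cohort subject sMRI features tied to its latent factors.

    The AD-signature atrophy pattern scales with ``severity_link`` times the
    inverse clinical-severity factor, and the white-matter lesion volume with
    age and ``wmsa_link`` times the inverse executive (anomic) factor.
    """
    latent = schema.latent_columns(cohort.df.columns)
    if "latent_severity" not in latent or "latent_executive" not in latent:
        raise SimulationError(
            "cohort lacks retained latent factors; generate it with "
            "simulate.generate_cohort")
    # keep the reference's age anchor: the age effect is one physical law
    # shared by reference and cohort, which residualization then removes
    params = smri_params or SMRIReferenceParams()
    rng = np.random.default_rng(seed)
    df = cohort.df.copy()
    n = len(df)
    icv = rng.normal(params.icv_mean, params.icv_sd, n)
    ad_load = severity_link * (-df["latent_severity"].to_numpy())
    feats = _draw_smri_block(rng, n, df["age"].to_numpy(), icv, ad_load, params)
    wmsa = np.exp(np.log(2200) + 0.035 * (df["age"].to_numpy() - params.age_mean)
                  + 0.4 * wmsa_link * (-df["latent_executive"].to_numpy())
                  + rng.normal(0, 0.45, n))
    df["icv"] = np.round(icv, 0)
    df["wmsa"] = np.round(wmsa, 1)
    for col in feats.columns:
        df[col] = feats[col].round(4).to_numpy()
    return cohort.with_df(df, smri="synthetic", smri_seed=seed)
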