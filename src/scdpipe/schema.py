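"""Canonical column names and the complaint questionnaire layout.

The cohort table is a wide, one-row-per-subject table. Complaint items are
binary {0,1} columns prefixed ``c_``, cognitive test scores are prefixed
``cog_``, cortical-thickness features ``ct_`` and subcortical volumes
``vol_`` (FreeSurfer aparc/aseg-style region names), plus ``icv`` and
``wmsa``.
"""

from __future__ import annotations

# The nine yes/no complaint items, in questionnaire order (Q1..Q9).
COMPLAINT_ITEMS: tuple[str, ...] = (
    "orientation",
    "memory",
    "face_recognition",
    "executive",
    "word_finding",
    "reading",
    "writing",
    "lang_production",
    "lang_comprehension",
)

COMPLAINT_COLUMNS: tuple[str, ...] = tuple(f"c_{item}" for item in COMPLAINT_ITEMS)

#: The five cognitive domains the questionnaire covers.
DOMAINS: tuple[str, ...] = (
    "orientation",
    "memory",
    "visuoperception",
    "executive",
    "language",
)

#: Default item -> domain map: Q1 orientation, Q2 memory, Q3 visuoperception,
#: Q4 executive, Q5-Q9 language.
DEFAULT_DOMAIN_MAP: dict[str, str] = {
    "orientation": "orientation",
    "memory": "memory",
    "face_recognition": "visuoperception",
    "executive": "executive",
    "word_finding": "language",
    "reading": "language",
    "writing": "language",
    "lang_production": "language",
    "lang_comprehension": "language",
}

#: Demographic / clinical scalar columns.
DEMOGRAPHIC_COLUMNS: tuple[str, ...] = ("age", "sex", "wais_info")
CLINICAL_COLUMNS: tuple[str, ...] = (
    "mmse",
    "faq",
    "bdrs_total",
    "bdrs_adl",
    "bdrs_habits",
    "bdrs_personality",
    "dep_raw",
    "dep_scale",
)

#: The four activities-of-daily-living measures entering the severity PCA.
ADL_COLUMNS: tuple[str, ...] = ("faq", "bdrs_adl", "bdrs_habits", "bdrs_personality")

MANDATORY_COLUMNS: tuple[str, ...] = (
    ("subject_id",) + DEMOGRAPHIC_COLUMNS + CLINICAL_COLUMNS + COMPLAINT_COLUMNS
)

COG_PREFIX = "cog_"
THICKNESS_PREFIX = "ct_"
VOLUME_PREFIX = "vol_"
LATENT_PREFIX = "latent_"

SEX_FEMALE = "female"
SEX_MALE = "male"

#: Numeric coding used when sex enters a model (study reports "% females").
SEX_CODES = {SEX_FEMALE: 1, SEX_MALE: 0}


def cognition_columns(columns) -> list[str]:
    """Cognitive-battery column names, in table order."""
    return [c for c in columns if c.startswith(COG_PREFIX)]


def thickness_columns(columns) -> list[str]:
    return [c for c in columns if c.startswith(THICKNESS_PREFIX)]


def volume_columns(columns) -> list[str]:
    return [c for c in columns if c.startswith(VOLUME_PREFIX)]


def smri_feature_columns(columns) -> list[str]:
    """All morphometric features entering the severity model (no icv/wmsa)."""
    return thickness_columns(columns) + volume_columns(columns)


def latent_columns(columns) -> list[str]:
    return [c for c in columns if c.startswith(LATENT_PREFIX)]
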