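"""Cohort data model: table I/O, depression harmonization, inclusion, imputation.

A cohort is a :class:`CohortTable`: a pandas DataFrame in the canonical wide
schema (see :mod:`scdpipe.schema`) plus a provenance note. All operations are
pure — they return a new table and never mutate their input.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import schema

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """The input table does not match the canonical cohort schema."""


class ParseError(ValueError):
    """A cell value cannot be parsed to its declared type."""


class HarmonizationError(ValueError):
    """Depression-score z-harmonization is not possible (degenerate subgroup)."""


class ImputationError(ValueError):
    """Missing-value imputation is not possible (e.g. an all-missing column)."""


@dataclass
class CohortTable:
    """An ordered collection of subject records in canonical wide form.

    Attributes
    ----------
    df : pandas.DataFrame
        One row per subject; columns per :mod:`scdpipe.schema`.
    provenance : dict
        Free-form note on origin (``source``: real/synthetic, ``seed``, ...).
    """

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        validate_cohort(self.df)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def cognition_columns(self) -> list[str]:
        return schema.cognition_columns(self.df.columns)

    @property
    def complaint_totals(self) -> pd.Series:
        """Total number of endorsed complaints per subject (0-9)."""
        return self.df[list(schema.COMPLAINT_COLUMNS)].sum(axis=1).astype(int)

    def with_df(self, df: pd.DataFrame, **extra_provenance) -> "CohortTable":
        return CohortTable(df, {**self.provenance, **extra_provenance})


def validate_cohort(df: pd.DataFrame) -> None:
    missing = [c for c in schema.MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise SchemaError(f"duplicate subject_ids: {dupes}")
    for col in schema.COMPLAINT_COLUMNS:
        bad = df.loc[~df[col].isin([0, 1]) & df[col].notna(), "subject_id"]
        if len(bad):
            raise ParseError(
                f"non-binary complaint value in column {col!r} "
                f"for subject(s) {bad.tolist()}"
            )
    if (df["age"] <= 0).any():
        raise SchemaError("age must be positive")
    if ((df["mmse"] < 0) | (df["mmse"] > 30)).any():
        raise SchemaError("mmse out of range [0, 30]")


def read_cohort(path: str | Path, schema_map: str | Path | dict | None = None) -> CohortTable:
    """Read a cohort from a delimited table (CSV or TSV, by extension).

    Parameters
    ----------
    path : path
        CSV (``.csv``) or TSV (``.tsv``/``.txt``) file with a header row.
    schema_map : mapping or path, optional
        Maps file column names to canonical names. May be a dict or a path
        to a flat YAML/JSON key-value file. Unmapped extra columns are
        ignored with a warning.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    if isinstance(schema_map, (str, Path)):
        schema_map = _load_mapping(schema_map)
    if schema_map:
        df = df.rename(columns=dict(schema_map))
    known_prefixes = (schema.COG_PREFIX, schema.THICKNESS_PREFIX,
                      schema.VOLUME_PREFIX, schema.LATENT_PREFIX)
    known = set(schema.MANDATORY_COLUMNS) | {"icv", "wmsa", "dep_z", "group"}
    extra = [c for c in df.columns
             if c not in known and not c.startswith(known_prefixes)]
    if extra:
        logger.warning("ignoring unmapped columns: %s", extra)
        df = df.drop(columns=extra)
    for col in schema.COMPLAINT_COLUMNS:
        if col in df.columns:
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as exc:
                raise ParseError(f"cannot parse complaint column {col!r}: {exc}") from exc
    table = CohortTable(df, {"source": str(path)})
    return table


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write the cohort as CSV/TSV (by extension); lossless round trip."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    cohort.df.to_csv(path, sep=sep, index=False)


def _load_mapping(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def combine_depression(cohort: CohortTable, age_cutoff: float = 63,
                       ddof: int = 1) -> CohortTable:
    """Harmonize BDI and GDS depression scores into one z-scored column.

    Subjects younger than ``age_cutoff`` must carry a BDI score and the rest
    a GDS score; each scale subgroup is z-scored against its own mean and SD
    (``ddof=1``: sample SD) and the two z columns are concatenated as
    ``dep_z``.
    """
    df = cohort.df.copy()
    expected = np.where(df["age"] < age_cutoff, "BDI", "GDS")
    mismatch = df.loc[df["dep_scale"] != expected, "subject_id"]
    if len(mismatch):
        raise HarmonizationError(
            f"depression scale inconsistent with the age-{age_cutoff} rule "
            f"for subject(s) {mismatch.tolist()}"
        )
    z = pd.Series(np.nan, index=df.index)
    for scale_name, sub in df.groupby("dep_scale"):
        if len(sub) < 2:
            raise HarmonizationError(f"{scale_name} subgroup has < 2 subjects")
        sd = sub["dep_raw"].std(ddof=ddof)
        if sd == 0 or not np.isfinite(sd):
            raise HarmonizationError(f"{scale_name} subgroup has zero SD")
        z.loc[sub.index] = (sub["dep_raw"] - sub["dep_raw"].mean()) / sd
    df["dep_z"] = z
    return cohort.with_df(df)


def apply_inclusion(cohort: CohortTable, bdrs_max: float = 4,
                    faq_max: float = 5, mmse_min: float = 26) -> CohortTable:
    """Keep subjects meeting the functional/global-cognition entry criteria.

    Inclusive boundaries: BDRS total <= 4, FAQ <= 5, MMSE >= 26.
    """
    df = cohort.df
    keep_bdrs = df["bdrs_total"] <= bdrs_max
    keep_faq = df["faq"] <= faq_max
    keep_mmse = df["mmse"] >= mmse_min
    logger.info(
        "inclusion removed %d (BDRS>%s), %d (FAQ>%s), %d (MMSE<%s) of %d",
        int((~keep_bdrs).sum()), bdrs_max, int((~keep_faq).sum()), faq_max,
        int((~keep_mmse).sum()), mmse_min, len(df),
    )
    out = df[keep_bdrs & keep_faq & keep_mmse].reset_index(drop=True)
    if out.empty:
        logger.warning("inclusion criteria removed every subject")
    return cohort.with_df(out)


def impute_missing(cohort: CohortTable, method: str = "median",
                   seed: int = 0) -> CohortTable:
    """Impute missing cognitive-battery values.

    Methods: ``median`` (per-column median over the cohort),
    ``stratified_median`` (per-column median within decade-of-age strata,
    cohort median as fallback for empty strata), ``iterative``
    (round-robin regression imputation, seeded). Only ``cog_`` columns may
    contain missing values; observed values are never altered.
    """
    df = cohort.df.copy()
    cog = cohort.cognition_columns
    other = [c for c in df.columns if c not in cog]
    bad = [c for c in other if df[c].isna().any()]
    if bad:
        raise ImputationError(f"missingness outside cognition columns: {bad}")
    if not df[cog].isna().any().any():
        return cohort.with_df(df)
    all_missing = [c for c in cog if df[c].isna().all()]
    if all_missing:
        raise ImputationError(f"entirely missing cognition columns: {all_missing}")

    n_missing = df[cog].isna().sum()
    if method == "median":
        df[cog] = df[cog].fillna(df[cog].median())
    elif method == "stratified_median":
        decade = (df["age"] // 10).astype(int)
        for col in cog:
            strat = df.groupby(decade)[col].transform("median")
            df[col] = df[col].fillna(strat).fillna(df[col].median())
    elif method == "iterative":
        from sklearn.experimental import enable_iterative_imputer  # noqa: F401
        from sklearn.impute import IterativeImputer

        imp = IterativeImputer(random_state=seed, sample_posterior=False)
        df[cog] = imp.fit_transform(df[cog])
    else:
        raise ValueError(f"unknown imputation method {method!r}")
    logger.info("imputed %d cells (%s): %s", int(n_missing.sum()), method,
                {c: int(k) for c, k in n_missing.items() if k})
    return cohort.with_df(df, imputation=method)
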