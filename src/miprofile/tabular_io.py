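"""Behavioral data model and lossless CSV round-tripping.

One row per participant: an id, two always-observed covariates (sex and
research site), age in years, five standardized test scores used for
reading-profile classification, four optional standardized validation
scores, and an optional profile label.  All scores are on the familiar
mean-100 / SD-15 scale and any score cell may be missing; missing cells
are carried as NaN in memory and serialized as the empty string.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: Closed vocabulary of reading profiles.
PROFILES = ("PoorDecoder", "PoorComprehender", "GenerallyPoorReader", "Control")

#: The five test scores the classifier uses.
CLASSIFICATION_VARS = ("pseudoword_id", "real_word_id", "passage_comp", "verbal_iq", "ran")

#: Independent validation measures (never imputed, never used for classification).
VALIDATION_VARS = ("piq", "spelling", "elision", "digit_span")

#: Variables eligible to carry induced missingness (age plus the five tests).
ELIGIBLE_MISSING_VARS = ("age",) + CLASSIFICATION_VARS

#: Tokens accepted as missing on read; the empty string is written on output.
MISSING_TOKENS = ("", "NA", "NaN", "nan")

DEFAULT_SEX_LEVELS = ("F", "M")
DEFAULT_SITE_LEVELS = tuple(f"site{i}" for i in range(1, 9))


class SchemaError(ValueError):
    """Structural problem: duplicate id, unknown category level, bad column set."""


class ParseError(ValueError):
    """A cell could not be parsed; the message names the row and column."""


def _canonical_columns(has_validation: bool, has_label: bool) -> list[str]:
    cols = ["id", "sex", "site", "age", *CLASSIFICATION_VARS]
    if has_validation:
        cols += list(VALIDATION_VARS)
    if has_label:
        cols.append("label")
    return cols


@dataclass
class BehavioralTable:
    """Participants-by-variables table with explicit missing cells.

    ``df`` holds one row per participant in canonical column order.  The
    table validates itself on construction: ids unique, category levels
    drawn from the declared vocabularies, non-missing scores finite,
    labels (when present) from the four-profile vocabulary.
    """

    df: pd.DataFrame
    sex_levels: tuple[str, ...] = DEFAULT_SEX_LEVELS
    site_levels: tuple[str, ...] = DEFAULT_SITE_LEVELS

    def __post_init__(self) -> None:
        df = self.df
        has_validation = all(v in df.columns for v in VALIDATION_VARS)
        has_label = "label" in df.columns
        cols = _canonical_columns(has_validation, has_label)
        missing_cols = [c for c in cols if c not in df.columns]
        if missing_cols:
            raise SchemaError(f"missing required columns: {missing_cols}")
        df = df.loc[:, cols].reset_index(drop=True)
        df["id"] = df["id"].astype(str)
        if df["id"].duplicated().any():
            dupes = df.loc[df["id"].duplicated(), "id"].tolist()
            raise SchemaError(f"duplicate participant ids: {dupes}")
        for col, levels in (("sex", self.sex_levels), ("site", self.site_levels)):
            df[col] = df[col].astype(str)
            bad = sorted(set(df[col]) - set(levels))
            if bad:
                raise SchemaError(f"unknown {col} level(s) {bad}; declared {list(levels)}")
        for col in self.numeric_vars:
            df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
            vals = df[col].to_numpy()
            if np.isinf(vals).any():
                raise SchemaError(f"non-finite value in column {col!r}")
        if has_label:
            df["label"] = df["label"].astype(str)
            bad = sorted(set(df["label"].dropna()) - set(PROFILES) - {"nan"})
            if bad:
                raise SchemaError(f"unknown profile label(s) {bad}")
        self.df = df

    # -- introspection -------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def has_labels(self) -> bool:
        return "label" in self.df.columns

    @property
    def has_validation(self) -> bool:
        return all(v in self.df.columns for v in VALIDATION_VARS)

    @property
    def numeric_vars(self) -> tuple[str, ...]:
        base = ("age",) + CLASSIFICATION_VARS
        if all(v in self.df.columns for v in VALIDATION_VARS):
            base = base + VALIDATION_VARS
        return base

    @property
    def labels(self) -> pd.Series:
        if not self.has_labels:
            raise SchemaError("table has no label column")
        return self.df["label"]

    def is_complete(self, columns=ELIGIBLE_MISSING_VARS) -> bool:
        return not self.df[list(columns)].isna().any().any()

    def copy(self) -> "BehavioralTable":
        return BehavioralTable(self.df.copy(), self.sex_levels, self.site_levels)

    def equals(self, other: "BehavioralTable") -> bool:
        return self.df.equals(other.df)


def read_table(
    path,
    sex_levels: tuple[str, ...] = DEFAULT_SEX_LEVELS,
    site_levels: tuple[str, ...] = DEFAULT_SITE_LEVELS,
) -> BehavioralTable:
    """Read a behavioral CSV, turning missing tokens into explicit NaN.

    Raises :class:`ParseError` naming the offending row and column for any
    score token that is neither numeric nor a recognized missing token, and
    :class:`SchemaError` for duplicate ids or unknown category levels.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    numeric = [c for c in raw.columns if c in ELIGIBLE_MISSING_VARS + VALIDATION_VARS]
    for col in numeric:
        parsed = []
        for i, token in enumerate(raw[col]):
            tok = token.strip()
            if tok in MISSING_TOKENS:
                parsed.append(np.nan)
                continue
            try:
                parsed.append(float(tok))
            except ValueError:
                raise ParseError(
                    f"cannot parse {tok!r} in column {col!r}, row {i + 2} of {path}"
                ) from None
        raw[col] = parsed
    if "label" in raw.columns:
        raw["label"] = raw["label"].replace({t: np.nan for t in MISSING_TOKENS})
    return BehavioralTable(raw, sex_levels=sex_levels, site_levels=site_levels)


def write_table(table: BehavioralTable, path) -> Path:
    """Write the table as UTF-8 CSV in canonical column order.

    Missing cells serialize as the empty string; floats use Python's
    shortest round-trip repr so ``read_table(write_table(t))`` recovers
    ``t`` exactly.
    """
    path = Path(path)
    table.df.to_csv(path, index=False, na_rep="")
    return path


def missingness_summary(table: BehavioralTable) -> dict:
    """Per-variable missing fraction and per-row missing count.

    Returns ``{"per_variable": Series, "per_row": Series, "total": int}``
    over the numeric variables (age, tests, and validation scores when
    present).
    """
    sub = table.df[list(table.numeric_vars)]
    mask = sub.isna()
    return {
        "per_variable": mask.mean(axis=0),
        "per_row": mask.sum(axis=1),
        "total": int(mask.to_numpy().sum()),
    }
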