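"""Readers/writers for the pipeline's tabular artifacts.

Canonical dialect is tab-separated values with a header row; comma is accepted
via ``sep=","``. Readers validate strictly and raise
:class:`~kinoscope.errors.ValidationError` naming offending rows/keys rather
than silently coercing. Writers produce files their readers accept.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from kinoscope.errors import ValidationError

EXPOSURE_COLUMNS = ["peptide_id", "group", "chip", "exposure_ms", "intensity"]
DESIGN_COLUMNS = ["sample_id", "group", "chip"]
KINASE_MAP_COLUMNS = ["kinase", "peptide_id"]
TOOL_SCORE_COLUMNS = ["kinase", "tool", "score", "score_direction"]
SCORE_DIRECTIONS = {"higher_is_better", "lower_is_better"}


def _read(path, sep: str, required: Iterable[str], renames: Mapping[str, str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if renames:
        df = df.rename(columns=dict(renames))
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    return df


def _numeric(df: pd.DataFrame, col: str, path) -> pd.Series:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = df.index[vals.isna()]
    if len(bad):
        # +2: header line and 1-based numbering
        rows = ", ".join(str(i + 2) for i in bad[:10])
        raise ValidationError(
            f"{path}: non-numeric {col!r} values on file row(s) {rows}"
        )
    return vals


def _no_duplicates(df: pd.DataFrame, keys: list[str], path) -> None:
    dup = df.duplicated(subset=keys, keep=False)
    if dup.any():
        sample = df.loc[dup, keys].drop_duplicates().head(5)
        keys_repr = "; ".join(
            "(" + ", ".join(map(str, row)) + ")" for row in sample.itertuples(index=False)
        )
        raise ValidationError(f"{path}: duplicate {tuple(keys)} keys: {keys_repr}")


def read_exposure_series(path, sep: str = "\t", renames: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read and validate a tidy exposure-series table.

    Requires columns peptide_id, group, chip, exposure_ms, intensity; the key
    (peptide_id, group, chip, exposure_ms) must be unique and every
    (peptide, group, chip) well must have >= 2 distinct exposures.
    """
    df = _read(path, sep, EXPOSURE_COLUMNS, renames)
    df["exposure_ms"] = _numeric(df, "exposure_ms", path)
    df["intensity"] = _numeric(df, "intensity", path)
    if (df["exposure_ms"] <= 0).any():
        raise ValidationError(f"{path}: exposure_ms must be strictly positive")
    if (df["intensity"] < 0).any():
        raise ValidationError(f"{path}: intensity must be nonnegative")
    _no_duplicates(df, ["peptide_id", "group", "chip", "exposure_ms"], path)
    n_exp = df.groupby(["peptide_id", "group", "chip"])["exposure_ms"].nunique()
    thin = n_exp[n_exp < 2]
    if len(thin):
        raise ValidationError(
            f"{path}: wells with < 2 distinct exposures (slope fitting needs >= 2): "
            f"{list(thin.index[:5])}"
        )
    return df[EXPOSURE_COLUMNS].reset_index(drop=True)


def read_design(path, sep: str = "\t") -> pd.DataFrame:
    df = _read(path, sep, DESIGN_COLUMNS)
    _no_duplicates(df, ["sample_id"], path)
    return df[DESIGN_COLUMNS].reset_index(drop=True)


def design_from_series(series: pd.DataFrame) -> pd.DataFrame:
    """Derive the implicit design (one sample per group x chip) from a series."""
    design = series[["group", "chip"]].drop_duplicates().reset_index(drop=True)
    design.insert(0, "sample_id", design["group"].astype(str) + ":" + design["chip"].astype(str))
    return design


def check_design(series: pd.DataFrame, design: pd.DataFrame) -> None:
    """Every (group, chip) sample present in the series must appear once in design."""
    have = set(zip(design["group"], design["chip"]))
    used = set(zip(series["group"].astype(str), series["chip"].astype(str)))
    missing = used - {(str(g), str(c)) for g, c in have}
    if missing:
        raise ValidationError(f"samples present in signals but absent from design: {sorted(missing)[:5]}")


def read_kinase_map(path, sep: str = "\t") -> pd.DataFrame:
    df = _read(path, sep, KINASE_MAP_COLUMNS)
    _no_duplicates(df, KINASE_MAP_COLUMNS, path)
    return df[KINASE_MAP_COLUMNS].reset_index(drop=True)


def check_map_against_universe(kinase_map: pd.DataFrame, universe: Iterable[str]) -> pd.DataFrame:
    """Warn on mapped peptides that are not in the signal universe; return the
    restricted map."""
    universe = set(universe)
    extra = sorted(set(kinase_map["peptide_id"]) - universe)
    if extra:
        warnings.warn(
            f"{len(extra)} mapped peptide(s) absent from the signal universe "
            f"(e.g. {extra[:5]}); ignored for scoring",
            stacklevel=2,
        )
    return kinase_map[kinase_map["peptide_id"].isin(universe)].reset_index(drop=True)


def read_tool_scores(path, sep: str = "\t") -> pd.DataFrame:
    df = _read(path, sep, TOOL_SCORE_COLUMNS)
    df["score"] = _numeric(df, "score", path)
    bad_dir = sorted(set(df["score_direction"]) - SCORE_DIRECTIONS)
    if bad_dir:
        raise ValidationError(
            f"{path}: invalid score_direction values {bad_dir}; "
            f"allowed: {sorted(SCORE_DIRECTIONS)}"
        )
    _no_duplicates(df, ["kinase", "tool"], path)
    return df[TOOL_SCORE_COLUMNS].reset_index(drop=True)


def read_alias_table(path, sep: str = "\t") -> pd.DataFrame:
    df = _read(path, sep, ["alias", "symbol"])
    _no_duplicates(df, ["alias"], path)
    return df[["alias", "symbol"]].reset_index(drop=True)


def write_table(df: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write any result table as delimited text (no index column)."""
    df.to_csv(path, sep=sep, index=False)
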