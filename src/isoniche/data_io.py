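"""Reading, validation and writing of isotope and diet tables.

Two tabular inputs drive every analysis in this package:

* an **isotope table** — one row per individual with species, sex, maturity
  stage, sampling season and bulk muscle δ13C / δ15N values (‰, relative to
  VPDB and atmospheric N2);
* a **diet table** — one row per individual with the same grouping factors
  and the wet weight (g) of each of ten broad prey categories recovered from
  the stomach.

Both are plain UTF-8 CSV.  Source files in the wild use arbitrary column
names and category spellings, so readers accept an optional ``column_map``
and match categorical levels case-insensitively after accent stripping.
"""

from __future__ import annotations

import logging
import unicodedata
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SPECIES = ("H_dipterurus", "N_entemedor", "R_steindachneri")
SEXES = ("female", "male")
STAGES = ("adult", "juvenile")
SEASONS = ("cold", "warm")

#: The ten broad prey categories used for stomach-content classification.
PREY_CATEGORIES = (
    "amphipods",
    "crabs",
    "bivalves",
    "echinoderms",
    "other_crustaceans",
    "shrimps",
    "polychaetes",
    "sipunculids",
    "stomatopods",
    "fishes",
)

FACTOR_COLUMNS = ("species", "sex", "stage", "season")
ISOTOPE_COLUMNS = ("d13C", "d15N")

#: Surface-water seasonality of the southern Gulf of California:
#: warm season May–September, cold season October–April.
WARM_MONTHS = frozenset({5, 6, 7, 8, 9})

# Sanity bounds for bulk muscle values (configurable in the readers).
D13C_BOUNDS = (-40.0, 0.0)
D15N_BOUNDS = (0.0, 30.0)


class SchemaError(ValueError):
    """A table does not conform to the expected schema."""


def _fold(s: str) -> str:
    """Case-fold and strip accents/punctuation for tolerant matching."""
    s = unicodedata.normalize("NFKD", str(s))
    s = "".join(c for c in s if not unicodedata.combining(c))
    return "".join(c for c in s.casefold() if c.isalnum())


# Synonyms observed in fisheries datasets, keyed by folded spelling.
_LEVEL_SYNONYMS: dict[str, dict[str, str]] = {
    "species": {
        _fold("H_dipterurus"): "H_dipterurus",
        _fold("Hypanus dipterurus"): "H_dipterurus",
        _fold("H. dipterurus"): "H_dipterurus",
        _fold("Hdipterurus"): "H_dipterurus",
        _fold("N_entemedor"): "N_entemedor",
        _fold("Narcine entemedor"): "N_entemedor",
        _fold("N. entemedor"): "N_entemedor",
        _fold("R_steindachneri"): "R_steindachneri",
        _fold("Rhinoptera steindachneri"): "R_steindachneri",
        _fold("R. steindachneri"): "R_steindachneri",
    },
    "sex": {
        "f": "female", "female": "female", "females": "female",
        "hembra": "female",
        "m": "male", "male": "male", "males": "male", "macho": "male",
    },
    "stage": {
        "a": "adult", "adult": "adult", "adults": "adult", "mature": "adult",
        "adulto": "adult",
        "j": "juvenile", "juvenile": "juvenile", "juveniles": "juvenile",
        "immature": "juvenile", "juvenil": "juvenile",
    },
    "season": {
        "c": "cold", "cold": "cold", "fria": "cold",
        "w": "warm", "warm": "warm", "calida": "warm",
    },
}

_CANONICAL_LEVELS = {
    "species": SPECIES,
    "sex": SEXES,
    "stage": STAGES,
    "season": SEASONS,
}

# Folded header spellings recognised without a user-supplied column map.
_HEADER_SYNONYMS: dict[str, str] = {}
for _canon, _alts in {
    "individual_id": ("individual_id", "id", "individual", "sample", "sample_id"),
    "species": ("species", "sp", "especie"),
    "sex": ("sex", "sexo"),
    "stage": ("stage", "maturity", "maturity_stage", "madurez"),
    "season": ("season", "temporada"),
    "month": ("month", "mes"),
    "d13C": ("d13c", "delta13c", "δ13c", "d13ccorr", "13c"),
    "d15N": ("d15n", "delta15n", "δ15n", "d15ncorr", "15n"),
}.items():
    for _a in _alts:
        _HEADER_SYNONYMS[_fold(_a)] = _canon
for _p in PREY_CATEGORIES:
    _HEADER_SYNONYMS[_fold(_p)] = _p


def _canonicalize_headers(
    df: pd.DataFrame, column_map: Mapping[str, str] | None
) -> pd.DataFrame:
    """Rename columns to canonical names; unknown columns pass through."""
    rename: dict[str, str] = {}
    explicit = { _fold(k): v for k, v in (column_map or {}).items() }
    for col in df.columns:
        key = _fold(col)
        if key in explicit:
            rename[col] = explicit[key]
        elif key in _HEADER_SYNONYMS:
            rename[col] = _HEADER_SYNONYMS[key]
    return df.rename(columns=rename)


def _map_levels(series: pd.Series, factor: str) -> pd.Series:
    syn = _LEVEL_SYNONYMS[factor]
    out = []
    for i, v in series.items():
        key = _fold(v)
        if key not in syn:
            raise SchemaError(
                f"unmappable {factor} level {v!r} in row {i}; "
                f"expected one of {_CANONICAL_LEVELS[factor]}"
            )
        out.append(syn[key])
    return pd.Series(out, index=series.index, dtype="object")


def _season_from_month(month: pd.Series) -> pd.Series:
    m = pd.to_numeric(month, errors="raise").astype(int)
    if not m.between(1, 12).all():
        raise SchemaError("month values must be in 1..12")
    return pd.Series(
        np.where(m.isin(list(WARM_MONTHS)), "warm", "cold"), index=month.index
    )


def validate_isotope_table(
    df: pd.DataFrame,
    d13c_bounds: tuple[float, float] | None = D13C_BOUNDS,
    d15n_bounds: tuple[float, float] | None = D15N_BOUNDS,
) -> pd.DataFrame:
    """Validate a canonical isotope table, returning a clean copy.

    Checks the required columns, categorical vocabularies, missing values
    and the configurable sanity bounds on the isotope axes (pass ``None``
    to disable a bound check, e.g. for heavy-tailed simulations).
    """
    required = ["individual_id", *FACTOR_COLUMNS, *ISOTOPE_COLUMNS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    out = df.copy()
    for factor in FACTOR_COLUMNS:
        bad = ~out[factor].isin(_CANONICAL_LEVELS[factor])
        if bad.any():
            i = out.index[bad][0]
            raise SchemaError(
                f"unmappable {factor} level {out.loc[i, factor]!r} in row {i}"
            )
    for col in ISOTOPE_COLUMNS:
        out[col] = pd.to_numeric(out[col], errors="raise")
        if out[col].isna().any():
            raise SchemaError(f"missing {col} values after validation")
    if d13c_bounds is not None:
        lo, hi = d13c_bounds
        if not out["d13C"].between(lo, hi, inclusive="neither").all():
            raise SchemaError(f"d13C outside sanity bounds {d13c_bounds}")
    if d15n_bounds is not None:
        lo, hi = d15n_bounds
        if not out["d15N"].between(lo, hi, inclusive="neither").all():
            raise SchemaError(f"d15N outside sanity bounds {d15n_bounds}")
    out["individual_id"] = out["individual_id"].astype(str)
    return out


def read_isotope_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    d13c_bounds: tuple[float, float] = D13C_BOUNDS,
    d15n_bounds: tuple[float, float] = D15N_BOUNDS,
) -> pd.DataFrame:
    """Read and validate an isotope CSV.

    If the file carries a ``month`` column but no ``season``, seasons are
    derived from it (warm = May–September).  Unknown extra columns are
    preserved but ignored by the analyses.
    """
    df = _canonicalize_headers(pd.read_csv(path), column_map)
    if "individual_id" not in df.columns:
        df.insert(0, "individual_id", [f"ind-{i:05d}" for i in range(len(df))])
    if "season" not in df.columns and "month" in df.columns:
        df["season"] = _season_from_month(df["month"])
    for factor in FACTOR_COLUMNS:
        if factor not in df.columns:
            raise SchemaError(f"missing required columns: ['{factor}']")
        df[factor] = _map_levels(df[factor], factor)
    return validate_isotope_table(df, d13c_bounds, d15n_bounds)


def validate_diet_table(df: pd.DataFrame, drop_empty: bool = True) -> pd.DataFrame:
    """Validate a canonical diet table; optionally drop all-zero prey rows."""
    required = ["individual_id", *FACTOR_COLUMNS, *PREY_CATEGORIES]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    out = df.copy()
    for factor in FACTOR_COLUMNS:
        bad = ~out[factor].isin(_CANONICAL_LEVELS[factor])
        if bad.any():
            i = out.index[bad][0]
            raise SchemaError(
                f"unmappable {factor} level {out.loc[i, factor]!r} in row {i}"
            )
    prey = list(PREY_CATEGORIES)
    for col in prey:
        out[col] = pd.to_numeric(out[col], errors="raise")
        if out[col].isna().any():
            raise SchemaError(f"missing weights in prey column {col}")
        if (out[col] < 0).any():
            i = out.index[out[col] < 0][0]
            raise SchemaError(f"negative prey weight in column {col}, row {i}")
    empty = (out[prey].to_numpy() <= 0).all(axis=1)
    if empty.any():
        if not drop_empty:
            raise SchemaError(f"{int(empty.sum())} rows have all-zero prey weights")
        logger.info("dropping %d rows with all-zero prey weights", int(empty.sum()))
        out = out.loc[~empty].reset_index(drop=True)
    out["individual_id"] = out["individual_id"].astype(str)
    return out


def read_diet_table(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read and validate a stomach-content CSV (weights in grams)."""
    df = _canonicalize_headers(pd.read_csv(path), column_map)
    if "individual_id" not in df.columns:
        df.insert(0, "individual_id", [f"ind-{i:05d}" for i in range(len(df))])
    if "season" not in df.columns and "month" in df.columns:
        df["season"] = _season_from_month(df["month"])
    for factor in FACTOR_COLUMNS:
        if factor not in df.columns:
            raise SchemaError(f"missing required columns: ['{factor}']")
        df[factor] = _map_levels(df[factor], factor)
    return validate_diet_table(df)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a table as UTF-8 CSV that round-trips exactly through pandas."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
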