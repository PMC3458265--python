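"""Unit-level data model, variable registry and delimited-table I/O.

The central container is :class:`UnitTable`: one row per territorial unit
(e.g. an administrative province), with centroid coordinates in signed
decimal degrees, one column per registered environmental variable and one
non-negative integer column per species-richness group.  Richness groups
follow a taxonomic hierarchy: ``SRa`` (all mammals) contains ``SRm``
(marsupials) and ``SRp`` (placentals), and ``SRp`` contains ``SRx``
(xenarthrans), ``SRc`` (carnivores), ``SRu`` (ungulates) and ``SRr``
(rodents).
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, TableParseError, TableValidationError

__all__ = [
    "VariableRegistry",
    "UnitTable",
    "DEFAULT_REGISTRY",
    "ENVIRONMENTAL_CODES",
    "RICHNESS_CODES",
    "GEOGRAPHICAL_CODES",
    "read_unit_table",
    "write_report_table",
    "round_half_even",
    "significance_mark",
    "format_value",
]

#: The ten environmental variable codes.
ENVIRONMENTAL_CODES = ("MT", "HT", "CT", "TR", "MP", "PR", "MA", "AR", "LR", "SA")

#: Species-richness group codes (all / marsupials / placentals / subgroups).
RICHNESS_CODES = ("SRa", "SRm", "SRp", "SRx", "SRc", "SRu", "SRr")

#: Geographic variable codes (unit coordinates + composite axis).
GEOGRAPHICAL_CODES = ("La", "Lo", "NNE-SSW")

#: Placental subgroups that must each be <= SRp.
PLACENTAL_SUBGROUPS = ("SRx", "SRc", "SRu", "SRr")

_ENV_NAMES = {
    "MT": "Mean annual temperature",
    "HT": "Mean temperature of the hottest month",
    "CT": "Mean temperature of the coldest month",
    "TR": "Annual temperature range",
    "MP": "Mean annual precipitation",
    "PR": "Annual precipitation range",
    "MA": "Mean altitude",
    "AR": "Altitude range",
    "LR": "Latitude range",
    "SA": "Surface area",
}

_RICHNESS_NAMES = {
    "SRa": "Species richness, all mammals",
    "SRm": "Species richness, marsupials",
    "SRp": "Species richness, placentals",
    "SRx": "Species richness, xenarthrans",
    "SRc": "Species richness, carnivores",
    "SRu": "Species richness, ungulates",
    "SRr": "Species richness, rodents",
}


@dataclass(frozen=True)
class Variable:
    code: str
    name: str
    category: str  # environmental | geographical | spatial | richness


@dataclass
class VariableRegistry:
    """Registry of variable codes grouped by category.

    The ten environmental codes, the geographic codes (``La``, ``Lo``,
    ``NNE-SSW``) and the richness group codes are pre-registered; extra
    codes (e.g. spatial filters ``SF_1`` ...) may be added.
    """

    variables: dict[str, Variable] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.variables:
            for code in ENVIRONMENTAL_CODES:
                self.register(code, _ENV_NAMES[code], "environmental")
            for code, name in (
                ("La", "Mean latitude"),
                ("Lo", "Mean longitude"),
                ("NNE-SSW", "Composite principal geographic axis"),
            ):
                self.register(code, name, "geographical")
            for code in RICHNESS_CODES:
                self.register(code, _RICHNESS_NAMES[code], "richness")

    def register(self, code: str, name: str, category: str) -> None:
        if category not in {"environmental", "geographical", "spatial", "richness"}:
            raise ValueError(f"unknown category {category!r}")
        if code in self.variables:
            raise ValueError(f"duplicate variable code {code!r}")
        self.variables[code] = Variable(code, name, category)

    def codes(self, category: str | None = None) -> tuple[str, ...]:
        if category is None:
            return tuple(self.variables)
        return tuple(c for c, v in self.variables.items() if v.category == category)

    def __contains__(self, code: str) -> bool:
        return code in self.variables


#: A registry holding the standard variable set.
DEFAULT_REGISTRY = VariableRegistry()

#: Columns every unit table must provide.
MANDATORY_COLUMNS = ("unit_id", "La", "Lo")


class UnitTable:
    """Validated per-unit table of coordinates, environment and richness.

    Parameters
    ----------
    df
        One row per unit.  Must contain ``unit_id``, ``La``, ``Lo``; any
        registered environmental/richness columns are validated, unknown
        columns are carried through and reported in :attr:`extra_columns`.
    registry
        Variable registry used to classify columns.
    """

    def __init__(self, df: pd.DataFrame, registry: VariableRegistry | None = None):
        self.registry = registry or DEFAULT_REGISTRY
        self._df = df.reset_index(drop=True).copy()
        self._validate()

    # -- construction -------------------------------------------------
    def _validate(self) -> None:
        df = self._df
        for col in MANDATORY_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"mandatory column {col!r} is missing")
        known = set(MANDATORY_COLUMNS) | set(self.registry.codes())
        self.extra_columns = tuple(c for c in df.columns if c not in known)
        self.env_columns = tuple(
            c for c in self.registry.codes("environmental") if c in df.columns
        )
        self.richness_columns = tuple(
            c for c in self.registry.codes("richness") if c in df.columns
        )

        numeric = ("La", "Lo") + self.env_columns + self.richness_columns
        for col in numeric:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise TableParseError(
                    f"non-numeric value {df[col].iloc[row]!r} in column {col!r}, "
                    f"row {row} (unit {df['unit_id'].iloc[row]!r})"
                )
            if coerced.isna().any():
                row = int(np.flatnonzero(coerced.isna().to_numpy())[0])
                raise TableValidationError(
                    f"missing value in column {col!r}, row {row} "
                    f"(unit {df['unit_id'].iloc[row]!r})"
                )
            df[col] = coerced

        for col in self.richness_columns:
            vals = df[col].to_numpy()
            if np.any(vals < 0) or np.any(vals != np.round(vals)):
                unit = df["unit_id"].iloc[
                    int(np.flatnonzero((vals < 0) | (vals != np.round(vals)))[0])
                ]
                raise TableValidationError(
                    f"richness column {col!r} must hold non-negative integers "
                    f"(offending unit {unit!r})"
                )
            df[col] = df[col].astype(int)

        self._check_hierarchy()

    def _check_hierarchy(self) -> None:
        df = self._df
        cols = set(self.richness_columns)

        def require(parent: str, child: str) -> None:
            if parent in cols and child in cols:
                bad = df[parent] < df[child]
                if bad.any():
                    unit = df["unit_id"][bad].iloc[0]
                    raise TableValidationError(
                        f"richness hierarchy violated: {child} > {parent} "
                        f"for unit {unit!r}"
                    )

        require("SRa", "SRm")
        require("SRa", "SRp")
        for sub in PLACENTAL_SUBGROUPS:
            require("SRp", sub)

    # -- accessors ----------------------------------------------------
    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def n_units(self) -> int:
        return len(self._df)

    @property
    def unit_ids(self) -> pd.Series:
        return self._df["unit_id"]

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of (La, Lo) in signed decimal degrees."""
        return self._df[["La", "Lo"]].to_numpy(float)

    def column(self, code: str) -> np.ndarray:
        if code not in self._df.columns:
            raise SchemaError(f"column {code!r} not present in the unit table")
        return self._df[code].to_numpy(float)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_units

    def to_csv(self, path, decimal_style: str = "point") -> None:
        """Write the table as comma-separated UTF-8 text."""
        df = self._df
        if decimal_style == "comma":
            df = df.copy()
            for c in df.columns:
                if pd.api.types.is_float_dtype(df[c]):
                    df[c] = df[c].map(lambda v: repr(float(v)).replace(".", ","))
            df.to_csv(path, sep=";", index=False)
        else:
            # full repr so numeric payloads survive a write/read cycle exactly
            df.to_csv(path, index=False)


def read_unit_table(
    path,
    registry: VariableRegistry | None = None,
    decimal_comma: bool = False,
) -> UnitTable:
    """Read and validate a delimited unit table.

    The canonical dialect is comma-separated with point decimals; with
    ``decimal_comma=True`` a semicolon-separated, comma-decimal file is
    accepted instead.
    """
    if decimal_comma:
        df = pd.read_csv(path, sep=";", decimal=",", float_precision="round_trip")
    else:
        df = pd.read_csv(path, float_precision="round_trip")
    return UnitTable(df, registry=registry)


# -- report formatting ------------------------------------------------

def round_half_even(value: float, ndigits: int) -> float:
    """Round to ``ndigits`` decimals with banker's (half-even) rounding.

    Goes through :mod:`decimal` so that e.g. 25.9375 -> 25.94 regardless of
    binary float representation of intermediate values.
    """
    q = decimal.Decimal(1).scaleb(-ndigits)
    d = decimal.Decimal(repr(float(value))).quantize(q, rounding=decimal.ROUND_HALF_EVEN)
    return float(d)


def significance_mark(p: float, alpha: float = 0.05, strong_alpha: float = 0.01) -> str:
    """Star convention: ``**`` for p < 0.01, ``*`` for p < 0.05, else empty."""
    if p < strong_alpha:
        return "**"
    if p < alpha:
        return "*"
    return ""


def format_value(
    value: float,
    ndigits: int,
    p: float | None = None,
    decimal_style: str = "point",
) -> str:
    """Format a number at the report precision with optional significance stars."""
    v = round_half_even(value, ndigits)
    text = f"{v:.{ndigits}f}"
    if decimal_style == "comma":
        text = text.replace(".", ",")
    if p is not None:
        text += significance_mark(p)
    return text


def write_report_table(
    rows: Iterable[Mapping[str, object]] | pd.DataFrame,
    path,
    decimal_style: str = "point",
    columns: Sequence[str] | None = None,
) -> None:
    """Write a report table of pre-formatted or raw cells as delimited text.

    ``rows`` may be a DataFrame or an iterable of mappings.  Cells that are
    plain floats are written as-is at full precision; formatted strings
    (e.g. produced by :func:`format_value`) pass through untouched.  An
    empty collection produces a header-only file (when ``columns`` names
    the header) or an empty file.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows.copy()
    else:
        rows = list(rows)
        df = pd.DataFrame(rows, columns=columns if (columns and not rows) else None)
    if columns is not None and len(df.columns) == 0:
        df = pd.DataFrame(columns=list(columns))
    sep = ";" if decimal_style == "comma" else ","
    if decimal_style == "comma":
        for c in df.columns:
            if pd.api.types.is_float_dtype(df[c]):
                df[c] = df[c].map(lambda v: repr(float(v)).replace(".", ","))
    df.to_csv(path, sep=sep, index=False)
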