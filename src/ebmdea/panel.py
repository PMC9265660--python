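"""Panel data model and I/O.

A balanced panel of decision-making units (DMUs) observed over consecutive
years, with nonnegative inputs, desirable outputs, undesirable outputs,
environmental covariates and a weighting basis (typically the desirable
output itself) used for weighted averages in report tables.

Two CSV dialects are accepted: *wide* (one row per unit-year, one column per
variable) and *long* (unit, year, variable, value). The mapping from columns
to roles lives in a schema dict or YAML/JSON file. Missing cells are a hard
error: the three-stage method requires a balanced panel and no imputation is
attempted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PanelDataset",
    "CarbonCoefficientSet",
    "SchemaError",
    "PanelValidationError",
    "load_panel",
    "write_panel",
    "load_schema",
    "apportion_by_sown_share",
    "aggregate_carbon",
]


class SchemaError(ValueError):
    """A schema/column mapping problem in an input file."""


class PanelValidationError(ValueError):
    """Panel content violates the balanced-positive-panel invariants."""


@dataclass
class PanelDataset:
    """Balanced DMU x period panel.

    Attributes
    ----------
    dmu_ids : list of str
        Unit labels (e.g. province names), length J.
    periods : list of int
        Strictly increasing consecutive years, length T.
    X : ndarray, shape (J, T, m)
        Inputs; must be strictly positive (DEA requirement).
    Y : ndarray, shape (J, T, s_g)
        Desirable outputs, nonnegative.
    B : ndarray, shape (J, T, s_b)
        Undesirable outputs, nonnegative. ``s_b`` may be 0.
    Z : ndarray, shape (J, T, p)
        Environmental covariates (any sign). ``p`` may be 0.
    W : ndarray, shape (J, T)
        Weighting basis for weighted means, nonnegative, not all zero.
    """

    dmu_ids: list
    periods: list
    X: np.ndarray
    Y: np.ndarray
    B: np.ndarray
    Z: np.ndarray
    W: np.ndarray
    input_names: list = field(default_factory=list)
    output_names: list = field(default_factory=list)
    bad_names: list = field(default_factory=list)
    env_names: list = field(default_factory=list)
    weight_name: str = "weight"

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.Z = np.asarray(self.Z, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        J, T = len(self.dmu_ids), len(self.periods)
        if self.B.size == 0:
            self.B = self.B.reshape(J, T, 0)
        if self.Z.size == 0:
            self.Z = self.Z.reshape(J, T, 0)
        if not self.input_names:
            self.input_names = [f"x{i+1}" for i in range(self.X.shape[2])]
        if not self.output_names:
            self.output_names = [f"y{i+1}" for i in range(self.Y.shape[2])]
        if not self.bad_names:
            self.bad_names = [f"b{i+1}" for i in range(self.B.shape[2])]
        if not self.env_names:
            self.env_names = [f"z{i+1}" for i in range(self.Z.shape[2])]
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self):
        J, T = len(self.dmu_ids), len(self.periods)
        if len(set(self.dmu_ids)) != J:
            raise PanelValidationError("duplicate unit labels")
        per = np.asarray(self.periods)
        if len(per) == 0 or np.any(np.diff(per) != 1):
            raise PanelValidationError(
                "periods must be strictly increasing consecutive years"
            )
        for name, arr, ncols in (
            ("X", self.X, None), ("Y", self.Y, None), ("B", self.B, None),
            ("Z", self.Z, None),
        ):
            if arr.ndim != 3 or arr.shape[0] != J or arr.shape[1] != T:
                raise PanelValidationError(
                    f"{name} has shape {arr.shape}, expected ({J}, {T}, *)"
                )
        if self.W.shape != (J, T):
            raise PanelValidationError(
                f"W has shape {self.W.shape}, expected ({J}, {T})"
            )
        for name, arr in (("X", self.X), ("Y", self.Y), ("B", self.B),
                          ("Z", self.Z), ("W", self.W)):
            if not np.all(np.isfinite(arr)):
                raise PanelValidationError(f"{name} contains non-finite values")
        bad = np.argwhere(self.X <= 0)
        if bad.size:
            j, t, i = bad[0]
            raise PanelValidationError(
                f"nonpositive input: unit={self.dmu_ids[j]}, "
                f"year={self.periods[t]}, variable={self.input_names[i]}"
            )
        if np.any(self.Y < 0) or np.any(self.B < 0) or np.any(self.W < 0):
            raise PanelValidationError("Y, B and W must be nonnegative")

    # -- convenience ------------------------------------------------------
    @property
    def n_units(self):
        return len(self.dmu_ids)

    @property
    def n_periods(self):
        return len(self.periods)

    @property
    def n_inputs(self):
        return self.X.shape[2]

    def flatten(self):
        """Stack (unit, period) cells into N = J*T observations.

        Returns (labels, Xo, Yo, Bo, Zo, Wo, period_index) where labels is a
        list of (j, t) index pairs in row-major (unit-major) order.
        """
        J, T = self.n_units, self.n_periods
        labels = [(j, t) for j in range(J) for t in range(T)]
        Xo = self.X.reshape(J * T, -1)
        Yo = self.Y.reshape(J * T, -1)
        Bo = self.B.reshape(J * T, -1)
        Zo = self.Z.reshape(J * T, -1)
        Wo = self.W.reshape(J * T)
        tidx = np.array([t for _, t in labels])
        return labels, Xo, Yo, Bo, Zo, Wo, tidx

    def replace_inputs(self, X_new):
        """Return a copy of the panel with a new input array."""
        X_new = np.asarray(X_new, dtype=float).reshape(self.X.shape)
        return PanelDataset(
            dmu_ids=list(self.dmu_ids), periods=list(self.periods),
            X=X_new, Y=self.Y.copy(), B=self.B.copy(), Z=self.Z.copy(),
            W=self.W.copy(), input_names=list(self.input_names),
            output_names=list(self.output_names),
            bad_names=list(self.bad_names), env_names=list(self.env_names),
            weight_name=self.weight_name,
        )

    def to_frame(self):
        """Wide-format DataFrame: one row per (unit, year)."""
        rows = []
        for j, u in enumerate(self.dmu_ids):
            for t, yr in enumerate(self.periods):
                row = {"unit": u, "year": yr}
                for i, nm in enumerate(self.input_names):
                    row[nm] = self.X[j, t, i]
                for i, nm in enumerate(self.output_names):
                    row[nm] = self.Y[j, t, i]
                for i, nm in enumerate(self.bad_names):
                    row[nm] = self.B[j, t, i]
                for i, nm in enumerate(self.env_names):
                    row[nm] = self.Z[j, t, i]
                row[self.weight_name] = self.W[j, t]
                rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class CarbonCoefficientSet:
    """Emission factors per activity category (user-supplied values)."""

    source_names: list
    coefficients: np.ndarray

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.source_names) != self.coefficients.shape[0]:
            raise ValueError("one coefficient per source required")
        if np.any(self.coefficients < 0):
            raise ValueError("coefficients must be nonnegative")


# ---------------------------------------------------------------------------
# schema + file loading
# ---------------------------------------------------------------------------

_SCHEMA_KEYS = ("inputs", "outputs_good")


def load_schema(source):
    """Load a schema mapping from a dict or a YAML/JSON file path."""
    if isinstance(source, dict):
        schema = dict(source)
    else:
        path = Path(source)
        if not path.exists():
            raise SchemaError(f"schema file not found: {path}")
        text = path.read_text()
        schema = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    for key in _SCHEMA_KEYS:
        if key not in schema:
            raise SchemaError(f"schema missing required key: {key!r}")
    schema.setdefault("format", "wide")
    schema.setdefault("unit_col", "unit")
    schema.setdefault("year_col", "year")
    schema.setdefault("outputs_bad", [])
    schema.setdefault("env", [])
    schema.setdefault("weight", None)
    return schema


def load_panel(path, schema) -> PanelDataset:
    """Read a wide- or long-format CSV into a validated :class:`PanelDataset`.

    ``schema`` maps column names to roles::

        format: wide | long
        unit_col: unit
        year_col: year
        inputs: [water, soil, fertilizer, machinery]
        outputs_good: [grain]
        outputs_bad: [carbon]
        env: [urbanization, gdp_pc, disaster, arable_pc, fiscal]
        weight: grain          # defaults to the first desirable output

    Fails loudly on missing columns, nonpositive inputs or an unbalanced
    panel; nothing is imputed.
    """
    schema = load_schema(schema)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)

    ucol, ycol = schema["unit_col"], schema["year_col"]
    if schema["format"] == "long":
        for col in (ucol, ycol, "variable", "value"):
            if col not in df.columns:
                raise SchemaError(f"long-format file missing column {col!r}")
        df = (
            df.pivot_table(index=[ucol, ycol], columns="variable",
                           values="value", aggfunc="first")
            .reset_index()
        )
        df.columns.name = None

    needed = (
        [ucol, ycol] + list(schema["inputs"]) + list(schema["outputs_good"])
        + list(schema["outputs_bad"]) + list(schema["env"])
    )
    wname = schema["weight"] or schema["outputs_good"][0]
    if wname not in needed:
        needed.append(wname)
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {missing}")

    units = sorted(df[ucol].astype(str).unique())
    years = sorted(df[ycol].astype(int).unique())
    J, T = len(units), len(years)
    if len(df) != J * T:
        raise PanelValidationError(
            f"unbalanced panel: {len(df)} rows, expected {J} units x {T} years"
        )
    df = df.assign(**{ucol: df[ucol].astype(str), ycol: df[ycol].astype(int)})
    df = df.set_index([ucol, ycol]).sort_index()
    if df.index.has_duplicates:
        raise PanelValidationError("duplicate (unit, year) rows")

    def cube(cols):
        if not cols:
            return np.zeros((J, T, 0))
        sub = df[list(cols)]
        if sub.isna().any().any():
            cell = sub[sub.isna().any(axis=1)].index[0]
            raise PanelValidationError(f"missing value at (unit, year)={cell}")
        return sub.to_numpy(dtype=float).reshape(J, T, len(cols))

    return PanelDataset(
        dmu_ids=units, periods=years,
        X=cube(schema["inputs"]), Y=cube(schema["outputs_good"]),
        B=cube(schema["outputs_bad"]), Z=cube(schema["env"]),
        W=cube([wname])[:, :, 0],
        input_names=list(schema["inputs"]),
        output_names=list(schema["outputs_good"]),
        bad_names=list(schema["outputs_bad"]),
        env_names=list(schema["env"]),
        weight_name=wname,
    )


def write_panel(data: PanelDataset, path, fmt="wide"):
    """Write a panel back to CSV (wide or long)."""
    df = data.to_frame()
    if fmt == "long":
        df = df.melt(id_vars=["unit", "year"], var_name="variable",
                     value_name="value")
    df.to_csv(path, index=False)
    return Path(path)


# ---------------------------------------------------------------------------
# derived-indicator helpers
# ---------------------------------------------------------------------------

def apportion_by_sown_share(total_quantity, grain_share):
    """Apportion an agriculture-wide quantity to grain by its sown-area share.

    Yearbook fertilizer and machinery totals cover all of agriculture; the
    grain-attributable part is total x (grain sown area / total sown area).
    """
    total_quantity = float(total_quantity)
    grain_share = float(grain_share)
    if not 0.0 <= grain_share <= 1.0:
        raise ValueError(f"grain_share must lie in [0, 1], got {grain_share}")
    if total_quantity < 0:
        raise ValueError("total_quantity must be nonnegative")
    return total_quantity * grain_share


def aggregate_carbon(activity, coeffs: CarbonCoefficientSet):
    """Total emissions as the inner product of activity levels and factors."""
    activity = np.asarray(activity, dtype=float)
    if activity.shape != coeffs.coefficients.shape:
        raise ValueError(
            f"activity length {activity.shape} does not match "
            f"{coeffs.coefficients.shape} coefficients"
        )
    if np.any(activity < 0):
        raise ValueError("activity quantities must be nonnegative")
    return float(activity @ coeffs.coefficients)
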