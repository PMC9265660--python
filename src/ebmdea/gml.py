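"""Global Malmquist(-Luenberger) total-factor-productivity index.

Productivity change between adjacent periods is measured against a single
*global* frontier built from every unit-period observation, which makes the
index transitive (circular): the change from t to t+2 is exactly the product
of the two adjacent changes, a property the contemporaneous-frontier
Malmquist index lacks.

With E_G the global-frontier CRS efficiency and E_t the contemporaneous CRS
efficiency (and V superscripts their VRS counterparts), for unit j between
periods t and t+1:

    GML  = E_G(t+1) / E_G(t)                         total change
    GEFC = E_{t+1}(t+1) / E_t(t)                     efficiency (catch-up)
    GETC = GML / GEFC                                technology (frontier shift)
    GPEC = E^V_{t+1}(t+1) / E^V_t(t)                 pure efficiency change
    GSEC = GEFC / GPEC                               scale efficiency change
    GPTC = [E^V_G(t+1)/E^V_{t+1}(t+1)] / [E^V_G(t)/E^V_t(t)]
    GSTC = GETC / GPTC                               technology scale change

so GML = GEFC x GETC, GEFC = GPEC x GSEC and GETC = GPTC x GSTC by
construction. Scores entering the index are plain (non-super-efficiency)
ratio efficiencies; super-efficiency is a ranking device for the static
tables only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["compute_gml", "average_index", "FACTORS"]

FACTORS = ["gml", "gefc", "getc", "gpec", "gsec", "gptc", "gstc"]


def _check(table, name):
    arr = np.asarray(table, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        bad = np.argwhere(~np.isfinite(arr) | (arr <= 0))[0]
        raise ValueError(
            f"{name} score table has a nonpositive/missing cell at "
            f"(unit={table.index[bad[0]]}, period={table.columns[bad[1]]})"
        )


def compute_gml(global_crs, contemp_crs, global_vrs, contemp_vrs) -> pd.DataFrame:
    """Productivity records for every unit and adjacent period pair.

    All four arguments are (J x T) DataFrames of non-super-efficiency scores
    sharing index (units) and columns (periods). Returns one row per
    (unit, t -> t+1) with the seven multiplicative factors.
    """
    tables = {"global CRS": global_crs, "contemporaneous CRS": contemp_crs,
              "global VRS": global_vrs, "contemporaneous VRS": contemp_vrs}
    ref = global_crs
    for name, tab in tables.items():
        if not (tab.index.equals(ref.index) and tab.columns.equals(ref.columns)):
            raise ValueError(f"{name} table is not aligned with the others")
        _check(tab, name)

    periods = list(ref.columns)
    rows = []
    for unit in ref.index:
        for a, b in zip(periods[:-1], periods[1:]):
            gml = global_crs.at[unit, b] / global_crs.at[unit, a]
            gefc = contemp_crs.at[unit, b] / contemp_crs.at[unit, a]
            getc = gml / gefc
            gpec = contemp_vrs.at[unit, b] / contemp_vrs.at[unit, a]
            gsec = gefc / gpec
            gptc = ((global_vrs.at[unit, b] / contemp_vrs.at[unit, b])
                    / (global_vrs.at[unit, a] / contemp_vrs.at[unit, a]))
            gstc = getc / gptc
            rows.append({"unit": unit, "period_from": a, "period_to": b,
                         "gml": gml, "gefc": gefc, "getc": getc,
                         "gpec": gpec, "gsec": gsec, "gptc": gptc,
                         "gstc": gstc})
    return pd.DataFrame(rows)


def average_index(records: pd.DataFrame, by="unit", how="geometric",
                  weights=None) -> pd.DataFrame:
    """Average the seven factors over units or period pairs.

    ``how="geometric"`` is the natural mean for multiplicative indices
    (exp of the mean log); ``how="arithmetic"`` mirrors the way published
    summary tables are usually printed. Optional ``weights`` is a mapping
    from the grouping key to a nonnegative weight.
    """
    if records.empty:
        raise ValueError("no productivity records to average")
    vals = records[FACTORS]
    if (vals <= 0).any().any():
        raise ValueError("indices must be positive to average")
    if by == "unit":
        key = records["unit"]
    elif by == "period":
        key = records["period_to"]
    elif by is None:
        key = pd.Series(["all"] * len(records), index=records.index)
    else:
        raise ValueError(f"unknown grouping: {by!r}")

    w = pd.Series(1.0, index=records.index)
    if weights is not None:
        w = key.map(lambda k: float(weights[k]))
        if (w < 0).any():
            raise ValueError("weights must be nonnegative")

    def agg(group):
        wi = w.loc[group.index]
        if wi.sum() <= 0:
            raise ValueError("group weights sum to zero")
        wi = wi / wi.sum()
        if how == "geometric":
            return np.exp((np.log(group) * wi.to_numpy()[:, None]).sum())
        if how == "arithmetic":
            return (group * wi.to_numpy()[:, None]).sum()
        raise ValueError(f"unknown mean: {how!r}")

    out = vals.groupby(key.rename("group"), sort=True).apply(agg)
    return out
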