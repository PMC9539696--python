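"""Four-case classification of the biogeochemical response to anthropogenic Fe.

Surface-ocean systems are binned by their underlying biogeochemistry —
degree of iron limitation and level of primary productivity — into four
cases:

==== ==================== =================
case Fe-limited?          productivity
==== ==================== =================
1    no                   high
2    no                   low  (subtropical-gyre-like)
3    yes                  high (subpolar-HNLC-like)
4    yes                  low
==== ==================== =================

The expected response pattern to anthropogenic iron deposition is: mixed-
layer dFe inventory increases in the non-Fe-limited cases (1–2), summer
primary production is stimulated in the Fe-limited cases (3–4),
δ⁵⁶Fe_diss decreases everywhere and most strongly in case 4, and case 1
shows *luxury* Fe uptake — uptake rises with essentially no production
response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

__all__ = ["RegimeThresholds", "RegimeLabel", "classify_regime",
           "regime_response_summary"]

CASE_RULE = {(False, True): 1, (False, False): 2, (True, True): 3, (True, False): 4}


class RegimeError(ValueError):
    """Missing diagnostics or inconsistent label/field inputs."""


@dataclass
class RegimeThresholds:
    """Thresholds of the 2×2 classification.

    ``fe_limited_fraction``: a column is Fe-limited when iron is the most
    limiting factor for at least this fraction of growing-season months.
    ``light_threshold`` defines the growing season (light index ≥ value).
    ``pp_threshold``: absolute cut (mmol C m⁻³ d⁻¹) for "high
    productivity"; ``None`` uses the median growing-season PP across the
    classified columns (relative, scenario-independent default).
    ``climatology_years``: classification uses the final N simulated years.
    """

    fe_limited_fraction: float = 0.5
    light_threshold: float = 0.5
    pp_threshold: float | None = None
    climatology_years: int = 5


@dataclass
class RegimeLabel:
    case: int
    fe_limited: bool
    high_productivity: bool
    weak_seasonal: bool


def _climatology(ds: xr.Dataset, years: int) -> xr.Dataset:
    last = int(ds.year.max())
    sub = ds.where(ds.year > last - years, drop=True)
    return sub.groupby("month").mean("time")


def classify_regime(run_output: xr.Dataset,
                    thresholds: RegimeThresholds | None = None) -> pd.DataFrame:
    """Assign every column a case label from a standard-run output.

    Iron limitation is diagnosed from the model's own limitation index
    (the argmin of the Fe-quota, nutrient and light terms), not from a
    nutrient-concentration proxy.  Returns a DataFrame indexed by column
    with ``case``, ``fe_limited``, ``high_productivity``,
    ``growing_pp`` and ``fe_limited_fraction`` columns.
    """
    th = thresholds or RegimeThresholds()
    for v in ("limitation", "pp", "light"):
        if v not in run_output:
            raise RegimeError(f"run output lacks the {v!r} diagnostic")
    clim = _climatology(run_output, th.climatology_years)
    growing = clim.light >= th.light_threshold
    n_grow = growing.sum("month")
    if int(n_grow.min()) == 0:
        raise RegimeError("no growing-season months under the light threshold")
    fe_frac = (clim.limitation == 0).where(growing).sum("month") / n_grow
    fe_limited = fe_frac >= th.fe_limited_fraction
    growing_pp = clim.pp.where(growing).mean("month")
    pp_cut = (float(growing_pp.median("column"))
              if th.pp_threshold is None else th.pp_threshold)
    high_pp = growing_pp > pp_cut
    cases = [CASE_RULE[(bool(f), bool(h))] for f, h in zip(fe_limited.values, high_pp.values)]
    return pd.DataFrame({
        "case": cases,
        "fe_limited": fe_limited.values,
        "high_productivity": high_pp.values,
        "fe_limited_fraction": fe_frac.values,
        "growing_pp": growing_pp.values,
        "pp_threshold": pp_cut,
    }, index=pd.Index(run_output.column.values, name="column"))


def _weak_seasonal_flags(delta_fields: xr.Dataset, standard_pp: xr.DataArray) -> np.ndarray:
    """Effect limited to peak-productivity months: |ΔPP| exceeds its own
    scale only inside the top productivity quartile of the climatology."""
    clim_dpp = np.abs(delta_fields.d_pp.groupby("month").mean("time"))
    clim_pp = standard_pp.groupby("month").mean("time")
    q75 = clim_pp.quantile(0.75, "month")
    top = clim_pp >= q75
    peak = clim_dpp.where(top).max("month")
    rest = clim_dpp.where(~top).max("month")
    with np.errstate(invalid="ignore"):
        return (rest.values < 0.25 * peak.values) & (peak.values > 0)


def regime_response_summary(delta_fields: xr.Dataset, labels: pd.DataFrame,
                            standard: xr.Dataset | None = None,
                            light_threshold: float = 0.5) -> pd.DataFrame:
    """Aggregate anthropogenic-impact fields by regime case.

    Emits, per case: mean Δ dFe inventory, mean Δδ⁵⁶Fe_diss, growing-season
    (summer) mean ΔPP, a luxury-uptake index (Fe-uptake increase per unit
    PP increase, floored), and flags for columns violating the expected
    sign pattern.
    """
    if delta_fields.sizes.get("time", 0) == 0 or delta_fields.sizes.get("column", 0) == 0:
        raise RegimeError("empty delta fields")
    missing = set(delta_fields.column.values) - set(labels.index)
    if missing:
        raise RegimeError(f"labels missing for columns {sorted(missing)}")

    if "light" in delta_fields:
        growing = delta_fields.light >= light_threshold
    elif standard is not None and "light" in standard:
        growing = standard.light >= light_threshold
    else:
        raise RegimeError("need a light index (in delta fields or standard run)")

    d_inv = delta_fields.d_dfe_inventory.mean("time")
    d_delta = delta_fields.d_delta.mean("time")
    d_pp_summer = delta_fields.d_pp.where(growing).mean("time")
    d_up_summer = delta_fields.d_fe_uptake.where(growing).mean("time")
    pp_floor = 1e-3  # mmol C m-3 d-1: treats smaller ΔPP as "no response"
    luxury = d_up_summer / np.maximum(d_pp_summer, pp_floor)

    df = labels.copy()
    df["d_dfe_inventory"] = d_inv.values
    df["d_delta"] = d_delta.values
    df["d_pp_summer"] = d_pp_summer.values
    df["d_fe_uptake_summer"] = d_up_summer.values
    df["luxury_index"] = luxury.values
    if standard is not None and "pp" in standard:
        df["weak_seasonal"] = _weak_seasonal_flags(delta_fields, standard.pp)

    expected_inv = df.case.isin([1, 2])
    df["violates_pattern"] = (
        (expected_inv & (df.d_dfe_inventory <= 0))
        | (df.case.isin([3, 4]) & (df.d_pp_summer <= 0))
        | (df.d_delta >= 0)
    )

    agg = df.groupby("case").agg(
        n_columns=("case", "size"),
        d_dfe_inventory=("d_dfe_inventory", "mean"),
        d_delta=("d_delta", "mean"),
        d_pp_summer=("d_pp_summer", "mean"),
        d_fe_uptake_summer=("d_fe_uptake_summer", "mean"),
        luxury_index=("luxury_index", "mean"),
        n_violations=("violates_pattern", "sum"),
    )
    agg.attrs = {"per_column": df}
    return agg
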