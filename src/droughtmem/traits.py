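"""Per-plant trait extraction and accession x treatment aggregation.

Four ecophysiological summaries feed the stress-memory indices:

* **S** — senescence rate: ordinary-least-squares slope of SPAD chlorophyll
  readings against days-after-transplant (DAT), fitted from the point of
  maximum greenness (earliest occurrence on ties) to the last measurement.
  Less negative means delayed senescence.
* **FA_max** — maximum foliar area (cm^2) reached by a plant over the
  repeated canopy assessments.
* **dT_min** — most negative leaf-minus-air temperature (degC) over the
  measurement events; a proxy for peak evaporative cooling.
* **Delta_max** — maximum leaf 13C discrimination (permil) over the isotope
  sampling occasions, each occasion summarised as the mean discrimination of
  its composite samples.

Per-plant statistics are averaged over replicates within an accession x
treatment; discrimination is computed at the accession x treatment level
because the leaf samples are composited across plants.  Missing results
carry reason codes and are excluded from replicate means with the count
decremented — never imputed as zeros.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import ComputationError, Missing, SchemaError, is_missing

logger = logging.getLogger(__name__)

#: delta13C of atmospheric CO2 (permil) used in the discrimination formula
DELTA_ATM_PERMIL = -8.0

#: soft upper validation bound for a single foliar-area reading (cm^2)
FA_SOFT_MAX_CM2 = 1537.3

_REQUIRED_COLUMNS = {
    "spad": ["accession_id", "treatment", "replicate", "DAT", "value"],
    "foliar_area": ["accession_id", "treatment", "replicate", "DAT", "value"],
    "leaf_temperature": ["accession_id", "treatment", "replicate", "DAT", "value"],
    "air_temperature": ["DAT", "air_temp_c"],
    "isotopes": ["accession_id", "treatment", "event", "delta13c_permil"],
    "biomass": ["accession_id", "treatment", "replicate", "dry_weight_g"],
}


@dataclass(frozen=True)
class PlantSeries:
    """One plant's repeated measurements of one variable over DAT."""

    accession_id: str
    treatment: str
    replicate: int
    variable: str
    dat: tuple
    values: tuple

    def __post_init__(self):
        if len(self.dat) != len(self.values) or len(self.dat) == 0:
            raise ValueError("series needs >= 1 (DAT, value) pair")
        if any(b <= a for a, b in zip(self.dat, self.dat[1:])):
            raise ValueError("DAT must be strictly increasing")


def fit_senescence_slope(dat: Sequence[float],
                         values: Sequence[float]) -> float | Missing:
    """OLS slope of SPAD vs DAT from the (earliest) maximum to the last point.

    Returns ``Missing('insufficient_post_peak_points')`` when fewer than
    three points lie at or after the maximum.
    """
    dat = np.asarray(dat, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(dat) == 0:
        return Missing("empty_series")
    i_peak = int(np.argmax(values))  # argmax returns the earliest tie
    x, y = dat[i_peak:], values[i_peak:]
    if len(x) < 3:
        return Missing("insufficient_post_peak_points")
    if np.ptp(x) == 0:
        return Missing("degenerate_time_axis")
    if np.ptp(y) == 0:
        return 0.0  # flat window: linregress would warn; slope is exactly 0
    return float(stats.linregress(x, y).slope)


def max_foliar_area(values: Sequence[float]) -> float | Missing:
    """Maximum foliar area over a plant's assessments (cm^2)."""
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        return Missing("empty_series")
    vmax = float(np.max(values))
    if vmax > FA_SOFT_MAX_CM2:
        logger.warning("foliar area %.1f cm^2 exceeds soft bound %.1f",
                       vmax, FA_SOFT_MAX_CM2)
    return vmax


def compute_dT(leaf_temp: float, air_temp: float) -> float | Missing:
    """Leaf-minus-air temperature (degC) for one measurement event."""
    if not np.isfinite(leaf_temp) or not np.isfinite(air_temp):
        return Missing("no_air_match")
    return float(leaf_temp) - float(air_temp)


def min_dT(dts: Sequence[float]) -> float | Missing:
    """Minimum leaf-minus-air temperature over a plant's events (degC)."""
    vals = [v for v in dts if not is_missing(v) and np.isfinite(v)]
    if not vals:
        return Missing("empty_series")
    return float(min(vals))


def delta13C_discrimination(delta_p: float,
                            delta_a: float = DELTA_ATM_PERMIL) -> float:
    """Leaf 13C discrimination Delta (permil) from tissue delta13C.

    Delta = (delta_a - delta_p) / (1 + delta_p/1000), with both deltas given
    in permil; the denominator converts the plant signature to fractional
    form so the expression is dimensionally consistent.
    """
    if delta_p <= -1000.0:
        raise ComputationError(f"delta_p={delta_p} permil is outside the "
                               "physical domain (must exceed -1000)")
    return (delta_a - delta_p) / (1.0 + delta_p / 1000.0)


def max_discrimination(event_means: Sequence[float]) -> float | Missing:
    """Maximum over isotope occasions of the event-mean discrimination (permil)."""
    vals = [v for v in event_means if not is_missing(v) and np.isfinite(v)]
    if not vals:
        return Missing("empty_series")
    return float(max(vals))


# ---------------------------------------------------------------------------
# aggregation


def validate_tables(tables: Mapping[str, pd.DataFrame],
                    required: Sequence[str] | None = None) -> None:
    """Raise :class:`SchemaError` naming any missing table or column."""
    for name in (required or _REQUIRED_COLUMNS):
        if name not in tables:
            raise SchemaError(f"required table {name!r} is missing")
        missing = [c for c in _REQUIRED_COLUMNS[name]
                   if c not in tables[name].columns]
        if missing:
            raise SchemaError(f"table {name!r} lacks columns {missing}")


def _replicate_mean(results: dict[int, float | Missing]) -> tuple[float, int]:
    vals = [v for v in results.values() if not is_missing(v)]
    if not vals:
        return float("nan"), 0
    return float(np.mean(vals)), len(vals)


def summarize(tables: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Aggregate measurement tables into one row per accession x treatment.

    Columns: S (SPAD/day), FA_max (cm^2), dT_min (degC), delta_max (permil),
    Y (g dry matter), each with its contributing replicate/event count.
    Per-leaf layouts (several rows per plant and DAT) are averaged on load.
    """
    validate_tables(tables)
    spad = (tables["spad"]
            .groupby(["accession_id", "treatment", "replicate", "DAT"],
                     as_index=False)["value"].mean())
    fa = (tables["foliar_area"]
          .groupby(["accession_id", "treatment", "replicate", "DAT"],
                   as_index=False)["value"].mean())
    leaf = tables["leaf_temperature"].merge(
        tables["air_temperature"][["DAT", "air_temp_c"]], on="DAT", how="left")
    n_unmatched = int(leaf["air_temp_c"].isna().sum())
    if n_unmatched:
        logger.warning("%d leaf-temperature rows had no concurrent air record "
                       "(no_air_match); excluded", n_unmatched)
    leaf["dT"] = leaf["value"] - leaf["air_temp_c"]

    rows = []
    keys = sorted(set(map(tuple, tables["biomass"][
        ["accession_id", "treatment"]].drop_duplicates().values))
        | set(map(tuple, spad[["accession_id", "treatment"]]
                  .drop_duplicates().values)))
    for acc, trt in keys:
        s_res = {rep: fit_senescence_slope(g["DAT"].to_numpy(),
                                           g["value"].to_numpy())
                 for rep, g in spad[(spad["accession_id"] == acc)
                                    & (spad["treatment"] == trt)]
                 .sort_values("DAT").groupby("replicate")}
        s_mean, s_n = _replicate_mean(s_res)
        fa_res = {rep: max_foliar_area(g["value"].to_numpy())
                  for rep, g in fa[(fa["accession_id"] == acc)
                                   & (fa["treatment"] == trt)]
                  .groupby("replicate")}
        fa_mean, fa_n = _replicate_mean(fa_res)
        dt_res = {rep: min_dT(g["dT"].to_numpy())
                  for rep, g in leaf[(leaf["accession_id"] == acc)
                                     & (leaf["treatment"] == trt)]
                  .groupby("replicate")}
        dt_mean, dt_n = _replicate_mean(dt_res)

        iso = tables["isotopes"]
        iso = iso[(iso["accession_id"] == acc) & (iso["treatment"] == trt)]
        if len(iso):
            event_means = [
                float(np.mean([delta13C_discrimination(dp)
                               for dp in g["delta13c_permil"]]))
                for _, g in iso.groupby("event")]
            d_max = max_discrimination(event_means)
            d_n = len(event_means)
        else:
            d_max, d_n = Missing("no_isotope_data"), 0
        bio = tables["biomass"]
        bio = bio[(bio["accession_id"] == acc) & (bio["treatment"] == trt)]
        y_mean = float(bio["dry_weight_g"].mean()) if len(bio) else float("nan")

        rows.append({
            "accession_id": acc, "treatment": trt,
            "S": s_mean, "S_n": s_n,
            "FA_max": fa_mean, "FA_n": fa_n,
            "dT_min": dt_mean, "dT_n": dt_n,
            "delta_max": float("nan") if is_missing(d_max) else d_max,
            "delta_n": d_n,
            "Y": y_mean, "Y_n": int(len(bio)),
        })
    out = pd.DataFrame(rows)
    by_acc = out.groupby("accession_id")["treatment"].nunique()
    unpaired = by_acc[by_acc < 2].index.tolist()
    if unpaired:
        logger.warning("accessions missing a treatment (excluded from the "
                       "memory-index stage): %s", unpaired)
    return out
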