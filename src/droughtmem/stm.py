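"""Short-term stress-memory (STM) indices and occurrence statistics.

Each index contrasts primed with non-primed plants of one accession:

* ``STM_S = S_pr - S_npr`` — difference of senescence slopes (SPAD/day);
  positive means priming delayed senescence.
* ``STM_FA = FA_max_pr / FA_max_npr`` — ratio of maximum foliar areas.
* ``STM_dT = dT_min_pr / dT_min_npr`` — ratio of minimum leaf-minus-air
  temperatures, defined only when both minima are negative (both
  treatments actually cooled below air temperature); with a negative
  denominator a ratio above one means *stronger* cooling under priming.
* ``STM_Delta = Delta_max_pr / Delta_max_npr`` — ratio of maximum 13C
  discriminations.

Occurrence is a strict inequality: STM_S > 0, or ratio > 1.  Population
occurrence percentages use, by default, the full accession panel as the
denominator, counting accessions with an undefined index as non-occurrence.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._errors import ComputationError, Missing, is_missing

logger = logging.getLogger(__name__)

INDEX_NAMES = ("stm_s", "stm_fa", "stm_dt", "stm_delta")


def stm_senescence(s_pr: float, s_npr: float) -> float | Missing:
    """Additive memory effect on the senescence slope: S_pr - S_npr."""
    if is_missing(s_pr) or is_missing(s_npr) \
            or not (np.isfinite(s_pr) and np.isfinite(s_npr)):
        return Missing("missing_operand")
    return float(s_pr) - float(s_npr)


def stm_ratio(x_pr: float, x_npr: float) -> float | Missing:
    """Multiplicative memory effect: x_pr / x_npr (foliar area, discrimination)."""
    if is_missing(x_pr) or is_missing(x_npr) \
            or not (np.isfinite(x_pr) and np.isfinite(x_npr)):
        return Missing("missing_operand")
    if x_npr == 0:
        return Missing("zero_denominator")
    return float(x_pr) / float(x_npr)


def stm_dT_ratio(dt_min_pr: float, dt_min_npr: float) -> float | Missing:
    """dT_min ratio, guarded: defined only when both minima are negative."""
    if is_missing(dt_min_pr) or is_missing(dt_min_npr) \
            or not (np.isfinite(dt_min_pr) and np.isfinite(dt_min_npr)):
        return Missing("missing_operand")
    if dt_min_pr >= 0 or dt_min_npr >= 0:
        reason = ("sign_mismatch" if (dt_min_pr < 0) != (dt_min_npr < 0)
                  else "nonnegative_operand")
        return Missing(reason)
    return float(dt_min_pr) / float(dt_min_npr)


def compute_profiles(summary: pd.DataFrame) -> pd.DataFrame:
    """Per-accession STM indices and occurrence flags from a trait summary.

    Expects one row per accession x treatment (columns ``S``, ``FA_max``,
    ``dT_min``, ``delta_max``).  Accessions lacking either treatment are
    dropped with a warning.  Undefined indices carry a reason code in the
    matching ``*_reason`` column; their flags are NA.
    """
    wide = summary.set_index(["accession_id", "treatment"])
    rows = []
    for acc in sorted(summary["accession_id"].unique()):
        try:
            pr = wide.loc[(acc, "primed")]
            npr = wide.loc[(acc, "non_primed")]
        except KeyError:
            logger.warning("accession %s lacks a treatment; skipped", acc)
            continue

        def _nan(v):
            return Missing("missing_operand") if pd.isna(v) else float(v)

        vals = {
            "stm_s": stm_senescence(_nan(pr["S"]), _nan(npr["S"])),
            "stm_fa": stm_ratio(_nan(pr["FA_max"]), _nan(npr["FA_max"])),
            "stm_dt": stm_dT_ratio(_nan(pr["dT_min"]), _nan(npr["dT_min"])),
            "stm_delta": stm_ratio(_nan(pr["delta_max"]), _nan(npr["delta_max"])),
        }
        row: dict = {"accession_id": acc}
        for name, v in vals.items():
            if is_missing(v):
                row[name] = np.nan
                row[f"{name}_reason"] = v.reason
                row[f"flag_{name[4:]}"] = pd.NA
            else:
                row[name] = v
                row[f"{name}_reason"] = ""
                threshold = 0.0 if name == "stm_s" else 1.0
                row[f"flag_{name[4:]}"] = bool(v > threshold)
        rows.append(row)
    return pd.DataFrame(rows)


def occurrence_percentage(flags, n_total: int | None = None,
                          denominator: str = "all") -> float:
    """Percent of accessions showing memory occurrence for one index.

    ``denominator='all'`` (study convention) divides the count of True flags
    by the total panel size, treating undefined flags as non-occurrence;
    ``'defined'`` divides by the number of defined flags only.  Reported to
    one decimal place.
    """
    flags = pd.Series(flags)
    defined = flags.dropna()
    n_true = int(defined.astype(bool).sum())
    if denominator == "all":
        denom = len(flags) if n_total is None else int(n_total)
    elif denominator == "defined":
        denom = len(defined)
    else:
        raise ValueError(f"unknown denominator policy {denominator!r}")
    if denom < 1:
        raise ComputationError("occurrence percentage over an empty population")
    logger.info("occurrence: %d true / %d (%s denominator)",
                n_true, denom, denominator)
    return round(100.0 * n_true / denom, 1)


def occurrence_summary(profiles: pd.DataFrame, n_total: int | None = None,
                       denominator: str = "all") -> dict:
    """Per-index occurrence counts and percentages for a profile table."""
    out = {}
    for name in INDEX_NAMES:
        flags = profiles[f"flag_{name[4:]}"]
        out[name] = {
            "n_true": int(flags.dropna().astype(bool).sum()),
            "n_defined": int(flags.notna().sum()),
            "percent": occurrence_percentage(flags, n_total=n_total,
                                             denominator=denominator),
        }
    return out
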