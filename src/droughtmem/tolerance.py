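"""Biomass-based drought-tolerance indices, 1-10 scores and group assignment.

From primed (stressed) and non-primed dry-biomass production ``Y_pr`` and
``Y_npr``:

* ``SSI = (1 - Y_pr/Y_npr) / (1 - Ybar_pr/Ybar_npr)`` — stress
  susceptibility index: an accession's relative biomass loss normalised by
  the population mean relative loss.  Lower (or negative) = more resilient.
* ``GMP = sqrt(Y_pr * Y_npr)`` — geometric mean productivity across
  conditions.  Higher = more productive.

The score-values conversion maps each index onto a 1-10 scale by
deterministic decile ranking (``1 + floor(10 * (rank-1) / n)``, rank 1 =
least tolerant, ties broken by accession id): the resilience capacity index
RCI scores SSI with the ordering inverted (low SSI -> high score) and the
production capacity index PCI scores GMP directly.  In replicate mode the
indices are computed per paired replicate, scored per replicate across the
population, then averaged — with four replicates scores move in quarter
steps.

Fernandez groups classify accessions against population-median thresholds:
A = superior under both stress and non-stress (both scores high),
B = productive but not resilient, C = resilient but not productive,
D = poor under both.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from ._errors import ComputationError

DIRECTIONS = ("higher_is_tolerant", "lower_is_tolerant")


def ssi(y_pr: float, y_npr: float, ybar_pr: float, ybar_npr: float) -> float:
    """Stress susceptibility index for one accession within a population."""
    for name, v in (("y_pr", y_pr), ("y_npr", y_npr),
                    ("ybar_pr", ybar_pr), ("ybar_npr", ybar_npr)):
        if v < 0:
            raise ComputationError(f"negative biomass {name}={v}")
    if y_npr == 0:
        raise ComputationError("zero denominator: y_npr")
    if ybar_npr == 0:
        raise ComputationError("zero denominator: ybar_npr")
    pop = 1.0 - ybar_pr / ybar_npr
    if pop == 0:
        raise ComputationError("zero denominator: population mean reduction "
                               "(1 - ybar_pr/ybar_npr)")
    return (1.0 - y_pr / y_npr) / pop


def gmp(y_pr: float, y_npr: float) -> float:
    """Geometric mean productivity: sqrt(Y_pr * Y_npr), g dry matter."""
    if y_pr < 0 or y_npr < 0:
        raise ComputationError("negative biomass passed to gmp")
    return math.sqrt(y_pr * y_npr)


def score_index(values: pd.Series, direction: str) -> pd.Series:
    """Convert an index to 1-10 decile scores across the population.

    *values* is indexed by accession id.  Rank 1 is the least tolerant unit
    (lowest value when ``direction='higher_is_tolerant'``, highest when
    ``'lower_is_tolerant'``); score = 1 + floor(10 * (rank-1) / n).  Ties
    are broken by accession id for determinism.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    values = values.astype(float)
    if values.isna().any():
        raise ComputationError("cannot score undefined index values")
    if values.nunique() < 2:
        raise ComputationError("degenerate_population: all index values equal")
    n = len(values)
    ascending = direction == "higher_is_tolerant"
    order = values.sort_index().sort_values(ascending=ascending, kind="stable")
    ranks = pd.Series(np.arange(1, n + 1), index=order.index)
    scores = 1 + np.floor(10 * (ranks - 1) / n).astype(int)
    return scores.reindex(values.index)


def assign_fernandez_group(rci: float, pci: float,
                           rci_threshold: float, pci_threshold: float) -> str:
    """Fernandez group from resilience/production scores vs thresholds."""
    r_hi, p_hi = rci >= rci_threshold, pci >= pci_threshold
    if r_hi and p_hi:
        return "A"
    if p_hi:
        return "B"
    if r_hi:
        return "C"
    return "D"


def _paired_replicates(biomass: pd.DataFrame) -> pd.DataFrame:
    """Wide frame of paired primed/non-primed biomass per accession x replicate.

    Pairs whose non-primed plant yielded no biomass cannot form a
    susceptibility ratio and are dropped (logged), mirroring how a dead or
    unharvestable control plant would be handled.
    """
    wide = biomass.pivot_table(index=["accession_id", "replicate"],
                               columns="treatment", values="dry_weight_g",
                               aggfunc="mean")
    wide = wide.dropna(subset=["primed", "non_primed"])
    bad = wide["non_primed"] <= 0
    if bad.any():
        logging.getLogger(__name__).warning(
            "dropped %d replicate pairs with zero non-primed biomass",
            int(bad.sum()))
    return wide[~bad].reset_index()


def score_panel(biomass: pd.DataFrame, mode: str = "accession") -> pd.DataFrame:
    """SSI, GMP, RCI, PCI and Fernandez group for a biomass table.

    *biomass* is long-format (accession_id, treatment, replicate,
    dry_weight_g).  ``mode='accession'`` scores accession-mean indices;
    ``mode='replicate'`` scores each paired replicate across the population
    and averages the per-replicate scores.  Group thresholds are the
    population medians of RCI and PCI.
    """
    if mode not in ("accession", "replicate"):
        raise ValueError(f"unknown scoring mode {mode!r}")
    means = biomass.pivot_table(index="accession_id", columns="treatment",
                                values="dry_weight_g", aggfunc="mean")
    if "primed" not in means or "non_primed" not in means:
        raise ComputationError("biomass table must contain both treatments")
    means = means.dropna(subset=["primed", "non_primed"])
    zero_ctrl = means["non_primed"] <= 0
    if zero_ctrl.any():
        logging.getLogger(__name__).warning(
            "dropped %d accessions with zero mean non-primed biomass",
            int(zero_ctrl.sum()))
        means = means[~zero_ctrl]
    ybar_pr = float(means["primed"].mean())
    ybar_npr = float(means["non_primed"].mean())

    out = pd.DataFrame(index=means.index)
    out["SSI"] = [ssi(r["primed"], r["non_primed"], ybar_pr, ybar_npr)
                  for _, r in means.iterrows()]
    out["GMP"] = [gmp(r["primed"], r["non_primed"]) for _, r in means.iterrows()]

    if mode == "accession":
        out["RCI"] = score_index(out["SSI"], "lower_is_tolerant").astype(float)
        out["PCI"] = score_index(out["GMP"], "higher_is_tolerant").astype(float)
    else:
        pairs = _paired_replicates(biomass)
        pairs["ssi"] = [ssi(r["primed"], r["non_primed"], ybar_pr, ybar_npr)
                        for _, r in pairs.iterrows()]
        pairs["gmp"] = [gmp(r["primed"], r["non_primed"])
                        for _, r in pairs.iterrows()]
        rci_scores, pci_scores = [], []
        for _, grp in pairs.groupby("replicate"):
            s = grp.set_index("accession_id")
            rci_scores.append(score_index(s["ssi"], "lower_is_tolerant"))
            pci_scores.append(score_index(s["gmp"], "higher_is_tolerant"))
        out["RCI"] = pd.concat(rci_scores, axis=1).mean(axis=1)
        out["PCI"] = pd.concat(pci_scores, axis=1).mean(axis=1)

    rci_thr = float(out["RCI"].median())
    pci_thr = float(out["PCI"].median())
    out["group"] = [assign_fernandez_group(r, p, rci_thr, pci_thr)
                    for r, p in zip(out["RCI"], out["PCI"])]
    return out.reset_index()
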