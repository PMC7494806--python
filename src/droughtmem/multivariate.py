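"""Population structure: correlations, standardized PCA and Ward clustering.

The feature matrix holds one row per accession and the six analysis
variables: the four stress-memory indices (stm_s, stm_fa, stm_dt,
stm_delta) and the two tolerance scores (RCI, PCI).  Rows with undefined
cells are excluded listwise (logged).  PCA is an eigen-decomposition of the
correlation matrix of z-standardized variables, so eigenvalues sum to the
number of variables; clustering is agglomerative with Ward linkage on the
scores of the leading components (those covering a configurable share of
the total variance), cut at k groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from ._errors import ComputationError
from .tolerance import assign_fernandez_group

logger = logging.getLogger(__name__)

FEATURES = ("stm_s", "stm_fa", "stm_dt", "stm_delta", "RCI", "PCI")


def build_feature_matrix(profiles: pd.DataFrame,
                         scores: pd.DataFrame) -> pd.DataFrame:
    """Join STM profiles and tolerance scores; drop incomplete rows listwise."""
    df = (profiles[["accession_id", "stm_s", "stm_fa", "stm_dt", "stm_delta"]]
          .merge(scores[["accession_id", "RCI", "PCI"]], on="accession_id")
          .set_index("accession_id"))
    complete = df.dropna()
    dropped = len(df) - len(complete)
    if dropped:
        logger.info("excluded %d accessions with undefined features "
                    "(listwise deletion)", dropped)
    if len(complete) < 3:
        raise ComputationError("fewer than 3 complete accessions for "
                               "multivariate analysis")
    return complete


def correlation_matrix(features: pd.DataFrame) -> tuple[pd.DataFrame,
                                                        pd.DataFrame,
                                                        pd.DataFrame]:
    """Pairwise Pearson r with two-sided significance stars.

    Returns (r, p, stars); stars are '**' for p < 0.01, '*' for p < 0.05,
    '' otherwise.  Constant columns yield NaN correlations (flagged NA).
    """
    cols = list(features.columns)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if j <= i:
                continue
            pair = features[[a, b]].dropna()
            if len(pair) < 3:
                raise ComputationError(f"fewer than 3 complete pairs for "
                                       f"({a}, {b})")
            if pair[a].nunique() < 2 or pair[b].nunique() < 2:
                logger.warning("constant column in pair (%s, %s); r undefined",
                               a, b)
                rij, pij = np.nan, np.nan
            else:
                res = stats.pearsonr(pair[a], pair[b])
                rij, pij = float(res.statistic), float(res.pvalue)
            r.loc[a, b] = r.loc[b, a] = rij
            p.loc[a, b] = p.loc[b, a] = pij
    stars = p.map(lambda v: "" if np.isnan(v) else
                  ("**" if v < 0.01 else "*" if v < 0.05 else ""))
    np.fill_diagonal(stars.values, "")
    return r, p, stars


@dataclass
class PCAResult:
    loadings: pd.DataFrame  # variables x components
    eigenvalues: np.ndarray
    cumulative_variance: np.ndarray  # fraction of total variance
    scores: pd.DataFrame  # observations x components


def pca(features: pd.DataFrame) -> PCAResult:
    """Standardized PCA: eigen-decomposition of the correlation matrix.

    Components are ordered by decreasing eigenvalue and signed so that each
    component's largest-magnitude loading is positive.  Rank-deficient
    input proceeds with (near-)zero eigenvalues flagged in the log.
    """
    X = features.dropna().astype(float)
    if len(X) < 3:
        raise ComputationError("PCA needs >= 3 complete rows")
    Z = (X - X.mean()) / X.std(ddof=1)
    corr = np.corrcoef(Z.to_numpy(), rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)  # eigh round-off can dip below zero
    if np.any(evals < 1e-10):
        logger.warning("rank-deficient feature matrix: %d zero eigenvalues",
                       int(np.sum(evals < 1e-10)))
    for c in range(evecs.shape[1]):
        if evecs[np.argmax(np.abs(evecs[:, c])), c] < 0:
            evecs[:, c] = -evecs[:, c]
    comp = [f"PC{i + 1}" for i in range(len(evals))]
    loadings = pd.DataFrame(evecs, index=X.columns, columns=comp)
    scores = pd.DataFrame(Z.to_numpy() @ evecs, index=X.index, columns=comp)
    cumvar = np.cumsum(evals) / evals.sum()
    return PCAResult(loadings=loadings, eigenvalues=evals,
                     cumulative_variance=cumvar, scores=scores)


@dataclass
class ClusterResult:
    labels: pd.Series  # cluster id (1..k) per accession
    k: int
    linkage: np.ndarray
    n_components_used: int


def ward_cluster(scores: pd.DataFrame, k: int,
                 order_by: pd.DataFrame | None = None) -> ClusterResult:
    """Ward-linkage agglomerative clustering of component scores, cut at *k*.

    Labels are renumbered 1..k by descending cluster mean of PCI then RCI
    (when *order_by* provides those columns) so that reported cluster ids
    are stable across row orderings.
    """
    n = len(scores)
    if k < 1:
        raise ComputationError("k must be >= 1")
    if k > n:
        raise ComputationError(f"k={k} exceeds number of observations n={n}")
    Z = hierarchy.linkage(scores.to_numpy(), method="ward")
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    labels = pd.Series(raw, index=scores.index, name="cluster")

    if order_by is not None and {"PCI", "RCI"} <= set(order_by.columns):
        key = order_by.loc[scores.index].groupby(labels)[["PCI", "RCI"]].mean()
        order = key.sort_values(["PCI", "RCI"], ascending=False).index
    else:
        sizes = labels.value_counts()
        order = sizes.sort_values(ascending=False).index
    remap = {old: new for new, old in enumerate(order, start=1)}
    labels = labels.map(remap)
    return ClusterResult(labels=labels, k=int(labels.nunique()), linkage=Z,
                         n_components_used=scores.shape[1])


def select_components(res: PCAResult, min_cumvar: float = 0.70) -> pd.DataFrame:
    """Scores of the leading components covering >= *min_cumvar* of variance."""
    m = int(np.searchsorted(res.cumulative_variance, min_cumvar) + 1)
    m = min(m, res.scores.shape[1])
    return res.scores.iloc[:, :m]


def cluster_summary(result: ClusterResult, features: pd.DataFrame,
                    occurrence_flags: pd.Series | None = None) -> pd.DataFrame:
    """Per-cluster mean +/- standard error of every feature column.

    *features* may include biomass columns (Y_npr, Y_pr) beyond the six
    analysis variables.  Standard error is sd/sqrt(n), undefined (NaN) for
    singleton clusters.  When *occurrence_flags* (boolean per accession) is
    given, the fraction of members with discrimination-memory occurrence is
    added.  A Fernandez group per cluster is derived from cluster-mean
    RCI/PCI against the population medians.
    """
    df = features.loc[result.labels.index].copy()
    df["cluster"] = result.labels
    rows = []
    rci_thr = float(df["RCI"].median()) if "RCI" in df else np.nan
    pci_thr = float(df["PCI"].median()) if "PCI" in df else np.nan
    for cid, grp in df.groupby("cluster"):
        row: dict = {"cluster": cid, "n": len(grp)}
        for col in features.columns:
            vals = grp[col].dropna()
            row[f"{col}_mean"] = float(vals.mean()) if len(vals) else np.nan
            row[f"{col}_se"] = (float(vals.std(ddof=1) / np.sqrt(len(vals)))
                                if len(vals) > 1 else np.nan)
        if occurrence_flags is not None:
            flags = occurrence_flags.reindex(grp.index).dropna()
            row["stm_delta_occurrence_frac"] = (
                float(flags.astype(bool).mean()) if len(flags) else np.nan)
        if "RCI" in df and "PCI" in df:
            row["group"] = assign_fernandez_group(
                row["RCI_mean"], row["PCI_mean"], rci_thr, pci_thr)
        rows.append(row)
    return pd.DataFrame(rows).sort_values("cluster").reset_index(drop=True)
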