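"""End-to-end orchestration shared by the command-line interface and scripts."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import multivariate, stm, tolerance, traits
from ._errors import SchemaError
from .config import SimConfig
from .simulate import MEASUREMENT_TABLES, generate_experiment


@dataclass
class AnalysisOptions:
    k_clusters: int = 3
    scoring_mode: str = "accession"  # or "replicate"
    occurrence_denominator: str = "all"  # or "defined"
    cluster_min_cumvar: float = 0.70
    cluster_on: str = "pca"  # or "features"


@dataclass
class AnalysisResult:
    trait_summary: pd.DataFrame
    stm_profiles: pd.DataFrame
    occurrence: dict
    tolerance_scores: pd.DataFrame
    features: pd.DataFrame
    correlations: pd.DataFrame
    correlation_stars: pd.DataFrame
    pca_loadings: pd.DataFrame
    eigenvalues: np.ndarray
    cumulative_variance: np.ndarray
    clusters: pd.Series
    cluster_table: pd.DataFrame
    options: AnalysisOptions = field(default_factory=AnalysisOptions)

    def tables(self) -> dict[str, pd.DataFrame]:
        eig = pd.DataFrame({
            "component": [f"PC{i+1}" for i in range(len(self.eigenvalues))],
            "eigenvalue": self.eigenvalues,
            "cumulative_variance_pct": 100 * self.cumulative_variance,
        })
        corr = self.correlations.round(6).astype(str) + self.correlation_stars
        return {
            "trait_summary": self.trait_summary,
            "stm_profiles": self.stm_profiles,
            "tolerance_scores": self.tolerance_scores,
            "correlations": corr.reset_index(names="variable"),
            "pca_loadings": self.pca_loadings.reset_index(names="variable"),
            "pca_eigenvalues": eig,
            "cluster_assignments": self.clusters.rename("cluster")
                                       .rename_axis("accession_id")
                                       .reset_index(),
            "cluster_summary": self.cluster_table,
        }


def read_tables(data_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Load the long-format measurement CSVs emitted by the simulator."""
    data_dir = Path(data_dir)
    tables = {}
    for name in MEASUREMENT_TABLES:
        path = data_dir / f"{name}.csv"
        if not path.exists():
            raise SchemaError(f"required table {name!r} not found at {path}")
        tables[name] = pd.read_csv(path)
    return tables


def run_analysis(tables: dict[str, pd.DataFrame],
                 options: AnalysisOptions | None = None) -> AnalysisResult:
    """Traits -> memory indices -> tolerance scores -> multivariate structure."""
    opts = options or AnalysisOptions()
    summary = traits.summarize(tables)
    profiles = stm.compute_profiles(summary)
    n_panel = summary["accession_id"].nunique()
    occurrence = stm.occurrence_summary(profiles, n_total=n_panel,
                                       denominator=opts.occurrence_denominator)
    scores = tolerance.score_panel(tables["biomass"], mode=opts.scoring_mode)

    features = multivariate.build_feature_matrix(profiles, scores)
    r, _, stars = multivariate.correlation_matrix(features)
    pca_res = multivariate.pca(features)
    basis = (multivariate.select_components(pca_res, opts.cluster_min_cumvar)
             if opts.cluster_on == "pca"
             else (features - features.mean()) / features.std(ddof=1))
    clus = multivariate.ward_cluster(basis, opts.k_clusters, order_by=features)

    biomass_means = tables["biomass"].pivot_table(
        index="accession_id", columns="treatment", values="dry_weight_g",
        aggfunc="mean").rename(columns={"primed": "Y_pr",
                                        "non_primed": "Y_npr"})
    full = features.join(biomass_means[["Y_npr", "Y_pr"]])
    flags = profiles.set_index("accession_id")["flag_delta"]
    table4 = multivariate.cluster_summary(clus, full, occurrence_flags=flags)

    return AnalysisResult(
        trait_summary=summary, stm_profiles=profiles, occurrence=occurrence,
        tolerance_scores=scores, features=features, correlations=r,
        correlation_stars=stars, pca_loadings=pca_res.loadings,
        eigenvalues=pca_res.eigenvalues,
        cumulative_variance=pca_res.cumulative_variance,
        clusters=clus.labels, cluster_table=table4, options=opts)


def recovery_report(config: SimConfig, n_seeds: int,
                    base_seed: int = 0) -> pd.DataFrame:
    """Bias and MAE of each estimated memory index vs ground truth over seeds."""
    errors: dict[str, list] = {k: [] for k in stm.INDEX_NAMES}
    for s in range(n_seeds):
        cfg = SimConfig.from_dict({**config.to_dict(),
                                   "seed": (base_seed + s) % (2**31)})
        exp = generate_experiment(cfg)
        summary = traits.summarize(exp.tables)
        profiles = stm.compute_profiles(summary).set_index("accession_id")
        truth = exp.truth.set_index("accession_id")
        for name in stm.INDEX_NAMES:
            err = (profiles[name] - truth[f"true_{name}"]).dropna()
            errors[name].extend(err.tolist())
    rows = []
    for name, errs in errors.items():
        arr = np.asarray(errs)
        rows.append({"index": name, "n": len(arr),
                     "bias": float(arr.mean()) if len(arr) else np.nan,
                     "mae": float(np.abs(arr).mean()) if len(arr) else np.nan,
                     "rmse": float(np.sqrt((arr ** 2).mean()))
                             if len(arr) else np.nan})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# run manifests


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(out_dir: str | Path, *, config: dict | None, seed: int | None,
                   inputs: list[Path], outputs: list[Path],
                   policies: dict) -> Path:
    """Write a reproducibility manifest tying outputs to config and inputs."""
    out_dir = Path(out_dir)
    config_json = json.dumps(config, sort_keys=True) if config else ""
    manifest = {
        "config_hash": hashlib.sha256(config_json.encode()).hexdigest(),
        "seed": seed,
        "policies": policies,
        "inputs": {str(p): file_digest(p) for p in inputs},
        "outputs": {str(p): file_digest(p) for p in outputs},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
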