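"""Synthetic priming-experiment generator with known ground truth.

Emulates a greenhouse pot experiment in which every accession is grown under
two watering treatments — full irrigation throughout (``non_primed``) and a
priming regime of repeated total water restrictions followed by recovery
(``primed``) — with four replicate plants per treatment.  Repeated
measurements are produced for leaf chlorophyll (SPAD), foliar area,
radiometric leaf temperature with concurrent air temperature, composite-leaf
carbon isotope signatures, and end-of-experiment dry biomass.

Accession-level stress-memory effects are embedded with known values so the
whole downstream index pipeline can be validated by parameter recovery:

* additive effect on the post-peak senescence slope (SPAD units/day),
* multiplicative effects on maximum foliar area, minimum leaf-minus-air
  temperature, and maximum 13C discrimination.

Trajectory shapes are deliberately simple — the summary statistics consumed
downstream (slope, max, min, max) are all that matters: SPAD rises
logistically to an accession peak at flowering onset then declines linearly;
foliar area grows logistically toward its maximum with transient
proportional dips while primed plants are under restriction; leaf-minus-air
temperature follows a seasonal bell whose minimum is scaled per treatment;
isotope discrimination follows per-event means scaled per treatment.
Replicates within an accession x treatment share the biological trajectory
and differ only through measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .config import TREATMENTS, SimConfig
from .traits import DELTA_ATM_PERMIL, delta13C_discrimination

# species composition of the study panel (counts over 59 accessions)
_SPECIES_POOL = (
    ["I. trifida"] * 16 + ["I. triloba"] * 8 + ["I. ramosissima"] * 8
    + ["I. australis"] * 5 + ["I. grandifolia"] * 5 + ["I. batatas"] * 6
    + ["I. splendor-sylvae"] * 3 + ["I. cynanchifolia"] * 3
    + ["I. leucantha"] * 2 + ["I. tiliacea"] * 2 + ["I. cordatotriloba"] * 1
)

MEASUREMENT_TABLES = ("spad", "foliar_area", "leaf_temperature",
                      "air_temperature", "isotopes", "biomass")


@dataclass
class Experiment:
    """Generated dataset: long measurement tables, accession table, ground truth."""

    tables: dict[str, pd.DataFrame]
    accessions: pd.DataFrame
    truth: pd.DataFrame
    config: SimConfig

    def write(self, outdir: str | Path) -> list[Path]:
        """Write all tables, the ground truth and the echoed config; return paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for name, df in self.tables.items():
            p = outdir / f"{name}.csv"
            df.to_csv(p, index=False)
            written.append(p)
        p = outdir / "accessions.csv"
        self.accessions.to_csv(p, index=False)
        written.append(p)
        p = outdir / "ground_truth.csv"
        self.truth.to_csv(p, index=False)
        written.append(p)
        p = outdir / "sim_config.json"
        p.write_text(self.config.to_json() + "\n")
        written.append(p)
        return written


def _event_days(lo: int, hi: int, n: int, force: int | None = None) -> np.ndarray:
    """n distinct integer measurement days in [lo, hi], optionally forcing one day."""
    days = np.unique(np.round(np.linspace(lo, hi, n)).astype(int))
    while len(days) < n:  # collisions after rounding: densify
        extra = np.setdiff1d(np.arange(lo, hi + 1), days)
        if len(extra) == 0:
            break
        days = np.unique(np.concatenate([days, extra[: n - len(days)]]))
    if force is not None and force not in days:
        days = days.copy()
        days[np.argmin(np.abs(days - force))] = force
        days = np.unique(days)
    return days


def _logistic(t: np.ndarray, mid: float, tau: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(np.asarray(t, dtype=float) - mid) / tau))


def _invert_discrimination(delta_cap: float) -> float:
    """delta13C (permil) of plant tissue whose discrimination equals delta_cap."""
    return (DELTA_ATM_PERMIL - delta_cap) / (1.0 + delta_cap / 1000.0)


def generate_experiment(config: SimConfig) -> Experiment:
    """Simulate a full priming experiment under *config*.

    Raises :class:`~droughtmem._errors.ConfigError` on invalid configuration.
    Fixed seed reproduces the output exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sched = config.schedule
    harvest = sched.harvest_day
    n_acc, n_rep = config.n_accessions, config.n_replicates

    acc_ids = [f"SIM-{i + 1:03d}" for i in range(n_acc)]
    species = [_SPECIES_POOL[i % len(_SPECIES_POOL)] for i in range(n_acc)]
    acc_species = dict(zip(acc_ids, species))

    # ---- accession-level biological parameters ---------------------------
    peak = rng.normal(config.spad_peak_mean, config.spad_peak_sd, n_acc)
    peak = np.clip(peak, 15.0, 80.0)
    slope_npr = rng.normal(config.senescence_slope_mean,
                           config.senescence_slope_sd, n_acc)
    slope_npr = np.minimum(slope_npr, -0.02)
    mem_s = rng.normal(config.memory_effect_S_mean, config.memory_effect_S_sd, n_acc)
    # the primed slope must stay a decline, or 'peak to harvest' is undefined
    slope_pr = np.minimum(slope_npr + mem_s, -0.02)
    mem_s = slope_pr - slope_npr  # realised effect recorded as truth

    fa_max_npr = np.clip(rng.normal(config.fa_max_mean, config.fa_max_sd, n_acc),
                         50.0, None)
    ratio_fa = np.clip(rng.normal(config.memory_ratio_FA_mean,
                                  config.memory_ratio_FA_sd, n_acc), 0.05, None)
    dt_min_npr = np.minimum(rng.normal(config.dt_min_mean, config.dt_min_sd, n_acc),
                            -0.5)
    ratio_dt = np.clip(rng.normal(config.memory_ratio_dT_mean,
                                  config.memory_ratio_dT_sd, n_acc), 0.05, None)
    delta_p = np.minimum(rng.normal(config.delta13c_leaf_mean,
                                    config.delta13c_leaf_sd, n_acc), -10.0)
    disc_max_npr = np.array([delta13C_discrimination(d) for d in delta_p])
    ratio_delta = np.clip(rng.normal(config.memory_ratio_delta_mean,
                                     config.memory_ratio_delta_sd, n_acc), 0.5, None)
    # lognormal keeps control biomass strictly positive: a panel with
    # near-zero control plants would produce unbounded susceptibility indices
    cv2 = (config.biomass_sd / config.biomass_mean) ** 2
    sigma = np.sqrt(np.log1p(cv2))
    mu = np.log(config.biomass_mean) - 0.5 * sigma ** 2
    y_npr = rng.lognormal(mu, sigma, n_acc)
    reduction = np.clip(rng.normal(config.drought_reduction_mean,
                                   config.drought_reduction_sd, n_acc), 0.0, 0.95)
    y_pr = y_npr * (1.0 - reduction)

    noise = config.measurement_noise

    # ---- measurement event grids -----------------------------------------
    spad_days = _event_days(max(7, sched.start_day - 32), harvest,
                            config.n_spad_events, force=sched.start_day)
    windows = sched.restriction_windows()
    dt_min_day = windows[-1][1]  # minimum reached at end of the last restriction
    temp_days = _event_days(max(7, sched.start_day - 10), harvest,
                            config.n_temp_events, force=dt_min_day)
    rec_ends = sched.recovery_ends()
    if config.n_isotope_events <= len(rec_ends):
        iso_days = rec_ends[-config.n_isotope_events:]
    else:
        iso_days = sorted(set(np.round(np.linspace(
            rec_ends[0], rec_ends[-1], config.n_isotope_events)).astype(int)))
    fa_days = [max(7, sched.start_day - 7)]
    for (ws, we) in windows:
        fa_days += [we, we + sched.recovery_length]

    def in_restriction(t: int) -> bool:
        return any(ws < t <= we for ws, we in windows)

    # ---- long tables ------------------------------------------------------
    spad_rows, fa_rows, leaf_rows, iso_rows, bio_rows = [], [], [], [], []

    air_temp = 28.0 + rng.normal(0.0, 2.0, len(temp_days))
    air_df = pd.DataFrame({"DAT": temp_days, "air_temp_c": air_temp})

    spad_t = np.asarray(spad_days, dtype=float)
    rise = _logistic(spad_t, sched.start_day - 18.0, 6.0)
    rise /= _logistic(np.array([float(sched.start_day)]), sched.start_day - 18.0, 6.0)[0]
    dt_w = 0.25 + 0.75 * np.exp(-(((temp_days - dt_min_day) / 28.0) ** 2))
    fa_t = np.asarray(fa_days, dtype=float)
    fa_growth = _logistic(fa_t, float(sched.start_day), 14.0)
    iso_u = np.linspace(0.93, 1.0, len(iso_days))

    for i, acc in enumerate(acc_ids):
        sp = acc_species[acc]
        for trt in TREATMENTS:
            primed = trt == "primed"
            slope = slope_pr[i] if primed else slope_npr[i]
            fa_max = fa_max_npr[i] * (ratio_fa[i] if primed else 1.0)
            dt_curve = dt_min_npr[i] * (ratio_dt[i] if primed else 1.0) * dt_w
            disc_curve = disc_max_npr[i] * (ratio_delta[i] if primed else 1.0) * iso_u

            spad_mean = np.where(
                spad_t <= sched.start_day,
                peak[i] * rise,
                peak[i] + slope * (spad_t - sched.start_day),
            )
            fa_mean = fa_max * fa_growth
            if primed:
                dip = np.array([0.7 if in_restriction(t) else 1.0 for t in fa_days])
                fa_mean = fa_mean * dip

            for rep in range(1, n_rep + 1):
                sv = spad_mean + rng.normal(0.0, noise.spad, len(spad_t))
                spad_rows += [(acc, sp, trt, rep, int(d), v)
                              for d, v in zip(spad_days, np.clip(sv, 0.0, 120.0))]
                fv = np.clip(fa_mean + rng.normal(0.0, noise.foliar_area, len(fa_t)),
                             0.0, None)
                fa_rows += [(acc, sp, trt, rep, int(d), v)
                            for d, v in zip(fa_days, fv)]
                lv = air_temp + dt_curve + rng.normal(0.0, noise.leaf_temp,
                                                      len(temp_days))
                leaf_rows += [(acc, sp, trt, rep, int(d), v)
                              for d, v in zip(temp_days, lv)]
                bio_rows.append((acc, trt, rep,
                                 max(0.0, (y_pr[i] if primed else y_npr[i])
                                     + rng.normal(0.0, noise.biomass))))

            # two composite leaf samples per accession x treatment x event
            for e, d in enumerate(iso_days):
                dp = _invert_discrimination(disc_curve[e])
                for samp in (1, 2):
                    iso_rows.append((acc, sp, trt, e + 1, int(d), samp,
                                     dp + rng.normal(0.0, noise.delta13c)))

    cols = ["accession_id", "species", "treatment", "replicate", "DAT", "value"]
    tables = {
        "spad": pd.DataFrame(spad_rows, columns=cols),
        "foliar_area": pd.DataFrame(fa_rows, columns=cols),
        "leaf_temperature": pd.DataFrame(leaf_rows, columns=cols),
        "air_temperature": air_df,
        "isotopes": pd.DataFrame(
            iso_rows, columns=["accession_id", "species", "treatment", "event",
                               "DAT", "sample", "delta13c_permil"]),
        "biomass": pd.DataFrame(
            bio_rows, columns=["accession_id", "treatment", "replicate",
                               "dry_weight_g"]),
    }
    accessions = pd.DataFrame({"accession_id": acc_ids, "species": species})
    truth = pd.DataFrame({
        "accession_id": acc_ids,
        "true_stm_s": mem_s,
        "true_stm_fa": ratio_fa,
        "true_stm_dt": ratio_dt,
        "true_stm_delta": ratio_delta,
        "true_y_pr": y_pr,
        "true_y_npr": y_npr,
    })
    return Experiment(tables=tables, accessions=accessions, truth=truth,
                      config=config)


def load_table1() -> pd.DataFrame:
    """Packaged metadata table of the 59-accession study panel."""
    with resources.files("droughtmem.data").joinpath(
            "table1_accessions.csv").open("r") as fh:
        return pd.read_csv(fh)


def write_fixture_table1(path: str | Path) -> Path:
    """Write the packaged 59-accession metadata table to *path*."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    load_table1().to_csv(path, index=False)
    return path
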