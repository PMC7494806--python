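"""Synthetic experiment generator: design counts, determinism, ground truth."""

import numpy as np
import pandas as pd
import pytest

from droughtmem._errors import ConfigError
from droughtmem.config import NoiseModel, PrimingSchedule, SimConfig
from droughtmem.pipeline import recovery_report
from droughtmem.simulate import generate_experiment, load_table1

ZERO = NoiseModel(0, 0, 0, 0, 0)


class TestSchedule:
    def test_default_timeline(self):
        s = PrimingSchedule()
        assert s.restriction_windows() == [(46, 54), (68, 79), (93, 107)]
        assert s.recovery_ends() == [68, 93, 121]
        assert s.harvest_day == 121

    def test_invariants_enforced(self):
        with pytest.raises(ConfigError, match="restriction_lengths"):
            PrimingSchedule(restriction_lengths=(8, 8, 14)).validate()
        with pytest.raises(ConfigError, match="recovery_length"):
            PrimingSchedule(recovery_length=0).validate()
        with pytest.raises(ConfigError, match="n_accessions"):
            SimConfig(n_accessions=0).validate()
        with pytest.raises(ConfigError, match="drought_reduction_mean"):
            SimConfig(drought_reduction_mean=1.0).validate()


class TestDesign:
    def test_study_design_row_counts(self, panel_exact):
        t = panel_exact.tables
        assert panel_exact.accessions.shape[0] == 59
        assert len(t["spad"]) == 59 * 2 * 4 * 17
        assert len(t["leaf_temperature"]) == 59 * 2 * 4 * 14
        assert len(t["biomass"]) == 59 * 2 * 4
        # two composite samples per accession x treatment x occasion
        assert len(t["isotopes"]) == 59 * 2 * 3 * 2
        assert len(t["air_temperature"]) == 14

    def test_every_plant_appears_in_all_plant_level_tables(self, panel_exact):
        t = panel_exact.tables
        def plants(df):
            return set(map(tuple, df[["accession_id", "treatment",
                                      "replicate"]].drop_duplicates().values))
        spad_plants = plants(t["spad"])
        assert plants(t["foliar_area"]) == spad_plants
        assert plants(t["leaf_temperature"]) == spad_plants
        assert plants(t["biomass"]) == spad_plants
        # isotopes exist only at accession x treatment x event level
        assert "replicate" not in t["isotopes"].columns

    def test_seed_determinism_byte_identical(self, tmp_path):
        cfg = SimConfig(n_accessions=5, seed=123)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_experiment(cfg).write(d1)
        generate_experiment(cfg).write(d2)
        for p1 in sorted(d1.iterdir()):
            assert p1.read_bytes() == (d2 / p1.name).read_bytes()

    def test_different_seed_differs(self):
        a = generate_experiment(SimConfig(n_accessions=5, seed=1))
        b = generate_experiment(SimConfig(n_accessions=5, seed=2))
        assert not a.tables["spad"]["value"].equals(b.tables["spad"]["value"])


class TestGroundTruth:
    def test_no_memory_no_noise_collapses_indices(self):
        cfg = SimConfig(n_accessions=6, seed=2, measurement_noise=ZERO,
                        memory_effect_S_mean=0.0, memory_effect_S_sd=0.0,
                        memory_ratio_FA_mean=1.0, memory_ratio_FA_sd=0.0,
                        memory_ratio_dT_mean=1.0, memory_ratio_dT_sd=0.0,
                        memory_ratio_delta_mean=1.0, memory_ratio_delta_sd=0.0)
        exp = generate_experiment(cfg)
        from droughtmem import stm, traits
        prof = stm.compute_profiles(traits.summarize(exp.tables))
        np.testing.assert_allclose(prof["stm_s"], 0.0, atol=1e-12)
        for name in ("stm_fa", "stm_dt", "stm_delta"):
            np.testing.assert_allclose(prof[name], 1.0, atol=1e-12)

    def test_truth_ratios_positive_one_row_per_accession(self, panel_exact):
        truth = panel_exact.truth
        assert truth["accession_id"].is_unique
        for col in ("true_stm_fa", "true_stm_dt", "true_stm_delta"):
            assert (truth[col] > 0).all()


def test_estimation_error_monotone_in_noise():
    """MAE of every memory index is non-decreasing in the noise level."""
    factors = [0.0, 0.5, 1.0, 2.0]
    n_seeds = 20
    base = SimConfig(n_accessions=10).to_dict()
    mae = {}
    for f in factors:
        cfg = SimConfig.from_dict({**base,
                                   "measurement_noise": NoiseModel().scaled(f)
                                   .__dict__})
        rep = recovery_report(cfg, n_seeds=n_seeds, base_seed=100)
        mae[f] = rep.set_index("index")["mae"]
    for name in ("stm_s", "stm_fa", "stm_dt", "stm_delta"):
        series = [mae[f][name] for f in factors]
        assert series[0] < 1e-12
        assert all(a <= b + 1e-12 for a, b in zip(series, series[1:])), \
            f"{name}: {series}"


class TestTable1Fixture:
    def test_panel_counts(self):
        df = load_table1()
        assert len(df) == 59
        assert (df["species"] == "I. trifida").sum() == 16
        assert (df["species"] == "I. ramosissima").sum() == 8
        assert df["accession_id"].is_unique
        assert set(df["group"]) <= set("ABCD")

    def test_reported_top_scorers_groups(self):
        df = load_table1().set_index("accession_id")
        assert df.loc["CIP 460116", "group"] == "C"
        assert df.loc["CIP 440166", "group"] == "B"
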