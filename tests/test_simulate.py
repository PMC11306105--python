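import io as _io

import numpy as np
import pytest

from lagshift.errors import ParameterError
from lagshift.expression import abundance_floor, de_filter, remove_rrna, tpm
from lagshift.io import read_plate_table
from lagshift.logistic import LogisticFit, doubling_time, lag_time, logistic
from lagshift.pipeline import analyze_plate
from lagshift.simulate import (
    ConditionSpec,
    SyntheticPlateConfig,
    lag_effect_via_n0,
    plate_frame_to_wide,
    simulate_feature_table,
    simulate_plate,
    standard_experiment,
)


def _fit(K, N0, r):
    return LogisticFit(K=K, N0=N0, r=r, sse=0.0, converged=True)


class TestSimulatePlate:
    def test_noiseless_limit_equals_logistic(self):
        cfg = SyntheticPlateConfig(
            conditions=(ConditionSpec("c", 0.5, 1e-4, 0.8, n_replicates=2),),
            noise_sd=0.0,
            background_level=0.0,
            calibration_factor=1.0,
            seed=0,
        )
        sim = simulate_plate(cfg)
        well = sim.frame[sim.frame["well"] == "A1"]
        expected = logistic(well["time_h"].to_numpy(), 0.5, 1e-4, 0.8)
        np.testing.assert_allclose(well["absorbance"].to_numpy(), expected, rtol=1e-12)

    def test_seed_determinism_bytes(self):
        cfg = standard_experiment({"dmsp": 1.0}, seed=9)
        a = simulate_plate(cfg).frame.to_csv(index=False)
        b = simulate_plate(cfg).frame.to_csv(index=False)
        assert a == b

    def test_different_seeds_differ(self):
        a = simulate_plate(standard_experiment({"d": 1.0}, seed=1)).frame
        b = simulate_plate(standard_experiment({"d": 1.0}, seed=2)).frame
        assert not np.allclose(a["absorbance"], b["absorbance"])

    def test_ground_truth_matches_closed_forms_exactly(self):
        cfg = standard_experiment({"dmsp": 1.0, "betaine": 2.5}, seed=0)
        sim = simulate_plate(cfg)
        for spec in cfg.conditions:
            fit = _fit(spec.K, spec.N0, spec.r)
            assert sim.truth.lag[spec.label] == lag_time(fit, cfg.lag_threshold)
            assert sim.truth.doubling[spec.label] == doubling_time(fit)
        assert sim.truth.delta_lag["dmsp"] == pytest.approx(1.0, abs=1e-12)
        assert sim.truth.delta_lag["betaine"] == pytest.approx(2.5, abs=1e-12)

    def test_wide_and_long_dialects_round_trip(self, tmp_path):
        sim = simulate_plate(standard_experiment({"dmsp": 1.0}, seed=4))
        long_path = tmp_path / "long.csv"
        wide_path = tmp_path / "wide.csv"
        sim.frame.to_csv(long_path, index=False)
        plate_frame_to_wide(sim.frame).to_csv(wide_path, index=False)
        from_long = read_plate_table(long_path, "long", sim.layout)
        from_wide = read_plate_table(wide_path, "wide", sim.layout)
        for a, b in zip(from_long, from_wide):
            assert a.well_id == b.well_id
            np.testing.assert_allclose(a.absorbance, b.absorbance, rtol=1e-12)


class TestLagEffectViaN0:
    def test_zero_target_is_identity(self):
        assert lag_effect_via_n0(1e-5, 0.0, 0.8, 0.5) == pytest.approx(1e-5, rel=1e-9)

    def test_round_trip_through_closed_form(self):
        n0 = lag_effect_via_n0(1e-4, 1.0, 0.8, 0.5, threshold=0.01)
        base = lag_time(_fit(0.5, 1e-4, 0.8), 0.01)
        shifted = lag_time(_fit(0.5, n0, 0.8), 0.01)
        assert base - shifted == pytest.approx(1.0, abs=1e-10)

    def test_doubling_time_essentially_unchanged(self):
        n0 = lag_effect_via_n0(1e-5, 2.0, 0.8, 0.5)
        d0 = doubling_time(_fit(0.5, 1e-5, 0.8))
        d1 = doubling_time(_fit(0.5, n0, 0.8))
        assert d1 == pytest.approx(d0, rel=1e-3)

    def test_infeasible_target_rejected(self):
        # shortening beyond the whole lag would need N0 >= threshold
        with pytest.raises(ParameterError):
            lag_effect_via_n0(1e-4, 50.0, 0.8, 0.5)

    def test_negative_target_prolongs_lag(self):
        n0 = lag_effect_via_n0(1e-4, -1.0, 0.8, 0.5)
        assert n0 < 1e-4


class TestEndToEndRecovery:
    def test_pipeline_recovers_injected_delta(self):
        hits = 0
        for seed in range(25):
            cfg = standard_experiment({"dmsp": 1.5}, seed=seed)
            sim = simulate_plate(cfg)
            _, deltas = analyze_plate(sim.frame, sim.layout, control="control", seed=seed)
            row = deltas.iloc[0]
            if abs(row["delta_lag_h"] - 1.5) <= 3 * row["sd_diff_h"]:
                hits += 1
        assert hits >= 22  # ~95 % coverage up to Monte-Carlo noise at n=25

    def test_time_shift_mode_shifts_the_lag(self):
        cfg = SyntheticPlateConfig(
            conditions=(
                ConditionSpec("control", 0.5, 1e-6, 0.8),
                ConditionSpec("late", 0.5, 1e-6, 0.8, time_shift=2.0),
            ),
            seed=0,
        )
        sim = simulate_plate(cfg)
        assert sim.truth.delta_lag["late"] == pytest.approx(-2.0)
        _, deltas = analyze_plate(sim.frame, sim.layout, control="control", seed=0)
        assert deltas.iloc[0]["delta_lag_h"] == pytest.approx(-2.0, abs=0.2)


class TestFeatureTableSimulation:
    def test_seed_determinism(self):
        a = simulate_feature_table(200, 4, seed=5).df
        b = simulate_feature_table(200, 4, seed=5).df
        assert a.equals(b)

    def test_null_de_fraction_recovers_empty_set(self):
        table = simulate_feature_table(300, 4, de_fraction=0.0, seed=1)
        out = de_filter(tpm(remove_rrna(table)))
        assert len(out) == 0
        assert not table.df["is_de_truth"].any()

    def test_filters_recover_exact_truth_set(self):
        table = simulate_feature_table(1000, 6, seed=2, n_groups=2)
        groups = table.df.attrs["sample_groups"]
        processed = tpm(remove_rrna(table))
        kept = abundance_floor(de_filter(processed), groups)
        truth = set(table.df.loc[table.df["is_de_truth"], "gene_id"])
        assert set(kept.gene_ids()) == truth
        assert len(truth) > 0

    def test_rrna_fraction_respected(self):
        table = simulate_feature_table(400, 3, rrna_fraction=0.1, seed=0)
        assert int(table.df["is_rrna"].sum()) == 40
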