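"""ΔK48 turnover statistics: cross-pair estimator, scaling, CHX analyses."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sizeflux.config import SimConfig
from sizeflux.simulate import simulate_chx_chase, simulate_snapshot
from sizeflux.staging import assign_stage, detect_thresholds
from sizeflux.turnover import (
    TurnoverError,
    TurnoverResult,
    chx_chase_slopes,
    chx_decomposition,
    delta_k48,
    g1s_deviation,
    marker_size_fit,
    scaling_analysis,
)


def wells_table(plus_values, minus_values, condition="control", cells_per_well=30):
    """Cells table with constant K48 per well (well-level oracle values)."""
    rows = []
    for arm, values in (("plus", plus_values), ("minus", minus_values)):
        for w, value in enumerate(values):
            wid = f"{condition}|{arm}|w{w}"
            for i in range(cells_per_well):
                rows.append(
                    {
                        "cell_id": f"{wid}:{i}",
                        "well_id": wid,
                        "condition": condition,
                        "fixation_time_h": 24.0,
                        "cfz_flag": arm == "plus",
                        "chx_flag": False,
                        "dna": 100.0,
                        "geminin": 3.0,
                        "size_se": 800.0,
                        "k48": float(value),
                    }
                )
    return pd.DataFrame(rows)


def make_result(condition, stage, plus, minus, sizes):
    plus = np.asarray(plus, dtype=float)
    minus = np.asarray(minus, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    return TurnoverResult(
        condition=condition,
        stage=stage,
        delta_k48=plus.mean() - minus.mean(),
        ci_low=np.nan,
        ci_high=np.nan,
        n_pairs=plus.size * minus.size,
        median_size=float(np.median(sizes)),
        wells_plus=plus,
        wells_minus=minus,
        sizes_plus=sizes,
        sizes_minus=sizes,
    )


class TestDeltaK48:
    def test_hand_computed_cross_pair_mean(self):
        cells = wells_table([130.0, 132.0, 128.0], [100.0, 101.0, 99.0])
        res = delta_k48(cells)[0]
        assert res.delta_k48 == pytest.approx(30.0)
        assert res.n_pairs == 9

    def test_identical_arms_give_zero_with_ci_spanning_zero(self):
        rng = np.random.default_rng(0)
        values = 100 + rng.normal(0, 1, 6)
        cells = wells_table(values[:3], values[3:])
        res = delta_k48(cells)[0]
        assert abs(res.delta_k48) < 2.0
        assert res.ci_low < 0 < res.ci_high

    def test_constant_background_cancels(self):
        cells = wells_table([130.0, 132.0, 128.0], [100.0, 101.0, 99.0])
        shifted = cells.copy()
        shifted["k48"] += 55.5
        assert delta_k48(shifted)[0].delta_k48 == pytest.approx(
            delta_k48(cells)[0].delta_k48
        )

    @settings(max_examples=30, deadline=None)
    @given(
        plus=st.lists(st.floats(1, 1e3), min_size=2, max_size=6),
        minus=st.lists(st.floats(1, 1e3), min_size=2, max_size=6),
    )
    def test_cross_pair_mean_equals_difference_of_arm_means(self, plus, minus):
        cells = wells_table(plus, minus, cells_per_well=3)
        res = delta_k48(cells)[0]
        assert res.delta_k48 == pytest.approx(
            np.mean(plus) - np.mean(minus), rel=1e-9, abs=1e-9
        )

    def test_single_pair_flags_undefined_ci(self):
        res = delta_k48(wells_table([130.0], [100.0]))[0]
        assert res.delta_k48 == pytest.approx(30.0)
        assert np.isnan(res.ci_low) and np.isnan(res.ci_high)

    def test_mixed_conditions_rejected(self):
        a = wells_table([130.0], [100.0], condition="control")
        b = wells_table([130.0], [100.0], condition="CDK2i")
        with pytest.raises(TurnoverError, match="single condition"):
            delta_k48(pd.concat([a, b], ignore_index=True))

    def test_missing_arm_rejected(self):
        cells = wells_table([130.0, 131.0], [])
        with pytest.raises(TurnoverError, match="CFZ arm"):
            delta_k48(cells)

    def test_planted_flux_recovered_within_ci(self, k48_pair):
        res = delta_k48(k48_pair, centre="mean")[0]
        truth = k48_pair.loc[k48_pair["cfz_flag"], "true_cfz_excess"].mean()
        assert res.ci_low <= truth <= res.ci_high


class TestScalingAnalysis:
    def test_proportional_null_gives_unit_excess(self):
        ctrl = make_result("control", "G1", [110.0] * 3, [100.0] * 3, [800.0] * 6)
        pert = make_result("x", "G1", [115.0] * 3, [100.0] * 3, [1200.0] * 6)
        fit = scaling_analysis([ctrl], [pert], n_boot=50)
        assert fit.fold_delta == pytest.approx(1.5)
        assert fit.fold_size == pytest.approx(1.5)
        assert fit.excess_ratio == pytest.approx(1.0)

    def test_reported_fold_changes_reproduce_excess_ratio(self):
        # +30% ΔK48 at +3.4% size: excess ratio ~ 1.257
        ctrl = make_result("control", "G1", [20.0] * 3, [10.0] * 3, [1000.0] * 6)
        pert = make_result("x", "G1", [23.0] * 3, [10.0] * 3, [1034.0] * 6)
        fit = scaling_analysis([ctrl], [pert], n_boot=50)
        assert fit.excess_ratio == pytest.approx(1.30 / 1.034, rel=1e-9)

    def test_nonpositive_fold_rejected(self):
        ctrl = make_result("control", "G1", [10.0] * 3, [20.0] * 3, [800.0] * 6)
        pert = make_result("x", "G1", [15.0] * 3, [10.0] * 3, [800.0] * 6)
        with pytest.raises(TurnoverError, match="non-positive"):
            scaling_analysis([ctrl], [pert], n_boot=10)

    def test_no_shared_stage_rejected(self):
        ctrl = make_result("control", "G1", [11.0] * 3, [10.0] * 3, [800.0] * 6)
        pert = make_result("x", "S", [11.0] * 3, [10.0] * 3, [800.0] * 6)
        with pytest.raises(TurnoverError, match="matching stages"):
            scaling_analysis([ctrl], [pert])


class TestChxDecomposition:
    def test_equal_deltas_mean_no_nascent_share(self):
        a = make_result("control", "all", [20.0] * 3, [10.0] * 3, [800.0] * 6)
        b = make_result("control", "all", [20.0] * 3, [10.0] * 3, [800.0] * 6)
        out = chx_decomposition(a, b)
        assert out["nascent_share"] == pytest.approx(0.0)

    def test_fully_chx_sensitive_flux_is_all_nascent(self):
        a = make_result("control", "all", [20.0] * 3, [10.0] * 3, [800.0] * 6)
        b = make_result("control", "all", [10.0] * 3, [10.0] * 3, [800.0] * 6)
        assert chx_decomposition(a, b)["nascent_share"] == pytest.approx(1.0)

    def test_overshoot_clipped_and_flagged(self):
        a = make_result("control", "all", [20.0] * 3, [10.0] * 3, [800.0] * 6)
        b = make_result("control", "all", [25.0] * 3, [10.0] * 3, [800.0] * 6)
        out = chx_decomposition(a, b)
        assert out["nascent_share"] == 0.0
        assert out["clipped"]

    def test_nonpositive_reference_flagged_undefined(self):
        a = make_result("control", "all", [10.0] * 3, [10.0] * 3, [800.0] * 6)
        b = make_result("control", "all", [9.0] * 3, [10.0] * 3, [800.0] * 6)
        assert not chx_decomposition(a, b)["defined"]

    def test_planted_nascent_fraction_recovered(self, k48_pair_cfg, k48_pair):
        cfg = k48_pair_cfg
        chx = pd.concat(
            [
                simulate_snapshot(cfg, "control", 24.0, cfz=False, chx=True),
                simulate_snapshot(cfg, "control", 24.0, cfz=True, chx=True),
            ],
            ignore_index=True,
        )
        out = chx_decomposition(
            delta_k48(k48_pair, centre="mean")[0], delta_k48(chx, centre="mean")[0]
        )
        # in the untreated arm growth and division dilution balance (steady
        # state), while the CHX-arrested arm shrinks slightly by residual
        # degradation over the window: a small predictable drift
        d_chx = cfg.basal_degradation_per_mass * (1 - cfg.nascent_fraction)
        window = cfg.chx_block_h - 0.5 * cfg.cfz_block_min / 60.0
        drift = np.exp(-d_chx * window * (1 + cfg.compensation_exponent))
        expected = 1.0 - (1.0 - cfg.nascent_fraction) * drift
        assert out["nascent_share"] == pytest.approx(expected, abs=0.05)
        assert out["nascent_share"] == pytest.approx(cfg.nascent_fraction, abs=0.1)


class TestChxChase:
    @staticmethod
    def synthetic_chase(decay_small, decay_large, times=(0.0, 1.5, 3.0, 6.0, 9.0)):
        rng = np.random.default_rng(1)
        rows = []
        for t in times:
            small = 500 * np.exp(-decay_small * t) * (1 + rng.normal(0, 0.01, 300))
            large = 1500 * np.exp(-decay_large * t) * (1 + rng.normal(0, 0.01, 300))
            sizes = np.concatenate([small, large, np.full(300, 900.0)])
            for i, s in enumerate(sizes):
                rows.append(
                    {"fixation_time_h": t, "size_se": s, "stage": "G1",
                     "well_id": f"t{t}", "cell_id": f"t{t}:{i}"}
                )
        return pd.DataFrame(rows)

    def test_no_degradation_means_flat_slopes(self):
        out = chx_chase_slopes(self.synthetic_chase(0.0, 0.0))
        assert np.allclose(out["loss_rate_per_h"], 0.0, atol=2e-3)

    def test_planted_first_order_loss_recovered(self):
        out = chx_chase_slopes(self.synthetic_chase(0.02, 0.02))
        # fractional slope ~ -d for small d*t
        assert np.allclose(out["loss_rate_per_h"], -0.02, atol=3e-3)

    def test_needs_three_timepoints(self):
        with pytest.raises(TurnoverError, match="3 chase timepoints"):
            chx_chase_slopes(self.synthetic_chase(0.0, 0.0, times=(0.0, 3.0)))

    def test_large_cells_lose_mass_faster_under_compensation(self):
        cfg = SimConfig(
            seed=1, n_wells=9, cells_per_well=300, burn_in_h=20.0,
            compensation_exponent=1.5,
        )
        chase = simulate_chx_chase(cfg, "control", (0.0, 1.5, 3.0, 6.0, 9.0))
        th = detect_thresholds(chase[chase["fixation_time_h"] == 0.0])
        g1 = assign_stage(chase, th).query("stage == 'G1'")
        sl = chx_chase_slopes(g1, per_stage=False).set_index("size_class")
        obs = sl.loc["small", "loss_rate_per_h"] - sl.loc["large", "loss_rate_per_h"]
        assert obs > 0  # large cells lose a larger size fraction per hour
        # one-sided test by resampling replicate wells within timepoints
        rng = np.random.default_rng(0)
        wells = g1.groupby("fixation_time_h")["well_id"].unique()
        boot = []
        for _ in range(100):
            parts = []
            for t, ws in wells.items():
                for w in rng.choice(ws, ws.size, replace=True):
                    parts.append(g1[(g1["fixation_time_h"] == t) & (g1["well_id"] == w)])
            s = chx_chase_slopes(pd.concat(parts), per_stage=False).set_index("size_class")
            boot.append(
                s.loc["small", "loss_rate_per_h"] - s.loc["large", "loss_rate_per_h"]
            )
        p = (np.sum(np.asarray(boot) <= 0) + 1) / (len(boot) + 1)
        assert p < 0.05


class TestMarkerSizeFit:
    def test_exact_linear_marker(self, control_snapshot):
        cells = control_snapshot.copy()
        cells["marker"] = 2.0 * cells["size_se"]
        fit = marker_size_fit(cells, "marker")
        assert fit.slope == pytest.approx(2.0, rel=1e-9)
        assert fit.pearson_r == pytest.approx(1.0)

    def test_independent_marker_uncorrelated(self):
        rng = np.random.default_rng(0)
        cells = pd.DataFrame(
            {"size_se": rng.normal(800, 100, 10_000), "m": rng.normal(0, 1, 10_000)}
        )
        assert abs(marker_size_fit(cells, "m").pearson_r) < 0.05

    def test_synthesis_readout_correlation_in_reported_band(self, control_snapshot):
        fit = marker_size_fit(control_snapshot, "aha")
        assert 0.85 <= fit.pearson_r <= 0.95

    def test_degenerate_size_rejected(self):
        cells = pd.DataFrame({"size_se": np.full(200, 1.0), "m": np.arange(200.0)})
        with pytest.raises(TurnoverError, match="zero size variance"):
            marker_size_fit(cells, "m")


class TestG1sDeviation:
    def test_collinear_stages_give_zero_residual(self):
        results = []
        for stage, size in (("G1", 700.0), ("G1/S", 850.0), ("S", 900.0), ("G2+M", 1100.0)):
            delta = 0.01 * size  # G1/S sits exactly on the line
            results.append(
                make_result("control", stage, [10.0 + delta] * 3, [10.0] * 3, [size] * 6)
            )
        out = g1s_deviation(results, n_boot=100)
        assert out["residual"] == pytest.approx(0.0, abs=1e-9)

    def test_planted_hyperactivity_detected(self, k48_pair):
        staged = assign_stage(k48_pair, detect_thresholds(k48_pair))
        res = delta_k48(staged, per_stage=True, centre="mean")
        out = g1s_deviation(res, n_boot=500, rng=np.random.default_rng(0))
        assert out["residual"] > 0
        assert out["excludes_zero"]

    def test_requires_all_trend_stages(self):
        results = [
            make_result("control", s, [11.0] * 3, [10.0] * 3, [800.0] * 6)
            for s in ("G1", "S", "G1/S")
        ]
        with pytest.raises(TurnoverError, match="G2\\+M"):
            g1s_deviation(results)
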