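"""Cleavage quantification and rank statistics against independent oracles."""
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sstats

from mirproc.quant_stats import (compute_relative_efficiencies,
                                 conserved_vs_unique, correlation_report,
                                 mann_whitney_u, raw_cleavage_ratio,
                                 relative_efficiency, spearman,
                                 timecourse_summary)


class TestRatios:
    @pytest.mark.parametrize("prod,sub,expected", [
        (0, 5000, 0.0), (5000, 0, 1.0), (3000, 1000, 0.75),
    ])
    def test_raw_ratio(self, prod, sub, expected):
        assert raw_cleavage_ratio(prod, sub) == expected

    def test_empty_lane_is_error(self):
        with pytest.raises(ValueError, match="empty lane"):
            raw_cleavage_ratio(0, 0)

    @pytest.mark.parametrize("raw,ctrl,expected", [
        (0.6, 0.6, 100.0), (0.3, 0.6, 50.0), (0.0, 0.4, 0.0),
    ])
    def test_relative_efficiency(self, raw, ctrl, expected):
        assert relative_efficiency(raw, ctrl) == expected

    def test_zero_control_is_error(self):
        with pytest.raises(ValueError, match="control"):
            relative_efficiency(0.5, 0.0)

    def test_scale_invariance_of_lane_intensities(self):
        lanes = pd.DataFrame({
            "substrate_id": ["ctrl", "a", "b"],
            "enzyme": ["Drosha"] * 3, "batch": [0] * 3,
            "timepoint": [np.nan] * 3,
            "product_intensity": [500.0, 900.0, 100.0],
            "substrate_intensity": [500.0, 100.0, 900.0],
            "control_flag": [True, False, False],
        })
        base = compute_relative_efficiencies(lanes)
        scaled = lanes.copy()
        scaled[["product_intensity", "substrate_intensity"]] *= 37.5
        again = compute_relative_efficiencies(scaled)
        pd.testing.assert_frame_equal(base, again)

    def test_missing_control_is_error(self):
        lanes = pd.DataFrame({
            "substrate_id": ["a"], "enzyme": ["Drosha"], "batch": [0],
            "timepoint": [np.nan], "product_intensity": [1.0],
            "substrate_intensity": [1.0], "control_flag": [False]})
        with pytest.raises(ValueError, match="control"):
            compute_relative_efficiencies(lanes)


class TestSpearman:
    def test_monotone_and_antitone(self):
        assert spearman([1, 2, 3], [10, 20, 30]).rho == pytest.approx(1.0)
        assert spearman([1, 2, 3], [30, 20, 10]).rho == pytest.approx(-1.0)

    def test_tied_data_equals_pearson_on_midranks(self):
        x, y = [1, 2, 2, 3], [2, 1, 3, 4]
        res = spearman(x, y)
        oracle = sstats.pearsonr(sstats.rankdata(x), sstats.rankdata(y))[0]
        assert res.rho == pytest.approx(oracle, abs=1e-12)

    def test_missing_pairs_dropped_from_n(self):
        x = [1, 2, np.nan, 4, 5, 6, 7, 8, 9, 10, 11, 12]
        y = [2, 1, 3, np.nan, 5, 7, 6, 8, 10, 9, 12, 11]
        assert spearman(x, y).n == 10

    def test_exact_small_n_p_matches_enumeration(self):
        x, y = [1, 2, 3, 4, 5], [2, 1, 4, 3, 5]
        res = spearman(x, y)
        rx = sstats.rankdata(x)
        count = total = 0
        for perm in itertools.permutations(sstats.rankdata(y)):
            r = sstats.pearsonr(rx, np.array(perm))[0]
            count += abs(r) >= abs(res.rho) - 1e-12
            total += 1
        assert res.p_value == pytest.approx(count / total, abs=1e-12)

    def test_zero_variance_is_error(self):
        with pytest.raises(ValueError, match="variance"):
            spearman([1, 1, 1], [1, 2, 3])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        base = spearman(x, y)
        warped = spearman(np.exp(x), y ** 3)
        assert warped.rho == pytest.approx(base.rho, abs=1e-12)
        assert warped.p_value == pytest.approx(base.p_value, abs=1e-12)


class TestMannWhitney:
    def test_exact_p_matches_enumeration_oracle(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        p = mann_whitney_u(a, b)
        # independent oracle: all C(6,3)=20 labelings of the pooled sample
        pooled = np.array(a + b)
        ranks = sstats.rankdata(pooled)
        mu = len(a) * len(b) / 2
        u_obs = ranks[:3].sum() - 3 * 4 / 2
        devs = []
        for idx in itertools.combinations(range(6), 3):
            u = ranks[list(idx)].sum() - 3 * 4 / 2
            devs.append(abs(u - mu) >= abs(u_obs - mu) - 1e-12)
        assert p == pytest.approx(np.mean(devs), abs=1e-12)
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_symmetric_under_group_swap(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=6), rng.normal(size=7) + 0.8
        assert mann_whitney_u(a, b) == mann_whitney_u(b, a)
        big_a, big_b = rng.normal(size=30), rng.normal(size=25) + 0.5
        assert mann_whitney_u(big_a, big_b) == pytest.approx(
            mann_whitney_u(big_b, big_a), abs=1e-12)

    def test_identical_groups_p_one(self):
        assert mann_whitney_u([2.0, 2.0, 2.0], [2.0, 2.0]) == 1.0

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestReports:
    def test_correlation_report_flags_constant_feature(self):
        feats = pd.DataFrame({"good": [1.0, 2, 3, 4, 5],
                              "flat": [7.0] * 5},
                             index=[f"m{i}" for i in range(5)])
        resp = {"eff": pd.Series([5.0, 3, 4, 1, 2],
                                 index=[f"m{i}" for i in range(5)])}
        rep = correlation_report(feats, resp)
        flat = rep[rep.feature == "flat"].iloc[0]
        assert flat["flag"] == "constant" and np.isnan(flat["rho"])
        good = rep[rep.feature == "good"].iloc[0]
        assert good["n"] == 5 and abs(good["rho"]) <= 1

    def test_pairwise_deletion_gives_per_row_n(self):
        idx = [f"m{i}" for i in range(10)]
        feats = pd.DataFrame({
            "a": np.arange(10.0),
            "b": [np.nan, np.nan] + list(np.arange(8.0))}, index=idx)
        rng = np.random.default_rng(1)
        resp = {"eff": pd.Series(rng.normal(size=10), index=idx)}
        rep = correlation_report(feats, resp).set_index("feature")
        assert rep.loc["a", "n"] == 10 and rep.loc["b", "n"] == 8

    def test_conserved_vs_unique_by_family_size(self):
        from mirproc.io_mirna import PriMiRNARecord
        recs = [PriMiRNARecord(f"m{i}", "syn", "ACGU" * 5,
                               family=("famA" if i < 3 else None))
                for i in range(4)]
        vals = {f"m{i}": float(i) for i in range(4)}
        out = conserved_vs_unique(recs, vals)
        assert out["conserved"]["n"] == 3 and out["unique"]["n"] == 1
        assert out["p"] is not None

    def test_all_singletons_skips_comparison(self):
        from mirproc.io_mirna import PriMiRNARecord
        recs = [PriMiRNARecord(f"m{i}", "syn", "ACGU" * 5, family=f"f{i}")
                for i in range(4)]
        out = conserved_vs_unique(recs, {f"m{i}": 1.0 * i for i in range(4)})
        assert out["conserved"]["n"] == 0 and out["p"] is None


class TestTimecourse:
    def _lanes(self, ratios_by_substrate):
        rows = []
        for sid, series in ratios_by_substrate.items():
            for t, r in series:
                rows.append({"substrate_id": sid, "enzyme": "Drosha",
                             "batch": 0, "timepoint": t,
                             "product_intensity": r * 1000,
                             "substrate_intensity": (1 - r) * 1000,
                             "control_flag": False})
        return pd.DataFrame(rows)

    def test_monotone_flag(self):
        lanes = self._lanes({"s1": [(10, 0.1), (30, 0.3), (60, 0.5)],
                             "s2": [(10, 0.4), (30, 0.2), (60, 0.5)]})
        summ = timecourse_summary(lanes)
        flags = summ.groupby("substrate_id")["monotone"].first()
        assert bool(flags["s1"]) and not bool(flags["s2"])

    def test_single_replicate_sd_zero(self):
        lanes = self._lanes({"s1": [(10, 0.1), (30, 0.3)]})
        summ = timecourse_summary(lanes)
        assert (summ["sd_ratio"] == 0).all()
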