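"""Position model: WLS, trimmed fitting, splits, gap confidence."""

import numpy as np
import pandas as pd
import pytest

from ltscaf.link_clustering import median_sd
from ltscaf.regression import (ContigPositionModel, exhaustive_wlts_objective,
                               maxerror_schedule)


def make_obs(rows):
    """rows: (i, j, Y, w) or (i, j, Y, w, n)."""
    full = [r if len(r) == 5 else (*r, 1) for r in rows]
    return pd.DataFrame(full, columns=["i", "j", "Y", "w", "n"])


LENGTHS10 = {f"c{k:02d}": 4500 for k in range(30)}


class TestWls:
    def test_three_row_normal_equations(self):
        obs = make_obs([("1", "2", 100.0, 1.0), ("1", "3", 160.0, 1.0),
                        ("2", "3", 50.0, 1.0)])
        res = ContigPositionModel(obs, {"1": 10, "2": 10, "3": 10}).fit_wls()
        assert res.params["1"] == 0.0
        assert res.params["2"] == pytest.approx(103.33, abs=0.005)
        assert res.params["3"] == pytest.approx(156.67, abs=0.005)

    def test_single_row_exact(self):
        obs = make_obs([("1", "2", 100.0, 1.0)])
        res = ContigPositionModel(obs, {"1": 10, "2": 10}).fit_wls()
        assert res.params["2"] == 100.0
        assert res.resid[0] == 0.0

    def test_weighted_mean(self):
        obs = make_obs([("1", "2", 100.0, 10.0), ("1", "2", 700.0, 2.0)])
        res = ContigPositionModel(obs, {"1": 10, "2": 10}).fit_wls()
        assert res.params["2"] == pytest.approx(200.0)


class TestWlts:
    def test_hand_trace_drops_outlier(self):
        obs = make_obs([("1", "2", 100.0, 10.0), ("1", "2", 700.0, 2.0)])
        res = ContigPositionModel(obs, {"1": 10, "2": 10}).fit(max_error=100)
        assert res.params["2"] == pytest.approx(100.0)
        assert res.selected.tolist() == [True, False]
        assert res.removed["Y"].tolist() == [700.0]

    def test_all_within_bound_keeps_everything(self):
        obs = make_obs([("1", "2", 100.0, 1.0), ("1", "2", 110.0, 1.0)])
        res = ContigPositionModel(obs, {"1": 10, "2": 10}).fit(max_error=100)
        assert res.selected.all()
        assert res.n_iter == 0

    def test_split_on_disconnection(self):
        # a chain 1-2-3 whose 2-3 evidence was entirely discarded upstream
        # (e.g. unsupported by orientation): the observation graph no longer
        # connects the component and the fit reports the sub-components
        obs = make_obs([("1", "2", 100.0, 1.0)] * 4)
        res = ContigPositionModel(
            obs, {"1": 10, "2": 10, "3": 10},
            component=["1", "2", "3"]).fit(max_error=100)
        assert res.split is not None
        assert sorted(map(tuple, res.split)) == [("1", "2"), ("3",)]
        with pytest.raises(ValueError):
            _ = res.params

    def test_removal_is_recorded(self):
        obs = make_obs([("1", "2", 0.0, 1.0)] * 5 + [("1", "2", 9000.0, 1.0)])
        res = ContigPositionModel(obs, {"1": 10, "2": 10}).fit(max_error=50)
        assert int((~res.selected).sum()) == 1
        assert np.abs(res.resid[res.selected]).max() <= 50

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        rows = [("a", "b", 100 + rng.normal(0, 5), 1.0) for _ in range(6)]
        rows += [("b", "c", 200 + rng.normal(0, 5), 1.0) for _ in range(6)]
        rows += [("a", "c", 5000.0, 1.0)]
        obs = make_obs(rows)
        lengths = {"a": 10, "b": 10, "c": 10}
        base = ContigPositionModel(obs, lengths).fit(max_error=30)
        perm = rng.permutation(len(obs))
        shuffled = ContigPositionModel(
            obs.iloc[perm].reset_index(drop=True), lengths).fit(max_error=30)
        pd.testing.assert_series_equal(base.params, shuffled.params)
        assert set(np.flatnonzero(base.selected)) == \
            set(perm[np.flatnonzero(shuffled.selected)])

    def test_shift_equivariance(self):
        rng = np.random.default_rng(6)
        rows = [(f"c{k}", f"c{k+1}", 1000 + rng.normal(0, 10), 1.0)
                for k in range(5) for _ in range(3)]
        obs = make_obs(rows)
        lengths = {f"c{k}": 900 for k in range(6)}
        base = ContigPositionModel(obs, lengths).fit(max_error=100)
        shifted_obs = obs.copy()
        shifted_obs["Y"] += 50.0
        shifted = ContigPositionModel(shifted_obs, lengths).fit(max_error=100)
        for k in range(6):
            assert shifted.params[f"c{k}"] == \
                pytest.approx(base.params[f"c{k}"] + 50.0 * k, abs=1e-6)

    def test_breakdown_contrast_small(self):
        rng = np.random.default_rng(8)
        ids = [f"c{k:02d}" for k in range(8)]
        true = {v: 2000.0 * k for k, v in enumerate(ids)}
        rows = []
        for a in range(7):
            i, j = ids[a], ids[a + 1]
            for r in range(6):
                y = true[j] - true[i] + rng.normal(0, 20)
                if r < 2:          # one third of each pair's rows are false
                    y += 5000.0
                rows.append((i, j, y, 1 / 400))
        obs = make_obs(rows)
        model = ContigPositionModel(obs, {v: 1800 for v in ids})
        robust = model.fit(max_error=100)
        plain = model.fit_wls()
        truth = np.array([true[v] for v in ids])
        rmse = lambda r: float(np.sqrt(np.mean((r.params.values - truth) ** 2)))
        assert rmse(robust) < 60
        assert rmse(plain) > 10 * rmse(robust)


class TestMaxErrorSchedule:
    @pytest.mark.parametrize("base,it,expected", [(100, 0, 100),
                                                  (100, 2, 200),
                                                  (150, 1, 200)])
    def test_schedule(self, base, it, expected):
        assert maxerror_schedule(base, it) == expected


class TestExhaustiveOracle:
    def build(self, seed):
        # weights calibrated so the subset penalty's implied removal
        # threshold sqrt(1/w) equals the 100 bp MaxError: only then do the
        # trimmed-sum objective and the residual-bound stopping rule agree
        rng = np.random.default_rng(seed)
        ids = list("abcd")
        true = {v: 1000.0 * k for k, v in enumerate(ids)}
        pairs = [("a", "b"), ("b", "c"), ("c", "d"), ("a", "c"),
                 ("b", "d"), ("a", "d"), ("a", "b"), ("c", "d")]
        rows = [(i, j, true[j] - true[i] + rng.normal(0, 25), 1e-4, 50)
                for i, j in pairs]
        obs = make_obs(rows)
        # one false mode per affected pair, a strict minority on every cut
        out = [0, 2]
        obs.loc[out, "Y"] += 5000.0
        return ContigPositionModel(obs, {v: 900 for v in ids}), set(out)

    def objective(self, model, res):
        rss = float(np.sum(model._w[res.selected] *
                           res.resid[res.selected] ** 2))
        return rss + int((~res.selected).sum())

    @pytest.mark.parametrize("seed", [1, 2, 3, 4])
    def test_greedy_matches_enumeration_with_planted_outliers(self, seed):
        model, planted = self.build(seed)
        res = model.fit(max_error=100)
        greedy = self.objective(model, res)
        best, best_mask = exhaustive_wlts_objective(model)
        assert greedy <= best * 1.05 + 1e-9
        assert set(np.flatnonzero(~res.selected)) == planted
        assert greedy == pytest.approx(best)

    def test_swap_local_optimality(self):
        model, _ = self.build(7)
        res = model.fit(max_error=100)
        base = self.objective(model, res)
        kept = np.flatnonzero(res.selected)
        dropped = np.flatnonzero(~res.selected)
        for k in kept:
            for d in dropped:
                mask = res.selected.copy()
                mask[k], mask[d] = False, True
                if len(model._connected(mask)) > 1:
                    continue
                _b, resid, _A = model._wls(mask)
                obj = float(np.sum(model._w[mask] * resid[mask] ** 2)) + \
                    int((~mask).sum())
                assert obj >= base - 1e-9


class TestGapConfidence:
    def test_single_cluster_model_based_se(self):
        # one supporting cluster of 150 links at sigma 500: the model-based
        # 2*SE equals the median-CLT bound of ~102.33 bp
        obs = make_obs([("1", "2", 2000.0, 150 / 500 ** 2, 150)])
        res = ContigPositionModel(obs, {"1": 1500, "2": 900}).fit(
            max_error=1e9)
        gaps = res.gap_confidence()
        assert bool(gaps["model_based"][0])
        assert 2 * gaps["se"][0] == pytest.approx(2 * median_sd(500, 150),
                                                  abs=0.01)
        assert gaps["gap"][0] == pytest.approx(500.0)

    def test_coverage_simulation(self):
        # nominal 95% CIs cover the true gaps in 93-97% of replicates
        rng = np.random.default_rng(42)
        m = 10
        ids = [f"c{k:02d}" for k in range(m)]
        true = {v: 5000.0 * k for k, v in enumerate(ids)}
        lengths = {v: 4500 for v in ids}
        cover = total = 0
        for _rep in range(1000):
            rows = []
            for a in range(m - 1):
                for b in (a + 1, a + 2):
                    if b >= m:
                        continue
                    for _ in range(2 if b == a + 1 else 1):
                        n = int(rng.integers(50, 200))
                        sd = median_sd(500.0, n)
                        y = true[ids[b]] - true[ids[a]] + rng.normal(0, sd)
                        rows.append((ids[a], ids[b], y, n / 500.0 ** 2, n))
            res = ContigPositionModel(make_obs(rows), lengths).fit(
                max_error=1e9)
            for r in res.gap_confidence(0.95).itertuples(index=False):
                total += 1
                cover += (r.ci_low <= 500.0 <= r.ci_high)
        assert 0.93 <= cover / total <= 0.97
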