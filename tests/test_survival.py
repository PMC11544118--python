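"""Survival-stage tests: hand oracles for log-rank and Cox, KM identities."""

import math

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test as ll_logrank
from scipy import optimize

from spongescreen.simulate import (SimConfig, hub_expression_z,
                                   simulate_clinical, simulate_expression)
from spongescreen.survival import (cox_fit, cox_screen, kaplan_meier,
                                   logrank_test, median_split, optimal_cutoff)


def _records(times, events, **covs):
    frame = pd.DataFrame({"time": times, "event": events, **covs})
    frame.index = [f"P{i}" for i in range(len(frame))]
    return frame


class TestMedianSplit:
    def test_even_split(self):
        groups = median_split(pd.Series([1, 2, 3, 4]))
        assert groups.tolist() == ["low", "low", "high", "high"]

    def test_ties_go_low(self):
        groups = median_split(pd.Series([1, 2, 2, 3]))
        assert groups.tolist() == ["low", "low", "low", "high"]

    def test_balance_within_tie_count(self, rng):
        values = pd.Series(rng.integers(0, 10, size=101).astype(float))
        groups = median_split(values)
        n_ties = int((values == values.median()).sum())
        assert abs((groups == "high").sum() - (groups == "low").sum()) <= n_ties

    def test_constant_values_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            median_split(pd.Series([2.0, 2.0, 2.0]))


class TestKaplanMeier:
    def test_single_event(self):
        km = kaplan_meier(_records([5.0], [1]))
        assert km.loc[km["time"] == 5.0, "survival"].iloc[0] == 0.0

    def test_all_censored_curve_flat(self):
        km = kaplan_meier(_records([1.0, 2.0, 3.0], [0, 0, 0]))
        assert (km["survival"] == 1.0).all()

    def test_product_limit_by_hand(self):
        km = kaplan_meier(_records([1.0, 2.0, 3.0], [1, 1, 1]))
        surv = km.set_index("time")["survival"]
        assert surv.loc[1.0] == pytest.approx(2 / 3)
        assert surv.loc[2.0] == pytest.approx(1 / 3)
        assert surv.loc[3.0] == pytest.approx(0.0)

    def test_no_censoring_equals_empirical_survival(self, rng):
        times = rng.exponential(10, size=40).round(2) + 0.01
        km = kaplan_meier(_records(times, [1] * 40))
        for t, s in zip(km["time"], km["survival"]):
            assert s == pytest.approx(np.mean(times > t), abs=1e-12)

    def test_curve_monotone_non_increasing(self, rng):
        times = rng.exponential(10, size=50) + 0.01
        events = rng.integers(0, 2, size=50)
        if events.sum() == 0:
            events[0] = 1
        km = kaplan_meier(_records(times, events))
        assert (np.diff(km["survival"]) <= 1e-12).all()


def _hand_logrank(records, group_col="group"):
    """Independent O-E tabulation over distinct event times."""
    df = records.sort_values("time")
    g1 = sorted(df[group_col].unique())[0]
    o_minus_e = var = 0.0
    for t in sorted(df.loc[df["event"] == 1, "time"].unique()):
        at_risk = df[df["time"] >= t]
        n, n1 = len(at_risk), (at_risk[group_col] == g1).sum()
        dead = at_risk[(at_risk["time"] == t) & (at_risk["event"] == 1)]
        d, d1 = len(dead), (dead[group_col] == g1).sum()
        if n > 1:
            o_minus_e += d1 - d * n1 / n
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogrank:
    def test_identical_groups_null(self):
        base = _records([1.0, 2.0, 3.0], [1, 1, 0])
        dup = pd.concat([base.assign(group="a"), base.assign(group="b")])
        res = logrank_test(dup)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == 1.0

    def test_hand_tabulated_fixture(self):
        rec = _records([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], [1, 1, 1, 1, 0, 1],
                       group=["a", "a", "a", "b", "b", "b"])
        res = logrank_test(rec)
        assert res.statistic == pytest.approx(_hand_logrank(rec), abs=1e-12)

    def test_label_swap_invariance(self, rng):
        rec = _records(rng.exponential(5, 30) + 0.01,
                       rng.integers(0, 2, 30),
                       group=rng.choice(["a", "b"], 30))
        if rec["event"].sum() == 0:
            rec.loc[rec.index[0], "event"] = 1
        swapped = rec.assign(group=rec["group"].map({"a": "b", "b": "a"}))
        r1, r2 = logrank_test(rec), logrank_test(swapped)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)

    def test_matches_lifelines(self, rng):
        rec = _records(rng.exponential(5, 60) + 0.01,
                       rng.integers(0, 2, 60),
                       group=rng.choice(["a", "b"], 60))
        ours = logrank_test(rec)
        a = rec[rec["group"] == "a"]
        b = rec[rec["group"] == "b"]
        ref = ll_logrank(a["time"], b["time"], a["event"], b["event"])
        assert ours.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
        assert ours.p == pytest.approx(ref.p_value, rel=1e-9)


def _grid_cox_beta(times, events, x):
    """Brute-force partial-likelihood maximiser (no ties in fixtures)."""
    order = np.argsort(times)
    times, events, x = times[order], events[order], x[order]

    def neg_pl(beta):
        pl = 0.0
        for i in range(len(times)):
            if events[i]:
                risk = times >= times[i]
                pl += beta * x[i] - math.log(np.sum(np.exp(beta * x[risk])))
        return -pl

    grid = np.linspace(-4, 4, 1601)
    best = grid[np.argmin([neg_pl(b) for b in grid])]
    res = optimize.minimize_scalar(neg_pl, bracket=(best - 0.02, best + 0.02))
    return float(res.x)


class TestCox:
    def test_binary_covariate_antisymmetry(self):
        rec = _records([1, 2, 3, 4, 5, 6, 7, 8.0], [1] * 8,
                       grp=[0, 1, 0, 1, 0, 1, 0, 1])
        flipped = rec.assign(grp=1 - rec["grp"])
        b1 = cox_fit(rec, ["grp"]).beta("grp")
        b2 = cox_fit(flipped, ["grp"]).beta("grp")
        assert b1 == pytest.approx(-b2, abs=1e-6)

    def test_matches_grid_search_oracle(self, rng):
        """Newton-Raphson fit equals brute-force partial-likelihood
        maximisation on tie-free 8-subject fixtures."""
        for _ in range(5):
            times = rng.exponential(5, 8) + rng.uniform(0, 0.1, 8)
            events = np.array([1, 1, 1, 1, 1, 1, 0, 1])
            x = rng.normal(size=8)
            rec = _records(times, events, x=x)
            ours = cox_fit(rec, ["x"]).beta("x")
            oracle = _grid_cox_beta(times, events, x)
            assert ours == pytest.approx(oracle, abs=1e-4)

    def test_ci_contains_hr(self, rng):
        rec = _records(rng.exponential(5, 50) + 0.01,
                       rng.integers(0, 2, 50), x=rng.normal(size=50))
        if rec["event"].sum() == 0:
            rec.loc[rec.index[0], "event"] = 1
        res = cox_fit(rec, ["x"])
        row = res.table.iloc[0]
        assert row["ci_low"] < row["hr"] < row["ci_high"]
        assert row["hr"] > 0

    def test_logrank_equals_cox_score_test_on_tie_free_data(self, rng):
        """Two-group log-rank chi-square equals the Cox score statistic
        U(0)^2 / I(0) for the group indicator (tie-free fixture)."""
        times = rng.exponential(5, 24) + rng.uniform(0, 0.2, 24)
        events = rng.integers(0, 2, 24)
        events[:4] = 1
        grp = rng.integers(0, 2, 24)
        rec = _records(times, events, group=np.where(grp, "b", "a"))
        lr = logrank_test(rec).statistic
        order = np.argsort(times)
        t_s, e_s, x_s = times[order], events[order], grp[order].astype(float)
        u = info = 0.0
        for i in range(len(t_s)):
            if e_s[i]:
                risk = t_s >= t_s[i]
                xbar = x_s[risk].mean()
                u += x_s[i] - xbar
                info += np.mean((x_s[risk] - xbar) ** 2)
        assert lr == pytest.approx(u**2 / info, rel=1e-6)


class TestCoxScreen:
    def test_single_passing_candidate_equals_univariate(self, rng):
        rec = _records(rng.exponential(5, 80) + 0.01, [1] * 80,
                       x=rng.normal(size=80))
        rec["time"] *= np.exp(-0.8 * rec["x"])  # strong signal
        univ, multi = cox_screen(rec, ["x"])
        assert multi is not None
        assert multi.beta("x") == pytest.approx(
            univ.set_index("term").loc["x", "beta"], abs=1e-10)

    def test_null_covariates_mostly_fail_entry(self, rng):
        n = 120
        rec = _records(rng.exponential(5, n) + 0.01, [1] * n,
                       **{f"x{i}": rng.normal(size=n) for i in range(10)})
        univ, multi = cox_screen(rec, [f"x{i}" for i in range(10)],
                                 univ_p_enter=0.05)
        n_pass = 10 - len(univ) + (univ["p"] < 0.05).sum()
        assert (univ["p"] < 0.05).sum() <= 3  # expect ~0.5 passes under null

    def test_planted_hub_retained_in_multivariate(self, default_bundle):
        cfg = default_bundle["config"]
        clin = simulate_clinical(default_bundle["expr"],
                                 default_bundle["truth"], cfg)
        z = hub_expression_z(default_bundle["expr"],
                             default_bundle["truth"].hub_lnc)
        values = z.loc[clin.index]
        rec = clin.assign(expr_group=median_split(values))
        univ, multi = cox_screen(
            rec, ["expr_group", "age", "sex", "stage", "grade", "msi", "ebv"])
        assert multi is not None
        assert "expr_group[high]" in multi.table["term"].tolist()
        assert multi.hr("expr_group[high]") > 1.0


class TestOptimalCutoff:
    def _clustered(self, rng, n=60):
        x = np.concatenate([rng.normal(0, 0.3, n // 2),
                            rng.normal(3, 0.3, n // 2)])
        lam = np.where(x > 1.5, 3.0, 0.3)
        times = rng.exponential(1 / lam) + 0.01
        rec = _records(times, [1] * n)
        return pd.Series(x, index=rec.index), rec

    def test_cut_separates_the_clusters(self, rng):
        values, rec = self._clustered(rng)
        out = optimal_cutoff(values, rec)
        # the chosen cut essentially splits along the two risk clusters
        # (exponential noise can move it by the odd boundary point)
        disagree = ((values <= out["cutpoint"]) != (values < 1.5)).sum()
        assert disagree <= 2
        assert out["multiplicity_corrected"] is False

    def test_exhaustive_scan_is_the_maximum(self, rng):
        values, rec = self._clustered(rng)
        out = optimal_cutoff(values, rec)
        lo, hi = values.quantile(0.1), values.quantile(0.9)
        stats = []
        for cut in values[(values >= lo) & (values < hi)].unique():
            grp = np.where(values <= cut, "low", "high")
            stats.append(logrank_test(rec.assign(group=grp)).statistic)
        assert out["statistic"] == pytest.approx(max(stats), abs=1e-9)

    def test_narrower_band_never_beats_wider(self, rng):
        values, rec = self._clustered(rng)
        wide = optimal_cutoff(values, rec, quantile_band=(0.05, 0.95))
        narrow = optimal_cutoff(values, rec, quantile_band=(0.3, 0.7))
        assert narrow["statistic"] <= wide["statistic"] + 1e-12


class TestClinicalSimulationNull:
    def test_null_hazard_gives_nominal_logrank_rate(self):
        """With no true hazard coupling, the median-split log-rank test
        rejects at roughly the nominal 5% level (n chosen large enough
        for the chi-square reference to be accurate)."""
        rej = 0
        reps = 300
        for seed in range(reps):
            cfg = SimConfig(n_tumor=160, n_normal=5, n_lnc=12, n_mi=4,
                            n_mrna=8, n_triplets=2, beta_hazard=0.0,
                            censor_rate=0.2, seed=seed)
            expr, truth = simulate_expression(cfg)
            clin = simulate_clinical(expr, truth, cfg)
            z = hub_expression_z(expr, truth.hub_lnc)
            rec = clin.assign(group=median_split(z.loc[clin.index]))
            rej += logrank_test(rec).p < 0.05
        assert 0.02 <= rej / reps <= 0.08
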