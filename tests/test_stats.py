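"""Replicate aggregation, hypothesis tests and the summary table."""

import numpy as np
import pandas as pd
import pytest

import capsulemech as cm


def frame(rows):
    return pd.DataFrame(rows, columns=["group_id", "animal_id", "tech_rep",
                                       "value"])


def summary_from_values(group_id, values, measure="m"):
    rows = [(group_id, i, 0, v) for i, v in enumerate(values)]
    return cm.aggregate(frame(rows), measure_id=measure)


def permutation_p(a, b, n_perm, seed):
    """Two-sided permutation test on the difference of means (the
    distribution-free oracle for the two-sample location problem)."""
    rng = np.random.default_rng(seed)
    obs = abs(np.mean(a) - np.mean(b))
    pool = np.concatenate([a, b])
    na = len(a)
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(pool)
        if abs(pool[:na].mean() - pool[na:].mean()) >= obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


class TestAggregate:
    def test_two_level_averaging(self):
        df = frame([("g", "a", 0, 1.0), ("g", "a", 1, 3.0),
                    ("g", "b", 0, 2.0), ("g", "b", 1, 2.0)])
        s = cm.aggregate(df)
        assert s.group_mean == 2.0
        assert s.group_sd == 0.0
        assert s.n_bio == 2

    def test_single_replicate_collapses_to_plain_stats(self):
        vals = [1.0, 4.0, 7.0]
        s = summary_from_values("g", vals)
        assert s.group_mean == pytest.approx(np.mean(vals))
        assert s.group_sd == pytest.approx(np.std(vals, ddof=1))

    def test_permutation_invariant_over_replicates(self):
        rows = [("g", a, r, 10 * a + r) for a in range(3) for r in range(4)]
        rng = np.random.default_rng(0)
        shuffled = list(rows)
        rng.shuffle(shuffled)
        assert cm.aggregate(frame(rows)).group_mean == \
            cm.aggregate(frame(shuffled)).group_mean

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cm.aggregate(frame([]))

    def test_pipeline_cohort_recovers_group_mean(self, configs):
        """Fb-P G'' cohort (n_bio=5, n_tech=3) aggregates near 541 Pa."""
        out = cm.rheology_stage(configs, seed=29, groups=("Fb-P",))
        s = out["Fb-P"]
        assert s.n_bio == 5
        se = 54.0 / np.sqrt(5)
        assert abs(s.group_mean - 541.0) < 3 * se


class TestTTest:
    def test_textbook_values(self):
        a = summary_from_values("A", [1.0, 2.0, 3.0])
        b = summary_from_values("B", [4.0, 5.0, 6.0])
        res = cm.t_test(a, b)
        assert res.statistic == pytest.approx(-3.674, abs=1e-3)
        assert res.df == 4
        assert res.p == pytest.approx(0.0214, abs=2e-4)
        assert res.stars == "*"

    def test_identical_groups_ns(self):
        a = summary_from_values("A", [1.0, 2.0, 3.0])
        b = summary_from_values("B", [1.0, 2.0, 3.0])
        res = cm.t_test(a, b)
        assert res.p == pytest.approx(1.0)
        assert res.stars == "ns"

    def test_degenerate_zero_variance(self):
        a = summary_from_values("A", [0.0, 0.0])
        b = summary_from_values("B", [1.0, 1.0])
        res = cm.t_test(a, b)
        assert "degenerate" in res.flags
        assert res.p == 0.0

    def test_matches_permutation_oracle_dense_design(self):
        """At n=10 vs 10 the pooled-t p agrees with a permutation oracle to
        0.02 (the permutation distribution is dense enough there; at the
        study's n=5 vs 2 it has only 21 atoms, so only rank agreement is
        checked below)."""
        rng = np.random.default_rng(5)
        for trial in range(5):
            x = rng.normal(0, 1, 10)
            y = rng.normal(0.9, 1, 10)
            res = cm.t_test(summary_from_values("A", x),
                            summary_from_values("B", y))
            p_perm = permutation_p(x, y, 20000, trial)
            assert abs(res.p - p_perm) < 0.02

    def test_rank_agreement_small_unbalanced_design(self):
        """n=5 vs 2: smaller t p-values go with smaller permutation p-values."""
        rng = np.random.default_rng(6)
        pairs = []
        for trial in range(6):
            x = rng.normal(0, 1, 5)
            y = rng.normal(trial * 0.7, 1, 2)
            res = cm.t_test(summary_from_values("A", x),
                            summary_from_values("B", y))
            pairs.append((res.p, permutation_p(x, y, 5000, trial)))
        t_ranks = np.argsort([p for p, _ in pairs])
        perm_ranks = np.argsort([q for _, q in pairs])
        rho = np.corrcoef(np.argsort(t_ranks), np.argsort(perm_ranks))[0, 1]
        assert rho > 0.7

    def test_welch_flag(self):
        a = summary_from_values("A", [1.0, 2.0, 3.0, 4.0, 5.0])
        b = summary_from_values("B", [10.0, 30.0])
        assert cm.t_test(a, b, welch=True).method == "welch_t"


class TestAnovaTukey:
    def test_identical_groups_all_ns(self):
        groups = [summary_from_values(g, [1.0, 2.0, 3.0]) for g in "ABC"]
        results = cm.anova_tukey(groups)
        assert results[0].statistic == pytest.approx(0.0, abs=1e-12)
        assert all(r.stars == "ns" for r in results)

    def test_outlier_group_flagged(self):
        """One far-off group is significant pairwise; the close pair is not.
        The omnibus F p agrees with a permutation-F oracle within 2pp."""
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, 5)
        b = rng.normal(0, 1, 5)
        c = rng.normal(8, 1, 5)
        results = cm.anova_tukey([summary_from_values("A", a),
                                  summary_from_values("B", b),
                                  summary_from_values("C", c)])
        by_label = {r.comparison: r for r in results}
        assert by_label["A vs C"].p < 0.05
        assert by_label["B vs C"].p < 0.05
        assert by_label["A vs B"].p >= 0.05
        # permutation oracle for the omnibus test
        from scipy.stats import f_oneway
        obs_F = f_oneway(a, b, c).statistic
        pool = np.concatenate([a, b, c])
        hits = 0
        n_perm = 10000
        for _ in range(n_perm):
            rng.shuffle(pool)
            if f_oneway(pool[:5], pool[5:10], pool[10:]).statistic >= obs_F:
                hits += 1
        p_perm = (hits + 1) / (n_perm + 1)
        assert abs(by_label["omnibus"].p - p_perm) < 0.02

    def test_two_groups_redirected(self):
        groups = [summary_from_values(g, [1.0, 2.0]) for g in "AB"]
        with pytest.raises(ValueError, match="t_test"):
            cm.anova_tukey(groups)

    def test_elastin_group_separation(self, configs):
        """Fibrous groups carry more elastin than adipose: Fb-P vs Ad clears
        Tukey at 1%, and the small Fb-PECM group clears Student's t vs Ad.
        (Tukey with n=2 against the Fb-P-inflated MSE lacks power.)"""
        hits_tukey = 0
        hits_t = 0
        n_seeds = 25
        for seed in range(n_seeds):
            el = cm.assay_stage(configs, seed=1000 + seed,
                                groups=("Fb-P", "Fb-PECM", "Ad"))
            results = cm.anova_tukey([el["Fb-P"], el["Fb-PECM"], el["Ad"]])
            by_label = {r.comparison: r for r in results}
            if by_label["Fb-P vs Ad"].p < 0.01:
                hits_tukey += 1
            if cm.t_test(el["Fb-PECM"], el["Ad"]).p < 0.05:
                hits_t += 1
        assert hits_tukey >= 0.8 * n_seeds
        assert hits_t >= 0.8 * n_seeds


class TestTwoFactorAnova:
    @staticmethod
    def make_design(rng, group_effect=0.0):
        rows = []
        for gi, g in enumerate(["a", "b", "c"]):
            for level in ["w1", "w2", "w3"]:
                for _ in range(4):
                    rows.append({"group_id": g, "level": level,
                                 "value": rng.normal(gi * group_effect, 1.0)})
        return pd.DataFrame(rows)

    def test_strong_effect_detected(self):
        hits = 0
        for seed in range(40):
            df = self.make_design(np.random.default_rng(seed), group_effect=3.0)
            res = {r.comparison: r for r in cm.two_factor_anova(df)}
            if res["group_id"].p < 0.001:
                hits += 1
        assert hits >= 38  # >= 95%

    def test_single_level_degenerates_to_one_factor(self):
        rng = np.random.default_rng(1)
        df = self.make_design(rng)
        df = df[df["level"] == "w1"]
        res = cm.two_factor_anova(df)
        assert len(res) == 1
        assert res[0].method == "anova_1f"

    def test_missing_cell_rejected(self):
        df = self.make_design(np.random.default_rng(2))
        df = df[~((df["group_id"] == "a") & (df["level"] == "w1"))]
        with pytest.raises(ValueError, match="cell"):
            cm.two_factor_anova(df)


class TestStarsAndReport:
    @pytest.mark.parametrize("p, label", [
        (0.0009, "***"), (0.001, "**"), (0.009, "**"), (0.01, "*"),
        (0.049, "*"), (0.05, "ns"), (0.5, "ns"),
    ])
    def test_star_thresholds(self, p, label):
        assert cm.stars(p) == label

    def test_report_rows_and_metrics(self, configs):
        res = cm.run_study(seed=17)
        table = res["table"]
        assert len(table) == 5  # all headline measures present
        assert set(table.columns) >= {"measure", "Fb-P", "Fb-PECM", "p", "stars"}
        m = res["metrics"]
        assert m["g_loss_low.Fb-P"] > m["g_loss_low.Fb-PECM"]
        assert m["E_high.Fb-P"] > m["E_high.Fb-PECM"]
        assert cm.qc_skin(m["skin_qc.ratio"])

    def test_missing_measure_warns_and_omits(self):
        a = summary_from_values("Fb-P", [1.0, 2.0, 3.0])
        b = summary_from_values("Fb-PECM", [4.0, 5.0])
        with pytest.warns(UserWarning, match="missing"):
            table, metrics = cm.build_report({"E_high": {"Fb-P": a,
                                                         "Fb-PECM": b}})
        assert len(table) == 1
        assert "E_high.p" in metrics

    def test_empty_input_warns_empty_table(self):
        with pytest.warns(UserWarning):
            table, metrics = cm.build_report({})
        assert table.empty
        assert metrics == {}
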