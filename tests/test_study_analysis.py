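"""Aggregation, ANOVA, post hoc, regression, and the end-to-end study."""

import numpy as np
import pytest
from scipy import stats

import fragdisp as fd
from fragdisp.study_analysis import ANOVA_OUTCOMES

from conftest import random_rigid


def dev(tfs, tfa, frag="f"):
    return fd.DisplacementResult(tfs, tfa, frag)


class TestAggregateCase:
    def test_two_fragment_mean(self):
        s = fd.aggregate_case("r1", "c1", [dev(2, 10), dev(4, 20)])
        assert (s.mean_tfs, s.mean_tfa, s.n_fragments) == (3.0, 15.0, 2)

    def test_single_fragment_identity(self):
        s = fd.aggregate_case("r1", "c1", [dev(1.5, 5)])
        assert (s.mean_tfs, s.mean_tfa) == (1.5, 5.0)

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(12)
        tfs = rng.uniform(0, 10, size=20)
        tfa = rng.uniform(0, 90, size=20)
        s = fd.aggregate_case("r", "c", [dev(a, b) for a, b in zip(tfs, tfa)])
        assert s.mean_tfs == pytest.approx(tfs.sum() / 20, abs=1e-12)
        assert s.mean_tfa == pytest.approx(tfa.sum() / 20, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(fd.UndefinedStatisticError):
            fd.aggregate_case("r", "c", [])


class TestAggregateRater:
    def _summaries(self, tfs_means):
        return [
            fd.CaseSummary("r1", f"c{i}", m, 2 * m, 1)
            for i, m in enumerate(tfs_means)
        ]

    def test_mean_and_sample_sd(self):
        s = fd.aggregate_rater(self._summaries([1.0, 3.0]), "BE")
        assert s.mean_tfs == 2.0
        assert s.sd_tfs == pytest.approx(np.sqrt(2), abs=1e-12)

    def test_identical_cases_zero_sd(self):
        s = fd.aggregate_rater(self._summaries([2.5] * 20), "SOR")
        assert (s.mean_tfs, s.sd_tfs) == (2.5, 0.0)

    def test_matches_two_pass_variance(self):
        vals = np.random.default_rng(3).uniform(0, 5, size=20)
        s = fd.aggregate_rater(self._summaries(vals), "JOR")
        mean = vals.sum() / len(vals)
        var = ((vals - mean) ** 2).sum() / (len(vals) - 1)
        assert s.sd_tfs == pytest.approx(np.sqrt(var), abs=1e-12)

    def test_single_case_sd_undefined(self):
        with pytest.raises(fd.UndefinedStatisticError):
            fd.aggregate_rater(self._summaries([1.0]), "BE")


class TestOnewayAnova:
    def test_hand_sums_of_squares(self):
        # SSB = 4, SSW = 1, F = (4/1) / (1/2) = 8
        res = fd.oneway_anova({"a": [1, 2], "b": [3, 4]})
        assert res.F == pytest.approx(8.0, abs=1e-12)
        assert (res.df_between, res.df_within) == (1, 2)

    def test_identical_groups_zero_f(self):
        res = fd.oneway_anova({"a": [1, 2], "b": [1, 2]})
        assert res.F == pytest.approx(0.0, abs=1e-12)

    def test_unbalanced_matches_formula_and_scipy(self):
        rng = np.random.default_rng(9)
        groups = {
            "BE": rng.normal(2, 1, size=2),
            "SOR": rng.normal(3, 1, size=3),
            "JOR": rng.normal(6, 1, size=3),
        }
        res = fd.oneway_anova(groups)
        # textbook formula oracle
        allv = np.concatenate(list(groups.values()))
        grand = allv.mean()
        ssb = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
        ssw = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
        f_oracle = (ssb / 2) / (ssw / 5)
        assert res.F == pytest.approx(f_oracle, abs=1e-10)
        assert (res.df_between, res.df_within) == (2, 5)
        # independent implementation
        f_sp, p_sp = stats.f_oneway(*groups.values())
        assert res.F == pytest.approx(f_sp, rel=1e-10)
        assert res.p == pytest.approx(p_sp, rel=1e-10)

    def test_degenerate_variance_raises(self):
        with pytest.raises(fd.DegenerateVarianceError):
            fd.oneway_anova({"a": [1, 1], "b": [2, 2]})

    def test_label_permutation_p_is_uniform(self):
        """Under exchangeability (random 2/3/3 relabelings of iid values)
        the ANOVA p-value is approximately uniform."""
        rng = np.random.default_rng(101)
        pvals = []
        for _ in range(1000):
            vals = rng.normal(size=8)
            rng.shuffle(vals)
            groups = {"BE": vals[:2], "SOR": vals[2:5], "JOR": vals[5:]}
            pvals.append(fd.oneway_anova(groups).p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestBonferroni:
    def test_adjustment_is_three_times_raw(self):
        rng = np.random.default_rng(30)
        groups = {
            "BE": rng.normal(0, 1, 4),
            "SOR": rng.normal(1, 1, 4),
            "JOR": rng.normal(5, 1, 4),
        }
        for ph in fd.bonferroni_posthoc(groups):
            assert ph.p_adjusted == pytest.approx(min(1.0, 3 * ph.p_raw), abs=1e-15)

    def test_cap_at_one(self):
        groups = {"a": [1.0, 2.0], "b": [1.1, 1.9], "c": [0.9, 2.1]}
        phs = fd.bonferroni_posthoc(groups)
        assert any(ph.p_adjusted == 1.0 for ph in phs)

    def test_matches_pooled_t_oracle(self):
        rng = np.random.default_rng(44)
        a = rng.normal(0, 1, 3)
        b = rng.normal(2, 1, 4)
        ph = fd.bonferroni_posthoc({"a": a, "b": b})[0]
        # pooled-variance t by hand
        sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (3 + 4 - 2)
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 4))
        p = 2 * stats.t.sf(abs(t), 5)
        assert ph.t == pytest.approx(t, abs=1e-10)
        assert ph.p_raw == pytest.approx(p, abs=1e-10)
        assert ph.df == 5

    def test_singleton_vs_singleton_rejected(self):
        with pytest.raises(fd.UndefinedStatisticError):
            fd.bonferroni_posthoc({"a": [1.0], "b": [2.0]})


class TestRegression:
    def test_perfect_line(self):
        res = fd.regress_experience([0, 1, 2], [0, 1, 2])
        assert res.slope == pytest.approx(1.0, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_outcome(self):
        res = fd.regress_experience([0, 1, 2, 5], [3.3] * 4)
        assert res.slope == 0.0
        assert res.r_squared == 0.0

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(55)
        x = rng.uniform(0, 10, size=8)
        y = 4 - 0.9 * x + rng.normal(scale=0.5, size=8)
        res = fd.regress_experience(x, y)
        X = np.c_[np.ones(8), x]
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        r2 = 1 - (resid**2).sum() / ((y - y.mean()) ** 2).sum()
        mse = (resid**2).sum() / 6
        se = np.sqrt(mse * np.linalg.inv(X.T @ X)[1, 1])
        f = (beta[1] / se) ** 2
        assert res.slope == pytest.approx(beta[1], abs=1e-10)
        assert res.intercept == pytest.approx(beta[0], abs=1e-10)
        assert res.r_squared == pytest.approx(r2, abs=1e-10)
        assert res.F == pytest.approx(f, rel=1e-10)
        assert res.df == (1, 6)

    def test_missing_experience_shrinks_df(self):
        # two of eight raters lack the variable -> df (1, 4)
        x = [None, None, 6.0, 6.0, 7.0, 1.5, 3.0, 1.5]
        y = [1.0, 1.2, 2.0, 2.1, 1.8, 4.0, 3.2, 4.1]
        res = fd.regress_experience(x, y)
        assert res.n == 6
        assert res.df == (1, 4)

    def test_zero_x_variance_rejected(self):
        with pytest.raises(fd.UndefinedStatisticError):
            fd.regress_experience([2, 2, 2], [1, 2, 3])


class TestRunStudy:
    def test_seed1_group_ordering(self, seed1_study):
        """Juniors (no planning, little clinical experience) deviate most."""
        _, result = seed1_study
        by_group = {}
        for s in result.rater_summaries:
            by_group.setdefault(s.profession, []).append(s.mean_tfs)
        assert np.mean(by_group["JOR"]) > np.mean(by_group["SOR"])
        assert np.mean(by_group["JOR"]) > np.mean(by_group["BE"])

    def test_seed1_df_structure(self, seed1_study):
        """Three profession groups of 8 raters: ANOVA df (2, 5); planning
        regression df (1, 6) over 8 raters; clinical df (1, 4) over the 6
        residents."""
        _, result = seed1_study
        anova = result.anova["tfs_mean"]
        assert (anova.df_between, anova.df_within) == (2, 5)
        assert result.regressions["tfs_planning"].df == (1, 6)
        assert result.regressions["tfs_clinical"].df == (1, 4)
        assert len(result.posthoc["tfs_mean"]) == 3

    def test_all_raters_reproduce_gold(self):
        """Zero deviation everywhere: means and sds are 0 and the ANOVA is
        reported as lacking variability instead of crashing."""
        sim = fd.simulate_study(seed=5, n_cases=3)
        poses = dict(sim.poses)
        gold_pose = {
            (r.case_id, r.fragment_id): poses[r.pose_ref]
            for r in sim.plans.rows
            if r.rater_id == sim.plans.gold_rater_id
        }
        for row in sim.plans.rows:
            poses[row.pose_ref] = gold_pose[(row.case_id, row.fragment_id)]
        result = fd.run_study(sim.plans, list(sim.profiles), sim.meshes, poses)
        for s in result.rater_summaries:
            assert s.mean_tfs == pytest.approx(0.0, abs=1e-9)
            assert s.sd_tfs == pytest.approx(0.0, abs=1e-9)
        assert all(result.anova[k] is None for k in ANOVA_OUTCOMES)
        assert any("no variability" in n for n in result.notes)

    def test_row_order_invariance(self):
        """Permuting plan rows changes no output."""
        profiles = [p for p in fd.table2_fixture() if p.rater_id in "1289"]
        sim = fd.simulate_study(seed=7, profiles=profiles, n_cases=3)
        res_a = fd.run_study(sim.plans, profiles, sim.meshes, sim.poses)
        rng = np.random.default_rng(0)
        shuffled = list(sim.plans.rows)
        rng.shuffle(shuffled)
        plans_b = fd.PlanTable(tuple(shuffled), sim.plans.gold_rater_id)
        res_b = fd.run_study(plans_b, profiles, sim.meshes, sim.poses)
        for a, b in zip(res_a.rater_summaries, res_b.rater_summaries, strict=True):
            assert a.mean_tfs == pytest.approx(b.mean_tfs, abs=1e-12)
            assert a.sd_tfa == pytest.approx(b.sd_tfa, abs=1e-12)
        assert res_a.anova["tfs_mean"].F == pytest.approx(
            res_b.anova["tfs_mean"].F, abs=1e-12
        )

    def test_pipeline_linearity(self):
        """Scaling all deviations by c scales means/sds by c and leaves F,
        R^2 and p unchanged."""
        rng = np.random.default_rng(77)
        profiles = fd.table2_fixture()
        c = 3.7

        def stats_for(scale):
            summaries = []
            for prof in profiles:
                if prof.profession == "SS":
                    continue
                level = 1.0 + 0.5 * prof.planning_years + rng_vals[prof.rater_id]
                cases = [
                    fd.CaseSummary(
                        prof.rater_id, f"c{i}", scale * level * noise[prof.rater_id][i],
                        scale * level * noise[prof.rater_id][i] * 2, 2,
                    )
                    for i in range(5)
                ]
                summaries.append(fd.aggregate_rater(cases, prof.profession))
            groups = {}
            for s in summaries:
                groups.setdefault(s.profession, []).append(s.mean_tfs)
            anova = fd.oneway_anova(groups)
            reg = fd.regress_experience(
                [p.planning_years for p in profiles if p.profession != "SS"],
                [s.mean_tfs for s in summaries],
            )
            return summaries, anova, reg

        rng_vals = {p.rater_id: rng.normal() for p in profiles}
        noise = {p.rater_id: 1 + rng.uniform(0, 0.3, size=5) for p in profiles}
        base_s, base_a, base_r = stats_for(1.0)
        scaled_s, scaled_a, scaled_r = stats_for(c)
        for b, s in zip(base_s, scaled_s, strict=True):
            assert s.mean_tfs == pytest.approx(c * b.mean_tfs, rel=1e-12)
            assert s.sd_tfs == pytest.approx(c * b.sd_tfs, rel=1e-9)
        assert scaled_a.F == pytest.approx(base_a.F, rel=1e-9)
        assert scaled_a.p == pytest.approx(base_a.p, rel=1e-9)
        assert scaled_r.r_squared == pytest.approx(base_r.r_squared, rel=1e-9)
        assert scaled_r.slope == pytest.approx(c * base_r.slope, rel=1e-9)

    def test_two_group_toy_study_matches_hand_f(self):
        """Hand-set rater means through the ANOVA stage."""
        groups = {"BE": [1.0, 2.0], "JOR": [3.0, 4.0]}
        res = fd.oneway_anova(groups)
        assert res.F == pytest.approx(8.0, abs=1e-12)
        assert res.p == pytest.approx(stats.f.sf(8.0, 1, 2), abs=1e-12)

    def test_missing_profile_rejected(self):
        sim = fd.simulate_study(seed=2, n_cases=2)
        profiles = [p for p in sim.profiles if p.rater_id != "9"]
        with pytest.raises(fd.TableValidationError, match="'9'"):
            fd.run_study(sim.plans, profiles, sim.meshes, sim.poses)
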