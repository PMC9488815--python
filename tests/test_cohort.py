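"""Individual-level stages: regressions, pregnancy selection, split cross-over,
fetal adjustment, multivariable regression and characteristic tables."""

import numpy as np
import pandas as pd
import pytest

from pregmr.cohort import (CohortError, CohortTable, crude_odds_ratio,
                           fetal_adjustment_compare, fit_many_snp_trait,
                           fit_snp_trait, multivariable_outcome_regression,
                           percent_of_total, prevalence_pct, round_half_up,
                           select_one_pregnancy, split_crossover,
                           tabulate_characteristics)
from pregmr.meta import StudyEstimate, fixed_effects_meta
from pregmr.simulate import SimulationConfig, simulate_cohort


def _pregnancy_cohort():
    rows = []
    for woman, n_preg in [(0, 1), (1, 3), (2, 2)]:
        for p in range(n_preg):
            rows.append({"woman_id": woman, "pregnancy": p,
                         "rs1": float((woman + p) % 3)})
    return CohortTable(data=pd.DataFrame(rows), snps=["rs1"],
                       pregnancy_col="pregnancy")


class TestSelectOnePregnancy:
    def test_one_row_per_woman(self):
        out = select_one_pregnancy(_pregnancy_cohort(), seed=1)
        assert len(out) == 3
        assert out.data["woman_id"].is_unique

    def test_single_pregnancy_always_kept(self):
        for seed in range(20):
            out = select_one_pregnancy(_pregnancy_cohort(), seed=seed)
            row = out.data[out.data["woman_id"] == 0]
            assert row["pregnancy"].iloc[0] == 0

    def test_selection_uniform_over_seeds(self):
        counts = np.zeros(3)
        n_seeds = 3000
        for seed in range(n_seeds):
            out = select_one_pregnancy(_pregnancy_cohort(), seed=seed)
            chosen = out.data.loc[out.data["woman_id"] == 1, "pregnancy"].iloc[0]
            counts[int(chosen)] += 1
        expected = n_seeds / 3
        sd = np.sqrt(n_seeds * (1 / 3) * (2 / 3))
        assert np.all(np.abs(counts - expected) < 3 * sd)

    def test_reproducible(self):
        a = select_one_pregnancy(_pregnancy_cohort(), seed=5)
        b = select_one_pregnancy(_pregnancy_cohort(), seed=5)
        pd.testing.assert_frame_equal(a.data, b.data)


class TestFitSnpTrait:
    def test_logistic_two_by_two_matches_cross_product(self):
        # 0/1 dosage predictor: the logistic slope is the log cross-product OR
        counts = {(0, 0): 400, (0, 1): 100, (1, 0): 300, (1, 1): 200}
        rows = []
        for (g, y), n in counts.items():
            rows += [{"woman_id": len(rows) + i, "rs1": float(g),
                      "out": float(y)} for i in range(n)]
        cohort = CohortTable(data=pd.DataFrame(rows), snps=["rs1"])
        assoc = fit_snp_trait(cohort, "rs1", "out", family="logistic")
        log_or = np.log((200 * 400) / (300 * 100))
        assert assoc.beta == pytest.approx(log_or, abs=1e-8)
        assert assoc.scale == "log-odds"

    def test_linear_matches_residualized_normal_equations(self, rng):
        n = 500
        g = rng.binomial(2, 0.3, n).astype(float)
        cov = rng.normal(size=n)
        y = 0.2 * g + 0.5 * cov + rng.normal(size=n)
        df = pd.DataFrame({"woman_id": range(n), "rs1": g, "y": y, "c": cov})
        cohort = CohortTable(data=df, snps=["rs1"])
        assoc = fit_snp_trait(cohort, "rs1", "y", family="linear",
                              covariates=["c"])
        # oracle: solve the normal equations directly
        X = np.column_stack([np.ones(n), g, cov])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert assoc.beta == pytest.approx(beta[1], abs=1e-8)

    def test_null_simulation_beta_within_3se(self):
        hits = 0
        n_rep = 300
        rng = np.random.default_rng(7)
        for _ in range(n_rep):
            n = 400
            g = rng.binomial(2, 0.3, n).astype(float)
            y = rng.normal(size=n)
            cohort = CohortTable(
                data=pd.DataFrame({"woman_id": range(n), "rs1": g, "y": y}),
                snps=["rs1"])
            a = fit_snp_trait(cohort, "rs1", "y", family="linear")
            hits += abs(a.beta) < 3 * a.se
        assert hits / n_rep >= 0.99 - 3 * np.sqrt(0.01 * 0.99 / n_rep)

    def test_orthogonal_covariate_leaves_beta_near_unchanged(self, rng):
        n = 2000
        g = rng.binomial(2, 0.4, n).astype(float)
        y = 0.3 * g + rng.normal(size=n)
        cov = rng.normal(size=n)  # independent of g and y|g
        df = pd.DataFrame({"woman_id": range(n), "rs1": g, "y": y, "c": cov})
        cohort = CohortTable(data=df, snps=["rs1"])
        without = fit_snp_trait(cohort, "rs1", "y", family="linear")
        with_cov = fit_snp_trait(cohort, "rs1", "y", family="linear",
                                 covariates=["c"])
        assert with_cov.beta == pytest.approx(without.beta, abs=3 * without.se)

    def test_zero_variance_dosage_errors(self):
        df = pd.DataFrame({"woman_id": range(10), "rs1": 1.0,
                           "y": np.arange(10.0)})
        cohort = CohortTable(data=df, snps=["rs1"])
        with pytest.raises(CohortError, match="zero-variance"):
            fit_snp_trait(cohort, "rs1", "y")

    def test_vectorized_fits_match_per_snp_path(self):
        cfg = SimulationConfig(seed=11, n_subjects=1500, n_snps=4,
                               target_r2=0.02, exposure_mode="continuous",
                               outcome_mode="continuous")
        cohort = simulate_cohort(cfg)
        fast = fit_many_snp_trait(cohort, cohort.snps, "exposure")
        for rsid in cohort.snps:
            slow = fit_snp_trait(cohort, rsid, "exposure", family="linear")
            rec = fast.get(rsid)
            assert rec.beta == pytest.approx(slow.beta, rel=1e-10)
            assert rec.se == pytest.approx(slow.se, rel=1e-10)
            assert rec.pvalue == pytest.approx(slow.pvalue, rel=1e-8)


@pytest.fixture(scope="module")
def crossover_cohort():
    cfg = SimulationConfig(seed=3, n_subjects=8000, n_snps=12,
                           target_r2=0.05, causal_effect=0.4,
                           outcome_prevalence=0.2)
    return simulate_cohort(cfg)


@pytest.fixture(scope="module")
def fetal_cohort():
    cfg = SimulationConfig(seed=21, n_subjects=6000, n_snps=3,
                           target_r2=0.03, causal_effect=0.3,
                           outcome_prevalence=0.2, fetal_genotypes=True)
    return simulate_cohort(cfg)


class TestSplitCrossover:
    def test_combined_is_fixed_effects_meta_of_halves(self, crossover_cohort):
        res = split_crossover(crossover_cohort, crossover_cohort.snps,
                              "exposure", "outcome", seed=5)
        pooled = fixed_effects_meta([
            StudyEstimate("a", res.a_on_b.beta, res.a_on_b.se),
            StudyEstimate("b", res.b_on_a.beta, res.b_on_a.se)])
        assert res.combined.beta == pytest.approx(pooled.beta, rel=1e-12)
        assert res.combined.se == pytest.approx(pooled.se, rel=1e-12)

    def test_same_seed_reproduces_split_exactly(self, crossover_cohort):
        a = split_crossover(crossover_cohort, crossover_cohort.snps,
                            "exposure", "outcome", seed=11)
        b = split_crossover(crossover_cohort, crossover_cohort.snps,
                            "exposure", "outcome", seed=11)
        assert a.a_on_b.beta == b.a_on_b.beta
        assert a.b_on_a.beta == b.b_on_a.beta
        assert a.combined.beta == b.combined.beta

    def test_refuses_when_too_few_cases(self):
        cfg = SimulationConfig(seed=2, n_subjects=400, n_snps=3,
                               target_r2=0.05, outcome_prevalence=0.01)
        cohort = simulate_cohort(cfg)
        with pytest.raises(CohortError, match="case"):
            split_crossover(cohort, cohort.snps, "exposure", "outcome",
                            seed=1, min_cases=10)

    def test_recovers_effect_in_continuous_mode(self):
        # parameter recovery smoke test at reduced scale; the full-size run
        # lives in the acceptance suite
        betas = []
        for seed in range(20):
            cfg = SimulationConfig(seed=100 + seed, n_subjects=6000,
                                   n_snps=30, target_r2=0.1,
                                   causal_effect=0.3,
                                   exposure_mode="continuous",
                                   outcome_mode="continuous")
            cohort = simulate_cohort(cfg)
            res = split_crossover(cohort, cohort.snps, "exposure", "outcome",
                                  seed=seed, outcome_family="linear")
            betas.append(res.combined.beta)
        assert np.mean(betas) == pytest.approx(0.3, abs=0.05)


class TestFetalAdjustment:
    def test_outcome_independent_fetal_genotype_leaves_betas(self, fetal_cohort):
        unadj, adj, deltas = fetal_adjustment_compare(
            fetal_cohort, fetal_cohort.snps, "outcome")
        # fetal dosage affects the outcome only through correlation with the
        # maternal dosage, so adjustment shifts betas within noise
        assert np.abs(deltas["delta_beta"]).mean() < 0.1

    def test_identical_n_in_both_fits(self, fetal_cohort):
        unadj, adj, _ = fetal_adjustment_compare(
            fetal_cohort, fetal_cohort.snps, "outcome")
        for rsid in fetal_cohort.snps:
            assert unadj.get(rsid).n == adj.get(rsid).n

    def test_collinear_fetal_dosage_rejected(self, fetal_cohort):
        broken = fetal_cohort.data.copy()
        broken["fetal_rs0001"] = broken["rs0001"]
        cohort = CohortTable(data=broken, snps=fetal_cohort.snps)
        with pytest.raises(CohortError, match="collinear"):
            fetal_adjustment_compare(cohort, ["rs0001"], "outcome")

    def test_no_fetal_data_errors(self, small_cohort):
        with pytest.raises(CohortError, match="fetal"):
            fetal_adjustment_compare(small_cohort, small_cohort.snps,
                                     "outcome")


class TestMultivariableRegression:
    def test_crude_or_matches_cross_product(self):
        # reconstruct a cohort from 2x2 cell counts; the crude logistic OR
        # must equal the cross-product ratio
        cells = {"a": 242, "b": 460, "c": 1207, "d": 7759}
        rows = []
        for key, n in cells.items():
            x = 1.0 if key in ("a", "c") else 0.0
            y = 1.0 if key in ("a", "b") else 0.0
            rows += [{"woman_id": len(rows) + i, "insomnia": x, "dep": y}
                     for i in range(n)]
        cohort = CohortTable(data=pd.DataFrame(rows), snps=[])
        crude, _ = multivariable_outcome_regression(cohort, "insomnia",
                                                    "dep", confounders=[])
        or_, lo, hi = crude.odds_ratio("insomnia")
        expected = crude_odds_ratio(242, 460, 1207, 7759)
        assert or_ == pytest.approx(expected, rel=1e-6)
        assert expected == pytest.approx(3.38, abs=0.005)

    def test_confounder_free_simulation_crude_equals_adjusted(self, rng):
        n = 5000
        x = rng.binomial(1, 0.2, n).astype(float)
        c = rng.normal(size=n)  # a covariate unrelated to exposure
        y = rng.binomial(1, 1 / (1 + np.exp(-(-2 + 0.8 * x)))).astype(float)
        df = pd.DataFrame({"woman_id": range(n), "x": x, "c": c, "y": y})
        cohort = CohortTable(data=df, snps=[])
        crude, adj = multivariable_outcome_regression(cohort, "x", "y", ["c"])
        b_crude = float(crude.term("x")["beta"])
        b_adj = float(adj.term("x")["beta"])
        assert b_adj == pytest.approx(b_crude, abs=0.05)

    def test_adjusted_n_at_most_crude_n(self, rng):
        n = 1000
        df = pd.DataFrame({
            "woman_id": range(n),
            "x": rng.binomial(1, 0.3, n).astype(float),
            "y": rng.binomial(1, 0.2, n).astype(float),
            "c": np.where(rng.random(n) < 0.1, np.nan, rng.normal(size=n)),
        })
        cohort = CohortTable(data=df, snps=[])
        crude, adj = multivariable_outcome_regression(cohort, "x", "y", ["c"])
        assert adj.n <= crude.n
        assert crude.n == n

    def test_separation_flagged(self):
        n = 200
        x = np.repeat([0.0, 1.0], n // 2)
        y = x.copy()  # perfect separation
        df = pd.DataFrame({"woman_id": range(n), "x": x, "y": y})
        cohort = CohortTable(data=df, snps=[])
        crude, _ = multivariable_outcome_regression(cohort, "x", "y", [])
        assert crude.separation_flag


class TestTabulation:
    @pytest.mark.parametrize("cases,controls,expected", [
        (42_717, 139_034, 23.5),
        (9_113, 89_340, 9.3),
        (4_907, 139_034, 3.4),
        (5_178, 25_130, 17.1),
    ])
    def test_prevalence_cells(self, cases, controls, expected):
        assert prevalence_pct(cases, controls) == expected

    def test_percent_of_total_half_up(self):
        assert percent_of_total(242, 10_540) == 2.3
        assert round_half_up(0.25, 1) == 0.3  # ties round up, not to even

    def test_empty_stratum_no_division_error(self):
        df = pd.DataFrame({"woman_id": [0, 1], "grp": ["a", "a"],
                           "age": [30.0, 32.0], "out": [0.0, 1.0]})
        cohort = CohortTable(data=df, snps=[])
        table = tabulate_characteristics(cohort, continuous=["age"],
                                         outcomes=["out"], stratifier="grp")
        assert not table.empty

    def test_outcome_rows_report_cases_and_controls(self, small_cohort):
        table = tabulate_characteristics(small_cohort, continuous=["age"],
                                         outcomes=["outcome"])
        row = table[table["variable"] == "outcome"].iloc[0]
        cases, rest = row["value"].split("/")
        controls = rest.split(" ")[0]
        assert int(cases) + int(controls) == row["n"]
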