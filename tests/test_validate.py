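"""Prognostic scoring, test-set forests, external and multivariate
validation, subtype stratification."""

import numpy as np
import pandas as pd
import pytest

import progsig as ps

from _util import gene_matrix, planted_cohort


def _toy_model(genes=("a", "b"), betas=(0.5, -0.5), cutpoint=0.0):
    genes = list(genes)
    beta = pd.Series(dict(zip(genes, betas)))
    return ps.SignatureModel(
        genes=genes,
        beta_mean=beta,
        beta_per_split=pd.DataFrame([beta.to_dict()]),
        cutpoint=cutpoint,
    )


def _matrix_from(values: dict, pids=None):
    df = pd.DataFrame(values).T  # genes x patients
    if pids is not None:
        df.columns = pids
    return ps.ExpressionMatrix(df, pd.Series("unlabeled", index=df.columns))


class TestPrognosticScore:
    def test_arithmetic_example(self):
        mat = _matrix_from({"a": [2.0], "b": [1.0]}, pids=["p1"])
        scores = ps.prognostic_score(mat, _toy_model())
        assert scores.iloc[0] == pytest.approx(0.5)

    def test_zero_betas_zero_scores(self):
        mat = _matrix_from({"a": [2.0, 3.0], "b": [1.0, 9.0]}, pids=["p1", "p2"])
        scores = ps.prognostic_score(mat, _toy_model(betas=(0.0, 0.0)))
        assert (scores == 0).all()

    def test_linearity_in_expression(self):
        rng = np.random.default_rng(0)
        mat = _matrix_from({"a": rng.normal(size=5), "b": rng.normal(size=5)})
        model = _toy_model(betas=(0.7, -0.2))
        base = ps.prognostic_score(mat, model)
        bumped = mat.values.copy()
        bumped.loc["a"] += 1.0
        mat2 = ps.ExpressionMatrix(bumped, mat.sample_class)
        np.testing.assert_allclose(
            ps.prognostic_score(mat2, model) - base, 0.7, atol=1e-12
        )

    def test_missing_gene_is_an_error(self):
        mat = _matrix_from({"a": [1.0]}, pids=["p1"])
        with pytest.raises(KeyError, match="missing"):
            ps.prognostic_score(mat, _toy_model())


@pytest.fixture(scope="module")
def strong():
    mat, cohort, genes, _ = planted_cohort(
        n_patients=393, n_genes=15, n_signature=6,
        beta_low=0.5, beta_high=0.8,
    )
    plan = ps.make_splits(393, 300, k=10, seed=2)
    model = ps.fit_signature_betas(mat, cohort, genes, plan)
    return mat, cohort, model, plan


class TestEvaluateTestSets:

    def test_one_row_per_test_set(self, strong):
        mat, cohort, model, plan = strong
        ft = ps.evaluate_test_sets(mat, cohort, model, plan)
        assert len(ft.rows) == plan.k

    def test_summary_is_recount_of_rows(self, strong):
        mat, cohort, model, plan = strong
        ft = ps.evaluate_test_sets(mat, cohort, model, plan)
        ok = ft.rows[~ft.rows["flagged"]]
        manual = ((ok["ci_low"] <= 1) & (ok["ci_high"] >= 1)).mean()
        assert ft.fraction_crossing_1 == pytest.approx(manual)

    def test_strong_signature_separates_test_sets(self, strong):
        mat, cohort, model, plan = strong
        ft = ps.evaluate_test_sets(mat, cohort, model, plan)
        assert ft.fraction_crossing_1 <= 0.3
        assert (ft.rows.loc[~ft.rows["flagged"], "hr"] > 1).all()

    def test_null_signature_rarely_separates(self):
        mat, cohort, genes, _ = planted_cohort(
            n_patients=393, n_genes=15, n_signature=0
        )
        plan = ps.make_splits(393, 300, k=10, seed=2)
        model = ps.fit_signature_betas(mat, cohort, mat.feature_ids[:6], plan)
        ft = ps.evaluate_test_sets(mat, cohort, model, plan)
        assert ft.fraction_crossing_1 >= 0.7


class TestValidateExternal:
    def test_transfer_to_independent_cohort(self):
        mat, cohort, genes, betas = planted_cohort(
            n_patients=300, n_genes=15, n_signature=6,
            beta_low=0.5, beta_high=0.8,
        )
        plan = ps.make_splits(300, 225, k=5, seed=2)
        model = ps.fit_signature_betas(mat, cohort, genes, plan)
        # independent cohort sharing the planted hazard structure
        mat2 = gene_matrix(15, 600, seed=10)
        cohort2 = ps.simulate_survival(mat2, genes, betas, censor_rate=0.3, seed=11)
        rep = ps.validate_external(mat2, cohort2, model)
        assert rep.logrank_p < 0.01
        assert rep.hr > 1
        assert set(rep.group.unique()) == {"low", "high"}
        assert (rep.group == "high").sum() == 300  # median split: equal halves

    def test_null_cohort_not_separated(self):
        mat, cohort, genes, _ = planted_cohort(
            n_patients=200, n_genes=8, n_signature=3
        )
        plan = ps.make_splits(200, 150, k=3, seed=2)
        model = ps.fit_signature_betas(mat, cohort, genes, plan)
        pvals = []
        for seed in range(5):
            mat2 = gene_matrix(8, 400, seed=20 + seed)
            cohort2 = ps.simulate_survival(mat2, [], [], censor_rate=0.2,
                                           seed=30 + seed)
            pvals.append(ps.validate_external(mat2, cohort2, model).logrank_p)
        assert min(pvals) > 0.001  # no systematic separation
        assert np.mean([p < 0.5 for p in pvals]) <= 0.8

    def test_refit_on_training_matches_forced_entry(self):
        mat, cohort, genes, _ = planted_cohort(
            n_patients=250, n_genes=10, n_signature=4
        )
        plan = ps.make_splits(250, 200, k=1, seed=2)
        model = ps.fit_signature_betas(mat, cohort, genes, plan)
        rep = ps.validate_external(mat, cohort, model, refit_betas=True)
        direct = ps.cox_fit(
            mat.values.loc[genes].T, cohort.time.to_numpy(), cohort.event.to_numpy()
        )
        # the refit path must reproduce a plain forced-entry fit exactly
        scores_direct = direct.beta.to_numpy() @ mat.values.loc[genes].to_numpy()
        np.testing.assert_allclose(rep.scores.to_numpy(), scores_direct, atol=1e-10)


class TestMultivariate:
    def test_single_numeric_covariate_reduces_to_cox_fit(self):
        rng = np.random.default_rng(0)
        n = 200
        pids = [f"P{i}" for i in range(n)]
        scores = pd.Series(rng.normal(size=n), index=pids)
        age = pd.DataFrame({"age": rng.normal(60, 10, n)}, index=pids)
        t = rng.exponential(size=n) + 1e-9
        e = np.ones(n, int)
        tab = ps.multivariate_validate(scores, age, t, e)
        design = pd.DataFrame(
            {"score_high": (scores > scores.median()).astype(float),
             "age": age["age"]}
        )
        direct = ps.cox_fit(design, t, e)
        np.testing.assert_allclose(tab["beta"], direct.beta, atol=1e-12)

    def test_adjusted_score_effect_recovered(self):
        """Score HR stays clear of 1 after adjusting for a covariate
        correlated (r~0.3) with the score."""
        mat, cohort, genes, betas = planted_cohort(
            n_patients=600, n_genes=10, n_signature=4,
            beta_low=0.5, beta_high=0.8, data_seed=0, surv_seed=1,
        )
        model = _toy_model(genes=genes, betas=betas)
        scores = ps.prognostic_score(mat, model)
        cov = ps.simulate_clinical_covariates(
            cohort.patient_ids, 2, confounder_with=scores.to_numpy(), r=0.3
        )
        tab = ps.multivariate_validate(
            scores, cov, cohort.time.to_numpy(), cohort.event.to_numpy()
        )
        assert tab.loc["score_high", "ci_low"] > 1.0

    def test_noise_covariates_mostly_null(self):
        crossing = 0
        total = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 250
            pids = [f"P{i}" for i in range(n)]
            scores = pd.Series(rng.normal(size=n), index=pids)
            cov = ps.simulate_clinical_covariates(pids, seed + 100)
            t = rng.exponential(size=n) + 1e-9
            tab = ps.multivariate_validate(scores, cov, t, np.ones(n, int))
            others = tab.drop(index="score_high")
            crossing += ((others["ci_low"] <= 1) & (others["ci_high"] >= 1)).sum()
            total += len(others)
        assert crossing / total >= 0.9

    def test_collinear_dummies_named(self):
        rng = np.random.default_rng(0)
        n = 50
        pids = [f"P{i}" for i in range(n)]
        scores = pd.Series(rng.normal(size=n), index=pids)
        cov = pd.DataFrame(
            {"a": rng.normal(size=n)}, index=pids
        )
        cov["b"] = 2 * cov["a"]  # exactly collinear
        with pytest.raises(ValueError, match="collinear.*b"):
            ps.multivariate_validate(scores, cov, rng.exponential(size=n) + 0.01,
                                     np.ones(n, int))

    def test_incomplete_cases_dropped(self):
        rng = np.random.default_rng(1)
        n = 100
        pids = [f"P{i}" for i in range(n)]
        scores = pd.Series(rng.normal(size=n), index=pids)
        cov = pd.DataFrame({"age": rng.normal(60, 8, n)}, index=pids)
        cov.iloc[:10, 0] = np.nan
        tab = ps.multivariate_validate(scores, cov,
                                       rng.exponential(size=n) + 0.01,
                                       np.ones(n, int))
        assert not tab["beta"].isna().any()


class TestSubtypeStratified:
    def _cohort_with_subtypes(self, seed=0):
        mat, cohort, genes, betas = planted_cohort(
            n_patients=400, n_genes=8, n_signature=3,
            beta_low=0.6, beta_high=0.9, data_seed=seed, surv_seed=seed + 1,
        )
        model = _toy_model(genes=genes, betas=betas)
        scores = ps.prognostic_score(mat, model)
        rng = np.random.default_rng(seed + 2)
        subtype = pd.Series(
            rng.choice(["LumA", "Basal"], size=400), index=cohort.patient_ids
        )
        return cohort, scores, subtype

    def test_single_subtype_equals_unstratified(self):
        cohort, scores, _ = self._cohort_with_subtypes()
        one = pd.Series("all", index=cohort.patient_ids)
        tab = ps.subtype_stratified(
            scores, one, cohort.time.to_numpy(), cohort.event.to_numpy()
        )
        direct = ps.logrank_test(
            cohort.time.to_numpy(), cohort.event.to_numpy(),
            np.where(scores > scores.median(), "high", "low"),
        )
        assert tab.loc["all", "logrank_chi2"] == pytest.approx(direct.chi2)

    def test_unknown_mode_rejected(self):
        cohort, scores, subtype = self._cohort_with_subtypes()
        with pytest.raises(ValueError, match="mode"):
            ps.subtype_stratified(scores, subtype, cohort.time, cohort.event,
                                  mode="bogus")

    def test_modes_agree_qualitatively_on_balanced_subtypes(self):
        cohort, scores, subtype = self._cohort_with_subtypes()
        t, e = cohort.time.to_numpy(), cohort.event.to_numpy()
        a = ps.subtype_stratified(scores, subtype, t, e, mode="global-cut")
        b = ps.subtype_stratified(scores, subtype, t, e, mode="within-subtype")
        for st in a.index:
            assert (a.loc[st, "logrank_p"] < 0.05) == (b.loc[st, "logrank_p"] < 0.05)

    def test_inert_subtype_not_significant(self):
        """A subtype whose outcomes ignore the signature stays null."""
        pvals = []
        for seed in range(5):
            mat = gene_matrix(4, 200, seed=seed)
            null_cohort = ps.simulate_survival(mat, [], [], censor_rate=0.2,
                                               seed=seed + 10)
            model = _toy_model(genes=mat.feature_ids[:2], betas=(0.5, -0.5))
            scores = ps.prognostic_score(mat, model)
            tab = ps.subtype_stratified(
                scores,
                pd.Series("inert", index=null_cohort.patient_ids),
                null_cohort.time.to_numpy(), null_cohort.event.to_numpy(),
            )
            pvals.append(tab.loc["inert", "logrank_p"])
        assert np.mean([p < 0.05 for p in pvals]) <= 0.2

    def test_tiny_subtype_skipped(self):
        cohort, scores, subtype = self._cohort_with_subtypes()
        subtype.iloc[:] = "big"
        subtype.iloc[0] = "tiny"
        tab = ps.subtype_stratified(
            scores, subtype, cohort.time.to_numpy(), cohort.event.to_numpy()
        )
        assert bool(tab.loc["tiny", "skipped"])
        assert not bool(tab.loc["big", "skipped"])
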