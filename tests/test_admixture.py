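import numpy as np
import pytest

from ancestrykit.admixture import (
    NoAdmixtureCluster,
    SupervisedAdmixture,
    UnsupervisedAdmixture,
    crosstab_percent,
    drop_parental_population,
    exact_posterior_mean_2pop,
    fit_admixture_supervised,
    fit_no_admixture,
)
from ancestrykit.io import MISSING, GenotypeMatrix, RunConfig
from .conftest import two_pop_fixed_panel


class TestSupervised:
    def test_fixed_alleles_force_origin(self):
        # individual homozygous everywhere for alleles fixed in pop A
        panel = two_pop_fixed_panel(L=24)
        est = SupervisedAdmixture(burn_in=500, reps=2000, random_state=0)
        est.fit(panel.dosages, panel.labels)
        fit = est.estimate(np.full((1, 24), 2))
        assert fit.Q["A"].iloc[0] >= 0.95

    def test_gibbs_matches_exact_integration(self):
        # K=2, L=2, fixed frequencies, uniform prior: deterministic oracle
        P = np.array([[0.9, 0.2], [0.1, 0.7]])
        dosages = [1, 2]
        exact = exact_posterior_mean_2pop(dosages, P)
        panel = two_pop_fixed_panel(L=2)
        est = SupervisedAdmixture(
            burn_in=2000, reps=20_000, random_state=5, update_alpha=False
        )
        est.fit(panel.dosages, panel.labels)
        fit = est.estimate(np.array([dosages]), P_fixed=P)
        assert fit.Q.iloc[0, 0] == pytest.approx(exact, abs=0.01)

    def test_no_shared_loci_rejected(self):
        study = GenotypeMatrix(["s"], ["rsX"], np.array([[1]]))
        panel = two_pop_fixed_panel(L=2)
        with pytest.raises(ValueError, match="shared"):
            fit_admixture_supervised(study, panel)

    def test_single_parental_population_rejected(self):
        X = np.zeros((4, 3), dtype=int)
        with pytest.raises(ValueError, match="K >= 2"):
            SupervisedAdmixture().fit(X, ["A"] * 4)

    def test_credible_interval_brackets_mean(self):
        panel = two_pop_fixed_panel(L=10)
        est = SupervisedAdmixture(burn_in=200, reps=800, random_state=1)
        est.fit(panel.dosages, panel.labels)
        fit = est.estimate(np.array([[1] * 10, [2] * 10]))
        assert (fit.ci_low.to_numpy() <= fit.Q.to_numpy() + 1e-9).all()
        assert (fit.Q.to_numpy() <= fit.ci_high.to_numpy() + 1e-9).all()

    def test_group_summary_percentiles_inside_range(self):
        panel = two_pop_fixed_panel(L=12)
        est = SupervisedAdmixture(burn_in=200, reps=600, random_state=2)
        est.fit(panel.dosages, panel.labels)
        rng = np.random.default_rng(0)
        fit = est.estimate(rng.integers(0, 3, size=(30, 12)))
        summ = fit.group_summary(["g1"] * 15 + ["g2"] * 15)
        for _, row in summ.iterrows():
            sub = fit.Q[row["population"]].to_numpy()
            grp = np.array(["g1"] * 15 + ["g2"] * 15) == row["group"]
            assert sub[grp].min() - 1e-12 <= row["pct_low"]
            assert row["pct_high"] <= sub[grp].max() + 1e-12

    def test_missing_dosages_contribute_nothing(self):
        panel = two_pop_fixed_panel(L=6)
        est = SupervisedAdmixture(burn_in=300, reps=1500, random_state=3)
        est.fit(panel.dosages, panel.labels)
        # all-missing individual: posterior is the prior, centred on 1/2
        fit = est.estimate(np.full((1, 6), MISSING))
        assert fit.Q.iloc[0, 0] == pytest.approx(0.5, abs=0.06)


class TestUnsupervised:
    def test_separable_populations_zero_misclassification(self, rng):
        panel = two_pop_fixed_panel(L=20, n_per_pop=25)
        est = UnsupervisedAdmixture(K=2, burn_in=300, reps=700, random_state=0)
        est.fit(panel.dosages)
        mis, matching = est.misclassification(panel.labels)
        assert mis == 0.0
        assert set(matching) == {"A", "B"}

    def test_k1_loglik_equals_pooled_binomial(self, rng):
        X = rng.integers(0, 3, size=(40, 15))
        est = UnsupervisedAdmixture(K=1, burn_in=200, reps=2000, random_state=1)
        est.fit(X)
        # closed form at the Beta posterior-mean pooled frequencies
        from scipy.special import comb

        p = (1 + X.sum(axis=0)) / (2 + 2 * X.shape[0])
        ll = (
            X * np.log(p) + (2 - X) * np.log(1 - p)
            + np.log(comb(2, X))
        ).sum()
        # the trace averages over Beta frequency draws, so it sits slightly
        # below the plug-in value (Jensen's inequality)
        assert est.loglik_ == pytest.approx(ll, rel=0.02)
        assert est.loglik_ <= ll

    def test_seeded_runs_agree_after_cluster_matching(self):
        panel = two_pop_fixed_panel(L=20, n_per_pop=20)
        runs = []
        for seed in range(5):
            est = UnsupervisedAdmixture(
                K=2, burn_in=300, reps=700, random_state=seed
            ).fit(panel.dosages)
            _, matching = est.misclassification(panel.labels)
            cols = [matching["A"], matching["B"]]
            runs.append(est.Q_[:, cols])
        for i in range(len(runs)):
            for j in range(i):
                assert np.abs(runs[i] - runs[j]).mean() <= 0.02


class TestNoAdmixture:
    def test_fixed_groups_split_perfectly(self):
        panel = two_pop_fixed_panel(L=15, n_per_pop=12)
        fitres = fit_no_admixture(panel, K=2, cfg=RunConfig(seed=0, burn_in=300, reps=300))
        tab = fitres.membership
        assert tab is not None
        # each self-declared group sits 100% in its own cluster
        assert sorted(tab.max(axis=1).tolist()) == [100.0, 100.0]
        assert tab.idxmax(axis=1)["A"] != tab.idxmax(axis=1)["B"]

    def test_crosstab_rows_sum_to_100(self, rng):
        assignments = rng.integers(0, 4, size=60)
        groups = rng.choice(["x", "y", "z"], size=60)
        tab = crosstab_percent(assignments, groups)
        np.testing.assert_allclose(tab.sum(axis=1), 100.0)

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError, match="K"):
            NoAdmixtureCluster(K=1).fit(np.zeros((4, 3), dtype=int))


class TestDropParentalPopulation:
    def test_k2_guard(self):
        panel = two_pop_fixed_panel()
        with pytest.raises(ValueError, match="K < 2"):
            drop_parental_population(panel, "A")

    def test_absent_population_rejected(self):
        panel = two_pop_fixed_panel()
        with pytest.raises(ValueError, match="not present"):
            drop_parental_population(panel, "Z")

    def test_null_donor_removal_leaves_q_unchanged(self, rng):
        # three pops with distinct frequency profiles; pop C contributes
        # nothing to the study individuals
        L, n = 40, 20
        pA = rng.uniform(0.05, 0.95, L)
        pB = rng.uniform(0.05, 0.95, L)
        pC = rng.uniform(0.05, 0.95, L)
        panel = GenotypeMatrix(
            [f"x{i}" for i in range(3 * n)],
            [f"rs{j}" for j in range(L)],
            np.vstack(
                [rng.binomial(2, p, size=(n, L)) for p in (pA, pB, pC)]
            ),
            labels=["A"] * n + ["B"] * n + ["C"] * n,
        )
        q = 0.7
        # per-copy origins from (q, 1-q, 0) keep the admixture model exact
        study_dos = np.zeros((20, L), dtype=int)
        for _copy in range(2):
            from_a = rng.random((20, L)) < q
            p_copy = np.where(from_a, pA, pB)
            study_dos += rng.random((20, L)) < p_copy
        study = GenotypeMatrix(
            [f"s{i}" for i in range(20)], panel.locus_ids, study_dos
        )
        cfg = RunConfig(seed=4, burn_in=500, reps=1000)
        fit3 = fit_admixture_supervised(study, panel, cfg)
        fit2 = fit_admixture_supervised(
            study, drop_parental_population(panel, "C"), cfg
        )
        dA = abs(fit3.Q["A"].mean() - fit2.Q["A"].mean())
        assert fit3.Q["C"].mean() < 0.12
        assert dA < 0.06
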