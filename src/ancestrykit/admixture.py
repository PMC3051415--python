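"""STRUCTURE-style admixture inference on small SNP panels.

Three estimators share one Gibbs sampler over the classic admixture model
with independent Beta(λ, λ) allele-frequency priors:

* :class:`SupervisedAdmixture` — parental panels with known population
  labels anchor the K allele-frequency vectors; each study individual gets
  a Dirichlet(α)-prior ancestry vector Q on the K-simplex, and every allele
  copy carries a latent continental origin z with
  ``p(z=k) ∝ q_k · p_{k,l}(allele)``.
* :class:`UnsupervisedAdmixture` — no labels; all Q free, the symmetric
  Dirichlet concentration α is itself sampled by a Metropolis step under a
  log-uniform prior (used to validate a marker panel on reference samples).
* :class:`NoAdmixtureCluster` — each individual belongs wholly to one of K
  clusters (the model behind self-declared-vs-genetic cross-tabulations).

Missing dosages contribute no allele copies. All estimators follow the
scikit-learn protocol (``fit`` / ``predict_proba`` / ``get_params``); thin
module-level functions operate directly on :class:`~ancestrykit.io.GenotypeMatrix`
objects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import gammaln
from sklearn.base import BaseEstimator

from .io import MISSING, GenotypeMatrix, RunConfig

_EPS = 1e-300


# ---------------------------------------------------------------------------
# results container
# ---------------------------------------------------------------------------

@dataclass
class AdmixtureFit:
    """Posterior summaries of one admixture run."""

    Q: pd.DataFrame            # n x K posterior-mean ancestry
    ci_low: pd.DataFrame       # per-individual equal-tail credible bounds
    ci_high: pd.DataFrame
    P_hat: pd.DataFrame        # K x L posterior-mean allele-1 frequencies
    loglik_trace: np.ndarray
    alpha_trace: np.ndarray | None = None

    @property
    def populations(self) -> list[str]:
        return list(self.Q.columns)

    def group_summary(
        self, groups: Sequence[str], percentiles: tuple[float, float] = (2.5, 97.5)
    ) -> pd.DataFrame:
        """Mean ancestry per group with empirical percentile intervals taken
        across individuals' posterior-mean ancestries (the interval
        convention behind wide printed group 'CIs')."""
        rows = []
        garr = np.asarray(groups)
        for g in pd.unique(garr):
            sub = self.Q.to_numpy()[garr == g]
            for k, pop in enumerate(self.populations):
                lo, hi = np.percentile(sub[:, k], percentiles)
                rows.append((g, pop, sub[:, k].mean(), lo, hi, len(sub)))
        return pd.DataFrame(
            rows, columns=["group", "population", "mean_q", "pct_low", "pct_high", "n"]
        )


@dataclass
class ClusterFit:
    """No-admixture clustering result."""

    assignments: np.ndarray        # modal cluster per individual
    membership: pd.DataFrame | None  # group x cluster row percentages
    loglik: float
    loglik_trace: np.ndarray | None = None


# ---------------------------------------------------------------------------
# sampler internals
# ---------------------------------------------------------------------------

def _copies(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split dosages into two exchangeable allele copies and a valid mask."""
    valid = dosages != MISSING
    d = np.where(valid, dosages, 0)
    alleles = np.stack([(d >= 1), (d == 2)])  # (2, n, L) allele-1 indicators
    return alleles, valid


def _sample_origins(
    Q: np.ndarray, P: np.ndarray, allele: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw latent origins z for one copy at every (individual, locus)."""
    # weight (n, L, K) = q_ik * p or (1-p)
    pl = np.where(allele[:, :, None], P.T[None, :, :], 1.0 - P.T[None, :, :])
    w = Q[:, None, :] * pl
    cw = np.cumsum(w, axis=2)
    tot = cw[:, :, -1]
    u = rng.random(tot.shape) * np.maximum(tot, _EPS)
    return (u[:, :, None] > cw[:, :, :-1]).sum(axis=2)


def _count(
    z: np.ndarray, allele: np.ndarray, valid: np.ndarray, K: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-individual origin counts and per-(k,l) allele counts of one copy."""
    n, L = z.shape
    li = np.broadcast_to(np.arange(L), (n, L))
    ii = np.broadcast_to(np.arange(n)[:, None], (n, L))
    zv, lv, iv, av = z[valid], li[valid], ii[valid], allele[valid]
    n_ik = np.bincount(iv * K + zv, minlength=n * K).reshape(n, K)
    c_tot = np.bincount(zv * L + lv, minlength=K * L).reshape(K, L)
    c_one = np.bincount(
        zv[av] * L + lv[av], minlength=K * L
    ).reshape(K, L)
    return n_ik, c_one, c_tot


def _loglik(dosages: np.ndarray, Q: np.ndarray, P: np.ndarray) -> float:
    valid = dosages != MISSING
    d = np.where(valid, dosages, 0).astype(float)
    m = np.clip(Q @ P, 1e-12, 1 - 1e-12)
    ll = d * np.log(m) + (2.0 - d) * np.log1p(-m) + np.log(np.where(d == 1, 2.0, 1.0))
    return float(ll[valid].sum())


def _dirichlet_rows(rng: np.random.Generator, alpha: np.ndarray) -> np.ndarray:
    g = rng.gamma(np.maximum(alpha, 1e-12))
    g = np.maximum(g, _EPS)
    return g / g.sum(axis=1, keepdims=True)


def _gibbs_admixture(
    dosages: np.ndarray,
    K: int,
    rng: np.random.Generator,
    burn_in: int,
    reps: int,
    parental_c1: np.ndarray | None = None,
    parental_c0: np.ndarray | None = None,
    fixed_rows: np.ndarray | None = None,
    fixed_Q: np.ndarray | None = None,
    P_fixed: np.ndarray | None = None,
    alpha: float = 1.0,
    update_alpha: bool = False,
    freq_lambda: float = 1.0,
    n_stored: int = 500,
) -> dict:
    """Shared Gibbs core.

    ``parental_c1``/``parental_c0`` are constant allele-count contributions
    of labelled panel individuals (whose origins are fixed by their label);
    ``fixed_rows``/``fixed_Q`` pin a subset of rows of Q (used when parental
    individuals are part of ``dosages``); ``P_fixed`` disables frequency
    updates entirely (used for validation against exact integration).
    """
    n, L = dosages.shape
    alleles, valid = _copies(dosages)
    c1p = np.zeros((K, L)) if parental_c1 is None else parental_c1
    c0p = np.zeros((K, L)) if parental_c0 is None else parental_c0

    Q = np.full((n, K), 1.0 / K)
    if fixed_rows is not None:
        Q[fixed_rows] = fixed_Q
    if P_fixed is not None:
        P = np.asarray(P_fixed, dtype=float)
    else:
        P = rng.beta(freq_lambda + c1p, freq_lambda + c0p)

    total = burn_in + reps
    store_every = max(1, reps // max(1, n_stored))
    q_sum = np.zeros((n, K))
    p_sum = np.zeros((K, L))
    q_draws: list[np.ndarray] = []
    ll_trace = np.empty(reps)
    alpha_trace = np.empty(reps) if update_alpha else None
    kept = 0

    for sweep in range(total):
        n_ik = np.zeros((n, K))
        c1 = np.zeros((K, L))
        c0 = np.zeros((K, L))
        for c in range(2):
            z = _sample_origins(Q, P, alleles[c], rng)
            nik, cone, ctot = _count(z, alleles[c], valid, K)
            n_ik += nik
            c1 += cone
            c0 += ctot - cone
        Q = _dirichlet_rows(rng, alpha + n_ik)
        if fixed_rows is not None:
            Q[fixed_rows] = fixed_Q
        if P_fixed is None:
            P = rng.beta(freq_lambda + c1 + c1p, freq_lambda + c0 + c0p)
            P = np.clip(P, 1e-9, 1 - 1e-9)
        if update_alpha:
            free = np.ones(n, dtype=bool)
            if fixed_rows is not None:
                free[fixed_rows] = False
            alpha = _alpha_metropolis(alpha, Q[free], rng)
        if sweep >= burn_in:
            i = sweep - burn_in
            q_sum += Q
            p_sum += P
            ll_trace[i] = _loglik(dosages, Q, P)
            if update_alpha:
                alpha_trace[i] = alpha
            if i % store_every == 0:
                q_draws.append(Q.copy())
            kept += 1

    draws = np.stack(q_draws)  # (S, n, K)
    return {
        "Q": q_sum / kept,
        "P": p_sum / kept,
        "ci_low": np.percentile(draws, 2.5, axis=0),
        "ci_high": np.percentile(draws, 97.5, axis=0),
        "loglik_trace": ll_trace,
        "alpha_trace": alpha_trace,
        "alpha": alpha,
    }


_ALPHA_RANGE = (1e-2, 10.0)


def _alpha_metropolis(
    alpha: float, Q: np.ndarray, rng: np.random.Generator, step: float = 0.3
) -> float:
    """One Metropolis update of the symmetric Dirichlet concentration under
    a log-uniform prior on [0.01, 10] (log-space random walk, so the
    proposal is symmetric in the sampled coordinate)."""
    prop = math.exp(math.log(alpha) + step * rng.standard_normal())
    lo, hi = _ALPHA_RANGE
    if not lo <= prop <= hi:
        return alpha
    n, K = Q.shape
    lq = np.log(np.clip(Q, 1e-12, None)).sum()

    def loglik(a: float) -> float:
        return n * (gammaln(K * a) - K * gammaln(a)) + (a - 1.0) * lq

    if math.log(rng.random() + 1e-300) < loglik(prop) - loglik(alpha):
        return prop
    return alpha


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def _validate_dosages(X) -> np.ndarray:
    X = np.asarray(X)
    if X.ndim != 2:
        raise ValueError("dosage matrix must be 2-d")
    ok = np.isin(X, (0, 1, 2, MISSING))
    if not ok.all():
        raise ValueError("dosages must be 0, 1, 2 or the missing sentinel")
    return X.astype(np.int64)


class SupervisedAdmixture(BaseEstimator):
    """Supervised admixture: ancestry proportions of study individuals
    against labelled parental panels.

    Parameters
    ----------
    burn_in, reps
        Gibbs sweeps discarded / retained.
    alpha
        Initial symmetric Dirichlet parameter for individual ancestry.
    update_alpha
        When True (default) α is re-sampled each sweep by a Metropolis step
        under a log-uniform hyperprior, as STRUCTURE does; a fixed flat
        prior (α = 1) systematically shrinks strong ancestries toward 1/K
        on panels of a few dozen loci.
    freq_lambda
        Beta(λ, λ) prior on parental allele frequencies.
    update_freqs_from_study
        When True (default) study copies assigned to population k also
        update that population's frequencies; when False only the parental
        panel counts do.
    random_state
        Seed for the sampler.
    """

    def __init__(
        self,
        burn_in: int = 10_000,
        reps: int = 10_000,
        alpha: float = 1.0,
        update_alpha: bool = True,
        freq_lambda: float = 1.0,
        update_freqs_from_study: bool = True,
        n_stored: int = 500,
        random_state: int | None = None,
    ):
        self.burn_in = burn_in
        self.reps = reps
        self.alpha = alpha
        self.update_alpha = update_alpha
        self.freq_lambda = freq_lambda
        self.update_freqs_from_study = update_freqs_from_study
        self.n_stored = n_stored
        self.random_state = random_state

    def fit(self, X, y):
        """Store the parental panel (dosages ``X``, population labels ``y``)."""
        X = _validate_dosages(X)
        y = np.asarray(y)
        if len(y) != X.shape[0]:
            raise ValueError("one population label per parental individual")
        self.populations_ = sorted(pd.unique(y).tolist())
        if len(self.populations_) < 2:
            raise ValueError("at least 2 parental populations are required (K >= 2)")
        self.parental_X_ = X
        self.parental_y_ = y
        valid = X != MISSING
        d = np.where(valid, X, 0)
        K, L = len(self.populations_), X.shape[1]
        c1 = np.zeros((K, L))
        c0 = np.zeros((K, L))
        for k, pop in enumerate(self.populations_):
            rows = y == pop
            c1[k] = d[rows].sum(axis=0)
            c0[k] = 2 * valid[rows].sum(axis=0) - c1[k]
        self.parental_c1_ = c1
        self.parental_c0_ = c0
        self.n_features_in_ = L
        return self

    def estimate(self, X, P_fixed: np.ndarray | None = None) -> AdmixtureFit:
        """Run the joint Gibbs sampler on study dosages ``X`` and return the
        full posterior summary."""
        if not hasattr(self, "parental_c1_"):
            raise ValueError("estimator is not fitted")
        X = _validate_dosages(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("study and parental panels must share the loci")
        rng = np.random.default_rng(self.random_state)
        if P_fixed is None and not self.update_freqs_from_study:
            # freeze frequencies at the parental posterior mean
            P_fixed = _posterior_mean_freqs(
                self.parental_c1_, self.parental_c0_, self.freq_lambda
            )
        out = _gibbs_admixture(
            X,
            K=len(self.populations_),
            rng=rng,
            burn_in=self.burn_in,
            reps=self.reps,
            parental_c1=self.parental_c1_,
            parental_c0=self.parental_c0_,
            P_fixed=P_fixed,
            alpha=self.alpha,
            update_alpha=self.update_alpha,
            freq_lambda=self.freq_lambda,
            n_stored=self.n_stored,
        )
        idx = pd.RangeIndex(X.shape[0])
        cols = self.populations_
        return AdmixtureFit(
            Q=pd.DataFrame(out["Q"], index=idx, columns=cols),
            ci_low=pd.DataFrame(out["ci_low"], index=idx, columns=cols),
            ci_high=pd.DataFrame(out["ci_high"], index=idx, columns=cols),
            P_hat=pd.DataFrame(out["P"], index=cols),
            loglik_trace=out["loglik_trace"],
            alpha_trace=out["alpha_trace"],
        )

    def predict_proba(self, X) -> np.ndarray:
        return self.estimate(X).Q.to_numpy()

    def predict(self, X) -> np.ndarray:
        q = self.predict_proba(X)
        return np.asarray(self.populations_)[q.argmax(axis=1)]


def _posterior_mean_freqs(c1, c0, lam):
    return (lam + c1) / (2 * lam + c1 + c0)


class UnsupervisedAdmixture(BaseEstimator):
    """Label-free admixture with K clusters; the Dirichlet concentration α
    is sampled by Metropolis under a log-uniform prior. Used to validate
    that a marker panel separates reference populations."""

    def __init__(
        self,
        K: int = 4,
        burn_in: int = 10_000,
        reps: int = 10_000,
        alpha_init: float = 1.0,
        freq_lambda: float = 1.0,
        n_stored: int = 500,
        random_state: int | None = None,
    ):
        self.K = K
        self.burn_in = burn_in
        self.reps = reps
        self.alpha_init = alpha_init
        self.freq_lambda = freq_lambda
        self.n_stored = n_stored
        self.random_state = random_state

    def fit(self, X, y=None):
        if self.K < 1:
            raise ValueError("K must be >= 1")
        X = _validate_dosages(X)
        rng = np.random.default_rng(self.random_state)
        out = _gibbs_admixture(
            X,
            K=self.K,
            rng=rng,
            burn_in=self.burn_in,
            reps=self.reps,
            alpha=self.alpha_init,
            update_alpha=self.K > 1,
            freq_lambda=self.freq_lambda,
            n_stored=self.n_stored,
        )
        cols = [f"cluster{k + 1}" for k in range(self.K)]
        idx = pd.RangeIndex(X.shape[0])
        self.fit_ = AdmixtureFit(
            Q=pd.DataFrame(out["Q"], index=idx, columns=cols),
            ci_low=pd.DataFrame(out["ci_low"], index=idx, columns=cols),
            ci_high=pd.DataFrame(out["ci_high"], index=idx, columns=cols),
            P_hat=pd.DataFrame(out["P"], index=cols),
            loglik_trace=out["loglik_trace"],
            alpha_trace=out["alpha_trace"],
        )
        self.Q_ = out["Q"]
        self.P_ = out["P"]
        self.alpha_ = out["alpha"]
        self.loglik_ = float(np.mean(out["loglik_trace"]))
        self.n_features_in_ = X.shape[1]
        return self

    def misclassification(self, labels: Sequence[str]) -> tuple[float, dict[str, int]]:
        """Match clusters to label groups by maximal mean membership and
        return the fraction of individuals whose modal cluster is not their
        group's matched cluster, plus the group->cluster matching."""
        labels = np.asarray(labels)
        groups = sorted(pd.unique(labels).tolist())
        mean_q = np.stack([self.Q_[labels == g].mean(axis=0) for g in groups])
        # optimal one-to-one assignment maximizing mean membership
        gi, ki = linear_sum_assignment(-mean_q)
        matched = dict(zip((groups[i] for i in gi), ki))
        modal = self.Q_.argmax(axis=1)
        wrong = sum(
            modal[i] != matched[labels[i]] for i in range(len(labels))
        )
        return wrong / len(labels), matched


class NoAdmixtureCluster(BaseEstimator):
    """No-admixture clustering: each individual belongs wholly to one of K
    clusters, Gibbs-sampled with a uniform prior over clusters."""

    def __init__(
        self,
        K: int = 4,
        burn_in: int = 2_000,
        reps: int = 2_000,
        freq_lambda: float = 1.0,
        random_state: int | None = None,
    ):
        self.K = K
        self.burn_in = burn_in
        self.reps = reps
        self.freq_lambda = freq_lambda
        self.random_state = random_state

    def fit(self, X, y=None):
        if self.K < 2:
            raise ValueError("K must be >= 2")
        X = _validate_dosages(X)
        n, L = X.shape
        rng = np.random.default_rng(self.random_state)
        valid = X != MISSING
        d = np.where(valid, X, 0).astype(float)

        z = rng.integers(self.K, size=n)
        counts = np.zeros((n, self.K))
        ll_trace = np.empty(self.reps)
        P = rng.random((self.K, L))
        for sweep in range(self.burn_in + self.reps):
            # P | z
            c1 = np.zeros((self.K, L))
            c0 = np.zeros((self.K, L))
            for k in range(self.K):
                rows = z == k
                c1[k] = d[rows].sum(axis=0)
                c0[k] = 2 * valid[rows].sum(axis=0) - c1[k]
            P = np.clip(
                rng.beta(self.freq_lambda + c1, self.freq_lambda + c0), 1e-9, 1 - 1e-9
            )
            # z | P : whole-individual binomial log-likelihood per cluster
            logp = np.log(P)
            log1p = np.log1p(-P)
            ll = d @ logp.T + (2.0 * valid - d) @ log1p.T  # (n, K)
            ll -= ll.max(axis=1, keepdims=True)
            w = np.exp(ll)
            w /= w.sum(axis=1, keepdims=True)
            u = rng.random(n)
            z = (u[:, None] > np.cumsum(w, axis=1)[:, :-1]).sum(axis=1)
            if sweep >= self.burn_in:
                counts[np.arange(n), z] += 1
                m = np.clip(P[z], 1e-12, 1 - 1e-12)
                lb = d * np.log(m) + (2.0 - d) * np.log1p(-m) + np.log(
                    np.where(d == 1, 2.0, 1.0)
                )
                ll_trace[sweep - self.burn_in] = lb[valid].sum()
        self.membership_counts_ = counts
        self.labels_ = counts.argmax(axis=1)
        self.loglik_ = float(ll_trace.mean())
        self.loglik_trace_ = ll_trace
        self.n_features_in_ = L
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


def crosstab_percent(assignments: Sequence[int], groups: Sequence[str]) -> pd.DataFrame:
    """Self-declared group x cluster cross-tabulation as row percentages."""
    df = pd.crosstab(pd.Series(groups, name="group"), pd.Series(assignments, name="cluster"))
    return df.div(df.sum(axis=1), axis=0) * 100.0


# ---------------------------------------------------------------------------
# GenotypeMatrix-level convenience wrappers
# ---------------------------------------------------------------------------

def shared_loci(a: GenotypeMatrix, b: GenotypeMatrix) -> list[str]:
    common = [l for l in a.locus_ids if l in set(b.locus_ids)]
    if not common:
        raise ValueError("no loci shared between the two genotype matrices")
    return common


def fit_admixture_supervised(
    study: GenotypeMatrix,
    parental: GenotypeMatrix,
    cfg: RunConfig | None = None,
    update_freqs_from_study: bool = True,
) -> AdmixtureFit:
    """Supervised admixture of study samples against a labelled parental
    panel, on the shared loci."""
    cfg = cfg or RunConfig()
    if parental.labels is None:
        raise ValueError("parental panel must carry population labels")
    loci = shared_loci(study, parental)
    est = SupervisedAdmixture(
        burn_in=cfg.burn_in,
        reps=cfg.reps,
        update_freqs_from_study=update_freqs_from_study,
        random_state=cfg.seed,
    ).fit(parental.subset_loci(loci).dosages, parental.labels)
    fit = est.estimate(study.subset_loci(loci).dosages)
    fit.Q.index = study.individual_ids
    fit.ci_low.index = study.individual_ids
    fit.ci_high.index = study.individual_ids
    fit.P_hat.columns = loci
    return fit

def fit_admixture_unsupervised(
    panel: GenotypeMatrix, K: int, cfg: RunConfig | None = None
) -> tuple[AdmixtureFit, float | None]:
    """Unsupervised admixture on a reference panel; when the panel carries
    labels the misclassification fraction vs those labels is also returned."""
    cfg = cfg or RunConfig()
    est = UnsupervisedAdmixture(
        K=K, burn_in=cfg.burn_in, reps=cfg.reps, random_state=cfg.seed
    ).fit(panel.dosages)
    mis = None
    if panel.labels is not None and K >= len(set(panel.labels)):
        mis, _ = est.misclassification(panel.labels)
    fit = est.fit_
    fit.Q.index = panel.individual_ids
    fit.ci_low.index = panel.individual_ids
    fit.ci_high.index = panel.individual_ids
    fit.P_hat.columns = panel.locus_ids
    return fit, mis


def fit_no_admixture(
    study: GenotypeMatrix, K: int, cfg: RunConfig | None = None
) -> ClusterFit:
    """No-admixture clustering with the self-declared-vs-cluster cross-tab."""
    cfg = cfg or RunConfig()
    est = NoAdmixtureCluster(
        K=K, burn_in=min(cfg.burn_in, 2000), reps=min(cfg.reps, 2000),
        random_state=cfg.seed,
    ).fit(study.dosages)
    membership = (
        crosstab_percent(est.labels_, study.labels) if study.labels else None
    )
    return ClusterFit(
        assignments=est.labels_,
        membership=membership,
        loglik=est.loglik_,
        loglik_trace=est.loglik_trace_,
    )


def drop_parental_population(
    parental: GenotypeMatrix, population: str
) -> GenotypeMatrix:
    """Remove one labelled parental population (re-running the supervised
    fit with K-1 panels probes how its ancestry share reallocates)."""
    if parental.labels is None or population not in set(parental.labels):
        raise ValueError(f"population {population!r} not present in panel")
    remaining = set(parental.labels) - {population}
    if len(remaining) < 2:
        raise ValueError("removing this population would leave K < 2")
    keep = [i for i, l in enumerate(parental.labels) if l != population]
    return parental.subset_individuals(keep)


# ---------------------------------------------------------------------------
# exact-integration oracle (2 populations, fixed frequencies)
# ---------------------------------------------------------------------------

def exact_posterior_mean_2pop(
    dosages: Sequence[int], P: np.ndarray, grid: int = 20_001
) -> float:
    """Posterior mean of q1 for one individual under the K=2 admixture model
    with *fixed* allele frequencies and a uniform prior on q1, by direct
    numerical integration on a grid — the deterministic yardstick for the
    Gibbs sampler.

    ``P`` is (2, L) allele-1 frequencies; each dosage is Binomial(2, m_l)
    with m_l = q1 p_{1l} + (1-q1) p_{2l}.
    """
    d = np.asarray(dosages, dtype=float)
    P = np.asarray(P, dtype=float)
    q = np.linspace(0.0, 1.0, grid)[:, None]
    m = np.clip(q * P[0][None, :] + (1 - q) * P[1][None, :], 1e-12, 1 - 1e-12)
    obs = d != MISSING
    ll = (d * np.log(m) + (2 - d) * np.log1p(-m))[:, obs].sum(axis=1)
    w = np.exp(ll - ll.max())
    q = q.ravel()
    return float(np.trapezoid(w * q, q) / np.trapezoid(w, q))
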