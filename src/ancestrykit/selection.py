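"""Ancestry-marker panel selection with a genetic algorithm.

The panel fitness is the sum of per-locus informativeness (I_n) over the
chosen subset — loci are treated as unlinked, so panel informativeness is
additive. Chromosomes are fixed-size locus subsets evolved by tournament
selection, uniform crossover repaired back to size m, swap mutation and
elitism; with elitism the best-ever fitness trace is non-decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

from .informativeness import AlleleFrequencyTable, compute_in_all, estimate_frequencies


@dataclass
class GaParams:
    """Genetic-algorithm knobs. ``mutation_rate`` is per gene (per subset
    slot); ``tournament_k`` the tournament size."""

    m: int
    population_size: int = 200
    generations: int = 300
    tournament_k: int = 3
    crossover_rate: float = 0.9
    mutation_rate: float = 0.02
    elitism: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("crossover_rate", "mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.m < 1:
            raise ValueError("subset size m must be >= 1")


def panel_score(freqs: AlleleFrequencyTable, subset: Sequence[str]) -> float:
    """Additive panel informativeness: sum of per-locus I_n over the subset."""
    if len(subset) == 0:
        raise ValueError("subset must be non-empty")
    per_locus = compute_in_all(freqs)
    missing = [l for l in subset if l not in per_locus.index]
    if missing:
        raise KeyError(f"unknown loci: {missing}")
    return float(per_locus[list(subset)].sum())


def ga_select(
    freqs: AlleleFrequencyTable, params: GaParams
) -> tuple[list[str], np.ndarray]:
    """Evolve a size-m locus subset maximizing panel informativeness.

    Returns the best-ever subset (locus ids) and the per-generation
    best-ever fitness trace.
    """
    L = len(freqs.locus_ids)
    if params.m > L:
        raise ValueError(f"m={params.m} exceeds the {L} available loci")
    scores = compute_in_all(freqs).to_numpy()
    if params.m == L:
        return list(freqs.locus_ids), np.array([float(scores.sum())])

    rng = np.random.default_rng(params.seed)
    P, m = params.population_size, params.m
    pop = np.stack([rng.choice(L, size=m, replace=False) for _ in range(P)])
    fit = scores[pop].sum(axis=1)
    best_idx = int(fit.argmax())
    best, best_fit = pop[best_idx].copy(), float(fit[best_idx])
    trace = np.empty(params.generations)

    for gen in range(params.generations):
        # tournament selection of parent indices
        contenders = rng.integers(P, size=(P, params.tournament_k))
        parents = contenders[np.arange(P), fit[contenders].argmax(axis=1)]
        children = pop[parents].copy()
        # uniform crossover on the union, repaired back to size m
        for i in range(0, P - 1, 2):
            if rng.random() < params.crossover_rate:
                a, b = _crossover(children[i], children[i + 1], m, rng)
                children[i], children[i + 1] = a, b
        # swap mutation: replace a member with a non-member
        for i in range(P):
            for j in range(m):
                if rng.random() < params.mutation_rate:
                    members = set(children[i])
                    candidates = np.setdiff1d(np.arange(L), list(members))
                    children[i, j] = rng.choice(candidates)
        cfit = scores[children].sum(axis=1)
        # elitism: best `elitism` of the current population survive
        if params.elitism > 0:
            elite = np.argsort(fit)[-params.elitism:]
            worst = np.argsort(cfit)[: params.elitism]
            children[worst] = pop[elite]
            cfit[worst] = fit[elite]
        pop, fit = children, cfit
        gi = int(fit.argmax())
        if fit[gi] > best_fit:
            best, best_fit = pop[gi].copy(), float(fit[gi])
        trace[gen] = best_fit

    return [freqs.locus_ids[i] for i in sorted(best)], trace


def _crossover(a: np.ndarray, b: np.ndarray, m: int, rng) -> tuple[np.ndarray, np.ndarray]:
    union = np.union1d(a, b)
    inter = np.intersect1d(a, b)
    free = np.setdiff1d(union, inter)
    rng.shuffle(free)
    need = m - len(inter)
    child_a = np.concatenate([inter, free[:need]])
    child_b = np.concatenate([inter, free[len(free) - need:]])
    return child_a.astype(a.dtype), child_b.astype(b.dtype)


def exhaustive_select(
    freqs: AlleleFrequencyTable, m: int
) -> tuple[list[str], float]:
    """Brute-force optimum over all C(L, m) subsets (oracle for small L).

    By additivity this is simply the m loci with the largest I_n, but the
    search enumerates subsets so it stays a genuinely independent check."""
    scores = compute_in_all(freqs).to_numpy()
    best, best_score = None, -np.inf
    for combo in combinations(range(len(scores)), m):
        s = scores[list(combo)].sum()
        if s > best_score:
            best, best_score = combo, s
    return [freqs.locus_ids[i] for i in best], float(best_score)


def sweep_m(
    freqs: AlleleFrequencyTable, m_range: Sequence[int], base: GaParams | None = None
) -> list[tuple[int, float]]:
    """Score-vs-m convenience sweep (the 'minimal panel' stopping rule is
    left to the user)."""
    out = []
    for m in m_range:
        params = GaParams(
            m=m,
            population_size=(base.population_size if base else 100),
            generations=(base.generations if base else 100),
            seed=(base.seed if base else 0) + m,
        )
        subset, trace = ga_select(freqs, params)
        out.append((m, float(trace[-1])))
    return out


class GeneticAlgorithmSelector(SelectorMixin, BaseEstimator):
    """scikit-learn feature selector: keep the m-locus subset maximizing
    panel informativeness, with allele frequencies estimated from labelled
    dosage data at fit time."""

    def __init__(
        self,
        m: int = 24,
        population_size: int = 200,
        generations: int = 300,
        tournament_k: int = 3,
        crossover_rate: float = 0.9,
        mutation_rate: float = 0.02,
        elitism: int = 2,
        random_state: int = 0,
    ):
        self.m = m
        self.population_size = population_size
        self.generations = generations
        self.tournament_k = tournament_k
        self.crossover_rate = crossover_rate
        self.mutation_rate = mutation_rate
        self.elitism = elitism
        self.random_state = random_state

    def fit(self, X, y):
        from .io import GenotypeMatrix

        X = np.asarray(X)
        g = GenotypeMatrix(
            [f"i{i}" for i in range(X.shape[0])],
            [f"l{j}" for j in range(X.shape[1])],
            X,
            labels=list(np.asarray(y, dtype=str)),
        )
        freqs = estimate_frequencies(g)
        params = GaParams(
            m=self.m,
            population_size=self.population_size,
            generations=self.generations,
            tournament_k=self.tournament_k,
            crossover_rate=self.crossover_rate,
            mutation_rate=self.mutation_rate,
            elitism=self.elitism,
            seed=self.random_state,
        )
        subset, trace = ga_select(freqs, params)
        self.subset_ = subset
        self.trace_ = trace
        support = np.zeros(X.shape[1], dtype=bool)
        support[[freqs.locus_ids.index(l) for l in subset]] = True
        self.support_ = support
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self) -> np.ndarray:
        return self.support_
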