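"""Per-locus ancestry informativeness: Rosenberg's I_n, single-population
F_ST, and the regression / prediction-interval procedure used to flag loci
that are anomalously informative for one population pairing relative to
another (the screen that singles out pigmentation-linked SNPs).

I_n is computed in nats, so its upper bound for K populations is exactly
``ln K``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io import MISSING, GenotypeMatrix


@dataclass
class AlleleFrequencyTable:
    """Populations x loci allele-1 frequencies (optionally with the number
    of chromosomes observed)."""

    population_ids: list[str]
    locus_ids: list[str]
    freq: np.ndarray  # (P, L) in [0, 1]
    counts: np.ndarray | None = None  # (P, L) chromosomes observed

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.shape != (len(self.population_ids), len(self.locus_ids)):
            raise ValueError("freq shape does not match population/locus ids")
        if ((self.freq < 0) | (self.freq > 1)).any():
            raise ValueError("allele frequencies must lie in [0, 1]")
        if self.counts is not None:
            self.counts = np.asarray(self.counts)
            if (self.counts < 0).any():
                raise ValueError("chromosome counts must be >= 0")

    def locus_index(self, locus: str) -> int:
        try:
            return self.locus_ids.index(locus)
        except ValueError:
            raise KeyError(f"unknown locus {locus!r}") from None

    def population_index(self, population: str) -> int:
        try:
            return self.population_ids.index(population)
        except ValueError:
            raise KeyError(f"unknown population {population!r}") from None


def estimate_frequencies(
    g: GenotypeMatrix, labels: Sequence[str] | None = None
) -> AlleleFrequencyTable:
    """Allele-1 frequencies by simple allele counting within label groups.

    Missing dosages are excluded from both numerator and denominator.
    """
    labels = list(labels if labels is not None else (g.labels or []))
    if len(labels) != g.n_individuals:
        raise ValueError("one label per individual is required")
    pops = sorted(set(labels))
    lab_arr = np.asarray(labels)
    obs = g.dosages != MISSING
    freq = np.zeros((len(pops), g.n_loci))
    counts = np.zeros((len(pops), g.n_loci), dtype=np.int64)
    for p, pop in enumerate(pops):
        rows = lab_arr == pop
        d = g.dosages[rows]
        m = obs[rows]
        chrom = 2 * m.sum(axis=0)
        allele1 = np.where(m, d, 0).sum(axis=0)
        counts[p] = chrom
        with np.errstate(invalid="ignore"):
            freq[p] = np.where(chrom > 0, allele1 / np.maximum(chrom, 1), np.nan)
    if np.isnan(freq).any():
        raise ValueError("a population has no observed genotypes at some locus")
    return AlleleFrequencyTable(pops, list(g.locus_ids), freq, counts)


# ---------------------------------------------------------------------------
# I_n and single-population F_ST
# ---------------------------------------------------------------------------

def _plogp(p: np.ndarray) -> np.ndarray:
    """x * ln(x) with the 0 * ln 0 = 0 convention."""
    out = np.zeros_like(p, dtype=float)
    nz = p > 0
    out[nz] = p[nz] * np.log(p[nz])
    return out


def compute_in(
    freqs: AlleleFrequencyTable,
    locus: str,
    populations: Sequence[str] | None = None,
) -> float:
    """Informativeness for assignment of one biallelic locus, in nats.

    With per-population allele-j frequencies p_ij and unweighted mean p̄_j
    over the K populations,

        I_n = sum_j [ -p̄_j ln p̄_j + sum_i (p_ij / K) ln p_ij ]

    which is the mutual information between a uniformly chosen population
    and one allele drawn from it; 0 when all populations share frequencies
    and at most ln K.
    """
    pops = populations if populations is not None else freqs.population_ids
    if len(pops) < 2:
        raise ValueError("compute_in requires at least 2 populations")
    li = freqs.locus_index(locus)
    p1 = np.array([freqs.freq[freqs.population_index(p), li] for p in pops])
    return float(_in_from_freqs(p1))


def _in_from_freqs(p1: np.ndarray) -> float:
    """I_n from the K allele-1 frequencies of one biallelic locus."""
    K = len(p1)
    alleles = np.stack([p1, 1.0 - p1])  # (2, K)
    pbar = alleles.mean(axis=1)
    return float((-_plogp(pbar) + _plogp(alleles).sum(axis=1) / K).sum())


def compute_in_all(
    freqs: AlleleFrequencyTable, populations: Sequence[str] | None = None
) -> pd.Series:
    """Vector of I_n over all loci in the table."""
    pops = populations if populations is not None else freqs.population_ids
    rows = [freqs.population_index(p) for p in pops]
    vals = [ _in_from_freqs(freqs.freq[rows, l]) for l in range(len(freqs.locus_ids)) ]
    return pd.Series(vals, index=freqs.locus_ids, name="I_n")


def single_pop_fst(
    freqs: AlleleFrequencyTable, locus: str, focal: str
) -> float:
    """Single-population F_ST of the focal population against the unweighted
    mean frequency over all populations:  (p_f - p̄)² / (p̄ (1 - p̄)),
    defined as 0 when the mean frequency is 0 or 1."""
    if len(freqs.population_ids) < 2:
        raise ValueError("single_pop_fst requires at least 2 populations")
    li = freqs.locus_index(locus)
    pf = freqs.freq[freqs.population_index(focal), li]
    pbar = freqs.freq[:, li].mean()
    denom = pbar * (1.0 - pbar)
    if denom == 0.0:
        return 0.0
    return float((pf - pbar) ** 2 / denom)


# ---------------------------------------------------------------------------
# I_n regression with prediction-interval outlier recovery
# ---------------------------------------------------------------------------

@dataclass
class InRegressionResult:
    """OLS of one set of per-locus I_n values on another, with a symmetric
    prediction interval and per-locus outlier flags.

    ``slope_vs_one_p`` is the two-tailed p-value of H0: slope = 1.
    """

    slope: float
    intercept: float
    r_squared: float
    p_value: float  # of the regression slope vs 0
    slope_vs_one_p: float
    pi_level: float
    table: pd.DataFrame  # x, y, predicted, pi_low, pi_high, outlier, direction

    @property
    def outliers(self) -> list[str]:
        return list(self.table.index[self.table["outlier"]])


def regress_in(
    set_x: pd.Series | Sequence[float],
    set_y: pd.Series | Sequence[float],
    pi_level: float = 0.99,
    locus_ids: Sequence[str] | None = None,
) -> InRegressionResult:
    """Regress per-locus I_n of one population pairing on another and flag
    loci falling outside the ``pi_level`` prediction interval.

    The prediction interval at x is  ŷ ± t_{α/2, n-2} s √(1 + 1/n + (x-x̄)²/Sxx);
    a locus is an outlier iff its y lies outside the band, with the side
    recorded as ``direction``.
    """
    x = np.asarray(set_x, dtype=float)
    y = np.asarray(set_y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("set_x and set_y must be 1-d and aligned")
    n = len(x)
    if n < 3:
        raise ValueError("at least 3 loci are required")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x; regression undefined")
    if locus_ids is None:
        if isinstance(set_x, pd.Series):
            locus_ids = list(set_x.index)
        else:
            locus_ids = [f"locus{i + 1}" for i in range(n)]

    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    intercept, slope = fit.params
    se_slope = fit.bse[1]
    t_one = (slope - 1.0) / se_slope
    slope_vs_one_p = 2.0 * stats.t.sf(abs(t_one), df=n - 2)

    pred = fit.get_prediction(X).summary_frame(alpha=1.0 - pi_level)
    lo = pred["obs_ci_lower"].to_numpy()
    hi = pred["obs_ci_upper"].to_numpy()
    yhat = pred["mean"].to_numpy()
    outlier = (y < lo) | (y > hi)
    direction = np.where(y > hi, "above", np.where(y < lo, "below", ""))

    table = pd.DataFrame(
        {
            "x": x,
            "y": y,
            "predicted": yhat,
            "pi_low": lo,
            "pi_high": hi,
            "outlier": outlier,
            "direction": direction,
        },
        index=pd.Index(locus_ids, name="locus"),
    )
    return InRegressionResult(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(fit.rsquared),
        p_value=float(fit.pvalues[1]),
        slope_vs_one_p=float(slope_vs_one_p),
        pi_level=pi_level,
        table=table,
    )
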