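"""Synthetic cohorts with the statistical structure of a multi-system
continental-ancestry study of U.S. Americans.

Parental panels are drawn under the Balding–Nichols model (population
allele frequencies Beta-distributed around an ancestral frequency with a
per-population divergence parameter F). Study individuals receive Dirichlet
admixture proportions per self-declared group, with optional sampling-region
shifts of the Dirichlet parameter; allele copies then pick a continental
origin from the individual's Q and an allele from that population's
frequency. Uniparental continental origins (NRY for males, mtDNA for all)
are drawn from per-group origin-probability vectors that may differ between
the paternal and maternal system — the sex-biased admixture structure the
analysis is designed to detect — and are dressed as haplogroup labels drawn
from per-continent label pools shipped as package data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .informativeness import AlleleFrequencyTable
from .io import GenotypeMatrix, HaplogroupRecord

CONTINENTS = ("Africa", "Europe", "EastAsia", "America")


def _load_packaged_yaml(name: str) -> dict:
    with resources.files("ancestrykit.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


@dataclass
class GroupSpec:
    """One self-declared study group.

    ``alpha`` is the Dirichlet parameter over the K parental populations;
    ``regions`` maps sampling-region name to its sampling weight and
    ``region_shifts`` adds a per-region offset to ``alpha`` (clipped to stay
    positive) so regional ancestry heterogeneity can be simulated.
    """

    name: str
    n: int
    alpha: tuple[float, ...]
    regions: dict[str, float] | None = None
    region_shifts: dict[str, tuple[float, ...]] | None = None

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError(f"group {self.name}: n must be positive")
        if any(a <= 0 for a in self.alpha):
            raise ValueError(f"group {self.name}: Dirichlet alpha must be > 0")


@dataclass
class SexBias:
    """Continental-origin probabilities of the paternal (NRY) and maternal
    (mtDNA) lineage for one group."""

    nry: tuple[float, ...]
    mt: tuple[float, ...]

    def __post_init__(self) -> None:
        for name, v in (("nry", self.nry), ("mt", self.mt)):
            if abs(sum(v) - 1.0) > 1e-9:
                raise ValueError(f"{name} origin probabilities must sum to 1")


@dataclass
class SimParams:
    """Study-generator configuration; defaults emulate a four-continent
    U.S. cohort design (see :func:`default_study_params`)."""

    L: int = 24
    pop_names: tuple[str, ...] = CONTINENTS
    fst: tuple[float, ...] = (0.20, 0.20, 0.20, 0.25)
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9)
    parental_n: tuple[int, ...] = (100, 160, 230, 64)
    groups: list[GroupSpec] = field(default_factory=list)
    sexbias: dict[str, SexBias] = field(default_factory=dict)
    male_fraction: float = 0.5
    #: when set, L panel loci are ascertained from this many candidate loci
    #: (round-robin top single-population F_ST per population), emulating the
    #: selection of ancestry-informative markers from a genome-wide scan;
    #: None draws L unascertained loci.
    ascertainment_pool: int | None = None
    seed: int = 0

    @property
    def K(self) -> int:
        return len(self.pop_names)

    def __post_init__(self) -> None:
        if len(self.fst) != self.K or len(self.parental_n) != self.K:
            raise ValueError("fst and parental_n must have one entry per population")
        if any(not 0.0 < f < 1.0 for f in self.fst):
            raise ValueError("every F must lie in (0, 1)")
        lo, hi = self.ancestral_freq_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError("ancestral_freq_range must lie within (0, 1)")
        for g in self.groups:
            if len(g.alpha) != self.K:
                raise ValueError(f"group {g.name}: alpha must have K entries")


@dataclass
class SyntheticDataset:
    """Everything the downstream pipeline consumes, plus the ground truth."""

    parental_panel: GenotypeMatrix
    study_samples: GenotypeMatrix
    true_Q: pd.DataFrame  # individuals x populations
    nry_origin: pd.Series  # males only
    mt_origin: pd.Series
    haplogroups: list[HaplogroupRecord]
    parental_freqs: AlleleFrequencyTable


def default_study_params(scale: float = 1.0, L: int = 24, seed: int = 0) -> SimParams:
    """Generator defaults emulating the study design: four HGDP-like
    parental panels, four self-declared U.S. groups with the admixture
    means and sex-biased uniparental origin distributions reported for such
    cohorts, and the published per-region sample sizes for the two groups
    with regional structure. ``scale`` shrinks all sample sizes
    proportionally (minimum 4 per group)."""

    def _n(x: int) -> int:
        return max(4, int(round(x * scale)))

    # Dirichlet means follow the reported group-average ancestry proportions
    # (U.S. Europeans 93.2% European; U.S. Africans 86.2% African; U.S.
    # Hispanics 61.2/14.9/10.8/11.6 Eur/Am/EAs/Afr; U.S. Asians 89.5% E-Asian);
    # concentrations are set so individual spreads resemble the wide reported
    # 2.5-97.5 percentile ranges.
    groups = [
        GroupSpec(
            name="US_African",
            n=_n(246),
            alpha=_alpha((0.862, 0.103, 0.020, 0.015), conc=6.0),
            regions={
                "Baltimore": 34, "Louisville": 21, "Memphis": 41,
                "Miami": 25, "Philadelphia": 104, "Temple": 17,
            },
            region_shifts={
                "Philadelphia": (1.2, -0.3, 0.0, 0.0),
                "Miami": (-0.8, 0.3, 0.0, 0.0),
            },
        ),
        GroupSpec(
            name="US_European",
            n=_n(245),
            alpha=_alpha((0.020, 0.932, 0.028, 0.020), conc=10.0),
        ),
        GroupSpec(
            name="US_Hispanic",
            n=_n(127),
            alpha=_alpha((0.116, 0.612, 0.108, 0.149), conc=3.0),
            regions={"Miami": 61, "Temple": 29, "Killeen": 17, "Philadelphia": 13},
            region_shifts={
                "Miami": (0.3, 0.3, 0.0, -0.25),
                "Temple": (-0.1, -0.4, 0.0, 0.45),
            },
        ),
        GroupSpec(
            name="US_Asian",
            n=_n(46),
            alpha=_alpha((0.015, 0.070, 0.895, 0.020), conc=8.0),
        ),
    ]
    sexbias = {
        "US_African": SexBias(nry=(0.695, 0.297, 0.004, 0.004),
                              mt=(0.927, 0.063, 0.005, 0.005)),
        "US_European": SexBias(nry=(0.025, 0.947, 0.018, 0.010),
                               mt=(0.013, 0.967, 0.010, 0.010)),
        "US_Hispanic": SexBias(nry=(0.213, 0.693, 0.016, 0.078),
                               mt=(0.158, 0.236, 0.118, 0.488)),
        "US_Asian": SexBias(nry=(0.004, 0.014, 0.978, 0.004),
                            mt=(0.004, 0.014, 0.978, 0.004)),
    }
    return SimParams(L=L, groups=groups, sexbias=sexbias, seed=seed,
                     ascertainment_pool=10_000,
                     parental_n=tuple(_n(x) for x in (100, 160, 230, 64)))


def _alpha(mean: tuple[float, ...], conc: float) -> tuple[float, ...]:
    s = sum(mean)
    return tuple(conc * m / s for m in mean)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def draw_parental_freqs(
    params: SimParams, rng: np.random.Generator
) -> AlleleFrequencyTable:
    """Balding–Nichols parental allele frequencies.

    For each locus an ancestral frequency p is uniform on
    ``ancestral_freq_range``; population i draws its frequency from
    Beta(p (1-F_i)/F_i, (1-p)(1-F_i)/F_i), whose mean is p and variance
    p(1-p) F_i.
    """
    lo, hi = params.ancestral_freq_range
    p = rng.uniform(lo, hi, size=params.L)
    freq = np.empty((params.K, params.L))
    for i, F in enumerate(params.fst):
        a = p * (1.0 - F) / F
        b = (1.0 - p) * (1.0 - F) / F
        freq[i] = rng.beta(a, b)
    loci = [f"rs{1000 + l}" for l in range(params.L)]
    return AlleleFrequencyTable(list(params.pop_names), loci, freq)


def ascertained_panel_freqs(
    params: SimParams, rng: np.random.Generator
) -> AlleleFrequencyTable:
    """Panel frequencies after marker ascertainment.

    When ``ascertainment_pool`` is set, a pool of candidate loci is drawn
    under the Balding–Nichols model and the L panel loci are picked
    round-robin as each population's top single-population-F_ST markers —
    a study panel is not a random sample of the genome but the tail of a
    genome-wide scan selected to differentiate each parental population.
    """
    pool = params.ascertainment_pool
    if pool is None or pool <= params.L:
        return draw_parental_freqs(params, rng)
    import dataclasses

    pool_params = dataclasses.replace(params, L=pool, ascertainment_pool=None)
    tab = draw_parental_freqs(pool_params, rng)
    F = tab.freq
    pbar = F.mean(axis=0)
    fst = (F - pbar) ** 2 / np.clip(pbar * (1 - pbar), 1e-12, None)
    per_pop = int(np.ceil(params.L / params.K))
    chosen: list[int] = []
    for k in range(params.K):
        for i in np.argsort(fst[k])[::-1]:
            if len(chosen) >= per_pop * (k + 1) or len(chosen) >= params.L:
                break
            if i not in chosen:
                chosen.append(int(i))
    chosen = sorted(chosen[: params.L])
    return AlleleFrequencyTable(
        list(tab.population_ids),
        [tab.locus_ids[i] for i in chosen],
        F[:, chosen],
    )


def _genotypes_from_freqs(
    freq_rows: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Binomial(2, p) dosages given per-individual-per-locus allele-1 probs."""
    return rng.binomial(2, freq_rows)


def simulate_dataset(
    params: SimParams, rng: np.random.Generator | None = None
) -> SyntheticDataset:
    """Draw a complete synthetic study (parental panel, admixed study
    samples with ground-truth Q, uniparental origins and haplogroup labels)."""
    rng = np.random.default_rng(params.seed) if rng is None else rng
    freqs = ascertained_panel_freqs(params, rng)
    P = freqs.freq  # (K, L)
    pools = _load_packaged_yaml("haplogroup_pools.yaml")

    # parental panel: one binomial draw per individual per locus
    par_ids, par_labels, par_rows = [], [], []
    for i, (pop, n) in enumerate(zip(params.pop_names, params.parental_n)):
        par_rows.append(_genotypes_from_freqs(np.tile(P[i], (n, 1)), rng))
        par_ids.extend(f"{pop}_{j}" for j in range(n))
        par_labels.extend([pop] * n)
    parental = GenotypeMatrix(
        par_ids, list(freqs.locus_ids), np.vstack(par_rows), labels=par_labels
    )

    # study samples
    ids, labels, regions, sexes, q_rows, dos_rows = [], [], [], [], [], []
    nry_origin: dict[str, str] = {}
    mt_origin: dict[str, str] = {}
    hap_records: list[HaplogroupRecord] = []
    for g in params.groups:
        region_names = list(g.regions) if g.regions else [""]
        weights = np.array(
            [g.regions[r] for r in region_names] if g.regions else [1.0], dtype=float
        )
        weights /= weights.sum()
        reg_idx = rng.choice(len(region_names), size=g.n, p=weights)
        alpha = np.asarray(g.alpha, dtype=float)
        q = np.empty((g.n, params.K))
        for i in range(g.n):
            a = alpha.copy()
            shift = (g.region_shifts or {}).get(region_names[reg_idx[i]])
            if shift is not None:
                a = np.clip(a + np.asarray(shift), 1e-3, None)
            q[i] = rng.dirichlet(a)
        # two allele copies: origin ~ Q per copy per locus, allele ~ Bern(p)
        dos = np.zeros((g.n, params.L), dtype=np.int64)
        cum = np.cumsum(q, axis=1)
        for _copy in range(2):
            u = rng.random((g.n, params.L))
            origin = (u[:, :, None] > cum[:, None, :]).sum(axis=2)
            dos += rng.random((g.n, params.L)) < P[origin, np.arange(params.L)]
        male = rng.random(g.n) < params.male_fraction
        sb = params.sexbias.get(g.name)
        for i in range(g.n):
            iid = f"{g.name}_{i}"
            ids.append(iid)
            labels.append(g.name)
            regions.append(region_names[reg_idx[i]])
            sexes.append("M" if male[i] else "F")
            if sb is not None:
                mt_c = params.pop_names[rng.choice(params.K, p=np.asarray(sb.mt))]
                mt_origin[iid] = mt_c
                hap_records.append(
                    HaplogroupRecord(iid, "mtDNA", _draw_label(pools, "mtDNA", mt_c, rng))
                )
                if male[i]:
                    nry_c = params.pop_names[rng.choice(params.K, p=np.asarray(sb.nry))]
                    nry_origin[iid] = nry_c
                    hap_records.append(
                        HaplogroupRecord(iid, "NRY", _draw_label(pools, "NRY", nry_c, rng))
                    )
        q_rows.append(q)
        dos_rows.append(dos)

    all_dos = (
        np.vstack(dos_rows) if dos_rows else np.zeros((0, params.L), dtype=np.int64)
    )
    all_q = np.vstack(q_rows) if q_rows else np.zeros((0, params.K))
    study = GenotypeMatrix(
        ids, list(freqs.locus_ids), all_dos,
        labels=labels or None, region=regions or None, sex=sexes or None,
    )
    true_Q = pd.DataFrame(all_q, index=ids, columns=list(params.pop_names))
    return SyntheticDataset(
        parental_panel=parental,
        study_samples=study,
        true_Q=true_Q,
        nry_origin=pd.Series(nry_origin, name="nry_origin", dtype=object),
        mt_origin=pd.Series(mt_origin, name="mt_origin", dtype=object),
        haplogroups=hap_records,
        parental_freqs=freqs,
    )


def _draw_label(pools: dict, system: str, continent: str, rng) -> str:
    pool = pools[system][continent]
    return pool[rng.integers(len(pool))]


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> None:
    """Write parental/study genotype CSVs, haplogroup CSV and truth CSV."""
    from .io import write_genotype_matrix, write_haplogroup_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_genotype_matrix(ds.parental_panel, out / "parental.csv")
    write_genotype_matrix(ds.study_samples, out / "study.csv")
    write_haplogroup_table(ds.haplogroups, out / "haplogroups.csv")
    ds.true_Q.rename_axis("id").to_csv(out / "true_Q.csv")
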