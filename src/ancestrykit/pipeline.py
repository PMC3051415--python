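"""End-to-end study orchestration on synthetic (or user-supplied) data.

``run_study`` chains the full analysis: simulate → supervised admixture →
no-admixture cross-tabulation → uniparental continental accounting with the
paternal-vs-maternal (sex-bias) exact test → regional heterogeneity tests →
AMOVA on all three systems (plus autosomal AMOVA grouped by uniparental-
derived ancestry) → IBS + non-metric MDS → the informativeness regressions.
Every output surface is a plain DataFrame / scalar collected in a
:class:`StudyReport`; ``write_report`` dumps tidy CSVs plus a JSON manifest
(seed, package version, continent-map checksum).
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .admixture import (
    AdmixtureFit,
    fit_admixture_supervised,
    fit_no_admixture,
)
from .informativeness import compute_in_all, estimate_frequencies, regress_in
from .io import GenotypeMatrix, RunConfig
from .popgen import (
    amova,
    amova_from_distances,
    haplogroup_squared_distances,
    ibs_distance_matrix,
    nmds,
)
from .simulate import SimParams, SyntheticDataset, default_study_params, simulate_dataset
from .uniparental import (
    ContinentMap,
    ancestry_count_table,
    compare_systems,
    regional_heterogeneity,
)


@dataclass
class StudyConfig:
    """Configuration of one full study run. MCMC and permutation sizes
    default to desk-scale values suited to the 24-locus design."""

    sim: SimParams = field(default_factory=default_study_params)
    run: RunConfig = field(default_factory=lambda: RunConfig(burn_in=1500, reps=1500))
    include_uniparental: bool = True
    include_mds: bool = True
    n_perm: int = 1000
    mc_tables: int = 20_000
    mds_max_n: int = 300  # subsample cap for the O(n^2) ordination


@dataclass
class StudyReport:
    """All result surfaces of one run, keyed like the published analysis."""

    group_ancestry: pd.DataFrame          # 3 systems x group x continent
    autosomal_summary: pd.DataFrame       # supervised group means + percentiles
    crosstab: pd.DataFrame                # self-declared x no-admixture cluster (%)
    sexbias_tests: pd.DataFrame           # per-group NRY vs mtDNA exact test
    regional_tests: pd.DataFrame
    amova_rows: pd.DataFrame
    mds_stress: float | None
    regressions: dict[str, Any]
    manifest: dict[str, Any]
    admixture_fit: AdmixtureFit
    dataset: SyntheticDataset


def run_study(config: StudyConfig | None = None, seed: int | None = None) -> StudyReport:
    config = config or StudyConfig()
    if seed is not None:
        config.sim.seed = seed
        config.run.seed = seed
    rng = np.random.default_rng(config.run.seed + 1)

    ds = simulate_dataset(config.sim)
    study, parental = ds.study_samples, ds.parental_panel
    groups = np.asarray(study.labels)
    pops = list(config.sim.pop_names)

    # --- supervised admixture (autosomal system) -----------------------
    fit = fit_admixture_supervised(study, parental, config.run)
    auto_summary = fit.group_summary(groups)

    # --- no-admixture cross-tabulation ---------------------------------
    cluster = fit_no_admixture(study, K=len(pops), cfg=config.run)
    crosstab = cluster.membership

    # --- uniparental accounting + sex-bias tests ------------------------
    rows, sexbias_rows, regional_rows = [], [], []
    for g in pd.unique(groups):
        sub = fit.Q.loc[np.asarray(study.individual_ids)[groups == g]]
        for pop in pops:
            rows.append(("autosomal", g, pop, float(sub[pop].mean())))

    if config.include_uniparental:
        nry_map = ContinentMap.packaged("NRY")
        mt_map = ContinentMap.packaged("mtDNA")
        by_sys_group: dict[str, dict[str, list[str]]] = {"NRY": {}, "mtDNA": {}}
        group_of = dict(zip(study.individual_ids, groups))
        for rec in ds.haplogroups:
            by_sys_group[rec.system].setdefault(
                group_of[rec.individual_id], []
            ).append(rec.haplogroup)
        nry_counts = ancestry_count_table(by_sys_group["NRY"], nry_map)
        mt_counts = ancestry_count_table(by_sys_group["mtDNA"], mt_map)
        for system, counts in (("NRY", nry_counts), ("mtDNA", mt_counts)):
            props = counts / counts.sum(axis=0)
            for g in props.columns:
                for cont in props.index:
                    rows.append((system, g, cont, float(props.loc[cont, g])))
        continents = sorted(set(nry_counts.index) | set(mt_counts.index))
        for g in nry_counts.columns:
            a = nry_counts.reindex(continents, fill_value=0)[g]
            b = mt_counts.reindex(continents, fill_value=0)[g]
            res = compare_systems(a, b, mc_tables=config.mc_tables, rng=rng)
            sexbias_rows.append(
                (g, res.p_value, res.statistic, res.method, res.mc_se)
            )

        # regional heterogeneity of uniparental ancestry (exact test)
        region_of = dict(zip(study.individual_ids, study.region))
        for system, cmap in (("NRY", nry_map), ("mtDNA", mt_map)):
            for g in pd.unique(groups):
                recs = [
                    (region_of[r.individual_id], cmap.resolve(r.haplogroup))
                    for r in ds.haplogroups
                    if r.system == system and group_of[r.individual_id] == g
                ]
                if not recs:
                    continue
                regs = [r for r, _ in recs]
                conts = np.asarray([c for _, c in recs])
                try:
                    stat, p = regional_heterogeneity(
                        conts, regs, min_n=config.run.min_region_n,
                        kind="exact", mc_tables=config.mc_tables, rng=rng,
                    )
                except ValueError:
                    continue
                regional_rows.append((f"{system}:{g}", "exact", stat, p))

    # autosomal regional Kruskal-Wallis on each group's majority component
    region_arr = np.asarray(study.region)
    for g in pd.unique(groups):
        mask = groups == g
        if len(set(region_arr[mask])) < 2:
            continue
        sub = fit.Q.loc[np.asarray(study.individual_ids)[mask]]
        major = sub.mean().idxmax()
        try:
            stat, p = regional_heterogeneity(
                sub[major].to_numpy(), region_arr[mask],
                min_n=config.run.min_region_n, kind="kruskal",
            )
        except ValueError:
            continue
        regional_rows.append((f"autosomal:{g}:{major}", "kruskal", stat, p))

    group_ancestry = pd.DataFrame(
        rows, columns=["system", "group", "continent", "proportion"]
    )
    sexbias = pd.DataFrame(
        sexbias_rows, columns=["group", "p_value", "statistic", "method", "mc_se"]
    )
    regional = pd.DataFrame(
        regional_rows, columns=["test", "kind", "statistic", "p_value"]
    )

    # --- AMOVA rows -----------------------------------------------------
    amova_rows = []
    res = amova(study, groups, n_perm=config.n_perm, rng=rng)
    amova_rows.append(("autosomal|self-declared", res.pct_among, res.phi_st, res.perm_p))
    if config.include_uniparental:
        for system in ("NRY", "mtDNA"):
            recs = [r for r in ds.haplogroups if r.system == system]
            grp_all = np.asarray([group_of[r.individual_id] for r in recs])
            vc = pd.Series(grp_all).value_counts()
            keep = np.isin(grp_all, [g for g in vc.index if vc[g] >= 2])
            if len(set(grp_all[keep])) < 2:
                continue
            labels = np.asarray([r.haplogroup for r in recs])[keep]
            res = amova_from_distances(
                haplogroup_squared_distances(labels), grp_all[keep],
                n_perm=config.n_perm, rng=rng,
            )
            amova_rows.append(
                (f"{system}|self-declared", res.pct_among, res.phi_st, res.perm_p)
            )
        # autosomal variation grouped by uniparental-derived ancestry
        for system, cmap, origin in (
            ("NRY", ContinentMap.packaged("NRY"), "NRY"),
            ("mtDNA", ContinentMap.packaged("mtDNA"), "mtDNA"),
        ):
            recs = [r for r in ds.haplogroups if r.system == system]
            cont_of = {r.individual_id: cmap.resolve(r.haplogroup) for r in recs}
            keep = [i for i, iid in enumerate(study.individual_ids) if iid in cont_of]
            sub = study.subset_individuals(keep)
            grp = [cont_of[iid] for iid in sub.individual_ids]
            vc = pd.Series(grp).value_counts()
            ok = [g for g in vc.index if vc[g] >= 2]
            keep2 = [i for i, g in enumerate(grp) if g in ok]
            if len(set(np.asarray(grp)[keep2])) < 2:
                continue
            res = amova(
                sub.subset_individuals(keep2),
                list(np.asarray(grp)[keep2]),
                n_perm=config.n_perm,
                rng=rng,
            )
            amova_rows.append(
                (f"autosomal|{system}-derived ancestry", res.pct_among, res.phi_st, res.perm_p)
            )
    amova_df = pd.DataFrame(
        amova_rows, columns=["analysis", "pct_among", "phi_st", "perm_p"]
    )

    # --- IBS + NMDS ------------------------------------------------------
    stress = None
    if config.include_mds:
        combined_ids = list(study.individual_ids) + list(parental.individual_ids)
        combined = GenotypeMatrix(
            combined_ids,
            list(study.locus_ids),
            np.vstack([study.dosages, parental.dosages]),
        )
        if combined.n_individuals > config.mds_max_n:
            idx = rng.choice(
                combined.n_individuals, size=config.mds_max_n, replace=False
            )
            combined = combined.subset_individuals(np.sort(idx))
        dist = ibs_distance_matrix(combined, config.run.zero_distance_fill)
        mres = nmds(
            dist, dims=config.run.mds_dims, n_starts=4,
            max_iter=200, random_state=config.run.seed,
        )
        stress = mres.stress

    # --- informativeness regressions (set A/B on set C analogs) ---------
    regressions = _in_regressions(ds, fit, groups, pops, config.run.pi_level)

    manifest = {
        "seed": config.run.seed,
        "version": __version__,
        "python": platform.python_version(),
        "n_study": study.n_individuals,
        "n_parental": parental.n_individuals,
        "L": study.n_loci,
        "continent_map_checksum": (
            ContinentMap.packaged("NRY").checksum()
            if config.include_uniparental else None
        ),
        "sections": {
            "uniparental": config.include_uniparental,
            "mds": config.include_mds,
        },
    }
    return StudyReport(
        group_ancestry=group_ancestry,
        autosomal_summary=auto_summary,
        crosstab=crosstab,
        sexbias_tests=sexbias,
        regional_tests=regional,
        amova_rows=amova_df,
        mds_stress=stress,
        regressions=regressions,
        manifest=manifest,
        admixture_fit=fit,
        dataset=ds,
    )


def _in_regressions(ds, fit, groups, pops, pi_level):
    """Set-pairing informativeness regressions: (study group vs opposite
    parental population) regressed on (parental vs parental)."""
    out: dict[str, Any] = {}
    study = ds.study_samples
    parental = ds.parental_panel
    # parental per-population frequency table
    par_freqs = estimate_frequencies(parental)
    euro_like = "US_European" if "US_European" in groups else None
    afr_like = "US_African" if "US_African" in groups else None
    if euro_like is None or afr_like is None:
        return out

    def _group_freqs(group_name):
        mask = np.asarray(groups) == group_name
        sub = study.subset_individuals(np.flatnonzero(mask))
        return estimate_frequencies(sub, [group_name] * sub.n_individuals)

    def _pair_table(f1, name1, f2, name2):
        from .informativeness import AlleleFrequencyTable

        i1 = f1.population_ids.index(name1)
        i2 = f2.population_ids.index(name2)
        return AlleleFrequencyTable(
            [name1, name2], list(f1.locus_ids),
            np.stack([f1.freq[i1], f2.freq[i2]]),
        )

    set_c = compute_in_all(_pair_table(par_freqs, pops[0], par_freqs, pops[1]))
    set_a = compute_in_all(
        _pair_table(_group_freqs(euro_like), euro_like, par_freqs, pops[0])
    )
    set_b = compute_in_all(
        _pair_table(_group_freqs(afr_like), afr_like, par_freqs, pops[1])
    )
    out["A_on_C"] = regress_in(set_c, set_a, pi_level=pi_level)
    out["B_on_C"] = regress_in(set_c, set_b, pi_level=pi_level)
    out["outliers"] = sorted(
        set(out["A_on_C"].outliers) | set(out["B_on_C"].outliers)
    )
    return out


def write_report(
    report: StudyReport, out_dir: str | Path, plots: bool = False
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if plots:
        from .plotting import plot_ancestry_bars

        plot_ancestry_bars(
            report.admixture_fit.Q,
            report.dataset.study_samples.labels,
            out / "ancestry_bars.png",
        )
    report.group_ancestry.to_csv(out / "group_ancestry.csv", index=False)
    report.autosomal_summary.to_csv(out / "autosomal_summary.csv", index=False)
    if report.crosstab is not None:
        report.crosstab.to_csv(out / "crosstab.csv")
    report.sexbias_tests.to_csv(out / "sexbias_tests.csv", index=False)
    report.regional_tests.to_csv(out / "regional_tests.csv", index=False)
    report.amova_rows.to_csv(out / "amova.csv", index=False)
    report.admixture_fit.Q.rename_axis("id").to_csv(out / "Q_matrix.csv")
    for name in ("A_on_C", "B_on_C"):
        if name in report.regressions:
            report.regressions[name].table.to_csv(out / f"regression_{name}.csv")
    manifest = dict(report.manifest)
    manifest["mds_stress"] = report.mds_stress
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
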