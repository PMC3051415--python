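"""Uniparental (NRY / mtDNA) continental-ancestry accounting.

NRY haplogroups are called by walking a rooted marker phylogeny: an edge is
taken when its defining SNP shows the derived state, and the call is the
deepest node whose entire root path is supported. mtDNA haplogroup labels
are consumed as-is (assignment from sequence is upstream of this package).
Both systems then resolve to continental origin through a longest-prefix
haplogroup->continent map, giving per-group continental ancestry counts that
are compared between systems (sex-bias test) and across sampling regions
with an exact conditional test on the contingency table, full enumeration
when feasible and Monte Carlo otherwise.
"""

from __future__ import annotations

import hashlib
import itertools
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

DERIVED = "D"
ANCESTRAL = "A"


class HaplogroupConflictError(ValueError):
    """Derived states observed on incompatible branches of the tree."""

    def __init__(self, markers: Sequence[str]):
        self.markers = list(markers)
        super().__init__(
            "derived states on incompatible branches: " + ", ".join(self.markers)
        )


@dataclass
class _Node:
    label: str
    marker: str | None  # marker on the edge leading into this node
    parent: "_Node | None"
    children: list["_Node"] = field(default_factory=list)

    def path_markers(self) -> list[str]:
        out, node = [], self
        while node.marker is not None:
            out.append(node.marker)
            node = node.parent
        return out[::-1]

    def depth(self) -> int:
        return len(self.path_markers())


class HaplogroupTree:
    """Rooted marker phylogeny: every edge carries the SNP whose derived
    state defines descent into the child haplogroup."""

    def __init__(self, spec: dict):
        self.root = self._build(spec, parent=None)
        self.by_marker: dict[str, _Node] = {}
        self.by_label: dict[str, _Node] = {}
        for node in self._walk(self.root):
            self.by_label[node.label] = node
            if node.marker is not None:
                if node.marker in self.by_marker:
                    raise ValueError(f"marker {node.marker} appears twice in the tree")
                self.by_marker[node.marker] = node

    @staticmethod
    def _build(spec: dict, parent: "_Node | None") -> _Node:
        node = _Node(label=str(spec["label"]), marker=(
            str(spec["marker"]) if "marker" in spec else None), parent=parent)
        for child in spec.get("children", []):
            node.children.append(HaplogroupTree._build(child, parent=node))
        return node

    @staticmethod
    def _walk(node: _Node):
        yield node
        for c in node.children:
            yield from HaplogroupTree._walk(c)

    @property
    def markers(self) -> set[str]:
        return set(self.by_marker)

    def is_descendant(self, label: str, ancestor_label: str) -> bool:
        node = self.by_label[label]
        while node is not None:
            if node.label == ancestor_label:
                return True
            node = node.parent
        return False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "HaplogroupTree":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    @classmethod
    def packaged(cls) -> "HaplogroupTree":
        """The NRY tree shipped with the package (42 markers)."""
        with resources.files("ancestrykit.data").joinpath("nry_tree.yaml").open() as fh:
            return cls(yaml.safe_load(fh))


def call_haplogroup(
    genotypes: Mapping[str, str | None], tree: HaplogroupTree
) -> tuple[str, list[str]]:
    """Deepest-consistent-node haplogroup call.

    ``genotypes`` maps marker -> state in {"D", "A", None} (derived,
    ancestral, missing; untyped markers may simply be absent). The call is
    the deepest node all of whose root-path markers are derived or missing
    with at least the terminal edge derived; a missing marker therefore does
    not block descent when a deeper derived marker confirms the path. All
    markers ancestral (or missing) calls the root. Derived states on two
    branches where neither is an ancestor of the other raise
    :class:`HaplogroupConflictError`, as does an explicitly ancestral marker
    above a derived one.
    """
    state = {m: s for m, s in genotypes.items() if s is not None}
    unknown = set(state) - tree.markers
    if unknown:
        raise KeyError(f"markers not in tree: {sorted(unknown)}")
    derived_nodes = [tree.by_marker[m] for m, s in state.items() if s == DERIVED]
    if not derived_nodes:
        return tree.root.label, []
    # all derived markers must lie on one root-to-leaf path
    deepest = max(derived_nodes, key=_Node.depth)
    path = set(deepest.path_markers())
    off_path = [n.marker for n in derived_nodes if n.marker not in path]
    if off_path:
        conflict = sorted(off_path + [deepest.marker])
        raise HaplogroupConflictError(conflict)
    # an ancestral (or missing) state on the supporting path does not block
    # descent: the deeper derived marker confirms the path (an explicitly
    # ancestral one is a likely genotyping dropout and is only warned about)
    contradicted = [m for m in deepest.path_markers() if state.get(m) == ANCESTRAL]
    if contradicted:
        import warnings

        warnings.warn(
            f"path markers {contradicted} typed ancestral above derived "
            f"{deepest.marker}; deeper evidence wins",
            stacklevel=2,
        )
    supporting = [m for m in deepest.path_markers() if state.get(m) == DERIVED]
    return deepest.label, supporting


def two_tier_typing(
    genotypes: Mapping[str, str | None],
    core_markers: Iterable[str],
    e_subtype_markers: Iterable[str],
    tree: HaplogroupTree,
    gate_label: str = "E",
) -> tuple[str, list[str]]:
    """Two-tier typing: call on the core marker set first; only when the
    core call falls inside the gate clade (haplogroup E by default) are the
    subtype markers consulted."""
    core = set(core_markers)
    sub = set(e_subtype_markers)
    if core & sub:
        raise ValueError("core and subtype marker sets must be disjoint")
    core_geno = {m: s for m, s in genotypes.items() if m in core}
    label, support = call_haplogroup(core_geno, tree)
    if label not in tree.by_label or not tree.is_descendant(label, gate_label):
        return label, support
    full_geno = {m: s for m, s in genotypes.items() if m in core | sub}
    return call_haplogroup(full_geno, tree)


# ---------------------------------------------------------------------------
# continent mapping and counting
# ---------------------------------------------------------------------------

class ContinentMap:
    """Longest-prefix haplogroup-label -> continent lookup."""

    def __init__(self, mapping: Mapping[str, str]):
        self.mapping = dict(mapping)

    def resolve(self, haplogroup: str) -> str:
        best = None
        for prefix, continent in self.mapping.items():
            if haplogroup.startswith(prefix):
                if best is None or len(prefix) > len(best):
                    best = prefix
        if best is None:
            raise KeyError(f"haplogroup {haplogroup!r} resolves to no continent")
        return self.mapping[best]

    def checksum(self) -> str:
        payload = yaml.safe_dump(self.mapping, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def packaged(cls, system: str) -> "ContinentMap":
        with resources.files("ancestrykit.data").joinpath("continent_map.yaml").open() as fh:
            data = yaml.safe_load(fh)
        if system not in data:
            raise KeyError(f"no packaged continent map for system {system!r}")
        return cls(data[system])

    @classmethod
    def from_yaml(cls, path: str | Path, system: str) -> "ContinentMap":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(data[system])


CONTINENT_ORDER = ("Africa", "Europe", "EastAsia", "America", "other")


def ancestry_proportions(
    haplogroups: Sequence[str], cmap: ContinentMap
) -> pd.DataFrame:
    """Continental-ancestry counts and proportions of one haplogroup list."""
    if len(haplogroups) == 0:
        raise ValueError("empty haplogroup list")
    continents = [cmap.resolve(h) for h in haplogroups]
    counts = pd.Series(continents).value_counts()
    counts = counts.reindex(
        [c for c in CONTINENT_ORDER if c in counts.index]
        + sorted(set(counts.index) - set(CONTINENT_ORDER)),
        fill_value=0,
    )
    return pd.DataFrame(
        {"count": counts, "proportion": counts / counts.sum()}
    ).rename_axis("continent")


def ancestry_count_table(
    haplogroups_by_group: Mapping[str, Sequence[str]], cmap: ContinentMap
) -> pd.DataFrame:
    """Continent x group count table for one uniparental system."""
    cols = {
        g: ancestry_proportions(h, cmap)["count"]
        for g, h in haplogroups_by_group.items()
    }
    return pd.DataFrame(cols).fillna(0).astype(int).rename_axis("continent")


# ---------------------------------------------------------------------------
# exact conditional tests on contingency tables
# ---------------------------------------------------------------------------

@dataclass
class ExactTestResult:
    p_value: float
    statistic: float  # -2 ln(point prob of observed / point prob of modal table)
    method: str  # "enumeration" or "monte_carlo"
    mc_se: float | None = None
    n_tables: int | None = None


def _log_point_prob(table: np.ndarray, lgam_margins: float) -> float:
    # multivariate hypergeometric point probability under fixed margins
    return lgam_margins - sum(math.lgamma(v + 1) for v in table.ravel())


def _margin_lgamma(table: np.ndarray) -> float:
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    n = table.sum()
    return (
        sum(math.lgamma(v + 1) for v in r)
        + sum(math.lgamma(v + 1) for v in c)
        - math.lgamma(n + 1)
    )


def _enumerate_tables(row_margins, col_margins):
    """Yield all non-negative integer tables with the given margins."""
    rows = list(row_margins)

    def rec(remaining_cols, row_idx):
        if row_idx == len(rows) - 1:
            yield [list(remaining_cols)]
            return
        r = rows[row_idx]
        for combo in _compositions(r, remaining_cols):
            rest = tuple(c - x for c, x in zip(remaining_cols, combo))
            for tail in rec(rest, row_idx + 1):
                yield [list(combo)] + tail

    yield from rec(tuple(col_margins), 0)


def _compositions(total, caps):
    """All ways to write ``total`` as a sum over len(caps) cells with cell
    i at most caps[i]."""
    if len(caps) == 1:
        if 0 <= total <= caps[0]:
            yield (total,)
        return
    for x in range(min(total, caps[0]) + 1):
        for rest in _compositions(total - x, caps[1:]):
            yield (x,) + rest


def fisher_exact_rc(
    table: np.ndarray | pd.DataFrame,
    mc_tables: int = 100_000,
    rng: np.random.Generator | None = None,
    max_enumeration: int = 200_000,
) -> ExactTestResult:
    """Exact conditional test of independence on an r x c contingency table.

    The p-value is the total probability, under fixed margins, of tables
    whose multivariate-hypergeometric point probability does not exceed the
    observed table's (the usual Fisher-exact ordering). Full enumeration is
    used when the table space is small; otherwise a Monte-Carlo estimate
    from ``mc_tables`` random tables with fixed margins, with its binomial
    standard error. The reported ``statistic`` is a descriptive, non-
    canonical quantity: -2 ln of the ratio of the observed table's point
    probability to the modal (most probable) table's.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2:
        raise ValueError("table must be 2-d")
    if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
        raise ValueError("degenerate table: all-zero row or column")
    rng = np.random.default_rng() if rng is None else rng
    lgam = _margin_lgamma(t)
    obs_lp = _log_point_prob(t, lgam)
    tol = 1e-9

    rmarg, cmarg = t.sum(axis=1), t.sum(axis=0)
    n_bound = _enumeration_bound(rmarg, cmarg)
    if n_bound <= max_enumeration:
        total, max_lp, count = 0.0, -np.inf, 0
        for tab in _enumerate_tables(rmarg, cmarg):
            lp = _log_point_prob(np.asarray(tab), lgam)
            max_lp = max(max_lp, lp)
            if lp <= obs_lp + tol:
                total += math.exp(lp)
            count += 1
        return ExactTestResult(
            p_value=min(total, 1.0),
            statistic=-2.0 * (obs_lp - max_lp),
            method="enumeration",
            n_tables=count,
        )

    # Monte Carlo: random tables with fixed margins via label permutation
    labels = np.repeat(np.arange(len(cmarg)), cmarg)
    hits = 0
    max_lp = obs_lp
    cuts = np.cumsum(rmarg)[:-1]
    for _ in range(mc_tables):
        rng.shuffle(labels)
        parts = np.split(labels, cuts)
        tab = np.stack([np.bincount(p, minlength=len(cmarg)) for p in parts])
        lp = _log_point_prob(tab, lgam)
        max_lp = max(max_lp, lp)
        if lp <= obs_lp + tol:
            hits += 1
    p = (hits + 1) / (mc_tables + 1)
    se = math.sqrt(p * (1.0 - p) / mc_tables)
    return ExactTestResult(
        p_value=p,
        statistic=-2.0 * (obs_lp - max_lp),
        method="monte_carlo",
        mc_se=se,
    )


def _enumeration_bound(rmarg, cmarg) -> float:
    """Cheap upper bound on the number of tables with the given margins."""
    bound = 1.0
    for r in rmarg[:-1]:
        for c in cmarg[:-1]:
            bound *= min(r, c) + 1
            if bound > 1e12:
                return bound
    return bound


def compare_systems(
    counts_a: pd.Series | Sequence[int],
    counts_b: pd.Series | Sequence[int],
    mc_tables: int = 100_000,
    rng: np.random.Generator | None = None,
) -> ExactTestResult:
    """Test equality of continental-ancestry composition between two
    systems (e.g. NRY vs mtDNA) with the exact conditional test on the
    2 x C system-by-continent table. Continents with zero counts in both
    systems are dropped (they carry no information and would degenerate the
    table)."""
    a = np.asarray(counts_a, dtype=np.int64)
    b = np.asarray(counts_b, dtype=np.int64)
    if a.shape != b.shape:
        raise ValueError("count vectors must share the continent rows")
    keep = (a + b) > 0
    if keep.sum() == 0:
        raise ValueError("degenerate table: no observations")
    return fisher_exact_rc(np.stack([a[keep], b[keep]]), mc_tables=mc_tables, rng=rng)


# ---------------------------------------------------------------------------
# regional heterogeneity
# ---------------------------------------------------------------------------

def regional_heterogeneity(
    values,
    regions: Sequence[str],
    min_n: int = 10,
    kind: str = "kruskal",
    mc_tables: int = 100_000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Test ancestry heterogeneity across sampling regions.

    Only regions with strictly more than ``min_n`` individuals enter the
    test. ``kind="kruskal"`` runs a tie-corrected Kruskal–Wallis test on
    per-individual ancestry fractions (complete ties return H = 0, p = 1);
    ``kind="exact"`` expects categorical continent labels per individual
    and runs the exact conditional test on the region x continent table.
    Returns ``(statistic, p_value)``.
    """
    values = np.asarray(values)
    regions = np.asarray(regions)
    if len(values) != len(regions):
        raise ValueError("values and regions must align")
    keep_regions = [
        r for r, c in pd.Series(regions).value_counts().items() if c > min_n
    ]
    if len(keep_regions) < 2:
        raise ValueError(
            f"fewer than 2 regions exceed min_n={min_n} individuals"
        )
    groups = [values[regions == r] for r in keep_regions]
    if kind == "kruskal":
        flat = np.concatenate(groups)
        if np.all(flat == flat[0]):
            return 0.0, 1.0  # complete ties: no evidence of heterogeneity
        h, p = stats.kruskal(*groups)
        return float(h), float(p)
    if kind == "exact":
        cats = sorted(set(np.concatenate(groups).tolist()))
        tab = np.array(
            [[int(np.sum(g == c)) for c in cats] for g in groups], dtype=np.int64
        )
        tab = tab[:, tab.sum(axis=0) > 0]
        res = fisher_exact_rc(tab, mc_tables=mc_tables, rng=rng)
        return res.statistic, res.p_value
    raise ValueError(f"unknown test kind {kind!r}")
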