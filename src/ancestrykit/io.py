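"""Readers and writers for genotype matrices, haplogroup tables and run configuration.

Two on-disk dialects are supported for diploid genotypes at biallelic SNPs:

* a tidy CSV with one row per individual (``id``, optional ``label``,
  ``region``, ``sex`` columns, then one dosage column per locus; missing
  genotypes are empty cells), and
* the classic STRUCTURE layout with two whitespace-separated rows per
  individual, one allele column per locus, ``-9`` for missing alleles.

Internally both collapse to an integer dosage of a declared reference allele
per locus (0/1/2) with a single missing sentinel.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("ancestrykit")

#: Internal missing-dosage sentinel (matches the STRUCTURE convention).
MISSING = -9

_META_COLS = ("id", "label", "region", "sex")


class GenotypeParseError(ValueError):
    """Raised when an input file cannot be interpreted as genotypes."""


@dataclass
class GenotypeMatrix:
    """Individuals x loci diploid dosages of a reference allele.

    Parameters
    ----------
    individual_ids, locus_ids
        Unique identifiers for rows and columns.
    dosages
        ``(n, L)`` integer array with entries in {0, 1, 2, MISSING}.
    labels, region, sex
        Optional per-individual annotations (self-declared group, sampling
        region, sex code ``"M"``/``"F"``).
    """

    individual_ids: list[str]
    locus_ids: list[str]
    dosages: np.ndarray
    labels: list[str] | None = None
    region: list[str] | None = None
    sex: list[str] | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int64)
        n, L = self.dosages.shape
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match dosage rows")
        if len(self.locus_ids) != L:
            raise ValueError("locus_ids length does not match dosage columns")
        if len(set(self.individual_ids)) != n:
            raise ValueError("individual_ids are not unique")
        if len(set(self.locus_ids)) != L:
            raise ValueError("locus_ids are not unique")
        ok = np.isin(self.dosages, (0, 1, 2, MISSING))
        if not ok.all():
            bad = np.argwhere(~ok)[0]
            raise ValueError(
                f"dosage at individual {self.individual_ids[bad[0]]}, locus "
                f"{self.locus_ids[bad[1]]} is not in {{0,1,2,{MISSING}}}"
            )
        for name in ("labels", "region", "sex"):
            v = getattr(self, name)
            if v is not None and len(v) != n:
                raise ValueError(f"{name} must have one entry per individual")

    # -- basic geometry -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def subset_loci(self, loci: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.locus_ids.index(l) for l in loci]
        return dataclasses.replace(
            self, locus_ids=list(loci), dosages=self.dosages[:, idx]
        )

    def subset_individuals(self, keep: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)

        def _take(v):
            return None if v is None else [v[i] for i in keep]

        return dataclasses.replace(
            self,
            individual_ids=[self.individual_ids[i] for i in keep],
            dosages=self.dosages[keep],
            labels=_take(self.labels),
            region=_take(self.region),
            sex=_take(self.sex),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.dosages, columns=self.locus_ids)
        df.insert(0, "id", self.individual_ids)
        for i, name in enumerate(("label", "region", "sex"), start=1):
            v = getattr(self, {"label": "labels"}.get(name, name))
            if v is not None:
                df.insert(i, name, v)
        return df


@dataclass
class RunConfig:
    """Knobs shared by the stochastic stages of the analysis.

    ``burn_in``/``reps`` are Gibbs sweeps discarded/retained; ``n_runs`` the
    number of replicate chains; ``min_region_n`` the smallest region sample
    size admitted to regional tests (strictly greater than); ``mds_dims``
    the NMDS embedding dimension; ``zero_distance_fill`` the constant used
    for exact-zero IBS distances; ``pi_level`` the prediction-interval level
    for the informativeness regression.
    """

    seed: int = 0
    burn_in: int = 10_000
    reps: int = 10_000
    n_runs: int = 1
    K: int = 4
    min_region_n: int = 10
    mds_dims: int = 3
    zero_distance_fill: float = 0.001
    pi_level: float = 0.99

    def __post_init__(self) -> None:
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if not 0.0 < self.pi_level < 1.0:
            raise ValueError("pi_level must be in (0, 1)")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# genotype readers / writers
# ---------------------------------------------------------------------------

def read_genotype_matrix(
    path: str | Path,
    format: str = "csv",
    ref_alleles: Sequence[int] | None = None,
) -> GenotypeMatrix:
    """Read genotypes from ``csv`` or ``structure_two_row`` files.

    ``ref_alleles`` declares, per locus, which allele code counts toward the
    dosage in the STRUCTURE dialect; by default the numerically smallest
    allele code observed at each locus is the reference.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        return _read_csv(path)
    if format == "structure_two_row":
        return _read_structure(path, ref_alleles)
    raise ValueError(f"unknown genotype format: {format!r}")


def _read_csv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, dtype={"id": str, "label": str, "region": str, "sex": str})
    if "id" not in df.columns:
        raise GenotypeParseError(f"{path}: missing required 'id' column")
    loci = [c for c in df.columns if c not in _META_COLS]
    dos = df[loci].to_numpy(dtype=float)
    dos = np.where(np.isnan(dos), MISSING, dos).astype(np.int64)
    return GenotypeMatrix(
        individual_ids=df["id"].tolist(),
        locus_ids=loci,
        dosages=dos,
        labels=df["label"].tolist() if "label" in df.columns else None,
        region=df["region"].tolist() if "region" in df.columns else None,
        sex=df["sex"].tolist() if "sex" in df.columns else None,
    )


def write_genotype_matrix(g: GenotypeMatrix, path: str | Path) -> None:
    """Write the tidy CSV dialect (missing dosages become empty cells)."""
    df = g.to_frame()
    for l in g.locus_ids:
        df[l] = df[l].astype(object)
        df.loc[df[l] == MISSING, l] = ""
    df.to_csv(path, index=False)


def _read_structure(path: Path, ref_alleles: Sequence[int] | None) -> GenotypeMatrix:
    rows: list[tuple[str, str | None, list[int]]] = []
    n_alleles: int | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            parts = raw.split()
            if not parts:
                continue
            # id [label] a1 a2 ... ; label present when the non-id column
            # count is odd relative to the established locus count
            if n_alleles is None:
                # first line fixes the geometry; assume no label column when
                # every trailing token is an integer and count both ways
                tail = parts[1:]
                if all(_is_int(t) for t in tail):
                    n_alleles = len(tail)
                    rows.append((parts[0], None, [int(t) for t in tail]))
                else:
                    n_alleles = len(tail) - 1
                    rows.append((parts[0], tail[0], [int(t) for t in tail[1:]]))
                continue
            tail = parts[1:]
            if len(tail) == n_alleles:
                label, codes = None, tail
            elif len(tail) == n_alleles + 1:
                label, codes = tail[0], tail[1:]
            else:
                raise GenotypeParseError(
                    f"{path}:{lineno}: expected {n_alleles} allele columns, "
                    f"found {len(tail)}"
                )
            if not all(_is_int(t) for t in codes):
                raise GenotypeParseError(f"{path}:{lineno}: non-integer allele code")
            rows.append((parts[0], label, [int(t) for t in codes]))
    if len(rows) % 2:
        raise GenotypeParseError(f"{path}: odd number of allele rows")

    L = n_alleles or 0
    ids, labels, dosages = [], [], []
    for (id1, lab1, a1), (id2, lab2, a2) in zip(rows[::2], rows[1::2]):
        if id1 != id2:
            raise GenotypeParseError(
                f"{path}: row pair {id1!r}/{id2!r} does not share an id"
            )
        ids.append(id1)
        labels.append(lab1 if lab1 is not None else lab2)
        dosages.append(list(zip(a1, a2)))

    # determine the reference allele per locus and validate biallelism
    dos = np.full((len(ids), L), MISSING, dtype=np.int64)
    for l in range(L):
        seen = sorted(
            {a for row in dosages for a in row[l] if a != MISSING}
        )
        if len(seen) > 2:
            raise ValueError(
                f"locus column {l + 1} has {len(seen)} allele codes {seen}; "
                "only biallelic loci are supported"
            )
        ref = ref_alleles[l] if ref_alleles is not None else (seen[0] if seen else None)
        for i, row in enumerate(dosages):
            pair = row[l]
            if MISSING in pair:
                continue
            dos[i, l] = sum(a == ref for a in pair)
    has_labels = any(lab is not None for lab in labels)
    return GenotypeMatrix(
        individual_ids=ids,
        locus_ids=[f"locus{l + 1}" for l in range(L)],
        dosages=dos,
        labels=[lab or "" for lab in labels] if has_labels else None,
    )


def _is_int(token: str) -> bool:
    try:
        int(token)
    except ValueError:
        return False
    return True


# ---------------------------------------------------------------------------
# haplogroup tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HaplogroupRecord:
    individual_id: str
    system: str  # "NRY" or "mtDNA"
    haplogroup: str


def read_haplogroup_table(
    path: str | Path,
    sex: dict[str, str] | None = None,
) -> list[HaplogroupRecord]:
    """Read a long-format haplogroup CSV (columns id, system, haplogroup).

    NRY records for individuals flagged female in ``sex`` are dropped with a
    warning; duplicate (individual, system) pairs are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str)
    required = {"id", "system", "haplogroup"}
    if not required.issubset(df.columns):
        raise GenotypeParseError(
            f"{path}: haplogroup table needs columns {sorted(required)}"
        )
    bad = set(df["system"]) - {"NRY", "mtDNA"}
    if bad:
        raise ValueError(f"unknown uniparental system(s): {sorted(bad)}")
    dup = df.duplicated(subset=["id", "system"])
    if dup.any():
        first = df[dup].iloc[0]
        raise ValueError(
            f"duplicate haplogroup record for ({first['id']}, {first['system']})"
        )
    records: list[HaplogroupRecord] = []
    for row in df.itertuples(index=False):
        if (
            row.system == "NRY"
            and sex is not None
            and sex.get(row.id, "").upper().startswith("F")
        ):
            warnings.warn(
                f"dropping NRY haplogroup for female-flagged individual {row.id}",
                stacklevel=2,
            )
            logger.warning("dropped NRY record for female individual %s", row.id)
            continue
        records.append(HaplogroupRecord(row.id, row.system, row.haplogroup))
    return records


def write_haplogroup_table(records: Iterable[HaplogroupRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(r.individual_id, r.system, r.haplogroup) for r in records],
        columns=["id", "system", "haplogroup"],
    ).to_csv(path, index=False)
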