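"""Data containers and file formats shared by every pipeline stage.

Three objects travel through the pipeline:

* :class:`ExpressionMatrix` — a genes × samples table of log2 intensities;
* a cohort design table (:class:`CohortDesign`) — one row per array, keyed
  by sample id, carrying patient id, diagnostic group (MDD / nonMDD),
  timepoint (baseline / post), MADRS score and optional covariates;
* :class:`GeneSetCollection` — named regulator → target-gene lists, read
  and written as GMT.

Expression is TSV (first column gene ids, header row sample ids), the
design CSV/TSV, gene sets GMT.  Gene identifiers are matched by exact
string after whitespace stripping; alias resolution is deliberately the
caller's problem.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("MDD", "nonMDD")
TIMEPOINTS = ("baseline", "post")

__all__ = [
    "ExpressionMatrix",
    "CohortDesign",
    "GeneSetCollection",
    "read_expression",
    "write_expression",
    "read_design",
    "read_gmt",
    "write_gmt",
]


class DataValidationError(ValueError):
    """Raised when an input file or container violates the data model."""


@dataclass
class ExpressionMatrix:
    """Genes × samples matrix of log2 expression values.

    Parameters
    ----------
    data : pandas.DataFrame
        Index = gene ids, columns = sample ids, float values.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate gene ids: {dups[:5]}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate sample ids: {dups[:5]}")
        self.data.index = self.data.index.astype(str).str.strip()
        self.data.columns = self.data.columns.astype(str).str.strip()
        self.data = self.data.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)].copy())

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.data.index]
        if missing:
            raise KeyError(f"unknown gene ids: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[list(gene_ids), :].copy())


@dataclass
class CohortDesign:
    """Per-sample metadata table.

    ``table`` is indexed by sample id with columns ``patient_id``,
    ``group`` (MDD/nonMDD), ``timepoint`` (baseline/post), ``madrs`` and
    optionally ``age``, ``sex``, ``bmi``.  Invariants enforced: unique
    (patient, timepoint) pairs, and every post-surgery patient must also
    be present at baseline (longitudinal pairing).
    """

    table: pd.DataFrame

    REQUIRED = ("patient_id", "group", "timepoint", "madrs")
    OPTIONAL = ("age", "sex", "bmi")

    def __post_init__(self) -> None:
        t = self.table
        for col in self.REQUIRED:
            if col not in t.columns:
                raise DataValidationError(f"design is missing required column {col!r}")
        bad_group = set(t["group"]) - set(GROUPS)
        if bad_group:
            raise DataValidationError(
                f"unknown group level(s) {sorted(bad_group)}; allowed: {GROUPS}"
            )
        bad_tp = set(t["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise DataValidationError(
                f"unknown timepoint level(s) {sorted(bad_tp)}; allowed: {TIMEPOINTS}"
            )
        pt = t[["patient_id", "timepoint"]]
        if pt.duplicated().any():
            dup = pt[pt.duplicated()].iloc[0]
            raise DataValidationError(
                f"duplicated (patient, timepoint): ({dup['patient_id']}, {dup['timepoint']})"
            )
        if (t["madrs"] < 0).any():
            raise DataValidationError("negative MADRS score in design")
        base = set(t.loc[t["timepoint"] == "baseline", "patient_id"])
        post = set(t.loc[t["timepoint"] == "post", "patient_id"])
        orphans = post - base
        if orphans:
            raise DataValidationError(
                f"post-surgery sample(s) without baseline: {sorted(orphans)[:5]}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def samples(self, group: str | None = None, timepoint: str | None = None) -> list[str]:
        """Sample ids filtered by group and/or timepoint."""
        mask = pd.Series(True, index=self.table.index)
        if group is not None:
            mask &= self.table["group"] == group
        if timepoint is not None:
            mask &= self.table["timepoint"] == timepoint
        return list(self.table.index[mask])

    def paired_patients(self, group: str | None = None) -> list[str]:
        """Patients with both a baseline and a post-surgery sample."""
        t = self.table if group is None else self.table[self.table["group"] == group]
        base = set(t.loc[t["timepoint"] == "baseline", "patient_id"])
        post = set(t.loc[t["timepoint"] == "post", "patient_id"])
        return sorted(base & post)

    def sample_of(self, patient_id: str, timepoint: str) -> str:
        t = self.table
        hit = t.index[(t["patient_id"] == patient_id) & (t["timepoint"] == timepoint)]
        if len(hit) != 1:
            raise KeyError(f"no unique sample for ({patient_id}, {timepoint})")
        return hit[0]

    @property
    def n_dropouts(self) -> int:
        base = set(self.table.loc[self.table["timepoint"] == "baseline", "patient_id"])
        post = set(self.table.loc[self.table["timepoint"] == "post", "patient_id"])
        return len(base - post)


@dataclass
class GeneSetCollection:
    """Named regulator → ordered, deduplicated target gene lists.

    Optional per-gene expected regulation directions (+1 activation-up /
    −1 activation-down) live in ``directions``; targets without a known
    direction contribute to overlap statistics but not to activation
    z-scores.
    """

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    directions: dict[str, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sets:
            raise DataValidationError("no gene sets")
        for name, genes in self.sets.items():
            if not genes:
                raise DataValidationError(f"gene set {name!r} is empty")
            deduped = list(dict.fromkeys(g.strip() for g in genes))
            self.sets[name] = deduped

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


# ---------------------------------------------------------------------------
# readers / writers


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes × samples TSV into an :class:`ExpressionMatrix`.

    First column holds gene ids, the header row sample ids.  Duplicate
    gene rows (multi-probe genes) are collapsed by the mean and logged;
    duplicate sample columns or non-numeric cells are hard errors.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        while header.startswith("#"):
            header = fh.readline()
    cols = [c.strip() for c in header.rstrip("\n").split("\t")[1:]]
    dups = sorted({c for c in cols if cols.count(c) > 1})
    if dups:
        raise DataValidationError(f"{path.name}: duplicate sample id(s) {dups}")
    raw = pd.read_csv(
        path, sep="\t", index_col=0, comment="#", dtype=str, keep_default_na=False
    )
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        g = bad.any(axis=1).idxmax()
        s = bad.loc[g].idxmax()
        raise DataValidationError(
            f"{path.name}: non-numeric value {raw.loc[g, s]!r} at gene {g!r}, sample {s!r}"
        )
    if numeric.isna().to_numpy().any():
        g = numeric.isna().any(axis=1).idxmax()
        raise DataValidationError(f"{path.name}: missing value in gene row {g!r}")
    numeric.index = numeric.index.astype(str).str.strip()
    if numeric.index.duplicated().any():
        n_dup = int(numeric.index.duplicated().sum())
        logger.info("collapsing %d duplicate gene rows by mean", n_dup)
        numeric = numeric.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(numeric)


def write_expression(m: ExpressionMatrix, path: str | Path, header_comment: str | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        m.data.to_csv(fh, sep="\t", index_label="gene_id")


def read_design(path: str | Path) -> CohortDesign:
    """Read a CSV/TSV cohort design; delimiter sniffed from the header."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if first.count("\t") >= first.count(",") else ","
    t = pd.read_csv(path, sep=sep, comment="#", dtype={"patient_id": str})
    if "sample_id" in t.columns:
        t = t.set_index("sample_id")
    else:
        raise DataValidationError(f"{path.name}: design needs a 'sample_id' column")
    t.index = t.index.astype(str).str.strip()
    return CohortDesign(t)


def write_design(d: CohortDesign, path: str | Path) -> None:
    d.table.to_csv(path, index_label="sample_id")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``name TAB description TAB gene1 TAB gene2 ...``.

    Gene tokens with a ``+``/``-`` suffix (e.g. ``CDKN1A+``) carry an
    expected regulation direction under regulator activation; the suffix
    is stripped from the stored gene id and recorded separately.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    directions: dict[str, dict[str, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataValidationError(
                    f"{path.name}:{lineno}: GMT line needs >=3 tab-separated fields"
                )
            name, desc, *genes = fields
            name = name.strip()
            if name in sets:
                raise DataValidationError(f"{path.name}:{lineno}: duplicate set name {name!r}")
            dirs: dict[str, int] = {}
            cleaned: list[str] = []
            for g in genes:
                g = g.strip()
                if not g:
                    continue
                if g.endswith("+"):
                    g = g[:-1].strip()
                    dirs[g] = +1
                elif g.endswith("-"):
                    g = g[:-1].strip()
                    dirs[g] = -1
                cleaned.append(g)
            if not cleaned:
                raise DataValidationError(f"{path.name}:{lineno}: set {name!r} has no genes")
            sets[name] = cleaned
            descriptions[name] = desc
            if dirs:
                directions[name] = dirs
    if not sets:
        raise DataValidationError(f"{path.name}: no gene sets")
    return GeneSetCollection(sets, descriptions, directions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            dirs = collection.directions.get(name, {})
            toks = [g + ("+" if dirs.get(g) == 1 else "-" if dirs.get(g) == -1 else "") for g in genes]
            fh.write("\t".join([name, desc, *toks]) + "\n")
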