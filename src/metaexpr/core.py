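"""Shared data types, file I/O, validation and probe collapsing.

Every downstream stage consumes :class:`ExpressionCohort` objects — one per
study — holding a log2 gene × sample matrix with case/control labels.
Cohorts failing the inclusion rules (fewer than 3 samples in either group,
or the target gene missing) are rejected before any pooling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class Platform(str, Enum):
    GENECHIP = "genechip"
    RNASEQ = "rnaseq"


class Ethnicity(str, Enum):
    ASIAN = "asian"
    NON_ASIAN = "non_asian"


class Group(str, Enum):
    CASE = "case"
    CONTROL = "control"


def _clean_symbol(symbol: str) -> str:
    """Gene identity = exact symbol match after uppercasing/trimming."""
    return symbol.strip().upper()


@dataclass
class ExpressionCohort:
    """One study's log2 expression matrix plus phenotype and metadata.

    The matrix is stored as a pandas DataFrame (genes × samples); ``group``
    maps each sample id to ``case`` or ``control``.
    """

    cohort_id: str
    values: pd.DataFrame
    group: pd.Series
    platform: Platform = Platform.GENECHIP
    ethnicity: Ethnicity = Ethnicity.NON_ASIAN

    def __post_init__(self) -> None:
        self.platform = Platform(self.platform)
        self.ethnicity = Ethnicity(self.ethnicity)
        self.values.index = [_clean_symbol(g) for g in self.values.index]
        missing = [s for s in self.values.columns if s not in self.group.index]
        if missing:
            raise ValueError(
                f"cohort {self.cohort_id}: samples missing from phenotype: {missing}"
            )
        self.group = self.group.loc[list(self.values.columns)]
        bad = set(self.group.unique()) - {"case", "control"}
        if bad:
            raise ValueError(f"cohort {self.cohort_id}: unknown group labels {sorted(bad)}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def case_mask(self) -> np.ndarray:
        return (self.group.values == "case")

    @property
    def n_case(self) -> int:
        return int(self.case_mask().sum())

    @property
    def n_control(self) -> int:
        return int((~self.case_mask()).sum())

    def case_values(self, gene: str) -> np.ndarray:
        return self.values.loc[_clean_symbol(gene)].values[self.case_mask()].astype(float)

    def control_values(self, gene: str) -> np.ndarray:
        return self.values.loc[_clean_symbol(gene)].values[~self.case_mask()].astype(float)


@dataclass(frozen=True)
class GroupStats:
    """Summary of one group's expression: n, mean, sample SD (n−1)."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style) with an optional background universe."""

    sets: dict[str, tuple[str, list[str]]]
    universe: list[str] | None = None

    def members(self, set_id: str) -> list[str]:
        return self.sets[set_id][1]

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class EdgeList:
    """Undirected, de-duplicated gene–gene interaction edges (no self-loops)."""

    edges: set[frozenset]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "EdgeList":
        edges = set()
        for a, b in pairs:
            a, b = _clean_symbol(a), _clean_symbol(b)
            if a != b:
                edges.add(frozenset((a, b)))
        return cls(edges=edges)

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class ValidationResult:
    accepted: bool
    reasons: list[str] = field(default_factory=list)


def read_expression(
    matrix_path: str | Path,
    phenotype_path: str | Path,
    cohort_id: str = "cohort",
    platform: str = "genechip",
    ethnicity: str = "non_asian",
    log2_transform: bool = False,
) -> ExpressionCohort:
    """Read a gene×sample TSV matrix plus a sample→group phenotype TSV.

    The matrix has a header row of sample ids and gene/probe symbols in the
    first column; duplicate symbols (multi-probe platforms) are collapsed to
    their arithmetic mean. Samples are restricted to those present in both
    files; a matrix sample absent from the phenotype file is an error.
    ``log2_transform`` applies log2(x+1) for matrices on a raw-count scale.
    """
    matrix_path, phenotype_path = Path(matrix_path), Path(phenotype_path)
    df = pd.read_csv(matrix_path, sep="\t", index_col=0,
                     float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    non_numeric = df.columns[[not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]]
    if len(non_numeric):
        col = non_numeric[0]
        bad_rows = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        raise ValueError(
            f"{matrix_path}: non-numeric value at row {bad_rows[0]!r}, column {col!r}"
        )
    if not np.isfinite(df.values).all():
        raise ValueError(f"{matrix_path}: non-finite expression values")

    pheno = pd.read_csv(
        phenotype_path, sep="\t", header=None, names=["sample_id", "group"], dtype=str,
        comment="#",
    )
    if pheno.iloc[0].tolist() == ["sample_id", "group"]:  # tolerate a header row
        pheno = pheno.iloc[1:]
    group = pd.Series(pheno["group"].values, index=pheno["sample_id"].values)

    missing = [s for s in df.columns if s not in group.index]
    if missing:
        raise ValueError(
            f"{phenotype_path}: samples in matrix but not in phenotype: {missing}"
        )
    shared = [s for s in df.columns if s in group.index]
    df = df[shared]
    if log2_transform:
        df = np.log2(df + 1.0)
    cohort = ExpressionCohort(
        cohort_id=cohort_id,
        values=df,
        group=group.loc[shared],
        platform=platform,
        ethnicity=ethnicity,
    )
    return collapse_probes(cohort)


def write_expression(cohort: ExpressionCohort, matrix_path: str | Path,
                     phenotype_path: str | Path) -> None:
    """Inverse of :func:`read_expression`; full-precision TSV round trip."""
    df = cohort.values.copy()
    df.index.name = "gene"
    df.to_csv(matrix_path, sep="\t")  # default float repr round-trips exactly
    pd.DataFrame({"sample_id": cohort.samples,
                  "group": cohort.group.values}).to_csv(
        phenotype_path, sep="\t", header=False, index=False)


def collapse_probes(cohort: ExpressionCohort) -> ExpressionCohort:
    """Collapse duplicate gene rows to their arithmetic mean (idempotent)."""
    if not cohort.values.index.has_duplicates:
        return cohort
    collapsed = cohort.values.groupby(level=0, sort=False).mean()
    return ExpressionCohort(
        cohort_id=cohort.cohort_id,
        values=collapsed,
        group=cohort.group,
        platform=cohort.platform,
        ethnicity=cohort.ethnicity,
    )


def validate(cohort: ExpressionCohort, target_gene: str) -> ValidationResult:
    """Apply the inclusion rules: ≥3 samples per group and target present."""
    reasons = []
    if cohort.n_case < 3 or cohort.n_control < 3:
        reasons.append("sample size <3")
    if _clean_symbol(target_gene) not in set(cohort.values.index):
        reasons.append("target gene absent")
    return ValidationResult(accepted=not reasons, reasons=reasons)


def group_stats(cohort: ExpressionCohort, gene: str) -> tuple[GroupStats, GroupStats]:
    """Per-group n, mean and sample SD (denominator n−1) for one gene."""
    case = cohort.case_values(gene)
    control = cohort.control_values(gene)
    return (
        GroupStats(n=len(case), mean=float(np.mean(case)), sd=float(np.std(case, ddof=1))),
        GroupStats(n=len(control), mean=float(np.mean(control)), sd=float(np.std(control, ddof=1))),
    )


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a tab-separated GMT file: set id, description, member genes."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: malformed GMT line {lineno} (<3 fields)")
            set_id, desc, *members = fields
            seen, dedup = set(), []
            for m in members:
                m = _clean_symbol(m)
                if m and m not in seen:
                    seen.add(m)
                    dedup.append(m)
            if not dedup:
                raise ValueError(f"{path}: GMT line {lineno} has no members")
            sets[set_id] = (desc, dedup)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for set_id, (desc, members) in collection.sets.items():
            fh.write("\t".join([set_id, desc, *members]) + "\n")


def read_edges(path: str | Path) -> EdgeList:
    """Read a 2-column TSV (or whitespace-separated) edge list."""
    pairs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace("\t", " ").split()
            if len(parts) < 2:
                raise ValueError(f"{path}: edge line with <2 fields: {line!r}")
            pairs.append((parts[0], parts[1]))
    return EdgeList.from_pairs(pairs)


@dataclass
class RegistryEntry:
    cohort_id: str
    matrix: Path
    phenotype: Path
    platform: str = "genechip"
    ethnicity: str = "non_asian"


def read_registry(path: str | Path) -> list[RegistryEntry]:
    """Read a cohort registry: JSON array of cohort descriptors with paths
    resolved relative to the registry file."""
    path = Path(path)
    entries = json.loads(path.read_text())
    base = path.parent
    out = []
    for e in entries:
        out.append(RegistryEntry(
            cohort_id=e["cohort_id"],
            matrix=base / e["matrix"],
            phenotype=base / e["phenotype"],
            platform=e.get("platform", "genechip"),
            ethnicity=e.get("ethnicity", "non_asian"),
        ))
    return out


def load_cohorts(registry_path: str | Path, log2_transform: bool = False) -> list[ExpressionCohort]:
    return [
        read_expression(e.matrix, e.phenotype, cohort_id=e.cohort_id,
                        platform=e.platform, ethnicity=e.ethnicity,
                        log2_transform=log2_transform)
        for e in read_registry(registry_path)
    ]
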