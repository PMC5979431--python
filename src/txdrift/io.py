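"""Readers, writers and design validation for expression data.

The pipeline operates on three plain-text inputs:

* an expression matrix — genes in rows, samples in columns, cells are
  RPKM values (TSV or CSV, one header row of sample ids, first column
  gene ids);
* a sample sheet — TSV with columns ``sample_id``, ``tissue``,
  ``cohort``, ``replicate`` describing the multi-cohort design;
* optional gene sets in GMT format (set name, description, members).

Cohorts are stored under canonical labels ``young`` / ``aged`` /
``aged_treated``; the study-style labels ``1W`` / ``4W`` / ``4W-IF`` are
accepted in files and mapped on load.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

logger = logging.getLogger("txdrift")

TISSUES = ("head", "thorax")
COHORTS = ("young", "aged", "aged_treated")

#: built-in mapping from study-style cohort labels to canonical ones.
COHORT_ALIASES: dict[str, str] = {
    "1W": "young",
    "4W": "aged",
    "4W-IF": "aged_treated",
    "young": "young",
    "aged": "aged",
    "aged_treated": "aged_treated",
}

#: canonical -> study-style labels, for display and table headers.
COHORT_DISPLAY: dict[str, str] = {
    "young": "1W",
    "aged": "4W",
    "aged_treated": "4W-IF",
}


class ParseError(ValueError):
    """A cell or line of an input file could not be parsed."""


class ValidationError(ValueError):
    """An input violates a structural invariant of the design."""


class DesignError(ValueError):
    """A requested cohort/tissue combination is absent from the design."""


@dataclass(frozen=True)
class SampleRecord:
    """One sequencing sample: a (tissue, cohort) replicate."""

    sample_id: str
    tissue: str
    cohort: str
    replicate: int

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValidationError(
                f"unknown tissue {self.tissue!r} for sample {self.sample_id!r}; "
                f"expected one of {TISSUES}"
            )
        if self.cohort not in COHORTS:
            raise ValidationError(
                f"unknown cohort {self.cohort!r} for sample {self.sample_id!r}; "
                f"expected one of {COHORTS} (or aliases {list(COHORT_ALIASES)})"
            )
        if self.replicate < 1:
            raise ValidationError(
                f"replicate index must be a positive integer, got "
                f"{self.replicate} for sample {self.sample_id!r}"
            )


@dataclass(frozen=True)
class ContrastDesign:
    """A named cohort-vs-cohort ratio within one tissue.

    The fold change for the contrast is
    ``mean(numerator cohort) / mean(denominator cohort)`` per gene.
    """

    name: str
    numerator_cohort: str
    denominator_cohort: str
    tissue: str

    def __post_init__(self) -> None:
        if self.numerator_cohort == self.denominator_cohort:
            raise ValidationError(
                f"contrast {self.name!r}: numerator and denominator cohorts "
                f"must differ"
            )
        for c in (self.numerator_cohort, self.denominator_cohort):
            if c not in COHORTS:
                raise ValidationError(f"contrast {self.name!r}: unknown cohort {c!r}")
        if self.tissue not in TISSUES:
            raise ValidationError(f"contrast {self.name!r}: unknown tissue {self.tissue!r}")


#: the three standard contrasts of the design, per tissue.
def standard_contrasts(tissue: str) -> tuple[ContrastDesign, ContrastDesign, ContrastDesign]:
    """Aging (4W/1W), treatment (4W/4W-IF) and young/treated (1W/4W-IF)."""
    return (
        ContrastDesign("age", "aged", "young", tissue),
        ContrastDesign("if", "aged", "aged_treated", tissue),
        ContrastDesign("young_treated", "young", "aged_treated", tissue),
    )


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable thresholds and switches of the analysis.

    Parameters
    ----------
    min_rpkm
        Expression filter: a gene is kept only if every sample of the
        tissue exceeds this RPKM value (strict inequality).
    fc_age_cutoff
        Fold-change cutoff for the aging contrast (aged/young); a gene
        changes with age iff fc > cutoff or fc < 1/cutoff (strict).
    fc_if_cutoff
        Fold-change cutoff for the treatment contrast (aged/treated).
    vc_cutoff
        Variance-change cutoff: high-VC iff VZ ratio > cutoff (strict).
        The alternative 3.5 used for the proteolytic gene set is
        supported by setting this field.
    pseudocount
        Added before log2; 0 by default because the >1 RPKM filter
        precedes every logarithm.
    fc_scale
        ``"linear"`` (ratio of cohort mean RPKM, default) or
        ``"geometric"`` (2 ** difference of mean log2 values).
    require_age_change_for_if
        If True, "change with IF" additionally requires the gene to pass
        the age cutoff. Default False: counted independently.
    drift_pool
        ``"samples"`` (pool per-sample drift values; default) or
        ``"cohort_mean"`` (drift of the cohort mean expression).
    epsilon
        Regulariser added to numerator and denominator of VC ratios.
    """

    min_rpkm: float = 1.0
    fc_age_cutoff: float = 1.4
    fc_if_cutoff: float = 1.3
    vc_cutoff: float = 3.75
    pseudocount: float = 0.0
    seed: int = 0
    permutations: int = 999
    fc_scale: str = "linear"
    require_age_change_for_if: bool = False
    drift_pool: str = "samples"
    epsilon: float = 1e-6
    pca_log_scale: bool = True
    cohort_aliases: Mapping[str, str] = field(
        default_factory=lambda: dict(COHORT_ALIASES)
    )

    def __post_init__(self) -> None:
        if self.min_rpkm <= 0:
            raise ValidationError("min_rpkm must be positive")
        for name in ("fc_age_cutoff", "fc_if_cutoff", "vc_cutoff"):
            if getattr(self, name) <= 1:
                raise ValidationError(f"{name} must be > 1")
        if self.pseudocount < 0:
            raise ValidationError("pseudocount must be nonnegative")
        if self.permutations < 1:
            raise ValidationError("permutations must be a positive integer")
        if self.fc_scale not in ("linear", "geometric"):
            raise ValidationError("fc_scale must be 'linear' or 'geometric'")
        if self.drift_pool not in ("samples", "cohort_mean"):
            raise ValidationError("drift_pool must be 'samples' or 'cohort_mean'")
        if self.epsilon <= 0:
            raise ValidationError("epsilon must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        """Load a config from a YAML file; unknown keys are rejected."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ParseError(f"config file {path}: expected a mapping at top level")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(
                f"config file {path}: unknown keys {sorted(unknown)}"
            )
        return cls(**raw)

    def replace(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["cohort_aliases"] = dict(d["cohort_aliases"])
        return d


# ---------------------------------------------------------------------------
# expression matrix


def read_expression_matrix(path: str | Path, dialect: str = "tsv") -> pd.DataFrame:
    """Read a genes x samples RPKM matrix from a TSV/CSV file.

    Returns a DataFrame indexed by gene id with sample ids as columns
    and float64 values. Missing, non-numeric or negative cells and
    duplicate gene ids are rejected with errors naming the offender.
    """
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'csv'")
    path = Path(path)
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate gene ids {dupes}")
    if pd.Index(raw.columns).has_duplicates:
        raise ValidationError(f"{path}: duplicate sample ids in header")
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() | raw.isna()
    if bad.any().any():
        gene, sample = _first_bad_cell(bad)
        cell = raw.loc[gene, sample]
        what = "missing" if pd.isna(cell) else f"non-numeric value {cell!r}"
        raise ParseError(f"{path}: {what} at gene {gene!r}, sample {sample!r}")
    if (values < 0).any().any():
        gene, sample = _first_bad_cell(values < 0)
        raise ParseError(
            f"{path}: negative value {values.loc[gene, sample]} at gene "
            f"{gene!r}, sample {sample!r} (RPKM must be nonnegative)"
        )
    return values.astype(float)


def _first_bad_cell(mask: pd.DataFrame) -> tuple[str, str]:
    stacked = mask.stack()
    gene, sample = stacked[stacked].index[0]
    return str(gene), str(sample)


def write_table(df: pd.DataFrame, path: str | Path, index_label: str | None = None) -> None:
    """Write a table as full-precision TSV with one header row."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index_label=index_label, float_format="%.17g")


def write_expression_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    write_table(matrix, path, index_label="gene")


# ---------------------------------------------------------------------------
# sample sheet


SHEET_COLUMNS = ("sample_id", "tissue", "cohort", "replicate")


def read_sample_sheet(
    path: str | Path, cohort_aliases: Mapping[str, str] | None = None
) -> list[SampleRecord]:
    """Read sample metadata from a TSV file into SampleRecords.

    The ``cohort`` column may use study-style labels (1W/4W/4W-IF) or
    canonical ones; ``cohort_aliases`` overrides the built-in mapping.
    """
    aliases = dict(COHORT_ALIASES if cohort_aliases is None else cohort_aliases)
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: sample sheet missing columns {missing}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"{path}: duplicate sample_id {dupes}")
    records = []
    for _, row in df.iterrows():
        cohort = row["cohort"]
        if cohort not in aliases:
            raise ValidationError(
                f"{path}: unknown cohort label {cohort!r} for sample "
                f"{row['sample_id']!r}; known labels: {sorted(aliases)}"
            )
        try:
            rep = int(row["replicate"])
        except (TypeError, ValueError):
            raise ParseError(
                f"{path}: non-integer replicate {row['replicate']!r} for "
                f"sample {row['sample_id']!r}"
            ) from None
        records.append(
            SampleRecord(
                sample_id=row["sample_id"],
                tissue=row["tissue"],
                cohort=aliases[cohort],
                replicate=rep,
            )
        )
    _check_replicate_uniqueness(records, source=str(path))
    return records


def _check_replicate_uniqueness(records: list[SampleRecord], source: str = "") -> None:
    seen: dict[tuple[str, str, int], str] = {}
    for r in records:
        key = (r.tissue, r.cohort, r.replicate)
        if key in seen:
            raise ValidationError(
                f"{source}: replicate index {r.replicate} duplicated within "
                f"({r.tissue}, {r.cohort}): samples {seen[key]!r} and {r.sample_id!r}"
            )
        seen[key] = r.sample_id


def write_sample_sheet(records: list[SampleRecord], path: str | Path) -> None:
    df = samples_to_frame(records)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def samples_to_frame(records: list[SampleRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.sample_id, r.tissue, r.cohort, r.replicate) for r in records],
        columns=list(SHEET_COLUMNS),
    )


def select_samples(
    records: list[SampleRecord], tissue: str, cohort: str | None = None
) -> list[SampleRecord]:
    """Samples of a tissue (and optionally one cohort), in sheet order."""
    out = [
        r
        for r in records
        if r.tissue == tissue and (cohort is None or r.cohort == cohort)
    ]
    return out


def cohort_sample_ids(records: list[SampleRecord], tissue: str, cohort: str) -> list[str]:
    ids = [r.sample_id for r in select_samples(records, tissue, cohort)]
    if not ids:
        raise DesignError(f"no samples for cohort {cohort!r} in tissue {tissue!r}")
    return ids


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gene_sets(path: str | Path) -> dict[str, list[str]]:
    """Read gene sets from a GMT file (name, description, members...).

    Duplicate members within a set are dropped (first occurrence kept);
    empty sets are skipped with a warning.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ParseError(
                f"{path}:{lineno}: malformed GMT line (need name, description, members)"
            )
        name = parts[0]
        members = [m for m in parts[2:] if m]
        if not members:
            warnings.warn(f"{path}:{lineno}: gene set {name!r} is empty; skipped")
            continue
        if name in sets:
            raise ValidationError(f"{path}:{lineno}: duplicate gene set name {name!r}")
        sets[name] = list(dict.fromkeys(members))
    return sets


# ---------------------------------------------------------------------------
# dataset validation


@dataclass
class ValidationReport:
    """Cross-check of matrix columns against the sample sheet."""

    matrix_only: list[str]
    sheet_only: list[str]

    @property
    def ok(self) -> bool:
        return not self.matrix_only and not self.sheet_only

    def __str__(self) -> str:
        if self.ok:
            return "dataset OK: matrix columns and sample sheet agree"
        lines = []
        if self.matrix_only:
            lines.append(f"samples in matrix but not in sheet: {self.matrix_only}")
        if self.sheet_only:
            lines.append(f"samples in sheet but not in matrix: {self.sheet_only}")
        return "; ".join(lines)


def validate_dataset(matrix: pd.DataFrame, samples: list[SampleRecord]) -> ValidationReport:
    """Report sample-id mismatches between matrix and sheet (order-insensitive)."""
    matrix_ids = set(matrix.columns)
    sheet_ids = {r.sample_id for r in samples}
    return ValidationReport(
        matrix_only=sorted(matrix_ids - sheet_ids),
        sheet_only=sorted(sheet_ids - matrix_ids),
    )
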