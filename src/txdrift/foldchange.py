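"""Contrast fold changes, differential tests and category classification.

Fold changes are linear ratios of cohort mean RPKM. The two thresholds
of the design are applied symmetrically and strictly: a gene "changes"
in a contrast iff fc > cutoff or fc < 1/cutoff.

Sign convention (the error-prone one): the treatment contrast is
aged/treated (4W/4W-IF). "IF Up" — expression restored UPWARD by the
treatment — therefore means fc_if < 1/cutoff (the treated cohort
exceeds the aged one), and "IF Down" means fc_if > cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import (
    AnalysisConfig,
    ContrastDesign,
    DesignError,
    SampleRecord,
    cohort_sample_ids,
)
from .preprocess import log2_matrix

__all__ = [
    "CategoryCounts",
    "cohort_means",
    "fold_change_contrast",
    "differential_test",
    "classify_flags",
    "classify_genes",
    "summarize_categories",
]


def cohort_means(
    matrix: pd.DataFrame,
    samples: list[SampleRecord],
    tissue: str,
    cohort: str,
) -> pd.Series:
    """Arithmetic mean RPKM across the cohort's replicates, per gene."""
    ids = cohort_sample_ids(samples, tissue, cohort)
    return matrix[ids].mean(axis=1)


def fold_change_contrast(
    matrix: pd.DataFrame,
    samples: list[SampleRecord],
    contrast: ContrastDesign,
    scale: str = "linear",
) -> pd.Series:
    """Per-gene fold change for a contrast.

    ``scale="linear"`` (default): ratio of arithmetic cohort means.
    ``scale="geometric"``: 2 ** (mean log2 numerator - mean log2
    denominator), i.e. the ratio of geometric means.
    """
    num = cohort_sample_ids(samples, contrast.tissue, contrast.numerator_cohort)
    den = cohort_sample_ids(samples, contrast.tissue, contrast.denominator_cohort)
    if scale == "linear":
        num_mean = matrix[num].mean(axis=1)
        den_mean = matrix[den].mean(axis=1)
        if (den_mean <= 0).any():
            raise ValueError(
                f"contrast {contrast.name!r}: nonpositive denominator mean; "
                "apply the expression filter first"
            )
        fc = num_mean / den_mean
    elif scale == "geometric":
        log2m = log2_matrix(matrix)
        fc = np.exp2(log2m[num].mean(axis=1) - log2m[den].mean(axis=1))
    else:
        raise ValueError(f"unknown fc scale {scale!r}")
    fc.name = f"fc_{contrast.name}"
    return fc


def differential_test(
    matrix: pd.DataFrame,
    samples: list[SampleRecord],
    contrast: ContrastDesign,
) -> pd.Series:
    """Two-sided Welch t-test on log2 values, per gene.

    An unequal-variance location test is the minimal defensible choice
    at 2-3 replicates; p-values are raw (no multiplicity adjustment is
    applied here). A cohort with a single replicate yields all-NaN
    p-values with a warning rather than an error, since duplicate
    designs are the supported minimum.
    """
    num = cohort_sample_ids(samples, contrast.tissue, contrast.numerator_cohort)
    den = cohort_sample_ids(samples, contrast.tissue, contrast.denominator_cohort)
    if min(len(num), len(den)) < 2:
        warnings.warn(
            f"contrast {contrast.name!r}: a cohort has a single replicate; "
            "p-values reported as missing"
        )
        return pd.Series(np.nan, index=matrix.index, name=f"p_{contrast.name}")
    a = log2_matrix(matrix[num]).to_numpy()
    b = log2_matrix(matrix[den]).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    # identical value multisets give 0/0 -> NaN; no evidence of change
    p = np.where(np.isnan(p), 1.0, p)
    return pd.Series(p, index=matrix.index, name=f"p_{contrast.name}")


def classify_flags(
    fc_age: pd.Series, fc_if: pd.Series, config: AnalysisConfig
) -> pd.DataFrame:
    """Boolean category flags from the two fold-change vectors.

    All cutoffs are strict (">"): a gene sitting exactly on a cutoff is
    not flagged. ``youthful`` marks genes whose age-direction change is
    reversed by the treatment.
    """
    for name, fc in (("fc_age", fc_age), ("fc_if", fc_if)):
        if (np.asarray(fc) <= 0).any():
            raise ValueError(f"{name}: fold changes must be strictly positive")
    c_age = config.fc_age_cutoff
    c_if = config.fc_if_cutoff
    age_up = fc_age > c_age
    age_down = fc_age < 1.0 / c_age
    if_down = fc_if > c_if  # aged exceeds treated: treatment lowers it back
    if_up = fc_if < 1.0 / c_if  # treated exceeds aged: treatment restores upward
    if config.require_age_change_for_if:
        changed = age_up | age_down
        if_down = if_down & changed
        if_up = if_up & changed
    flags = pd.DataFrame(
        {
            "age_up": age_up,
            "age_down": age_down,
            "if_up": if_up,
            "if_down": if_down,
        }
    )
    flags["youthful"] = (age_down & if_up) | (age_up & if_down)
    return flags


def classify_genes(
    matrix: pd.DataFrame,
    samples: list[SampleRecord],
    tissue: str,
    config: AnalysisConfig,
) -> pd.DataFrame:
    """Per-gene fold-change records for one tissue.

    Returns a DataFrame indexed by gene with columns fc_age, log2_fc_age,
    p_age, q_age, fc_if, log2_fc_if, p_if, q_if and the category flags.
    The q columns are Benjamini-Hochberg adjusted p-values, reported for
    reference only — classification uses the fold-change cutoffs, not p.
    """
    from statsmodels.stats.multitest import multipletests

    age, iff, _ = _standard(tissue)
    fc_age = fold_change_contrast(matrix, samples, age, scale=config.fc_scale)
    fc_if = fold_change_contrast(matrix, samples, iff, scale=config.fc_scale)
    p_age = differential_test(matrix, samples, age)
    p_if = differential_test(matrix, samples, iff)
    records = pd.DataFrame(
        {
            "fc_age": fc_age,
            "log2_fc_age": np.log2(fc_age),
            "p_age": p_age,
            "q_age": _bh(p_age, multipletests),
            "fc_if": fc_if,
            "log2_fc_if": np.log2(fc_if),
            "p_if": p_if,
            "q_if": _bh(p_if, multipletests),
        }
    )
    flags = classify_flags(fc_age, fc_if, config)
    return pd.concat([records, flags], axis=1)


def _standard(tissue: str):
    from .io import standard_contrasts

    return standard_contrasts(tissue)


def _bh(p: pd.Series, multipletests) -> pd.Series:
    if p.isna().all():
        return p
    out = p.copy()
    mask = p.notna()
    out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


@dataclass(frozen=True)
class CategoryCounts:
    """Gene counts in the seven-column layout of the fold-change table."""

    change_with_age: int
    age_down: int
    age_up: int
    change_with_if: int
    age_down_if_up: int
    age_up_if_down: int
    if_more_youthful: int

    def __post_init__(self) -> None:
        if self.change_with_age != self.age_down + self.age_up:
            raise ValueError("change_with_age must equal age_down + age_up")
        if self.if_more_youthful != self.age_down_if_up + self.age_up_if_down:
            raise ValueError(
                "if_more_youthful must equal age_down_if_up + age_up_if_down"
            )

    COLUMNS = (
        "change_with_age",
        "age_down",
        "age_up",
        "change_with_if",
        "age_down_if_up",
        "age_up_if_down",
        "if_more_youthful",
    )

    @classmethod
    def from_flags(cls, flags: pd.DataFrame) -> "CategoryCounts":
        age_down = int(flags["age_down"].sum())
        age_up = int(flags["age_up"].sum())
        down_up = int((flags["age_down"] & flags["if_up"]).sum())
        up_down = int((flags["age_up"] & flags["if_down"]).sum())
        return cls(
            change_with_age=age_down + age_up,
            age_down=age_down,
            age_up=age_up,
            change_with_if=int((flags["if_up"] | flags["if_down"]).sum()),
            age_down_if_up=down_up,
            age_up_if_down=up_down,
            if_more_youthful=down_up + up_down,
        )

    def to_frame(self, label: str = "") -> pd.DataFrame:
        row = {c: getattr(self, c) for c in self.COLUMNS}
        return pd.DataFrame([row], index=[label or "counts"])


def summarize_categories(records: pd.DataFrame) -> CategoryCounts:
    """Tally classified records into CategoryCounts."""
    return CategoryCounts.from_flags(records)
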