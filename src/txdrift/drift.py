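"""Transcriptional drift, drift-variance (TD), VZ/VC statistics.

Transcriptional drift measures how far each sample's expression has
moved from a young baseline:

    d(g, s) = log10( x(g, s) / mean over young replicates of gene g )

The drift-variance of a cohort (TD) is the variance of d pooled across
all genes and all of the cohort's replicates. TD rises with age as
between-replicate regulation loosens, and an effective intervention
pulls it back toward the young value.

Per-gene dispersion is summarised by the variance Z score
VZ = SD / mean of replicate RPKM (the coefficient of variation, n-1 SD),
and the variance change between two cohorts by the VC ratio of their VZ
values. Genes whose VC exceeds a strict cutoff are "high-VC".

Significance of a TD difference between two cohorts is assessed by a
gene-level permutation test: drift values are gene-wise dependent within
a sample and heavy-tailed, so genes — not individual values — are the
exchangeable units. For each permutation every gene independently swaps
its two cohorts' drift vectors; the statistic is the absolute TD
difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import (
    AnalysisConfig,
    DesignError,
    SampleRecord,
    cohort_sample_ids,
    select_samples,
    standard_contrasts,
)

__all__ = [
    "DriftSummary",
    "compute_drift",
    "drift_variance_summary",
    "drift_variance_test",
    "compute_vz",
    "variance_change",
    "classify_variance",
    "scaled_vz_profile",
]


def compute_drift(
    matrix: pd.DataFrame,
    samples: list[SampleRecord],
    tissue: str,
    reference_cohort: str = "young",
) -> pd.DataFrame:
    """Per-(gene, sample) drift against the reference-cohort mean.

    Expects the filtered (all-positive) matrix of one tissue. Returns a
    genes x samples DataFrame of d values covering every sample of the
    tissue, reference replicates included (their drift is centred near
    zero by construction).
    """
    ref_ids = cohort_sample_ids(samples, tissue, reference_cohort)
    tissue_ids = [r.sample_id for r in select_samples(samples, tissue)]
    sub = matrix[tissue_ids]
    ref_mean = sub[ref_ids].mean(axis=1)
    if (ref_mean <= 0).any():
        raise ValueError(
            "reference cohort has nonpositive gene means; apply the "
            "expression filter first"
        )
    return np.log10(sub.div(ref_mean, axis=0))


def _pool(
    drift: pd.DataFrame, samples: list[SampleRecord], tissue: str, cohort: str, how: str
) -> np.ndarray:
    ids = cohort_sample_ids(samples, tissue, cohort)
    if how == "samples":
        return drift[ids].to_numpy().ravel()
    if how == "cohort_mean":
        return drift[ids].mean(axis=1).to_numpy()
    raise ValueError(f"unknown drift pooling {how!r}")


@dataclass(frozen=True)
class DriftSummary:
    """Pooled drift distribution of one cohort."""

    cohort: str
    n_genes: int
    n_values: int
    drift_variance: float
    q1: float
    median: float
    q3: float

    def to_row(self) -> dict:
        return {
            "cohort": self.cohort,
            "n_genes": self.n_genes,
            "n_values": self.n_values,
            "drift_variance": self.drift_variance,
            "q1": self.q1,
            "median": self.median,
            "q3": self.q3,
        }


def drift_variance_summary(
    drift: pd.DataFrame,
    samples: list[SampleRecord],
    tissue: str,
    cohort: str,
    pool: str = "samples",
) -> DriftSummary:
    """TD of one cohort: variance of pooled drift values, plus quartiles.

    Pooling is across all genes and the cohort's replicates
    (``pool="samples"``, the drift-plot construction) or across the
    per-gene drift of the cohort mean (``pool="cohort_mean"``). Sample
    variance (n-1).
    """
    values = _pool(drift, samples, tissue, cohort, pool)
    if values.size == 0:
        raise DesignError(f"empty drift pool for cohort {cohort!r}")
    var = float(np.var(values, ddof=1)) if values.size > 1 else 0.0
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return DriftSummary(
        cohort=cohort,
        n_genes=drift.shape[0],
        n_values=int(values.size),
        drift_variance=var,
        q1=float(q1),
        median=float(med),
        q3=float(q3),
    )


def _pooled_variance_from_sums(s: np.ndarray, ss: np.ndarray, n: int) -> np.ndarray:
    """Sample variance of a pooled set given per-gene sums/sumsquares."""
    total = s.sum(axis=-1)
    total_ss = ss.sum(axis=-1)
    return (total_ss - total**2 / n) / (n - 1)


def drift_variance_test(
    drift: pd.DataFrame,
    samples: list[SampleRecord],
    tissue: str,
    cohort_a: str,
    cohort_b: str,
    permutations: int = 999,
    seed: int = 0,
    pool: str = "samples",
) -> float:
    """Permutation p-value for equal drift dispersion of two cohorts.

    Statistic: |TD(a) - TD(b)| of the pooled drift values. Null
    resampling swaps, gene by gene, the pair of per-cohort drift vectors
    between the two cohort labels (each gene flips with probability 1/2),
    preserving the within-gene dependence structure. With add-one
    smoothing, p = (1 + #{permuted >= observed}) / (1 + permutations);
    deterministic given the seed.

    Requires equal replicate counts in the two cohorts under
    ``pool="samples"`` (the designs in scope are balanced within a
    tissue); ``pool="cohort_mean"`` has no such restriction.

    Note on the reference cohort: drift values of the reference cohort
    are centred by their own mean, which deflates its TD by
    construction. Comparisons of a non-reference cohort against the
    reference therefore mix the anchoring effect with any genuine
    dispersion change (exactly as in the drift-plot construction, where
    the young box hugs zero); the gene-swap null is exchangeable — and
    the test calibrated — when neither compared cohort is the reference.
    """
    if permutations < 99:
        raise ValueError("permutations must be >= 99 for a meaningful p-value")
    ids_a = cohort_sample_ids(samples, tissue, cohort_a)
    ids_b = cohort_sample_ids(samples, tissue, cohort_b)
    if set(ids_a) == set(ids_b):
        return 1.0  # identical cohorts: observed statistic is exactly 0
    if pool == "samples":
        a = drift[ids_a].to_numpy()
        b = drift[ids_b].to_numpy()
        if a.shape[1] != b.shape[1]:
            raise DesignError(
                "gene-wise swap permutation requires equal replicate counts; "
                f"got {a.shape[1]} vs {b.shape[1]} — use pool='cohort_mean'"
            )
    elif pool == "cohort_mean":
        a = drift[ids_a].mean(axis=1).to_numpy()[:, None]
        b = drift[ids_b].mean(axis=1).to_numpy()[:, None]
    else:
        raise ValueError(f"unknown drift pooling {pool!r}")

    n_genes, n_rep = a.shape
    n = n_genes * n_rep
    sa, ssa = a.sum(axis=1), (a**2).sum(axis=1)
    sb, ssb = b.sum(axis=1), (b**2).sum(axis=1)

    def stat(swap: np.ndarray) -> np.ndarray:
        # swap: (..., n_genes) boolean; True exchanges the gene's cohorts
        s_a = np.where(swap, sb, sa)
        ss_a = np.where(swap, ssb, ssa)
        s_b = np.where(swap, sa, sb)
        ss_b = np.where(swap, ssa, ssb)
        va = _pooled_variance_from_sums(s_a, ss_a, n)
        vb = _pooled_variance_from_sums(s_b, ss_b, n)
        return np.abs(va - vb)

    observed = float(stat(np.zeros(n_genes, dtype=bool)))
    rng = np.random.default_rng(seed)
    swaps = rng.random((permutations, n_genes)) < 0.5
    permuted = stat(swaps)
    exceed = int(np.sum(permuted >= observed - 1e-15))  # guard fp ties
    return (1 + exceed) / (1 + permutations)


def compute_vz(
    matrix: pd.DataFrame,
    samples: list[SampleRecord],
    tissue: str,
    cohort: str,
) -> pd.Series:
    """Variance Z score per gene: SD / mean of replicate RPKM (n-1 SD)."""
    ids = cohort_sample_ids(samples, tissue, cohort)
    if len(ids) < 2:
        raise DesignError(
            f"VZ needs >= 2 replicates; cohort {cohort!r} in {tissue!r} has {len(ids)}"
        )
    sub = matrix[ids]
    vz = sub.std(axis=1, ddof=1) / sub.mean(axis=1)
    vz.name = f"vz_{cohort}"
    return vz


def variance_change(vz_a: pd.Series, vz_b: pd.Series, epsilon: float = 1e-6) -> pd.Series:
    """Per-gene VC ratio (vz_a + eps) / (vz_b + eps).

    The regulariser keeps genes with a zero-SD cohort finite; a gene
    with zero dispersion in both cohorts gets VC = 1 exactly.
    """
    if (vz_a < 0).any() or (vz_b < 0).any():
        raise ValueError("VZ values must be nonnegative")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    vc = (vz_a + epsilon) / (vz_b + epsilon)
    vc[(vz_a == 0) & (vz_b == 0)] = 1.0
    return vc


#: (label, numerator cohort, denominator cohort) of the variance table.
VC_CONTRASTS = (
    ("4W/1W", "aged", "young"),
    ("4W/4W-IF", "aged", "aged_treated"),
    ("1W/4W-IF", "young", "aged_treated"),
)


def classify_variance(
    matrix: pd.DataFrame,
    samples: list[SampleRecord],
    tissue: str,
    config: AnalysisConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """VZ per cohort, VC per contrast and high-VC flags for one tissue.

    Returns ``(records, counts)``: per-gene records with vz_<cohort>,
    vc_<label> and high_vc_<label> columns, and a one-row table of
    high-VC gene counts per contrast (vc > cutoff, strict).
    """
    records = pd.DataFrame(index=matrix.index)
    for cohort in ("young", "aged", "aged_treated"):
        records[f"vz_{cohort}"] = compute_vz(matrix, samples, tissue, cohort)
    counts = {}
    for label, num, den in VC_CONTRASTS:
        vc = variance_change(
            records[f"vz_{num}"], records[f"vz_{den}"], epsilon=config.epsilon
        )
        high = vc > config.vc_cutoff
        records[f"vc_{label}"] = vc
        records[f"high_vc_{label}"] = high
        counts[label] = int(high.sum())
    counts_df = pd.DataFrame([counts], index=[f"vc>{config.vc_cutoff:g}"])
    return records, counts_df


def scaled_vz_profile(
    records: pd.DataFrame,
    gene_list: list[str],
    cohorts: tuple[str, str] = ("aged", "aged_treated"),
) -> pd.DataFrame:
    """Per-gene VZ scaled by the gene's maximum across the two cohorts.

    Used for two-cohort scatter profiles of a gene set: the cohort where
    the gene is most variable sits at 1, the other in (0, 1]. Genes with
    zero VZ in both cohorts are emitted as (1, 1) with a warning.
    """
    missing = [g for g in gene_list if g not in records.index]
    if missing:
        raise KeyError(f"genes not in the variance records: {missing[:5]}")
    a, b = cohorts
    sub = records.loc[gene_list, [f"vz_{a}", f"vz_{b}"]].copy()
    top = sub.max(axis=1)
    degenerate = top == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} gene(s) with zero VZ in both cohorts "
            "emitted as (1, 1)"
        )
        top = top.where(~degenerate, 1.0)
        sub.loc[degenerate] = 1.0
    return sub.div(top, axis=0)
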