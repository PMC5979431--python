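"""Synthetic replicate RPKM matrices with planted structure.

The generator emulates the statistical skeleton of a multi-cohort bulk
RNA-seq design over one tissue: a young reference cohort, an aged cohort
and an aged-but-treated cohort, each measured as a handful of replicate
RPKM columns. Planted structure, recorded gene-by-gene in a truth table:

* log-normal baseline expression across genes;
* a subset of age-responsive genes whose aged mean moves up or down by a
  fixed fold;
* a subset of those whose treated mean returns to the young mean
  ("restored" genes — the treatment acts on the mean);
* a subset of "drift" genes whose between-replicate coefficient of
  variation (CV) is inflated in the aged cohort and partially inflated
  in the treated cohort (the treatment acts on the dispersion).

Replicate noise is multiplicative log-normal with unit mean and a
specified CV, so values are strictly positive and cohort means equal the
planted true means in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .io import (
    COHORT_DISPLAY,
    COHORTS,
    TISSUES,
    AnalysisConfig,
    SampleRecord,
    ValidationError,
)

__all__ = ["SyntheticSpec", "generate_dataset", "expected_category_counts"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic replicate-RPKM generator.

    Defaults describe the study conditions the pipeline targets: ~10,000
    genes after filtering, triplicate cohorts, ~12% of genes
    age-responsive (half up, half down) at 2-fold, a fifth of those
    restored by treatment, and 15% of genes with age-inflated
    between-replicate dispersion (CV x4 aged, x1.5 treated, from a base
    CV of 0.2).

    Parameters
    ----------
    n_genes
        Number of genes simulated.
    replicates_per_cohort
        Mapping cohort -> replicate count. Head-style designs use 3,
        thorax-style 2.
    baseline_log_mean, baseline_log_sd
        Natural-log mean / SD of the per-gene baseline (young) RPKM.
    frac_age_up, frac_age_down
        Fractions of genes whose aged mean is multiplied / divided by
        ``age_effect_fold``. Counts are exact: genes are assigned by
        slicing a seeded permutation, with fraction * n_genes rounded.
    frac_restored
        Fraction of age-responsive genes whose treated mean returns to
        the young mean; the rest keep the aged mean.
    frac_drift
        Fraction of genes (age-responsive or not) with inflated aged CV.
    base_cv
        Between-replicate CV of every gene in the young cohort and of
        non-drift genes everywhere.
    drift_cv_factor, treatment_cv_factor
        CV multipliers for drift genes in the aged and treated cohorts.
    """

    n_genes: int = 10_000
    replicates_per_cohort: Mapping[str, int] = field(
        default_factory=lambda: {"young": 3, "aged": 3, "aged_treated": 3}
    )
    baseline_log_mean: float = 2.5
    baseline_log_sd: float = 1.5
    frac_age_up: float = 0.06
    frac_age_down: float = 0.06
    age_effect_fold: float = 2.0
    frac_restored: float = 0.2
    frac_drift: float = 0.15
    base_cv: float = 0.2
    drift_cv_factor: float = 4.0
    treatment_cv_factor: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValidationError("n_genes must be a positive integer")
        for cohort, n in self.replicates_per_cohort.items():
            if cohort not in COHORTS:
                raise ValidationError(f"unknown cohort {cohort!r} in replicates_per_cohort")
            if n < 1:
                raise ValidationError(f"replicates for {cohort!r} must be >= 1")
        if set(self.replicates_per_cohort) != set(COHORTS):
            raise ValidationError(
                f"replicates_per_cohort must cover all cohorts {COHORTS}"
            )
        for name in ("frac_age_up", "frac_age_down", "frac_restored", "frac_drift"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.frac_age_up + self.frac_age_down > 1.0:
            raise ValidationError("frac_age_up + frac_age_down must be <= 1")
        if self.age_effect_fold <= 1.0:
            raise ValidationError("age_effect_fold must be > 1")
        if self.base_cv < 0:
            raise ValidationError("base_cv must be nonnegative")
        if self.drift_cv_factor < 1.0:
            raise ValidationError("drift_cv_factor must be >= 1")
        if not 1.0 <= self.treatment_cv_factor <= self.drift_cv_factor:
            raise ValidationError(
                "treatment_cv_factor must lie in [1, drift_cv_factor]"
            )
        if self.baseline_log_sd <= 0:
            raise ValidationError("baseline_log_sd must be positive")

    def replace(self, **kwargs) -> "SyntheticSpec":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["replicates_per_cohort"] = dict(d["replicates_per_cohort"])
        return d


TRUTH_COLUMNS = [
    "is_age_up",
    "is_age_down",
    "is_restored",
    "is_drift",
    "true_young_mean",
    "true_aged_mean",
    "true_treated_mean",
    "true_cv_young",
    "true_cv_aged",
    "true_cv_aged_treated",
]


def _lognormal_unit_mean(rng: np.ndarray, cv: np.ndarray, size) -> np.ndarray:
    """Multiplicative noise with E=1 and the given CV (log-normal law)."""
    cv = np.asarray(cv, dtype=float)
    sigma2 = np.log1p(cv**2)
    out = np.exp(rng.normal(-sigma2 / 2.0, np.sqrt(sigma2), size=size))
    # cv == 0 must give exactly 1, not exp(gaussian * 0 - 0) noise-free path
    return np.where(np.broadcast_to(cv, out.shape) == 0.0, 1.0, out)


def generate_dataset(
    spec: SyntheticSpec, tissue: str = "head"
) -> tuple[pd.DataFrame, list[SampleRecord], pd.DataFrame]:
    """Draw one tissue's (matrix, samples, truth table) from the spec.

    Replicate values are ``true_mean[g, cohort] * noise`` with log-normal
    unit-mean noise of CV ``true_cv[g, cohort]``. Identical
    (spec, tissue, seed) give bit-identical outputs.
    """
    if tissue not in TISSUES:
        raise ValidationError(f"unknown tissue {tissue!r}; expected one of {TISSUES}")
    n = spec.n_genes
    # independent, reproducible streams per (seed, tissue)
    root = np.random.SeedSequence(entropy=spec.seed, spawn_key=(TISSUES.index(tissue),))
    assign_rng, base_rng, noise_rng = (
        np.random.default_rng(s) for s in root.spawn(3)
    )

    genes = [f"g{i:05d}" for i in range(n)]
    n_up = round(spec.frac_age_up * n)
    n_down = round(spec.frac_age_down * n)
    perm = assign_rng.permutation(n)
    up_idx = perm[:n_up]
    down_idx = perm[n_up : n_up + n_down]
    # restored genes: slice of a reshuffle of the age-responsive genes,
    # so the fraction gives an exact count drawn from both directions
    responsive = assign_rng.permutation(perm[: n_up + n_down])
    n_restored = round(spec.frac_restored * responsive.size)
    restored_idx = responsive[:n_restored]
    drift_perm = assign_rng.permutation(n)
    drift_idx = drift_perm[: round(spec.frac_drift * n)]

    is_up = np.zeros(n, dtype=bool)
    is_up[up_idx] = True
    is_down = np.zeros(n, dtype=bool)
    is_down[down_idx] = True
    is_restored = np.zeros(n, dtype=bool)
    is_restored[restored_idx] = True
    is_drift = np.zeros(n, dtype=bool)
    is_drift[drift_idx] = True

    young_mean = np.exp(
        base_rng.normal(spec.baseline_log_mean, spec.baseline_log_sd, size=n)
    )
    aged_mean = young_mean.copy()
    aged_mean[is_up] *= spec.age_effect_fold
    aged_mean[is_down] /= spec.age_effect_fold
    treated_mean = aged_mean.copy()
    treated_mean[is_restored] = young_mean[is_restored]

    cv = {
        "young": np.full(n, spec.base_cv),
        "aged": np.where(is_drift, spec.base_cv * spec.drift_cv_factor, spec.base_cv),
        "aged_treated": np.where(
            is_drift, spec.base_cv * spec.treatment_cv_factor, spec.base_cv
        ),
    }
    means = {"young": young_mean, "aged": aged_mean, "aged_treated": treated_mean}

    columns: dict[str, np.ndarray] = {}
    samples: list[SampleRecord] = []
    for cohort in COHORTS:  # fixed cohort order for determinism
        n_rep = spec.replicates_per_cohort[cohort]
        noise = _lognormal_unit_mean(noise_rng, cv[cohort][:, None], (n, n_rep))
        values = means[cohort][:, None] * noise
        for j in range(n_rep):
            sid = f"{tissue}_{COHORT_DISPLAY[cohort]}_r{j + 1}"
            columns[sid] = values[:, j]
            samples.append(
                SampleRecord(sample_id=sid, tissue=tissue, cohort=cohort, replicate=j + 1)
            )
    matrix = pd.DataFrame(columns, index=pd.Index(genes, name="gene"))

    truth = pd.DataFrame(
        {
            "is_age_up": is_up,
            "is_age_down": is_down,
            "is_restored": is_restored,
            "is_drift": is_drift,
            "true_young_mean": young_mean,
            "true_aged_mean": aged_mean,
            "true_treated_mean": treated_mean,
            "true_cv_young": cv["young"],
            "true_cv_aged": cv["aged"],
            "true_cv_aged_treated": cv["aged_treated"],
        },
        index=matrix.index,
    )
    return matrix, samples, truth


def expected_category_counts(truth: pd.DataFrame, config: AnalysisConfig):
    """Noise-free category counts implied by the planted true means.

    Classifies each gene's TRUE cohort means with the configured fold
    cutoffs, giving the recovery baseline a noisy run is compared to.
    """
    from .foldchange import CategoryCounts, classify_flags

    fc_age = truth["true_aged_mean"] / truth["true_young_mean"]
    fc_if = truth["true_aged_mean"] / truth["true_treated_mean"]
    flags = classify_flags(fc_age, fc_if, config)
    return CategoryCounts.from_flags(flags)
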