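"""Model/Results interface over the analysis.

`AgingTranscriptomeModel` bundles one tissue's expression matrix, the
sample design and an `AnalysisConfig`; `fit()` runs filtering, fold
changes, differential tests, classification, drift/TD with its
permutation test, VZ/VC classification and PCA, returning an
`AgingTranscriptomeResults` that carries every table and a `summary()`.

Example
-------
>>> from txdrift import SyntheticSpec, generate_dataset
>>> from txdrift.model import AgingTranscriptomeModel
>>> matrix, samples, truth = generate_dataset(SyntheticSpec(seed=7), "head")
>>> res = AgingTranscriptomeModel(matrix, samples, tissue="head").fit()
>>> print(res.summary())        # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import drift as drift_mod
from .enrichment import ora_hypergeometric, pca_qc
from .foldchange import CategoryCounts, classify_genes, summarize_categories
from .io import (
    COHORT_DISPLAY,
    COHORTS,
    AnalysisConfig,
    SampleRecord,
    ValidationError,
    read_expression_matrix,
    read_sample_sheet,
    select_samples,
    validate_dataset,
)
from .preprocess import filter_expressed, log2_matrix

__all__ = ["AgingTranscriptomeModel", "AgingTranscriptomeResults"]


class AgingTranscriptomeModel:
    """One tissue's aging / treatment expression analysis.

    Parameters
    ----------
    matrix
        Genes x samples RPKM DataFrame (may contain other tissues'
        columns; only the given tissue's samples are used).
    samples
        The design as SampleRecords.
    tissue
        Tissue to analyse; tissues are never pooled.
    config
        Analysis thresholds; defaults reproduce the standard cutoffs
        (>1 RPKM filter, 1.4/1.3 fold cutoffs, VC > 3.75).
    """

    def __init__(
        self,
        matrix: pd.DataFrame,
        samples: list[SampleRecord],
        tissue: str = "head",
        config: AnalysisConfig | None = None,
    ) -> None:
        self.config = config or AnalysisConfig()
        self.tissue = tissue
        self.samples = list(samples)
        report = validate_dataset(matrix, self.samples)
        if report.sheet_only:
            raise ValidationError(f"design/matrix mismatch: {report}")
        if not select_samples(self.samples, tissue):
            raise ValidationError(f"no samples for tissue {tissue!r}")
        self.matrix = matrix

    @classmethod
    def from_files(
        cls,
        matrix_path: str | Path,
        sheet_path: str | Path,
        tissue: str = "head",
        config: AnalysisConfig | None = None,
        dialect: str = "tsv",
    ) -> "AgingTranscriptomeModel":
        config = config or AnalysisConfig()
        matrix = read_expression_matrix(matrix_path, dialect=dialect)
        samples = read_sample_sheet(sheet_path, cohort_aliases=config.cohort_aliases)
        return cls(matrix, samples, tissue=tissue, config=config)

    def fit(self) -> "AgingTranscriptomeResults":
        cfg = self.config
        tissue = self.tissue
        filtered = filter_expressed(self.matrix, self.samples, tissue, cfg.min_rpkm)
        tissue_samples = select_samples(self.samples, tissue)

        fold_changes = classify_genes(filtered, self.samples, tissue, cfg)
        category_counts = summarize_categories(fold_changes)

        drift = drift_mod.compute_drift(filtered, self.samples, tissue, "young")
        summaries = {
            c: drift_mod.drift_variance_summary(
                drift, self.samples, tissue, c, pool=cfg.drift_pool
            )
            for c in COHORTS
        }
        drift_tests = {}
        for i, (a, b) in enumerate(
            [("aged", "young"), ("aged", "aged_treated"), ("aged_treated", "young")]
        ):
            drift_tests[f"{COHORT_DISPLAY[a]} vs {COHORT_DISPLAY[b]}"] = (
                drift_mod.drift_variance_test(
                    drift, self.samples, tissue, a, b,
                    permutations=cfg.permutations,
                    seed=cfg.seed + i,
                    pool=cfg.drift_pool,
                )
            )

        variance_records, variance_counts = drift_mod.classify_variance(
            filtered, self.samples, tissue, cfg
        )

        pca_input = log2_matrix(filtered, cfg.pseudocount) if cfg.pca_log_scale else filtered
        n_comp = min(2, len(tissue_samples))
        pca_coords, pca_var = pca_qc(pca_input, n_components=n_comp)

        return AgingTranscriptomeResults(
            model=self,
            n_genes_total=self.matrix.shape[0],
            filtered_matrix=filtered,
            fold_changes=fold_changes,
            category_counts=category_counts,
            drift=drift,
            drift_summaries=summaries,
            drift_test_p=drift_tests,
            variance_records=variance_records,
            variance_counts=variance_counts,
            pca_coordinates=pca_coords,
            pca_variance_ratio=pca_var,
        )


@dataclass
class AgingTranscriptomeResults:
    """Fitted tables, statistics and diagnostics of one tissue."""

    model: AgingTranscriptomeModel
    n_genes_total: int
    filtered_matrix: pd.DataFrame
    fold_changes: pd.DataFrame
    category_counts: CategoryCounts
    drift: pd.DataFrame
    drift_summaries: dict[str, drift_mod.DriftSummary]
    drift_test_p: dict[str, float]
    variance_records: pd.DataFrame
    variance_counts: pd.DataFrame
    pca_coordinates: pd.DataFrame
    pca_variance_ratio: np.ndarray = field(repr=False, default=None)

    @property
    def n_genes(self) -> int:
        """Size of the filtered gene universe."""
        return self.filtered_matrix.shape[0]

    @property
    def drift_variance(self) -> dict[str, float]:
        """TD per cohort (variance of pooled drift values)."""
        return {c: s.drift_variance for c, s in self.drift_summaries.items()}

    def enrich(self, selection: list[str], sets: dict[str, list[str]]) -> pd.DataFrame:
        """Hypergeometric over-representation against the filtered universe."""
        return ora_hypergeometric(selection, list(self.filtered_matrix.index), sets)

    def summary(self) -> str:
        """Human-readable account of the fitted quantities."""
        cfg = self.model.config
        lines = [
            f"Aging transcriptome analysis — tissue: {self.model.tissue}",
            "=" * 60,
            f"genes: {self.n_genes_total} total, {self.n_genes} expressed "
            f"(> {cfg.min_rpkm:g} RPKM in every sample)",
            "",
            f"Fold-change categories (age cutoff > {cfg.fc_age_cutoff:g}, "
            f"IF cutoff > {cfg.fc_if_cutoff:g}, strict):",
        ]
        cc = self.category_counts
        header = ("Change w/ Age", "Age Down", "Age Up", "Change w/ IF",
                  "AgeDown IFUp", "AgeUp IFDown", "IF More Youthful")
        values = (cc.change_with_age, cc.age_down, cc.age_up, cc.change_with_if,
                  cc.age_down_if_up, cc.age_up_if_down, cc.if_more_youthful)
        lines.append("  " + "  ".join(f"{h}" for h in header))
        lines.append("  " + "  ".join(f"{v:^{len(h)}d}" for h, v in zip(header, values)))
        lines += ["", "Transcriptional drift-variance (TD), young reference:"]
        for c in COHORTS:
            s = self.drift_summaries[c]
            lines.append(
                f"  {COHORT_DISPLAY[c]:>6}: TD = {s.drift_variance:.5f}  "
                f"(IQR {s.q1:+.4f} .. {s.q3:+.4f}, n = {s.n_values})"
            )
        for label, p in self.drift_test_p.items():
            lines.append(f"  permutation test {label}: p = {p:.4g}")
        lines += ["", f"High-VC genes (VZ ratio > {cfg.vc_cutoff:g}, strict):"]
        for col in self.variance_counts.columns:
            lines.append(f"  {col:>9}: {int(self.variance_counts[col].iloc[0])}")
        if self.pca_variance_ratio is not None and len(self.pca_variance_ratio) >= 2:
            lines += [
                "",
                f"PCA: PC1 {100 * self.pca_variance_ratio[0]:.1f}%, "
                f"PC2 {100 * self.pca_variance_ratio[1]:.1f}% of variance",
            ]
        return "\n".join(lines)
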