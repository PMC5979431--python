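"""End-to-end pipeline: load or simulate, fit, write every artifact."""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import pandas as pd

from . import __version__
from .io import (
    COHORTS,
    AnalysisConfig,
    SampleRecord,
    read_expression_matrix,
    read_gene_sets,
    read_sample_sheet,
    validate_dataset,
    write_expression_matrix,
    write_sample_sheet,
    write_table,
)
from .model import AgingTranscriptomeModel, AgingTranscriptomeResults
from .plots import (
    make_drift_plot,
    make_heatmap,
    make_pca_plot,
    make_volcano_plot,
)
from .simulate import SyntheticSpec, generate_dataset

logger = logging.getLogger("txdrift")

__all__ = ["run_pipeline"]


def run_pipeline(
    config: AnalysisConfig,
    outdir: str | Path,
    tissue: str = "head",
    matrix_path: str | Path | None = None,
    sheet_path: str | Path | None = None,
    synthetic_spec: SyntheticSpec | None = None,
    gene_sets_path: str | Path | None = None,
    force: bool = False,
    figures: bool = True,
) -> AgingTranscriptomeResults:
    """Run the full analysis for one tissue and write all outputs.

    Inputs are either file paths (matrix + sample sheet) or a
    ``SyntheticSpec`` to simulate from. Identical config + seed give
    byte-identical output tables. On a stage failure a FAILED marker
    naming the stage is left in the output directory alongside whatever
    was already written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        if (matrix_path is None) == (synthetic_spec is None):
            raise ValueError("provide either matrix_path+sheet_path or synthetic_spec")
        stage = "load"
        if synthetic_spec is not None:
            matrix, samples, truth = generate_dataset(synthetic_spec, tissue)
            write_expression_matrix(matrix, outdir / "matrix.tsv")
            write_sample_sheet(samples, outdir / "samples.tsv")
            write_table(truth, outdir / "truth.tsv", index_label="gene")
        else:
            if sheet_path is None:
                raise ValueError("sheet_path is required with matrix_path")
            matrix = read_expression_matrix(matrix_path)
            samples = read_sample_sheet(sheet_path, cohort_aliases=config.cohort_aliases)
            truth = None

        stage = "validate"
        report = validate_dataset(matrix, samples)
        if not report.ok and not force:
            raise ValueError(f"dataset validation failed: {report} (use force=True to override)")

        stage = "fit"
        model = AgingTranscriptomeModel(matrix, samples, tissue=tissue, config=config)
        results = model.fit()

        stage = "write-tables"
        write_table(results.filtered_matrix, outdir / "filtered_matrix.tsv", index_label="gene")
        write_table(results.fold_changes, outdir / "fold_changes.tsv", index_label="gene")
        write_table(
            results.category_counts.to_frame(tissue),
            outdir / "category_counts.tsv", index_label="tissue",
        )
        drift_long = results.drift.stack().rename("drift").reset_index()
        drift_long.columns = ["gene", "sample_id", "drift"]
        drift_long.to_csv(outdir / "drift.tsv", sep="\t", index=False, float_format="%.17g")
        summary_rows = pd.DataFrame([results.drift_summaries[c].to_row() for c in COHORTS])
        summary_rows.to_csv(outdir / "drift_summary.tsv", sep="\t", index=False,
                            float_format="%.17g")
        pd.DataFrame(
            sorted(results.drift_test_p.items()), columns=["comparison", "p"]
        ).to_csv(outdir / "drift_tests.tsv", sep="\t", index=False, float_format="%.17g")
        write_table(results.variance_records, outdir / "variance_records.tsv",
                    index_label="gene")
        write_table(results.variance_counts, outdir / "variance_counts.tsv",
                    index_label="cutoff")
        (outdir / "summary.txt").write_text(results.summary() + "\n")

        stage = "enrichment"
        if gene_sets_path is not None:
            sets = read_gene_sets(gene_sets_path)
            changed = results.fold_changes.index[
                results.fold_changes["age_up"] | results.fold_changes["age_down"]
            ].tolist()
            if changed:
                enr = results.enrich(changed, sets)
                write_table(enr, outdir / "enrichment_age_changed.tsv",
                            index_label="set_name")

        stage = "figures"
        if figures:
            make_volcano_plot(results.fold_changes, outdir / "volcano_age.png", "age")
            make_drift_plot(
                results.drift, samples, tissue, outdir / "drift_plot.png",
                p_aged_vs_young=results.drift_test_p.get("4W vs 1W"),
            )
            make_pca_plot(
                results.pca_coordinates, results.pca_variance_ratio, samples,
                outdir / "pca.png",
            )
            top = (
                results.fold_changes.reindex(
                    results.fold_changes["log2_fc_age"].abs().sort_values(ascending=False).index
                )
                .head(30)
                .index.tolist()
            )
            if len(top) >= 2:
                make_heatmap(results.filtered_matrix, top, outdir / "heatmap_top_age.png")

        stage = "manifest"
        manifest = {
            "version": __version__,
            "python": platform.python_version(),
            "tissue": tissue,
            "config": config.to_dict(),
            "synthetic_spec": synthetic_spec.to_dict() if synthetic_spec else None,
            "inputs": {
                "matrix": str(matrix_path) if matrix_path else None,
                "sample_sheet": str(sheet_path) if sheet_path else None,
                "gene_sets": str(gene_sets_path) if gene_sets_path else None,
            },
            "n_genes_total": int(results.n_genes_total),
            "n_genes_filtered": int(results.n_genes),
            "n_samples": len(samples),
            "drift_variance": results.drift_variance,
            "drift_test_p": results.drift_test_p,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        failed = outdir / "FAILED"
        if failed.exists():
            failed.unlink()
        return results
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        logger.error("pipeline failed at stage %r: %s", stage, exc)
        raise
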