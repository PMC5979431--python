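"""Figure-data builders and figure writers.

Every figure is accompanied by a TSV of the plotted values so tests and
downstream consumers assert on data, never on pixels.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist

from .io import COHORT_DISPLAY, SampleRecord, cohort_sample_ids, write_table
from .preprocess import row_zscore

__all__ = ["make_volcano_data", "make_drift_plot", "make_heatmap", "make_pca_plot",
           "make_vz_scatter"]


def make_volcano_data(records: pd.DataFrame, contrast: str = "age") -> pd.DataFrame:
    """(log2 fc, -log10 p) coordinates per gene for a volcano plot.

    Zero p-values are clamped to the smallest positive float so the
    y-coordinate stays finite.
    """
    fc = records[f"fc_{contrast}"]
    p = records[f"p_{contrast}"].clip(lower=np.finfo(float).tiny)
    return pd.DataFrame(
        {"log2_fc": np.log2(fc), "neg_log10_p": -np.log10(p)}, index=records.index
    )


def make_volcano_plot(
    records: pd.DataFrame, path: str | Path, contrast: str = "age"
) -> pd.DataFrame:
    data = make_volcano_data(records, contrast)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(data["log2_fc"], data["neg_log10_p"], s=4, alpha=0.4, lw=0)
    ax.set_xlabel(f"log2 fold change ({contrast})")
    ax.set_ylabel("-log10 p")
    _save(fig, path)
    write_table(data, Path(path).with_suffix(".tsv"), index_label="gene")
    return data


def make_drift_plot(
    drift: pd.DataFrame,
    samples: list[SampleRecord],
    tissue: str,
    path: str | Path,
    p_aged_vs_young: float | None = None,
    cohort_order: tuple[str, ...] = ("young", "aged", "aged_treated"),
) -> pd.DataFrame:
    """Box plot of pooled drift values per cohort (a drift-plot).

    The pooled values are also written as a long-format TSV
    (cohort, drift) next to the figure, from which the plot can be
    re-rendered.
    """
    pooled = {}
    for cohort in cohort_order:
        ids = cohort_sample_ids(samples, tissue, cohort)
        pooled[cohort] = drift[ids].to_numpy().ravel()
    long = pd.concat(
        [pd.DataFrame({"cohort": c, "drift": v}) for c, v in pooled.items()],
        ignore_index=True,
    )
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.boxplot(
        [pooled[c] for c in cohort_order],
        tick_labels=[COHORT_DISPLAY[c] for c in cohort_order],
        showfliers=False,
    )
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.set_ylabel("drift  log10(x / young mean)")
    title = f"{tissue} drift-plot ({drift.shape[0]} genes)"
    if p_aged_vs_young is not None:
        stars = "***" if p_aged_vs_young <= 0.001 else f"p={p_aged_vs_young:.3g}"
        title += f"  4W vs 1W: {stars}"
    ax.set_title(title, fontsize=9)
    _save(fig, path)
    long.to_csv(Path(path).with_suffix(".tsv"), sep="\t", index=False, float_format="%.17g")
    return long


def make_heatmap(
    matrix: pd.DataFrame,
    gene_list: list[str],
    path: str | Path,
) -> pd.DataFrame:
    """Row-z-scored heat map of a gene list, rows clustered, TSV emitted.

    Rows are ordered by average-linkage hierarchical clustering on the
    Euclidean distance of z-scored rows; columns stay in design order.
    Genes missing from the matrix are dropped with a warning.
    """
    import warnings

    present = [g for g in gene_list if g in matrix.index]
    missing = sorted(set(gene_list) - set(present))
    if missing:
        warnings.warn(f"{len(missing)} gene(s) not in matrix, omitted: {missing[:5]}")
    if not present:
        raise ValueError("no requested genes present in the matrix")
    scaled = row_zscore(matrix.loc[present])
    if len(present) > 2:
        order = leaves_list(average(pdist(scaled.to_numpy(), metric="euclidean")))
        scaled = scaled.iloc[order]
    elif len(present) == 2 and np.allclose(scaled.iloc[0], scaled.iloc[1]):
        pass  # two identical rows are trivially adjacent
    fig, ax = plt.subplots(figsize=(5, max(2.0, 0.15 * len(present))))
    im = ax.imshow(scaled.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-2, vmax=2)
    ax.set_xticks(range(scaled.shape[1]), scaled.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(scaled.shape[0]), scaled.index, fontsize=5)
    fig.colorbar(im, ax=ax, label="row z-score")
    _save(fig, path)
    write_table(scaled, Path(path).with_suffix(".tsv"), index_label="gene")
    return scaled


def make_pca_plot(
    coords: pd.DataFrame,
    variance_ratio: np.ndarray,
    samples: list[SampleRecord],
    path: str | Path,
) -> None:
    cohort_of = {r.sample_id: r.cohort for r in samples}
    fig, ax = plt.subplots(figsize=(4.5, 4))
    for cohort, marker in (("young", "o"), ("aged", "D"), ("aged_treated", "s")):
        ids = [s for s in coords.index if cohort_of.get(s) == cohort]
        if ids:
            ax.scatter(
                coords.loc[ids, "PC1"], coords.loc[ids, "PC2"],
                marker=marker, label=COHORT_DISPLAY[cohort],
            )
    ax.set_xlabel(f"PC1 ({100 * variance_ratio[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * variance_ratio[1]:.1f}%)")
    ax.legend(fontsize=7)
    _save(fig, path)
    write_table(coords, Path(path).with_suffix(".tsv"), index_label="sample_id")


def make_vz_scatter(scaled: pd.DataFrame, path: str | Path) -> None:
    """Scatter of scaled VZ values of a gene set across two cohorts."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    x = np.arange(len(scaled))
    for col, marker in zip(scaled.columns, ("D", "s")):
        ax.scatter(x, scaled[col], marker=marker, label=col)
    ax.set_xticks(x, scaled.index, rotation=90, fontsize=5)
    ax.set_ylabel("scaled VZ (SD/Ave)")
    ax.set_ylim(0, 1.05)
    ax.legend(fontsize=7)
    _save(fig, path)
    write_table(scaled, Path(path).with_suffix(".tsv"), index_label="gene")


def _save(fig, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
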