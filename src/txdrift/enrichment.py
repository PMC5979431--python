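"""Gene-set over-representation and PCA quality control."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ora_hypergeometric", "pca_qc"]


def ora_hypergeometric(
    selection: list[str],
    universe: list[str],
    sets: dict[str, list[str]],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of gene sets.

    For each set, tests whether the selection contains more of the set's
    genes than expected when drawing ``len(selection)`` genes from the
    universe without replacement: p = P(overlap >= observed). Gene sets
    are intersected with the universe before testing; sets with no
    universe overlap are skipped with a warning. Benjamini-Hochberg
    adjusted p-values are computed across the tested sets.

    Returns a DataFrame indexed by set name with columns set_size,
    overlap, universe_size, selection_size, p, adjusted_p, sorted by p.
    """
    from statsmodels.stats.multitest import multipletests

    if not selection or not universe:
        raise ValueError("selection and universe must be non-empty")
    uni = set(universe)
    sel = set(selection)
    stray = sel - uni
    if stray:
        raise ValueError(
            f"selection contains genes outside the universe: {sorted(stray)[:5]}"
        )
    M, N = len(uni), len(sel)
    rows = []
    for name, members in sets.items():
        in_universe = uni.intersection(members)
        if not in_universe:
            warnings.warn(f"gene set {name!r} has no overlap with the universe; skipped")
            continue
        n = len(in_universe)
        k = len(sel.intersection(in_universe))
        p = float(stats.hypergeom.sf(k - 1, M, n, N))
        rows.append((name, n, k, M, N, min(p, 1.0)))
    if not rows:
        return pd.DataFrame(
            columns=["set_size", "overlap", "universe_size", "selection_size", "p", "adjusted_p"]
        )
    out = pd.DataFrame(
        rows,
        columns=["set_name", "set_size", "overlap", "universe_size", "selection_size", "p"],
    ).set_index("set_name")
    out["adjusted_p"] = multipletests(out["p"], method="fdr_bh")[1]
    return out.sort_values("p")


def pca_qc(matrix: pd.DataFrame, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Project samples onto the top principal components of the matrix.

    Input is the filtered (and typically log2-transformed) genes x
    samples matrix; genes are centred, samples are the observations.
    Returns per-sample coordinates (columns PC1, PC2, ...) and the
    variance-explained fractions, which are non-increasing and sum <= 1.
    Used as the replicate-clustering quality check: replicates of a
    cohort should sit near each other, cohorts apart.
    """
    from sklearn.decomposition import PCA

    n_samples = matrix.shape[1]
    if n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    if n_components > n_samples:
        raise ValueError(
            f"cannot extract {n_components} components from {n_samples} samples"
        )
    X = matrix.to_numpy().T  # samples x genes
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X - X.mean(axis=0))
    frame = pd.DataFrame(
        coords,
        index=matrix.columns,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return frame, pca.explained_variance_ratio_
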