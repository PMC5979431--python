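"""Expression filtering and transformations applied before all statistics."""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .io import DesignError, SampleRecord, select_samples

logger = logging.getLogger("txdrift")

__all__ = ["filter_expressed", "log2_matrix", "row_zscore"]


def filter_expressed(
    matrix: pd.DataFrame,
    samples: list[SampleRecord],
    tissue: str,
    min_rpkm: float = 1.0,
) -> pd.DataFrame:
    """Restrict to the tissue's samples and drop weakly expressed genes.

    A gene is retained iff its value is strictly greater than
    ``min_rpkm`` in EVERY sample of the tissue (all cohorts jointly);
    gene order is preserved. The retained genes form the tissue's gene
    universe for every downstream statistic.
    """
    tissue_samples = select_samples(samples, tissue)
    if not tissue_samples:
        raise DesignError(f"no samples for tissue {tissue!r} in the sample sheet")
    sub = matrix[[r.sample_id for r in tissue_samples]]
    keep = (sub > min_rpkm).all(axis=1)
    out = sub.loc[keep]
    logger.info(
        "filter_expressed(%s, >%g RPKM): retained %d / %d genes",
        tissue, min_rpkm, len(out), len(matrix),
    )
    return out


def log2_matrix(matrix: pd.DataFrame, pseudocount: float = 0.0) -> pd.DataFrame:
    """Cellwise log2(value + pseudocount); nonpositive cells are errors."""
    shifted = matrix + pseudocount
    if (shifted <= 0).any().any():
        stacked = (shifted <= 0).stack()
        gene, sample = stacked[stacked].index[0]
        raise ValueError(
            f"log2 undefined at gene {gene!r}, sample {sample!r}: value "
            f"{matrix.loc[gene, sample]} + pseudocount {pseudocount} <= 0"
        )
    return np.log2(shifted)


def row_zscore(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each row to mean 0 and SD 1 (sample SD, n-1 convention).

    Constant rows cannot be scaled; they are emitted as all-zeros with a
    warning so heat-map builders do not crash on flat genes.
    """
    if matrix.shape[1] < 2:
        raise ValueError("row_zscore needs at least 2 samples per row")
    mean = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant row(s) emitted as all-zeros: "
            f"{matrix.index[constant].tolist()[:5]}"
        )
    safe_sd = sd.where(~constant, 1.0)
    out = matrix.sub(mean, axis=0).div(safe_sd, axis=0)
    out.loc[constant] = 0.0
    return out
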