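"""Normalization, probe-to-gene collapsing and sample-level diagnostics.

Quantile normalization forces every array onto a common intensity
distribution (the row-wise mean of the column-sorted data), which controls
inter-sample variance before differential testing.  Probes interrogating
the same transcript are then collapsed by averaging, yielding one row per
gene symbol.  Principal component analysis on the collapsed, row-centered
matrix summarises the global expression structure of the samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ConfigError, ExpressionMatrix, FormatError

logger = logging.getLogger("renin_gsx")


def log2_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log2(x + 1) for raw-scale input; intensities must be non-negative."""
    arr = matrix.values.to_numpy(float)
    if (arr < 0).any():
        raise FormatError("raw intensities must be non-negative for log2(x+1)")
    return matrix.with_values(
        pd.DataFrame(np.log2(arr + 1.0), index=matrix.values.index,
                     columns=matrix.values.columns)
    )


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize sample columns against their common mean distribution.

    After normalization every column's sorted value vector equals the
    row-wise mean of the column-sorted input, and within-column rank order
    is preserved.  Tied values receive the mean of the reference values
    their ranks span.  A single-column matrix is returned unchanged.
    """
    vals = matrix.values
    arr = vals.to_numpy(float)
    if arr.shape[1] < 1 or arr.size == 0:
        raise ConfigError("empty expression matrix")
    if arr.shape[1] == 1:
        return matrix.with_values(vals.copy())
    ref = np.sort(arr, axis=0, kind="stable").mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(ref)
        assigned[order] = ref
        # ties: every repeat of a value gets the mean of the spanned refs
        s = pd.Series(assigned)
        out[:, j] = s.groupby(col, sort=False).transform("mean").to_numpy()
    return matrix.with_values(pd.DataFrame(out, index=vals.index, columns=vals.columns))


def collapse_probes(matrix: ExpressionMatrix, probe_map: dict[str, str]) -> ExpressionMatrix:
    """Average probes mapping to the same gene symbol into one row per gene.

    Probes absent from ``probe_map`` (unannotated) are dropped with a logged
    count.  Symbols are uppercased; output rows are sorted by symbol.
    """
    if not probe_map:
        raise ConfigError("empty probe map")
    upper = {p: g.upper() for p, g in probe_map.items()}
    mapped = [p for p in matrix.row_ids if p in upper]
    n_dropped = matrix.n_rows - len(mapped)
    if n_dropped:
        logger.info("collapse_probes: dropped %d unannotated probes", n_dropped)
    if not mapped:
        raise ConfigError("no probes could be mapped to gene symbols")
    sub = matrix.values.loc[mapped]
    genes = pd.Index([upper[p] for p in mapped], name="gene")
    collapsed = sub.groupby(genes, sort=True).mean()
    logger.info(
        "collapse_probes: %d probes -> %d genes", len(mapped), collapsed.shape[0]
    )
    return ExpressionMatrix(
        collapsed, None if matrix.groups is None else dict(matrix.groups)
    )


@dataclass
class PcaSummary:
    """Sample coordinates and per-component explained-variance fractions."""

    coordinates: pd.DataFrame  # samples x components, columns PC1..PCk
    explained_variance_ratio: np.ndarray

    def top_variance(self, k: int) -> float:
        """Summed variance fraction of the first k components."""
        return float(self.explained_variance_ratio[:k].sum())


def pca(matrix: ExpressionMatrix) -> PcaSummary:
    """PCA of samples over the entire transcriptional profile.

    Computed from the SVD of the row-(gene-)centered data with samples as
    observations; genes are not standardized.  Component signs are fixed by
    making the largest-magnitude gene loading positive, so output is fully
    deterministic.  A constant matrix yields all-zero variance ratios.
    """
    if matrix.n_samples < 2:
        raise ConfigError("PCA requires at least two samples")
    x = matrix.values.to_numpy(float).T  # samples x genes
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s**2 / max(x.shape[0] - 1, 1)
    total = var.sum()
    ratio = var / total if total > 0 else np.zeros_like(var)
    coords = u * s
    for k in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            coords[:, k] = -coords[:, k]
            vt[k] = -vt[k]
    cols = [f"PC{i+1}" for i in range(coords.shape[1])]
    return PcaSummary(
        pd.DataFrame(coords, index=matrix.sample_ids, columns=cols), ratio
    )


def variance_summary(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-sample spread statistics: quartiles, median and IQR.

    After :func:`quantile_normalize` every sample has identical statistics.
    """
    if matrix.n_rows == 0:
        raise ConfigError("empty expression matrix")
    arr = matrix.values.to_numpy(float)
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75], axis=0)
    return pd.DataFrame(
        {"sample": matrix.sample_ids, "q1": q1, "median": med, "q3": q3,
         "iqr": q3 - q1}
    )
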