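"""Regularized Bayesian two-group differential expression (CyberT-style).

With n = 4 arrays per group, per-gene sample variances are unstable; the
regularized t-test stabilizes them by shrinking each gene's variance toward
a *background* variance estimated from genes of similar expression level.
Concretely, for each group the genes are ranked by their group mean and the
background variance sigma0^2 of a gene is the average sample variance over a
sliding window of ``window_w`` genes centred on its rank.  The regularized
variance is the inverse-gamma posterior point estimate

    sigma_tilde^2 = (v0 * sigma0^2 + (n - 1) * s^2) / (v0 + n - 2)

where ``v0`` acts as the number of pseudo-observations backing the prior.
The test statistic and its reference distribution are

    t' = (mean2 - mean1) / sqrt(sigma_tilde1^2/n1 + sigma_tilde2^2/n2)
    t' ~ t(v0 + n1 + v0 + n2 - 4)   under the null,

and two-sided p-values are adjusted by the Benjamini-Hochberg step-up
procedure.  Defaults (window 101, v0 = 10) follow the published web-tool
defaults of the method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ConfigError, ExpressionMatrix

#: Columns of the differential-expression result table.
DE_COLUMNS = (
    "gene",
    "mean_g1",
    "mean_g2",
    "log2fc",
    "s2_g1",
    "s2_g2",
    "s2_bg_g1",
    "s2_bg_g2",
    "t_reg",
    "p_nominal",
    "q_fdr",
    "direction",
)


@dataclass(frozen=True)
class CybertParams:
    """Tuning knobs of the regularized t-test.

    window_w
        Odd number of genes in the sliding background-variance window;
        must not exceed the number of genes.
    prior_df_v0
        Prior confidence v0 (pseudo-observations) weighting the background
        variance against the per-gene sample variance.
    """

    window_w: int = 101
    prior_df_v0: float = 10.0

    def validate(self, n_genes: int, n_min: int) -> None:
        if self.window_w < 1 or self.window_w % 2 == 0:
            raise ConfigError(f"window_w must be odd and positive, got {self.window_w}")
        if self.window_w > n_genes:
            raise ConfigError(
                f"window_w ({self.window_w}) exceeds number of genes ({n_genes})"
            )
        if self.prior_df_v0 < 0:
            raise ConfigError("prior_df_v0 must be non-negative")
        if self.prior_df_v0 + n_min - 2 <= 0:
            raise ConfigError("v0 + n - 2 must be positive for the variance posterior")


def _windowed_background(group_means: np.ndarray, s2: np.ndarray, w: int) -> np.ndarray:
    """Mean sample variance over the w genes nearest in rank of group mean.

    Ranks are by ascending group mean with a stable sort; at the edges the
    window is shifted inward so it always contains exactly w genes.
    """
    m = group_means.shape[0]
    order = np.argsort(group_means, kind="stable")
    s2_sorted = s2[order]
    csum = np.concatenate(([0.0], np.cumsum(s2_sorted)))
    half = w // 2
    pos = np.arange(m)
    start = np.clip(pos - half, 0, m - w)
    bg_sorted = (csum[start + w] - csum[start]) / w
    bg = np.empty(m)
    bg[order] = bg_sorted
    return bg


def cybert_test(matrix: ExpressionMatrix, params: CybertParams | None = None) -> pd.DataFrame:
    """Run the regularized t-test between the matrix's two sample groups.

    Returns a DataFrame with one row per gene (matrix row order preserved)
    and columns :data:`DE_COLUMNS`.  ``log2fc`` is mean(group2) - mean(group1)
    with group order taken from first appearance over samples, i.e. a positive
    value means higher expression in the second (test) group.
    """
    params = params or CybertParams()
    g1, g2 = matrix.two_groups()
    cols1 = matrix.samples_in(g1)
    cols2 = matrix.samples_in(g2)
    n1, n2 = len(cols1), len(cols2)
    if n1 < 2 or n2 < 2:
        raise ConfigError(f"each group needs >=2 samples (got {n1} and {n2})")
    params.validate(matrix.n_rows, min(n1, n2))

    x1 = matrix.values[cols1].to_numpy(float)
    x2 = matrix.values[cols2].to_numpy(float)
    m1 = x1.mean(axis=1)
    m2 = x2.mean(axis=1)
    s2_1 = x1.var(axis=1, ddof=1)
    s2_2 = x2.var(axis=1, ddof=1)

    v0 = float(params.prior_df_v0)
    bg1 = _windowed_background(m1, s2_1, params.window_w)
    bg2 = _windowed_background(m2, s2_2, params.window_w)
    reg1 = (v0 * bg1 + (n1 - 1) * s2_1) / (v0 + n1 - 2)
    reg2 = (v0 * bg2 + (n2 - 1) * s2_2) / (v0 + n2 - 2)

    delta = m2 - m1
    se = np.sqrt(reg1 / n1 + reg2 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_reg = np.where(delta == 0.0, 0.0, delta / se)
    dof = v0 + n1 + v0 + n2 - 4
    p = np.where(delta == 0.0, 1.0, 2.0 * stats.t.sf(np.abs(t_reg), dof))
    q = bh_adjust(p)

    return pd.DataFrame(
        {
            "gene": matrix.row_ids,
            "mean_g1": m1,
            "mean_g2": m2,
            "log2fc": delta,
            "s2_g1": s2_1,
            "s2_g2": s2_2,
            "s2_bg_g1": bg1,
            "s2_bg_g2": bg2,
            "t_reg": t_reg,
            "p_nominal": p,
            "q_fdr": q,
            "direction": np.sign(delta).astype(int),
        }
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    For sorted p-values p_(1) <= ... <= p_(m),
    q_(i) = min_{j >= i} p_(j) * m / j, clipped at 1, mapped back to the
    input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ConfigError("p_values must be one-dimensional")
    if p.size == 0:
        return np.array([])
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ConfigError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def direction_counts(results: pd.DataFrame) -> tuple[int, int]:
    """(n_down, n_up): genes with negative / positive log2 fold change."""
    if len(results) == 0:
        raise ConfigError("empty differential-expression table")
    fc = results["log2fc"].to_numpy(float)
    return int((fc < 0).sum()), int((fc > 0).sum())


def de_gene_list(
    results: pd.DataFrame, fdr: float = 0.01, direction: str | None = None
) -> list[str]:
    """Genes passing the FDR cut, optionally restricted to one direction.

    ``direction`` may be ``"up"``, ``"down"`` or None (both directions).
    """
    mask = results["q_fdr"].to_numpy(float) <= fdr
    fc = results["log2fc"].to_numpy(float)
    if direction == "up":
        mask &= fc > 0
    elif direction == "down":
        mask &= fc < 0
    elif direction is not None:
        raise ConfigError(f"direction must be 'up', 'down' or None, got {direction!r}")
    return [str(g) for g in results.loc[mask, "gene"]]
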