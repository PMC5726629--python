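"""Gene set enrichment analysis with a gene-set permutation null.

Genes are ranked by a differential metric between the two sample groups;
each gene set is scored by the weighted Kolmogorov-Smirnov running sum of
the ranked list.  Walking down the ranking, encountering a set member at
rank j increments the sum by |r_j|^p / N_R (N_R the sum of |r|^p over
members) and a non-member decrements it by 1 / (N - N_hits).  The
enrichment score ES is the running-sum value of maximal absolute deviation
from zero; members at or before (after, for negative ES) the extremum form
the leading edge.

Significance uses *gene-set permutation*: for each set size, random
same-size gene sets are drawn from the ranked universe.  The normalized
enrichment score NES divides ES by the mean magnitude of same-sign
permuted scores, the nominal p-value is the same-sign permutation tail
fraction with a +1 pseudo-count, and the FDR q-value is the standard ratio
of the pooled-permutation and observed NES tail fractions, computed
separately for the positive and negative sides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ConfigError, ExpressionMatrix, GeneSetCollection
from .diffexp import CybertParams, cybert_test

#: Columns of the GSEA result table.
GSEA_COLUMNS = (
    "set_name",
    "size_used",
    "es",
    "nes",
    "p_nominal",
    "q_fdr",
    "direction",
    "leading_edge",
)

RANK_METRICS = ("signal2noise", "t_reg")


@dataclass(frozen=True)
class GseaParams:
    """Knobs of the enrichment run.

    weight_p
        Exponent on |score| in the running sum (1 = the standard weighted
        statistic; 0 = classic unweighted Kolmogorov-Smirnov).
    n_perm
        Number of random same-size gene sets per set size.
    min_size, max_size
        Set-size bounds applied after restricting sets to dataset genes.
    metric
        ``signal2noise`` (group-difference over summed floored sds) or
        ``t_reg`` (the regularized t statistic).
    """

    weight_p: float = 1.0
    n_perm: int = 1000
    min_size: int = 15
    max_size: int = 500
    metric: str = "signal2noise"
    seed: int = 0

    def validate(self) -> None:
        if self.n_perm < 1:
            raise ConfigError("n_perm must be >= 1")
        if self.min_size > self.max_size or self.min_size < 1:
            raise ConfigError("need 1 <= min_size <= max_size")
        if self.weight_p < 0:
            raise ConfigError("weight_p must be non-negative")
        if self.metric not in RANK_METRICS:
            raise ConfigError(f"metric must be one of {RANK_METRICS}")


def rank_genes(
    matrix: ExpressionMatrix,
    metric: str = "signal2noise",
    cybert_params: CybertParams | None = None,
) -> pd.DataFrame:
    """Rank all genes by a two-group differential metric, best-up first.

    signal2noise is (mean_test - mean_ref) / (sd_test + sd_ref) with each
    sd floored at max(0.2 * |group mean|, 0.2).  Ties are broken by gene
    symbol ascending, so the ranking is deterministic.
    """
    if metric == "t_reg":
        de = cybert_test(matrix, cybert_params)
        df = pd.DataFrame({"gene": de["gene"].astype(str).str.upper(),
                           "score": de["t_reg"].to_numpy(float)})
    elif metric == "signal2noise":
        g1, g2 = matrix.two_groups()
        c1, c2 = matrix.samples_in(g1), matrix.samples_in(g2)
        if len(c1) < 2 or len(c2) < 2:
            raise ConfigError("signal2noise requires >=2 samples per group")
        x1 = matrix.values[c1].to_numpy(float)
        x2 = matrix.values[c2].to_numpy(float)
        m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
        s1 = np.maximum(x1.std(axis=1, ddof=1), np.maximum(0.2 * np.abs(m1), 0.2))
        s2 = np.maximum(x2.std(axis=1, ddof=1), np.maximum(0.2 * np.abs(m2), 0.2))
        df = pd.DataFrame(
            {"gene": [str(g).upper() for g in matrix.row_ids],
             "score": (m2 - m1) / (s2 + s1)}
        )
    else:
        raise ConfigError(f"unknown metric {metric!r}")
    if df["gene"].duplicated().any():
        raise ConfigError("ranking requires collapsed (unique) gene symbols")
    return df.sort_values(
        ["score", "gene"], ascending=[False, True], kind="stable", ignore_index=True
    )


@dataclass
class ESResult:
    es: float
    running_sum: np.ndarray
    leading_edge_idx: np.ndarray  # positions (ranks) of leading-edge members


def enrichment_score(
    scores: np.ndarray, member_flags: np.ndarray, weight_p: float = 1.0
) -> ESResult:
    """Running-sum enrichment score of one set over a ranked score vector.

    ``scores`` must already be in ranking order (descending);
    ``member_flags`` marks set members.  Returns the signed ES, the full
    running sum (which ends at zero up to rounding) and the ranks of the
    leading-edge members.
    """
    scores = np.asarray(scores, dtype=float)
    member = np.asarray(member_flags, dtype=bool)
    n = scores.size
    n_hit = int(member.sum())
    if n_hit == 0:
        raise ConfigError("gene set has no members in the ranked list")
    w = np.where(member, np.abs(scores) ** weight_p, 0.0)
    n_r = w.sum()
    if n_r == 0.0:
        raise ConfigError("all member scores are zero; running sum is undefined")
    miss = 1.0 / (n - n_hit) if n > n_hit else 0.0
    inc = np.where(member, w / n_r, -miss)
    run = np.cumsum(inc)
    # earliest extremum wins; the 1e-12 slack makes the choice stable when a
    # positive peak and a negative dip tie in magnitude up to rounding
    absrun = np.abs(run)
    i = int(np.argmax(absrun >= absrun.max() - 1e-12))
    es = float(np.clip(run[i], -1.0, 1.0))  # rounding can overshoot |es| = 1
    idx = np.flatnonzero(member)
    leading = idx[idx <= i] if es >= 0 else idx[idx >= i]
    return ESResult(es, run, leading)


def _es_from_indices(idx: np.ndarray, w: np.ndarray, n: int) -> np.ndarray:
    """Enrichment scores from member rank indices alone (vectorized).

    ``idx`` is (..., k) of ascending member positions, ``w`` the matching
    |score|^p weights.  Only the running-sum values at hits and immediately
    before hits can be extrema, so the full N-length walk is avoided.
    Rows whose weights sum to zero get ES = 0.
    """
    idx = np.atleast_2d(idx)
    w = np.atleast_2d(w)
    k = idx.shape[-1]
    cumw = np.cumsum(w, axis=-1)
    n_r = cumw[..., -1:]
    safe = np.where(n_r == 0.0, 1.0, n_r)
    miss = 1.0 / (n - k) if n > k else 0.0
    j = np.arange(k)
    at_hit = cumw / safe - (idx - j) * miss
    before = (cumw - w) / safe - (idx - j) * miss
    cand = np.empty(idx.shape[:-1] + (2 * k,))
    cand[..., 0::2] = before
    cand[..., 1::2] = at_hit
    # candidates are laid out in walk order; same earliest-extremum tie rule
    # (with 1e-12 slack) as the full running-sum path
    absc = np.abs(cand)
    mx = absc.max(axis=-1, keepdims=True)
    best = np.argmax(absc >= mx - 1e-12, axis=-1)
    es = np.clip(np.take_along_axis(cand, best[..., None], axis=-1)[..., 0], -1.0, 1.0)
    return np.where(n_r[..., 0] == 0.0, 0.0, es)


def _tail_fraction(pool: np.ndarray, value: float, side: str) -> float:
    if pool.size == 0:
        return 0.0
    if side == "ge":
        return float((pool >= value).sum()) / pool.size
    return float((pool <= value).sum()) / pool.size


def gsea_run(
    matrix: ExpressionMatrix,
    catalog: GeneSetCollection,
    params: GseaParams | None = None,
    ranking: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Score every catalog set on the ranked dataset.

    ``ranking`` may be supplied to reuse a precomputed gene ranking (e.g.
    when scoring several catalogs against the same comparison); otherwise
    it is computed from the matrix with the configured metric.  Returns a
    DataFrame with columns :data:`GSEA_COLUMNS`, sorted by descending NES.
    Deterministic given the seed: permutations are drawn once from a seeded
    generator and shared across set sizes.
    """
    params = params or GseaParams()
    params.validate()
    if ranking is None:
        ranking = rank_genes(matrix, params.metric)
    genes = ranking["gene"].to_numpy(dtype=object)
    scores = ranking["score"].to_numpy(float)
    n = genes.size
    pos_of = {g: i for i, g in enumerate(genes)}
    weights_full = np.abs(scores) ** params.weight_p

    kept = []
    for s in catalog:
        idx = np.array(sorted(pos_of[m] for m in s.members if m in pos_of), dtype=int)
        if params.min_size <= idx.size <= params.max_size:
            kept.append((s.name, idx))
    if not kept:
        raise ConfigError(
            f"no gene sets within size bounds [{params.min_size}, {params.max_size}]"
        )

    rng = np.random.default_rng(params.seed)
    # one permutation table reused for every set size: the first k columns of
    # each random permutation are a uniform k-subset of the universe
    perms = np.argsort(rng.random((params.n_perm, n)), axis=1)

    sizes = sorted({idx.size for _, idx in kept})
    perm_es_by_size: dict[int, np.ndarray] = {}
    pos_mean: dict[int, float] = {}
    neg_mean: dict[int, float] = {}
    perm_nes_by_size: dict[int, np.ndarray] = {}
    for k in sizes:
        pidx = np.sort(perms[:, :k], axis=1)
        pes = _es_from_indices(pidx, weights_full[pidx], n)
        perm_es_by_size[k] = pes
        pos = pes[pes > 0]
        neg = pes[pes < 0]
        fallback = np.abs(pes).mean() if pes.size else 1.0
        pos_mean[k] = float(pos.mean()) if pos.size else float(fallback or 1.0)
        neg_mean[k] = float(np.abs(neg).mean()) if neg.size else float(fallback or 1.0)
        nes = np.where(pes > 0, pes / pos_mean[k], np.where(pes < 0, pes / neg_mean[k], 0.0))
        perm_nes_by_size[k] = nes

    rows = []
    for name, idx in kept:
        member = np.zeros(n, dtype=bool)
        member[idx] = True
        esr = enrichment_score(scores, member, params.weight_p)
        es = esr.es
        k = idx.size
        pes = perm_es_by_size[k]
        if es > 0:
            nes = es / pos_mean[k]
            pool = pes[pes > 0]
            p = (1.0 + float((pool >= es).sum())) / (1.0 + pool.size)
        elif es < 0:
            nes = es / neg_mean[k]
            pool = pes[pes < 0]
            p = (1.0 + float((pool <= es).sum())) / (1.0 + pool.size)
        else:
            nes, p = 0.0, 1.0
        leading = [str(genes[i]) for i in esr.leading_edge_idx]
        rows.append((name, k, es, nes, p, leading))

    obs_nes = np.array([r[3] for r in rows])
    pooled = np.concatenate([perm_nes_by_size[r[1]] for r in rows])
    pooled_pos = pooled[pooled > 0]
    pooled_neg = pooled[pooled < 0]
    obs_pos = obs_nes[obs_nes > 0]
    obs_neg = obs_nes[obs_nes < 0]
    qs = []
    for nes in obs_nes:
        if nes > 0:
            num = _tail_fraction(pooled_pos, nes, "ge")
            den = _tail_fraction(obs_pos, nes, "ge")
        elif nes < 0:
            num = _tail_fraction(pooled_neg, nes, "le")
            den = _tail_fraction(obs_neg, nes, "le")
        else:
            num, den = 1.0, 1.0
        q = num / den if den > 0 else 0.0
        qs.append(min(max(q, 0.0), 1.0))

    df = pd.DataFrame(
        {
            "set_name": [r[0] for r in rows],
            "size_used": [r[1] for r in rows],
            "es": [r[2] for r in rows],
            "nes": obs_nes,
            "p_nominal": [r[4] for r in rows],
            "q_fdr": qs,
            "direction": np.sign(obs_nes).astype(int),
            "leading_edge": [",".join(r[5]) for r in rows],
        }
    )
    return df.sort_values(
        ["nes", "set_name"], ascending=[False, True], kind="stable", ignore_index=True
    )[list(GSEA_COLUMNS)]


def running_sum_table(
    ranking: pd.DataFrame, members, weight_p: float = 1.0
) -> pd.DataFrame:
    """Per-rank running-sum trace of one set against a ranking (for export)."""
    genes = ranking["gene"].to_numpy(dtype=object)
    scores = ranking["score"].to_numpy(float)
    mset = {str(m).upper() for m in members}
    flags = np.array([g in mset for g in genes])
    esr = enrichment_score(scores, flags, weight_p)
    return pd.DataFrame(
        {"rank": np.arange(1, genes.size + 1), "gene": genes, "score": scores,
         "member": flags.astype(int), "running_sum": esr.running_sum}
    )
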