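"""Hypergeometric over-representation analysis of DE gene lists.

Given a list of differentially expressed genes, a gene universe (by default
all genes on the collapsed array, not the genome) and a catalog of gene
sets, each set is scored by the upper-tail hypergeometric probability of
observing at least the seen overlap:

    p = P(X >= k),  X ~ Hypergeom(N, K, n)

with N the universe size, K the set's members inside the universe, n the
DE-list size and k the observed overlap.  Up- and downregulated lists are
tested separately; p-values are BH-adjusted across all tested sets.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd
from scipy import stats

from .containers import ConfigError, GeneSetCollection
from .diffexp import bh_adjust

#: Columns of the ORA result table.
ORA_COLUMNS = ("set_name", "N", "K", "n", "k", "p_nominal", "q_fdr", "overlap_genes")


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Exact upper-tail P(X >= k) for X ~ Hypergeom(N, K, n)."""
    if not 0 <= k <= min(K, n):
        raise ConfigError(f"infeasible overlap k={k} for K={K}, n={n}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def ora_test(
    de_list: Iterable[str],
    catalog: GeneSetCollection,
    universe: Iterable[str],
) -> pd.DataFrame:
    """Score every catalog set for over-representation in ``de_list``.

    ``de_list`` must be a subset of ``universe``; catalog members are
    intersected with the universe before testing.  Returns a DataFrame with
    columns :data:`ORA_COLUMNS`, ordered by ascending nominal p then name.
    """
    uni = {str(g).upper() for g in universe}
    de = {str(g).upper() for g in de_list}
    if not uni:
        raise ConfigError("empty universe")
    if not de:
        raise ConfigError("empty DE gene list")
    stray = de - uni
    if stray:
        raise ConfigError(
            f"{len(stray)} DE genes are outside the universe (e.g. {sorted(stray)[:5]})"
        )
    N, n = len(uni), len(de)
    rows = []
    for s in catalog:
        inside = [m for m in s.members if m in uni]
        K = len(inside)
        if K == 0:
            continue
        overlap = sorted(m for m in inside if m in de)
        k = len(overlap)
        p = hypergeom_tail(N, K, n, k)
        rows.append((s.name, N, K, n, k, p, ",".join(overlap)))
    if not rows:
        raise ConfigError("no catalog set intersects the universe")
    df = pd.DataFrame(
        rows, columns=["set_name", "N", "K", "n", "k", "p_nominal", "overlap_genes"]
    )
    df["q_fdr"] = bh_adjust(df["p_nominal"].to_numpy())
    df = df.sort_values(["p_nominal", "set_name"], kind="stable", ignore_index=True)
    return df[list(ORA_COLUMNS)]
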