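"""Transcription-factor x pathway integration of enrichment results.

The headline analysis of the pipeline: build a search space of
significantly enriched transcription-factor target sets and canonical
pathway / hallmark sets (one direction at a time), intersect every TF set
with every pathway set through the genes they share, keep only genes that
are themselves significantly dysregulated in the matching direction, and
summarise the surviving connections as a TF x pathway contingency table
(ready for a Circos table viewer) plus per-connection gene lists.  An
enrichment-map overlap graph of the enriched sets is exported alongside.

Direction conventions: ``down`` uses negatively enriched sets and
negative fold changes at the looser FDR (default 0.01); ``up`` uses
positively enriched sets and positive fold changes at the stricter FDR
(default 0.001) and additionally drops connections with fewer than four
member genes, mirroring the plotted day-5 analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .containers import ConfigError, GeneSetCollection

logger = logging.getLogger("renin_gsx")

DIRECTIONS = ("down", "up")


@dataclass(frozen=True)
class IntegrationThresholds:
    """Direction-specific significance and plotting filters."""

    fdr_set_down: float = 0.01
    fdr_gene_down: float = 0.01
    fdr_set_up: float = 0.001
    fdr_gene_up: float = 0.001
    #: plotted up-direction connections need at least this many member genes
    min_connection_genes_up: int = 4
    #: drop TFs connected to a single pathway from the plotted table
    drop_single_pathway_tfs: bool = True

    def validate(self) -> None:
        for name in ("fdr_set_down", "fdr_gene_down", "fdr_set_up", "fdr_gene_up"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name} must lie in (0, 1), got {v}")
        if self.min_connection_genes_up < 1:
            raise ConfigError("min_connection_genes_up must be >= 1")

    def set_fdr(self, direction: str) -> float:
        return self.fdr_set_down if direction == "down" else self.fdr_set_up

    def gene_fdr(self, direction: str) -> float:
        return self.fdr_gene_down if direction == "down" else self.fdr_gene_up


def _check_direction(direction: str) -> None:
    if direction not in DIRECTIONS:
        raise ConfigError(f"direction must be one of {DIRECTIONS}, got {direction!r}")


def build_search_space(
    gsea_tft: pd.DataFrame,
    gsea_pathways: pd.DataFrame,
    thresholds: IntegrationThresholds,
    direction: str,
) -> tuple[list[str], list[str]]:
    """Significantly enriched TF and pathway set names for one direction.

    A set is retained when its FDR q-value is at or below the direction's
    set threshold and its NES sign matches the direction.  An empty search
    space is a warning, not an error.
    """
    _check_direction(direction)
    thresholds.validate()
    fdr = thresholds.set_fdr(direction)

    def _pick(df: pd.DataFrame) -> list[str]:
        q = df["q_fdr"].to_numpy(float)
        nes = df["nes"].to_numpy(float)
        sign_ok = nes < 0 if direction == "down" else nes > 0
        return [str(n) for n in df.loc[(q <= fdr) & sign_ok, "set_name"]]

    tf_names, pw_names = _pick(gsea_tft), _pick(gsea_pathways)
    if not tf_names or not pw_names:
        logger.warning(
            "empty %s search space (%d TF sets, %d pathway sets retained)",
            direction, len(tf_names), len(pw_names),
        )
    return tf_names, pw_names


@dataclass
class IntersectionTable:
    """TF x pathway connections through significantly dysregulated genes.

    ``connections`` holds every non-empty intersection after the gene-level
    significance and direction filters; ``plot_connections`` additionally
    applies the plotting filters (minimum connection size for the up
    direction, removal of single-pathway TFs).  ``matrix`` is the count
    table of the plotted connections.
    """

    direction: str
    connections: dict[tuple[str, str], list[str]]
    thresholds: IntegrationThresholds = field(default_factory=IntegrationThresholds)

    @property
    def plot_connections(self) -> dict[tuple[str, str], list[str]]:
        conns = dict(self.connections)
        if self.direction == "up":
            conns = {
                key: genes
                for key, genes in conns.items()
                if len(genes) >= self.thresholds.min_connection_genes_up
            }
        if self.thresholds.drop_single_pathway_tfs:
            n_paths: dict[str, int] = {}
            for (tf, _pw) in conns:
                n_paths[tf] = n_paths.get(tf, 0) + 1
            conns = {k: v for k, v in conns.items() if n_paths[k[0]] > 1}
        return conns

    @property
    def matrix(self) -> pd.DataFrame:
        return connection_matrix(self.plot_connections)

    def gene_table(self) -> pd.DataFrame:
        """Long-format table of every (TF, pathway, gene) triple (unfiltered)."""
        rows = [
            (tf, pw, g)
            for (tf, pw), genes in sorted(self.connections.items())
            for g in genes
        ]
        return pd.DataFrame(rows, columns=["tf_set", "pathway_set", "gene"])


def connection_matrix(connections: Mapping[tuple[str, str], list[str]]) -> pd.DataFrame:
    """Count matrix of a connection map; stable, sum-then-name ordered axes."""
    tfs = sorted({k[0] for k in connections})
    pws = sorted({k[1] for k in connections})
    mat = pd.DataFrame(0, index=tfs, columns=pws, dtype=int)
    for (tf, pw), genes in connections.items():
        mat.loc[tf, pw] = len(genes)
    row_order = sorted(tfs, key=lambda t: (-int(mat.loc[t].sum()), t))
    col_order = sorted(pws, key=lambda p: (-int(mat[p].sum()), p))
    mat = mat.loc[row_order, col_order]
    mat.index.name = "tf_set"
    return mat


def _members_of(sets, names: Iterable[str]) -> dict[str, frozenset[str]]:
    if isinstance(sets, GeneSetCollection):
        table = {s.name: s.member_set() for s in sets}
    else:
        table = {str(n): frozenset(str(m).upper() for m in ms) for n, ms in sets.items()}
    out = {}
    for name in names:
        if name not in table:
            raise ConfigError(f"set {name!r} missing from the supplied catalog")
        out[name] = table[name]
    return out


def intersect(
    tf_sets,
    pathway_sets,
    de_results: pd.DataFrame,
    thresholds: IntegrationThresholds | None = None,
    direction: str = "up",
    tf_names: Iterable[str] | None = None,
    pathway_names: Iterable[str] | None = None,
) -> IntersectionTable:
    """Intersect TF and pathway sets through significant, direction-matched genes.

    ``tf_sets`` and ``pathway_sets`` may be :class:`GeneSetCollection`
    objects or plain name -> members mappings; ``tf_names`` /
    ``pathway_names`` optionally restrict them (e.g. to a search space from
    :func:`build_search_space`).  A gene joins connection (T, P) iff it
    belongs to both sets, its BH q-value is at or below the direction's
    gene threshold, and its fold-change sign matches the direction.
    """
    _check_direction(direction)
    thresholds = thresholds or IntegrationThresholds()
    thresholds.validate()
    tf_map = _members_of(
        tf_sets,
        tf_names if tf_names is not None
        else (tf_sets.names() if isinstance(tf_sets, GeneSetCollection) else tf_sets.keys()),
    )
    pw_map = _members_of(
        pathway_sets,
        pathway_names if pathway_names is not None
        else (pathway_sets.names() if isinstance(pathway_sets, GeneSetCollection)
              else pathway_sets.keys()),
    )

    q = de_results["q_fdr"].to_numpy(float)
    fc = de_results["log2fc"].to_numpy(float)
    sign_ok = fc < 0 if direction == "down" else fc > 0
    keep = (q <= thresholds.gene_fdr(direction)) & sign_ok
    sig_genes = {str(g).upper() for g in de_results.loc[keep, "gene"]}

    connections: dict[tuple[str, str], list[str]] = {}
    for tf, t_members in tf_map.items():
        t_sig = t_members & sig_genes
        if not t_sig:
            continue
        for pw, p_members in pw_map.items():
            shared = sorted(t_sig & p_members)
            if shared:
                connections[(tf, pw)] = shared
    return IntersectionTable(direction, connections, thresholds)


def validate_table(
    table: IntersectionTable,
    tf_sets,
    pathway_sets,
    de_results: pd.DataFrame,
) -> None:
    """Independently re-check every exported gene against all three predicates.

    Raises :class:`ConfigError` on the first violation; used as a
    self-consistency guard after :func:`intersect`.
    """
    tf_map = _members_of(tf_sets, {k[0] for k in table.connections})
    pw_map = _members_of(pathway_sets, {k[1] for k in table.connections})
    de = de_results.set_index(de_results["gene"].astype(str).str.upper())
    fdr = table.thresholds.gene_fdr(table.direction)
    for (tf, pw), genes in table.connections.items():
        for g in genes:
            if g not in tf_map[tf] or g not in pw_map[pw]:
                raise ConfigError(f"{g} not a member of both {tf} and {pw}")
            row = de.loc[g]
            if float(row["q_fdr"]) > fdr:
                raise ConfigError(f"{g} fails the gene FDR filter in ({tf}, {pw})")
            fc = float(row["log2fc"])
            if (table.direction == "down") != (fc < 0) or fc == 0:
                raise ConfigError(f"{g} has the wrong fold-change sign in ({tf}, {pw})")
    mat = table.matrix
    for (tf, pw), genes in table.plot_connections.items():
        if int(mat.loc[tf, pw]) != len(genes):
            raise ConfigError(f"matrix cell ({tf}, {pw}) disagrees with its gene list")


def contingency_export(table: IntersectionTable, path: str | Path) -> None:
    """Write the plotted count matrix as a Circos-tableviewer-ready TSV.

    First row holds the pathway labels, first column the TF labels, cells
    the gene counts (zeros written as 0).  An empty table yields a
    header-only file.
    """
    mat = table.matrix
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(["tf_set", *map(str, mat.columns)]) + "\n")
        for tf in mat.index:
            fh.write("\t".join([str(tf), *(str(int(v)) for v in mat.loc[tf])]) + "\n")


def gene_detail_table(table: IntersectionTable, de_results: pd.DataFrame) -> pd.DataFrame:
    """Fold change and q-value of every connection gene (long format)."""
    de = de_results.set_index(de_results["gene"].astype(str).str.upper())
    rows = []
    for (tf, pw), genes in sorted(table.connections.items()):
        for g in genes:
            rows.append(
                (tf, pw, g, float(de.loc[g, "log2fc"]), float(de.loc[g, "q_fdr"]))
            )
    return pd.DataFrame(rows, columns=["tf_set", "pathway_set", "gene", "log2fc", "q_fdr"])


def top_connection_genes(
    table: IntersectionTable, de_results: pd.DataFrame, n: int = 4
) -> list[str]:
    """The n most significant distinct genes across all connections.

    Ranked by BH q-value ascending, then |log2 fold change| descending,
    then symbol; this is the rule behind the genes picked for qPCR-style
    validation.
    """
    detail = gene_detail_table(table, de_results).drop_duplicates("gene")
    detail = detail.assign(absfc=detail["log2fc"].abs())
    ordered = detail.sort_values(
        ["q_fdr", "absfc", "gene"], ascending=[True, False, True], kind="stable"
    )
    return [str(g) for g in ordered["gene"].head(n)]


def overlap_coefficient(a: frozenset[str], b: frozenset[str]) -> float:
    """|A n B| / min(|A|, |B|); 0 for an empty smaller set."""
    m = min(len(a), len(b))
    return len(a & b) / m if m else 0.0


def enrichment_map(
    enriched: pd.DataFrame,
    members: Mapping[str, Iterable[str]],
    similarity_cutoff: float = 0.5,
) -> nx.Graph:
    """Overlap graph of enriched sets (the enrichment-map visual summary).

    ``enriched`` is a GSEA result table restricted to the sets to plot
    (typically FDR <= 0.01); ``members`` maps each of those set names to
    its dataset-restricted members.  Nodes carry nes, q, size and
    direction; an edge joins two sets whose overlap coefficient reaches
    ``similarity_cutoff``, weighted by the coefficient.
    """
    g = nx.Graph()
    msets: dict[str, frozenset[str]] = {}
    for row in enriched.itertuples(index=False):
        name = str(row.set_name)
        if name not in members:
            raise ConfigError(f"no member list supplied for enriched set {name!r}")
        msets[name] = frozenset(str(m).upper() for m in members[name])
        g.add_node(
            name,
            nes=float(row.nes),
            q=float(row.q_fdr),
            size=len(msets[name]),
            direction=int(np.sign(row.nes)),
        )
    names = list(msets)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            coef = overlap_coefficient(msets[a], msets[b])
            if coef >= similarity_cutoff:
                g.add_edge(a, b, weight=coef)
    return g


def export_graph(graph: nx.Graph, nodes_path: str | Path, edges_path: str | Path) -> None:
    """Node and edge TSVs importable by graph tools."""
    nodes = pd.DataFrame(
        [
            {"set_name": n, **{k: d[k] for k in ("nes", "q", "size", "direction")}}
            for n, d in sorted(graph.nodes(data=True))
        ]
    )
    edges = pd.DataFrame(
        [
            {"source": a, "target": b, "weight": d["weight"]}
            for a, b, d in sorted(graph.edges(data=True))
        ],
        columns=["source", "target", "weight"],
    )
    from .io import write_tsv_results

    write_tsv_results(nodes, nodes_path)
    write_tsv_results(edges, edges_path)
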