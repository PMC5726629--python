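"""Readers and writers for the standard file formats the pipeline touches.

Supported formats: GCT v1.2 (expression), CLS categorical (two-group
design), GMT (gene-set catalogs), RNK (ranked gene lists) and plain TSV as
the canonical internal interchange.  All writers are deterministic: stable
ordering, UTF-8, Unix line endings, floats at six significant digits.

Gene symbols are uppercased on ingestion everywhere.  The study organism is
mouse but the motif/pathway catalogs use human-centric symbols, so
case-insensitive matching is the only join that works across catalogs;
matched/unmatched counts are logged where symbols are joined.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, FormatError, GeneSet, GeneSetCollection

logger = logging.getLogger("renin_gsx")

#: fixed float format used by every writer
FLOAT_FMT = "%.6g"


def _fmt(x: float) -> str:
    return FLOAT_FMT % x


# ---------------------------------------------------------------------------
# GCT v1.2


def read_gct(path: str | Path) -> ExpressionMatrix:
    """Read a GCT v1.2 expression file (no group labels attached)."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        version = fh.readline().strip()
        if not version.startswith("#1.2"):
            raise FormatError(f"{path}:1: expected '#1.2' header, got {version!r}")
        dims = fh.readline().split()
        if len(dims) < 2:
            raise FormatError(f"{path}:2: expected '<rows>\\t<cols>' dimension line")
        n_rows, n_cols = int(dims[0]), int(dims[1])
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2 + n_cols:
            raise FormatError(
                f"{path}:3: header declares {len(header) - 2} samples, "
                f"dimension line declares {n_cols}"
            )
        samples = header[2 : 2 + n_cols]
        ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=4):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2 + n_cols:
                raise FormatError(
                    f"{path}:{lineno}: expected {2 + n_cols} fields, got {len(parts)}"
                )
            ids.append(parts[0])
            try:
                rows.append([float(v) for v in parts[2:]])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric value ({exc})") from None
    if len(ids) != n_rows:
        raise FormatError(
            f"{path}: dimension line declares {n_rows} rows but body contains {len(ids)}"
        )
    values = pd.DataFrame(np.asarray(rows, dtype=float), index=ids, columns=samples)
    return ExpressionMatrix(values)


def write_gct(matrix: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    vals = matrix.values
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("#1.2\n")
        fh.write(f"{vals.shape[0]}\t{vals.shape[1]}\n")
        fh.write("NAME\tDescription\t" + "\t".join(map(str, vals.columns)) + "\n")
        arr = vals.to_numpy(float)
        for rid, row in zip(vals.index, arr):
            fh.write(str(rid) + "\tna\t" + "\t".join(_fmt(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# CLS (categorical)


def read_cls(path: str | Path) -> list[str]:
    """Read a categorical CLS file; returns the per-sample group labels.

    The pipeline's comparisons are two-group, so fewer than two distinct
    classes is rejected here.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text(encoding="utf-8").splitlines() if ln.strip()]
    if len(lines) < 3:
        raise FormatError(f"{path}: CLS requires 3 lines")
    head = lines[0].split()
    if len(head) < 3:
        raise FormatError(f"{path}:1: expected '<n> <k> 1'")
    n, k = int(head[0]), int(head[1])
    labels_line = lines[1].split()
    if not labels_line or labels_line[0] != "#":
        raise FormatError(f"{path}:2: expected '# <labels>'")
    labels = labels_line[1:]
    if len(labels) != k:
        raise FormatError(f"{path}:2: {len(labels)} labels declared, header says {k}")
    if k < 2:
        raise FormatError(f"{path}: two groups required, found {k}")
    tokens = lines[2].split()
    if len(tokens) != n:
        raise FormatError(f"{path}:3: {len(tokens)} assignments, header says {n}")
    out: list[str] = []
    for tok in tokens:
        if tok in labels:
            out.append(tok)
        else:
            try:
                out.append(labels[int(tok)])
            except (ValueError, IndexError):
                raise FormatError(f"{path}:3: unknown class token {tok!r}") from None
    if len(set(out)) != k:
        raise FormatError(
            f"{path}: assignments use {len(set(out))} distinct classes, header says {k}"
        )
    return out


def write_cls(labels: Sequence[str], path: str | Path) -> None:
    distinct: list[str] = []
    for lab in labels:
        if lab not in distinct:
            distinct.append(lab)
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"{len(labels)} {len(distinct)} 1\n")
        fh.write("# " + " ".join(distinct) + "\n")
        fh.write(" ".join(str(distinct.index(lab)) for lab in labels) + "\n")


def attach_groups(matrix: ExpressionMatrix, labels: Sequence[str]) -> ExpressionMatrix:
    """Pair a CLS label vector with a matrix's samples, by position."""
    if len(labels) != matrix.n_samples:
        raise FormatError(
            f"CLS declares {len(labels)} samples, matrix has {matrix.n_samples}"
        )
    return ExpressionMatrix(
        matrix.values, dict(zip(matrix.sample_ids, map(str, labels)))
    )


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: str | Path, catalog_tag: str = "OTHER") -> GeneSetCollection:
    """Read a GMT catalog; members are uppercased and de-duplicated per line."""
    path = Path(path)
    coll = GeneSetCollection()
    n_dupes = 0
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            what = f"gene set {parts[0]!r}" if parts[0].strip() else "GMT line"
            raise FormatError(
                f"{path}:{lineno}: {what} needs a description and >=1 member"
            )
        name, desc = parts[0], parts[1]
        raw = [p for p in parts[2:] if p.strip()]
        members: list[str] = []
        seen: set[str] = set()
        for m in raw:
            u = m.upper()
            if u in seen:
                n_dupes += 1
                continue
            seen.add(u)
            members.append(u)
        if not members:
            raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
        if name in coll:
            raise FormatError(f"{path}:{lineno}: duplicate gene set name {name!r}")
        coll.add(GeneSet(name, catalog_tag, desc, tuple(members)))
    if n_dupes:
        logger.warning("read_gmt(%s): dropped %d duplicate members", path, n_dupes)
    return coll


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description or "na", *s.members]) + "\n")


# ---------------------------------------------------------------------------
# RNK and generic TSV


def write_rnk(ranking: pd.DataFrame, path: str | Path) -> None:
    """Write a two-column RNK file ordered by descending score.

    ``ranking`` must have columns ``gene`` and ``score``.  Ties are broken
    by gene symbol ascending so output is deterministic; NaN scores are
    rejected.
    """
    if ranking["score"].isna().any():
        raise FormatError("RNK scores must not be NaN")
    ordered = ranking.sort_values(
        ["score", "gene"], ascending=[False, True], kind="stable"
    )
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for gene, score in zip(ordered["gene"], ordered["score"]):
            fh.write(f"{gene}\t{_fmt(score)}\n")


def read_rnk(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "score"])
    if df["score"].isna().any():
        raise FormatError(f"{path}: non-numeric or missing scores")
    df["gene"] = df["gene"].astype(str).str.upper()
    return df


def write_tsv_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write any results table as TSV with fixed 6-significant-digit floats."""
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT, lineterminator="\n")


def read_tsv_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Expression matrix as TSV: first column row id, then sample columns."""
    out = matrix.values.copy()
    out.index.name = "id"
    out.to_csv(path, sep="\t", float_format=FLOAT_FMT, lineterminator="\n")


def read_tsv_matrix(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.map(str)
    return ExpressionMatrix(df)


def read_probe_map(path: str | Path) -> dict[str, str]:
    """Two-column probe -> gene-symbol TSV; symbols are uppercased."""
    df = pd.read_csv(path, sep="\t", header=None, names=["probe", "gene"], dtype=str)
    df = df.dropna()
    return {str(p): str(g).upper() for p, g in zip(df["probe"], df["gene"])}


def write_probe_map(probe_map: dict[str, str], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for probe, gene in probe_map.items():
            fh.write(f"{probe}\t{gene}\n")


def save_experiment(
    matrix: ExpressionMatrix,
    catalog: GeneSetCollection,
    truth,
    outdir: str | Path,
) -> dict[str, Path]:
    """Persist a simulated experiment in pipeline-consumable formats.

    Writes the probe matrix (GCT + TSV), group labels (CLS), the TF and
    pathway catalogs (GMT, split by tag), the probe map and the truth table
    (TSV).  Returns the paths written, keyed by artifact name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gct": outdir / "probes.gct",
        "tsv": outdir / "probes.tsv",
        "cls": outdir / "groups.cls",
        "gmt_tft": outdir / "sets_tft.gmt",
        "gmt_cp": outdir / "sets_cp.gmt",
        "probe_map": outdir / "probe_map.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_gct(matrix, paths["gct"])
    write_tsv_matrix(matrix, paths["tsv"])
    write_cls([matrix.groups[s] for s in matrix.sample_ids], paths["cls"])
    tft = GeneSetCollection()
    cp = GeneSetCollection()
    for s in catalog:
        (tft if s.catalog == "TFT" else cp).add(s)
    write_gmt(tft, paths["gmt_tft"])
    write_gmt(cp, paths["gmt_cp"])
    write_probe_map(truth.probe_map, paths["probe_map"])
    truth_df = pd.DataFrame(
        sorted(truth.de_genes.items()), columns=["gene", "effect"]
    )
    write_tsv_results(truth_df, paths["truth"])
    return paths
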