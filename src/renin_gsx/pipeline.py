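"""End-to-end orchestration: simulate -> preprocess -> diffexp -> ora -> gsea -> integrate.

A run is driven by a :class:`RunConfig` (built in code or loaded from a
YAML file).  Inputs either come from disk (GCT + CLS + probe map + GMT
catalogs) or are generated by the synthetic-data module when no input
paths are given.  Every output lands in ``outdir`` together with a
``manifest.json`` recording the configuration, package and library
versions, per-stage seeds, input checksums and record counts, so a run can
be reproduced and audited.

One global seed is expanded into per-stage sub-seeds through a fixed
name-keyed derivation (:func:`stage_seed`), so adding a stage never shifts
another stage's random stream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .containers import ConfigError, GeneSetCollection
from .diffexp import CybertParams, cybert_test, de_gene_list, direction_counts
from .gsea import GseaParams, gsea_run, rank_genes
from .integrate import (
    IntegrationThresholds,
    build_search_space,
    contingency_export,
    enrichment_map,
    export_graph,
    gene_detail_table,
    intersect,
    validate_table,
)
from .ora import ora_test
from .preprocess import collapse_probes, pca, quantile_normalize, variance_summary
from .simulate import SimulationConfig, simulate_experiment

logger = logging.getLogger("renin_gsx")

#: fixed stage-name -> derivation-index map; append only, never reorder
_STAGE_KEYS = {"simulate": 0, "gsea_tft": 1, "gsea_cp": 2}


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage sub-seed derived from the global seed by a fixed mapping."""
    if stage not in _STAGE_KEYS:
        raise ConfigError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence(entropy=global_seed, spawn_key=(_STAGE_KEYS[stage],))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    outdir: str = "run_out"
    #: input file paths; leave empty to simulate inputs instead
    gct: str | None = None
    cls: str | None = None
    probe_map: str | None = None
    gmt_tft: str | None = None
    gmt_cp: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    cybert: CybertParams = field(default_factory=CybertParams)
    gsea: GseaParams = field(default_factory=GseaParams)
    integration: IntegrationThresholds = field(default_factory=IntegrationThresholds)
    #: gene-level FDR for the ORA DE lists
    ora_gene_fdr: float = 0.01
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        for key, sub in (
            ("simulation", SimulationConfig),
            ("cybert", CybertParams),
            ("gsea", GseaParams),
            ("integration", IntegrationThresholds),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                block = dict(kwargs[key])
                if key == "simulation":
                    for tup in (
                        "probes_per_gene", "baseline_mean_range", "gene_sd_range",
                        "set_size_range", "background_effect_range",
                    ):
                        if tup in block and isinstance(block[tup], list):
                            block[tup] = tuple(block[tup])
                try:
                    kwargs[key] = sub(**block)
                except TypeError as exc:
                    raise ConfigError(f"bad {key} block: {exc}") from None
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    def validate(self) -> None:
        given = [p for p in (self.gct, self.cls) if p]
        if len(given) == 1:
            missing = "cls" if self.gct else "gct"
            raise ConfigError(f"config field {missing!r} is required alongside the other input")
        for name in ("gct", "cls", "probe_map", "gmt_tft", "gmt_cp"):
            p = getattr(self, name)
            if p and not Path(p).exists():
                raise ConfigError(f"config field {name!r}: file not found: {p}")
        if not 0 < self.ora_gene_fdr < 1:
            raise ConfigError("ora_gene_fdr must lie in (0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns the manifest written to the output dir."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "versions": _versions(),
        "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGE_KEYS},
        "inputs": {},
        "counts": {},
        "wall_times_s": {},
    }
    t_all = time.perf_counter()

    def timed(stage):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s: start", stage)

            def __exit__(self, et, ev, tb):
                if et is None:
                    dt = time.perf_counter() - self.t0
                    manifest["wall_times_s"][stage] = round(dt, 3)
                    logger.info("stage %s: done in %.2fs", stage, dt)
                return False

        return _T()

    def guard(stage, fn):
        try:
            with timed(stage):
                return fn()
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

    # ------------------------------------------------------------------ inputs
    def _inputs():
        if config.gct:
            matrix = rio.attach_groups(rio.read_gct(config.gct), rio.read_cls(config.cls))
            probe_map = rio.read_probe_map(config.probe_map) if config.probe_map else {
                r: r for r in matrix.row_ids
            }
            tft = rio.read_gmt(config.gmt_tft, "TFT") if config.gmt_tft else GeneSetCollection()
            cp = rio.read_gmt(config.gmt_cp, "CP") if config.gmt_cp else GeneSetCollection()
            for name in ("gct", "cls", "probe_map", "gmt_tft", "gmt_cp"):
                p = getattr(config, name)
                if p:
                    manifest["inputs"][name] = {"path": p, "sha256": _sha256(Path(p))}
            return matrix, tft, cp, None
        sim = dataclasses.replace(
            config.simulation, seed=stage_seed(config.seed, "simulate")
        )
        matrix, catalog, truth = simulate_experiment(sim)
        paths = rio.save_experiment(matrix, catalog, truth, out / "inputs")
        manifest["inputs"] = {
            k: {"path": str(p), "sha256": _sha256(p)} for k, p in paths.items()
        }
        tft = GeneSetCollection()
        cp = GeneSetCollection()
        for s in catalog:
            (tft if s.catalog == "TFT" else cp).add(s)
        return matrix, tft, cp, truth.probe_map

    matrix, tft, cp, sim_probe_map = guard("inputs", _inputs)
    if config.gct:
        probe_map = (
            rio.read_probe_map(config.probe_map)
            if config.probe_map
            else {r: r for r in matrix.row_ids}
        )
    else:
        probe_map = sim_probe_map
    manifest["counts"]["probes"] = matrix.n_rows
    manifest["counts"]["samples"] = matrix.n_samples

    # -------------------------------------------------------------- preprocess
    def _preprocess():
        norm = quantile_normalize(matrix)
        genes = collapse_probes(norm, probe_map)
        rio.write_gct(genes, out / "genes.gct")
        summary = pca(genes)
        coords = summary.coordinates.copy()
        coords.insert(0, "sample", coords.index)
        rio.write_tsv_results(coords, out / "pca.tsv")
        rio.write_tsv_results(
            pd.DataFrame(
                {
                    "component": [f"PC{i+1}" for i in range(summary.explained_variance_ratio.size)],
                    "explained_variance_ratio": summary.explained_variance_ratio,
                }
            ),
            out / "pca_variance.tsv",
        )
        rio.write_tsv_results(variance_summary(genes), out / "variance_summary.tsv")
        return genes, summary

    genes, pca_summary = guard("preprocess", _preprocess)
    manifest["counts"]["genes"] = genes.n_rows
    manifest["counts"]["pca_top3_variance"] = round(pca_summary.top_variance(3), 4)

    # ----------------------------------------------------------------- diffexp
    def _diffexp():
        de = cybert_test(genes, config.cybert)
        rio.write_tsv_results(de, out / "de.tsv")
        return de

    de = guard("diffexp", _diffexp)
    n_down, n_up = direction_counts(de)
    manifest["counts"]["genes_down"] = n_down
    manifest["counts"]["genes_up"] = n_up

    # --------------------------------------------------------------------- ora
    def _ora():
        universe = [str(g).upper() for g in genes.row_ids]
        merged = tft.merge(cp) if len(tft) and len(cp) else (tft if len(tft) else cp)
        for direction in ("up", "down"):
            de_list = de_gene_list(de, config.ora_gene_fdr, direction)
            if not de_list or not len(merged):
                logger.warning("ora: skipping %s (empty DE list or catalog)", direction)
                continue
            res = ora_test(de_list, merged, universe)
            rio.write_tsv_results(res, out / f"ora_{direction}.tsv")
            manifest["counts"][f"ora_{direction}_sets"] = len(res)

    guard("ora", _ora)

    # -------------------------------------------------------------------- gsea
    def _gsea():
        ranking = rank_genes(genes, config.gsea.metric, config.cybert)
        rio.write_rnk(ranking, out / "ranking.rnk")
        results = {}
        for tag, cat in (("tft", tft), ("cp", cp)):
            if not len(cat):
                continue
            params = dataclasses.replace(
                config.gsea, seed=stage_seed(config.seed, f"gsea_{tag}")
            )
            res = gsea_run(genes, cat, params, ranking=ranking)
            rio.write_tsv_results(res, out / f"gsea_{tag}.tsv")
            results[tag] = res
            manifest["counts"][f"gsea_{tag}_sets"] = len(res)
        if "cp" in results:
            enriched = results["cp"][results["cp"]["q_fdr"] <= 0.01]
            if len(enriched):
                members = {
                    s.name: [m for m in s.members if m.upper() in
                             {str(g).upper() for g in genes.row_ids}]
                    for s in cp if s.name in set(enriched["set_name"])
                }
                graph = enrichment_map(enriched, members)
                export_graph(graph, out / "emap_nodes.tsv", out / "emap_edges.tsv")
                manifest["counts"]["emap_nodes"] = graph.number_of_nodes()
                manifest["counts"]["emap_edges"] = graph.number_of_edges()
        return results

    gsea_results = guard("gsea", _gsea)

    # --------------------------------------------------------------- integrate
    def _integrate():
        if "tft" not in gsea_results or "cp" not in gsea_results:
            logger.warning("integrate: skipped (need both TFT and CP GSEA results)")
            return
        for direction in ("down", "up"):
            tf_names, pw_names = build_search_space(
                gsea_results["tft"], gsea_results["cp"], config.integration, direction
            )
            table = intersect(
                tft, cp, de, config.integration, direction,
                tf_names=tf_names, pathway_names=pw_names,
            )
            validate_table(table, tft, cp, de)
            prefix = out / f"integration_{direction}"
            contingency_export(table, f"{prefix}_contingency.tsv")
            rio.write_tsv_results(table.gene_table(), f"{prefix}_genes.tsv")
            rio.write_tsv_results(
                gene_detail_table(table, de), f"{prefix}_gene_stats.tsv"
            )
            manifest["counts"][f"integration_{direction}_connections"] = len(
                table.connections
            )
            manifest["counts"][f"integration_{direction}_plotted"] = len(
                table.plot_connections
            )

    guard("integrate", _integrate)

    manifest["wall_times_s"]["total"] = round(time.perf_counter() - t_all, 3)
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest


def _versions() -> dict:
    import scipy

    from . import __version__

    return {
        "renin_gsx": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
    }
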