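"""Synthetic microarray experiments with planted, fully known structure.

The generator emulates the study design that motivates this package: two
groups of four arrays (baseline vs day-5 disease), a probes x samples table
of log2 intensities with many-to-one probe-to-gene mapping, per-gene
variance heterogeneity, and differential expression planted coherently
inside designated "active" gene sets.  Every downstream stage
(normalization, probe collapsing, differential expression, ORA, GSEA,
TF/pathway integration) therefore has a recoverable ground truth without
any external download.

Model
-----
Each gene g has a baseline mean mu_g ~ U(baseline_mean_range) and a
standard deviation sd_g ~ U(gene_sd_range), both on the log2 scale.  The
per-sample gene signal is mu_g + effect_g * 1[sample in group 2] +
N(0, sd_g); each probe replicate adds independent probe-level noise
N(0, probe_noise_fraction * sd_g).  Effects come from two sources:

* *active sets* — named gene sets whose members all receive the set's
  signed log2 effect (a gene claimed by an earlier listed set keeps that
  set's effect; effects do not stack);
* *background* — a fraction of the remaining genes receives an individual
  effect with random magnitude, biased toward downregulation to mirror the
  expression asymmetry observed after podocyte ablation.

Pathway sets draw a controlled fraction of their members from a designated
partner transcription-factor set (round-robin pairing), so TF x pathway
intersections are non-trivial by construction and the integration stage can
be tested against known overlaps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import ConfigError, ExpressionMatrix, GeneSet, GeneSetCollection

GROUP_BASELINE = "baseline"
GROUP_TEST = "day5"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic experiment.

    Defaults mirror the motivating study where it states a value (4 vs 4
    arrays; 18,138 unique genes assayed by ~1.4x as many probes) and
    otherwise use values typical of Illumina expression arrays.
    """

    n_genes: int = 18138
    #: probes per gene; an int, or an inclusive (lo, hi) range sampled per gene
    probes_per_gene: int | tuple[int, int] = (1, 2)
    n_per_group: int = 4
    baseline_mean_range: tuple[float, float] = (6.0, 12.0)
    gene_sd_range: tuple[float, float] = (0.1, 0.6)
    n_tf_sets: int = 615
    n_pathway_sets: int = 1379
    set_size_range: tuple[int, int] = (15, 100)
    #: fraction of each pathway set drawn from its partner TF set
    tf_pathway_overlap: float = 0.3
    #: set name -> signed log2 effect added to group-2 means of its members
    active_sets: dict[str, float] = field(default_factory=dict)
    #: fraction of genes outside all active sets given an individual effect
    de_background_fraction: float = 0.05
    background_effect_range: tuple[float, float] = (0.5, 2.0)
    #: probability a background effect is negative (downregulation excess)
    background_down_fraction: float = 0.55
    #: probe-level noise sd as a fraction of the gene sd
    probe_noise_fraction: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_per_group < 1:
            raise ConfigError("n_genes and n_per_group must be positive")
        ppg = self.probes_per_gene
        if isinstance(ppg, int):
            if ppg < 1:
                raise ConfigError("probes_per_gene must be >= 1")
        else:
            lo, hi = ppg
            if lo < 1 or hi < lo:
                raise ConfigError(f"invalid probes_per_gene range {ppg}")
        for name, rng_ in (
            ("baseline_mean_range", self.baseline_mean_range),
            ("gene_sd_range", self.gene_sd_range),
            ("background_effect_range", self.background_effect_range),
        ):
            lo, hi = rng_
            if not (math.isfinite(lo) and math.isfinite(hi)) or hi < lo:
                raise ConfigError(f"invalid {name}: {rng_}")
        if self.gene_sd_range[0] <= 0:
            raise ConfigError("gene sd must be positive")
        lo, hi = self.set_size_range
        if lo < 1 or hi < lo:
            raise ConfigError(f"invalid set_size_range {self.set_size_range}")
        if hi > self.n_genes:
            raise ConfigError(
                f"set sizes up to {hi} exceed n_genes = {self.n_genes}"
            )
        for frac_name in (
            "tf_pathway_overlap",
            "de_background_fraction",
            "background_down_fraction",
        ):
            v = getattr(self, frac_name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{frac_name} must lie in [0, 1], got {v}")
        if self.probe_noise_fraction < 0:
            raise ConfigError("probe_noise_fraction must be non-negative")
        for name, eff in self.active_sets.items():
            if not math.isfinite(eff):
                raise ConfigError(f"non-finite effect for active set {name!r}")


@dataclass
class SimulationTruth:
    """Exact bookkeeping of what was planted.

    de_genes
        gene symbol -> true signed log2 effect (non-zero effects only).
    active_sets
        set name -> signed effect, as configured (zero effects retained
        here for the record even though they plant no DE).
    probe_map
        probe id -> gene symbol for every generated probe.
    """

    de_genes: dict[str, float]
    active_sets: dict[str, float]
    probe_map: dict[str, str]


def _gene_symbols(n: int) -> list[str]:
    return [f"G{i:06d}" for i in range(1, n + 1)]


def _build_catalog(
    genes: list[str], config: SimulationConfig, rng: np.random.Generator
) -> GeneSetCollection:
    sizes_tf = rng.integers(
        config.set_size_range[0], config.set_size_range[1] + 1, config.n_tf_sets
    )
    sizes_pw = rng.integers(
        config.set_size_range[0], config.set_size_range[1] + 1, config.n_pathway_sets
    )
    gene_arr = np.array(genes)
    coll = GeneSetCollection()
    tf_members: list[np.ndarray] = []
    for i, size in enumerate(sizes_tf, start=1):
        members = rng.choice(gene_arr, size=int(size), replace=False)
        tf_members.append(members)
        coll.add(GeneSet(f"TF{i:04d}", "TFT", "synthetic TF target set", tuple(members)))
    for i, size in enumerate(sizes_pw, start=1):
        size = int(size)
        if config.n_tf_sets > 0:
            partner = tf_members[(i - 1) % config.n_tf_sets]
        else:
            partner = np.array([], dtype=gene_arr.dtype)
        n_shared = min(int(round(config.tf_pathway_overlap * size)), partner.size, size)
        shared = rng.choice(partner, size=n_shared, replace=False) if n_shared else partner[:0]
        pool = np.setdiff1d(gene_arr, shared, assume_unique=False)
        rest = rng.choice(pool, size=size - n_shared, replace=False)
        members = tuple(np.concatenate([shared, rest]))
        coll.add(GeneSet(f"PW{i:04d}", "CP", "synthetic pathway set", members))
    return coll


def _plant_effects(
    genes: list[str], catalog: GeneSetCollection, config: SimulationConfig,
    rng: np.random.Generator,
) -> dict[str, float]:
    effects: dict[str, float] = {}
    for name, eff in config.active_sets.items():
        if name not in catalog:
            raise ConfigError(f"active set {name!r} not present in the catalog")
        if eff == 0.0:
            continue
        for g in catalog[name].members:
            effects.setdefault(g, eff)  # first listed set wins; no stacking
    active_members = {
        g for name in config.active_sets for g in catalog[name].members
    }
    pool = [g for g in genes if g not in active_members]
    n_bg = int(round(config.de_background_fraction * len(pool)))
    if n_bg:
        chosen = rng.choice(np.array(pool), size=n_bg, replace=False)
        lo, hi = config.background_effect_range
        mags = rng.uniform(lo, hi, n_bg)
        signs = np.where(rng.random(n_bg) < config.background_down_fraction, -1.0, 1.0)
        for g, m, s in zip(chosen, mags, signs):
            effects[str(g)] = float(m * s)
    return effects


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, GeneSetCollection, SimulationTruth]:
    """Generate one probes x samples experiment plus its ground truth.

    Returns the probe-level expression matrix (with group labels), the
    combined TF + pathway catalog, and a :class:`SimulationTruth` recording
    exactly the planted effects and the probe-to-gene map.  Identical
    configs (including seed) produce identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _gene_symbols(config.n_genes)

    catalog = _build_catalog(genes, config, rng)
    effects = _plant_effects(genes, catalog, config, rng)

    mu = rng.uniform(*config.baseline_mean_range, config.n_genes)
    sd = rng.uniform(*config.gene_sd_range, config.n_genes)
    eff = np.array([effects.get(g, 0.0) for g in genes])

    n = config.n_per_group
    samples = [f"{GROUP_BASELINE}_{i+1}" for i in range(n)] + [
        f"{GROUP_TEST}_{i+1}" for i in range(n)
    ]
    groups = {s: (GROUP_BASELINE if i < n else GROUP_TEST) for i, s in enumerate(samples)}

    group2 = np.array([0.0] * n + [1.0] * n)
    gene_signal = (
        mu[:, None]
        + eff[:, None] * group2[None, :]
        + rng.normal(0.0, sd[:, None], (config.n_genes, 2 * n))
    )

    ppg = config.probes_per_gene
    if isinstance(ppg, int):
        counts = np.full(config.n_genes, ppg)
    else:
        counts = rng.integers(ppg[0], ppg[1] + 1, config.n_genes)
    n_probes = int(counts.sum())
    gene_idx = np.repeat(np.arange(config.n_genes), counts)
    probe_ids = [f"P{i:07d}" for i in range(1, n_probes + 1)]
    probe_map = {p: genes[gi] for p, gi in zip(probe_ids, gene_idx)}

    probe_noise = rng.normal(
        0.0, config.probe_noise_fraction * sd[gene_idx][:, None], (n_probes, 2 * n)
    )
    values = pd.DataFrame(
        gene_signal[gene_idx] + probe_noise, index=probe_ids, columns=samples
    )
    matrix = ExpressionMatrix(values, groups)
    truth = SimulationTruth(
        de_genes=effects, active_sets=dict(config.active_sets), probe_map=probe_map
    )
    return matrix, catalog, truth


def null_config(**overrides) -> SimulationConfig:
    """A convenience global-null configuration: no planted effects at all."""
    base = SimulationConfig(active_sets={}, de_background_fraction=0.0)
    return replace(base, **overrides)
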