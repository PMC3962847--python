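"""Synthetic multi-sample OTU datasets with planted structure.

The generator emulates a small soil-survey design: a handful of samples of
moderate amplicon depth over a few hundred OTUs, a contamination gradient that
monotonically suppresses richness, and a planted "core" of OTUs that are
present everywhere with near-equal relative abundance. Every downstream stage
(subsampling, diversity estimation, dissimilarities, core delineation,
correlation) can therefore be exercised against known ground truth without any
external data.

Mechanism
---------
* Each OTU draws a base abundance from a log-normal species-abundance
  distribution and a stress tolerance t ~ Uniform(0, sensitivity_scale).
* Sample j carries a stress (contamination) level z_j; a non-core OTU is
  present in sample j iff t > z_j, so true per-sample richness falls exactly
  with the gradient.
* Non-core OTUs additionally receive independent per-sample log-normal
  abundance noise (``sample_sigma``), mimicking the between-site heterogeneity
  of real soil taxa; planted core OTUs instead spread their abundance over
  samples by a high-concentration Dirichlet, so their cross-sample evenness is
  near 1 by construction, and their base abundance is boosted so they clear a
  0.1% frequency floor in expectation in every sample.
* Reads are drawn per sample by a multinomial at the configured depth
  (with replacement — generation of reads from a composition), deliberately
  distinct from the without-replacement down-sampling applied downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io import (EnvTable, OtuTable, TaxonomyTable, pad_lineage,
                 write_env, write_shared, write_taxonomy)

__all__ = ["SimulationConfig", "SyntheticDataset", "simulate", "write_dataset"]

#: Even-depth read totals typical of a five-sample pyrosequencing survey.
DEFAULT_DEPTHS = (2632, 3446, 7062, 5852, 4440)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for :func:`simulate` (defaults emulate a
    five-sample metal-gradient survey)."""

    n_samples: int = 5
    n_otus: int = 600
    depths: tuple[int, ...] = DEFAULT_DEPTHS
    sad_mu: float = 0.0
    sad_sigma: float = 1.5
    core_size: int = 20
    core_mean_freq: float = 0.004       # expected relative abundance of a core OTU
    core_freq_sigma: float = 0.25       # log-normal spread of core base frequency
    core_concentration: float = 300.0   # Dirichlet conc. of core per-sample shares
    core_evenness_target: float = 0.95
    sample_sigma: float = 1.5           # per-sample log-normal noise, non-core OTUs
    contamination: tuple[float, ...] = (0.0, 0.30, 0.55, 0.75, 0.90)
    sensitivity_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 2 or self.n_otus < 1 or self.core_size < 0:
            raise ValueError("sizes must be positive")
        if self.core_size > self.n_otus:
            raise ValueError("core_size exceeds n_otus")
        if len(self.depths) != self.n_samples:
            raise ValueError("need one depth per sample")
        if len(self.contamination) != self.n_samples:
            raise ValueError("need one contamination value per sample")
        if any(z < 0 for z in self.contamination):
            raise ValueError("contamination values must be >= 0")
        if any(d <= 0 for d in self.depths):
            raise ValueError("depths must be positive")


@dataclass
class SyntheticDataset:
    """A simulated survey with its ground truth."""

    table: OtuTable
    env: EnvTable
    tree: TreeNode
    taxonomy: TaxonomyTable
    true_richness: pd.Series          # per-sample number of truly present OTUs
    core_otu_ids: list[str]           # the planted core
    config: SimulationConfig


def simulate(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Generate one dataset under ``config`` (deterministic per seed)."""
    config = config or SimulationConfig()
    root_ss = np.random.SeedSequence(config.seed)
    ss_abund, ss_reads, ss_tree, ss_tax = root_ss.spawn(4)
    rng = np.random.default_rng(ss_abund)

    n_s, n_o = config.n_samples, config.n_otus
    sample_ids = [f"S{j + 1}" for j in range(n_s)]
    otu_ids = [f"Otu{i + 1:04d}" for i in range(n_o)]
    is_core = np.zeros(n_o, dtype=bool)
    is_core[:config.core_size] = True  # ids are opaque; position carries no info
    z = np.asarray(config.contamination, dtype=float)

    base = rng.lognormal(config.sad_mu, config.sad_sigma, size=n_o)
    tolerance = rng.uniform(0.0, config.sensitivity_scale, size=n_o)

    present = (tolerance[None, :] > z[:, None]) | is_core[None, :]
    empty = ~present.any(axis=1)
    if empty.any():
        bad = [sample_ids[j] for j in np.nonzero(empty)[0]]
        raise ValueError(f"contamination too high: sample(s) {bad} would be "
                         "empty (no tolerant OTUs and no core)")

    # Core OTUs own a fixed slice of every sample's composition: OTU i takes
    # expected proportion q_i, jittered across samples by a high-concentration
    # Dirichlet so cross-sample evenness stays near 1 at even depth. Non-core
    # OTUs split the remaining composition in proportion to base abundance ×
    # per-sample heterogeneity × presence.
    probs = np.zeros((n_s, n_o))
    core_frac = 0.0
    if config.core_size:
        q = rng.lognormal(np.log(config.core_mean_freq),
                          config.core_freq_sigma, size=config.core_size)
        shares = rng.dirichlet(
            np.full(n_s, config.core_concentration), size=config.core_size)
        probs[:, is_core] = (q[:, None] * n_s * shares).T
        core_frac = probs[:, is_core].sum(axis=1)
        if np.any(core_frac >= 0.5):
            raise ValueError("core_size * core_mean_freq too large: planted "
                             "core would dominate the community")
    remainder = (1.0 - core_frac)[:, None] if config.core_size else 1.0
    noise = rng.lognormal(0.0, config.sample_sigma, size=(n_s, n_o))
    w = base[~is_core] * noise[:, ~is_core] * present[:, ~is_core]
    probs[:, ~is_core] = w / w.sum(axis=1, keepdims=True) * remainder

    reads_rng = np.random.default_rng(ss_reads)
    counts = np.zeros((n_s, n_o), dtype=np.int64)
    for j in range(n_s):
        counts[j] = reads_rng.multinomial(config.depths[j],
                                          probs[j] / probs[j].sum())

    # OTUs never hit by a read are unobservable and are dropped from the table
    table = OtuTable(
        pd.DataFrame(counts, index=sample_ids, columns=otu_ids),
        label="0.03", drop_empty=True)
    env = EnvTable(pd.DataFrame({"metal": z}, index=sample_ids),
                   units={"metal": "stress-units"})
    tree = _random_ultrametric_tree(otu_ids, np.random.default_rng(ss_tree))
    taxonomy = _dummy_taxonomy(otu_ids, np.random.default_rng(ss_tax))
    true_richness = pd.Series(present.sum(axis=1), index=sample_ids,
                              name="true_richness")
    return SyntheticDataset(table, env, tree, taxonomy, true_richness,
                            [otu_ids[i] for i in np.nonzero(is_core)[0]],
                            config)


def _random_ultrametric_tree(leaf_names, rng: np.random.Generator) -> TreeNode:
    """Random coalescent-style ultrametric tree over the given leaves."""
    nodes = [TreeNode(name=name, length=0.0) for name in leaf_names]
    heights = [0.0] * len(nodes)
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += float(rng.exponential(1.0 / k))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        b = nodes.pop(j); hb = heights.pop(j)
        a = nodes.pop(i); ha = heights.pop(i)
        a.length = t - ha
        b.length = t - hb
        parent = TreeNode(children=[a, b], length=0.0)
        nodes.append(parent)
        heights.append(t)
    root = nodes[0]
    root.length = None
    return root


_TAX_FANOUT = (6, 4, 4, 4, 4, 6)  # children per rank, domain -> genus


def _dummy_taxonomy(otu_ids, rng: np.random.Generator) -> TaxonomyTable:
    """Six-rank dummy lineages drawn from a small random hierarchy."""
    prefixes = ("D", "P", "C", "O", "F", "G")
    assignments = {}
    for otu in otu_ids:
        lineage = []
        path = []
        for level, fanout in enumerate(_TAX_FANOUT):
            choice = 1 if level == 0 else int(rng.integers(1, fanout + 1))
            path.append(str(choice))
            lineage.append(f"{prefixes[level]}{'_'.join(path)}")
        assignments[otu] = pad_lineage(lineage)
    return TaxonomyTable(assignments)


def write_dataset(ds: SyntheticDataset, directory: str | Path) -> dict[str, Path]:
    """Write the dataset as .shared / env TSV / newick / constaxonomy plus a
    ground-truth JSON sidecar; all files re-read losslessly."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "shared": directory / "community.shared",
        "env": directory / "env.tsv",
        "tree": directory / "tree.nwk",
        "taxonomy": directory / "community.taxonomy",
        "truth": directory / "ground_truth.json",
    }
    write_shared(ds.table, paths["shared"])
    write_env(ds.env, paths["env"])
    ds.tree.write(str(paths["tree"]), format="newick")
    write_taxonomy(ds.taxonomy, paths["taxonomy"])
    truth = {
        "core_otu_ids": ds.core_otu_ids,
        "true_richness": {k: int(v) for k, v in ds.true_richness.items()},
        "config": asdict(ds.config),
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
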