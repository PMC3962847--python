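"""Pairwise community dissimilarities and shared-OTU (Venn) accounting.

Two abundance-based dissimilarities are provided: Bray-Curtis,
``Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ)``, which is sensitive to total-count scaling, and
Morisita-Horn, which is invariant to scaling one sample's counts and dominated
by the abundant taxa. Sørensen (incidence-based) is available as a third
option for presence/absence comparisons. The overlap report partitions OTUs by
the exact subset of samples they occur in — the numbers behind a Venn diagram —
plus the fraction of all reads carried by the OTUs shared by every sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .io import OtuTable

__all__ = [
    "DistMatrix",
    "OverlapReport",
    "bray_curtis",
    "morisita_horn",
    "sorensen",
    "dist_matrix",
    "overlap_report",
    "METRICS",
]


def bray_curtis(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_pair(x, y)
    denom = (x + y).sum()
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.abs(x - y).sum() / denom)


def morisita_horn(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_pair(x, y)
    tx, ty = x.sum(), y.sum()
    if tx == 0 or ty == 0:
        raise ValueError("Morisita-Horn undefined for an all-zero vector")
    dx = (x ** 2).sum() / tx ** 2
    dy = (y ** 2).sum() / ty ** 2
    sim = 2.0 * (x * y).sum() / ((dx + dy) * tx * ty)
    return float(1.0 - sim)


def sorensen(x, y) -> float:
    """Incidence-based Sørensen dissimilarity, 1 − 2|A∩B|/(|A|+|B|)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_pair(x, y)
    a, b = x > 0, y > 0
    denom = a.sum() + b.sum()
    if denom == 0:
        raise ValueError("Sørensen undefined for two all-zero vectors")
    return float(1.0 - 2.0 * (a & b).sum() / denom)


def _check_pair(x: np.ndarray, y: np.ndarray) -> None:
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("negative counts")


METRICS = {
    "braycurtis": bray_curtis,
    "morisitahorn": morisita_horn,
    "sorensen": sorensen,
}


@dataclass
class DistMatrix:
    """Symmetric pairwise sample dissimilarities in [0, 1] for one metric."""

    sample_ids: list[str]
    values: np.ndarray
    metric: str

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.sample_ids),) * 2:
            raise ValueError("matrix shape does not match sample ids")
        if not np.allclose(v, v.T):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("diagonal is not zero")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.sample_ids)

    def to_tsv(self, path, header_lines: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            fh.write(f"# metric={self.metric}\n")
            self.to_frame().to_csv(fh, sep="\t", index_label="sample",
                                   float_format="%.6f")

    def __getitem__(self, pair) -> float:
        i = self.sample_ids.index(pair[0])
        j = self.sample_ids.index(pair[1])
        return float(self.values[i, j])

    def plot(self, ax=None):
        """Plain matrix-to-image heatmap (darker = more dissimilar)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(self.values, cmap="Greys", vmin=0, vmax=1)
        ax.set_xticks(range(len(self.sample_ids)), self.sample_ids, rotation=90)
        ax.set_yticks(range(len(self.sample_ids)), self.sample_ids)
        ax.set_title(self.metric)
        ax.figure.colorbar(im, ax=ax)
        return ax


def dist_matrix(table: OtuTable, metric: str = "braycurtis") -> DistMatrix:
    """All pairwise dissimilarities between the table's samples.

    Sample order follows the table; per-pair errors are re-raised with the
    offending pair named.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(METRICS)}")
    if len(table.sample_ids) < 2:
        raise ValueError("need at least 2 samples")
    fn = METRICS[metric]
    n = len(table.sample_ids)
    counts = table.to_numpy()
    out = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        try:
            d = fn(counts[i], counts[j])
        except ValueError as exc:
            pair = (table.sample_ids[i], table.sample_ids[j])
            raise ValueError(f"pair {pair}: {exc}") from exc
        out[i, j] = out[j, i] = d
    return DistMatrix(list(table.sample_ids), out, metric)


@dataclass
class OverlapReport:
    """Partition of OTUs by the exact sample subset they occur in.

    ``cells`` maps a frozenset of sample ids to the number of OTUs whose
    support (presence at ≥ min_count) is exactly that subset; absent subsets
    hold zero OTUs. ``shared_read_fraction`` is the fraction of all reads in
    the OTUs present in every sample.
    """

    sample_ids: list[str]
    cells: dict[frozenset, int]
    shared_read_fraction: float
    min_count: float
    otus_by_cell: dict[frozenset, list[str]]

    @property
    def n_otus(self) -> int:
        return sum(self.cells.values())

    @property
    def shared_by_all(self) -> int:
        return self.cells.get(frozenset(self.sample_ids), 0)

    def count(self, samples) -> int:
        return self.cells.get(frozenset(samples), 0)

    def to_json_dict(self) -> dict:
        return {
            "samples": self.sample_ids,
            "min_count": self.min_count,
            "shared_by_all": self.shared_by_all,
            "shared_read_fraction": self.shared_read_fraction,
            "cells": {"&".join(sorted(k)): v for k, v in self.cells.items()},
        }


def overlap_report(table: OtuTable, min_count: float = 1) -> OverlapReport:
    """Venn accounting: OTU counts per exact support subset.

    Presence means count ≥ ``min_count`` (default one read). The read fraction
    for the shared-by-all cell is computed over the input table's totals.
    """
    counts = table.to_numpy()
    present = counts >= min_count
    cells: dict[frozenset, int] = {}
    members: dict[frozenset, list[str]] = {}
    samples = np.array(table.sample_ids)
    for j, otu in enumerate(table.otu_ids):
        key = frozenset(samples[present[:, j]])
        cells[key] = cells.get(key, 0) + 1
        members.setdefault(key, []).append(otu)
    all_key = frozenset(table.sample_ids)
    total = counts.sum()
    shared_cols = [j for j in range(counts.shape[1])
                   if frozenset(samples[present[:, j]]) == all_key]
    frac = float(counts[:, shared_cols].sum() / total) if total > 0 else 0.0
    return OverlapReport(list(table.sample_ids), cells, frac,
                         min_count, members)
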