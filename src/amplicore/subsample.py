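"""Even-depth down-sampling of OTU tables and replicate-averaged shared tables.

Down-sampling draws reads without replacement (multivariate hypergeometric),
which is the rarefaction semantics of the standard 16S toolchain: reducing a
sample to a common depth is subsampling its observed reads, not resampling an
estimated composition. The averaged table is the entry-wise mean of several
independent down-samplings, so per-sample totals stay exactly at the target
depth while counts become fractional.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import OtuTable

__all__ = ["SubsampleSpec", "downsample", "averaged_shared"]


@dataclass(frozen=True)
class SubsampleSpec:
    """Depth, replicate count and seed for even-depth normalization."""

    depth: int
    replicates: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def _check_depth(table: OtuTable, depth: int) -> None:
    if not table.is_integer:
        raise ValueError("down-sampling requires an integer count table")
    totals = table.sample_totals()
    short = totals[totals < depth]
    if len(short):
        worst = short.index[0]
        raise ValueError(
            f"depth {depth} exceeds total reads of sample(s) "
            f"{list(short.index)} (e.g. {worst}: {int(short.iloc[0])})")


def downsample(table: OtuTable, depth: int, seed: int = 0) -> OtuTable:
    """Down-sample every sample to exactly ``depth`` reads without replacement.

    Each sample's counts are one multivariate-hypergeometric draw from that
    sample's reads; an OTU absent from a sample stays absent. Reproducible
    under a fixed seed (one independent stream per sample).
    """
    _check_depth(table, depth)
    rng_streams = np.random.SeedSequence(seed).spawn(len(table.sample_ids))
    out = np.empty(table.shape, dtype=np.int64)
    counts = table.counts.to_numpy().astype(np.int64)
    for i, stream in enumerate(rng_streams):
        rng = np.random.default_rng(stream)
        out[i] = rng.multivariate_hypergeometric(counts[i], depth)
    frame = pd.DataFrame(out, index=table.sample_ids, columns=table.otu_ids)
    return OtuTable(frame, label=table.label, drop_empty=False)


def averaged_shared(table: OtuTable, spec: SubsampleSpec) -> OtuTable:
    """Entry-wise mean of ``spec.replicates`` independent down-samplings.

    Replicate r uses the deterministically derived seed ``spec.seed + r``, so
    the set of replicates is reproducible and ``replicates=1`` coincides with
    a single :func:`downsample` at the master seed. Fractional means are kept;
    no rounding. Per-sample totals of the result equal ``spec.depth`` exactly.
    """
    reps = replicate_tables(table, spec)
    acc = np.zeros(table.shape, dtype=float)
    for rep in reps:
        acc += rep.counts.to_numpy()
    acc /= spec.replicates
    frame = pd.DataFrame(acc, index=table.sample_ids, columns=table.otu_ids)
    return OtuTable(frame, label=table.label, drop_empty=False)


def replicate_tables(table: OtuTable, spec: SubsampleSpec) -> list[OtuTable]:
    """The individual down-sampled replicates behind :func:`averaged_shared`."""
    _check_depth(table, spec.depth)
    return [downsample(table, spec.depth, seed=spec.seed + r)
            for r in range(spec.replicates)]
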