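"""Core-microbiome delineation by cross-sample Shannon evenness.

A "core microbiome" is usually taken to be the set of OTUs present in every
sample. That definition is fragile at amplicon depths: an OTU can appear in
all samples through a handful of reads that are there by chance (sequencing
noise, barcode bleed-through). The delineation implemented here therefore adds
two abundance filters and an evenness filter. An OTU belongs to the core iff

1. in *every* sample its count is at least ``min_reads_per_sample``
   (default 3, i.e. "more than two reads"),
2. in *every* sample its relative frequency exceeds ``min_freq_per_sample``
   (default 0.1%), and
3. its cross-sample Shannon evenness exceeds ``evenness_min`` (default 0.9),
   where evenness treats the samples as categories and the OTU's reads as
   individuals: E = (−Σ pⱼ ln pⱼ)/ln S over samples j with pⱼ > 0.

The two abundance conditions are deliberately kept as separate, simultaneously
applied filters: at typical even depths around 1,500 reads they are *not*
equivalent (0.1% of 1,500 is 1.5 reads), and applying both is the strictest
reading. All thresholds are strict/inclusive exactly as stated above
(count ≥ min_reads, frequency > min_freq, evenness > evenness_min).

The user-facing surface follows the model→results idiom:
``CoreMicrobiome(table, taxonomy).fit(criteria)`` returns a :class:`CoreReport`
carrying per-OTU diagnostics, near-misses and a printable summary table.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alpha import shannon_evenness
from .io import (RANKS, UNCLASSIFIED, OtuTable, TaxonomyTable,
                 serialize_lineage)

logger = logging.getLogger(__name__)

__all__ = [
    "CoreCriteria",
    "CoreMicrobiome",
    "CoreReport",
    "otu_evenness",
    "delineate_core",
    "consensus_taxonomy",
]


@dataclass(frozen=True)
class CoreCriteria:
    """Thresholds defining core membership.

    evenness_min
        Cross-sample Shannon evenness must be strictly greater than this.
    min_reads_per_sample
        Count in every sample must be at least this many reads.
    min_freq_per_sample
        Relative frequency in every sample must be strictly greater than this.
    """

    evenness_min: float = 0.9
    min_reads_per_sample: float = 3
    min_freq_per_sample: float = 0.001

    def __post_init__(self):
        if not 0.0 <= self.evenness_min <= 1.0:
            raise ValueError("evenness_min must lie in [0, 1]")
        if self.min_reads_per_sample < 1:
            raise ValueError("min_reads_per_sample must be >= 1")
        if not 0.0 <= self.min_freq_per_sample < 1.0:
            raise ValueError("min_freq_per_sample must lie in [0, 1)")


def otu_evenness(per_sample_counts) -> float:
    """Cross-sample evenness of one OTU: E = (−Σ pⱼ ln pⱼ)/ln S.

    Samples act as the categories, the OTU's reads as the individuals, so an
    OTU spread equally over all S samples scores 1 and an OTU concentrated in
    one sample scores 0.
    """
    c = np.asarray(per_sample_counts, dtype=float)
    if c.size < 2:
        raise ValueError("evenness across samples needs at least 2 samples")
    if c.sum() <= 0:
        raise ValueError("OTU has zero total reads")
    return shannon_evenness(c, n_categories=c.size)


_CRITERIA_COLS = ("pass_min_reads", "pass_min_freq", "pass_evenness")


class CoreMicrobiome:
    """Core-microbiome delineation model for one shared OTU table.

    Parameters
    ----------
    table
        Samples × OTUs table; integer counts for raw tables or fractional
        means for subsample-averaged ones (the thresholds then apply to the
        means, which is flagged in the report).
    taxonomy
        Optional per-OTU lineages used to annotate the report.
    """

    def __init__(self, table: OtuTable, taxonomy: TaxonomyTable | None = None):
        if np.any(table.sample_totals().to_numpy() <= 0):
            raise ValueError("every sample must have at least one read")
        if len(table.sample_ids) < 2:
            raise ValueError("core delineation needs at least 2 samples")
        self.table = table
        self.taxonomy = taxonomy

    def fit(self, criteria: CoreCriteria | None = None) -> "CoreReport":
        """Apply the filters and return the per-OTU report."""
        criteria = criteria or CoreCriteria()
        table = self.table
        counts = table.to_numpy()
        totals = counts.sum(axis=1, keepdims=True)
        freqs = counts / totals
        n_samples = len(table.sample_ids)
        log_s = math.log(n_samples)

        pass_reads = (counts >= criteria.min_reads_per_sample).all(axis=0)
        pass_freq = (freqs > criteria.min_freq_per_sample).all(axis=0)

        evenness = np.zeros(counts.shape[1])
        otu_totals = counts.sum(axis=0)
        for j in range(counts.shape[1]):
            col = counts[:, j]
            p = col[col > 0] / col.sum()
            evenness[j] = -(p * np.log(p)).sum() / log_s
        pass_even = evenness > criteria.evenness_min

        near = np.abs(evenness - criteria.evenness_min) < 0.005
        for otu in np.array(table.otu_ids)[near & pass_reads & pass_freq]:
            logger.warning("OTU %s has evenness within 0.005 of the %.3f "
                           "threshold", otu, criteria.evenness_min)

        report = pd.DataFrame(
            counts.T, index=table.otu_ids, columns=table.sample_ids)
        report["total"] = otu_totals
        report["evenness"] = evenness
        report["pass_min_reads"] = pass_reads
        report["pass_min_freq"] = pass_freq
        report["pass_evenness"] = pass_even
        report["core"] = pass_reads & pass_freq & pass_even
        if self.taxonomy is not None:
            report["taxonomy"] = [
                self.taxonomy.lineage_string(o) if o in self.taxonomy else ""
                for o in table.otu_ids]
        report = report.sort_values(
            ["total", "evenness"], ascending=False, kind="mergesort")
        return CoreReport(report, criteria, list(table.sample_ids),
                          averaged=not table.is_integer, label=table.label)


@dataclass
class CoreReport:
    """Per-OTU diagnostics from core delineation (results object).

    ``data`` has one row per OTU, sorted by total reads descending: per-sample
    counts, total, cross-sample evenness, pass/fail per criterion, the final
    ``core`` flag (the conjunction of the three criteria) and, when a taxonomy
    was supplied, the consensus lineage string.
    """

    data: pd.DataFrame
    criteria: CoreCriteria
    sample_ids: list[str]
    averaged: bool = False
    label: str = ""

    @property
    def core_otus(self) -> list[str]:
        return list(self.data.index[self.data["core"]])

    @property
    def n_core(self) -> int:
        return int(self.data["core"].sum())

    def near_misses(self) -> pd.DataFrame:
        """OTUs failing exactly one of the three criteria (diagnostics)."""
        passes = self.data[list(_CRITERIA_COLS)].sum(axis=1)
        return self.data[passes == len(_CRITERIA_COLS) - 1]

    def core_table(self) -> pd.DataFrame:
        return self.data[self.data["core"]]

    def summary(self) -> str:
        c = self.criteria
        lines = [
            f"Core microbiome delineation (label {self.label or '?'})",
            f"  samples: {', '.join(self.sample_ids)}",
            f"  criteria: count >= {c.min_reads_per_sample} in every sample; "
            f"frequency > {c.min_freq_per_sample:.2%} in every sample; "
            f"cross-sample evenness > {c.evenness_min}",
        ]
        if self.averaged:
            lines.append("  note: thresholds applied to subsample-averaged "
                         "(fractional) counts")
        lines.append(f"  core OTUs: {self.n_core} of {len(self.data)} "
                     f"({len(self.near_misses())} near-misses)")
        cols = [*self.sample_ids, "evenness", "total"]
        if "taxonomy" in self.data.columns:
            cols.append("taxonomy")
        core = self.core_table()[cols].copy()
        core["evenness"] = core["evenness"].round(3)
        lines.append("")
        lines.append(core.to_string())
        return "\n".join(lines)

    def to_tsv(self, path, header_lines: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            c = self.criteria
            fh.write(f"# label={self.label} evenness_min={c.evenness_min} "
                     f"min_reads={c.min_reads_per_sample} "
                     f"min_freq={c.min_freq_per_sample}"
                     + (" averaged_counts" if self.averaged else "") + "\n")
            out = self.data.copy()
            out["evenness"] = out["evenness"].round(4)
            out.to_csv(fh, sep="\t", index_label="OTU")


def delineate_core(table: OtuTable, criteria: CoreCriteria | None = None,
                   taxonomy: TaxonomyTable | None = None) -> CoreReport:
    """Functional wrapper: ``CoreMicrobiome(table, taxonomy).fit(criteria)``."""
    return CoreMicrobiome(table, taxonomy).fit(criteria)


def consensus_taxonomy(lineages, depth: int | None = None) -> str:
    """Majority-rule consensus lineage over a collection of lineages.

    At each rank the taxon held by more than half of the members is kept;
    at and below the first rank with no majority every level becomes the
    ``unclassified`` sentinel. ``depth`` defaults to the deepest member
    lineage, so a unanimous set returns its lineage verbatim. Serialized in
    the semicolon style of constaxonomy files.
    """
    lineages = [list(lin) for lin in lineages]
    if not lineages:
        raise ValueError("consensus of an empty set of lineages")
    if depth is None:
        depth = max(len(lin) for lin in lineages)
    n = len(lineages)
    out: list[str] = []
    broken = False
    for level in range(depth):
        if broken:
            out.append(UNCLASSIFIED)
            continue
        names = Counter(
            lin[level] if level < len(lin) else UNCLASSIFIED
            for lin in lineages)
        name, votes = names.most_common(1)[0]
        if votes * 2 > n and name != UNCLASSIFIED:
            out.append(name)
        else:
            out.append(UNCLASSIFIED)
            broken = True
    return serialize_lineage(out)
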