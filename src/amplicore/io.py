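"""Data model and file formats for shared OTU tables, taxonomy, metadata and trees.

The central container is :class:`OtuTable`, a samples × OTUs count matrix at a
single OTU-clustering dissimilarity level (the mothur ``label``, e.g. ``"0.03"``).
Readers accept the mothur text dialects produced by standard 16S pipelines:
``.shared`` tables, ``constaxonomy`` assignments, a TSV of per-sample
environmental variables, and newick trees (via scikit-bio).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger(__name__)

__all__ = [
    "OtuTable",
    "TaxonomyTable",
    "EnvTable",
    "FormatError",
    "read_shared",
    "write_shared",
    "read_taxonomy",
    "read_env",
    "read_tree",
    "shared_labels",
]

#: Canonical rank order for bacterial lineages, domain → genus.
RANKS = ("domain", "phylum", "class", "order", "family", "genus")

#: Sentinel used for lineage levels without a resolved assignment.
UNCLASSIFIED = "unclassified"


class FormatError(ValueError):
    """A file does not conform to the expected text dialect."""


class OtuTable:
    """Samples × OTUs count matrix at one clustering level.

    Parameters
    ----------
    counts
        DataFrame with sample ids as index and OTU ids as columns. Values must
        be non-negative; integers for raw tables, reals for subsample-averaged
        tables.
    label
        Name of the OTU dissimilarity level, e.g. ``"0.03"``.
    drop_empty
        Drop all-zero OTU columns (logged). Every retained OTU has support in
        at least one sample.
    """

    def __init__(self, counts: pd.DataFrame, label: str = "0.03",
                 drop_empty: bool = True):
        counts = pd.DataFrame(counts).copy()
        if counts.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if counts.columns.has_duplicates:
            raise ValueError("duplicate OTU ids")
        values = counts.to_numpy()
        if values.size and (values < 0).any():
            raise ValueError("negative counts are not allowed")
        if drop_empty and counts.shape[1]:
            empty = counts.columns[(values == 0).all(axis=0)]
            if len(empty):
                logger.info("dropping %d all-zero OTU columns: %s",
                            len(empty), ", ".join(map(str, empty[:10])))
                counts = counts.drop(columns=empty)
        counts.index = counts.index.astype(str)
        counts.columns = counts.columns.astype(str)
        self.counts = counts
        self.label = str(label)

    # -- basic introspection -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def is_integer(self) -> bool:
        """True when every count is integral (raw, not averaged, table)."""
        v = self.counts.to_numpy()
        return bool(np.all(np.mod(v, 1) == 0))

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def otu_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def to_numpy(self) -> np.ndarray:
        return self.counts.to_numpy()

    def select_samples(self, sample_ids: Sequence[str]) -> "OtuTable":
        missing = [s for s in sample_ids if s not in self.counts.index]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        return OtuTable(self.counts.loc[list(sample_ids)], self.label)

    def __eq__(self, other) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return (self.label == other.label
                and self.counts.shape == other.counts.shape
                and list(self.counts.index) == list(other.counts.index)
                and list(self.counts.columns) == list(other.counts.columns)
                and np.allclose(self.counts.to_numpy(), other.counts.to_numpy()))

    def __repr__(self) -> str:
        n_s, n_o = self.shape
        kind = "integer" if self.is_integer else "real"
        return f"<OtuTable label={self.label!r} {n_s} samples x {n_o} OTUs ({kind})>"


@dataclass
class TaxonomyTable:
    """Per-OTU lineage assignments in fixed rank order domain → genus.

    ``assignments`` maps otu_id to a list of taxon names, padded with the
    ``unclassified`` sentinel so that unresolved levels are explicit, never
    omitted mid-lineage. ``confidences`` optionally carries per-level bootstrap
    support in [0, 100]; ``sizes`` the read count behind each consensus.
    """

    assignments: dict[str, list[str]]
    confidences: dict[str, list[float | None]] = field(default_factory=dict)
    sizes: dict[str, int] = field(default_factory=dict)

    def lineage(self, otu_id: str) -> list[str]:
        return self.assignments[otu_id]

    def lineage_string(self, otu_id: str) -> str:
        return serialize_lineage(self.assignments[otu_id])

    def __contains__(self, otu_id: str) -> bool:
        return otu_id in self.assignments

    def __len__(self) -> int:
        return len(self.assignments)


@dataclass
class EnvTable:
    """Per-sample environmental variables (metal concentrations, pH, OM...).

    ``data`` is a DataFrame with sample ids as index; ``units`` optionally maps
    variable name to a unit string (e.g. ``Zn_ba`` → ``mg/kg``).
    """

    data: pd.DataFrame
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.data = pd.DataFrame(self.data)
        self.data.index = self.data.index.astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    def check_samples(self, table: OtuTable) -> None:
        """Raise when sample sets differ from an OtuTable's (no silent subset)."""
        mine, theirs = set(self.sample_ids), set(table.sample_ids)
        if mine != theirs:
            raise ValueError(
                "environment/table sample mismatch: "
                f"only in env {sorted(mine - theirs)}, "
                f"only in table {sorted(theirs - mine)}")


# ---------------------------------------------------------------------------
# shared table dialect
# ---------------------------------------------------------------------------

_REAL_FLAG = "# real-valued counts (subsample-averaged); 6 decimal places"


def _parse_shared_lines(path: Path) -> tuple[list[str], list[list[str]]]:
    header: list[str] | None = None
    rows: list[list[str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                if fields[:3] != ["label", "Group", "numOtus"]:
                    raise FormatError(
                        f"{path}: line {lineno}: expected header "
                        "'label<TAB>Group<TAB>numOtus<TAB>...'")
                header = fields
                continue
            if len(fields) != len(header):
                raise FormatError(
                    f"{path}: line {lineno}: expected {len(header)} fields, "
                    f"got {len(fields)} (ragged row)")
            rows.append(fields)
    if header is None:
        raise FormatError(f"{path}: empty file, no header line")
    return header, rows


def shared_labels(path: str | Path) -> list[str]:
    """Distinct clustering labels present in a .shared file, in file order."""
    _, rows = _parse_shared_lines(Path(path))
    seen: list[str] = []
    for row in rows:
        if row[0] not in seen:
            seen.append(row[0])
    return seen


def read_shared(path: str | Path, label: str | None = None) -> OtuTable:
    """Read one clustering level of a mothur-dialect ``.shared`` table.

    The file may hold several labels; ``label`` selects one. With ``label=None``
    a single-label file is read directly and a multi-label file raises an error
    listing the available labels.
    """
    path = Path(path)
    header, rows = _parse_shared_lines(path)
    otu_ids = header[3:]
    available = []
    for row in rows:
        if row[0] not in available:
            available.append(row[0])
    if label is None:
        if len(available) > 1:
            raise ValueError(
                f"{path} holds labels {available}; pass label= to choose one")
        label = available[0]
    if label not in available:
        raise ValueError(
            f"label {label!r} not in {path}; available labels: {available}")

    samples, data = [], []
    for row in rows:
        if row[0] != label:
            continue
        samples.append(row[1])
        n_declared = int(row[2])
        if n_declared != len(otu_ids):
            raise FormatError(
                f"{path}: sample {row[1]}: numOtus={n_declared} inconsistent "
                f"with {len(otu_ids)} OTU columns")
        data.append([float(x) for x in row[3:]])

    counts = pd.DataFrame(data, index=samples, columns=otu_ids)
    if (counts.to_numpy() % 1 == 0).all():
        counts = counts.astype(np.int64)
    return OtuTable(counts, label=label)


def write_shared(table: OtuTable, path: str | Path) -> None:
    """Write an OtuTable in the ``.shared`` dialect, re-readable losslessly.

    Integer tables are written without decimal points; averaged (real) tables
    with 6 decimal places and a flagging header comment.
    """
    path = Path(path)
    integer = table.is_integer
    with open(path, "w") as fh:
        if not integer:
            fh.write(_REAL_FLAG + "\n")
        fh.write("\t".join(["label", "Group", "numOtus", *table.otu_ids]) + "\n")
        n = len(table.otu_ids)
        for sample in table.sample_ids:
            row = table.counts.loc[sample]
            if integer:
                cells = [str(int(v)) for v in row]
            else:
                cells = [f"{v:.6f}" for v in row]
            fh.write("\t".join([table.label, sample, str(n), *cells]) + "\n")


# ---------------------------------------------------------------------------
# taxonomy (constaxonomy dialect)
# ---------------------------------------------------------------------------

def parse_lineage(text: str) -> tuple[list[str], list[float | None]]:
    """Parse ``Bacteria(100);Proteobacteria(98);`` into names and confidences.

    A trailing semicolon is accepted; an empty lineage is rejected.
    """
    parts = [p.strip() for p in text.strip().split(";")]
    if parts and parts[-1] == "":
        parts = parts[:-1]
    if not parts or all(p == "" for p in parts):
        raise FormatError(f"empty lineage: {text!r}")
    names: list[str] = []
    confs: list[float | None] = []
    for part in parts:
        if part == "":
            raise FormatError(f"empty level mid-lineage: {text!r}")
        if part.endswith(")") and "(" in part:
            name, conf = part.rsplit("(", 1)
            names.append(name.strip())
            confs.append(float(conf[:-1]))
        else:
            names.append(part)
            confs.append(None)
    return names, confs


def serialize_lineage(names: Iterable[str]) -> str:
    return ";".join(names) + ";"


def pad_lineage(names: Sequence[str], depth: int = len(RANKS)) -> list[str]:
    """Pad a lineage with the ``unclassified`` sentinel out to ``depth`` ranks."""
    out = list(names)[:depth]
    out += [UNCLASSIFIED] * (depth - len(out))
    return out


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    """Read a mothur-style constaxonomy file (``OTU<TAB>Size<TAB>Taxonomy``).

    A headerless two-column ``otu<TAB>lineage`` file is accepted too.
    """
    path = Path(path)
    assignments: dict[str, list[str]] = {}
    confidences: dict[str, list[float | None]] = {}
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() == "otu":
                continue
            if len(fields) == 3:
                otu, size, lineage = fields
                sizes[otu] = int(size)
            elif len(fields) == 2:
                otu, lineage = fields
            else:
                raise FormatError(f"{path}: line {lineno}: expected 2 or 3 "
                                  f"tab-separated fields, got {len(fields)}")
            names, confs = parse_lineage(lineage)
            assignments[otu] = names
            confidences[otu] = confs
    return TaxonomyTable(assignments, confidences, sizes)


def write_taxonomy(tax: TaxonomyTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("OTU\tSize\tTaxonomy\n")
        for otu, names in tax.assignments.items():
            size = tax.sizes.get(otu, 0)
            fh.write(f"{otu}\t{size}\t{serialize_lineage(names)}\n")


# ---------------------------------------------------------------------------
# environment table & tree
# ---------------------------------------------------------------------------

def read_env(path: str | Path) -> EnvTable:
    """Read a TSV of per-sample environmental variables (first column = sample).

    A ``# units: var=unit,...`` comment line, when present, populates units.
    """
    path = Path(path)
    units: dict[str, str] = {}
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("# units:"):
        for item in first[len("# units:"):].strip().split(","):
            if "=" in item:
                k, v = item.split("=", 1)
                units[k.strip()] = v.strip()
    data = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    numeric = data.select_dtypes(include=[np.number])
    bad = (numeric.drop(columns=[c for c in ("pH",) if c in numeric]) < 0)
    if bad.to_numpy().any():
        raise ValueError(f"{path}: negative concentrations")
    return EnvTable(data, units)


def write_env(env: EnvTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        if env.units:
            fh.write("# units: " +
                     ",".join(f"{k}={v}" for k, v in env.units.items()) + "\n")
        env.data.to_csv(fh, sep="\t", index_label="sample")


def read_tree(path: str | Path) -> TreeNode:
    """Read a rooted newick tree, validating unique leaves and lengths ≥ 0."""
    tree = TreeNode.read(str(path), format="newick")
    names = [leaf.name for leaf in tree.tips()]
    if len(names) != len(set(names)):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate leaf names in tree: {dupes}")
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            raise ValueError(f"negative branch length at {node.name!r}")
    return tree


def total_branch_length(tree: TreeNode) -> float:
    return sum(n.length or 0.0 for n in tree.traverse(include_self=False))
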