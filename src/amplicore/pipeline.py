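"""End-to-end orchestration and the sequencing read-accounting report.

``run_pipeline`` glues the stages together for one YAML config: even-depth
subsampling → per-sample diversity → pairwise dissimilarities → Venn overlap →
core-microbiome delineation → environment correlation. Every output file
carries the hash of the config that produced it, and a fixed seed reproduces
all outputs bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .alpha import alpha_summary
from .beta import dist_matrix, overlap_report
from .core import CoreCriteria, CoreMicrobiome
from .correlate import correlate_all
from .io import read_env, read_shared, read_taxonomy, read_tree
from .subsample import SubsampleSpec, averaged_shared, downsample

logger = logging.getLogger(__name__)

__all__ = ["ReadAccounting", "read_accounting", "run_pipeline", "config_hash"]


@dataclass
class ReadAccounting:
    """Per-sample read bookkeeping: raw → high-quality → non-chimeric.

    Percentages follow the usual presentation: high-quality and final
    (high-quality non-chimeric) reads as a percent of raw reads, chimeras as a
    percent of high-quality reads. Display rounds to one decimal; full
    precision is retained in the frame.
    """

    data: pd.DataFrame  # rows: samples + "Total"

    @property
    def totals(self) -> pd.Series:
        return self.data.loc["Total"]

    def to_tsv(self, path, header_lines: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            out = self.data.copy()
            for col in out.columns:
                if col.endswith("_pct"):
                    out[col] = out[col].round(1)
            out.to_csv(fh, sep="\t", index_label="sample")

    def summary(self) -> str:
        out = self.data.copy()
        for col in out.columns:
            if col.endswith("_pct"):
                out[col] = out[col].round(1)
        return out.to_string()


def read_accounting(per_sample: dict[str, tuple[int, int, int]]) -> ReadAccounting:
    """Build the accounting report from per-sample (raw, hq, chimera) triples.

    ``hqnc = hq − chimeras`` is derived; sample rows must satisfy
    0 ≤ chimeras ≤ hq ≤ raw. A totals row sums the counts and recomputes the
    percentages from the summed counts.
    """
    rows = {}
    for sample, (raw, hq, chim) in per_sample.items():
        if not (0 <= chim <= hq <= raw):
            raise ValueError(
                f"sample {sample}: need 0 <= chimeras ({chim}) <= "
                f"high-quality ({hq}) <= raw ({raw})")
        rows[sample] = (raw, hq, chim)
    if "Total" in rows:
        raise ValueError("'Total' is a reserved row name")
    frame = pd.DataFrame.from_dict(
        rows, orient="index", columns=["raw", "hq", "chimeras"])
    frame.loc["Total"] = frame.sum()
    frame["hqnc"] = frame["hq"] - frame["chimeras"]
    frame["hq_pct"] = 100.0 * frame["hq"] / frame["raw"]
    frame["chimera_pct"] = 100.0 * frame["chimeras"] / frame["hq"]
    frame["hqnc_pct"] = 100.0 * frame["hqnc"] / frame["raw"]
    return ReadAccounting(frame)


def config_hash(config: dict) -> str:
    """Short stable hash of the analysis configuration (order-insensitive).

    The artifact destination (``out``) is excluded: two runs of the same
    analysis into different directories share a hash.
    """
    keyed = {k: v for k, v in config.items() if k != "out"}
    blob = json.dumps(keyed, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None
                 ) -> dict[str, Path]:
    """Run the full analysis described by a YAML config (path or mapping).

    Config keys: ``shared`` (path, required), ``label``, ``taxonomy``,
    ``tree``, ``env``, ``accounting`` (mapping sample → [raw, hq, chimeras]),
    ``depth`` (default: smallest sample total), ``replicates`` (default 5),
    ``seed`` (default 0), ``use_averaged`` (default true: run Venn/core on the
    replicate-averaged table rather than a single down-sampling), ``metrics``
    (default braycurtis + morisitahorn), ``core`` criteria mapping, ``out``.

    Returns a mapping of artifact name → written path.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = dict(config)
    out = Path(out_dir or cfg.get("out", "amplicore_out"))
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    seed = int(cfg.get("seed", 0))

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("amplicore")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    paths: dict[str, Path] = {"log": log_path}
    header = [f"amplicore {__version__}", f"config={chash}", f"seed={seed}"]

    stage = "setup"

    def _stage(name):
        nonlocal stage
        stage = name
        logger.info("stage %s", name)

    try:
        _stage("load")
        table = read_shared(cfg["shared"], label=cfg.get("label"))
        taxonomy = read_taxonomy(cfg["taxonomy"]) if cfg.get("taxonomy") else None
        tree = read_tree(cfg["tree"]) if cfg.get("tree") else None
        env = read_env(cfg["env"]) if cfg.get("env") else None
        logger.info("table %s; parameters %s", table, {
            k: cfg.get(k) for k in ("label", "depth", "replicates", "seed")})

        depth = int(cfg.get("depth") or table.sample_totals().min())
        spec = SubsampleSpec(depth=depth,
                             replicates=int(cfg.get("replicates", 5)),
                             seed=seed)

        _stage("subsample")
        use_averaged = bool(cfg.get("use_averaged", True))
        norm = (averaged_shared(table, spec) if use_averaged
                else downsample(table, depth, seed=seed))

        _stage("alpha")
        alpha = alpha_summary(table, spec, tree=tree)
        for note in alpha.notes:
            logger.info("alpha: %s", note)
        paths["alpha"] = out / "alpha.tsv"
        alpha.to_tsv(paths["alpha"], header_lines=header)

        _stage("dist")
        for metric in cfg.get("metrics", ["braycurtis", "morisitahorn"]):
            dm = dist_matrix(norm, metric)
            paths[f"dist_{metric}"] = out / f"dist_{metric}.tsv"
            dm.to_tsv(paths[f"dist_{metric}"], header_lines=header)

        _stage("venn")
        ov = overlap_report(norm, min_count=float(cfg.get("min_count", 1)))
        paths["venn"] = out / "venn.json"
        with open(paths["venn"], "w") as fh:
            json.dump({"_meta": header, **ov.to_json_dict()}, fh, indent=1,
                      sort_keys=True)
            fh.write("\n")

        _stage("core")
        core_cfg = cfg.get("core", {})
        criteria = CoreCriteria(
            evenness_min=float(core_cfg.get("evenness_min", 0.9)),
            min_reads_per_sample=float(core_cfg.get("min_reads", 3)),
            min_freq_per_sample=float(core_cfg.get("min_freq", 0.001)))
        report = CoreMicrobiome(norm, taxonomy).fit(criteria)
        logger.info("core: %d of %d OTUs", report.n_core, len(report.data))
        paths["core"] = out / "core_report.tsv"
        report.to_tsv(paths["core"], header_lines=header)

        _stage("correlate")
        if env is not None:
            corr = correlate_all(alpha, env)
            paths["correlations"] = out / "correlations.tsv"
            with open(paths["correlations"], "w") as fh:
                for line in header:
                    fh.write(f"# {line}\n")
                fh.write(f"# n_tests={corr.attrs['n_tests']}\n")
                corr.to_csv(fh, sep="\t", index=False, float_format="%.6g")
        else:
            logger.info("no env table: correlation stage skipped")

        if cfg.get("accounting"):
            _stage("accounting")
            acc = read_accounting(
                {k: tuple(v) for k, v in cfg["accounting"].items()})
            paths["accounting"] = out / "accounting.tsv"
            acc.to_tsv(paths["accounting"], header_lines=header)
    except Exception as exc:
        logger.error("pipeline aborted at stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
    return paths
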