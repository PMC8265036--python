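"""End-to-end pipeline: network -> fibers -> blocks -> coexpression report."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .blocks import classify_all, fiber_size_histogram
from .fibration import FiberPartition, minimal_balanced_coloring
from .grn import OperonTable, RegNetwork, collapse_operons, read_grn, remove_sigma_factors, write_grn
from .stats import fiber_significance, read_expression

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "write_partition", "read_partition",
           "write_blocks"]


@dataclass
class PipelineConfig:
    """Paths, modes and parameters for one pipeline run."""

    network: str
    dialect: str = "plain"
    nodes_file: Optional[str] = None
    operon_table: Optional[str] = None
    sigma_list: Optional[str] = None
    expression: Optional[str] = None
    out_dir: str = "fibersync_out"
    filtering: str = "none"
    n_samples: int = 10_000
    min_size: int = 2
    max_size: int = 24
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        if not isinstance(data, dict):
            raise ValueError(f"config {path} must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def write_partition(partition: FiberPartition, path: str | Path) -> None:
    sizes = partition.sizes()
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("node\tfiber_id\tfiber_size\n")
        for node in sorted(partition.colors):
            fid = partition.colors[node]
            fh.write(f"{node}\t{fid}\t{sizes[fid]}\n")


def read_partition(path: str | Path) -> FiberPartition:
    df = pd.read_csv(path, sep="\t", dtype={"node": str})
    return FiberPartition.from_colors(
        dict(zip(df["node"], df["fiber_id"].astype(int)))
    )


def write_blocks(blocks, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("fiber_id\tmembers\tregulators\tn\tl\tclass\tlabel\n")
        for b in blocks:
            n_str = f"{b.n:.4f}".rstrip("0").rstrip(".") if b.n is not None else ""
            fh.write(
                f"{b.fiber_id}\t{','.join(sorted(b.members))}\t"
                f"{','.join(sorted(b.regulators))}\t{n_str}\t{b.l}\t"
                f"{b.class_label}\t{b.label}\n"
            )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run network normalisation, fiber detection, classification and (if an
    expression matrix is configured) the coexpression significance analysis.

    Writes every stage artifact plus ``report.json`` into the output
    directory and returns the report dict.  Reruns with identical config
    reproduce identical files.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net = read_grn(config.network, dialect=config.dialect,
                   nodes_path=config.nodes_file)
    if config.operon_table:
        net = collapse_operons(net, OperonTable.from_tsv(config.operon_table))
    if config.sigma_list:
        sigma = [
            s.strip()
            for s in Path(config.sigma_list).read_text(encoding="utf-8").splitlines()
            if s.strip() and not s.startswith("#")
        ]
        net = remove_sigma_factors(net, sigma)
    write_grn(net, out / "network_processed.tsv", out / "network_processed.nodes")

    partition = minimal_balanced_coloring(net)
    write_partition(partition, out / "partition.tsv")
    blocks = classify_all(net, partition)
    write_blocks(blocks, out / "blocks.tsv")
    hist = fiber_size_histogram(partition, config.min_size, config.max_size)

    report = {
        "version": __version__,
        "seed": config.seed,
        "n_nodes": len(net.nodes),
        "n_edges": len(net.edges),
        "n_fibers": len(partition),
        "n_nontrivial_fibers": sum(1 for s in partition.sizes().values() if s >= 2),
        "size_histogram": {str(k): v for k, v in hist.items()},
        "classes": {
            str(b.fiber_id): {
                "members": sorted(b.members),
                "n": b.n,
                "l": b.l,
                "class": b.class_label,
                "label": b.label,
            }
            for b in blocks
            if len(b.members) >= 2
        },
    }

    if config.expression:
        expr = read_expression(config.expression)
        result = fiber_significance(
            partition,
            expr,
            filtering=config.filtering,
            n_samples=config.n_samples,
            seed=config.seed,
            size_range=(config.min_size, config.max_size),
        )
        result.table.to_csv(out / "significance_table.tsv", sep="\t", index=False)
        result.per_fiber.to_csv(out / "per_fiber.tsv", sep="\t", index=False)
        report["significance"] = {
            "filtering": result.meta["filtering"],
            "n_samples": result.meta["n_samples"],
            "fibers_dropped": result.meta["fibers_dropped"],
            "per_size": result.table.to_dict(orient="records"),
            "n_significant_sizes": int(result.table["significant"].sum())
            if not result.table.empty
            else 0,
        }

    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    logger.info("pipeline complete: %s", out / "report.json")
    return report
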