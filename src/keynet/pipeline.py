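"""End-to-end orchestration: config, staged execution, report bundle.

``run_pipeline`` executes the whole procedure in order — gene-list loading,
Venn partitioning, per-network topology, key-protein selection with
subnetwork extraction, degree/score frequency distributions, and gene-set
enrichment for the full lists and the key sets — and writes a deterministic
TSV report bundle plus a JSON run manifest. A failure in any stage removes
the partial outputs and raises :class:`PipelineError` naming the stage.

Configuration is a flat ``key=value`` text format (one pair per line,
``#`` comments) whose defaults encode the procedure's standard choices:
top-2 hubs, the 90th combined-score percentile with the nearest-rank rule,
two closure steps, induced-subgraph edges, five frequency classes.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .distributions import cs_distribution, degree_distribution, write_frequency_table
from .enrichment import AnnotationSet, enrich, read_gmt, write_enrichment_report
from .keyselect import key_protein_analysis, write_key_protein_report
from .listops import venn_partition, write_membership_table, write_region_report
from .netcore import (
    ScoredGeneList,
    ScoredNetwork,
    logger,
    read_edge_table,
    read_gene_list,
    write_edge_table,
)
from .synthetic_data import (
    HubNetworkSpec,
    generate_annotation,
    generate_hub_network,
    make_fixture_lists,
)
from .topology import network_topology, node_topology, write_node_report, write_topology_report


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


_BOOL_TRUE = {"1", "true", "yes", "on"}


@dataclass
class PipelineConfig:
    """Flat pipeline configuration with procedure-standard defaults."""

    #: ordered list of gene-list names
    names: list[str] = field(default_factory=lambda: ["PoS", "AcouStim", "Tin"])
    #: name -> gene list path (empty in simulate mode)
    gene_lists: dict[str, str] = field(default_factory=dict)
    #: name -> edge table path (empty in simulate mode)
    edge_tables: dict[str, str] = field(default_factory=dict)
    annotation: str = ""
    simulate: bool = False
    k: int = 2
    q: float = 0.90
    quantile_rule: str = "nearest_rank"
    max_depth: int = 2
    edge_policy: str = "all_member_edges"
    n_classes: int = 5
    cs_class_width: int = 120
    cs_range_start: int = 400
    degree_normalizer_policy: str = "all_nodes"
    score_scale: str = "millis"
    out_dir: str = "keynet-out"
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        cfg = cls()
        for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {lineno} is not key=value: {raw!r}")
            key, _, value = line.partition("=")
            cfg.set(key.strip(), value.strip())
        return cfg

    def set(self, key: str, value: str) -> None:
        """Apply one ``key=value`` override (dotted keys address per-list paths)."""
        if key == "names":
            self.names = [n.strip() for n in value.split(",") if n.strip()]
            return
        if key.startswith("gene_list."):
            self.gene_lists[key.split(".", 1)[1]] = value
            return
        if key.startswith("edge_table."):
            self.edge_tables[key.split(".", 1)[1]] = value
            return
        if key not in {f.name for f in dataclasses.fields(self)}:
            raise KeyError(f"unknown config key: {key}")
        current = getattr(self, key)
        if isinstance(current, bool):
            setattr(self, key, value.lower() in _BOOL_TRUE)
        elif isinstance(current, int):
            setattr(self, key, int(value))
        elif isinstance(current, float):
            setattr(self, key, float(value))
        else:
            setattr(self, key, value)

    def apply_overrides(self, overrides: list[str]) -> None:
        for item in overrides:
            if "=" not in item:
                raise ValueError(f"override is not key=value: {item!r}")
            key, _, value = item.partition("=")
            self.set(key.strip(), value.strip())

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _setup_logging(out_dir: Path) -> logging.Handler:
    handler = logging.FileHandler(out_dir / "run.log", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    if logger.level == logging.NOTSET or logger.level > logging.INFO:
        logger.setLevel(logging.INFO)
    return handler


def _load_inputs(config: PipelineConfig):
    if config.simulate:
        lists = make_fixture_lists(seed=config.seed)
        lists = [gl for gl in lists if gl.name in config.names] or lists
        nets = []
        for i, gl in enumerate(lists):
            spec = HubNetworkSpec(seed=config.seed + 101 * (i + 1), name=gl.name)
            nets.append(generate_hub_network(spec))
        union = sorted(set().union(*(gl.symbol_set for gl in lists)))
        annot = generate_annotation(union, n_terms=30, seed=config.seed + 7)
        return lists, nets, annot
    lists = [read_gene_list(config.gene_lists[n], n) for n in config.names]
    nets = [
        read_edge_table(config.edge_tables[n], score_scale=config.score_scale, name=n)
        for n in config.names
        if n in config.edge_tables
    ]
    annot: AnnotationSet | None = read_gmt(config.annotation) if config.annotation else None
    return lists, nets, annot


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage and return the bundle of output paths (by report name)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(out_dir)
    outputs: dict[str, Path] = {}
    timings: dict[str, float] = {}
    stage = "setup"

    def emit(key: str, filename: str) -> Path:
        path = out_dir / filename
        outputs[key] = path
        return path

    try:
        t0 = time.perf_counter()
        stage = "load"
        logger.info("stage load: reading inputs (simulate=%s)", config.simulate)
        lists, nets, annot = _load_inputs(config)
        timings[stage] = time.perf_counter() - t0

        t0 = time.perf_counter()
        stage = "venn"
        logger.info("stage venn: partitioning %d lists", len(lists))
        partition = venn_partition(lists)
        write_region_report(partition, emit("venn_regions", "venn_regions.tsv"))
        write_membership_table(partition, emit("membership", "membership.tsv"))
        timings[stage] = time.perf_counter() - t0

        t0 = time.perf_counter()
        stage = "topology"
        reports = []
        for net in nets:
            logger.info("stage topology: %r", net)
            reports.append(network_topology(net))
            write_node_report(
                node_topology(net), emit(f"nodes_{net.name}", f"topology_nodes_{net.name}.tsv")
            )
        write_topology_report(
            reports,
            emit("topology", "topology_networks.tsv"),
            emit("topology_json", "topology_networks.json"),
        )
        timings[stage] = time.perf_counter() - t0

        t0 = time.perf_counter()
        stage = "keyselect"
        key_results = []
        for net in nets:
            res = key_protein_analysis(
                net,
                k=config.k,
                q=config.q,
                quantile_rule=config.quantile_rule,
                max_depth=config.max_depth,
                edge_policy=config.edge_policy,
            )
            logger.info(
                "stage keyselect: %s HDPs=%s threshold=%g",
                net.name, [h.node for h in res.hdps], res.cs_threshold,
            )
            key_results.append(res)
            write_edge_table(
                res.subnetwork, emit(f"subnetwork_{net.name}", f"subnetwork_{net.name}.tsv")
            )
        if key_results:
            write_key_protein_report(key_results, emit("key_proteins", "key_proteins.tsv"))
            write_topology_report(
                [r.subnetwork_topology for r in key_results],
                emit("subnetworks_topology", "subnetworks_topology.tsv"),
            )
        timings[stage] = time.perf_counter() - t0

        t0 = time.perf_counter()
        stage = "distributions"
        for net in nets:
            logger.info("stage distributions: %s", net.name)
            write_frequency_table(
                degree_distribution(
                    net, config.n_classes, config.degree_normalizer_policy
                ),
                emit(f"degree_dist_{net.name}", f"degree_dist_{net.name}.tsv"),
            )
            write_frequency_table(
                cs_distribution(net, config.cs_class_width, config.cs_range_start, config.n_classes),
                emit(f"cs_dist_{net.name}", f"cs_dist_{net.name}.tsv"),
            )
        timings[stage] = time.perf_counter() - t0

        t0 = time.perf_counter()
        stage = "enrichment"
        if annot is not None:
            for gl in lists:
                logger.info("stage enrichment: list %s", gl.name)
                write_enrichment_report(
                    enrich(gl.symbol_set, annot),
                    emit(f"enrichment_{gl.name}", f"enrichment_{gl.name}.tsv"),
                )
            for res in key_results:
                key_set = {h.node for h in res.hdps} | {
                    r.partner for recs in res.hsips.values() for r in recs
                }
                key_set &= annot.universe
                if key_set:
                    write_enrichment_report(
                        enrich(key_set, annot),
                        emit(f"enrichment_key_{res.network}", f"enrichment_key_{res.network}.tsv"),
                    )
        timings[stage] = time.perf_counter() - t0

        stage = "manifest"
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "timings_s": {k: round(v, 4) for k, v in timings.items()},
            "outputs": {k: str(p) for k, p in outputs.items()},
        }
        path = emit("manifest", "manifest.json")
        path.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    except Exception as exc:
        for path in outputs.values():
            path.unlink(missing_ok=True)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
    return outputs
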