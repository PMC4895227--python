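"""End-to-end orchestration: data → projections → metrics → communities → reports.

:func:`run_pipeline` drives the whole analysis for one trait table (read
from file or drawn synthetically): it builds the species and feature
projections, then for every requested weight threshold prunes the species
graph, computes the metric suite, runs the community algorithms, and writes
the composition report for the reporting partition (Louvain by default).
All artifacts land in one run directory together with a machine-readable
manifest (SHA-256 per artifact) and a log of the seeds and settings used.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from . import community as comm
from . import metrics as met
from . import projection as proj
from .report import cluster_report, feature_report
from .trait_data import SyntheticSpec, TraitMatrix, generate_synthetic, read_trait_table, write_trait_table

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """What to analyse and how.

    Exactly one of ``input_table`` / ``synthetic`` must be given.
    ``thresholds`` lists minimum edge weights; threshold 1 analyses the
    unpruned graph (isolates kept), thresholds ≥ 2 drop isolated vertices,
    matching the usual pruning convention.
    """

    input_table: str | Path | None = None
    mode: str = "binary"  # binary | categorical, for input_table
    synthetic: SyntheticSpec | None = None
    thresholds: list[int] = field(default_factory=lambda: [1, 2, 3, 4])
    algorithms: list[str] = field(default_factory=lambda: ["fg", "wt", "bl", "lp"])
    seed: int = 0
    weighted: bool = True
    outdir: str | Path = "traitnet_out"
    run_name: str | None = None  # default: timestamped directory name

    def __post_init__(self) -> None:
        if (self.input_table is None) == (self.synthetic is None):
            raise ValueError("give exactly one of input_table or synthetic")
        bad = [a for a in self.algorithms if a not in comm._ALGORITHMS]
        if bad:
            raise ValueError(f"unknown algorithm(s): {bad}; choose from fg, wt, bl, lp")
        if any(t < 1 for t in self.thresholds):
            raise ValueError("thresholds must be >= 1")


@dataclass
class PipelineResult:
    run_dir: Path
    trait_matrix: TraitMatrix
    species_graph: nx.Graph
    feature_graph: nx.Graph
    summary_rows: list[comm.SummaryRow]
    partitions: dict[int, dict[str, comm.Partition]]  # threshold -> algo -> partition
    manifest: dict


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def _run_algorithms(
    g: nx.Graph, algorithms: list[str], seed: int, weighted: bool
) -> dict[str, comm.Partition]:
    out: dict[str, comm.Partition] = {}
    for a in algorithms:
        if a == "fg":
            out[a] = comm.fastgreedy(g, weighted=weighted)
        elif a == "wt":
            out[a] = comm.walktrap(g, weighted=weighted)
        elif a == "bl":
            out[a] = comm.louvain(g, seed, weighted=weighted)
        elif a == "lp":
            out[a] = comm.label_propagation(g, seed + 1, weighted=weighted)
    return out


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis; returns the artifact bundle.

    The same config and seed produce bitwise-identical artifacts (the run
    directory name and log timestamps aside), so the manifest checksums are
    reproducible.
    """
    outdir = Path(config.outdir)
    run_name = config.run_name or time.strftime("run_%Y%m%dT%H%M%S", time.gmtime())
    run_dir = outdir / run_name
    run_dir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"seed: {config.seed}", f"weighted: {config.weighted}"]
    artifacts: list[Path] = []

    with _stage("load"):
        if config.synthetic is not None:
            tm = generate_synthetic(config.synthetic)
            log_lines.append(f"synthetic spec: {dataclasses.asdict(config.synthetic)}")
        else:
            tm = read_trait_table(config.input_table, mode=config.mode)
            log_lines.append(f"input table: {config.input_table} (mode={config.mode})")
        table_path = run_dir / "trait_table.csv"
        write_trait_table(tm, table_path)
        artifacts.append(table_path)

    with _stage("projection"):
        gp = proj.project_species(tm)
        gf = proj.project_features(tm)
        p = run_dir / "species_graph.tsv"
        proj.write_edge_list(gp, p)
        artifacts.append(p)
        p = run_dir / "feature_graph.tsv"
        proj.write_edge_list(gf, p)
        artifacts.append(p)
        p = run_dir / "species_graph.graphml"
        proj.write_graphml(gp, p)
        artifacts.append(p)

    with _stage("feature_report"):
        fr = feature_report(gf)
        p = run_dir / "feature_report.json"
        p.write_text(json.dumps(fr.as_dict(), indent=2) + "\n")
        artifacts.append(p)

    summary_rows: list[comm.SummaryRow] = []
    partitions: dict[int, dict[str, comm.Partition]] = {}
    report_algo = "bl" if "bl" in config.algorithms else config.algorithms[0]
    for t in config.thresholds:
        with _stage(f"threshold_{t}"):
            gt = proj.filter_by_weight(gp, t, drop_isolated=(t > 1))
            log_lines.append(
                f"threshold w>={t} (w>{t - 1}): N={gt.number_of_nodes()} E={gt.number_of_edges()}"
            )
            p = run_dir / f"species_graph_w{t}.tsv"
            proj.write_edge_list(gt, p)
            artifacts.append(p)

            gm = met.graph_metrics(gt)
            p = run_dir / f"metrics_w{t}.json"
            p.write_text(json.dumps(gm.to_dict(), indent=2) + "\n")
            artifacts.append(p)

            parts = _run_algorithms(gt, config.algorithms, config.seed, config.weighted)
            partitions[t] = parts
            for a, part in parts.items():
                p = run_dir / f"membership_{a}_w{t}.tsv"
                with open(p, "w") as fh:
                    fh.write("vertex\tcommunity\n")
                    for v in sorted(map(str, part.membership)):
                        fh.write(f"{v}\t{part.membership[v]}\n")
                artifacts.append(p)

            N, E = gt.number_of_nodes(), gt.number_of_edges()
            summary_rows.append(
                comm.SummaryRow(
                    fg=parts["fg"].n_communities if "fg" in parts else -1,
                    wt=parts["wt"].n_communities if "wt" in parts else -1,
                    bl=parts["bl"].n_communities if "bl" in parts else -1,
                    lp=parts["lp"].n_communities if "lp" in parts else -1,
                    weight_threshold=t,
                    E=E,
                    N=N,
                    is_connected=(N > 0 and nx.is_connected(gt)),
                    density=met.density(N, E) if N >= 2 else None,
                )
            )

            if N > 0:
                rep = cluster_report(gt, parts[report_algo], tm)
                p = run_dir / f"cluster_report_w{t}.json"
                p.write_text(json.dumps(rep.as_dict(), indent=2) + "\n")
                artifacts.append(p)
                p = run_dir / f"cluster_report_w{t}.tsv"
                p.write_text(rep.to_tsv())
                artifacts.append(p)

    with _stage("summary"):
        p = run_dir / "summary.tsv"
        with open(p, "w") as fh:
            fh.write("FG\tWT\tBL\tLP\tWeight\tE\tN\tIs.connected\tDensity\n")
            for r in summary_rows:
                dens = f"{r.density:.7f}" if r.density is not None else "NA"
                fh.write(
                    f"{r.fg}\t{r.wt}\t{r.bl}\t{r.lp}\t{r.weight_threshold}"
                    f"\t{r.E}\t{r.N}\t{r.is_connected}\t{dens}\n"
                )
        artifacts.append(p)

    manifest = {
        "seed": config.seed,
        "algorithms": config.algorithms,
        "thresholds": config.thresholds,
        "weighted": config.weighted,
        "reporting_algorithm": report_algo,
        "files": {a.name: _sha256(a) for a in sorted(artifacts)},
    }
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    (run_dir / "log.txt").write_text("\n".join(log_lines) + "\n")
    return PipelineResult(run_dir, tm, gp, gf, summary_rows, partitions, manifest)
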