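"""End-to-end orchestration: normalize -> DEM -> catalog -> enrichment -> network.

Every stage writes its intermediate as TSV under the output directory
and the run ends with a machine-readable summary (JSON).  Stage failures
raise :class:`StageError` carrying the stage name; reruns with identical
inputs, config and seed are byte-identical apart from no timestamps
being written at all.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .catalog import GeromiRCatalog, reference_catalog, restrict_to_platform
from .dem import DEMParams, call_dems, rank_dems, volcano_points
from .enrichment import enrichment_frame, hallmark_enrichment, set_enrichment
from .expression import quantile_normalize, read_matrix
from .network import (
    build_network,
    export_network,
    load_interactions,
    reverse_expression_screen,
)

__all__ = ["RunConfig", "RunSummary", "StageError", "run_pipeline"]

log = logging.getLogger("geromir")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage label."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Inputs, thresholds and outputs of one pipeline run."""

    mirna_matrix: Path
    annotations: Path
    out_dir: Path
    gene_matrix: Path | None = None
    gene_annotations: Path | None = None
    catalog: Path | None = None  # None -> packaged compilation
    interactions: Path | None = None
    mirna_params: DEMParams = field(default_factory=DEMParams)
    gene_params: DEMParams = field(default_factory=DEMParams)
    cell_types: tuple[str, ...] = ("E", "I", "K")
    normalize: bool = True
    linear_scale: bool = False
    make_plots: bool = False
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("mirna_matrix", "annotations", "out_dir", "gene_matrix",
                    "gene_annotations", "catalog", "interactions"):
            if raw.get(key) is not None:
                kwargs[key] = Path(raw[key])
        for layer in ("mirna_params", "gene_params"):
            if layer in raw:
                kwargs[layer] = DEMParams(**raw[layer])
        for key in ("cell_types", "normalize", "linear_scale", "make_plots",
                    "seed", "log_level"):
            if key in raw:
                kwargs[key] = (
                    tuple(raw[key]) if key == "cell_types" else raw[key]
                )
        missing = {"mirna_matrix", "annotations", "out_dir"} - set(kwargs)
        if missing:
            raise ValueError(f"run config missing required keys: {sorted(missing)}")
        return cls(**kwargs)

    def validate(self) -> None:
        for label, path in (
            ("mirna_matrix", self.mirna_matrix),
            ("annotations", self.annotations),
            ("gene_matrix", self.gene_matrix),
            ("gene_annotations", self.gene_annotations),
            ("catalog", self.catalog),
            ("interactions", self.interactions),
        ):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{label}: no such file {path}")


@dataclass
class RunSummary:
    """Headline counts plus references to the written artifacts."""

    n_mirnas_tested: int
    n_dems_down: int
    n_dems_up: int
    n_geromirs_catalog: int
    n_geromirs_on_platform: int
    n_geromirs_down: int
    n_geromirs_up: int
    geromir_enrichment_p: float | None
    top_hallmarks: list[str]
    reverse_expression_hits: list[str]
    version: str
    config: dict
    outputs: dict[str, str]

    def __post_init__(self) -> None:
        # internal consistency: asserted on every run, not just tested
        assert self.n_geromirs_down <= self.n_dems_down
        assert self.n_geromirs_up <= self.n_dems_up
        assert self.n_geromirs_on_platform <= self.n_geromirs_catalog
        assert self.n_geromirs_down <= self.n_geromirs_on_platform

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, str(exc)) from exc
        return wrapped
    return deco


def _config_echo(config: RunConfig) -> dict:
    echo = dataclasses.asdict(config)
    return {
        k: (str(v) if isinstance(v, Path) else v) for k, v in echo.items()
    }


def run_pipeline(config: RunConfig) -> RunSummary:
    """Execute all stages in order and write every intermediate as TSV."""
    logging.basicConfig(level=config.log_level,
                        format="%(levelname)s %(name)s: %(message)s")
    try:
        config.validate()
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
    except Exception as exc:
        raise StageError("config", str(exc)) from exc
    outputs: dict[str, str] = {}

    @_stage("ingest")
    def ingest():
        return read_matrix(config.mirna_matrix, config.annotations,
                           linear_scale=config.linear_scale)

    matrix, annot = ingest()
    log.info("ingest: %d miRNAs x %d samples", *matrix.shape)

    @_stage("normalize")
    def normalize(m):
        return quantile_normalize(m) if config.normalize else m

    matrix = normalize(matrix)
    norm_path = out / "mirna_matrix.normalized.tsv"
    matrix.to_csv(norm_path, sep="\t", float_format="%.6g")
    outputs["normalized_matrix"] = str(norm_path)

    @_stage("dem")
    def dem():
        return call_dems(matrix, annot, config.mirna_params,
                         set(config.cell_types))

    dems = dem()
    n_down = len(dems.features("down"))
    n_up = len(dems.features("up"))
    log.info("dem: %d down / %d up of %d tested",
             n_down, n_up, dems.population_size)
    dems.write_tsv(out / "dems.tsv")
    points = volcano_points(matrix, annot, config.mirna_params,
                            set(config.cell_types))
    points.to_csv(out / "volcano.tsv", sep="\t", index=False)
    outputs["dems"] = str(out / "dems.tsv")
    outputs["volcano"] = str(out / "volcano.tsv")
    if config.make_plots:
        from .plotting import plot_expression_heatmap, plot_volcano

        plot_volcano(points, out / "volcano.png",
                     config.mirna_params.log2_theta,
                     config.mirna_params.alpha)
        called = matrix.loc[matrix.index.astype(str).isin(dems.features())]
        if not called.empty:
            plot_expression_heatmap(called, annot, out / "dem_heatmap.png",
                                    title="differentially expressed miRNAs")
        outputs["volcano_png"] = str(out / "volcano.png")

    @_stage("catalog")
    def load_cat() -> GeromiRCatalog:
        cat = (GeromiRCatalog.read_tsv(config.catalog)
               if config.catalog is not None else reference_catalog())
        platform_names = set(matrix.index.astype(str))
        return cat, restrict_to_platform(cat, platform_names)

    full_catalog, platform_cat = load_cat()
    platform_cat.write_tsv(out / "catalog.platform.tsv")
    outputs["platform_catalog"] = str(out / "catalog.platform.tsv")
    log.info("catalog: %d geromiRs, %d on platform",
             len(full_catalog), len(platform_cat))

    @_stage("enrichment")
    def enrich():
        population = set(matrix.index.astype(str))
        down_gero = dems.features("down") & platform_cat.names
        up_gero = dems.features("up") & platform_cat.names
        gero_p = None
        if platform_cat.names:
            gero_p = set_enrichment(
                dems.features("down"), platform_cat.names, population,
                category_id="geromiRs",
            ).p_value
        hallmark = hallmark_enrichment(
            down_gero, platform_cat, population_size=dems.population_size
        )
        return down_gero, up_gero, gero_p, hallmark

    down_gero, up_gero, gero_p, hallmark_results = enrich()
    enrichment_frame(hallmark_results).to_csv(
        out / "hallmark_enrichment.tsv", sep="\t", index=False)
    outputs["hallmark_enrichment"] = str(out / "hallmark_enrichment.tsv")
    if config.make_plots:
        from .plotting import plot_enrichment_bars

        plot_enrichment_bars(hallmark_results,
                             out / "hallmark_enrichment.png")
        outputs["hallmark_enrichment_png"] = str(
            out / "hallmark_enrichment.png")
    log.info("enrichment: %d down / %d up geromiRs, geromiR p=%s",
             len(down_gero), len(up_gero), gero_p)

    hits: list[str] = []
    if config.interactions is not None:
        @_stage("network")
        def network():
            interactions = load_interactions(config.interactions)
            graph = build_network(down_gero, interactions)
            export_network(graph, out / "network.graphml",
                           out / "network.edges.tsv")
            if config.gene_matrix is None:
                return graph, None
            gmat, gannot = read_matrix(
                config.gene_matrix,
                config.gene_annotations or config.annotations,
                linear_scale=config.linear_scale,
            )
            if config.normalize:
                gmat = quantile_normalize(gmat)
            screen = reverse_expression_screen(
                graph, gmat, gannot, config.gene_params,
                set(config.cell_types),
            )
            screen.to_csv(out / "reverse_expression_hits.tsv",
                          sep="\t", index=False)
            return graph, screen

        graph, screen = network()
        outputs["network_graphml"] = str(out / "network.graphml")
        outputs["network_edges"] = str(out / "network.edges.tsv")
        if screen is not None:
            outputs["reverse_expression_hits"] = str(
                out / "reverse_expression_hits.tsv")
            hits = sorted(screen["gene"].astype(str))
        log.info("network: %d nodes, hits: %s",
                 graph.number_of_nodes(), hits)

    summary = RunSummary(
        n_mirnas_tested=dems.population_size,
        n_dems_down=n_down,
        n_dems_up=n_up,
        n_geromirs_catalog=len(full_catalog),
        n_geromirs_on_platform=len(platform_cat),
        n_geromirs_down=len(down_gero),
        n_geromirs_up=len(up_gero),
        geromir_enrichment_p=gero_p,
        top_hallmarks=[r.category_id for r in hallmark_results[:3]],
        reverse_expression_hits=hits,
        version=__version__,
        config=_config_echo(config),
        outputs=outputs,
    )
    summary.to_json(out / "summary.json")
    return summary
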