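"""Synthetic two-condition microarray data with planted ground truth.

The generator emulates the study design: three liver cell types (E, I,
K) under control (C) and tumor-microenvironment (T) conditions, log2
intensities with additive Gaussian noise (microarray-style, not count
data), a geromiR catalog covering a fraction of the miRNA universe, a
planted set of down/upregulated miRNAs whose downregulated members are
enriched for a designated hallmark, and planted upregulated target genes
wired to downregulated miRNAs in the interaction table.  Every draw
comes from one seeded generator in a fixed, documented order, so a seed
pins the whole dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import (
    HALLMARKS,
    GeromiRCatalog,
    GeromiRRecord,
    get_hallmark,
)
from .dem import DEMTable
from .expression import ANNOTATION_COLUMNS, write_annotations, write_matrix

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "Truth",
    "reference_config",
    "simulate",
    "evaluate_recovery",
    "write_dataset",
]

#: replicate design of the miRNA arrays: three biological replicates per
#: (cell type, condition) except two for endothelial controls and
#: Kupffer TME samples
STUDY_REPLICATES: dict[tuple[str, str], int] = {
    ("E", "C"): 2, ("E", "T"): 3,
    ("I", "C"): 3, ("I", "T"): 3,
    ("K", "C"): 3, ("K", "T"): 2,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated dataset.

    Planted sets may be given explicitly; when left ``None`` they are
    drawn from the seeded stream with the stated counts
    (``n_planted_down`` miRNAs of which ``n_planted_down_geromirs`` are
    catalog members, ``n_planted_up`` non-geromiR miRNAs, and
    ``n_planted_up_genes`` genes).
    """

    n_mirnas: int = 600
    n_genes: int = 2000
    geromir_fraction: float = 0.125  # 75 of 600, the platform proportion
    planted_down: frozenset[str] | None = None
    planted_up: frozenset[str] | None = None
    planted_up_genes: frozenset[str] | None = None
    n_planted_down: int = 30
    n_planted_down_geromirs: int = 10
    n_planted_up: int = 10
    n_planted_up_genes: int = 2
    effect_log2: float = 3.0
    noise_sd: float = 0.5
    replicates: dict[tuple[str, str], int] = field(
        default_factory=lambda: dict(STUDY_REPLICATES)
    )
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    celltype_sd: float = 0.25
    designated_hallmark: str = "histone modifications"
    n_background_interactions: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.effect_log2 < 0:
            raise ValueError("effect_log2 must be non-negative")
        if not 0 <= self.geromir_fraction <= 1:
            raise ValueError("geromir_fraction must be a proportion")
        if min(self.replicates.values()) < 2:
            raise ValueError("need >= 2 replicates per (cell_type, condition)")
        if self.planted_down is not None and self.planted_up is not None:
            if self.planted_down & self.planted_up:
                raise ValueError("planted_down and planted_up must be disjoint")
        get_hallmark(self.designated_hallmark)


@dataclass(frozen=True)
class Truth:
    """The planted ground truth of one simulated dataset."""

    planted_down: frozenset[str]
    planted_up: frozenset[str]
    planted_up_genes: frozenset[str]
    effect_log2: float
    designated_hallmark: str


@dataclass
class SimulatedDataset:
    mirna_matrix: pd.DataFrame
    gene_matrix: pd.DataFrame
    annotations: pd.DataFrame
    truth: Truth
    catalog: GeromiRCatalog
    interactions: pd.DataFrame


def reference_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The reference recovery scenario (see the methods note)."""
    return replace(SimulationConfig(seed=seed), **overrides)


def _sample_frame(replicates: dict[tuple[str, str], int]) -> pd.DataFrame:
    rows = [
        (f"{ct}{cond}{r}", ct, cond, r)
        for (ct, cond) in sorted(replicates)
        for r in range(1, replicates[(ct, cond)] + 1)
    ]
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Generate one dataset.  Deterministic for a fixed seed.

    Draw order: geromiR membership, planted miRNA sets, planted gene
    set, hallmark assignment, miRNA baselines, gene baselines, miRNA
    cell-type offsets, gene cell-type offsets, miRNA noise, gene noise,
    interaction wiring.
    """
    rng = np.random.default_rng(config.seed)
    width = max(4, len(str(config.n_mirnas)))
    mirnas = np.array(
        [f"miR-s{i:0{width}d}" for i in range(1, config.n_mirnas + 1)]
    )
    genes = np.array([f"Gene{i:05d}" for i in range(1, config.n_genes + 1)])

    n_gero = int(round(config.geromir_fraction * config.n_mirnas))
    geromirs = set(rng.choice(mirnas, size=n_gero, replace=False))

    if config.planted_down is None:
        gero_down = set(
            rng.choice(sorted(geromirs),
                       size=config.n_planted_down_geromirs, replace=False)
        )
        non_gero = sorted(set(mirnas) - geromirs)
        other_down = set(
            rng.choice(non_gero,
                       size=config.n_planted_down - len(gero_down),
                       replace=False)
        )
        planted_down = frozenset(gero_down | other_down)
    else:
        planted_down = frozenset(config.planted_down)
    if config.planted_up is None:
        # the study found no upregulated geromiRs; emulate that
        pool = sorted(set(mirnas) - geromirs - planted_down)
        planted_up = frozenset(
            rng.choice(pool, size=config.n_planted_up, replace=False)
        )
    else:
        planted_up = frozenset(config.planted_up)
    if config.planted_up_genes is None:
        planted_up_genes = frozenset(
            rng.choice(genes, size=config.n_planted_up_genes, replace=False)
        )
    else:
        planted_up_genes = frozenset(config.planted_up_genes)
    bad = (planted_down | planted_up) - set(mirnas)
    if bad or planted_up_genes - set(genes):
        raise ValueError("planted identifiers outside the simulated universes")

    designated = get_hallmark(config.designated_hallmark)
    all_codes = [h.code for h in HALLMARKS]
    records = []
    for name in sorted(geromirs):
        codes = set()
        if name in planted_down:
            codes.add(designated.code)  # the enrichment signal
        n_extra = int(rng.integers(1, 3))
        codes.update(rng.choice(all_codes, size=n_extra, replace=False))
        records.append(
            GeromiRRecord(
                canonical_name=name,
                hallmarks=frozenset(codes),
                sources=frozenset({"synthetic"}),
                on_platform=True,
                downregulated_flag=name in planted_down,
            )
        )
    catalog = GeromiRCatalog(records)

    annot = _sample_frame(config.replicates)
    ct_index = {ct: i for i, ct in enumerate(("E", "I", "K"))}

    base_m = rng.normal(config.baseline_mean, config.baseline_sd, config.n_mirnas)
    base_g = rng.normal(config.baseline_mean, config.baseline_sd, config.n_genes)
    off_m = rng.normal(0.0, config.celltype_sd, (config.n_mirnas, 3))
    off_g = rng.normal(0.0, config.celltype_sd, (config.n_genes, 3))

    def build(feats, baseline, offsets, down_set, up_set):
        n = len(feats)
        eff = np.zeros(n)
        in_down = np.isin(feats, sorted(down_set))
        in_up = np.isin(feats, sorted(up_set))
        eff[in_down] = -config.effect_log2
        eff[in_up] = config.effect_log2
        cols = np.empty((n, len(annot)))
        for j, row in enumerate(annot.itertuples(index=False)):
            cols[:, j] = baseline + offsets[:, ct_index[row.cell_type]]
            if row.condition == "T":
                cols[:, j] += eff
        cols += rng.normal(0.0, config.noise_sd, cols.shape)
        return pd.DataFrame(cols, index=feats, columns=annot["sample_id"])

    mirna_matrix = build(mirnas, base_m, off_m, planted_down, planted_up)
    gene_matrix = build(genes, base_g, off_g, set(), planted_up_genes)

    # interaction wiring: each planted up-gene gets three downregulated
    # geromiR partners; background edges are uniform (miRNA, gene) pairs
    gero_down_sorted = sorted(planted_down & set(catalog.names))
    edges = []
    for gene in sorted(planted_up_genes):
        k = min(3, len(gero_down_sorted))
        partners = rng.choice(gero_down_sorted, size=k, replace=False)
        edges.extend((m, gene) for m in partners)
    bg_m = rng.choice(mirnas, size=config.n_background_interactions)
    bg_g = rng.choice(genes, size=config.n_background_interactions)
    edges.extend(zip(bg_m, bg_g))
    interactions = (
        pd.DataFrame(edges, columns=["mirna", "gene"])
        .assign(evidence="simulated")
        .drop_duplicates(subset=["mirna", "gene"])
        .reset_index(drop=True)
    )

    truth = Truth(planted_down, planted_up, frozenset(planted_up_genes),
                  config.effect_log2, designated.name)
    return SimulatedDataset(mirna_matrix, gene_matrix, annot, truth,
                            catalog, interactions)


def evaluate_recovery(
    dataset: SimulatedDataset, dem_table: DEMTable
) -> dict[str, float]:
    """Precision and recall of a DEM call against the planted truth.

    Empty call lists have precision 1 by convention (no false
    positives); empty truth sets have recall 1.
    """
    universe = set(dataset.mirna_matrix.index.astype(str))
    called_all = dem_table.features()
    if not called_all <= universe:
        raise ValueError("DEM table features outside the simulated universe")
    out: dict[str, float] = {}
    for direction, truth_set in (
        ("down", dataset.truth.planted_down),
        ("up", dataset.truth.planted_up),
    ):
        called = dem_table.features(direction)
        tp = len(called & truth_set)
        out[f"precision_{direction}"] = tp / len(called) if called else 1.0
        out[f"recall_{direction}"] = tp / len(truth_set) if truth_set else 1.0
    return out


def write_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write every component in the pipeline's input formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "mirna_matrix": out / "mirna_matrix.tsv",
        "gene_matrix": out / "gene_matrix.tsv",
        "annotations": out / "annotations.tsv",
        "catalog": out / "catalog.tsv",
        "interactions": out / "interactions.tsv",
        "truth": out / "truth.tsv",
    }
    write_matrix(dataset.mirna_matrix, paths["mirna_matrix"], digits=10)
    write_matrix(dataset.gene_matrix, paths["gene_matrix"], digits=10)
    write_annotations(dataset.annotations, paths["annotations"])
    dataset.catalog.write_tsv(paths["catalog"])
    dataset.interactions.to_csv(paths["interactions"], sep="\t", index=False)
    truth_rows = (
        [("planted_down", m) for m in sorted(dataset.truth.planted_down)]
        + [("planted_up", m) for m in sorted(dataset.truth.planted_up)]
        + [("planted_up_gene", g) for g in sorted(dataset.truth.planted_up_genes)]
    )
    pd.DataFrame(truth_rows, columns=["role", "identifier"]).to_csv(
        paths["truth"], sep="\t", index=False
    )
    return paths
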