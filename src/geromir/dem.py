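"""Differential-expression calling with a joint fold-change/significance rule.

A feature (miRNA or gene) is called differentially expressed between the
control (C) and tumor-microenvironment (T) samples when BOTH

* ``|mean_T - mean_C| >= log2(theta)`` (fold-change selection threshold,
  ``theta`` on the linear scale, default 4), and
* ``p < alpha`` for a two-sided two-sample location test on the log2
  intensities (default Welch's unequal-variance t-test, ``alpha`` 0.001).

Boundary equality on the fold-change criterion selects.  No multiple
testing correction enters the rule itself; a Benjamini-Hochberg column
is reported for information only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import CONDITIONS, TME_CELL_TYPES, _contrast_samples

__all__ = ["DEMParams", "DEMTable", "call_dems", "rank_dems", "volcano_points"]

_TESTS = ("welch", "student", "wilcoxon")


@dataclass(frozen=True)
class DEMParams:
    """Selection threshold (linear-scale fold change) and significance level."""

    theta: float = 4.0
    alpha: float = 0.001
    test: str = "welch"

    def __post_init__(self) -> None:
        if self.theta < 1:
            raise ValueError("theta must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.test not in _TESTS:
            raise ValueError(f"test must be one of {_TESTS}")

    @property
    def log2_theta(self) -> float:
        return float(np.log2(self.theta))


@dataclass
class DEMTable:
    """Selected features plus the size of the tested universe.

    ``records`` has columns feature_id, mean_C, mean_T, log2_fc,
    p_value, bh_q, direction and is sorted by ascending p-value.
    ``population_size`` is the number of features tested (the N of the
    downstream over-representation tests).
    """

    records: pd.DataFrame
    params: DEMParams
    population_size: int

    def __post_init__(self) -> None:
        if self.records["feature_id"].duplicated().any():
            raise ValueError("duplicate feature ids in DEM table")
        if self.population_size < len(self.records):
            raise ValueError("population_size smaller than number of records")

    def __len__(self) -> int:
        return len(self.records)

    def features(self, direction: str | None = None) -> frozenset[str]:
        rec = self.records
        if direction is not None:
            rec = rec[rec["direction"] == direction]
        return frozenset(rec["feature_id"])

    def write_tsv(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def _test_features(
    matrix: pd.DataFrame,
    annot: pd.DataFrame,
    params: DEMParams,
    cell_types: tuple[str, ...] | set[str],
) -> pd.DataFrame:
    """Per-feature means, log2 fold change and p-value for every feature."""
    if matrix.empty:
        raise ValueError("empty expression matrix")
    annot = _contrast_samples(annot, cell_types)
    groups = {}
    for cond in CONDITIONS:
        ids = list(annot.loc[annot["condition"] == cond, "sample_id"])
        if len(ids) < 2:
            raise ValueError(
                f"need >= 2 samples in condition {cond}, found {len(ids)}"
            )
        groups[cond] = matrix[ids].to_numpy(dtype=float)
    xc, xt = groups["C"], groups["T"]

    if params.test == "welch":
        res = stats.ttest_ind(xt, xc, axis=1, equal_var=False)
        p = res.pvalue
    elif params.test == "student":
        res = stats.ttest_ind(xt, xc, axis=1, equal_var=True)
        p = res.pvalue
    else:  # wilcoxon rank-sum (Mann-Whitney U)
        res = stats.mannwhitneyu(xt, xc, axis=1, alternative="two-sided")
        p = res.pvalue
    # zero-variance features give NaN t-test p; identical groups are null
    p = np.where(np.isnan(p), 1.0, p)

    mean_c = xc.mean(axis=1)
    mean_t = xt.mean(axis=1)
    lfc = mean_t - mean_c
    out = pd.DataFrame(
        {
            "feature_id": matrix.index.astype(str),
            "mean_C": mean_c,
            "mean_T": mean_t,
            "log2_fc": lfc,
            "p_value": p,
        }
    )
    out["bh_q"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["direction"] = np.where(lfc < 0, "down", "up")
    return out


def call_dems(
    matrix: pd.DataFrame,
    annot: pd.DataFrame,
    params: DEMParams = DEMParams(),
    cell_types: tuple[str, ...] | set[str] = TME_CELL_TYPES,
) -> DEMTable:
    """Call differentially expressed features between control and TME."""
    tested = _test_features(matrix, annot, params, cell_types)
    selected = (np.abs(tested["log2_fc"]) >= params.log2_theta) & (
        tested["p_value"] < params.alpha
    )
    records = (
        tested[selected]
        .sort_values(["p_value", "feature_id"], kind="stable")
        .reset_index(drop=True)
    )
    return DEMTable(records=records, params=params, population_size=len(tested))


def rank_dems(table: DEMTable, direction: str) -> list[tuple[str, float]]:
    """Selected features of one direction, by descending -log10 p.

    Ties are broken lexicographically by feature id; numerically
    underflowed p-values are floored at machine tiny for display.
    """
    if direction not in ("down", "up"):
        raise ValueError("direction must be 'down' or 'up'")
    rec = table.records[table.records["direction"] == direction]
    neglog = -np.log10(np.maximum(rec["p_value"].to_numpy(), np.finfo(float).tiny))
    ordered = sorted(
        zip(rec["feature_id"], neglog), key=lambda fv: (-fv[1], fv[0])
    )
    return [(f, float(v)) for f, v in ordered]


def volcano_points(
    matrix: pd.DataFrame,
    annot: pd.DataFrame,
    params: DEMParams = DEMParams(),
    cell_types: tuple[str, ...] | set[str] = TME_CELL_TYPES,
) -> pd.DataFrame:
    """One (log2_fc, -log10 p, selected) point per tested feature."""
    tested = _test_features(matrix, annot, params, cell_types)
    tested["neg_log10_p"] = -np.log10(
        np.maximum(tested["p_value"].to_numpy(), np.finfo(float).tiny)
    )
    tested["selected"] = (np.abs(tested["log2_fc"]) >= params.log2_theta) & (
        tested["p_value"] < params.alpha
    )
    return tested[
        ["feature_id", "log2_fc", "neg_log10_p", "p_value", "selected", "direction"]
    ]
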