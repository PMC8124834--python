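"""Differential-expression calling under the joint theta/alpha rule."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_annotations, make_matrix
from geromir.dem import DEMParams, call_dems, rank_dems, volcano_points
from geromir.simulate import SimulationConfig, simulate


def test_params_validation():
    with pytest.raises(ValueError):
        DEMParams(theta=0.5)
    with pytest.raises(ValueError):
        DEMParams(alpha=1.5)
    with pytest.raises(ValueError):
        DEMParams(test="anova")
    assert DEMParams().log2_theta == pytest.approx(2.0)


def test_planted_four_fold_feature_is_called(three_vs_three_annot):
    annot = three_vs_three_annot
    c_vals, t_vals = [10.0, 10.1, 9.9], [6.0, 6.1, 5.9]
    order = np.where(annot["condition"] == "C", 0, 1)
    values = [c_vals.pop(0) if o == 0 else t_vals.pop(0) for o in order]
    matrix = make_matrix({"miR-x": values, "miR-null": [8.0] * 6}, annot)
    table = call_dems(matrix, annot)
    assert table.features() == {"miR-x"}
    rec = table.records.iloc[0]
    assert rec["direction"] == "down"
    assert rec["log2_fc"] == pytest.approx(-4.0)
    assert rec["p_value"] < 1e-4


def test_identical_groups_yield_empty_table(three_vs_three_annot):
    matrix = make_matrix({"miR-1": [8.0] * 6, "miR-2": [5.0] * 6},
                         three_vs_three_annot)
    table = call_dems(matrix, three_vs_three_annot)
    assert len(table) == 0
    assert table.population_size == 2


def test_two_fold_change_is_below_default_theta(three_vs_three_annot):
    annot = three_vs_three_annot
    vals = np.where(annot["condition"] == "C", 8.0, 9.0) + \
        np.array([0.001, -0.001, 0.002, -0.002, 0.0005, -0.0005])
    matrix = make_matrix({"miR-1": vals}, annot)
    table = call_dems(matrix, annot)
    assert len(table) == 0  # |log2 fc| = 1 < log2(4) no matter the p
    assert len(call_dems(matrix, annot, DEMParams(theta=1.5))) == 1


def test_boundary_fold_change_selects(three_vs_three_annot):
    annot = three_vs_three_annot
    # group means exactly 8 and 10: |log2 fc| == log2(theta) on the boundary
    vals = np.where(annot["condition"] == "C", 8.0, 10.0) + \
        np.array([-1.0, -1.0, 0.0, 0.0, 1.0, 1.0])
    matrix = make_matrix({"miR-1": vals}, annot)
    table = call_dems(matrix, annot, DEMParams(theta=4, alpha=0.2))
    assert table.features() == {"miR-1"}
    assert table.records.iloc[0]["log2_fc"] == 2.0


def test_condition_swap_flips_direction(three_vs_three_annot):
    rng = np.random.default_rng(5)
    annot = three_vs_three_annot
    effect = np.where(annot["condition"] == "T", -3.0, 0.0)
    matrix = make_matrix(
        {f"miR-{i}": 8 + effect + rng.normal(0, 0.3, 6) for i in range(5)},
        annot,
    )
    swapped = annot.assign(
        condition=annot["condition"].map({"C": "T", "T": "C"})
    )
    t1 = call_dems(matrix, annot).records.set_index("feature_id")
    t2 = call_dems(matrix, swapped).records.set_index("feature_id")
    assert set(t1.index) == set(t2.index)
    for f in t1.index:
        assert t1.loc[f, "log2_fc"] == pytest.approx(-t2.loc[f, "log2_fc"])
        assert t1.loc[f, "p_value"] == pytest.approx(t2.loc[f, "p_value"])
        assert {t1.loc[f, "direction"], t2.loc[f, "direction"]} == {"down", "up"}


def test_selection_monotone_in_theta_and_alpha(three_vs_three_annot):
    rng = np.random.default_rng(6)
    annot = three_vs_three_annot
    effect = np.where(annot["condition"] == "T", 1.0, 0.0)
    matrix = make_matrix(
        {f"miR-{i}": 8 + rng.normal(0, 1) * effect * 3 + rng.normal(0, 0.4, 6)
         for i in range(40)},
        annot,
    )
    base = call_dems(matrix, annot, DEMParams(theta=4, alpha=0.001)).features()
    looser_theta = call_dems(matrix, annot,
                             DEMParams(theta=2, alpha=0.001)).features()
    looser_alpha = call_dems(matrix, annot,
                             DEMParams(theta=4, alpha=0.05)).features()
    assert base <= looser_theta
    assert base <= looser_alpha


def test_alternative_tests_run(three_vs_three_annot):
    annot = three_vs_three_annot
    vals = np.where(annot["condition"] == "C", 10.0, 5.0) + \
        np.array([0.1, -0.1, 0.05, -0.05, 0.15, -0.2])
    matrix = make_matrix({"miR-1": vals}, annot)
    for test in ("student", "wilcoxon"):
        table = call_dems(matrix, annot, DEMParams(test=test, alpha=0.2))
        assert table.features() == {"miR-1"}


def test_requires_two_samples_per_condition():
    annot = make_annotations({("E", "C"): 2, ("E", "T"): 1})
    matrix = make_matrix({"miR-1": [1.0, 2.0, 3.0]}, annot)
    with pytest.raises(ValueError, match="condition T"):
        call_dems(matrix, annot)
    with pytest.raises(ValueError, match="empty"):
        call_dems(matrix.iloc[:0], annot)


def test_rank_dems_ordering_and_ties(three_vs_three_annot):
    table = call_dems(
        make_matrix({"miR-1": [8.0] * 6}, three_vs_three_annot),
        three_vs_three_annot,
    )
    table.records = pd.DataFrame(
        {
            "feature_id": ["b", "a", "c"],
            "mean_C": [8, 8, 8],
            "mean_T": [4, 4, 4],
            "log2_fc": [-4, -4, -4],
            "p_value": [1e-3, 1e-5, 1e-5],
            "bh_q": [1e-3, 1e-5, 1e-5],
            "direction": ["down", "down", "down"],
        }
    )
    ranked = rank_dems(table, "down")
    assert [f for f, _ in ranked] == ["a", "c", "b"]
    assert rank_dems(table, "up") == []
    with pytest.raises(ValueError):
        rank_dems(table, "sideways")


def test_planted_features_occupy_top_ranks():
    config = SimulationConfig(n_mirnas=100, n_genes=10, n_planted_down=5,
                              n_planted_down_geromirs=3, n_planted_up=2,
                              effect_log2=4.0, noise_sd=0.3, seed=11)
    ds = simulate(config)
    table = call_dems(ds.mirna_matrix, ds.annotations,
                      DEMParams(theta=2, alpha=0.01))
    ranked = [f for f, _ in rank_dems(table, "down")]
    assert set(ranked[: len(ds.truth.planted_down)]) == ds.truth.planted_down


def test_recovery_with_balanced_replicates():
    """Planted effects of 3 log2 units are recovered from 9 vs 9 samples."""
    from geromir.simulate import evaluate_recovery, reference_config

    replicates = {(ct, cond): 3 for ct in "EIK" for cond in "CT"}
    recalls, precisions = [], []
    for seed in range(20):
        ds = simulate(reference_config(seed=seed, replicates=replicates,
                                       n_genes=10))
        rec = evaluate_recovery(ds, call_dems(ds.mirna_matrix, ds.annotations))
        recalls += [rec["recall_down"], rec["recall_up"]]
        precisions += [rec["precision_down"], rec["precision_up"]]
    assert np.median(recalls) >= 0.9
    assert np.median(precisions) >= 0.9


def test_volcano_points_cover_population(three_vs_three_annot):
    annot = three_vs_three_annot
    rng = np.random.default_rng(7)
    down = np.where(annot["condition"] == "T", -5.0, 0.0)
    matrix = make_matrix(
        {
            "miR-hit": 10 + down + rng.normal(0, 0.2, 6),
            "miR-null1": 8 + rng.normal(0, 0.2, 6),
            "miR-null2": 6 + rng.normal(0, 0.2, 6),
        },
        annot,
    )
    pts = volcano_points(matrix, annot)
    table = call_dems(matrix, annot)
    assert len(pts) == table.population_size == 3
    assert set(pts.loc[pts["selected"], "feature_id"]) == table.features()
    null_pts = volcano_points(
        make_matrix({"miR-1": [8.0] * 6, "miR-2": [7.0] * 6}, annot), annot
    )
    assert not null_pts["selected"].any()
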