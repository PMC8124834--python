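"""Matrix ingestion, quantile normalization, group means, panel slicing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra.numpy import arrays

from conftest import make_annotations, make_matrix
from geromir.expression import (
    AnnotationError,
    extract_gene_panel,
    group_means,
    quantile_normalize,
    read_geo_series_matrix,
    read_matrix,
    write_annotations,
    write_matrix,
)


def _write_fixture(tmp_path, matrix, annot):
    mpath, apath = tmp_path / "m.tsv", tmp_path / "a.tsv"
    write_matrix(matrix, mpath, digits=10)
    write_annotations(annot, apath)
    return mpath, apath


def test_read_matrix_dimensions(tmp_path, six_sample_annot):
    rng = np.random.default_rng(0)
    matrix = make_matrix(
        {f"miR-{i}": rng.normal(8, 1, 6) for i in range(4)}, six_sample_annot
    )
    mpath, apath = _write_fixture(tmp_path, matrix, six_sample_annot)
    m, a = read_matrix(mpath, apath)
    assert m.shape == (4, 6)
    assert list(a["sample_id"]) == list(m.columns)


def test_read_matrix_unannotated_column_errors(tmp_path, six_sample_annot):
    matrix = make_matrix({"miR-1": np.arange(6.0)}, six_sample_annot)
    mpath, apath = _write_fixture(
        tmp_path, matrix, six_sample_annot.iloc[:-1]
    )
    with pytest.raises(AnnotationError, match="lacking annotation"):
        read_matrix(mpath, apath)


def test_read_matrix_roundtrip(tmp_path, six_sample_annot):
    rng = np.random.default_rng(1)
    matrix = make_matrix(
        {f"miR-{i}": rng.normal(8, 2, 6) for i in range(5)}, six_sample_annot
    )
    mpath, apath = _write_fixture(tmp_path, matrix, six_sample_annot)
    m, _ = read_matrix(mpath, apath)
    np.testing.assert_allclose(m.to_numpy(), matrix.to_numpy(), rtol=1e-9)


def test_read_matrix_non_numeric_cell_errors(tmp_path, six_sample_annot):
    matrix = make_matrix({"miR-1": np.arange(6.0)}, six_sample_annot).astype(object)
    matrix.iloc[0, 0] = "oops"
    mpath, apath = _write_fixture(tmp_path, matrix, six_sample_annot)
    with pytest.raises((ValueError, TypeError)):
        read_matrix(mpath, apath)


def test_probe_collapse_and_missing_drop(tmp_path, six_sample_annot):
    mpath, apath = tmp_path / "m.tsv", tmp_path / "a.tsv"
    rows = ["feature\t" + "\t".join(six_sample_annot["sample_id"])]
    rows.append("miR-1\t" + "\t".join("1" for _ in range(6)))
    rows.append("miR-1\t" + "\t".join("3" for _ in range(6)))  # second probe
    rows.append("miR-2\t1\t2\t3\t4\t5\t")  # missing value
    mpath.write_text("\n".join(rows) + "\n")
    write_annotations(six_sample_annot, apath)
    with pytest.warns(UserWarning, match="missing"):
        m, _ = read_matrix(mpath, apath)
    assert list(m.index) == ["miR-1"]
    assert (m.loc["miR-1"] == 2.0).all()  # median of the two probes


def test_quantile_normalize_rank_mean_example():
    m = pd.DataFrame({"s1": [1.0, 2.0, 3.0], "s2": [4.0, 6.0, 8.0]})
    q = quantile_normalize(m)
    np.testing.assert_allclose(q["s1"], [2.5, 4.0, 5.5])
    np.testing.assert_allclose(q["s2"], [2.5, 4.0, 5.5])


def test_quantile_normalize_identity_and_idempotence():
    m = pd.DataFrame({"a": [5.0, 1.0, 3.0], "b": [5.0, 1.0, 3.0]})
    np.testing.assert_allclose(quantile_normalize(m).to_numpy(), m.to_numpy())
    rng = np.random.default_rng(2)
    m2 = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
    once = quantile_normalize(m2)
    np.testing.assert_allclose(
        quantile_normalize(once).to_numpy(), once.to_numpy(), atol=1e-12
    )


def test_quantile_normalize_tie_handling():
    # tied values share the mean of the reference at their tied ranks
    m = pd.DataFrame({"a": [1.0, 1.0, 10.0], "b": [2.0, 4.0, 6.0]})
    q = quantile_normalize(m)
    ref = np.sort(m.to_numpy(), axis=0).mean(axis=1)  # [1.5, 2.5, 8.0]
    assert q["a"].iloc[0] == q["a"].iloc[1] == pytest.approx(ref[:2].mean())
    assert q["a"].iloc[2] == pytest.approx(ref[2])


@given(
    arrays(
        float,
        (12, 4),
        elements=st.floats(-8, 8, allow_nan=False, width=32),
        unique=True,  # tie-free input; ties are averaged by design
    )
)
def test_quantile_normalize_equalizes_column_multisets(values):
    q = quantile_normalize(pd.DataFrame(values, columns=list("wxyz")))
    sorted_cols = np.sort(q.to_numpy(), axis=0)
    for j in range(1, 4):
        np.testing.assert_allclose(sorted_cols[:, j], sorted_cols[:, 0],
                                   atol=1e-9)


def test_quantile_normalize_single_sample_errors():
    with pytest.raises(ValueError):
        quantile_normalize(pd.DataFrame({"only": [1.0, 2.0]}))


def test_group_means_arithmetic():
    # sample order after sorting: EC1, ET1, IC1 -> C values {2, 4}, T value {6}
    annot = make_annotations({("E", "C"): 1, ("I", "C"): 1, ("E", "T"): 1})
    matrix = make_matrix({"miR-1": [2.0, 6.0, 4.0]}, annot)
    gm = group_means(matrix, annot, cell_types=("E", "I"))
    assert gm.loc["miR-1", "mean_C"] == pytest.approx(3.0)
    assert gm.loc["miR-1", "mean_T"] == pytest.approx(6.0)


def test_group_means_cell_type_subset_and_permutation(three_vs_three_annot):
    rng = np.random.default_rng(3)
    annot = three_vs_three_annot
    matrix = make_matrix({"miR-1": rng.normal(8, 1, 6),
                          "miR-2": rng.normal(8, 1, 6)}, annot)
    only_e = group_means(matrix, annot, cell_types=("E",))
    e_ids = annot.loc[annot["cell_type"] == "E", "sample_id"]
    expected = matrix[list(e_ids)].mean(axis=1)
    c_id = annot.loc[(annot.cell_type == "E") & (annot.condition == "C"),
                     "sample_id"].iloc[0]
    assert only_e.loc["miR-1", "mean_C"] == pytest.approx(matrix.loc["miR-1", c_id])
    shuffled = matrix[list(rng.permutation(matrix.columns))]
    pd.testing.assert_frame_equal(
        group_means(matrix, annot), group_means(shuffled, annot)
    )
    assert expected is not None  # silence linters; expectation used above


def test_group_means_requires_both_conditions():
    annot = make_annotations({("E", "C"): 2})
    matrix = make_matrix({"miR-1": [1.0, 2.0]}, annot)
    with pytest.raises(ValueError, match="condition T"):
        group_means(matrix, annot)


def test_group_means_excludes_tumor_cell_columns():
    with pytest.raises(ValueError, match="not part of the control-vs-TME"):
        group_means(pd.DataFrame(), pd.DataFrame(), cell_types=("TP",))


def test_extract_gene_panel_order_and_missing(six_sample_annot):
    matrix = make_matrix(
        {"Hdac7": np.ones(6), "Sirt3": np.zeros(6), "Dnmt1": np.ones(6)},
        six_sample_annot,
    )
    panel, missing = extract_gene_panel(matrix, ["Sirt3", "Hdac7"])
    assert list(panel.index) == ["Sirt3", "Hdac7"]
    assert missing == []
    with pytest.warns(UserWarning, match="absent"):
        panel, missing = extract_gene_panel(matrix, ["Nope1"])
    assert panel.empty and missing == ["Nope1"]
    panel, _ = extract_gene_panel(matrix, ["HDAC7"])  # case-insensitive
    assert list(panel.index) == ["Hdac7"]


GEO_FIXTURE = """!Series_title\t"synthetic mini series"
!Sample_title\t"EC1"\t"ET1"
!Sample_geo_accession\t"GSM1"\t"GSM2"
!series_matrix_table_begin
"ID_REF"\t"GSM1"\t"GSM2"
"miR-1"\t7.5\t3.5
"miR-2"\t8.0\t8.1
!series_matrix_table_end
"""


def test_read_geo_series_matrix(tmp_path):
    path = tmp_path / "series.txt"
    path.write_text(GEO_FIXTURE)
    matrix, annot = read_geo_series_matrix(path)
    assert matrix.shape == (2, 2)
    assert list(annot["cell_type"]) == ["E", "E"]
    assert list(annot["condition"]) == ["C", "T"]
    assert matrix.loc["miR-1", "GSM1"] == pytest.approx(7.5)


def test_read_geo_series_matrix_bad_title(tmp_path):
    path = tmp_path / "series.txt"
    path.write_text(GEO_FIXTURE.replace('"ET1"', '"weird title"'))
    with pytest.raises(AnnotationError, match="weird title"):
        read_geo_series_matrix(path)


def test_read_geo_series_matrix_missing_markers(tmp_path):
    path = tmp_path / "series.txt"
    path.write_text(GEO_FIXTURE.replace("!series_matrix_table_end\n", ""))
    with pytest.raises(ValueError, match="markers"):
        read_geo_series_matrix(path)


def test_geo_roundtrip_preserves_distributions(tmp_path, six_sample_annot):
    """Quantile-normalized values survive a write/re-read cycle."""
    rng = np.random.default_rng(4)
    matrix = quantile_normalize(
        make_matrix({f"miR-{i}": rng.normal(8, 2, 6) for i in range(20)},
                    six_sample_annot)
    )
    lines = ["!Sample_title\t" + "\t".join(
        f'"{s}"' for s in six_sample_annot["sample_id"])]
    lines.append("!series_matrix_table_begin")
    lines.append("ID_REF\t" + "\t".join(matrix.columns))
    for feat, row in matrix.iterrows():
        lines.append(feat + "\t" + "\t".join(f"{v:.10g}" for v in row))
    lines.append("!series_matrix_table_end")
    path = tmp_path / "series.txt"
    path.write_text("\n".join(lines) + "\n")
    reread, _ = read_geo_series_matrix(path)
    for col in matrix.columns:
        np.testing.assert_allclose(
            np.sort(reread[col]), np.sort(matrix[col]), rtol=1e-9
        )
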