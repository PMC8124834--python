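"""Expression-matrix ingestion, annotation, normalization and slicing.

Matrices are plain :class:`pandas.DataFrame` objects with features
(miRNA canonical names or gene symbols) as the row index and sample ids
as columns; intensities are on the log2 scale.  Sample annotations are a
DataFrame with columns ``sample_id``, ``cell_type`` (E, I, K for the
three liver cell types, TP/TM for the tumor comparison columns),
``condition`` (C control, T tumor microenvironment) and ``replicate``.
"""

from __future__ import annotations

import io
import re
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CELL_TYPES",
    "TME_CELL_TYPES",
    "CONDITIONS",
    "AnnotationError",
    "read_matrix",
    "read_annotations",
    "write_matrix",
    "read_geo_series_matrix",
    "quantile_normalize",
    "group_means",
    "extract_gene_panel",
    "collapse_probes",
]

CELL_TYPES = ("E", "I", "K", "TP", "TM")
#: the liver cell types entering the control-vs-TME contrast
TME_CELL_TYPES = ("E", "I", "K")
CONDITIONS = ("C", "T")

ANNOTATION_COLUMNS = ["sample_id", "cell_type", "condition", "replicate"]


class AnnotationError(ValueError):
    """Sample annotation is missing, inconsistent or unparsable."""


def _validate_annotations(annot: pd.DataFrame) -> pd.DataFrame:
    missing = set(ANNOTATION_COLUMNS) - set(annot.columns)
    if missing:
        raise AnnotationError(f"annotation missing columns: {sorted(missing)}")
    annot = annot[ANNOTATION_COLUMNS].copy()
    annot["replicate"] = annot["replicate"].astype(int)
    bad_ct = set(annot["cell_type"]) - set(CELL_TYPES)
    if bad_ct:
        raise AnnotationError(f"unknown cell types: {sorted(bad_ct)}")
    bad_cond = set(annot["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise AnnotationError(f"unknown conditions: {sorted(bad_cond)}")
    if (annot["replicate"] < 1).any():
        raise AnnotationError("replicate indices must be positive")
    keys = annot[["cell_type", "condition", "replicate"]]
    if keys.duplicated().any():
        dup = keys[keys.duplicated()].to_records(index=False).tolist()
        raise AnnotationError(f"duplicate (cell_type, condition, replicate): {dup}")
    if annot["sample_id"].duplicated().any():
        raise AnnotationError("duplicate sample ids in annotation")
    return annot


def read_annotations(path: str | Path) -> pd.DataFrame:
    return _validate_annotations(pd.read_csv(path, sep="\t", dtype=str))


def collapse_probes(matrix: pd.DataFrame) -> pd.DataFrame:
    """Collapse multiple probes per feature to the median probe value."""
    if matrix.index.duplicated().any():
        matrix = matrix.groupby(level=0, sort=False).median()
    return matrix


def _finalize_matrix(matrix: pd.DataFrame, *, linear_scale: bool) -> pd.DataFrame:
    matrix = matrix.apply(pd.to_numeric)
    matrix = collapse_probes(matrix)
    # the downstream thresholding has no missing-data contract: drop and log
    incomplete = matrix.index[matrix.isna().any(axis=1)]
    if len(incomplete):
        warnings.warn(
            f"dropping {len(incomplete)} features with missing values",
            stacklevel=3,
        )
        matrix = matrix.drop(index=incomplete)
    if not np.isfinite(matrix.to_numpy()).all():
        raise ValueError("non-finite intensities after ingestion")
    if linear_scale:
        if (matrix.to_numpy() <= 0).any():
            raise ValueError("linear-scale intensities must be positive")
        matrix = np.log2(matrix)
    return matrix


def read_matrix(
    path: str | Path,
    annotation_path: str | Path,
    *,
    linear_scale: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a features x samples TSV and its sample-annotation TSV.

    Every matrix column must be annotated.  Input is assumed log2 unless
    ``linear_scale`` is set, in which case it is log2-transformed.
    """
    try:
        matrix = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed matrix file {path}: {exc}") from exc
    annot = read_annotations(annotation_path)
    unannotated = [c for c in matrix.columns if c not in set(annot["sample_id"])]
    if unannotated:
        raise AnnotationError(f"matrix columns lacking annotation: {unannotated}")
    annot = annot[annot["sample_id"].isin(matrix.columns)].reset_index(drop=True)
    return _finalize_matrix(matrix, linear_scale=linear_scale), annot


def write_matrix(matrix: pd.DataFrame, path: str | Path, *, digits: int = 6) -> None:
    """Write a matrix as TSV at a stated decimal precision (round-trip safe)."""
    matrix.to_csv(path, sep="\t", float_format=f"%.{digits}g")


def write_annotations(annot: pd.DataFrame, path: str | Path) -> None:
    annot[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


#: default pattern for GEO sample titles like "EC1", "IT3", "TM2", "E C 1"
DEFAULT_TITLE_PATTERN = (
    r"^\s*(?P<cell_type>TP|TM|E|I|K)\s*(?P<condition>C|T)?\s*(?P<replicate>\d+)\s*$"
)


def read_geo_series_matrix(
    path: str | Path,
    *,
    title_pattern: str = DEFAULT_TITLE_PATTERN,
    linear_scale: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parse a GEO series-matrix file into a matrix plus annotations.

    The file format is a sequence of ``!``-prefixed metadata lines with
    the expression table between ``!series_matrix_table_begin`` and
    ``!series_matrix_table_end``.  Sample titles are parsed into
    (cell_type, condition, replicate) with ``title_pattern``; TP/TM
    samples may omit the condition letter and default to T.
    """
    meta: dict[str, list[str]] = {}
    table_lines: list[str] = []
    in_table = False
    saw_begin = saw_end = False
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table, saw_begin = True, True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table, saw_end = False, True
                continue
            if in_table:
                table_lines.append(line)
            elif line.startswith("!"):
                key, _, rest = line.partition("\t")
                values = [v.strip().strip('"') for v in rest.split("\t")]
                meta.setdefault(key.lstrip("!"), []).extend(values)
    if not (saw_begin and saw_end):
        raise ValueError(f"{path}: missing series-matrix table markers")

    matrix = pd.read_csv(io.StringIO("\n".join(table_lines)), sep="\t", index_col=0)
    matrix.columns = [str(c).strip().strip('"') for c in matrix.columns]
    matrix.index = [str(i).strip().strip('"') for i in matrix.index]

    titles = meta.get("Sample_title", [])
    if len(titles) != matrix.shape[1]:
        raise AnnotationError(
            f"{len(titles)} sample titles for {matrix.shape[1]} table columns"
        )
    pat = re.compile(title_pattern)
    rows, offenders = [], []
    for sample_id, title in zip(matrix.columns, titles):
        m = pat.match(title)
        if m is None:
            offenders.append(title)
            continue
        condition = m.group("condition")
        if condition is None:
            condition = "T"  # tumor comparison columns carry T by convention
        rows.append((sample_id, m.group("cell_type"), condition,
                     int(m.group("replicate"))))
    if offenders:
        raise AnnotationError(f"unparsable sample titles: {offenders}")
    annot = _validate_annotations(pd.DataFrame(rows, columns=ANNOTATION_COLUMNS))
    return _finalize_matrix(matrix, linear_scale=linear_scale), annot


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample onto the common distribution of rank means.

    Each column's sorted values are replaced by the across-column mean
    of sorted values; ties within a column receive the mean of the
    reference values at their tied ranks.  Idempotent; feature and
    sample order are unchanged.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    values = matrix.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(col)
        assigned[order] = reference
        # average the reference over tied ranks
        assigned = pd.Series(assigned).groupby(col).transform("mean").to_numpy()
        out[:, j] = assigned
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def _contrast_samples(
    annot: pd.DataFrame, cell_types: tuple[str, ...] | set[str]
) -> pd.DataFrame:
    chosen = set(cell_types)
    unknown = chosen - set(TME_CELL_TYPES)
    if unknown:
        raise ValueError(
            f"cell types {sorted(unknown)} are not part of the control-vs-TME contrast"
        )
    return annot[annot["cell_type"].isin(chosen)]


def group_means(
    matrix: pd.DataFrame,
    annot: pd.DataFrame,
    cell_types: tuple[str, ...] | set[str] = TME_CELL_TYPES,
    *,
    within_cell_type_first: bool = False,
) -> pd.DataFrame:
    """Per-feature control and TME means over the selected liver cell types.

    TP/TM samples are never included.  By default all samples of a
    condition are pooled directly; ``within_cell_type_first`` instead
    averages replicates within each cell type before averaging across
    cell types.
    """
    annot = _contrast_samples(annot, cell_types)
    result = {}
    for cond in CONDITIONS:
        ids = annot.loc[annot["condition"] == cond, "sample_id"]
        if ids.empty:
            raise ValueError(f"no samples for condition {cond}")
        sub = matrix[list(ids)]
        if within_cell_type_first:
            ct = annot.set_index("sample_id").loc[list(ids), "cell_type"]
            means = sub.T.groupby(ct.to_numpy()).mean().mean(axis=0)
        else:
            means = sub.mean(axis=1)
        result[f"mean_{cond}"] = means
        result[f"n_{cond}"] = len(ids)
    return pd.DataFrame(result, index=matrix.index)


def extract_gene_panel(
    matrix: pd.DataFrame, genes: list[str]
) -> tuple[pd.DataFrame, list[str]]:
    """Slice a gene panel, preserving request order.

    Matching is case-insensitive with the matrix capitalization
    preserved.  Returns the submatrix and the list of absent genes
    (reported, not fatal).
    """
    by_lower: dict[str, str] = {}
    for name in matrix.index:
        by_lower.setdefault(str(name).lower(), str(name))
    found, missing = [], []
    for gene in genes:
        hit = by_lower.get(gene.lower())
        (found if hit is not None else missing).append(hit or gene)
    if missing:
        warnings.warn(f"genes absent from matrix: {missing}", stacklevel=2)
    return matrix.loc[found], missing
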