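import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

from geromir.catalog import platform_catalog, reference_catalog
from geromir.expression import ANNOTATION_COLUMNS
from geromir.simulate import reference_config, simulate


@pytest.fixture(scope="session")
def ref_catalog():
    return reference_catalog()


@pytest.fixture(scope="session")
def plat_catalog():
    return platform_catalog()


@pytest.fixture(scope="session")
def reference_dataset():
    """One reference-scenario simulation shared across read-only tests."""
    return simulate(reference_config(seed=7))


def make_annotations(replicates):
    """Annotation frame from a {(cell_type, condition): count} mapping."""
    rows = [
        (f"{ct}{cond}{r}", ct, cond, r)
        for (ct, cond) in sorted(replicates)
        for r in range(1, replicates[(ct, cond)] + 1)
    ]
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def make_matrix(values_by_feature, annot):
    """Matrix from {feature: list of per-sample values} in annotation order."""
    return pd.DataFrame(
        {f: pd.Series(v, index=annot["sample_id"])
         for f, v in values_by_feature.items()}
    ).T


@pytest.fixture
def six_sample_annot():
    """One C and one T sample for each of E, I, K."""
    return make_annotations({(ct, cond): 1 for ct in "EIK" for cond in "CT"})


@pytest.fixture
def three_vs_three_annot():
    """Three C and three T samples spread over the liver cell types."""
    return make_annotations(
        {("E", "C"): 1, ("I", "C"): 1, ("K", "C"): 1,
         ("E", "T"): 1, ("I", "T"): 1, ("K", "T"): 1}
    )
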