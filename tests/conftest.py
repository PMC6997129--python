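"""Shared fixtures: small synthetic bundles reused across test modules."""

import numpy as np
import pandas as pd
import pytest

import kernelsig as ks


@pytest.fixture(scope="session")
def small_matrix() -> ks.ExpressionMatrix:
    """Tiny hand-checkable expression matrix: 4 genes, 3 tumor + 2 normal."""
    values = pd.DataFrame(
        {
            "TCGA-AA-0001-01A": [8.0, 2.0, 5.0, 1.0],
            "TCGA-AA-0002-01A": [8.0, 3.0, 5.0, 2.0],
            "TCGA-AA-0003-01A": [8.0, 4.0, 5.0, 3.0],
            "TCGA-AA-0004-11A": [2.0, 3.0, 5.0, 7.0],
            "TCGA-AA-0005-11A": [2.0, 3.0, 5.0, 9.0],
        },
        index=["gUP", "gFLAT", "gCONST", "gDOWN"],
    )
    groups = pd.Series(
        ["tumor", "tumor", "tumor", "normal", "normal"], index=values.columns
    )
    return ks.ExpressionMatrix(values=values, groups=groups)


@pytest.fixture(scope="session")
def study_dataset() -> "ks.synthetic.SyntheticDataset":
    """One full synthetic study at the default conditions (seed 11)."""
    return ks.generate_dataset(ks.SimulationConfig(seed=11))


def es_bruteforce(positions, n):
    """Term-by-term evaluation of the two running maxima and the score.

    Independent oracle for the KS enrichment score: pure-Python loop over
    p = 1..m, no shared code with the implementation.
    """
    m = len(positions)
    a = max(p / m - positions[p - 1] / n for p in range(1, m + 1))
    b = max(positions[p - 1] / n - (p - 1) / m for p in range(1, m + 1))
    if a > b:
        return a, b, a
    if b > a:
        return a, b, -b
    return a, b, 0.0
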