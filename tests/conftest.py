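"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from neofit.synthetic_data import CohortConfig, generate_cohort, worked_example

AA = "ACDEFGHIKLMNPQRSTVWY"


def sw_oracle(
    query: str,
    target: str,
    matrix_name: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
) -> int:
    """Brute-force Gotoh local-alignment DP, independent of the package.

    A gap of length g costs gap_open + g * gap_extend.  Returns the
    optimal local alignment score (floored at 0).
    """
    mat = substitution_matrices.load(matrix_name)
    m, n = len(query), len(target)
    neg = float("-inf")
    H = [[0.0] * (n + 1) for _ in range(m + 1)]  # best ending at (i, j)
    E = [[neg] * (n + 1) for _ in range(m + 1)]  # gap in target (query consumed)
    F = [[neg] * (n + 1) for _ in range(m + 1)]  # gap in query
    best = 0.0
    open_cost = gap_open + gap_extend  # first gapped column
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i - 1][j] - open_cost, E[i - 1][j] - gap_extend)
            F[i][j] = max(H[i][j - 1] - open_cost, F[i][j - 1] - gap_extend)
            s = mat[query[i - 1], target[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return int(round(best))


def random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA), size=length))


@pytest.fixture(scope="session")
def worked():
    return worked_example()


@pytest.fixture(scope="session")
def small_cohort():
    """A compact default-regime cohort shared across tests."""
    return generate_cohort(CohortConfig(n_patients=120, seed=7))
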