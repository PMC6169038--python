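"""Shared fixtures: small synthetic databases and an independent DP oracle."""

from __future__ import annotations

import numpy as np
import pytest

from pelagiq.align import DEFAULT_SCHEME
from pelagiq.synthetic import evolve_reference_db


def sw_oracle(query: str, subject: str, scheme=DEFAULT_SCHEME) -> int:
    """Exhaustive affine-gap Smith-Waterman score, independent of the engine.

    Full O(m*n) Gotoh recurrence with explicit matrices; a gap of length k
    costs gap_open + k * gap_extend; N matches nothing. For small inputs only.
    """
    m, n = len(query), len(subject)
    NEG = -10 ** 9
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    goe = scheme.gap_open + scheme.gap_extend
    best = 0
    for i in range(1, m + 1):
        qi = query[i - 1]
        for j in range(1, n + 1):
            E[i][j] = max(E[i][j - 1] - scheme.gap_extend, H[i][j - 1] - goe)
            F[i][j] = max(F[i - 1][j] - scheme.gap_extend, H[i - 1][j] - goe)
            match = (scheme.match if qi == subject[j - 1] and qi != "N"
                     else -scheme.mismatch)
            H[i][j] = max(0, H[i - 1][j - 1] + match, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


@pytest.fixture(scope="session")
def small_db():
    """3 classes x 3 sequences at 16% between-class divergence, 800 nt."""
    return evolve_reference_db(root_length=800, n_classes=3,
                               per_class_divergence=0.16, seqs_per_class=3,
                               seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250921)
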