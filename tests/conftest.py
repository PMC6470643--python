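"""Shared fixtures and independent oracles used across the test suite."""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
import pytest

from eegfuse.synth import SynthCohortSpec, generate_cohort


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive; never share code with the package)
# ---------------------------------------------------------------------------

def pe_bruteforce(x, m: int, tau: int = 1) -> float:
    """Brute-force permutation entropy: enumerate windows, rank, count."""
    x = list(x)
    counts: Counter = Counter()
    for i in range(len(x) - (m - 1) * tau):
        w = [x[i + j * tau] for j in range(m)]
        # ties broken by position, matching a stable sort
        pattern = tuple(sorted(range(m), key=lambda j: (w[j], j)))
        counts[pattern] += 1
    total = sum(counts.values())
    return -sum((c / total) * math.log(c / total) for c in counts.values())


def auc_pairwise(scores, labels) -> float:
    """O(n^2) AUC: fraction of (positive, negative) pairs ranked correctly."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def cca_correlations_eig(A, B) -> np.ndarray:
    """Naive CCA through the generalized-eigenvalue formulation."""
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    Sxx, Syy, Sxy = A.T @ A, B.T @ B, A.T @ B
    M = np.linalg.solve(Sxx, Sxy) @ np.linalg.solve(Syy, Sxy.T)
    ev = np.linalg.eigvals(M).real
    return np.sort(np.sqrt(np.clip(ev, 0.0, 1.0)))[::-1]


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small, fast cohort at the working rate with the default class contrast."""
    spec = SynthCohortSpec(
        n_subjects_per_class=4,
        n_channels=2,
        fs=250.0,
        epoch_seconds=8.0,
        epochs_per_subject=2,
        seed=99,
    )
    return spec, generate_cohort(spec)
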