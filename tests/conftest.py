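"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import datetime

import numpy as np
import pytest
from hypothesis import settings

from oawear import CohortSpec, EpochSeries, generate_cohort, process_cohort

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=150)
settings.load_profile("suite")

DATE = datetime.date(2008, 1, 7)


# --- brute-force non-wear oracles --------------------------------------------
#
# Both oracles enumerate candidate windows [a, b) directly from the rule
# definition (every epoch zero except at most `allowance` strictly interior
# epochs with 0 < count < threshold; first and last epoch zero; length >=
# min_window) and then apply greedy leftmost-start / longest-window selection.
# They share no code with the run-merging scan in oawear.wear.


def _greedy_select(windows: list[tuple[int, int]]) -> list[tuple[int, int]]:
    chosen, cursor = [], 0
    for a, b in sorted(windows):
        if a >= cursor:
            chosen.append((a, b))
            cursor = b
    return chosen


def brute_force_nonwear(counts, min_window=90, allowance=2, threshold=100):
    """Pure-Python O(n^2) enumeration oracle (for small sequences)."""
    counts = list(counts)
    n = len(counts)
    nz = np.concatenate([[0], np.cumsum([c > 0 for c in counts])])
    big = np.concatenate([[0], np.cumsum([c >= threshold for c in counts])])
    windows = []
    for a in range(n):
        if counts[a] != 0:
            continue
        best = None
        for b in range(a + min_window, n + 1):
            if (
                counts[b - 1] == 0
                and big[b] - big[a] == 0
                and nz[b] - nz[a] <= allowance
            ):
                best = b
        if best is not None:
            windows.append((a, best))
    return _greedy_select(windows)


def enumerate_nonwear_windows(counts, min_window=90, allowance=2, threshold=100):
    """All per-start maximal qualifying windows (numpy-vectorised over ends)."""
    counts = np.asarray(counts)
    n = len(counts)
    nz = np.concatenate([[0], np.cumsum(counts > 0)])
    big = np.concatenate([[0], np.cumsum(counts >= threshold)])
    ends_zero = counts == 0
    windows = []
    for a in np.flatnonzero(counts == 0):
        bs = np.arange(a + min_window, n + 1)
        if bs.size == 0:
            continue
        ok = ends_zero[bs - 1] & (big[bs] == big[a]) & (nz[bs] - nz[a] <= allowance)
        hits = bs[ok]
        if hits.size:
            windows.append((int(a), int(hits.max())))
    return windows


def vectorized_oracle_nonwear(counts, min_window=90, allowance=2, threshold=100):
    """Greedy selection over the enumerated windows (for long sequences)."""
    return _greedy_select(
        enumerate_nonwear_windows(counts, min_window, allowance, threshold)
    )


@pytest.fixture(scope="session")
def nonwear_oracle():
    return brute_force_nonwear


@pytest.fixture(scope="session")
def nonwear_oracle_fast():
    return vectorized_oracle_nonwear


# --- series builders ----------------------------------------------------------


def make_series(
    day_counts: list[np.ndarray],
    day_steps: list[np.ndarray] | None = None,
    participant_id: str = "P0000",
    visit: str = "baseline",
) -> EpochSeries:
    counts = np.vstack([np.asarray(d, dtype=np.int64) for d in day_counts])
    if day_steps is None:
        steps = np.zeros_like(counts)
    else:
        steps = np.vstack([np.asarray(d, dtype=np.int64) for d in day_steps])
    return EpochSeries(participant_id, visit, DATE, counts, steps)


@pytest.fixture(scope="session")
def series_builder():
    return make_series


# --- shared synthetic cohorts -------------------------------------------------


@pytest.fixture(scope="session")
def small_cohort():
    """25 participants, both visits; cheap enough for unit-level checks."""
    spec = CohortSpec(n_participants=25, seed=7)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def cohort200():
    """Seed-fixed 200-participant cohort used by the conservation suite."""
    spec = CohortSpec(n_participants=200, seed=2024)
    series, clinical, truth = generate_cohort(spec)
    return series, clinical, truth


@pytest.fixture(scope="session")
def cohort200_result(cohort200):
    series, clinical, truth = cohort200
    return process_cohort(series, clinical)
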