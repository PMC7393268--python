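"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately use naive explicit loops so they stay
independent of the vectorized implementation paths they are used to check.
"""

from collections import Counter

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


# ---------------------------------------------------------------------------
# brute-force CRQA oracle: explicit run enumeration


def oracle_line_counts(mask, orientation):
    """Count maximal runs of True along one orientation by explicit scan."""
    n_rows, n_cols = len(mask), len(mask[0])
    counts = Counter()
    if orientation == "vertical":
        for j in range(n_cols):
            run = 0
            for i in range(n_rows):
                if mask[i][j]:
                    run += 1
                elif run:
                    counts[run] += 1
                    run = 0
            if run:
                counts[run] += 1
    else:
        for i in range(n_rows):
            run = 0
            for j in range(n_cols):
                if mask[i][j]:
                    run += 1
                elif run:
                    counts[run] += 1
                    run = 0
            if run:
                counts[run] += 1
    return counts


def oracle_anisotropic(rec, orientation, l_min=2):
    """LAM/TT/Max_L/Ent_L from explicit run enumeration of the binarized matrix."""
    mask = [[bool(v) for v in row] for row in rec]
    counts = oracle_line_counts(mask, orientation)
    total = sum(l * c for l, c in counts.items())
    qual = {l: c for l, c in counts.items() if l >= l_min}
    if not qual or total == 0:
        return None, None, None, None
    qp = sum(l * c for l, c in qual.items())
    ql = sum(qual.values())
    probs = [c / ql for c in qual.values()]
    ent = -sum(p * np.log(p) for p in probs)
    return qp / total, qp / ql, max(qual), ent


def oracle_chromatic(rec):
    """Per-category recurrence rates by explicit cell counting."""
    n2 = rec.shape[0] * rec.shape[1]
    counts = Counter()
    for row in rec:
        for v in row:
            if v != 0:
                counts[int(v)] += 1
    total = sum(counts.values())
    rr = {c: k / n2 for c, k in counts.items()}
    rrr = {c: k / total for c, k in counts.items()} if total else None
    return rr, rrr, total / n2


# ---------------------------------------------------------------------------
# brute-force presence-resampling oracle


def oracle_presence(records, bin_width, code, n_bins):
    """Mark bin b iff any event of `code` overlaps [b*w, (b+1)*w)."""
    out = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        lo, hi = b * bin_width, (b + 1) * bin_width
        for onset, offset, c in records:
            if c == code and onset < hi - 1e-12 and offset > lo + 1e-12:
                out[b] = 1
                break
    return out


@pytest.fixture
def random_chromatic_matrix(rng):
    """Factory for random small three-category CRP matrices."""

    def make(n=None, p_zero=0.5):
        n = n or int(rng.integers(1, 51))
        return rng.choice([0, 1, -1], size=(n, n), p=[p_zero, (1 - p_zero) / 2, (1 - p_zero) / 2])

    return make
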