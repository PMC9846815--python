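"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive every formula from scratch in plain
Python (loops, itertools, math.comb) so they stay independent of the
vectorized implementation paths they check.
"""

from __future__ import annotations

import itertools
import math
import statistics

import numpy as np
import pandas as pd
import pytest

from gliascope.mas5 import ExpressionMatrix


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def biweight_oracle(values, c=5.0, epsilon=1e-4):
    """Plain-Python one-step Tukey biweight."""
    xs = list(map(float, values))
    med = statistics.median(xs)
    mad = statistics.median([abs(x - med) for x in xs])
    num = den = 0.0
    for x in xs:
        u = (x - med) / (c * mad + epsilon)
        if abs(u) < 1.0:
            w = (1.0 - u * u) ** 2
            num += w * x
            den += w
    return num / den


def midranks(values):
    """Average ranks of a sequence, computed by explicit enumeration."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def signed_rank_oracle(pm, mm, tau=0.015):
    """Exact one-sided signed-rank p by enumerating every sign assignment."""
    d = [(p - m) / (p + m) - tau for p, m in zip(pm, mm)]
    d = [x for x in d if x != 0.0]
    n = len(d)
    if n == 0:
        return 1.0
    ranks = midranks([abs(x) for x in d])
    w_obs = sum(r for r, x in zip(ranks, d) if x > 0)
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w >= w_obs - 1e-9:
            count += 1
    return count / 2 ** n


def bh_oracle(pvals):
    """Step-up BH by the textbook definition: q_i = min over p_j >= p_i of
    m * p_j / rank_j, clipped at 1."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * pvals[i] / rank)
        q[i] = running
    return q


def hypergeom_tail_oracle(k, N, m, n):
    """P(X >= k) for a hypergeometric draw, by direct combinatorics."""
    total = math.comb(N, n)
    upper = min(m, n)
    return sum(math.comb(m, i) * math.comb(N - m, n - i)
               for i in range(max(k, 0), upper + 1)) / total


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

def make_expression(signals: dict, calls: dict | None = None,
                    target: float = 500.0) -> ExpressionMatrix:
    """Hand-build a small ExpressionMatrix for unit tests.

    ``signals`` maps sample -> list of values; calls default to all 'P'.
    """
    sig = pd.DataFrame(signals, dtype=float)
    sig.index = [f"ps{i}" for i in range(len(sig))]
    sig.index.name = "probeset_id"
    if calls is None:
        calls_df = pd.DataFrame("P", index=sig.index, columns=sig.columns)
    else:
        calls_df = pd.DataFrame(calls)
        calls_df.index = sig.index
    pvals = pd.DataFrame(0.01, index=sig.index, columns=sig.columns)
    factors = pd.Series(1.0, index=sig.columns, name="scale_factor")
    return ExpressionMatrix(signals=sig, pvalues=pvals, calls=calls_df,
                            scale_factors=factors, target=target)


@pytest.fixture(scope="session")
def tiny_study():
    """A small but realistic multi-comparison study, shared across tests."""
    from gliascope.synthetic_data import simulate_deg_study
    return simulate_deg_study(n_genes=400, n_deg=20, n_comparisons=3,
                              seed=42)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230104)
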