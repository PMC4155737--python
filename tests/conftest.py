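"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-implement operations in the most literal
way possible (per-base scans, exhaustive probability summation, double
loops over node pairs) so the optimized implementations can be checked
against them.
"""

from __future__ import annotations

from math import comb

import numpy as np
import pandas as pd
import pytest

from xspecies.io_core import ExpressionMatrix, GenomicInterval


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def naive_segment(values, threshold, min_run, max_gap, merge_first=True):
    """Literal per-base reading of minimum-run/maximum-gap segmentation."""
    covered = [v >= threshold for v in values]
    runs = []
    start = None
    for i, c in enumerate(covered):
        if c and start is None:
            start = i
        elif not c and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(covered)))
    if not merge_first:
        runs = [(s, e) for s, e in runs if e - s >= min_run]
    merged = []
    for s, e in runs:
        if merged and s - merged[-1][1] <= max_gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    if merge_first:
        merged = [(s, e) for s, e in merged if e - s >= min_run]
    return merged


def hypergeom_upper_tail(k, N, K, n):
    """Exact upper-tail P(X >= k) by summation of the pmf."""
    total = comb(N, n)
    acc = 0
    for x in range(k, min(K, n) + 1):
        if n - x > N - K:
            continue
        acc += comb(K, x) * comb(N - K, n - x)
    return acc / total


def brute_modularity(graph, labels, gamma=1.0):
    """Modularity by the double sum over all node pairs."""
    nodes = list(graph.nodes)
    two_m = sum(d for _, d in graph.degree(weight="weight"))
    if two_m == 0:
        return 0.0
    deg = dict(graph.degree(weight="weight"))
    q = 0.0
    for u in nodes:
        for v in nodes:
            if labels[u] != labels[v]:
                continue
            w = graph.get_edge_data(u, v, default={}).get("weight", 0.0) if u != v else 0.0
            q += w - gamma * deg[u] * deg[v] / two_m
    return q / two_m


def brute_coupled_score(net, labels):
    """Independent evaluation of the coupled-modularity objective."""
    score = sum(
        brute_modularity(g, labels, net.gamma) for g in net.layers.values()
    )
    if net.couplings:
        co = sum(1 for a, b in net.couplings if labels[a] == labels[b])
        score += net.kappa * co / len(net.couplings)
    return score


def set_partitions(items):
    """All set partitions of a list (Bell-number many)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def mask_of(intervals, length):
    mask = np.zeros(length, dtype=bool)
    for iv in intervals:
        mask[iv.start : iv.end] = True
    return mask


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def random_intervals(rng):
    def make(n, chrom="chr1", max_pos=10_000):
        out = []
        for i in range(n):
            start = int(rng.integers(0, max_pos - 2))
            end = int(rng.integers(start + 1, min(start + 200, max_pos)))
            strand = str(rng.choice(["+", "-", "."]))
            out.append(
                GenomicInterval(chrom, start, end, strand, f"iv{i}",
                                float(np.round(rng.random(), 3)))
            )
        return out

    return make


@pytest.fixture
def small_expression():
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0], [3.0, 2.0, 1.0], [5.0, 5.0, 5.0]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3"],
    )
    meta = pd.DataFrame(
        {
            "species": "sp0",
            "stage_index": [0, 1, 2],
            "stage_label": ["a", "b", "c"],
            "tissue": "whole",
        },
        index=pd.Index(["s1", "s2", "s3"], name="sample"),
    )
    return ExpressionMatrix(species="sp0", values=values, sample_meta=meta)
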