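"""Independent brute-force oracles used to validate the statistics.

These deliberately avoid the code paths (and where possible the library
calls) used by the implementation: ranking is done by explicit sorting,
exact p-values by exhaustive enumeration, Bray-Curtis by the literal
formula.
"""
from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import t as t_dist


def average_ranks(values: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties replaced by their average, via explicit sorting."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    ranks[order] = np.arange(1, len(values) + 1, dtype=float)
    for v in np.unique(values):
        mask = values == v
        ranks[mask] = ranks[mask].mean()
    return ranks


def spearman_oracle(x, y) -> tuple[float, float]:
    """Spearman rho as Pearson on average ranks; p from the t approximation."""
    rx = average_ranks(np.asarray(x, dtype=float))
    ry = average_ranks(np.asarray(y, dtype=float))
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
    if denom == 0:
        return float("nan"), float("nan")
    rho = float(rx_c @ ry_c / denom)
    rho = max(-1.0, min(1.0, rho))
    n = len(rx)
    if abs(rho) == 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    return rho, float(2.0 * t_dist.sf(abs(t), df=n - 2))


def bray_curtis_oracle(x, y) -> float:
    """Literal sum|x-y| / sum(x+y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.abs(x - y).sum() / (x + y).sum())


def wilcoxon_oracle(a, b) -> tuple[float, float]:
    """Exact two-sided signed-rank test by enumerating all sign assignments.

    Zero differences are dropped; the statistic is the smaller of the
    positive/negative rank sums (scipy's convention).
    """
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    d = d[d != 0]
    ranks = average_ranks(np.abs(d))
    w_pos = ranks[d > 0].sum()
    sums = np.array(
        [
            sum(r for s, r in zip(signs, ranks) if s)
            for signs in itertools.product((0, 1), repeat=len(d))
        ]
    )
    p = 2.0 * min((sums <= w_pos).mean(), (sums >= w_pos).mean())
    return float(min(w_pos, ranks.sum() - w_pos)), float(min(p, 1.0))


def mannwhitney_oracle(a, b) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney U by enumerating all rank assignments."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = len(a)
    ranks = average_ranks(np.concatenate([a, b]))
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    us = np.array(
        [
            ranks[list(comb)].sum() - n * (n + 1) / 2
            for comb in itertools.combinations(range(len(ranks)), n)
        ]
    )
    p = 2.0 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return float(u_obs), float(min(p, 1.0))
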