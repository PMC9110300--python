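"""Jackknife standard errors used throughout the package.

Both the leave-one-out and the block jackknife use the same delete-one
formula: with B pseudo-estimates theta_k,

    se = sqrt((B - 1) / B * sum_k (theta_k - mean(theta))^2)

For 100 blocks this is the familiar sqrt(99/100 * sum (theta_k - mu)^2).
"""

from __future__ import annotations

import warnings

import numpy as np


def jackknife_se(estimates) -> float:
    """Delete-one jackknife SE from the vector of leave-one-out estimates."""
    theta = np.asarray(estimates, dtype=float)
    b = len(theta)
    if b < 2:
        raise ValueError("jackknife needs at least 2 leave-one-out estimates")
    mu = theta.mean()
    return float(np.sqrt((b - 1) / b * np.sum((theta - mu) ** 2)))


def block_bounds(n: int, n_blocks: int) -> np.ndarray:
    """Start indices of ``n_blocks`` contiguous, near-equal-count blocks."""
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    if n < 2 * n_blocks:
        new = max(2, n // 2)
        warnings.warn(f"only {n} observations; reducing blocks "
                      f"{n_blocks} -> {new}")
        n_blocks = new
    edges = np.linspace(0, n, n_blocks + 1).round().astype(int)
    return edges


def block_jackknife(values_order: int, estimator, n_blocks: int = 100):
    """Generic block jackknife: ``estimator(mask)`` maps a keep-mask to a stat.

    Returns (leave-one-block-out estimates, se). Blocks are contiguous in the
    supplied ordering, so callers must pass data already sorted by genomic
    position when local correlation matters.
    """
    edges = block_bounds(values_order, n_blocks)
    loo = []
    for k in range(len(edges) - 1):
        mask = np.ones(values_order, dtype=bool)
        mask[edges[k]:edges[k + 1]] = False
        loo.append(estimator(mask))
    loo = np.asarray(loo, dtype=float)
    return loo, jackknife_se(loo)
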