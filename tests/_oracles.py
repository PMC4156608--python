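"""Independent test oracles, deliberately kept separate from the library code."""

from __future__ import annotations

import numpy as np


def permutation_welch_p(
    a: np.ndarray, b: np.ndarray, n_draws: int = 100_000, seed: int = 0
) -> float:
    """Two-sided permutation p for the Welch statistic, by random relabeling.

    Uses the add-one estimator (observed split counts as one draw), the
    standard bias-safe convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    na = a.size

    def welch_t(x: np.ndarray, y: np.ndarray) -> np.ndarray:
        vx = x.var(ddof=1, axis=-1)
        vy = y.var(ddof=1, axis=-1)
        return (x.mean(axis=-1) - y.mean(axis=-1)) / np.sqrt(
            vx / x.shape[-1] + vy / y.shape[-1]
        )

    obs = abs(float(welch_t(a, b)))
    rng = np.random.default_rng(seed)
    idx = np.argsort(rng.random((n_draws, pooled.size)), axis=1)
    perm = pooled[idx]
    ts = welch_t(perm[:, :na], perm[:, na:])
    return float((np.sum(np.abs(ts) >= obs - 1e-12) + 1) / (n_draws + 1))


def brute_force_holm(pvalues: np.ndarray, alpha: float) -> np.ndarray:
    """Literal evaluation of the standard Holm step-down rule, one p at a time."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    flags = np.zeros(m, dtype=bool)
    for i, idx in enumerate(order):
        if p[idx] <= alpha / (m - i):
            flags[idx] = True
        else:
            break
    return flags
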