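"""Vectorised random-set samplers shared by the permutation tests."""

from __future__ import annotations

import numpy as np

# chunk sizes keep the temporary gather arrays around a few tens of MB
_MAX_CELLS = 4_000_000


def sample_index_sets(rng: np.random.Generator, n_universe: int, k: int,
                      n_sets: int) -> np.ndarray:
    """Draw ``n_sets`` uniform random k-subsets of ``range(n_universe)``.

    Sampling is without replacement within a set and independent between
    sets. For small universes this uses one argpartition over random keys
    (exactly uniform over k-subsets); large universes fall back to repeated
    ``Generator.choice``.
    """
    if k > n_universe:
        raise ValueError(f"cannot draw {k} distinct items from {n_universe}")
    if n_universe <= 4096:
        out = np.empty((n_sets, k), dtype=np.intp)
        chunk = max(1, _MAX_CELLS // n_universe)
        for start in range(0, n_sets, chunk):
            m = min(chunk, n_sets - start)
            keys = rng.random((m, n_universe))
            out[start:start + m] = np.argpartition(keys, k - 1, axis=1)[:, :k]
        return out
    return np.array([rng.choice(n_universe, size=k, replace=False)
                     for _ in range(n_sets)], dtype=np.intp)


def _nanmean_rows(sub: np.ndarray) -> np.ndarray:
    finite = np.isfinite(sub)
    count = finite.sum(axis=1)
    total = np.where(finite, sub, 0.0).sum(axis=1)
    return np.where(count > 0, total / np.maximum(count, 1), np.nan)


def null_group_means(values: np.ndarray, k: int, n_perm: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Mean within-set ERC of ``n_perm`` random k-gene sets.

    ``values`` is the full symmetric ERC matrix (NaN = undefined entry).
    Undefined pairs are excluded from each mean; a set with no defined pair
    yields NaN.
    """
    n_universe = values.shape[0]
    ii, jj = np.triu_indices(k, 1)
    out = np.empty(n_perm)
    chunk = max(1, _MAX_CELLS // max(len(ii), 1))
    for start in range(0, n_perm, chunk):
        m = min(chunk, n_perm - start)
        idx = sample_index_sets(rng, n_universe, k, m)
        sub = values[idx[:, ii], idx[:, jj]]
        out[start:start + m] = _nanmean_rows(sub)
    return out


def null_cross_means(values: np.ndarray, ka: int, kb: int, n_perm: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Mean cross-set ERC of ``n_perm`` random disjoint (ka, kb) set pairs."""
    n_universe = values.shape[0]
    out = np.empty(n_perm)
    chunk = max(1, _MAX_CELLS // max(ka * kb, 1))
    for start in range(0, n_perm, chunk):
        m = min(chunk, n_perm - start)
        idx = sample_index_sets(rng, n_universe, ka + kb, m)
        sub = values[idx[:, :ka][:, :, None], idx[:, ka:][:, None, :]]
        out[start:start + m] = _nanmean_rows(sub.reshape(m, ka * kb))
    return out
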