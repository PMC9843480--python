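"""Brute-force reference implementations for texture matrices and features.

Deliberately naive (explicit Python loops over voxels and lattice walks)
and independent of the vectorised code paths in ``salirad.texture``.
"""

from __future__ import annotations

import numpy as np

N_LEVELS = 16


def glcm_oracle(labels: np.ndarray, direction: tuple[int, ...]) -> np.ndarray:
    """Count every ordered labelled pair at the given offset, both orderings."""
    counts = np.zeros((N_LEVELS, N_LEVELS))
    shape = labels.shape
    for pos in np.ndindex(*shape):
        a = labels[pos]
        if a == 0:
            continue
        nb = tuple(p + d for p, d in zip(pos, direction))
        if any(c < 0 or c >= s for c, s in zip(nb, shape)):
            continue
        b = labels[nb]
        if b == 0:
            continue
        counts[a - 1, b - 1] += 1
        counts[b - 1, a - 1] += 1
    return counts


def glrlm_oracle(labels: np.ndarray, direction: tuple[int, ...]) -> np.ndarray:
    """Walk every lattice line, restarting runs at zeros and label changes."""
    shape = labels.shape
    runs: list[tuple[int, int]] = []
    for pos in np.ndindex(*shape):
        prev = tuple(p - d for p, d in zip(pos, direction))
        inside = all(0 <= c < s for c, s in zip(prev, shape))
        if inside:
            continue  # not a line start
        cur = pos
        run_val, run_len = 0, 0
        while all(0 <= c < s for c, s in zip(cur, shape)):
            v = labels[cur]
            if v == run_val:
                run_len += 1
            else:
                if run_val > 0:
                    runs.append((run_val, run_len))
                run_val, run_len = v, 1
            cur = tuple(c + d for c, d in zip(cur, direction))
        if run_val > 0:
            runs.append((run_val, run_len))
    lmax = max((l for _, l in runs), default=1)
    counts = np.zeros((N_LEVELS, lmax))
    for v, l in runs:
        counts[v - 1, l - 1] += 1
    return counts


def sre_oracle(run_counts: np.ndarray) -> float:
    total = run_counts.sum()
    acc = 0.0
    for i in range(run_counts.shape[0]):
        for j in range(run_counts.shape[1]):
            acc += run_counts[i, j] / (j + 1) ** 2
    return acc / total


def idm_oracle(pair_counts: np.ndarray) -> float:
    p = pair_counts / pair_counts.sum()
    acc = 0.0
    for i in range(p.shape[0]):
        for j in range(p.shape[1]):
            acc += p[i, j] / (1 + (i - j) ** 2)
    return acc


def random_masked_slice(rng: np.random.Generator, size: int = 8) -> np.ndarray:
    """Random labelled slice with an irregular mask (0 = outside)."""
    labels = rng.integers(1, N_LEVELS + 1, size=(size, size))
    mask = rng.random((size, size)) < rng.uniform(0.4, 0.95)
    return np.where(mask, labels, 0).astype(np.uint8)
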