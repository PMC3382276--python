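"""Fused Hardy-Weinberg genotype sampling kernel.

Rejection-sampling cases at prevalences of a few per mille means simulating
millions of individuals per replicate, so genotype generation is the hot
path of the whole package.  The kernel below draws one 32-bit uniform per
genotype from a counter-based splitmix64 stream (the same finalizer numpy
uses for seeding), thresholds it against the cumulative Hardy-Weinberg
probabilities (1-p)^2 and 1-p^2 scaled to uint32, and accumulates the
genetic value in the same pass.  Counters are indexed by (individual, locus),
so any row range of a cohort can be regenerated independently and the stream
never overlaps between chunks.

`hwe_genotypes_numpy` is the plain numpy reference implementation; it is
distribution-identical (not bit-identical) and serves as the cross-check
oracle in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_SCALE = 4294967296.0  # 2^32


def hwe_thresholds(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """uint32 cumulative genotype thresholds for allele frequencies ``p``."""
    p = np.asarray(p, dtype=float)
    t1 = np.minimum(np.round((1.0 - p) ** 2 * _SCALE), _SCALE - 1)
    t2 = np.minimum(np.round((1.0 - p * p) * _SCALE), _SCALE - 1)
    return t1.astype(np.uint32), t2.astype(np.uint32)


@njit(cache=True, fastmath=True)
def _fill_genotypes(thr1, thr2, beta, key, row0, X, g):  # pragma: no cover
    n, m = X.shape
    for i in range(n):
        base = np.uint64(key) + np.uint64(row0 + i) * np.uint64(m)
        acc = 0.0
        for j in range(m):
            z = (base + np.uint64(j)) * np.uint64(0x9E3779B97F4A7C15)
            z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
            z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
            z = z ^ (z >> np.uint64(31))
            u = np.uint32(z >> np.uint64(32))
            x = np.int8(0)
            if u >= thr1[j]:
                x = np.int8(1)
                if u >= thr2[j]:
                    x = np.int8(2)
            X[i, j] = x
            acc += x * beta[j]
        g[i] = acc


def hwe_genotypes_block(
    p: np.ndarray,
    beta: np.ndarray,
    n: int,
    key: int,
    row0: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` individuals' genotypes and genetic values.

    Genotypes are 0/1/2 copies of the risk allele, binomial(2, p_j) per locus
    under linkage equilibrium; ``g_i = sum_j X_ij beta_j`` (uncentered).
    ``key`` seeds the counter-based stream; ``row0`` offsets the individual
    index so consecutive blocks of one cohort continue the same stream.
    """
    p = np.asarray(p, dtype=float)
    thr1, thr2 = hwe_thresholds(p)
    beta64 = np.ascontiguousarray(beta, dtype=np.float64)
    X = np.empty((n, p.size), dtype=np.int8)
    g = np.empty(n, dtype=np.float64)
    _fill_genotypes(thr1, thr2, beta64, np.uint64(key & (2**64 - 1)), row0, X, g)
    return X, g


def hwe_genotypes_numpy(
    p: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Reference sampler: one uniform per genotype, same thresholds."""
    p = np.asarray(p, dtype=float)
    u = rng.random((n, p.size))
    q2 = (1.0 - p) ** 2
    c2 = 1.0 - p * p
    return ((u >= q2).view(np.int8) + (u >= c2).view(np.int8)).astype(np.int8)
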