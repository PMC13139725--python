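"""Numba kernels for fixed-row-sum / fixed-column-sum matrix randomization.

Both samplers operate in place on a uint8 matrix and preserve every row and
column sum by construction:

* ``sequential_swap`` — the classic checkerboard swap: draw two rows and two
  columns uniformly; if the 2x2 submatrix is [[1,0],[0,1]] or [[0,1],[1,0]],
  flip it. Rejected draws do NOT count toward the requested number of swaps
  (``n_swaps`` counts effective moves); an attempt cap guards matrices that
  contain no checkerboard at all.

* ``curveball`` — draw two distinct rows, pool the species held by exactly
  one of them, shuffle the pool and deal it back keeping each row's richness.
  Every trade is accepted, which mixes much faster on sparse matrices.

Seeding uses numba's per-kernel NumPy legacy RNG; the same (matrix, seed,
n) triple always yields the same output.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def sequential_swap_kernel(mat, n_swaps, max_attempts, seed):  # pragma: no cover
    np.random.seed(seed)
    n_rows, n_cols = mat.shape
    done = 0
    attempts = 0
    if n_rows < 2 or n_cols < 2:
        return 0
    while done < n_swaps and attempts < max_attempts:
        attempts += 1
        r1 = np.random.randint(n_rows)
        r2 = np.random.randint(n_rows)
        c1 = np.random.randint(n_cols)
        c2 = np.random.randint(n_cols)
        if r1 == r2 or c1 == c2:
            continue
        x11 = mat[r1, c1]
        x12 = mat[r1, c2]
        x21 = mat[r2, c1]
        x22 = mat[r2, c2]
        if x11 == 1 and x22 == 1 and x12 == 0 and x21 == 0:
            mat[r1, c1] = 0
            mat[r2, c2] = 0
            mat[r1, c2] = 1
            mat[r2, c1] = 1
            done += 1
        elif x11 == 0 and x22 == 0 and x12 == 1 and x21 == 1:
            mat[r1, c1] = 1
            mat[r2, c2] = 1
            mat[r1, c2] = 0
            mat[r2, c1] = 0
            done += 1
    return done


@njit(cache=True)
def curveball_kernel(mat, n_trades, seed):  # pragma: no cover
    np.random.seed(seed)
    n_rows, n_cols = mat.shape
    if n_rows < 2:
        return
    pool = np.empty(n_cols, dtype=np.int64)
    for _ in range(n_trades):
        r1 = np.random.randint(n_rows)
        r2 = np.random.randint(n_rows)
        while r2 == r1:
            r2 = np.random.randint(n_rows)
        # species held by exactly one of the two rows
        k1 = 0  # count unique to r1
        total = 0
        for c in range(n_cols):
            v1 = mat[r1, c]
            if v1 != mat[r2, c]:
                pool[total] = c
                total += 1
                if v1 == 1:
                    k1 += 1
        if total == 0 or k1 == 0 or k1 == total:
            continue
        # Fisher-Yates shuffle of the pooled non-shared species
        for i in range(total - 1, 0, -1):
            j = np.random.randint(i + 1)
            tmp = pool[i]
            pool[i] = pool[j]
            pool[j] = tmp
        # first k1 go to r1, the rest to r2 (richness of each row unchanged)
        for i in range(total):
            c = pool[i]
            if i < k1:
                mat[r1, c] = 1
                mat[r2, c] = 0
            else:
                mat[r1, c] = 0
                mat[r2, c] = 1
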