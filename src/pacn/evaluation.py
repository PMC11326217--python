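"""Benchmarking utilities: independent oracles and truth comparison.

These deliberately re-solve the genotyping subproblems by exhaustive or
enumerative methods — slow but exact — so the production solvers can be
validated against them on small instances.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np

from .pipeline import Database, GroupBundle
from .simulate import TruthSet

__all__ = [
    "best_integer_solution",
    "expected_row_cn",
    "nnls_by_enumeration",
    "random_projection_instance",
]


def nnls_by_enumeration(M: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact non-negative least squares by active-set enumeration.

    For every support subset S of rows, solve the unconstrained least
    squares restricted to S; keep the feasible (c >= 0) solution with the
    smallest residual.  Exponential in the number of rows — use only for
    small matrices.
    """
    M = np.asarray(M, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    m = M.shape[0]
    best_c = np.zeros(m)
    best_r = float(np.linalg.norm(v))
    for size in range(1, m + 1):
        for support in combinations(range(m), size):
            A = M[list(support)].T
            sol, *_ = np.linalg.lstsq(A, v, rcond=None)
            if (sol < -1e-9).any():
                continue
            c = np.zeros(m)
            c[list(support)] = np.maximum(sol, 0.0)
            r = float(np.linalg.norm(M.T @ c - v))
            if r < best_r - 1e-12:
                best_r = r
                best_c = c
    return best_c, best_r


_GRIDS: dict[tuple[int, int], np.ndarray] = {}


def _integer_grid(m: int, cn_max: int) -> np.ndarray:
    key = (m, cn_max)
    if key not in _GRIDS:
        _GRIDS[key] = np.array(list(product(range(cn_max + 1), repeat=m)), dtype=np.float64)
    return _GRIDS[key]


def best_integer_solution(
    M: np.ndarray, v: np.ndarray, cn_max: int = 5
) -> tuple[np.ndarray, float]:
    """Exhaustive search for the best integer copy-number vector (CN <= cn_max)."""
    M = np.asarray(M, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    grid = _integer_grid(M.shape[0], cn_max)
    resid = np.linalg.norm(grid @ M - v[None, :], axis=1)
    i = int(np.argmin(resid))
    return grid[i].astype(np.int64), float(resid[i])


def random_projection_instance(
    rng: np.random.Generator,
    max_rows: int = 6,
    max_cols: int = 12,
    cn_max: int = 3,
    noise_sd: float = 0.15,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One random genotyping instance: (M, c_true, noisy normalized counts).

    Rows are sparse non-negative multiplicity profiles (every row and
    column non-empty); the observation is Mᵀ c_true plus Gaussian noise,
    clipped at zero as counts are.
    """
    m = int(rng.integers(2, max_rows + 1))
    n = int(rng.integers(max(m + 2, 8), max_cols + 1))
    while True:
        M = rng.integers(0, 4, size=(m, n)).astype(np.float64)
        if (M.sum(axis=1) > 0).all() and (M.sum(axis=0) > 0).all():
            break
    c_true = rng.integers(0, cn_max + 1, size=m).astype(np.float64)
    v = M.T @ c_true + rng.normal(0.0, noise_sd, size=n)
    return M, c_true, np.maximum(v, 0.0)


def expected_row_cn(db: Database, bundle: GroupBundle, hap_pair: tuple[str, str]) -> np.ndarray:
    """Truth copy number of each matrix row for a diploid sample.

    Every allele interval present in a haplotype is exactly one member of
    one row, so a row's true CN is the number of its members carried by
    the sample's haplotypes (a homozygous pair counts twice).
    """
    out = np.zeros(len(bundle.matrix.pa_ids), dtype=np.int64)
    for i, pid in enumerate(bundle.matrix.pa_ids):
        for member in bundle.matrix.row_members.get(pid, [pid]):
            hap = db.pas[member].haplotype_id
            out[i] += sum(1 for h in hap_pair if h == hap)
    return out


def truth_subgroup_table(
    db: Database, truth: TruthSet, sample_pairs: dict[str, tuple[str, str]]
):
    """Samples x subgroups truth CN table (error-free genotyping baseline)."""
    import pandas as pd

    cols: dict[str, dict[str, int]] = {}
    for sample, pair in sample_pairs.items():
        row: dict[str, int] = {}
        for g in db.groups:
            cn = expected_row_cn(db, g, pair)
            for pid, c in zip(g.matrix.pa_ids, cn):
                sid = f"{g.group_id}:{g.subgroups.assignment[pid]}"
                row[sid] = row.get(sid, 0) + int(c)
        cols[sample] = row
    return pd.DataFrame(cols).T.fillna(0).astype(int)
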