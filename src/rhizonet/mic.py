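"""Maximal information coefficient (MIC) association inference.

MIC measures dependence between two variables by searching over grids: one
axis is equipartitioned by rank into a fixed number of bins, the other axis
is partitioned by a dynamic program that maximizes mutual information over
candidate cut points. The normalized maximum over all grid resolutions
(k_x, k_y) with k_x * k_y <= B(n) is the MIC. Because only rank order enters
the binning, MIC is exactly invariant under strictly increasing transforms
of either variable, and detects monotone as well as non-monotone dependence.

This module scores all unordered OTU pairs of a count table, attaches
permutation p-values from a null distribution shared across pairs (the null
depends only on the sample size under exchangeability), controls FDR by
Benjamini-Hochberg, and classifies significant pairs as positive, negative,
or nonlinear.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MicConfig",
    "mic_score",
    "mic_matrix",
    "permutation_pvalues",
    "bh_fdr",
    "classify_edges",
]

_EPS = 1e-12


@dataclass
class MicConfig:
    """Tuning parameters for MIC scoring and edge significance.

    b_exponent
        Grid budget exponent: grids satisfy k_x * k_y <= B(n) = n**b_exponent
        (clamped to >= 4 so a 2x2 grid always exists).
    max_clumps_factor
        Cap on the number of candidate atomic units fed to the DP, as a
        multiple of the column budget; bounds worst-case cost on large n.
    n_permutations
        Size of the shared null distribution for p-values.
    alpha
        FDR level for edge calling.
    nonlinearity_threshold
        tau: a significant pair with mic - r^2 > tau is classed nonlinear.
    low_support_min_nonzero
        Pairs where either vector has fewer nonzero entries than this are
        flagged ``low_support`` (scored anyway).
    """

    b_exponent: float = 0.6
    max_clumps_factor: int = 15
    n_permutations: int = 1000
    alpha: float = 0.05
    nonlinearity_threshold: float = 0.2
    low_support_min_nonzero: int = 4
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.b_exponent < 1.0:
            raise ValueError("b_exponent must be in (0, 1)")
        if self.n_permutations < 99:
            raise ValueError("n_permutations must be >= 99")

    def grid_budget(self, n: int) -> int:
        return max(int(np.floor(n**self.b_exponent)), 4)


def _xlogx(v: np.ndarray) -> np.ndarray:
    out = np.zeros_like(v, dtype=float)
    nz = v > _EPS
    out[nz] = v[nz] * np.log2(v[nz])
    return out


def equipartition_assignment(values: np.ndarray, k: int) -> np.ndarray:
    """Assign each point to one of <= k rank-bins of near-equal size.

    Ties always land in the same bin; bin sizes adapt greedily to stay close
    to the ideal n/k as tie groups are consumed (the standard MINE
    equipartition). Returns integer bin labels aligned with ``values``.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    order = np.argsort(values, kind="mergesort")
    sv = values[order]
    # tie-group start indices
    starts = np.flatnonzero(np.r_[True, sv[1:] != sv[:-1]])
    sizes = np.diff(np.r_[starts, n])
    labels_sorted = np.empty(n, dtype=np.int64)
    curr = 0
    h = 0  # points in current bin
    assigned = 0
    rowsize = n / k
    for s0, sz in zip(starts, sizes):
        if h != 0 and abs(h + sz - rowsize) >= abs(h - rowsize):
            curr += 1
            h = 0
            remaining_bins = k - curr
            if remaining_bins > 0:
                rowsize = (n - assigned) / remaining_bins
        labels_sorted[s0 : s0 + sz] = curr
        h += sz
        assigned += sz
    labels = np.empty(n, dtype=np.int64)
    labels[order] = labels_sorted
    return labels


def _tie_group_ids(values: np.ndarray) -> np.ndarray:
    """Clump ids (0..m-1) of x-sorted points: one clump per distinct value."""
    sv = np.sort(values)
    return np.cumsum(np.r_[0, sv[1:] != sv[:-1]])


def _superclump(clump_ids: np.ndarray, cap: int) -> np.ndarray:
    """Merge adjacent clumps so that at most ``cap`` atomic units remain."""
    m = clump_ids[-1] + 1
    if m <= cap:
        return clump_ids
    # merge by equipartitioning the clump index range on point mass
    n = clump_ids.size
    target = n / cap
    sizes = np.bincount(clump_ids)
    new_ids = np.empty(m, dtype=np.int64)
    acc = 0
    curr = 0
    for c in range(m):
        if acc >= target and curr < cap - 1:
            curr += 1
            acc = 0
        new_ids[c] = curr
        acc += sizes[c]
    return new_ids[clump_ids]


def _column_profile(
    row_labels_xsorted: np.ndarray,
    clump_ids: np.ndarray,
    n_rows: int,
    kx_max: int,
) -> np.ndarray:
    """Best achievable MI for partitions of the x-axis into <= kx columns.

    Given row assignments (y equipartition) of the points in x-sorted order
    and atomic clump ids (points in a clump may not be separated), run the
    additive-column dynamic program and return ``best[kx]`` for
    kx = 0..kx_max, where best[kx] is the maximum mutual information over
    partitions into at most kx columns whose boundaries respect clumps.
    """
    n = row_labels_xsorted.size
    m = clump_ids[-1] + 1
    # per-clump row counts -> prefix sums cum[i, r], i = 0..m
    flat = clump_ids * n_rows + row_labels_xsorted
    counts = np.bincount(flat, minlength=m * n_rows).reshape(m, n_rows)
    cum = np.zeros((m + 1, n_rows), dtype=float)
    np.cumsum(counts, axis=0, out=cum[1:])
    cum_n = cum.sum(axis=1)

    # T[s, i] = column contribution of clumps (s, i]:  sum_r p_sr log2 p_sr
    #           - p_c log2 p_c  (valid for s < i)
    diff = (cum[None, :, :] - cum[:, None, :]) / n  # (m+1, m+1, R)
    T = _xlogx(diff).sum(axis=2) - _xlogx((cum_n[None, :] - cum_n[:, None]) / n)
    s_idx, i_idx = np.meshgrid(np.arange(m + 1), np.arange(m + 1), indexing="ij")
    T[s_idx >= i_idx] = -np.inf

    p_r = cum[m] / n
    h_q = -_xlogx(p_r).sum()

    best = np.full(kx_max + 1, -np.inf)
    if kx_max < 1:
        return best
    # F[i] = best sum of column terms for first i clumps in exactly l columns
    F = T[0, :].copy()  # l = 1
    best[1] = h_q + F[m]  # == 0 up to fp error
    for l in range(2, kx_max + 1):
        F = (F[:, None] + T).max(axis=0)
        best[l] = max(best[l - 1], h_q + F[m])
    return best


def _char_matrix_one_orientation(
    x: np.ndarray, y: np.ndarray, b: int, clump_cap: int
) -> dict[tuple[int, int], float]:
    """Unnormalized max-MI values I[kx, ky]: y equipartitioned, x optimized."""
    out: dict[tuple[int, int], float] = {}
    order = np.argsort(x, kind="mergesort")
    clump_ids = _superclump(_tie_group_ids(x), clump_cap)
    for ky in range(2, b // 2 + 1):
        kx_max = b // ky
        rows = equipartition_assignment(y, ky)
        n_rows = rows.max() + 1
        prof = _column_profile(rows[order], clump_ids, n_rows, kx_max)
        for kx in range(2, kx_max + 1):
            out[(kx, ky)] = prof[kx]
    return out


def mic_compute(
    x: np.ndarray, y: np.ndarray, cfg: MicConfig | None = None
) -> tuple[float, dict[tuple[int, int], float]]:
    """MIC of two numeric vectors, plus the full characteristic matrix.

    Returns ``(mic, char)`` where ``char[(kx, ky)]`` is the normalized
    characteristic value for grids with kx x-bins and ky y-bins (the larger
    of the two axis orientations), and ``mic`` is its maximum.
    """
    cfg = cfg or MicConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 8:
        raise ValueError("MIC requires at least 8 observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("MIC is undefined for a constant vector")
    b = cfg.grid_budget(n)
    cap = cfg.max_clumps_factor * max(b // 2, 2)
    a_vals = _char_matrix_one_orientation(x, y, b, cap)  # kx cols opt, ky rows
    b_vals = _char_matrix_one_orientation(y, x, b, cap)  # ky cols opt, kx rows
    char: dict[tuple[int, int], float] = {}
    mic = 0.0
    for kx in range(2, b // 2 + 1):
        for ky in range(2, b // kx + 1):
            i_best = max(a_vals.get((kx, ky), -np.inf), b_vals.get((ky, kx), -np.inf))
            val = max(i_best, 0.0) / np.log2(min(kx, ky))
            char[(kx, ky)] = min(val, 1.0)
            mic = max(mic, char[(kx, ky)])
    return mic, char


def mic_score(x: np.ndarray, y: np.ndarray, cfg: MicConfig | None = None) -> float:
    """MIC in [0, 1] of two numeric vectors (see :func:`mic_compute`)."""
    return mic_compute(x, y, cfg)[0]


def mic_exhaustive(
    x: np.ndarray, y: np.ndarray, cfg: MicConfig | None = None
) -> tuple[float, dict[tuple[int, int], float]]:
    """Brute-force MIC: enumerate every cut-point partition of the free axis.

    Independent oracle for small n (cost grows as 2^n): for every grid
    resolution and both orientations, enumerates all interval partitions of
    the DP axis over distinct-value boundaries instead of running the DP.
    """
    cfg = cfg or MicConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    b = cfg.grid_budget(n)

    def all_partition_mi(free: np.ndarray, fixed: np.ndarray, ky: int, kx_max: int):
        rows = equipartition_assignment(fixed, ky)
        n_rows = rows.max() + 1
        order = np.argsort(free, kind="mergesort")
        clumps = _tie_group_ids(free)
        m = clumps[-1] + 1
        rows_sorted = rows[order]
        p_r = np.bincount(rows, minlength=n_rows) / n
        h_q = -_xlogx(p_r).sum()
        best = np.full(kx_max + 1, -np.inf)
        for ncols in range(1, kx_max + 1):
            if ncols > m:
                break
            for cuts in itertools.combinations(range(1, m), ncols - 1):
                bounds = (0,) + cuts + (m,)
                col_of_clump = np.empty(m, dtype=np.int64)
                for c, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:])):
                    col_of_clump[lo:hi] = c
                cols = col_of_clump[clumps]
                joint = np.bincount(
                    cols * n_rows + rows_sorted, minlength=ncols * n_rows
                ).reshape(ncols, n_rows) / n
                p_c = joint.sum(axis=1)
                mi = h_q + _xlogx(joint).sum() - _xlogx(p_c).sum()
                best[ncols] = max(best[ncols], mi)
        for ncols in range(2, kx_max + 1):
            best[ncols] = max(best[ncols], best[ncols - 1])
        return best

    char: dict[tuple[int, int], float] = {}
    mic = 0.0
    prof_a = {
        ky: all_partition_mi(x, y, ky, b // ky) for ky in range(2, b // 2 + 1)
    }
    prof_b = {
        kx: all_partition_mi(y, x, kx, b // kx) for kx in range(2, b // 2 + 1)
    }
    for kx in range(2, b // 2 + 1):
        for ky in range(2, b // kx + 1):
            i_best = max(prof_a[ky][kx], prof_b[kx][ky])
            val = max(i_best, 0.0) / np.log2(min(kx, ky))
            char[(kx, ky)] = min(val, 1.0)
            mic = max(mic, char[(kx, ky)])
    return mic, char


# ---------------------------------------------------------------------------
# pairwise scoring over an OTU table
# ---------------------------------------------------------------------------


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx = x.std()
    sy = y.std()
    if sx < _EPS or sy < _EPS:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def mic_matrix(table: pd.DataFrame, cfg: MicConfig | None = None) -> pd.DataFrame:
    """Score every unordered OTU pair of a samples x OTUs count table.

    Returns an association table with one row per pair: ``otu_a``, ``otu_b``
    (a < b in column order), ``mic``, ``pearson_r``, ``low_support``.
    Deterministic; symmetric by construction.
    """
    cfg = cfg or MicConfig()
    if table.shape[1] < 2:
        raise ValueError("association inference requires at least 2 OTUs")
    X = table.to_numpy(dtype=float)
    otus = list(table.columns)
    n_nonzero = (X > 0).sum(axis=0)
    rows = []
    for i in range(len(otus)):
        for j in range(i + 1, len(otus)):
            xi, xj = X[:, i], X[:, j]
            if np.unique(xi).size < 2 or np.unique(xj).size < 2:
                mic = np.nan
            else:
                mic = mic_score(xi, xj, cfg)
            rows.append(
                (
                    otus[i],
                    otus[j],
                    mic,
                    _pearson(xi, xj),
                    bool(
                        n_nonzero[i] < cfg.low_support_min_nonzero
                        or n_nonzero[j] < cfg.low_support_min_nonzero
                    ),
                )
            )
    return pd.DataFrame(
        rows, columns=["otu_a", "otu_b", "mic", "pearson_r", "low_support"]
    )


def null_mic_distribution(
    table: pd.DataFrame, cfg: MicConfig, rng: np.random.Generator
) -> np.ndarray:
    """Shared null MIC distribution for the table's sample size.

    Under exchangeability the null law of MIC depends only on n (and the
    tie structure typical of the table), so one distribution serves every
    pair: each draw picks two columns at random, independently permutes
    each, and scores the shuffled pair.
    """
    X = table.to_numpy(dtype=float)
    n, p = X.shape
    usable = [j for j in range(p) if np.unique(X[:, j]).size >= 2]
    if len(usable) < 2:
        raise ValueError("need at least 2 non-constant OTUs for the null")
    out = np.empty(cfg.n_permutations)
    for k in range(cfg.n_permutations):
        i, j = rng.choice(usable, size=2, replace=False)
        out[k] = mic_score(rng.permutation(X[:, i]), rng.permutation(X[:, j]), cfg)
    return out


def permutation_pvalues(
    assoc: pd.DataFrame,
    table: pd.DataFrame,
    cfg: MicConfig | None = None,
    null: np.ndarray | None = None,
) -> pd.DataFrame:
    """Attach permutation p-values (and BH q-values) to an association table.

    p = (1 + #{null >= observed}) / (1 + n_permutations) against the shared
    null; pass ``null`` to reuse a precomputed distribution.
    """
    cfg = cfg or MicConfig()
    rng = np.random.default_rng(cfg.seed)
    if null is None:
        null = null_mic_distribution(table, cfg, rng)
    null_sorted = np.sort(null)
    mics = assoc["mic"].to_numpy()
    n_ge = null.size - np.searchsorted(null_sorted, mics, side="left")
    p = (1.0 + n_ge) / (1.0 + null.size)
    p = np.where(np.isnan(mics), np.nan, p)
    out = assoc.copy()
    out["p_value"] = p
    out["q_value"] = bh_fdr(p)
    return out


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, original order restored.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1; NaNs pass through and
    do not count toward m.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    qv = np.minimum.accumulate(ranked[::-1])[::-1]
    qv = np.minimum(qv, 1.0)
    out = np.empty(m)
    out[order] = qv
    q[ok] = out
    return q


def classify_edges(assoc: pd.DataFrame, cfg: MicConfig | None = None) -> pd.DataFrame:
    """Label significant pairs positive / negative / nonlinear.

    For pairs with q < alpha: nonlinear if mic - r^2 exceeds the
    nonlinearity threshold (or r is undefined), otherwise the sign of r.
    Non-significant pairs get an empty label.
    """
    cfg = cfg or MicConfig()
    if "q_value" not in assoc.columns:
        raise ValueError("q-values required; run permutation_pvalues first")
    out = assoc.copy()
    rel = np.full(len(out), "", dtype=object)
    sig = out["q_value"].to_numpy() < cfg.alpha
    mic = out["mic"].to_numpy()
    r = out["pearson_r"].to_numpy()
    nonlin = np.isnan(r) | ((mic - np.square(np.nan_to_num(r))) > cfg.nonlinearity_threshold)
    rel[sig & nonlin] = "nonlinear"
    rel[sig & ~nonlin & (r > 0)] = "positive"
    rel[sig & ~nonlin & (r <= 0)] = "negative"
    out["relationship"] = rel
    return out
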