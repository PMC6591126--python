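"""Community-level statistics: alpha diversity, Bray-Curtis beta diversity
with PERMANOVA / PERMDISP, and indicator species analysis.

All permutation tests use the (1 + more-extreme) / (1 + n_permutations)
convention, are driven by an explicit seed, and are vectorized across
permutations so that calibration simulations with thousands of replicates
stay cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "alpha_diversity",
    "bray_curtis",
    "permanova",
    "permdisp",
    "indicator_species",
    "PermutationTestResult",
]


@dataclass
class PermutationTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    explained_variation: float | None = None  # percent, PERMANOVA only


def alpha_diversity(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample richness, Shannon index (nats), and Sheldon evenness.

    richness = number of OTUs with nonzero counts; H = -sum p_i ln p_i over
    nonzero relative abundances; Sheldon evenness = e^H / richness (Pielou's
    H / ln richness is exposed as an extra column for reference).
    """
    X = table.to_numpy(dtype=float)
    if (X.sum(axis=1) == 0).any():
        raise ValueError("empty sample(s) in table")
    p = X / X.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    shannon = -plogp.sum(axis=1)
    richness = (X > 0).sum(axis=1)
    sheldon = np.exp(shannon) / richness
    with np.errstate(divide="ignore", invalid="ignore"):
        pielou = np.where(richness > 1, shannon / np.log(richness), 1.0)
    return pd.DataFrame(
        {
            "richness": richness,
            "shannon": shannon,
            "sheldon_evenness": sheldon,
            "pielou_evenness": pielou,
        },
        index=table.index,
    )


def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Bray-Curtis dissimilarity matrix between samples."""
    X = table.to_numpy(dtype=float)
    if (X.sum(axis=1) == 0).any():
        raise ValueError("empty sample(s) in table")
    D = squareform(pdist(X, metric="braycurtis"))
    return pd.DataFrame(D, index=table.index, columns=table.index)


def _as_groups(groups) -> tuple[np.ndarray, list]:
    labels = np.asarray(groups)
    uniq = sorted(set(labels.tolist()))
    codes = np.searchsorted(np.array(uniq), labels)
    return codes, uniq


def _group_masks(codes_matrix: np.ndarray, n_groups: int) -> list[np.ndarray]:
    return [(codes_matrix == g).astype(float) for g in range(n_groups)]


def _permuted_codes(codes: np.ndarray, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    reps = np.tile(codes, (n_perm, 1))
    return rng.permuted(reps, axis=1)


def _ss_within(Dsq: np.ndarray, codes_matrix: np.ndarray, n_groups: int) -> np.ndarray:
    """Within-group sum of squared distances / n_g, rows = permutations."""
    out = np.zeros(codes_matrix.shape[0])
    for g in range(n_groups):
        M = (codes_matrix == g).astype(float)
        n_g = M.sum(axis=1)
        quad = ((M @ Dsq) * M).sum(axis=1) / 2.0
        out += quad / n_g
    return out


def permanova(
    dist: pd.DataFrame,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermutationTestResult:
    """One-way PERMANOVA pseudo-F with unrestricted permutation of samples.

    Partitions the total sum of squared distances into between- and
    within-group components; the pseudo-F null distribution comes from
    permuting group labels over raw observations.
    """
    D = np.asarray(dist, dtype=float)
    n = D.shape[0]
    codes, uniq = _as_groups(groups)
    a = len(uniq)
    if a < 2 or np.bincount(codes).min() < 2:
        raise ValueError("PERMANOVA needs >= 2 groups with >= 2 samples each")
    Dsq = D**2
    if Dsq.sum() == 0:
        raise ValueError("degenerate all-zero distance matrix")
    ss_total = Dsq.sum() / (2.0 * n)
    ss_within = _ss_within(Dsq, codes[None, :], a)[0]
    ss_between = ss_total - ss_within
    f_obs = (ss_between / (a - 1)) / (ss_within / (n - a))
    rng = np.random.default_rng(seed)
    perm_codes = _permuted_codes(codes, n_perm, rng)
    ss_w = _ss_within(Dsq, perm_codes, a)
    f_perm = ((ss_total - ss_w) / (a - 1)) / (ss_w / (n - a))
    p = (1.0 + np.sum(f_perm >= f_obs)) / (1.0 + n_perm)
    return PermutationTestResult(
        statistic=float(f_obs),
        p_value=float(p),
        n_permutations=n_perm,
        explained_variation=float(100.0 * ss_between / ss_total),
    )


def _pcoa_dispersion(D: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    """Distance of each sample to its group's spatial centroid.

    Principal-coordinates embedding with the standard imaginary-part
    correction: squared distances along negative-eigenvalue axes subtract
    from the real part (clamped at zero before the square root).
    """
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D**2) @ J
    G = (G + G.T) / 2.0
    eigval, eigvec = np.linalg.eigh(G)
    coords = eigvec * np.sqrt(np.abs(eigval))[None, :]
    pos = eigval > 1e-10
    neg = eigval < -1e-10
    zsq = np.zeros(n)
    for g in range(n_groups):
        idx = codes == g
        c = coords[idx].mean(axis=0)
        dev = coords[idx] - c
        zsq[idx] = (dev[:, pos] ** 2).sum(axis=1) - (dev[:, neg] ** 2).sum(axis=1)
    return np.sqrt(np.clip(zsq, 0.0, None))


def _anova_f(values_matrix: np.ndarray, codes_matrix: np.ndarray, n_groups: int) -> np.ndarray:
    """Row-wise one-way ANOVA F; rows pair values with label assignments."""
    n = values_matrix.shape[1]
    grand = values_matrix.mean(axis=1, keepdims=True)
    ssb = np.zeros(values_matrix.shape[0])
    ssw = np.zeros(values_matrix.shape[0])
    for g in range(n_groups):
        M = codes_matrix == g
        n_g = M.sum(axis=1)
        mean_g = (values_matrix * M).sum(axis=1) / n_g
        ssb += n_g * (mean_g - grand.ravel()) ** 2
        ssw += ((values_matrix - mean_g[:, None]) ** 2 * M).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (ssb / (n_groups - 1)) / (ssw / (n - n_groups))


def permdisp(
    dist: pd.DataFrame,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermutationTestResult:
    """Homogeneity of multivariate dispersions (distance to group centroid).

    Embeds samples by PCoA, computes each sample's distance to its group
    spatial centroid, and tests the one-way F on those distances by
    permuting the least-squares residuals.
    """
    D = np.asarray(dist, dtype=float)
    codes, uniq = _as_groups(groups)
    a = len(uniq)
    if a < 2 or np.bincount(codes).min() < 2:
        raise ValueError("PERMDISP needs >= 2 groups with >= 2 samples each")
    z = _pcoa_dispersion(D, codes, a)
    f_obs = _anova_f(z[None, :], codes[None, :], a)[0]
    group_means = np.array([z[codes == g].mean() for g in range(a)])
    resid = z - group_means[codes]
    rng = np.random.default_rng(seed)
    perm_resid = _permuted_codes(np.arange(z.size), n_perm, rng)
    f_perm = _anova_f(resid[perm_resid], np.tile(codes, (n_perm, 1)), a)
    if not np.isfinite(f_obs):
        raise ValueError("dispersion F undefined (degenerate grouping)")
    p = (1.0 + np.sum(f_perm >= f_obs)) / (1.0 + n_perm)
    return PermutationTestResult(float(f_obs), float(p), n_perm)


def _indval_components(
    X: np.ndarray,
    pres: np.ndarray,
    codes_matrix: np.ndarray,
    n_groups: int,
    group_equalized: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """IndVal, A, B per (permutation row, group, OTU).

    Group-equalized specificity uses group mean abundances (multipatt's
    IndVal.g); the raw variant uses group total abundances.
    """
    P, n = codes_matrix.shape
    p_otus = X.shape[1]
    abun = np.empty((P, n_groups, p_otus))
    fidelity = np.empty((P, n_groups, p_otus))
    for g in range(n_groups):
        M = (codes_matrix == g).astype(float)
        n_g = M.sum(axis=1)[:, None]
        sums = M @ X
        abun[:, g, :] = sums / n_g if group_equalized else sums
        fidelity[:, g, :] = (M @ pres) / n_g
    denom = abun.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        A = np.where(denom > 0, abun / denom, 0.0)
    return np.sqrt(A * fidelity), A, fidelity


def indicator_species(
    table: pd.DataFrame,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
    group_equalized: bool = True,
) -> pd.DataFrame:
    """Indicator value analysis (IndVal) of every OTU against sample groups.

    For OTU i and group g, specificity A is the group's share of mean
    abundance (group-equalized variant; the raw variant uses group sums) and
    fidelity B is the fraction of the group's samples where i occurs.
    IndVal = sqrt(A * B); the per-OTU p-value permutes group labels against
    the max-over-groups IndVal statistic.

    Returns one row per OTU: best group, A, B, indval, p_value.
    """
    X = table.to_numpy(dtype=float)
    codes, uniq = _as_groups(groups)
    a = len(uniq)
    if a < 2:
        raise ValueError("indicator analysis needs >= 2 groups")
    pres = (X > 0).astype(float)
    iv3, A3, B3 = _indval_components(X, pres, codes[None, :], a, group_equalized)
    iv, A_all, B_all = iv3[0], A3[0], B3[0]  # groups x OTUs
    obs_max = iv.max(axis=0)
    best_g = iv.argmax(axis=0)
    rng = np.random.default_rng(seed)
    perm_codes = _permuted_codes(codes, n_perm, rng)
    iv_perm = _indval_components(X, pres, perm_codes, a, group_equalized)[0].max(
        axis=1
    )  # P x OTUs
    p = (1.0 + (iv_perm >= obs_max[None, :] - 1e-12).sum(axis=0)) / (1.0 + n_perm)
    idx = np.arange(X.shape[1])
    return pd.DataFrame(
        {
            "group": [uniq[g] for g in best_g],
            "specificity": A_all[best_g, idx],
            "fidelity": B_all[best_g, idx],
            "indval": obs_max,
            "p_value": p,
        },
        index=table.columns,
    )
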