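"""Network comparison across management groups.

Node-attribute distributions are compared between group networks with the
two-sample Kolmogorov-Smirnov test (applied to raw per-node attribute
vectors by default; a bootstrap-then-KS mode reproduces the older workflow
but inflates the effective sample size, so it is off by default). Per-farm
connectivity is the mean degree of the group network induced on the OTUs
observed in that farm, regressed on the farm's agricultural-intensity index
by ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "bootstrap_attribute",
    "ks_two_sample",
    "KsResult",
    "farm_subgraph_connectivity",
    "connectivity_vs_intensity",
    "pairwise_attribute_tests",
]


@dataclass
class KsResult:
    d_statistic: float
    p_value: float
    n_a: int
    n_b: int


def bootstrap_attribute(
    values, n_iter: int = 10000, seed: int | None = None
) -> dict:
    """Bootstrap resampling of a node-attribute vector.

    Draws ``n_iter`` resamples with replacement of the same size and returns
    the resampled means with their percentile confidence interval.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot bootstrap an empty attribute vector")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(n_iter, v.size))
    means = v[idx].mean(axis=1)
    return {
        "mean": float(v.mean()),
        "boot_means": means,
        "ci_low": float(np.percentile(means, 2.5)),
        "ci_high": float(np.percentile(means, 97.5)),
    }


def ks_two_sample(a, b) -> KsResult:
    """Two-sample KS test: D = sup |F_a - F_b|, asymptotic p-value.

    The p-value uses the asymptotic Kolmogorov distribution at the
    effective sample size n_a * n_b / (n_a + n_b).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    d = float(stats.ks_2samp(a, b, method="asymp").statistic)
    ne = a.size * b.size / (a.size + b.size)
    p = float(special.kolmogorov(np.sqrt(ne) * d))
    return KsResult(d_statistic=d, p_value=min(p, 1.0), n_a=a.size, n_b=b.size)


def farm_subgraph_connectivity(
    net: nx.Graph, table: pd.DataFrame, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Mean degree of the group network induced on each farm's OTUs.

    For every sample (farm) in ``table``, the network is restricted to the
    OTUs with nonzero counts in that farm and connectivity is the mean
    degree within that induced subgraph (0 when no network OTU occurs).
    Returns one row per farm with its system label and intensity index when
    available in ``metadata``.
    """
    missing = [s for s in table.index if s not in metadata.index]
    if missing:
        raise ValueError(f"farms absent from metadata: {missing}")
    rows = []
    node_set = set(net.nodes)
    for farm in table.index:
        present = set(table.columns[table.loc[farm].to_numpy() > 0]) & node_set
        if present:
            sub = net.subgraph(present)
            degs = [d for _, d in sub.degree()]
            conn = float(np.mean(degs)) if degs else 0.0
        else:
            conn = 0.0
        rows.append(
            {
                "farm": farm,
                "connectivity": conn,
                "system": metadata.loc[farm].get("system"),
                "intensity": metadata.loc[farm].get("intensity_index", np.nan),
            }
        )
    return pd.DataFrame(rows).set_index("farm")


def connectivity_vs_intensity(conn: pd.DataFrame) -> dict:
    """OLS of per-farm connectivity on agricultural intensity.

    Returns slope, R^2, and the slope's t-test p-value. Requires at least
    3 farms with finite values and non-degenerate intensity.
    """
    df = conn.dropna(subset=["connectivity", "intensity"])
    if len(df) < 3:
        raise ValueError("need >= 3 farms with finite connectivity and intensity")
    x = df["intensity"].to_numpy(dtype=float)
    y = df["connectivity"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("intensity has zero variance")
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue**2),
        "p_value": float(res.pvalue),
        "n": int(len(df)),
    }


def pairwise_attribute_tests(
    attrs_by_group: dict[str, pd.DataFrame],
    attribute: str = "degree",
    bootstrap: bool = False,
    n_iter: int = 10000,
    seed: int | None = None,
) -> pd.DataFrame:
    """KS comparisons of one node attribute between every pair of groups.

    With ``bootstrap=True`` the KS test runs on bootstrap distributions of
    the attribute (the legacy procedure; note this inflates the effective n
    and deflates p-values). p-values are BH-corrected across the pairs.
    """
    from rhizonet.mic import bh_fdr

    names = sorted(attrs_by_group)
    rows = []
    rng = np.random.default_rng(seed)
    for i, g1 in enumerate(names):
        for g2 in names[i + 1 :]:
            a = attrs_by_group[g1][attribute].to_numpy(dtype=float)
            b = attrs_by_group[g2][attribute].to_numpy(dtype=float)
            if bootstrap:
                a = bootstrap_attribute(a, n_iter, int(rng.integers(2**31)))[
                    "boot_means"
                ]
                b = bootstrap_attribute(b, n_iter, int(rng.integers(2**31)))[
                    "boot_means"
                ]
            ks = ks_two_sample(a, b)
            rows.append(
                {
                    "group_a": g1,
                    "group_b": g2,
                    "attribute": attribute,
                    "d_statistic": ks.d_statistic,
                    "p_value": ks.p_value,
                }
            )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    return out
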