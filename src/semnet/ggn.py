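"""Unsupervised comparison baseline: shrinkage graphical Gaussian network.

Edges of a graphical Gaussian network (GGN) are nonzero partial
correlations — conditional dependencies given all other measured genes.
The correlation matrix is estimated with analytic shrinkage toward the
identity (the unbiased-risk lambda of the Ledoit-Wolf / Schaefer-Strimmer
family), which keeps the estimate invertible even when genes outnumber
samples; partial correlations come from the standardized inverse. Edge
selection is either Benjamini-Hochberg FDR on Fisher-z p-values or a fixed
top-k cutoff on |partial correlation| (the comparisons of interest use
FDR 0.2 and top 20). Networks are undirected throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PartialCorrelationNetwork",
    "shrink_partial_correlations",
    "select_edges",
    "extract_neighborhood",
]


@dataclass(frozen=True)
class PartialCorrelationNetwork:
    pcor: pd.DataFrame       # symmetric, unit diagonal
    lam: float               # shrinkage intensity in [0, 1]
    n: int

    @property
    def labels(self) -> list[str]:
        return list(self.pcor.columns)

    def edge_table(self) -> pd.DataFrame:
        """All unordered pairs with their partial correlations, |pcor| desc."""
        rows = [
            {"a": a, "b": b, "pcor": self.pcor.loc[a, b]}
            for a, b in combinations(self.labels, 2)
        ]
        frame = pd.DataFrame(rows)
        return frame.sort_values(
            by=["pcor", "a", "b"], key=lambda c: -c.abs() if c.name == "pcor" else c
        ).reset_index(drop=True)


def shrink_partial_correlations(data: pd.DataFrame) -> PartialCorrelationNetwork:
    """Shrinkage-regularized partial correlations of a samples x genes frame.

    lambda* = sum of estimated Var(r_ij) over the sum of r_ij^2 (off-diagonal),
    clipped to [0, 1]; the shrunk correlation (1 - lambda) R + lambda I is
    inverted and standardized to partial correlations.
    """
    x = data.to_numpy(dtype=float)
    n, p = x.shape
    if n < 3 or p < 2:
        raise ValueError("need at least 3 samples and 2 variables")
    sd = x.std(axis=0, ddof=1)
    constant = [str(c) for c, s in zip(data.columns, sd) if s == 0]
    if constant:
        raise ValueError(f"constant columns cannot be correlated: {constant}")

    xs = (x - x.mean(axis=0)) / sd
    r = (xs.T @ xs) / (n - 1)
    np.fill_diagonal(r, 1.0)

    # unbiased-risk shrinkage intensity toward the identity target:
    # var(r_ij) estimated from the empirical spread of the per-sample
    # products w_kij = xs_ki * xs_kj
    w_mean = r * (n - 1) / n
    var_sum = 0.0
    r2_sum = 0.0
    for j in range(1, p):
        w = xs[:, :j] * xs[:, j:j + 1]  # n x j block of products
        var_w = np.sum((w - w_mean[:j, j]) ** 2, axis=0)
        var_sum += float(np.sum(var_w)) * n / (n - 1) ** 3
        r2_sum += float(np.sum(r[:j, j] ** 2))
    lam = 1.0 if r2_sum == 0 else min(1.0, max(0.0, var_sum / r2_sum))

    r_shrunk = (1.0 - lam) * r
    np.fill_diagonal(r_shrunk, 1.0)
    omega = np.linalg.inv(r_shrunk)
    d = np.sqrt(np.diag(omega))
    pcor = -omega / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    pcor = np.clip((pcor + pcor.T) / 2.0, -1.0, 1.0)

    labels = [str(c) for c in data.columns]
    return PartialCorrelationNetwork(
        pcor=pd.DataFrame(pcor, index=labels, columns=labels), lam=lam, n=n
    )


def select_edges(
    network: PartialCorrelationNetwork, method: str, cutoff: float
) -> pd.DataFrame:
    """Select GGN edges by FDR (q <= cutoff) or by the top-k largest |pcor|.

    FDR mode: Fisher z statistics with effective sample size
    kappa = max(n - p - 1, 3) (each partial correlation conditions on the
    other p - 2 genes), two-sided normal p-values, Benjamini-Hochberg
    q-values. Top-k ties are broken lexicographically.
    """
    table = network.edge_table()
    p = len(network.labels)
    if method == "topk":
        k = int(cutoff)
        if k < 0:
            raise ValueError("top-k cutoff must be nonnegative")
        return table.head(min(k, len(table))).reset_index(drop=True)
    if method != "fdr":
        raise ValueError(f"unknown selection method {method!r}")
    if not 0 < cutoff <= 1:
        raise ValueError("FDR cutoff must be in (0, 1]")

    kappa = max(network.n - p - 1, 3)
    z = np.arctanh(np.clip(table["pcor"].to_numpy(), -1 + 1e-12, 1 - 1e-12))
    pvals = 2.0 * stats.norm.sf(np.abs(z) * np.sqrt(kappa))
    order = np.argsort(pvals, kind="stable")
    m = len(pvals)
    q = np.empty(m)
    prev = 1.0
    for rank, i in enumerate(order[::-1]):
        rank_i = m - rank
        prev = min(prev, pvals[i] * m / rank_i)
        q[i] = prev
    table = table.assign(p_value=pvals, q_value=q)
    return table[table["q_value"] <= cutoff].reset_index(drop=True)


def extract_neighborhood(
    edges: pd.DataFrame | list[tuple[str, str]],
    seed_genes: list[str],
    steps: int,
    nodes: list[str] | None = None,
) -> tuple[nx.Graph, dict[str, int]]:
    """Breadth-first k-step neighborhood of seed genes on an undirected edge set.

    Returns the induced subgraph and each retained node's step distance from
    the nearest seed. Seeds absent from the edge set are kept as isolated
    nodes; if a node universe is supplied, unknown seeds raise.
    """
    if steps not in (1, 2):
        raise ValueError("steps must be 1 or 2")
    if isinstance(edges, pd.DataFrame):
        pairs = list(zip(edges["a"], edges["b"]))
    else:
        pairs = list(edges)
    g = nx.Graph(pairs)
    if nodes is not None:
        g.add_nodes_from(nodes)
        unknown = [s for s in seed_genes if s not in g]
        if unknown:
            raise KeyError(f"unknown seed genes: {unknown}")
    g.add_nodes_from(seed_genes)

    dist: dict[str, int] = {}
    for s in seed_genes:
        for node, d in nx.single_source_shortest_path_length(g, s, cutoff=steps).items():
            if node not in dist or d < dist[node]:
                dist[node] = d
    return g.subgraph(dist).copy(), dist
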