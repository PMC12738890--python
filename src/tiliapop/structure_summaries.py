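"""PCoA ordination, UPGMA clustering, and the Evanno delta-K statistic.

The Bayesian clustering itself (STRUCTURE) is an external tool; this module
only post-processes: it ordinates a genetic distance matrix (classical
metric MDS / PCoA), builds the average-linkage population dendrogram with
ultrametric branch lengths, and computes Evanno's delta-K from a table of
replicate log-likelihoods per K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .popgen_stats import DistanceMatrix

__all__ = [
    "PCoAResult",
    "UPGMATree",
    "DeltaKResult",
    "pcoa",
    "upgma",
    "evanno_delta_k",
]


# ---------------------------------------------------------------------------
# PCoA (classical metric MDS)
# ---------------------------------------------------------------------------


@dataclass
class PCoAResult:
    """Principal-coordinate ordination of a distance matrix.

    ``coordinates`` has one row per entity and one column per retained axis
    (positive eigenvalues only), ordered by descending eigenvalue.
    ``eigenvalues`` includes negative ones (reported, never embedded);
    ``percent_variance`` is each positive eigenvalue as a percentage of the
    positive-eigenvalue total.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    percent_variance: np.ndarray


def pcoa(dm: DistanceMatrix, n_axes: int = 3) -> PCoAResult:
    """Gower double-centering of -d^2/2 followed by eigendecomposition.

    Coordinates are eigenvectors scaled by the square root of their
    eigenvalue; axes with non-positive eigenvalues are excluded from the
    coordinates but their eigenvalues are still reported.
    """
    if n_axes < 1:
        raise ValueError("n_axes must be >= 1")
    d = dm.values
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ a @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = 1e-12 * max(abs(evals[0]), 1.0)
    pos = evals > tol
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    k = min(n_axes, coords.shape[1])
    pos_sum = evals[pos].sum()
    pct = 100.0 * evals[pos] / pos_sum if pos_sum > 0 else np.zeros(0)
    cols = [f"Axis{i + 1}" for i in range(k)]
    return PCoAResult(
        coordinates=pd.DataFrame(coords[:, :k], index=dm.labels, columns=cols),
        eigenvalues=evals,
        percent_variance=pct[:k],
    )


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------


@dataclass
class _Node:
    labels: tuple[str, ...]
    height: float
    newick: str


@dataclass
class UPGMATree:
    """Rooted ultrametric average-linkage tree over population labels.

    Ultrametricity holds by construction: every leaf sits at height 0 and
    each merge is placed at half the average-linkage distance, so all
    root-to-leaf path lengths equal ``height``.
    """

    newick: str
    height: float
    leaf_labels: list[str]
    merge_heights: list[float]


def upgma(dm: DistanceMatrix) -> UPGMATree:
    """Average-linkage clustering with ultrametric heights (= half the
    merge distance).

    Ties in the minimum distance are broken by merging the pair whose
    sorted label tuple is lexicographically smallest, so the output is
    stable across runs. Branch lengths are written with 6 decimals.
    """
    labels = list(dm.labels)
    if len(labels) < 2:
        raise ValueError("need at least two labels")
    if np.isnan(dm.values).any():
        raise ValueError("distance matrix contains NaN")
    nodes: dict[tuple[str, ...], _Node] = {
        (l,): _Node((l,), 0.0, l) for l in labels
    }
    dist: dict[frozenset[tuple[str, ...]], float] = {}
    keys = list(nodes)
    for i, a in enumerate(keys):
        for b in keys[i + 1 :]:
            dist[frozenset((a, b))] = float(
                dm.values[labels.index(a[0]), labels.index(b[0])]
            )
    merge_heights = []
    while len(nodes) > 1:
        best = None
        for pair, d in dist.items():
            a, b = sorted(pair)
            key = (d, a, b)
            if best is None or key < best:
                best = key
        d, a, b = best
        na, nb = nodes.pop(a), nodes.pop(b)
        h = d / 2.0
        merge_heights.append(h)
        new_labels = tuple(sorted(na.labels + nb.labels))
        children = sorted([na, nb], key=lambda nd: nd.labels)
        parts = ",".join(
            f"{ch.newick}:{h - ch.height:.6f}" for ch in children
        )
        new = _Node(new_labels, h, f"({parts})")
        # average linkage: weighted by cluster sizes
        for other in list(nodes):
            da = dist.pop(frozenset((a, other)))
            db = dist.pop(frozenset((b, other)))
            wa, wb = len(na.labels), len(nb.labels)
            dist[frozenset((new_labels, other))] = (wa * da + wb * db) / (wa + wb)
        del dist[frozenset((a, b))]
        nodes[new_labels] = new
    root = next(iter(nodes.values()))
    return UPGMATree(
        newick=root.newick + ";",
        height=root.height,
        leaf_labels=labels,
        merge_heights=merge_heights,
    )


# ---------------------------------------------------------------------------
# Evanno delta-K
# ---------------------------------------------------------------------------


@dataclass
class DeltaKResult:
    """Evanno table: per K, mean/sd of L(K) over runs and delta-K."""

    table: pd.DataFrame
    best_k: int
    flags: list[str]


def evanno_delta_k(logliks: pd.DataFrame) -> DeltaKResult:
    """Delta-K = |L(K+1) - 2 L(K) + L(K-1)| / sd(L(K)) over replicate runs.

    ``logliks`` needs columns ``K`` and ``L`` (a ``run`` column is allowed
    and ignored). Requires at least 3 consecutive K values with >= 2 runs
    each. K values where the replicate sd is zero get an undefined (NaN)
    delta-K and a flag rather than a silent infinity. The reported
    ``best_k`` maximizes delta-K over interior K with defined values.
    """
    if not {"K", "L"}.issubset(logliks.columns):
        raise ValueError("log-likelihood table needs columns 'K' and 'L'")
    grp = logliks.groupby("K")["L"]
    mean, sd, nruns = grp.mean(), grp.std(ddof=1), grp.size()
    ks = np.array(sorted(mean.index))
    if ks.size < 3 or np.any(np.diff(ks) != 1):
        raise ValueError("need >= 3 consecutive K values")
    if (nruns < 2).any():
        raise ValueError("need >= 2 replicate runs per K")
    flags: list[str] = []
    rows = []
    for k in ks:
        dk = np.nan
        if ks[0] < k < ks[-1]:
            second = mean[k + 1] - 2 * mean[k] + mean[k - 1]
            if sd[k] == 0:
                flags.append(f"K={k}: zero replicate sd, delta-K undefined")
            else:
                dk = abs(second) / sd[k]
        rows.append(
            {"K": int(k), "mean_L": mean[k], "sd_L": sd[k], "n_runs": int(nruns[k]), "delta_K": dk}
        )
    table = pd.DataFrame(rows).set_index("K")
    defined = table["delta_K"].dropna()
    if defined.empty:
        raise ValueError("delta-K undefined at every interior K")
    return DeltaKResult(table=table, best_k=int(defined.idxmax()), flags=flags)
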