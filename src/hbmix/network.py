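"""Sparse Gaussian graphical model estimation and community detection.

The co-exposure network is the conditional-dependence graph of the
preprocessed biomarker panel: nodes are biomarkers, an edge means the
two biomarkers are dependent given all the others.  Estimation uses
the graphical lasso (L1-penalized precision estimation) along a path
of 10 equally spaced penalties from the empty-graph penalty down to
10% of it.  The penalty is chosen by stability selection (StARS):
refit on random subsamples and keep the densest graph whose average
edge instability stays within a threshold (default 0.1).  The selected
graph is partitioned into communities with the walktrap algorithm
(4-step random-walk distances, agglomerative merging, dendrogram cut
at maximum modularity).
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.covariance import graphical_lasso as _sk_graphical_lasso

__all__ = [
    "lambda_path",
    "fit_glasso",
    "partial_correlations",
    "stars_select",
    "StarsResult",
    "NetworkModel",
    "estimate_network",
    "CommunityAssignment",
    "walktrap_communities",
    "export_network",
]

#: entries of the estimated precision below this magnitude count as zero
EDGE_TOL = 1e-8


def _check_correlation(S: np.ndarray) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("S must be a square matrix")
    if S.shape[0] < 2:
        raise ValueError("need at least 2 biomarkers")
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("S must be symmetric")
    if not np.allclose(np.diag(S), 1.0, atol=1e-8):
        raise ValueError("S must have unit diagonal (a correlation matrix)")
    return S


def lambda_path(S: np.ndarray, n_lambdas: int = 10, min_fraction: float = 0.1) -> np.ndarray:
    """Equally spaced penalty path from the empty-graph penalty down.

    The largest penalty is ``max |S_ij|`` over off-diagonal entries (at
    which the graphical lasso returns an empty graph); the smallest is
    ``min_fraction`` of it.  Returned in descending order.
    """
    S = _check_correlation(S)
    off = np.abs(S - np.diag(np.diag(S)))
    lam_max = off.max()
    if lam_max <= 0:
        raise ValueError("no dependence signal: all off-diagonal correlations are zero")
    return np.linspace(lam_max, min_fraction * lam_max, n_lambdas)


def fit_glasso(
    S: np.ndarray,
    lam: float,
    tol: float = 1e-6,
    max_iter: int = 1000,
    mode: str = "lars",
) -> np.ndarray:
    """L1-penalized maximum-likelihood precision estimate.

    Maximizes ``log det(K) - tr(S K) - lam * ||K||_1(off-diagonal)``.
    At ``lam = 0`` this is the unpenalized MLE ``inv(S)``.  The default
    LARS inner solver converges to high entry-wise accuracy; the
    coordinate-descent mode (``mode="cd"``) is much faster and is used
    for the StARS subsample refits, where only the edge pattern
    matters.  Convergence failures are reported as warnings carrying
    the achieved duality gap.
    """
    S = _check_correlation(S)
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if lam == 0:
        return np.linalg.inv(S)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        _, precision = _sk_graphical_lasso(S, alpha=float(lam), tol=tol,
                                           max_iter=max_iter, mode=mode)
    for w in caught:
        if "did not converge" in str(w.message):
            warnings.warn(
                f"graphical lasso did not converge at lambda={lam:.4g}: {w.message}",
                stacklevel=2,
            )
    return 0.5 * (precision + precision.T)


def partial_correlations(precision: np.ndarray) -> np.ndarray:
    """Partial-correlation matrix ``-K_ij / sqrt(K_ii K_jj)`` with unit diagonal."""
    K = np.asarray(precision, dtype=float)
    d = np.sqrt(np.diag(K))
    P = -K / np.outer(d, d)
    np.fill_diagonal(P, 1.0)
    return P


def _adjacency(precision: np.ndarray) -> np.ndarray:
    A = np.abs(precision) > EDGE_TOL
    np.fill_diagonal(A, False)
    return A


@dataclasses.dataclass
class StarsResult:
    lambdas: np.ndarray
    instability: np.ndarray           # raw D(lambda), sparse end first
    monotonized: np.ndarray           # running max from the sparse end
    selected_lambda: float
    selected_index: int
    edge_frequencies: np.ndarray      # per-lambda p x p subsample edge frequencies
    no_stable_graph: bool = False


def stars_select(
    data: np.ndarray | pd.DataFrame,
    lambdas: np.ndarray | None = None,
    n_subsamples: int = 20,
    subsample_size: int | None = None,
    threshold: float = 0.1,
    seed: int = 0,
    fit_tol: float = 1e-3,
    fit_max_iter: int = 100,
) -> StarsResult:
    """Stability selection of the graphical-lasso penalty (StARS).

    For each penalty, the graph is refit on ``n_subsamples`` random
    subsamples without replacement (default size ``floor(10 sqrt(n))``).
    Edge instability is ``2 f (1 - f)`` where ``f`` is the fraction of
    subsamples containing the edge — 0 for an always/never edge, 0.5
    at maximum disagreement.  The per-penalty instability D is the mean
    over all node pairs, monotonized by a running maximum from the
    sparse end of the path.  Selected: the smallest penalty (densest
    graph) whose monotonized D stays within ``threshold``; if none
    qualifies the sparsest penalty is returned with a warning.
    """
    X = np.asarray(data, dtype=float)
    n, p = X.shape
    if lambdas is None:
        lambdas = lambda_path(np.corrcoef(X, rowvar=False))
    lambdas = np.asarray(lambdas, dtype=float)
    if subsample_size is None:
        subsample_size = int(np.floor(10 * np.sqrt(n)))
        subsample_size = min(subsample_size, int(np.floor(0.8 * n)))
    if not 0 < subsample_size < n:
        raise ValueError(f"subsample_size must lie in (0, n); got {subsample_size} for n={n}")
    rng = np.random.default_rng(seed)

    counts = np.zeros((len(lambdas), p, p))
    for _ in range(n_subsamples):
        idx = rng.choice(n, size=subsample_size, replace=False)
        S = np.corrcoef(X[idx], rowvar=False)
        for k, lam in enumerate(lambdas):
            K = fit_glasso(S, lam, tol=fit_tol, max_iter=fit_max_iter, mode="cd")
            counts[k] += _adjacency(K)

    freq = counts / n_subsamples
    xi = 2.0 * freq * (1.0 - freq)
    iu = np.triu_indices(p, k=1)
    instability = np.array([xi[k][iu].mean() for k in range(len(lambdas))])
    monotonized = np.maximum.accumulate(instability)

    ok = np.flatnonzero(monotonized <= threshold)
    if len(ok) == 0:
        warnings.warn("no stable graph at threshold; returning the sparsest penalty",
                      stacklevel=2)
        sel = 0
        no_stable = True
    else:
        sel = int(ok[-1])  # densest qualifying penalty
        no_stable = False
    return StarsResult(
        lambdas=lambdas,
        instability=instability,
        monotonized=monotonized,
        selected_lambda=float(lambdas[sel]),
        selected_index=sel,
        edge_frequencies=freq,
        no_stable_graph=no_stable,
    )


@dataclasses.dataclass
class NetworkModel:
    """Fitted co-exposure network.

    ``precision`` is the graphical-lasso estimate at the StARS-selected
    penalty refit on the full data; ``adjacency`` its off-diagonal
    support; ``partial_correlation`` the scaled negative precision.
    """

    biomarkers: list[str]
    lambdas: np.ndarray
    instability: np.ndarray
    monotonized: np.ndarray
    selected_lambda: float
    precision: pd.DataFrame
    adjacency: pd.DataFrame
    partial_correlation: pd.DataFrame
    edge_frequencies: pd.DataFrame
    no_stable_graph: bool = False

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.to_numpy().sum() // 2)

    def edge_list(self) -> pd.DataFrame:
        A = self.adjacency.to_numpy()
        P = self.partial_correlation.to_numpy()
        rows = []
        names = self.biomarkers
        for i, j in zip(*np.triu_indices_from(A, k=1)):
            if A[i, j]:
                rows.append((names[i], names[j], P[i, j]))
        return pd.DataFrame(rows, columns=["biomarker_a", "biomarker_b", "partial_correlation"])


def estimate_network(
    data: pd.DataFrame,
    n_subsamples: int = 20,
    subsample_size: int | None = None,
    threshold: float = 0.1,
    seed: int = 0,
    final_tol: float = 1e-6,
) -> NetworkModel:
    """Full estimation: penalty path, StARS selection, final refit."""
    names = list(data.columns)
    X = data.to_numpy(dtype=float)
    S = np.corrcoef(X, rowvar=False)
    lambdas = lambda_path(S)
    stars = stars_select(X, lambdas=lambdas, n_subsamples=n_subsamples,
                         subsample_size=subsample_size, threshold=threshold, seed=seed)
    K = fit_glasso(S, stars.selected_lambda, tol=final_tol)
    A = _adjacency(K)
    P = partial_correlations(K)
    sel = stars.selected_index
    return NetworkModel(
        biomarkers=names,
        lambdas=stars.lambdas,
        instability=stars.instability,
        monotonized=stars.monotonized,
        selected_lambda=stars.selected_lambda,
        precision=pd.DataFrame(K, index=names, columns=names),
        adjacency=pd.DataFrame(A, index=names, columns=names),
        partial_correlation=pd.DataFrame(P, index=names, columns=names),
        edge_frequencies=pd.DataFrame(stars.edge_frequencies[sel], index=names, columns=names),
        no_stable_graph=stars.no_stable_graph,
    )


# ---------------------------------------------------------------------------
# walktrap community detection
# ---------------------------------------------------------------------------

_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
          "XI", "XII", "XIII", "XIV", "XV", "XVI", "XVII", "XVIII", "XIX", "XX"]


def _roman(i: int) -> str:
    return _ROMAN[i] if i < len(_ROMAN) else f"C{i + 1}"


@dataclasses.dataclass
class CommunityAssignment:
    """Partition of the network nodes into communities.

    Groups smaller than ``min_size`` are not called communities; their
    members are listed under ``singletons`` with ``community_of`` None.
    """

    community_of: dict[str, str | None]
    min_size: int
    modularity: float

    @property
    def communities(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for node, lab in self.community_of.items():
            if lab is not None:
                out.setdefault(lab, []).append(node)
        return out

    @property
    def singletons(self) -> list[str]:
        return [n for n, lab in self.community_of.items() if lab is None]

    @property
    def n_communities(self) -> int:
        return len(self.communities)

    def labels(self, nodes: list[str]) -> np.ndarray:
        """Integer labels for ARI-style comparisons (singletons get
        unique negative labels)."""
        labs = sorted(self.communities)
        lab_id = {lab: i for i, lab in enumerate(labs)}
        out = np.empty(len(nodes), dtype=int)
        next_single = -1
        for i, n in enumerate(nodes):
            lab = self.community_of[n]
            if lab is None:
                out[i] = next_single
                next_single -= 1
            else:
                out[i] = lab_id[lab]
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"community": [self.community_of[n] for n in self.community_of]},
            index=pd.Index(list(self.community_of), name="biomarker"),
        )


def _modularity(adj: np.ndarray, membership: np.ndarray, weights: np.ndarray) -> float:
    """Newman modularity of a partition on a (possibly weighted) graph."""
    W = weights
    m2 = W.sum()  # = 2m
    if m2 == 0:
        return 0.0
    deg = W.sum(axis=1)
    q = 0.0
    for c in np.unique(membership):
        mask = membership == c
        q += W[np.ix_(mask, mask)].sum() / m2 - (deg[mask].sum() / m2) ** 2
    return float(q)


def walktrap_communities(
    adjacency: pd.DataFrame | np.ndarray,
    steps: int = 4,
    min_size: int = 3,
    weights: pd.DataFrame | np.ndarray | None = None,
) -> CommunityAssignment:
    """Walktrap community detection (random-walk agglomeration).

    Each node's ``steps``-step random-walk probability profile defines
    a distance; communities are merged bottom-up by the Ward-style
    criterion restricted to pairs of communities joined by at least one
    edge (so connected components are never merged together), and the
    dendrogram is cut at the partition of maximum modularity (ties go
    to the cut with fewer communities).  Isolated nodes and groups
    smaller than ``min_size`` are reported as singletons.
    """
    if isinstance(adjacency, pd.DataFrame):
        names = list(adjacency.columns)
        A = adjacency.to_numpy().astype(bool)
    else:
        A = np.asarray(adjacency).astype(bool)
        names = [f"B{i + 1:02d}" for i in range(A.shape[0])]
    if A.shape[0] != A.shape[1] or not np.array_equal(A, A.T):
        raise ValueError("adjacency must be square and symmetric")
    if np.diag(A).any():
        raise ValueError("adjacency must have no self-loops")
    n = A.shape[0]
    if weights is None:
        W = A.astype(float)
    else:
        W = np.asarray(weights, dtype=float) * A
        W = np.abs(W)

    deg = W.sum(axis=1)
    active = deg > 0
    membership = np.arange(n)

    if active.sum() >= 2 and W[np.ix_(active, active)].sum() > 0:
        idx = np.flatnonzero(active)
        Wa = W[np.ix_(idx, idx)]
        da = Wa.sum(axis=1)
        P = Wa / da[:, None]
        Pt = np.linalg.matrix_power(P, steps)
        inv_d = 1.0 / da

        # community state: profile = mean member row of Pt, size, members
        m = len(idx)
        profiles = Pt.copy()
        sizes = np.ones(m, dtype=int)
        comm_adj = Wa > 0
        alive = np.ones(m, dtype=bool)
        members: list[list[int]] = [[i] for i in range(m)]
        merges: list[tuple[int, int]] = []

        def dist2(a: int, b: int) -> float:
            diff = profiles[a] - profiles[b]
            return float(np.sum(diff * diff * inv_d))

        total_n = m
        merge_memberships = []
        cur = np.arange(m)
        merge_memberships.append(cur.copy())
        while True:
            pairs = []
            alive_idx = np.flatnonzero(alive)
            for ii, a in enumerate(alive_idx):
                for b in alive_idx[ii + 1:]:
                    if comm_adj[a, b]:
                        ds = (sizes[a] * sizes[b]) / (sizes[a] + sizes[b]) * dist2(a, b) / total_n
                        pairs.append((ds, a, b))
            if not pairs:
                break
            pairs.sort(key=lambda t: (t[0], t[1], t[2]))
            _, a, b = pairs[0]
            # merge b into a
            profiles[a] = (sizes[a] * profiles[a] + sizes[b] * profiles[b]) / (sizes[a] + sizes[b])
            sizes[a] += sizes[b]
            members[a].extend(members[b])
            comm_adj[a] = comm_adj[a] | comm_adj[b]
            comm_adj[:, a] = comm_adj[a]
            comm_adj[a, a] = False
            alive[b] = False
            merges.append((a, b))
            cur = cur.copy()
            cur[np.isin(cur, [b])] = a
            merge_memberships.append(cur.copy())

        # choose the cut with maximum modularity (ties -> fewer communities)
        best_q, best_cut = -np.inf, 0
        for ci, mm in enumerate(merge_memberships):
            memb = membership.copy()
            memb[idx] = mm + n  # distinct labels from isolated nodes
            q = _modularity(A, memb, W)
            if q > best_q + 1e-12 or (abs(q - best_q) <= 1e-12 and
                                      len(np.unique(mm)) < len(np.unique(merge_memberships[best_cut]))):
                best_q, best_cut = q, ci
        final = membership.copy()
        final[idx] = merge_memberships[best_cut] + n
        best_modularity = best_q
    else:
        final = membership
        best_modularity = 0.0

    # group, apply min_size, label by decreasing size (stable tie-break
    # by smallest member index)
    groups: dict[int, list[int]] = {}
    for i, g in enumerate(final):
        groups.setdefault(int(g), []).append(i)
    big = [sorted(v) for v in groups.values() if len(v) >= min_size]
    big.sort(key=lambda g: (-len(g), g[0]))
    community_of: dict[str, str | None] = {nm: None for nm in names}
    for ci, group in enumerate(big):
        for i in group:
            community_of[names[i]] = _roman(ci)
    return CommunityAssignment(community_of=community_of, min_size=min_size,
                               modularity=best_modularity)


def export_network(
    model: NetworkModel,
    communities: CommunityAssignment,
    graphml_path: str | Path,
    edges_csv_path: str | Path,
) -> None:
    """Write the selected graph as GraphML plus an edge-list CSV.

    Edge rows carry the partial correlation and whether both endpoints
    share a community.
    """
    import networkx as nx

    G = nx.Graph()
    for b in model.biomarkers:
        G.add_node(b, community=communities.community_of[b] or "")
    edges = model.edge_list()
    within = []
    for _, row in edges.iterrows():
        ca = communities.community_of[row["biomarker_a"]]
        cb = communities.community_of[row["biomarker_b"]]
        w = ca is not None and ca == cb
        within.append(w)
        G.add_edge(row["biomarker_a"], row["biomarker_b"],
                   partial_correlation=float(row["partial_correlation"]),
                   within_community=bool(w))
    edges["within_community"] = within
    nx.write_graphml(G, str(graphml_path))
    edges.to_csv(edges_csv_path, index=False)
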