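"""Regularized Ising network estimation (eLasso) and centrality.

The undirected network over p binary items is estimated by p node-wise
L1-penalized logistic regressions on the raw {0, 1} scale.  Each node's
neighborhood is selected by the Extended Bayesian Information Criterion

    EBIC_gamma = -2 loglik + k ln(n) + 2 gamma k ln(p - 1),

with k the number of nonzero coefficients, along a decreasing lambda
path; the two directed coefficient estimates per pair are then
symmetrized by the AND rule (edge present only if both regressions keep
it; weight = mean) or the OR rule (present if either keeps it; weight =
mean of the nonzero estimates).

Centrality is expected influence: the signed sum of a node's edge
weights, reported raw and as z-scores across nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import json

import numpy as np
import pandas as pd

from ._lasso import lambda_grid, lasso_logistic_path
from .datatypes import BinaryDataset

DEFAULT_GAMMA = 0.25


@dataclass(frozen=True)
class IsingNetwork:
    """Symmetric signed edge-weight matrix plus node thresholds."""

    labels: tuple
    weights: np.ndarray
    thresholds: np.ndarray
    gamma: float = DEFAULT_GAMMA
    rule: str = "AND"

    def __post_init__(self):
        W = np.asarray(self.weights, dtype=float)
        if not np.array_equal(W, W.T):
            raise ValueError("weight matrix must be exactly symmetric")
        if np.any(np.diag(W) != 0.0):
            raise ValueError("weight matrix must have zero diagonal")
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "weights", W)
        object.__setattr__(self, "thresholds",
                           np.asarray(self.thresholds, dtype=float))

    @property
    def p(self) -> int:
        return len(self.labels)

    def edge_vector(self) -> np.ndarray:
        """Upper-triangle weights as a flat vector (row-major pair order)."""
        iu = np.triu_indices(self.p, k=1)
        return self.weights[iu]

    def to_edgelist(self) -> pd.DataFrame:
        i, j = np.triu_indices(self.p, k=1)
        df = pd.DataFrame({
            "item_a": [self.labels[a] for a in i],
            "item_b": [self.labels[b] for b in j],
            "weight": self.weights[i, j],
        })
        return df[df["weight"] != 0.0].reset_index(drop=True)

    def to_graphml(self, path) -> None:
        import networkx as nx
        g = nx.Graph()
        g.add_nodes_from(self.labels)
        for _, row in self.to_edgelist().iterrows():
            g.add_edge(row["item_a"], row["item_b"],
                       weight=float(row["weight"]),
                       sign="positive" if row["weight"] > 0 else "negative")
        nx.write_graphml(g, path)

    def thresholds_to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dict(zip(self.labels, self.thresholds.tolist())), fh,
                      indent=1)


@dataclass(frozen=True)
class CentralityResult:
    """Per-node expected influence, raw and standardized."""

    labels: tuple
    expected_influence: np.ndarray
    z_scores: np.ndarray

    def ranking(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "item": list(self.labels),
            "expected_influence": self.expected_influence,
            "z_score": self.z_scores,
        })
        return df.sort_values("z_score", ascending=False,
                              kind="stable").reset_index(drop=True)


def fit_nodewise_logistic(data: BinaryDataset, gamma: float = DEFAULT_GAMMA,
                          n_lambda: int = 100, lambda_ratio: float = 0.001,
                          tol: float = 1e-7) -> tuple:
    """EBIC-selected L1 logistic regression of each item on the rest.

    Returns ``(coef_matrix, intercepts)``: ``coef_matrix[j, i]`` is the
    selected coefficient of item i in item j's regression (diagonal 0).
    """
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    if data.n < 10:
        raise ValueError("need at least 10 observations")
    const = data.constant_columns()
    if const:
        raise ValueError(
            f"constant column(s) {const}: conditional model is degenerate")
    X_all = np.asarray(data.values, dtype=np.float64)
    n, p = X_all.shape
    coef = np.zeros((p, p))
    intercepts = np.zeros(p)
    for j in range(p):
        others = [i for i in range(p) if i != j]
        X = np.ascontiguousarray(X_all[:, others])
        y = X_all[:, j]
        lams = lambda_grid(X, y, n_lambda=n_lambda, ratio=lambda_ratio)
        betas, b0s, lls = lasso_logistic_path(X, y, lams, tol, 2000)
        # round-off at the soft-threshold boundary can leave ~1e-16
        # coefficients on the path; they are zeros for model selection
        betas[np.abs(betas) < 10 * tol] = 0.0
        k = (betas != 0.0).sum(axis=1)
        ebic = -2.0 * lls + k * np.log(n) + 2.0 * gamma * k * np.log(p - 1)
        # path runs from lambda_max down; argmin keeps the sparser model on ties
        best = int(np.argmin(ebic))
        coef[j, others] = betas[best]
        intercepts[j] = b0s[best]
    return coef, intercepts


def symmetrize(coef: np.ndarray, intercepts: np.ndarray, labels,
               rule: str = "AND", gamma: float = DEFAULT_GAMMA
               ) -> IsingNetwork:
    """Combine the two directed coefficient estimates per pair into one
    undirected edge weight under the AND or OR rule."""
    if rule not in ("AND", "OR"):
        raise ValueError("rule must be 'AND' or 'OR'")
    B = np.asarray(coef, dtype=float)
    p = B.shape[0]
    W = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            a, b = B[i, j], B[j, i]
            if rule == "AND":
                w = (a + b) / 2.0 if (a != 0.0 and b != 0.0) else 0.0
            else:
                present = [v for v in (a, b) if v != 0.0]
                w = float(np.mean(present)) if present else 0.0
            W[i, j] = W[j, i] = w
    return IsingNetwork(tuple(labels), W, np.asarray(intercepts, dtype=float),
                        gamma=gamma, rule=rule)


def expected_influence(net: IsingNetwork) -> CentralityResult:
    """Signed sum of each node's edge weights, with z-scores across nodes."""
    ei = net.weights.sum(axis=1)
    sd = ei.std(ddof=1) if net.p > 1 else 0.0
    z = (ei - ei.mean()) / sd if sd > 0 else np.zeros_like(ei)
    return CentralityResult(net.labels, ei, z)


def edge_summary(net: IsingNetwork) -> dict:
    """Edge counts and the |weight|-ranked edge list.

    Ties in |weight| are broken lexicographically by (item_a, item_b).
    """
    edges = []
    for i in range(net.p):
        for j in range(i + 1, net.p):
            w = net.weights[i, j]
            if w != 0.0:
                edges.append((net.labels[i], net.labels[j], float(w)))
    edges.sort(key=lambda e: (-abs(e[2]), e[0], e[1]))
    return {
        "total": len(edges),
        "positive": sum(1 for e in edges if e[2] > 0),
        "negative": sum(1 for e in edges if e[2] < 0),
        "max_possible": net.p * (net.p - 1) // 2,
        "ranked_edges": edges,
    }


class IsingModel:
    """Ising network model for a binary item cohort.

    Examples
    --------
    >>> model = IsingModel(cohort)          # doctest: +SKIP
    >>> res = model.fit(gamma=0.25, rule="AND")
    >>> res.centrality().ranking()
    """

    def __init__(self, data: BinaryDataset):
        if not isinstance(data, BinaryDataset):
            data = BinaryDataset.from_dataframe(pd.DataFrame(data))
        self.data = data

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "IsingModel":
        return cls(BinaryDataset.from_dataframe(df))

    def fit(self, gamma: float = DEFAULT_GAMMA, rule: str = "AND",
            n_lambda: int = 100, lambda_ratio: float = 0.001,
            tol: float = 1e-7) -> "IsingResults":
        coef, intercepts = fit_nodewise_logistic(
            self.data, gamma=gamma, n_lambda=n_lambda,
            lambda_ratio=lambda_ratio, tol=tol)
        net = symmetrize(coef, intercepts, self.data.labels, rule=rule,
                         gamma=gamma)
        return IsingResults(self, net, coef)


@dataclass
class IsingResults:
    """Fitted Ising network with centrality and reporting helpers."""

    model: IsingModel
    network: IsingNetwork
    nodewise_coef: np.ndarray = field(repr=False, default=None)

    @property
    def weights(self) -> np.ndarray:
        return self.network.weights

    @property
    def thresholds(self) -> np.ndarray:
        return self.network.thresholds

    @property
    def labels(self) -> tuple:
        return self.network.labels

    def centrality(self) -> CentralityResult:
        return expected_influence(self.network)

    def edge_summary(self) -> dict:
        return edge_summary(self.network)

    def summary(self) -> str:
        es = self.edge_summary()
        cent = self.centrality().ranking()
        lines = [
            "Ising network (eLasso, EBIC gamma=%.2f, %s rule)"
            % (self.network.gamma, self.network.rule),
            "items: %d   observations: %d" % (self.network.p,
                                              self.model.data.n),
            "edges: %d of %d possible (%d positive, %d negative)"
            % (es["total"], es["max_possible"], es["positive"],
               es["negative"]),
            "",
            "strongest edges:",
        ]
        for a, b, w in es["ranked_edges"][:5]:
            lines.append("  %-18s -- %-18s %+.3f" % (a, b, w))
        lines += ["", "expected influence (z-scores):"]
        for _, row in cent.iterrows():
            lines.append("  %-18s %+.3f" % (row["item"], row["z_score"]))
        return "\n".join(lines)
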