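"""Bayesian-network structure learning over binary items.

A directed acyclic graph is learned by greedy hill-climbing on the BIC
score (higher is better),

    BIC = loglik - (ln n / 2) * k,   k = sum_nodes 2^|parents(node)|,

with the multinomial log-likelihood maximized at the empirical
conditional frequencies.  The search starts from the empty graph and
applies the best acyclicity-preserving single-arc addition, deletion or
reversal until no move improves the score; scoring is decomposable, so
each move only re-scores affected children.

The learned structure is stabilized by bootstrap model averaging: many
row-resampled replicates are re-learned, each unordered pair's
*strength* (appearance frequency in either direction) and *directional
probability* are tabulated, pairs above a significance threshold
(Scutari-Nagarajan L1 cutoff, or a fixed 0.5) are retained and oriented
by majority direction, and each retained arc is annotated with its BIC
strength: the score change from deleting it from the final model (more
negative = more structurally important).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import BinaryDataset

DISPLAY_RULE = 0.51


@dataclass(frozen=True)
class DAGStructure:
    """Acyclic directed graph over labelled nodes; arcs are
    (parent, child) label pairs."""

    labels: tuple
    arcs: frozenset

    def __post_init__(self):
        labels = tuple(self.labels)
        arcs = frozenset((str(a), str(b)) for a, b in self.arcs)
        known = set(labels)
        for a, b in arcs:
            if a not in known or b not in known:
                raise ValueError(f"arc ({a}, {b}) uses unknown label")
            if a == b:
                raise ValueError(f"self-arc on {a}")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "arcs", arcs)
        if self.topological_order() is None:
            raise ValueError("arc set contains a cycle")

    @property
    def p(self) -> int:
        return len(self.labels)

    def parents_of(self, label: str) -> tuple:
        return tuple(sorted(a for a, b in self.arcs if b == label))

    def parent_sets(self) -> dict:
        ps = {lab: [] for lab in self.labels}
        for a, b in self.arcs:
            ps[b].append(a)
        return {lab: tuple(sorted(v)) for lab, v in ps.items()}

    def topological_order(self):
        """Kahn's algorithm; None if cyclic."""
        indeg = {lab: 0 for lab in self.labels}
        children = {lab: [] for lab in self.labels}
        for a, b in self.arcs:
            indeg[b] += 1
            children[a].append(b)
        ready = sorted(lab for lab, d in indeg.items() if d == 0)
        order = []
        while ready:
            u = ready.pop(0)
            order.append(u)
            newly = []
            for v in children[u]:
                indeg[v] -= 1
                if indeg[v] == 0:
                    newly.append(v)
            ready = sorted(ready + newly)
        return order if len(order) == len(self.labels) else None


# ---------------------------------------------------------------------
# decomposable BIC scoring


def _config_index(vals: np.ndarray, parents: tuple) -> np.ndarray:
    if not parents:
        return np.zeros(vals.shape[0], dtype=np.int64)
    w = 1 << np.arange(len(parents) - 1, -1, -1)
    return vals[:, list(parents)].astype(np.int64) @ w


def _local_loglik(vals: np.ndarray, child: int, parents: tuple) -> float:
    """Max multinomial log-likelihood of one child given its parents
    (empirical conditional frequencies; 0*log 0 = 0)."""
    idx = _config_index(vals, parents)
    ncfg = 2 ** len(parents)
    n1 = np.bincount(idx, weights=vals[:, child], minlength=ncfg)
    nc = np.bincount(idx, minlength=ncfg).astype(float)
    n0 = nc - n1
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(n1 > 0, n1 * np.log(n1 / nc), 0.0)
        t0 = np.where(n0 > 0, n0 * np.log(n0 / nc), 0.0)
    return float(t1.sum() + t0.sum())


def _local_bic(vals: np.ndarray, child: int, parents: tuple, n: int) -> float:
    return (_local_loglik(vals, child, parents)
            - 0.5 * np.log(n) * 2 ** len(parents))


def _index_parent_sets(dag: DAGStructure, data: BinaryDataset) -> list:
    missing = set(dag.labels) - set(data.labels)
    if missing:
        raise ValueError(f"labels {sorted(missing)} absent from data")
    col = {lab: k for k, lab in enumerate(data.labels)}
    ps = dag.parent_sets()
    return [(col[lab], tuple(sorted(col[a] for a in ps[lab])))
            for lab in dag.labels]


def bn_loglik(dag: DAGStructure, data: BinaryDataset) -> float:
    """Maximized log-likelihood of the network (CPTs at their MLE)."""
    vals = data.values
    return sum(_local_loglik(vals, c, ps)
               for c, ps in _index_parent_sets(dag, data))


def bn_bic(dag: DAGStructure, data: BinaryDataset) -> float:
    """Network BIC, higher is better: loglik - (ln n / 2) * free params."""
    vals = data.values
    n = data.n
    return sum(_local_bic(vals, c, ps, n)
               for c, ps in _index_parent_sets(dag, data))


# ---------------------------------------------------------------------
# hill climbing

_MOVE_RANK = {"add": 0, "delete": 1, "reverse": 2}


class _Searcher:
    """Greedy BIC hill-climber with a local-score cache."""

    def __init__(self, data: BinaryDataset):
        self.vals = data.values
        self.labels = data.labels
        self.n = data.n
        self.p = data.p
        self._cache: dict = {}

    def local(self, child: int, parents: frozenset) -> float:
        key = (child, parents)
        if key not in self._cache:
            self._cache[key] = _local_bic(self.vals, child,
                                          tuple(sorted(parents)), self.n)
        return self._cache[key]

    @staticmethod
    def _reaches(children, src, dst):
        """True if dst is reachable from src along arcs."""
        stack, seen = [src], {src}
        while stack:
            u = stack.pop()
            if u == dst:
                return True
            for v in children[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return False

    def run(self, max_iter: int = 1000):
        p = self.p
        parents = [frozenset() for _ in range(p)]
        children = [set() for _ in range(p)]
        score = sum(self.local(j, parents[j]) for j in range(p))
        trace = [score]
        converged = False
        for _ in range(max_iter):
            best = None  # (gain, rank, parent_label, child_label, apply)
            for u in range(p):
                for v in range(p):
                    if u == v:
                        continue
                    if u in parents[v]:
                        # delete u -> v
                        gain = (self.local(v, parents[v] - {u})
                                - self.local(v, parents[v]))
                        best = self._better(best, gain, "delete", u, v,
                                            ("delete", u, v))
                        # reverse u -> v  (becomes v -> u)
                        children[u].discard(v)
                        ok = not self._reaches(children, u, v)
                        children[u].add(v)
                        if ok:
                            gain = (self.local(v, parents[v] - {u})
                                    - self.local(v, parents[v])
                                    + self.local(u, parents[u] | {v})
                                    - self.local(u, parents[u]))
                            best = self._better(best, gain, "reverse", u, v,
                                                ("reverse", u, v))
                    else:
                        # add u -> v, if it keeps the graph acyclic
                        if not self._reaches(children, v, u):
                            gain = (self.local(v, parents[v] | {u})
                                    - self.local(v, parents[v]))
                            best = self._better(best, gain, "add", u, v,
                                                ("add", u, v))
            if best is None or best[0] <= 1e-12:
                converged = True
                break
            kind, u, v = best[4]
            if kind == "add":
                parents[v] = parents[v] | {u}
                children[u].add(v)
            elif kind == "delete":
                parents[v] = parents[v] - {u}
                children[u].discard(v)
            else:
                parents[v] = parents[v] - {u}
                children[u].discard(v)
                parents[u] = parents[u] | {v}
                children[v].add(u)
            score += best[0]
            trace.append(score)
        arcs = frozenset((self.labels[u], self.labels[v])
                         for v in range(p) for u in parents[v])
        return DAGStructure(self.labels, arcs), score, trace, converged

    def _better(self, best, gain, kind, u, v, move):
        if move is None:
            return best
        key = (-gain, _MOVE_RANK[kind], self.labels[u], self.labels[v])
        if best is None or key < (-best[0], best[1], best[2], best[3]):
            return (gain, _MOVE_RANK[kind], self.labels[u],
                    self.labels[v], move)
        return best


def hill_climb(data: BinaryDataset, max_iter: int = 1000):
    """Learn a DAG by greedy BIC hill-climbing from the empty graph.

    Returns ``(dag, bic, trace, converged)``; ``trace`` is the strictly
    increasing score sequence across accepted moves.  Ties among
    equal-gain moves break lexicographically by
    (add < delete < reverse, parent label, child label).
    """
    if data.n < 10:
        raise ValueError("need at least 10 observations")
    return _Searcher(data).run(max_iter=max_iter)


# ---------------------------------------------------------------------
# bootstrap model averaging


@dataclass(frozen=True)
class ArcTable:
    """Bootstrap arc frequencies per unordered pair.

    ``strength(a, b)`` is the fraction of replicates containing an arc
    between a and b in either direction; ``direction_prob(a, b)`` is,
    among those replicates, the fraction with the arc pointing a -> b.
    """

    labels: tuple
    m: int
    _either: dict = field(repr=False, default_factory=dict)
    _directed: dict = field(repr=False, default_factory=dict)
    redraws: int = 0

    def _key(self, a: str, b: str) -> tuple:
        return tuple(sorted((a, b)))

    def strength(self, a: str, b: str) -> float:
        return self._either.get(self._key(a, b), 0) / self.m

    def direction_prob(self, a: str, b: str) -> float:
        either = self._either.get(self._key(a, b), 0)
        if either == 0:
            return 0.0
        return self._directed.get((a, b), 0) / either

    def pairs(self) -> list:
        """All unordered label pairs, including never-seen ones."""
        labs = self.labels
        return [(labs[i], labs[j]) for i in range(len(labs))
                for j in range(i + 1, len(labs))]

    def strengths(self) -> np.ndarray:
        return np.array([self.strength(a, b) for a, b in self.pairs()])

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for a, b in self.pairs():
            rows.append({"item_a": a, "item_b": b,
                         "strength": self.strength(a, b),
                         "direction_prob_a_to_b": self.direction_prob(a, b)})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, lineterminator="\n")


def bootstrap_dags(data: BinaryDataset, m: int = 10000, seed: int = 0,
                   max_iter: int = 1000, max_redraws: int = 1000) -> ArcTable:
    """Re-learn the structure on ``m`` row-resampled replicates and
    tabulate arc presence/direction frequencies.  Degenerate replicates
    (constant columns) are redrawn and counted."""
    if m < 2:
        raise ValueError("m must be >= 2")
    rng = np.random.default_rng(seed)
    either: dict = {}
    directed: dict = {}
    redraws = 0
    for _ in range(m):
        for _ in range(max_redraws):
            idx = rng.integers(0, data.n, size=data.n)
            boot = BinaryDataset(data.values[idx], data.labels)
            if not boot.constant_columns():
                break
            redraws += 1
        else:
            raise RuntimeError("could not draw a non-degenerate replicate")
        dag, _, _, _ = hill_climb(boot, max_iter=max_iter)
        for a, b in dag.arcs:
            key = tuple(sorted((a, b)))
            either[key] = either.get(key, 0) + 1
            directed[(a, b)] = directed.get((a, b), 0) + 1
    return ArcTable(data.labels, m, either, directed, redraws)


def significance_threshold(strengths) -> float:
    """Scutari-Nagarajan significance cutoff for arc strengths.

    Picks the split of the observed strengths into "noise" (ideally 0)
    and "significant" (ideally 1) whose ideal two-point CDF is closest
    in L1 distance to the empirical CDF; returns the threshold between
    the two groups.  If every strength is equal the threshold is set
    just below that value (everything significant).
    """
    s = np.sort(np.asarray(strengths, dtype=float))
    k = s.size
    if k == 0:
        raise ValueError("need at least one strength value")
    if np.all(s == s[0]):
        return float(s[0]) - 1e-9
    # empirical CDF steps at the order statistics; candidate noise
    # fractions pi = c/k for c = 0..k
    knots = np.concatenate(([0.0], s, [1.0]))
    widths = np.diff(knots)
    cdf = np.concatenate(([0.0], np.arange(1, k + 1) / k))  # value on each interval
    best_c, best_l1 = 0, np.inf
    for c in range(k + 1):
        pi = c / k
        l1 = float(np.sum(np.abs(cdf - pi) * widths))
        if l1 < best_l1 - 1e-12:
            best_l1, best_c = l1, c
    lo = s[best_c - 1] if best_c > 0 else 0.0
    hi = s[best_c] if best_c < k else 1.0
    return float((lo + hi) / 2.0)


@dataclass(frozen=True)
class ArcRecord:
    parent: str
    child: str
    strength: float
    direction_prob: float
    bic_strength: float
    displayed: bool          # direction_prob >= display rule
    bidirectional: bool      # direction_prob < display rule


@dataclass(frozen=True)
class AveragedDAG:
    """Bootstrap-averaged DAG with per-arc annotations."""

    labels: tuple
    arcs: tuple               # ArcRecord, ordered by |bic_strength| desc
    threshold: float
    display_rule: float
    cycle_reversals: tuple = field(default=())

    def structure(self) -> DAGStructure:
        return DAGStructure(self.labels,
                            frozenset((a.parent, a.child) for a in self.arcs))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "parent": a.parent, "child": a.child, "strength": a.strength,
            "direction_prob": a.direction_prob,
            "bic_strength": a.bic_strength,
            "bidirectional_tendency": a.bidirectional} for a in self.arcs])

    def to_dot(self, path) -> None:
        lines = ["digraph averaged {"]
        for lab in self.labels:
            lines.append(f'  "{lab}";')
        for a in self.arcs:
            style = "dashed" if a.bidirectional else "solid"
            lines.append(
                f'  "{a.parent}" -> "{a.child}" '
                f'[label="{a.direction_prob:.2f}", style={style}, '
                f'strength="{a.strength:.3f}", '
                f'bic_strength="{a.bic_strength:.2f}"];')
        lines.append("}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    def to_graphml(self, path) -> None:
        import networkx as nx
        g = nx.DiGraph()
        g.add_nodes_from(self.labels)
        for a in self.arcs:
            g.add_edge(a.parent, a.child, strength=a.strength,
                       direction_prob=a.direction_prob,
                       bic_strength=a.bic_strength)
        nx.write_graphml(g, path)


def arc_bic_strength(dag: DAGStructure, data: BinaryDataset) -> dict:
    """Per-arc BIC(model without the arc) - BIC(model with the arc).

    More negative = removal costs more score = more important.  Only the
    child's local score changes, so the difference is local.
    """
    col = {lab: k for k, lab in enumerate(data.labels)}
    vals, n = data.values, data.n
    ps = dag.parent_sets()
    out = {}
    for a, b in dag.arcs:
        with_par = tuple(sorted(col[x] for x in ps[b]))
        without = tuple(x for x in with_par if x != col[a])
        out[(a, b)] = (_local_bic(vals, col[b], without, n)
                       - _local_bic(vals, col[b], with_par, n))
    return out


def averaged_network(table: ArcTable, data: BinaryDataset,
                     threshold: float | None = None,
                     display_rule: float = DISPLAY_RULE) -> AveragedDAG:
    """Build the averaged DAG: retain pairs above the significance
    threshold (estimated if not given), orient by majority direction,
    resolve any induced cycle by reversing the arc with direction
    probability closest to 0.5, and annotate BIC strengths."""
    if set(table.labels) != set(data.labels):
        raise ValueError("arc table and data labels differ")
    if threshold is None:
        threshold = significance_threshold(table.strengths())
    arcs = {}
    for a, b in table.pairs():
        st = table.strength(a, b)
        if st <= threshold:
            continue
        dp = table.direction_prob(a, b)
        if dp > 0.5 or (dp == 0.5 and (a, b) == tuple(sorted((a, b)))):
            arcs[(a, b)] = (st, dp)
        else:
            arcs[(b, a)] = (st, 1.0 - dp)
    reversals = []
    for _ in range(len(arcs) + 1):
        cyc = _find_cycle_arcs(table.labels, arcs)
        if not cyc:
            break
        flip = min(cyc, key=lambda ab: (abs(arcs[ab][1] - 0.5), ab))
        st, dp = arcs.pop(flip)
        arcs[(flip[1], flip[0])] = (st, 1.0 - dp)
        reversals.append(flip)
    else:
        raise RuntimeError("cycle resolution did not terminate")
    structure = DAGStructure(table.labels, frozenset(arcs))
    bics = arc_bic_strength(structure, data)
    records = tuple(sorted(
        (ArcRecord(a, b, st, dp, bics[(a, b)], dp >= display_rule,
                   dp < display_rule)
         for (a, b), (st, dp) in arcs.items()),
        key=lambda r: (r.bic_strength, r.parent, r.child)))
    return AveragedDAG(table.labels, records, float(threshold),
                       float(display_rule), tuple(reversals))


def _find_cycle_arcs(labels, arcs):
    """Arcs lying on at least one directed cycle."""
    children = {lab: set() for lab in labels}
    for a, b in arcs:
        children[a].add(b)

    def reaches(src, dst):
        stack, seen = [src], {src}
        while stack:
            u = stack.pop()
            if u == dst:
                return True
            for v in children[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return False

    return [ab for ab in arcs if reaches(ab[1], ab[0])]


# ---------------------------------------------------------------------
# model/results surface


class BayesNetModel:
    """Hill-climbing Bayesian-network model for a binary cohort."""

    def __init__(self, data: BinaryDataset):
        if not isinstance(data, BinaryDataset):
            data = BinaryDataset.from_dataframe(pd.DataFrame(data))
        self.data = data

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "BayesNetModel":
        return cls(BinaryDataset.from_dataframe(df))

    def fit(self, max_iter: int = 1000) -> "BayesNetResults":
        dag, bic, trace, converged = hill_climb(self.data, max_iter=max_iter)
        return BayesNetResults(self, dag, bic, tuple(trace), converged)


@dataclass
class BayesNetResults:
    model: BayesNetModel
    dag: DAGStructure
    bic: float
    score_trace: tuple
    converged: bool

    def bootstrap(self, m: int = 10000, seed: int = 0) -> ArcTable:
        return bootstrap_dags(self.model.data, m=m, seed=seed)

    def averaged(self, m: int = 10000, seed: int = 0,
                 threshold: float | None = None,
                 display_rule: float = DISPLAY_RULE) -> AveragedDAG:
        table = self.bootstrap(m=m, seed=seed)
        return averaged_network(table, self.model.data,
                                threshold=threshold,
                                display_rule=display_rule)

    def summary(self) -> str:
        lines = [
            "Bayesian network (BIC hill-climbing)",
            "items: %d   observations: %d" % (self.dag.p, self.model.data.n),
            "BIC: %.3f   arcs: %d   converged: %s"
            % (self.bic, len(self.dag.arcs), self.converged),
            "arcs:",
        ]
        for a, b in sorted(self.dag.arcs):
            lines.append(f"  {a} -> {b}")
        return "\n".join(lines)
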