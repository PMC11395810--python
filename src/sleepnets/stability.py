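"""Bootstrap accuracy and stability of the Ising network.

Three instruments, all nonparametric:

* ``bootstrap_edges`` — row resampling with replacement, full
  re-estimation per replicate, 95% empirical CIs per edge;
* ``difference_test`` — an edge/centrality pair differs significantly
  when the 95% CI of the bootstrapped differences excludes zero;
* ``case_dropping`` + ``cs_coefficient`` — the CS-coefficient is the
  largest fraction of respondents that can be dropped while the
  subsample statistic keeps Pearson correlation >= 0.7 with the
  full-sample statistic with 95% probability.  Values above 0.5 are
  considered stable; below 0.25, unstable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import json

import numpy as np

from .datatypes import BinaryDataset
from .ising import DEFAULT_GAMMA, IsingModel, expected_influence

CS_BANDS = {"ideal_above": 0.5, "not_below": 0.25}

DEFAULT_DROP_GRID = tuple(np.round(np.arange(0.05, 0.751, 0.05), 2))


@dataclass(frozen=True)
class EdgeBootstrap:
    """Bootstrapped edge-weight samples and 95% CIs."""

    labels: tuple
    pairs: tuple                      # (i, j) index pairs, upper triangle
    original: np.ndarray              # full-sample edge weights
    edge_samples: np.ndarray          # (nboots, n_pairs)
    ci_low: np.ndarray
    ci_high: np.ndarray
    redraws: int = 0

    @property
    def nboots(self) -> int:
        return self.edge_samples.shape[0]

    def pair_labels(self) -> list:
        return [(self.labels[i], self.labels[j]) for i, j in self.pairs]

    def samples_for(self, a: str, b: str) -> np.ndarray:
        i, j = sorted((self.labels.index(a), self.labels.index(b)))
        return self.edge_samples[:, self.pairs.index((i, j))]

    def ci_excludes_zero(self) -> np.ndarray:
        return (self.ci_low > 0) | (self.ci_high < 0)


@dataclass(frozen=True)
class StabilityProfile:
    """Correlations between subsample and full-sample statistics across
    case-drop proportions.  NaN marks a degenerate/unavailable replicate."""

    drop_proportions: tuple
    correlations: np.ndarray          # (n_props, reps_per_point)
    statistic: str
    unavailable: tuple = field(default=())

    def __post_init__(self):
        props = tuple(float(q) for q in self.drop_proportions)
        if any(not (0 < q < 1) for q in props):
            raise ValueError("drop proportions must lie in (0, 1)")
        if any(b <= a for a, b in zip(props, props[1:])):
            raise ValueError("drop proportions must be strictly increasing")
        object.__setattr__(self, "drop_proportions", props)
        object.__setattr__(self, "correlations",
                           np.asarray(self.correlations, dtype=float))

    def fraction_above(self, cor_threshold: float = 0.7) -> np.ndarray:
        """Per grid point, the fraction of replicates with correlation
        >= threshold; NaN correlations count as failures."""
        ok = np.where(np.isnan(self.correlations), False,
                      self.correlations >= cor_threshold)
        return ok.mean(axis=1)

    def to_json(self, path, cor_threshold: float = 0.7,
                prob: float = 0.95) -> None:
        qs = np.nanquantile(self.correlations, [0.025, 0.5, 0.975], axis=1)
        payload = {
            "statistic": self.statistic,
            "drop_proportions": list(self.drop_proportions),
            "correlation_quantiles": {
                "q025": qs[0].tolist(), "median": qs[1].tolist(),
                "q975": qs[2].tolist()},
            "fraction_above_threshold": self.fraction_above(
                cor_threshold).tolist(),
            "cs_coefficient": cs_coefficient(self, cor_threshold, prob),
            "interpretation_bands": CS_BANDS,
            "unavailable_points": list(self.unavailable),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _refit(data: BinaryDataset, gamma: float, rule: str):
    return IsingModel(data).fit(gamma=gamma, rule=rule)


def bootstrap_edges(data: BinaryDataset, nboots: int = 1000, seed: int = 0,
                    gamma: float = DEFAULT_GAMMA, rule: str = "AND",
                    max_redraws: int = 1000) -> EdgeBootstrap:
    """Nonparametric bootstrap of all edge weights.

    Each replicate resamples the n rows with replacement and re-estimates
    the whole network with identical settings.  Replicates that produce a
    constant column are redrawn (and counted in ``redraws``).
    """
    if nboots < 2:
        raise ValueError("nboots must be >= 2")
    rng = np.random.default_rng(seed)
    full = _refit(data, gamma, rule)
    p = data.p
    pairs = tuple((i, j) for i in range(p) for j in range(i + 1, p))
    samples = np.empty((nboots, len(pairs)))
    redraws = 0
    for b in range(nboots):
        for _ in range(max_redraws):
            idx = rng.integers(0, data.n, size=data.n)
            boot = BinaryDataset(data.values[idx], data.labels)
            if not boot.constant_columns():
                break
            redraws += 1
        else:
            raise RuntimeError("could not draw a non-degenerate replicate")
        samples[b] = _refit(boot, gamma, rule).network.edge_vector()
    lo, hi = np.quantile(samples, [0.025, 0.975], axis=0)
    return EdgeBootstrap(data.labels, pairs, full.network.edge_vector(),
                         samples, lo, hi, redraws)


def difference_test(samples_a: np.ndarray, samples_b: np.ndarray,
                    level: float = 0.95) -> bool:
    """True when the (1-level) empirical CI of paired bootstrap
    differences a - b excludes zero."""
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("need two equal-length 1-D bootstrap vectors")
    d = a - b
    if np.all(d == 0):
        return False
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(d, [alpha, 1.0 - alpha])
    return bool(lo > 0 or hi < 0)


def _statistic_vector(res, statistic: str) -> np.ndarray:
    if statistic == "expected_influence":
        return expected_influence(res.network).expected_influence
    if statistic == "edge":
        return res.network.edge_vector()
    raise ValueError("statistic must be 'expected_influence' or 'edge'")


def case_dropping(data: BinaryDataset, statistic: str = "expected_influence",
                  drop_grid=DEFAULT_DROP_GRID, reps_per_point: int = 250,
                  seed: int = 0, gamma: float = DEFAULT_GAMMA,
                  rule: str = "AND", min_rows: int = 20) -> StabilityProfile:
    """Case-dropping subsample stability of a network statistic.

    For each drop proportion q, ``reps_per_point`` subsamples of
    ceil((1-q) n) rows are drawn without replacement, the network is
    re-estimated, and the subsample statistic is Pearson-correlated with
    the full-sample statistic.  Degenerate subsamples (constant columns,
    or a constant statistic vector) yield NaN; grid points whose retained
    size falls below ``min_rows`` are flagged unavailable.
    """
    rng = np.random.default_rng(seed)
    full = _statistic_vector(_refit(data, gamma, rule), statistic)
    grid = tuple(float(q) for q in drop_grid)
    cors = np.full((len(grid), reps_per_point), np.nan)
    unavailable = []
    for gi, q in enumerate(grid):
        keep = int(np.ceil((1.0 - q) * data.n))
        if keep < min_rows:
            unavailable.append(q)
            continue
        for r in range(reps_per_point):
            idx = rng.choice(data.n, size=keep, replace=False)
            sub = BinaryDataset(data.values[idx], data.labels)
            if sub.constant_columns():
                continue  # NaN stays: counted as a failed replicate
            stat = _statistic_vector(_refit(sub, gamma, rule), statistic)
            if np.std(stat) == 0 or np.std(full) == 0:
                continue
            cors[gi, r] = np.corrcoef(full, stat)[0, 1]
    return StabilityProfile(grid, cors, statistic, tuple(unavailable))


def cs_coefficient(profile: StabilityProfile, cor_threshold: float = 0.7,
                   prob: float = 0.95) -> float:
    """Largest drop proportion q such that the fraction of replicates
    with correlation >= ``cor_threshold`` is >= ``prob`` at q AND at
    every smaller grid point; 0.0 if the smallest grid point fails."""
    if len(profile.drop_proportions) == 0:
        raise ValueError("empty stability profile")
    frac = profile.fraction_above(cor_threshold)
    cs = 0.0
    for q, f in zip(profile.drop_proportions, frac):
        if q in profile.unavailable or f < prob:
            break
        cs = q
    return cs
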