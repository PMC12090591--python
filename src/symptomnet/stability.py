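"""Bootstrap accuracy, difference tests and case-dropping stability.

Three procedures, mirroring the standard robustness toolkit for
regularized partial-correlation networks:

- nonparametric bootstrap of the whole estimation pipeline for per-edge 95%
  percentile confidence intervals (edge-weight accuracy);
- bootstrap difference tests for pairs of edges and pairs of nodes: a pair
  differs significantly when the percentile interval of the bootstrapped
  difference excludes zero (no multiplicity correction by default, matching
  the reference procedure; a Bonferroni flag is available);
- case-dropping bootstrap: re-estimate on subsamples with an increasing
  proportion of patients removed and correlate subsample centralities with
  the full-sample ones.  The correlation-stability (CS) coefficient is the
  largest drop proportion at which at least 95% of subsamples still reach a
  correlation of 0.7, required to hold at every smaller proportion as well;
  CS > 0.25 is conventionally "acceptable" and CS > 0.50 "good".

All replicate randomness flows from one root seed through spawned
per-replicate streams, so runs are reproducible and order-independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .centrality import CENTRALITY_FUNCS
from .datasets import SymptomDataset
from .network import WeightedNetwork, estimate_network

_MAX_REDRAWS = 100

NODE_INDICES = ("strength", "expected_influence", "closeness", "betweenness")


def _resample_valid(data: SymptomDataset, rng: np.random.Generator, replace: bool, size: int) -> np.ndarray:
    """Row indices for a resample with no constant column (bounded redraws)."""
    for _ in range(_MAX_REDRAWS):
        if replace:
            idx = rng.integers(0, data.n, size)
        else:
            idx = rng.choice(data.n, size=size, replace=False)
        sub = data.scores[idx]
        if (sub.min(axis=0) != sub.max(axis=0)).all():
            return idx
    raise RuntimeError(
        f"could not draw a resample without constant columns in {_MAX_REDRAWS} tries"
    )


@dataclass
class BootstrapResult:
    """Replicate edge weights and node centralities from B resamples."""

    point: WeightedNetwork
    replicate_edges: np.ndarray          # (B, n_pairs) over all node pairs
    replicate_strength: np.ndarray       # (B, p)
    replicate_expected_influence: np.ndarray
    B: int
    seed: int
    pair_index: tuple[tuple[int, int], ...] = field(repr=False, default=())

    @property
    def pair_labels(self) -> list[str]:
        labs = self.point.labels
        return [f"{labs[i]}--{labs[j]}" for i, j in self.pair_index]

    def edge_ci(self, level: float = 0.95, nonzero_only: bool = False) -> pd.DataFrame:
        """Percentile confidence intervals for every edge weight."""
        lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
        lo = np.quantile(self.replicate_edges, lo_q, axis=0)
        hi = np.quantile(self.replicate_edges, hi_q, axis=0)
        est = np.array([self.point.weights[i, j] for i, j in self.pair_index])
        df = pd.DataFrame(
            {
                "edge": self.pair_labels,
                "estimate": est,
                "lower": lo,
                "upper": hi,
                "boot_mean": self.replicate_edges.mean(axis=0),
            }
        )
        if nonzero_only:
            df = df[df["estimate"] != 0].reset_index(drop=True)
        return df


def bootstrap_network(
    data: SymptomDataset,
    B: int = 1000,
    seed: int = 0,
    estimator: Callable[..., WeightedNetwork] = estimate_network,
    estimator_kwargs: Mapping | None = None,
) -> BootstrapResult:
    """Nonparametric bootstrap of the full network-estimation pipeline.

    Each of the ``B`` replicates resamples patients with replacement,
    re-runs ``estimator`` from scratch, and stores all pairwise edge weights
    plus node strength and expected influence.  Deterministic given ``seed``.
    """
    if B < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    if B < 1000:
        warnings.warn("fewer than 1000 bootstrap replicates; CIs will be rough", stacklevel=2)
    kwargs = dict(estimator_kwargs or {})
    kwargs.setdefault("warn_small_n", False)
    point = estimator(data, **kwargs)
    p = data.p
    iu, ju = np.triu_indices(p, k=1)
    pairs = tuple(zip(iu.tolist(), ju.tolist()))
    children = np.random.SeedSequence(seed).spawn(B)
    edges = np.empty((B, len(pairs)))
    s = np.empty((B, p))
    ei = np.empty((B, p))
    from .centrality import expected_influence, strength  # local to avoid cycle at import

    for b in range(B):
        rng = np.random.default_rng(children[b])
        idx = _resample_valid(data, rng, replace=True, size=data.n)
        try:
            net = estimator(SymptomDataset(data.scores[idx], data.labels, data.names), **kwargs)
        except Exception as exc:  # noqa: BLE001 - annotate replicate and re-raise
            raise RuntimeError(f"estimator failed on bootstrap replicate {b}") from exc
        edges[b] = net.weights[iu, ju]
        s[b] = strength(net)
        ei[b] = expected_influence(net)
    return BootstrapResult(point, edges, s, ei, B, seed, pairs)


@dataclass(frozen=True)
class DifferenceMatrix:
    """Pairwise bootstrap difference-test decisions (symmetric, false diagonal)."""

    significant: np.ndarray
    labels: tuple[str, ...]
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.significant, index=list(self.labels), columns=list(self.labels))


def _pairwise_difference(replicates: np.ndarray, alpha: float, bonferroni: bool) -> np.ndarray:
    m = replicates.shape[1]
    sig = np.zeros((m, m), dtype=bool)
    n_tests = m * (m - 1) // 2
    a = alpha / n_tests if (bonferroni and n_tests) else alpha
    for i in range(m):
        diff = replicates[:, i : i + 1] - replicates[:, i + 1 :]
        if diff.shape[1] == 0:
            continue
        lo = np.quantile(diff, a / 2, axis=0)
        hi = np.quantile(diff, 1 - a / 2, axis=0)
        hit = (lo > 0) | (hi < 0)
        sig[i, i + 1 :] = hit
        sig[i + 1 :, i] = hit
    return sig


def edge_difference_test(
    boot: BootstrapResult,
    alpha: float = 0.05,
    nonzero_only: bool = True,
    bonferroni: bool = False,
) -> DifferenceMatrix:
    """Bootstrap test of whether two edge weights differ.

    By default only edges present in the point-estimate network are compared
    (zero-zero comparisons are uninformative); pass ``nonzero_only=False``
    to compare all node pairs.
    """
    est = np.array([boot.point.weights[i, j] for i, j in boot.pair_index])
    keep = np.ones(len(est), dtype=bool) if not nonzero_only else est != 0
    if keep.sum() < 2:
        raise ValueError("need at least two edges to compare")
    reps = boot.replicate_edges[:, keep]
    labels = tuple(np.array(boot.pair_labels)[keep])
    return DifferenceMatrix(_pairwise_difference(reps, alpha, bonferroni), labels, alpha)


def node_difference_test(
    boot: BootstrapResult,
    index: str = "expected_influence",
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> DifferenceMatrix:
    """Bootstrap test of whether two nodes differ on strength or expected influence."""
    if index == "strength":
        reps = boot.replicate_strength
    elif index == "expected_influence":
        reps = boot.replicate_expected_influence
    else:
        raise ValueError("index must be 'strength' or 'expected_influence'")
    return DifferenceMatrix(
        _pairwise_difference(reps, alpha, bonferroni), boot.point.labels, alpha
    )


@dataclass(frozen=True)
class StabilityResult:
    """Case-dropping correlations by drop proportion, plus the CS coefficient."""

    index: str
    drop_proportions: tuple[float, ...]
    correlations: Mapping[float, np.ndarray]
    criterion_correlation: float = 0.7
    confidence: float = 0.95

    @property
    def cs_coefficient(self) -> float:
        return cs_coefficient(self)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"proportion": q, "replicate": b, "correlation": c}
            for q in self.drop_proportions
            for b, c in enumerate(self.correlations[q])
        ]
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "proportion": list(self.drop_proportions),
                "mean_correlation": [float(np.mean(self.correlations[q])) for q in self.drop_proportions],
                "pass_rate": [
                    float(np.mean(self.correlations[q] >= self.criterion_correlation))
                    for q in self.drop_proportions
                ],
            }
        )


DEFAULT_DROP_GRID = tuple(np.round(np.arange(0.05, 0.751, 0.05), 2))


def case_dropping(
    data: SymptomDataset,
    index: str | Sequence[str] = "strength",
    drop_grid: Sequence[float] = DEFAULT_DROP_GRID,
    B: int = 1000,
    seed: int = 0,
    method: str = "pearson",
    estimator: Callable[..., WeightedNetwork] = estimate_network,
    estimator_kwargs: Mapping | None = None,
) -> StabilityResult | dict[str, StabilityResult]:
    """Case-dropping bootstrap of centrality stability.

    For each drop proportion q, draws ``B`` subsamples of ``floor(n(1-q))``
    patients without replacement, re-estimates the network, and records the
    correlation between the original and subsample centrality vectors.
    Proportions leaving fewer than p+1 rows are skipped with a warning.
    Passing several indices computes them on the same subsample networks
    (one result per index); a single index returns one result.
    """
    if B < 50:
        raise ValueError("need at least 50 case-dropping replicates")
    single = isinstance(index, str)
    indices = (index,) if single else tuple(index)
    for ix in indices:
        if ix not in CENTRALITY_FUNCS:
            raise ValueError(f"unknown centrality index {ix!r}")
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    kwargs = dict(estimator_kwargs or {})
    kwargs.setdefault("warn_small_n", False)
    full_net = estimator(data, **kwargs)
    original = {ix: CENTRALITY_FUNCS[ix](full_net) for ix in indices}

    grid = sorted(float(q) for q in drop_grid)
    if any(not (0 < q < 1) for q in grid):
        raise ValueError("drop proportions must lie in (0, 1)")
    results: dict[str, dict[float, np.ndarray]] = {ix: {} for ix in indices}
    kept: list[float] = []
    for qi, q in enumerate(grid):
        m = int(np.floor(data.n * (1 - q)))
        if m < data.p + 1:
            warnings.warn(
                f"drop proportion {q} leaves only {m} rows (< p+1 = {data.p + 1}); skipped",
                stacklevel=2,
            )
            continue
        kept.append(q)
        children = np.random.SeedSequence((seed, qi)).spawn(B)
        corr = {ix: np.empty(B) for ix in indices}
        for b in range(B):
            rng = np.random.default_rng(children[b])
            idx = _resample_valid(data, rng, replace=False, size=m)
            net = estimator(SymptomDataset(data.scores[idx], data.labels, data.names), **kwargs)
            for ix in indices:
                sub = CENTRALITY_FUNCS[ix](net)
                corr[ix][b] = _safe_corr(original[ix], sub, method)
        for ix in indices:
            results[ix][q] = corr[ix]
    out = {
        ix: StabilityResult(ix, tuple(kept), results[ix]) for ix in indices
    }
    return out[indices[0]] if single else out


def _safe_corr(a: np.ndarray, b: np.ndarray, method: str) -> float:
    """Correlation between centrality vectors; 0 when either is constant."""
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    if method == "spearman":
        from scipy.stats import spearmanr

        return float(spearmanr(a, b).statistic)
    return float(np.corrcoef(a, b)[0, 1])


def cs_coefficient(result: StabilityResult) -> float:
    """Largest drop proportion at which centrality correlations stay reliable.

    The criterion (>= ``confidence`` of replicates with correlation >=
    ``criterion_correlation``) must hold at the returned proportion and at
    every smaller one in the grid; 0.0 if it fails everywhere.
    """
    if not result.drop_proportions:
        raise ValueError("empty stability result")
    cs = 0.0
    for q in result.drop_proportions:
        ok = np.mean(result.correlations[q] >= result.criterion_correlation)
        if ok >= result.confidence:
            cs = q
        else:
            break
    return cs
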