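"""Synthetic MDASI-like data from a known sparse Gaussian graphical model.

The study data this package was written around (postoperative symptom scores
of NSCLC patients) are not publicly deposited, so every downstream stage is
exercised on synthetic datasets drawn from a *known* ground-truth network.
The generator is a latent Gaussian copula: draw multivariate normal vectors
whose precision matrix is the ground truth, then discretize each coordinate
through per-symptom thresholds calibrated to target marginals (prevalence of
a nonzero score, and mean severity on the 0-10 scale).  Thresholds are fit
per column from the marginals alone, independent of the correlation
structure, so the latent network and the observed marginals can be varied
separately.

Category thresholds for scores 1-10 start from an equal-probability
partition of the symptomatic mass and are reshaped by a single "temperature"
parameter: conditional on being symptomatic, ``P(score = k) ∝ exp(tau * k)``.
``tau`` is tuned by bisection until the expected mean severity matches the
target; the map from ``tau`` to the conditional mean is strictly increasing
with range (1, 10), so the fit is deterministic and reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .datasets import SymptomDataset

_EIG_FLOOR = 0.05  # smallest latent-precision eigenvalue tolerated before shifting


def precision_to_partials(precision: np.ndarray) -> np.ndarray:
    """Partial correlations -k_ij / sqrt(k_ii * k_jj), zero diagonal."""
    d = np.sqrt(np.diag(precision))
    partials = -precision / np.outer(d, d)
    np.fill_diagonal(partials, 0.0)
    return partials


@dataclass(frozen=True)
class TrueNetwork:
    """Ground-truth latent Gaussian graphical model.

    ``precision`` is the symmetric positive-definite concentration matrix on
    the latent scale; ``partials`` the implied partial correlations (zero
    diagonal); ``labels`` the node identifiers.
    """

    precision: np.ndarray
    partials: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        prec = np.asarray(self.precision, dtype=float)
        if prec.ndim != 2 or prec.shape[0] != prec.shape[1]:
            raise ValueError("precision must be square")
        if not np.allclose(prec, prec.T, atol=1e-10):
            raise ValueError("precision must be symmetric")
        if np.linalg.eigvalsh(prec).min() <= 0:
            raise ValueError("precision must be positive definite")
        object.__setattr__(self, "precision", prec)
        object.__setattr__(self, "partials", np.asarray(self.partials, dtype=float))
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(self.labels) != prec.shape[0]:
            raise ValueError("labels must match precision dimension")

    @classmethod
    def from_precision(
        cls, precision: np.ndarray, labels: tuple[str, ...] | None = None
    ) -> "TrueNetwork":
        precision = np.asarray(precision, dtype=float)
        p = precision.shape[0]
        if labels is None:
            labels = tuple(f"S{i + 1}" for i in range(p))
        return cls(precision, precision_to_partials(precision), tuple(labels))

    @property
    def p(self) -> int:
        return int(self.precision.shape[0])

    def latent_correlation(self) -> np.ndarray:
        """Covariance implied by the precision, rescaled to unit diagonal."""
        cov = np.linalg.inv(self.precision)
        d = np.sqrt(np.diag(cov))
        return cov / np.outer(d, d)

    def edge_support(self) -> np.ndarray:
        """Boolean upper-triangle-symmetric adjacency of nonzero partials."""
        return np.abs(self.partials) > 1e-12

    def to_json(self, path: str | Path, **extra) -> None:
        payload = {
            "labels": list(self.labels),
            "precision": self.precision.tolist(),
            "partials": self.partials.tolist(),
            **extra,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "TrueNetwork":
        payload = json.loads(Path(path).read_text())
        return cls(
            np.asarray(payload["precision"], dtype=float),
            np.asarray(payload["partials"], dtype=float),
            tuple(payload["labels"]),
        )


@dataclass(frozen=True)
class MarginalSpec:
    """Per-symptom marginal targets: prevalence of score >= 1 and mean severity."""

    prevalence: np.ndarray
    mean_severity: np.ndarray
    labels: tuple[str, ...]
    names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        prev = np.asarray(self.prevalence, dtype=float)
        mean = np.asarray(self.mean_severity, dtype=float)
        if prev.shape != mean.shape or prev.ndim != 1:
            raise ValueError("prevalence and mean_severity must be 1-D and aligned")
        if (prev < 0).any() or (prev > 1).any():
            raise ValueError("prevalences must lie in [0, 1]")
        if (mean < 0).any() or (mean > 10).any():
            raise ValueError("mean severities must lie in [0, 10]")
        if (mean > 10 * prev + 1e-12).any():
            bad = np.nonzero(mean > 10 * prev + 1e-12)[0]
            raise ValueError(
                f"infeasible marginals at columns {bad.tolist()}: "
                "mean severity cannot exceed 10 x prevalence (zeros score 0)"
            )
        object.__setattr__(self, "prevalence", prev)
        object.__setattr__(self, "mean_severity", mean)
        labels = tuple(self.labels)
        if len(labels) != prev.shape[0]:
            raise ValueError("labels must align with prevalence")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(
            self, "names", tuple(self.names) if self.names else labels
        )

    @property
    def p(self) -> int:
        return int(self.prevalence.shape[0])


def make_true_network(
    p: int,
    edge_density: float,
    weight_range: tuple[float, float] = (0.2, 0.4),
    seed: int = 0,
    negative_fraction: float = 0.0,
) -> TrueNetwork:
    """Random sparse ground-truth network with controlled partial correlations.

    The support is a uniformly random graph with ``round(density * p(p-1)/2)``
    edges (at least one).  Absolute partial correlations are drawn uniformly
    from ``weight_range``; a fraction ``negative_fraction`` of edges gets a
    negative sign.  The precision matrix starts at identity minus the partial
    pattern; if its smallest eigenvalue falls below a floor it is repaired by
    shifting the diagonal, which shrinks all partials uniformly.  If the
    repair shrinks the weakest requested edge below half its requested
    magnitude the combination is rejected.

    Deterministic given ``seed``.
    """
    if p < 2:
        raise ValueError("need at least two nodes")
    if not (0 < edge_density <= 1):
        raise ValueError("edge_density must lie in (0, 1]")
    lo, hi = float(weight_range[0]), float(weight_range[1])
    if not (0 < lo <= hi < 1):
        raise ValueError("weight_range must satisfy 0 < lo <= hi < 1")
    n_pairs = p * (p - 1) // 2
    n_edges = max(1, int(round(edge_density * n_pairs)))
    rng = np.random.default_rng(seed)
    pair_idx = rng.choice(n_pairs, size=n_edges, replace=False)
    iu, ju = np.triu_indices(p, k=1)
    weights = rng.uniform(lo, hi, size=n_edges)
    signs = np.where(rng.random(n_edges) < negative_fraction, -1.0, 1.0)

    omega = np.eye(p)
    omega[iu[pair_idx], ju[pair_idx]] = -weights * signs
    omega[ju[pair_idx], iu[pair_idx]] = -weights * signs

    eigmin = np.linalg.eigvalsh(omega).min()
    if eigmin < _EIG_FLOOR:
        omega += (_EIG_FLOOR - eigmin) * np.eye(p)
    net = TrueNetwork.from_precision(omega)
    realized = np.abs(net.partials[iu[pair_idx], ju[pair_idx]])
    if realized.min() < 0.5 * lo:
        raise ValueError(
            "positive-definiteness repair shrank the weakest edge to "
            f"{realized.min():.3f} < half the requested minimum {lo:.3f}; "
            "lower edge_density or the weight range"
        )
    return net


def _conditional_category_probs(tau: float) -> np.ndarray:
    """P(score = k | score >= 1) for k = 1..10 at temperature tau."""
    k = np.arange(1, 11, dtype=float)
    logits = tau * k
    logits -= logits.max()
    w = np.exp(logits)
    return w / w.sum()


def _fit_temperature(cond_mean: float, tol: float = 1e-10) -> float:
    """Bisection for tau such that the conditional mean hits ``cond_mean``."""
    k = np.arange(1, 11, dtype=float)
    lo, hi = -50.0, 50.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        m = float(_conditional_category_probs(mid) @ k)
        if abs(m - cond_mean) < tol:
            return mid
        if m < cond_mean:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def column_thresholds(prevalence: float, mean_severity: float) -> np.ndarray:
    """Latent standard-normal cutpoints for one symptom column.

    Returns 10 ascending thresholds t_0..t_9; a latent draw z maps to the
    score ``#{k : t_k <= z}``.  t_0 is the quantile of (1 - prevalence); the
    remaining cutpoints partition the symptomatic mass so the expected mean
    equals ``mean_severity``.
    """
    if prevalence == 0.0:
        if mean_severity > 0:
            raise ValueError("prevalence 0 forces mean severity 0")
        return np.full(10, np.inf)
    cond_mean = mean_severity / prevalence
    if cond_mean < 1.0 - 1e-9:
        raise ValueError(
            f"infeasible marginal: conditional mean {cond_mean:.3f} < 1 "
            "(every symptomatic patient scores at least 1)"
        )
    if cond_mean > 10.0 + 1e-9:
        raise ValueError("infeasible marginal: mean severity > 10 x prevalence")
    cond_mean = min(max(cond_mean, 1.0), 10.0)
    if cond_mean == 1.0:
        probs = np.zeros(10)
        probs[0] = 1.0
    elif cond_mean == 10.0:
        probs = np.zeros(10)
        probs[-1] = 1.0
    else:
        probs = _conditional_category_probs(_fit_temperature(cond_mean))
    cdf = (1.0 - prevalence) + prevalence * np.concatenate(([0.0], np.cumsum(probs)[:-1]))
    with np.errstate(divide="ignore"):
        return stats.norm.ppf(np.clip(cdf, 0.0, 1.0))


def generate_dataset(
    truth: TrueNetwork,
    marginals: MarginalSpec,
    n: int,
    seed: int = 0,
) -> SymptomDataset:
    """Draw an n-patient ordinal dataset from the latent model.

    Latent vectors are multivariate normal with correlation matrix implied by
    ``truth.precision``; each coordinate is discretized through the column
    thresholds fit from ``marginals``.  Deterministic given ``seed``.
    """
    if truth.p != marginals.p:
        raise ValueError("truth and marginals dimensions differ")
    if n < 2:
        raise ValueError("need at least two patients")
    thresholds = np.stack(
        [
            column_thresholds(marginals.prevalence[j], marginals.mean_severity[j])
            for j in range(marginals.p)
        ]
    )  # (p, 10)
    corr = truth.latent_correlation()
    chol = np.linalg.cholesky(corr)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, truth.p)) @ chol.T
    scores = np.empty((n, truth.p), dtype=np.int64)
    for j in range(truth.p):
        scores[:, j] = np.searchsorted(thresholds[j], z[:, j], side="right")
    return SymptomDataset(scores, marginals.labels, marginals.names)


# Symptom marginals of the modeled study population (n = 367 postoperative
# NSCLC patients; 13 MDASI core items + 6 revised lung-cancer-specific
# items).  Per row: label, name, occurrence count, prevalence %, mean, SD,
# median, P25, P75.
TABLE2_ROWS: tuple[tuple, ...] = (
    ("S1", "Pain", 367, 100.00, 4.05, 1.53, 4, 3, 5),
    ("S2", "Fatigue", 362, 98.64, 3.77, 1.99, 3, 2.5, 5),
    ("S3", "Nausea", 75, 20.44, 0.23, 0.52, 0, 0, 0),
    ("S4", "Disturbed sleep", 355, 96.73, 1.96, 1.13, 2, 1, 2),
    ("S5", "Distress", 181, 49.32, 0.55, 0.67, 0, 0, 1),
    ("S6", "Shortness of breath", 361, 98.37, 2.63, 1.53, 2, 2, 3),
    ("S7", "Difficulty remembering", 226, 61.58, 0.93, 0.94, 1, 0, 1),
    ("S8", "Appetite loss", 335, 91.28, 1.56, 1.03, 1, 1, 2),
    ("S9", "Drowsiness", 286, 77.93, 0.96, 0.71, 1, 1, 1),
    ("S10", "Dry mouth", 274, 74.66, 1.08, 0.85, 1, 0, 2),
    ("S11", "Sadness", 168, 45.78, 0.49, 0.57, 0, 0, 1),
    ("S12", "Vomiting", 64, 17.44, 0.21, 0.49, 0, 0, 0),
    ("S13", "Numbness", 27, 7.36, 0.95, 0.37, 0, 0, 0),
    ("S14", "Cough", 360, 98.09, 2.29, 1.17, 2, 1, 3),
    ("S15", "Expectoration", 334, 91.01, 1.74, 1.10, 2, 1, 2),
    ("S16", "Hemoptysis", 238, 64.85, 0.74, 0.62, 1, 0, 1),
    ("S17", "Chest tightness", 253, 68.94, 1.05, 0.97, 1, 0, 2),
    ("S18", "Constipation", 303, 82.56, 1.38, 1.12, 1, 1, 2),
    ("S19", "Weight loss", 95, 25.89, 0.27, 0.46, 0, 0, 1),
)

STUDY_N = 367

# The numbness row reports mean 0.95 at 7.36% prevalence: on a 0-10 scale
# averaged over all patients that mean cannot exceed 0.736, so the printed
# value cannot be an all-patient mean.  The generator substitutes a feasible
# 0.095 (consistent with the reported median of 0 and near-zero prevalence)
# and warns; the original value is kept in TABLE2_ROWS for reference.
NUMBNESS_FEASIBLE_MEAN = 0.095


def table2_marginals(warn: bool = True) -> MarginalSpec:
    """Default synthetic targets: the study population's symptom marginals."""
    labels = tuple(r[0] for r in TABLE2_ROWS)
    names = tuple(r[1] for r in TABLE2_ROWS)
    prevalence = np.array([r[3] / 100.0 for r in TABLE2_ROWS])
    mean = np.array([r[4] for r in TABLE2_ROWS], dtype=float)
    infeasible = mean > 10 * prevalence
    if infeasible.any():
        for j in np.nonzero(infeasible)[0]:
            if warn:
                warnings.warn(
                    f"marginal for {labels[j]} ({names[j]}) is infeasible "
                    f"(mean {mean[j]} > 10 x prevalence {prevalence[j]:.4f}); "
                    f"substituting {NUMBNESS_FEASIBLE_MEAN}",
                    stacklevel=2,
                )
            mean[j] = NUMBNESS_FEASIBLE_MEAN
    return MarginalSpec(prevalence, mean, labels, names)


def study_true_network(seed: int = 20240901) -> TrueNetwork:
    """A study-scale (p = 19) ground truth with a few dominant edges.

    Emulates the qualitative structure the modeled study reports: strong
    pain-fatigue, pain-shortness-of-breath, pain-disturbed-sleep,
    nausea-vomiting and distress-sadness ties over a sparse random
    background.
    """
    marg = table2_marginals(warn=False)
    p = marg.p
    idx = {lab: i for i, lab in enumerate(marg.labels)}
    rng = np.random.default_rng(seed)
    omega = np.eye(p)

    strong = {
        ("S1", "S2"): 0.35,   # pain - fatigue
        ("S1", "S6"): 0.32,   # pain - shortness of breath
        ("S1", "S4"): 0.30,   # pain - disturbed sleep
        ("S3", "S12"): 0.45,  # nausea - vomiting
        ("S5", "S11"): 0.45,  # distress - sadness
        ("S2", "S6"): 0.30,   # fatigue - shortness of breath
        ("S14", "S15"): 0.35, # cough - expectoration
        ("S6", "S17"): 0.28,  # shortness of breath - chest tightness
    }
    background_density = 0.10
    iu, ju = np.triu_indices(p, k=1)
    taken = {(idx[a], idx[b]) for a, b in strong}
    free = [k for k in range(len(iu)) if (iu[k], ju[k]) not in taken]
    n_bg = int(round(background_density * len(iu)))
    bg = rng.choice(len(free), size=n_bg, replace=False)
    for (a, b), w in strong.items():
        i, j = idx[a], idx[b]
        omega[i, j] = omega[j, i] = -w
    for k in bg:
        i, j = iu[free[k]], ju[free[k]]
        w = rng.uniform(0.08, 0.18) * (1 if rng.random() < 0.9 else -1)
        omega[i, j] = omega[j, i] = -w
    eigmin = np.linalg.eigvalsh(omega).min()
    if eigmin < _EIG_FLOOR:
        omega += (_EIG_FLOOR - eigmin) * np.eye(p)
    net = TrueNetwork.from_precision(omega, marg.labels)
    return net
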