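"""Descriptive layer: symptom prevalence/severity summaries, response rate,
and the parameter-counting sample-size planner for network estimation.

All severity statistics are computed over *all* patients, zeros included:
with 0 meaning "symptom absent" on the 0-10 numeric rating scale, a mean of
0.23 at 20% prevalence is only consistent with the all-patient convention.
Quartiles default to linear interpolation (the mainstream statistical
software default); a discrete order-statistic convention is available via
``interpolation="nearest"`` since questionnaires rarely state one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import SymptomDataset


@dataclass(frozen=True)
class SampleSizePlan:
    """Minimum-n plan from the GGM parameter count.

    A p-node Gaussian graphical model over ordinal items estimates p
    threshold parameters and p(p-1)/2 pairwise association parameters; the
    planner requires n at least equal to the total, inflated for expected
    non-response.
    """

    p: int
    threshold_params: int
    pairwise_params: int
    total_params: int
    nonresponse_rate: float
    min_n: int
    inflation: str = "multiplicative"


def plan_sample_size(
    p: int,
    nonresponse_rate: float = 0.20,
    inflation: str = "multiplicative",
) -> SampleSizePlan:
    """Parameter-count sample-size plan for a p-symptom network.

    ``inflation="multiplicative"`` computes ``ceil(total * (1 + rate))``;
    ``"divisive"`` computes ``ceil(total / (1 - rate))``.  The multiplicative
    rule is the default because it reproduces the published plan for p = 19
    at a 20% non-response rate (190 parameters -> 228 patients).
    """
    if p < 2:
        raise ValueError("need at least two symptoms")
    if not (0 <= nonresponse_rate < 1):
        raise ValueError("nonresponse_rate must lie in [0, 1)")
    if inflation not in ("multiplicative", "divisive"):
        raise ValueError("inflation must be 'multiplicative' or 'divisive'")
    thresholds = p
    pairwise = p * (p - 1) // 2
    total = thresholds + pairwise
    if inflation == "multiplicative":
        min_n = math.ceil(total * (1 + nonresponse_rate))
    else:
        min_n = math.ceil(total / (1 - nonresponse_rate))
    return SampleSizePlan(p, thresholds, pairwise, total, nonresponse_rate, min_n, inflation)


def response_rate(distributed: int, valid: int) -> float:
    """Effective response rate in percent, rounded to one decimal."""
    if distributed <= 0 or valid <= 0:
        raise ValueError("counts must be positive")
    if valid > distributed:
        raise ValueError("valid questionnaires cannot exceed distributed")
    return round(100.0 * valid / distributed, 1)


def summarize_symptoms(
    data: SymptomDataset,
    interpolation: str = "linear",
) -> pd.DataFrame:
    """Per-symptom prevalence and severity summary over all patients.

    Returns one row per symptom with occurrence count (score >= 1),
    prevalence %, mean, sample SD, median and quartiles, sorted by
    descending prevalence with ties broken by column order.
    """
    if data.n < 1:
        raise ValueError("empty dataset")
    scores = data.scores.astype(float)
    count = (scores >= 1).sum(axis=0)
    prevalence_pct = 100.0 * count / data.n
    mean = scores.mean(axis=0)
    sd = scores.std(axis=0, ddof=1) if data.n > 1 else np.zeros(data.p)
    method = {"linear": "linear", "nearest": "nearest"}[interpolation]
    q25, q50, q75 = np.quantile(scores, [0.25, 0.5, 0.75], axis=0, method=method)
    df = pd.DataFrame(
        {
            "label": list(data.labels),
            "symptom": list(data.names),
            "occurrence_count": count.astype(int),
            "prevalence_pct": np.round(prevalence_pct, 2),
            "severity_mean": mean,
            "severity_sd": sd,
            "median": q50,
            "p25": q25,
            "p75": q75,
        }
    )
    order = np.lexsort((np.arange(data.p), -prevalence_pct))
    return df.iloc[order].reset_index(drop=True)
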