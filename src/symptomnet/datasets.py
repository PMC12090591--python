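"""Symptom score datasets: the n x p ordinal matrix every stage consumes.

A dataset holds integer severity scores on the 0-10 numeric rating scale used
by the MD Anderson Symptom Inventory family of questionnaires (0 = symptom
absent).  Rows are patients, columns are symptoms.  The matrix is complete by
construction: missing cells are a hard error at load time, because the study
design this package models analyzes valid (fully answered) questionnaires
only and no imputation procedure is defined.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SCORE_MIN = 0
SCORE_MAX = 10


@dataclass(frozen=True)
class SymptomDataset:
    """An n x p matrix of integer symptom severity scores in [0, 10].

    Parameters
    ----------
    scores : ndarray of shape (n, p), integer dtype
        Per-patient severity scores; 0 means the symptom did not occur.
    labels : tuple of str
        Short unique symptom identifiers (column order), e.g. ``S1``..``S19``.
    names : tuple of str, optional
        Human-readable symptom names aligned with ``labels``.
    """

    scores: np.ndarray
    labels: tuple[str, ...]
    names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores)
        if scores.ndim != 2:
            raise ValueError("scores must be a 2-D matrix (patients x symptoms)")
        if scores.shape[0] < 1 or scores.shape[1] < 1:
            raise ValueError("scores must have at least one row and one column")
        if not np.issubdtype(scores.dtype, np.integer):
            if np.isnan(np.asarray(scores, dtype=float)).any():
                raise ValueError("dataset contains missing cells; complete cases only")
            if not np.array_equal(scores, np.round(scores)):
                raise ValueError("scores must be integers on the 0-10 scale")
            scores = scores.astype(np.int64)
        if scores.min() < SCORE_MIN or scores.max() > SCORE_MAX:
            raise ValueError("scores must lie in [0, 10]")
        object.__setattr__(self, "scores", scores)
        labels = tuple(self.labels)
        if len(labels) != scores.shape[1]:
            raise ValueError("label count must equal the number of columns")
        if len(set(labels)) != len(labels):
            raise ValueError("symptom labels must be unique")
        object.__setattr__(self, "labels", labels)
        names = tuple(self.names) if self.names else labels
        if len(names) != len(labels):
            raise ValueError("names must align with labels")
        object.__setattr__(self, "names", names)

    @property
    def n(self) -> int:
        return int(self.scores.shape[0])

    @property
    def p(self) -> int:
        return int(self.scores.shape[1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, columns=list(self.labels))

    def to_csv(self, path: str | Path, names_sidecar: bool = True) -> None:
        """Write scores as CSV (header = labels); optionally a JSON name map."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        if names_sidecar and self.names != self.labels:
            sidecar = path.with_suffix(".names.json")
            sidecar.write_text(
                json.dumps(dict(zip(self.labels, self.names)), indent=2)
            )

    @classmethod
    def from_csv(cls, path: str | Path) -> "SymptomDataset":
        path = Path(path)
        df = pd.read_csv(path)
        if df.isna().any().any():
            bad = [c for c in df.columns if df[c].isna().any()]
            raise ValueError(f"missing cells in columns {bad}; complete cases only")
        names: tuple[str, ...] = ()
        sidecar = path.with_suffix(".names.json")
        if sidecar.exists():
            mapping = json.loads(sidecar.read_text())
            names = tuple(mapping.get(c, c) for c in df.columns)
        return cls(df.to_numpy(), tuple(map(str, df.columns)), names)
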