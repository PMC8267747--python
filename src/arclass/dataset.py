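"""In-memory container joining identifiers, fingerprints, docking scores, labels."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fingerprints import Fingerprint

__all__ = ["LabeledDataset"]


@dataclass
class LabeledDataset:
    """One row per compound: id, fingerprint, docking score, optional label.

    Docking scores are in kcal/mol with 0 meaning "no docking pose".
    ``labels`` is None for prediction-only data; when present, 1 = binder.
    """

    ids: list
    fingerprints: list = field(repr=False)
    scores: np.ndarray = field(repr=False)
    labels: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        n = len(self.ids)
        if len(self.fingerprints) != n or self.scores.shape[0] != n:
            raise ValueError("ids, fingerprints and scores differ in length")
        if len(set(self.ids)) != n:
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise ValueError(f"duplicate compound ids: {dupes[:5]}")
        lengths = {fp.length for fp in self.fingerprints}
        if len(lengths) > 1:
            raise ValueError(f"mixed fingerprint lengths: {sorted(lengths)}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels).astype(int)
            if self.labels.shape[0] != n:
                raise ValueError("labels differ in length")
            if not np.isin(self.labels, (0, 1)).all():
                raise ValueError("labels must be binary 0/1")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def fp_length(self) -> int:
        return self.fingerprints[0].length

    @property
    def n_active(self) -> int:
        if self.labels is None:
            raise ValueError("dataset is unlabeled")
        return int(self.labels.sum())

    @property
    def n_inactive(self) -> int:
        return len(self) - self.n_active

    def bit_matrix(self) -> np.ndarray:
        """(n, fp_length) 0/1 matrix of the fingerprints."""
        return np.vstack([fp.bits for fp in self.fingerprints])

    def X(self) -> np.ndarray:
        """Estimator feature matrix: column 0 is the docking score, the
        remaining ``fp_length`` columns are the fingerprint bits."""
        return np.hstack([self.scores[:, None], self.bit_matrix().astype(float)])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"id": self.ids, "dock_score": self.scores})
        if self.labels is not None:
            df["label"] = self.labels
        return df

    @classmethod
    def from_arrays(cls, ids, bit_matrix, scores, labels=None) -> "LabeledDataset":
        fps = [Fingerprint(row) for row in np.asarray(bit_matrix, dtype=np.uint8)]
        return cls(ids=list(ids), fingerprints=fps, scores=scores, labels=labels)
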