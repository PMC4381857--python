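"""Kennard-Stone calibration/validation sample-set partitioning.

The Kennard-Stone algorithm deterministically picks the most mutually
distant samples for the calibration set: the first two picks are the pair
at maximal Euclidean distance, and each subsequent pick maximizes its
minimal distance to the already-picked samples (greedy maximin). Ties are
broken toward the lowest index so the split is reproducible across
platforms.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .errors import ParameterError


@dataclass
class SplitResult:
    """Index partition produced by :func:`kennard_stone`."""

    calibration_indices: list[int]
    validation_indices: list[int]
    distance_metric: str = "euclidean"
    selection_order: list[int] = field(default_factory=list)

    @property
    def n_cal(self) -> int:
        return len(self.calibration_indices)

    @property
    def n_val(self) -> int:
        return len(self.validation_indices)

    def write_csv(self, path, sample_ids: list[str]) -> None:
        """Persist as a two-column CSV (sample_id, set in {cal, val})."""
        roles = {i: "cal" for i in self.calibration_indices}
        roles.update({i: "val" for i in self.validation_indices})
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["sample_id", "set"])
            for i, sid in enumerate(sample_ids):
                w.writerow([sid, roles[i]])


def kennard_stone(X: np.ndarray, n_cal: int) -> SplitResult:
    """Greedy maximin (Kennard-Stone) selection of ``n_cal`` calibration rows.

    Parameters
    ----------
    X : ndarray, shape (n_samples, n_features)
        Feature matrix; distances are Euclidean over all features (so the
        split is invariant to feature-order permutation). Duplicate rows are
        allowed; exact ties resolve to the lowest index.
    n_cal : int
        Calibration-set size, between 2 and n_samples.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if not (2 <= n_cal <= n):
        raise ParameterError(f"n_cal must be in [2, {n}], got {n_cal}")
    D = squareform(pdist(X, metric="euclidean"))

    # Farthest pair; row-major argmax over the upper triangle gives the
    # lexicographically smallest (i, j) among ties.
    iu = np.triu_indices(n, k=1)
    flat = D[iu]
    best = int(np.argmax(flat))
    i0, j0 = int(iu[0][best]), int(iu[1][best])
    order = [i0, j0]
    selected = np.zeros(n, dtype=bool)
    selected[[i0, j0]] = True
    # min distance of every sample to the selected set
    mind = np.minimum(D[i0], D[j0])
    mind[selected] = -np.inf
    while len(order) < n_cal:
        nxt = int(np.argmax(mind))  # first occurrence = lowest index on ties
        order.append(nxt)
        selected[nxt] = True
        mind = np.minimum(mind, D[nxt])
        mind[selected] = -np.inf
    cal = sorted(order)
    val = [i for i in range(n) if not selected[i]]
    return SplitResult(cal, val, "euclidean", order)
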