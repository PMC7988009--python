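"""Spatial clustering of responder cells within a monolayer.

Responder lineages expand in place, so heritable responder state predicts
spatial aggregation of responders.  The statistic is the median, over
responder cells, of each responder's median distance to its k nearest
responder neighbours; significance comes from a label-permutation null that
preserves the monolayer geometry and the responder count.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "MonolayerField",
    "PermutationTestResult",
    "responder_knn_statistic",
    "permutation_test",
]

logger = logging.getLogger(__name__)


@dataclass
class MonolayerField:
    """2-D cell positions (µm) with binary responder labels."""

    positions: np.ndarray
    labels: np.ndarray
    field_id: str = "field"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.labels = np.asarray(self.labels, dtype=bool)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be an (n, 2) array")
        if len(self.labels) != len(self.positions):
            raise ValueError("labels and positions length mismatch")
        if len(self.positions) < 2:
            raise ValueError("need at least 2 cells")

    @classmethod
    def from_arrays(
        cls,
        positions: np.ndarray,
        labels: np.ndarray,
        field_id: str = "field",
        jitter_seed: int = 0,
    ) -> "MonolayerField":
        """Construct a field, jittering duplicated coordinates by <0.01 µm."""
        positions = np.asarray(positions, dtype=float).copy()
        _, inverse, counts = np.unique(
            positions, axis=0, return_inverse=True, return_counts=True
        )
        dup = counts[inverse] > 1
        if dup.any():
            rng = np.random.default_rng(jitter_seed)
            positions[dup] += rng.uniform(-0.005, 0.005, size=(int(dup.sum()), 2))
            logger.info(
                "field %s: jittered %d duplicated coordinates", field_id, dup.sum()
            )
        return cls(positions, labels, field_id)

    @property
    def n_responders(self) -> int:
        return int(self.labels.sum())


def _knn_median_per_row(D: np.ndarray, k: int) -> np.ndarray:
    """Per-row median of the k smallest distances, ties included.

    ``D`` has shape (..., m, m) with the self-distance on the diagonal; the
    diagonal is excluded.  If the k-th smallest distance is tied with later
    entries, all tied distances enter the median (deterministic tie rule).
    """
    m = D.shape[-1]
    D = D.copy()
    idx = np.arange(m)
    D[..., idx, idx] = np.inf
    S = np.sort(D, axis=-1)
    dk = S[..., k - 1 : k]  # k-th smallest, keepdims
    masked = np.where(S <= dk, S, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmedian(masked, axis=-1)


def responder_knn_statistic(
    field: MonolayerField, k: int = 5
) -> tuple[np.ndarray, float]:
    """Median distance from each responder to its k nearest responders.

    Returns the per-responder statistics and their median (the field
    summary).  Euclidean distances, self excluded; requires at least k+1
    responders.
    """
    m = field.n_responders
    if m < k + 1:
        raise ValueError(
            f"{m} responders < k+1 = {k + 1} required for a {k}-NN statistic"
        )
    pos = field.positions[field.labels]
    D = squareform(pdist(pos))
    per = _knn_median_per_row(D, k)
    return per, float(np.median(per))


@dataclass
class PermutationTestResult:
    observed: float
    null: np.ndarray
    p_value: float
    k: int
    n_perm: int
    field_id: str


def permutation_test(
    field: MonolayerField,
    k: int = 5,
    n_perm: int = 1000,
    seed: int | None = None,
    null: str = "label_permutation",
    chunk: int = 200,
) -> PermutationTestResult:
    """One-sided permutation test for responder spatial clustering.

    The null keeps the positions and the responder count and permutes the
    labels uniformly (``null="label_permutation"``); alternatively
    responder positions are redrawn uniformly in the field's bounding box
    (``null="position_redraw"``).  Small distances mean clustering, so
    ``p = (1 + #{null <= observed}) / (1 + n_perm)``.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} < 100: p-values are coarse", stacklevel=2)
    _, observed = responder_knn_statistic(field, k=k)
    rng = np.random.default_rng(seed)
    n, m = len(field.labels), field.n_responders

    null_stats = np.empty(n_perm)
    if null == "label_permutation":
        D_full = squareform(pdist(field.positions))
        done = 0
        while done < n_perm:
            size = min(chunk, n_perm - done)
            # responder index sets for `size` permutations
            picks = np.array(
                [rng.choice(n, size=m, replace=False) for _ in range(size)]
            )
            sub = D_full[picks[:, :, None], picks[:, None, :]]
            per = _knn_median_per_row(sub, k)
            null_stats[done : done + size] = np.median(per, axis=-1)
            done += size
    elif null == "position_redraw":
        lo = field.positions.min(axis=0)
        hi = field.positions.max(axis=0)
        for i in range(n_perm):
            pos = rng.uniform(lo, hi, size=(m, 2))
            D = squareform(pdist(pos))
            null_stats[i] = float(np.median(_knn_median_per_row(D, k)))
    else:
        raise ValueError(f"unknown null {null!r}")

    p = (1.0 + np.sum(null_stats <= observed)) / (1.0 + n_perm)
    return PermutationTestResult(observed, null_stats, float(p), k, n_perm, field.field_id)
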