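"""Min-max scaling of inputs and targets to [-1, +1].

Each dimension is mapped linearly so that its observed minimum goes to -1
and its maximum to +1, with an exact inverse (the mapminmax convention).
Scaling both inputs and targets keeps dimensions with large raw magnitudes
from dominating the training loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ScalerParams", "fit_scaler", "apply_scaler", "invert_scaler"]


@dataclass(frozen=True)
class ScalerParams:
    """Per-dimension minimum and maximum of the fitted data (original units)."""

    minimum: tuple[float, ...]
    maximum: tuple[float, ...]

    def __post_init__(self) -> None:
        lo = np.asarray(self.minimum, float)
        hi = np.asarray(self.maximum, float)
        if lo.shape != hi.shape or lo.ndim != 1:
            raise ValueError("minimum/maximum must be 1-D and equal length")
        if not (np.isfinite(lo).all() and np.isfinite(hi).all()):
            raise ValueError("non-finite scaler bounds")
        if np.any(hi < lo):
            raise ValueError("maximum < minimum in some dimension")

    @property
    def n_dims(self) -> int:
        return len(self.minimum)


def fit_scaler(data: np.ndarray) -> ScalerParams:
    """Record per-column extremes of a samples-by-dimensions matrix."""
    arr = np.atleast_2d(np.asarray(data, float))
    if arr.size == 0:
        raise ValueError("cannot fit scaler on empty data")
    return ScalerParams(
        tuple(arr.min(axis=0).tolist()), tuple(arr.max(axis=0).tolist())
    )


def _check_dims(params: ScalerParams, arr: np.ndarray) -> None:
    if arr.shape[-1] != params.n_dims:
        raise ValueError(
            f"data has {arr.shape[-1]} dimensions, scaler has {params.n_dims}"
        )


def apply_scaler(params: ScalerParams, x: np.ndarray) -> np.ndarray:
    """Map original units into [-1, +1]; constant dimensions map to 0."""
    arr = np.asarray(x, float)
    _check_dims(params, arr)
    lo = np.asarray(params.minimum)
    hi = np.asarray(params.maximum)
    span = hi - lo
    safe = np.where(span == 0, 1.0, span)
    scaled = 2.0 * (arr - lo) / safe - 1.0
    return np.where(span == 0, 0.0, scaled)


def invert_scaler(params: ScalerParams, x_scaled: np.ndarray) -> np.ndarray:
    """Exact inverse of :func:`apply_scaler` (constant dims return the constant)."""
    arr = np.asarray(x_scaled, float)
    _check_dims(params, arr)
    lo = np.asarray(params.minimum)
    hi = np.asarray(params.maximum)
    return (arr + 1.0) * (hi - lo) / 2.0 + lo
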