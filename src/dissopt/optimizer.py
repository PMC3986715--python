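"""Brute-force formulation optimization over the surrogate.

Every candidate composition on a rectangular grid inside the experimental
domain is simulated with the trained network and scored by f2 similarity
against the reference dissolution profile; the candidate with the highest
f2 wins.  Exhaustive enumeration keeps the search trivially global — the
default grid (5 mg / 5 mg / 2.5 mg / 2 % steps) has 42,525 candidates and
evaluates in well under a second with batched forward passes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .core import (
    FACTOR_BOUNDS,
    FACTOR_NAMES,
    DissolutionProfile,
    DomainError,
    Formulation,
)
from .similarity import f2_similarity
from .surrogate import MLPSurrogate, forward_batch

__all__ = ["SearchGrid", "OptimizationResult", "enumerate_grid", "optimize"]


@dataclass(frozen=True)
class SearchGrid:
    """Per-factor arithmetic sequences min, min+step, ... <= max."""

    methocel: tuple[float, float, float] = (0.0, 120.0, 5.0)
    xanthan: tuple[float, float, float] = (0.0, 100.0, 5.0)
    carbopol: tuple[float, float, float] = (0.0, 20.0, 2.5)
    surelease: tuple[float, float, float] = (4.0, 20.0, 2.0)

    def __post_init__(self) -> None:
        for name, (lo, hi, step) in zip(FACTOR_NAMES, self.axes()):
            if step <= 0:
                raise ValueError(f"{name}: step must be positive")
            if lo > hi:
                raise ValueError(f"{name}: min {lo} > max {hi}")
            blo, bhi = FACTOR_BOUNDS[name]
            if lo < blo or hi > bhi:
                raise DomainError(
                    f"{name}: grid [{lo}, {hi}] outside domain [{blo}, {bhi}]"
                )

    def axes(self) -> tuple[tuple[float, float, float], ...]:
        return (self.methocel, self.xanthan, self.carbopol, self.surelease)

    def levels(self) -> tuple[np.ndarray, ...]:
        out = []
        for lo, hi, step in self.axes():
            n = int(np.floor((hi - lo) / step + 1e-9)) + 1
            out.append(lo + step * np.arange(n))
        return tuple(out)

    @property
    def n_candidates(self) -> int:
        return int(np.prod([len(ax) for ax in self.levels()]))

    @property
    def steps(self) -> tuple[float, float, float, float]:
        return tuple(ax[2] for ax in self.axes())


@dataclass(frozen=True)
class OptimizationResult:
    """Grid-search winner and audit trail."""

    best: Formulation
    predicted_profile: DissolutionProfile
    f2: float
    n_evaluated: int
    top_k: tuple[tuple[Formulation, float], ...]


def enumerate_grid(grid: SearchGrid):
    """Yield grid candidates in deterministic lexicographic factor order."""
    levels = grid.levels()
    for lv in levels:
        if len(lv) == 0:
            raise ValueError("empty grid axis")
    for combo in itertools.product(*levels):
        yield Formulation(*(float(v) for v in combo))


def optimize(
    net: MLPSurrogate,
    reference: DissolutionProfile,
    grid: SearchGrid | None = None,
    top_k: int = 10,
    chunk_size: int = 8192,
) -> OptimizationResult:
    """Exhaustively score the grid against the reference profile.

    Predicted profiles are NOT clipped to [0, 100] before scoring (clipping
    would silently reorder candidates); the winner's reported profile is
    the raw prediction.  Ties break to the first candidate in enumeration
    order.
    """
    grid = grid if grid is not None else SearchGrid()
    if tuple(reference.times_h) != tuple(net.times_h):
        raise ValueError(
            f"reference schedule {reference.times_h} does not match "
            f"network schedule {net.times_h}"
        )
    levels = grid.levels()
    mesh = np.stack(
        [m.ravel() for m in np.meshgrid(*levels, indexing="ij")], axis=1
    )
    ref = np.asarray(reference.release_pct, float)
    n_total = mesh.shape[0]

    f2_all = np.empty(n_total)
    for start in range(0, n_total, chunk_size):
        X = mesh[start:start + chunk_size]
        pred = forward_batch(net, X)
        msd = np.mean((pred - ref) ** 2, axis=1)
        f2_all[start:start + X.shape[0]] = 100.0 - 25.0 * np.log10(1.0 + msd)

    if not np.isfinite(f2_all).all():
        bad = int(np.flatnonzero(~np.isfinite(f2_all))[0])
        raise ValueError(
            f"non-finite f2 for candidate {tuple(mesh[bad])}"
        )

    best_i = int(np.argmax(f2_all))  # argmax takes the first maximum
    best = Formulation(*(float(v) for v in mesh[best_i]))
    best_profile = DissolutionProfile(
        net.times_h, forward_batch(net, mesh[best_i][None, :])[0].tolist()
    )
    # cross-check the vectorized score against the scalar f2 implementation
    best_f2 = f2_similarity(reference, best_profile).f2

    k = min(top_k, n_total)
    # stable ordering: descending f2, enumeration order among ties
    order = np.lexsort((np.arange(n_total), -f2_all))[:k]
    ranked = tuple(
        (Formulation(*(float(v) for v in mesh[i])), float(f2_all[i]))
        for i in order
    )
    return OptimizationResult(
        best=best,
        predicted_profile=best_profile,
        f2=best_f2,
        n_evaluated=n_total,
        top_k=ranked,
    )
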