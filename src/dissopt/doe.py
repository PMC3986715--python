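"""Central composite design (CCD) generation for the 4-factor domain.

The training corpus is a CCD: a 2^4 full factorial at coded levels +/-1,
eight axial points at +/-alpha on one factor at a time, and replicated
center runs.  Actual levels are ``center + coded * step``.  The study's
design uses alpha = 2 coded units (for k = 4 this coincides with the
rotatable alpha = (2^4)^(1/4) = 2).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .core import FACTOR_BOUNDS, FACTOR_NAMES, DomainError, Formulation

__all__ = ["CCDSpec", "STUDY_CCD_SPEC", "generate_ccd", "shuffle_design"]

_K = 4  # factors


@dataclass(frozen=True)
class CCDSpec:
    """Factor centers and coded-unit steps for the design.

    Defaults reproduce the study design: centers (60 mg, 50 mg, 10 mg,
    12 %), steps (30 mg, 25 mg, 5 mg, 4 %), axial distance 2, six center
    replicates.
    """

    center: tuple[float, float, float, float] = (60.0, 50.0, 10.0, 12.0)
    step: tuple[float, float, float, float] = (30.0, 25.0, 5.0, 4.0)
    axial_distance: float = 2.0
    n_center: int = 6

    def __post_init__(self) -> None:
        if len(self.center) != _K or len(self.step) != _K:
            raise ValueError("center and step must have 4 entries")
        if any(s <= 0 for s in self.step):
            raise ValueError("steps must be positive")
        if self.axial_distance <= 0:
            raise ValueError("axial_distance must be positive")
        if self.n_center < 1:
            raise ValueError("n_center must be >= 1")
        for name, c, s in zip(FACTOR_NAMES, self.center, self.step):
            lo, hi = FACTOR_BOUNDS[name]
            a = self.axial_distance * s
            if c - a < lo or c + a > hi:
                raise DomainError(
                    f"axial point on {name} ({c}±{a}) leaves domain [{lo}, {hi}]"
                )


#: The default 30-run design specification.
STUDY_CCD_SPEC = CCDSpec()


def _point(spec: CCDSpec, coded: tuple[float, ...]) -> Formulation:
    vals = [c + u * s for c, u, s in zip(spec.center, coded, spec.step)]
    for name, v in zip(FACTOR_NAMES, vals):
        lo, hi = FACTOR_BOUNDS[name]
        if not (lo <= v <= hi):
            raise DomainError(f"design point leaves domain on {name}: {v}")
    return Formulation(*vals)


def generate_ccd(spec: CCDSpec = STUDY_CCD_SPEC) -> list[Formulation]:
    """Generate the design: 2^4 factorial, 2*4 axial, then center points.

    Order is fixed (factorial in lexicographic -1/+1 order, axial low/high
    per factor, center replicates last) for reproducibility; the physical
    manufacture order was randomized, which is irrelevant computationally
    (see :func:`shuffle_design`).
    """
    points: list[Formulation] = []
    for coded in itertools.product((-1.0, 1.0), repeat=_K):
        points.append(_point(spec, coded))
    a = spec.axial_distance
    for i in range(_K):
        for sign in (-1.0, 1.0):
            coded = [0.0] * _K
            coded[i] = sign * a
            points.append(_point(spec, tuple(coded)))
    center = _point(spec, (0.0,) * _K)
    points.extend([center] * spec.n_center)
    return points


def shuffle_design(design: list[Formulation], seed: int) -> list[Formulation]:
    """Seeded random run order, emulating randomized manufacture order."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(design))
    return [design[i] for i in order]
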