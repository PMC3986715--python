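"""Synthetic dissolution-study generator.

The experimental corpus exists only as figures in print, so testing the
pipeline end to end requires a generative stand-in with the same
statistical structure: a 30-run design whose profiles release roughly
25-50% of the dose in the first hour, climb concavely (rate decreasing in
time, as for a diffusion-controlled water-soluble drug), and reach >=80%
by 12 h, with retardation increasing in every polymer level.

The generative family is a Weibull release curve

    y(t) = 100 * (1 - exp(-(t / tau)^beta))

with a log-linear composition response for the time scale,

    tau = exp(a0 + a1 u1 + a2 u2 + a3 u3 + a4 u4 + a12 u1 u2),

where u is the composition scaled to [-1, 1]^4 over the experimental
domain, and a mild shape trend beta = beta_base + beta_slope * u1.
Positive a-coefficients make every polymer (and the ethylcellulose
dispersion) retard release monotonically; the a12 interaction mimics the
joint gelling of the HPMC/xanthan pair.  Measurement noise is additive
Gaussian on the percent scale, clipped to [0, 100], then repaired to be
non-decreasing in time (cumulative release cannot fall).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    CANONICAL_TIMES_H,
    FACTOR_BOUNDS,
    FACTOR_NAMES,
    DissolutionProfile,
    Formulation,
    FormulationDataset,
)

__all__ = [
    "ReleaseModelParams",
    "simulate_profile",
    "generate_study",
    "make_reference",
]

_DOMAIN_LO = np.array([FACTOR_BOUNDS[n][0] for n in FACTOR_NAMES])
_DOMAIN_HI = np.array([FACTOR_BOUNDS[n][1] for n in FACTOR_NAMES])


@dataclass(frozen=True)
class ReleaseModelParams:
    """Coefficients of the synthetic release model.

    Defaults are calibrated so the 30-run design's noiseless first-hour
    releases span roughly 25-48% and 12-h releases roughly 82-99%, the
    envelope of the study corpus.  The negative beta slope makes
    slow-releasing (polymer-rich) formulations flatter as well as slower,
    which is what keeps their 12-h release down near 83% while
    fast-releasing runs approach complete release.
    """

    tau_coeffs: tuple[float, float, float, float, float, float] = (
        1.135, 0.45, 0.325, 0.15, 0.225, 0.075
    )  # a0, a1..a4, a12 — log hours
    beta_base: float = 0.765
    beta_slope: float = -0.07
    noise_sd: float = 1.0  # percentage points
    seed: int = 0
    times_h: tuple[float, ...] = CANONICAL_TIMES_H

    def __post_init__(self) -> None:
        if len(self.tau_coeffs) != 6:
            raise ValueError("tau_coeffs must have 6 entries (a0, a1..a4, a12)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        # check tau > 0 (automatic for exp) and beta in (0.3, 1.5) over the
        # domain corners, where the linear parts are extremal
        a0, a1, a2, a3, a4, a12 = self.tau_coeffs
        amp = abs(a1) + abs(a2) + abs(a3) + abs(a4) + abs(a12)
        if not np.isfinite(np.exp(a0 + amp)):
            raise ValueError("tau overflows over the domain")
        for u1 in (-1.0, 1.0):
            b = self.beta_base + self.beta_slope * u1
            if not (0.3 < b < 1.5):
                raise ValueError(f"beta={b} outside (0.3, 1.5) at u1={u1}")


def _coded(formulation: Formulation) -> np.ndarray:
    """Composition scaled to [-1, 1]^4 over the experimental domain."""
    x = formulation.as_array()
    return 2.0 * (x - _DOMAIN_LO) / (_DOMAIN_HI - _DOMAIN_LO) - 1.0


def _noiseless(formulation: Formulation, params: ReleaseModelParams) -> np.ndarray:
    u = _coded(formulation)
    a0, a1, a2, a3, a4, a12 = params.tau_coeffs
    tau = float(np.exp(a0 + a1 * u[0] + a2 * u[1] + a3 * u[2] + a4 * u[3]
                       + a12 * u[0] * u[1]))
    beta = params.beta_base + params.beta_slope * u[0]
    t = np.asarray(params.times_h, float)
    return 100.0 * (1.0 - np.exp(-((t / tau) ** beta)))


def simulate_profile(
    formulation: Formulation,
    params: ReleaseModelParams | None = None,
    with_noise: bool = True,
    rng: np.random.Generator | None = None,
) -> DissolutionProfile:
    """Simulate one dissolution profile.

    With noise, seeded Gaussian deviations (sd ``params.noise_sd``) are
    added, values are clipped to [0, 100], and monotonicity is restored by
    a running maximum.  Pass an explicit ``rng`` to draw several profiles
    from one stream; otherwise ``params.seed`` seeds a fresh one.
    """
    params = params if params is not None else ReleaseModelParams()
    y = _noiseless(formulation, params)
    if with_noise and params.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(params.seed)
        y = y + rng.normal(0.0, params.noise_sd, size=y.shape)
        y = np.clip(y, 0.0, 100.0)
        y = np.maximum.accumulate(y)
    return DissolutionProfile(params.times_h, y.tolist())


def generate_study(
    params: ReleaseModelParams | None = None,
    design: list[Formulation] | None = None,
) -> FormulationDataset:
    """One noisy profile per design row, with SAL-style run ids.

    Deterministic given ``params.seed``; the default design is the study's
    30-run central composite design.
    """
    from .io import study_design_fixture  # deferred: io imports core only

    params = params if params is not None else ReleaseModelParams()
    design = design if design is not None else study_design_fixture()
    if not design:
        raise ValueError("empty design")
    rng = np.random.default_rng(params.seed)
    records = []
    for i, f in enumerate(design, start=1):
        prof = simulate_profile(f, params, with_noise=True, rng=rng)
        records.append((f"SAL{i:03d}", f, prof))
    return FormulationDataset(records)


def make_reference(
    params: ReleaseModelParams | None = None,
    composition: Formulation | None = None,
) -> DissolutionProfile:
    """Noiseless profile at a composition — the synthetic reference product.

    Defaults to (45 mg, 30 mg, 5 mg, 10 % w/w), an in-domain point lying
    on the default search grid.
    """
    params = params if params is not None else ReleaseModelParams()
    if composition is None:
        composition = Formulation(45.0, 30.0, 5.0, 10.0)
    return simulate_profile(composition, params, with_noise=False)
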