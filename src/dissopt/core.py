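"""Domain types for hydrophilic-matrix formulation optimization.

A formulation is a point in the four-factor composition space studied in a
central composite design: three matrix-forming polymers (Methocel K100M,
xanthan gum, Carbopol 974P, in mg per tablet) and the concentration of the
Surelease granulating dispersion (% w/w).  Its measurable response is a
cumulative dissolution profile: percent drug released at an ordered set of
sampling times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "CANONICAL_TIMES_H",
    "FACTOR_NAMES",
    "FACTOR_BOUNDS",
    "DomainError",
    "SchemaError",
    "RecordError",
    "ScheduleMismatchError",
    "Formulation",
    "DissolutionProfile",
    "FormulationDataset",
]

#: Sampling schedule of the dissolution test (hours).
CANONICAL_TIMES_H: tuple[float, ...] = (1.0, 2.0, 4.0, 6.0, 8.0, 12.0)

#: Composition factors, in canonical order x1..x4.
FACTOR_NAMES: tuple[str, ...] = (
    "methocel_mg",
    "xanthan_mg",
    "carbopol_mg",
    "surelease_pct",
)

#: Experimental domain spanned by the central composite design.
FACTOR_BOUNDS: dict[str, tuple[float, float]] = {
    "methocel_mg": (0.0, 120.0),
    "xanthan_mg": (0.0, 100.0),
    "carbopol_mg": (0.0, 20.0),
    "surelease_pct": (4.0, 20.0),
}


class DomainError(ValueError):
    """A composition lies outside the experimental domain."""


class SchemaError(ValueError):
    """A dataset file is missing or misnames a required column."""


class RecordError(ValueError):
    """A dataset row holds a non-numeric or out-of-domain value."""


class ScheduleMismatchError(ValueError):
    """Two profiles do not share the same sampling schedule."""


@dataclass(frozen=True)
class Formulation:
    """One candidate composition x = (x1, x2, x3, x4).

    Parameters
    ----------
    methocel_mg, xanthan_mg, carbopol_mg
        Polymer masses per tablet, mg.
    surelease_pct
        Concentration of the Surelease granulating dispersion, % w/w.
    check
        When True (default) the composition must lie inside the
        experimental domain.  Pass ``check=False`` only for deliberate
        extrapolation experiments; the surrogate is fitted, and therefore
        only trustworthy, inside the domain.
    """

    methocel_mg: float
    xanthan_mg: float
    carbopol_mg: float
    surelease_pct: float
    check: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self) -> None:
        vals = self.as_tuple()
        if not all(math.isfinite(v) for v in vals):
            raise DomainError(f"non-finite composition {vals!r}")
        if self.check:
            for name, v in zip(FACTOR_NAMES, vals):
                lo, hi = FACTOR_BOUNDS[name]
                if not (lo <= v <= hi):
                    raise DomainError(
                        f"{name}={v!r} outside experimental domain [{lo}, {hi}]"
                    )

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (
            float(self.methocel_mg),
            float(self.xanthan_mg),
            float(self.carbopol_mg),
            float(self.surelease_pct),
        )

    def as_array(self) -> np.ndarray:
        return np.asarray(self.as_tuple(), dtype=float)


@dataclass(frozen=True)
class DissolutionProfile:
    """Cumulative % drug released at an ordered set of sampling times.

    Times must be strictly increasing and positive.  Release values are not
    range-checked here: observed profiles live in [0, 100] (enforced on
    file read), but raw surrogate predictions may transiently fall outside
    that interval and are only clipped at reporting time.
    """

    times_h: tuple[float, ...]
    release_pct: tuple[float, ...]

    def __init__(self, times_h: Sequence[float], release_pct: Sequence[float]):
        t = tuple(float(x) for x in times_h)
        r = tuple(float(x) for x in release_pct)
        if len(t) == 0:
            raise ValueError("empty profile")
        if len(t) != len(r):
            raise ValueError(
                f"{len(t)} times but {len(r)} release values"
            )
        if any(not math.isfinite(x) for x in t + r):
            raise ValueError("non-finite profile entries")
        if t[0] <= 0 or any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError(f"times must be strictly increasing and > 0, got {t!r}")
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "release_pct", r)

    def __len__(self) -> int:
        return len(self.times_h)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.release_pct, dtype=float)

    def clipped(self) -> "DissolutionProfile":
        """Copy with release values clipped to [0, 100] (reporting form)."""
        return DissolutionProfile(
            self.times_h, tuple(min(100.0, max(0.0, v)) for v in self.release_pct)
        )

    def same_schedule(self, other: "DissolutionProfile") -> bool:
        return self.times_h == other.times_h


@dataclass(frozen=True)
class FormulationDataset:
    """Paired formulations and dissolution profiles — the training corpus.

    Ids are unique and every profile shares one common sampling schedule.
    """

    records: tuple[tuple[str, Formulation, DissolutionProfile], ...]

    def __init__(
        self, records: Iterable[tuple[str, Formulation, DissolutionProfile]]
    ):
        recs = tuple((str(i), f, p) for i, f, p in records)
        ids = [r[0] for r in recs]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids: {dup}")
        if recs:
            t0 = recs[0][2].times_h
            for rid, _, prof in recs:
                if prof.times_h != t0:
                    raise ScheduleMismatchError(
                        f"record {rid!r} has schedule {prof.times_h}, expected {t0}"
                    )
        object.__setattr__(self, "records", recs)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r[0] for r in self.records)

    @property
    def times_h(self) -> tuple[float, ...]:
        if not self.records:
            return CANONICAL_TIMES_H
        return self.records[0][2].times_h

    def inputs(self) -> np.ndarray:
        """N x 4 matrix of compositions in canonical factor order."""
        return np.array([f.as_array() for _, f, _ in self.records], dtype=float)

    def targets(self) -> np.ndarray:
        """N x T matrix of % released at each sampling time."""
        return np.array([p.as_array() for _, _, p in self.records], dtype=float)

    def subset(self, indices: Sequence[int]) -> "FormulationDataset":
        return FormulationDataset(self.records[i] for i in indices)
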