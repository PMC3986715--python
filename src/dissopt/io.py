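"""Dataset file I/O and the 30-run design fixture.

File format: comma-delimited UTF-8 text with header
``id, methocel_mg, xanthan_mg, carbopol_mg, surelease_pct, t1h, t2h, ...``.
Profile columns are named ``t<hours>h``; sampling times are parsed from the
headers, so schedules other than the canonical 1/2/4/6/8/12 h round-trip too.
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd

from .core import (
    FACTOR_NAMES,
    DissolutionProfile,
    DomainError,
    Formulation,
    FormulationDataset,
    RecordError,
    SchemaError,
)

__all__ = ["read_dataset", "write_dataset", "study_design_fixture", "time_column_name"]

_TIME_COL = re.compile(r"^t(\d+(?:\.\d+)?)h$")


def time_column_name(t_h: float) -> str:
    """Header name for a sampling time, e.g. 1.0 -> 't1h', 2.5 -> 't2.5h'."""
    return f"t{t_h:g}h"


def _profile_columns(columns) -> list[tuple[str, float]]:
    out = []
    for c in columns:
        m = _TIME_COL.match(str(c).strip())
        if m:
            out.append((c, float(m.group(1))))
    return out


def read_dataset(path: str | Path, require_profiles: bool = True) -> FormulationDataset:
    """Read a formulation/dissolution table from delimited text.

    Raises :class:`SchemaError` for missing columns and :class:`RecordError`
    (carrying the row id) for non-numeric or out-of-domain cells.
    """
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    df.columns = [str(c).strip() for c in df.columns]
    if "id" not in df.columns:
        raise SchemaError("missing column 'id'")
    for name in FACTOR_NAMES:
        if name not in df.columns:
            raise SchemaError(f"missing column {name!r}")
    prof_cols = _profile_columns(df.columns)
    if require_profiles and not prof_cols:
        raise SchemaError("no profile columns (expected headers like 't1h')")
    prof_cols.sort(key=lambda ct: ct[1])
    times = tuple(t for _, t in prof_cols)

    records = []
    for _, row in df.iterrows():
        rid = str(row["id"]).strip()
        comp = []
        for name in FACTOR_NAMES:
            raw = row[name]
            try:
                comp.append(float(raw))
            except (TypeError, ValueError):
                raise RecordError(f"record {rid!r}: non-numeric {name}={raw!r}")
        try:
            formulation = Formulation(*comp)
        except DomainError as e:
            raise RecordError(f"record {rid!r}: {e}") from e
        release = []
        for col, t in prof_cols:
            raw = row[col]
            try:
                v = float(raw)
            except (TypeError, ValueError):
                raise RecordError(f"record {rid!r}: non-numeric {col}={raw!r}")
            if not (0.0 <= v <= 100.0):
                raise RecordError(
                    f"record {rid!r}: {col}={v!r} outside [0, 100]"
                )
            release.append(v)
        records.append((rid, formulation, DissolutionProfile(times, release)))
    return FormulationDataset(records)


def write_dataset(
    dataset: FormulationDataset, path: str | Path, float_format: str = "%.10g"
) -> None:
    """Write a dataset as delimited text; round-trips through read_dataset."""
    times = dataset.times_h
    cols = ["id", *FACTOR_NAMES, *(time_column_name(t) for t in times)]
    rows = []
    for rid, f, p in dataset:
        rows.append([rid, *f.as_tuple(), *p.release_pct])
    df = pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)
    df.to_csv(path, index=False, float_format=float_format)


# The 30 compositions of the study's central composite design, in printed
# order SAL001-SAL030: 16 factorial points at coded +/-1, 8 axial points at
# coded +/-2 on a single factor, and 6 replicated center runs.
_DESIGN_ROWS: tuple[tuple[str, float, float, float, float], ...] = (
    ("SAL001", 120, 50, 10, 12),
    ("SAL002", 60, 50, 10, 12),
    ("SAL003", 60, 50, 10, 4),
    ("SAL004", 60, 50, 20, 12),
    ("SAL005", 90, 75, 15, 16),
    ("SAL006", 60, 50, 10, 20),
    ("SAL007", 90, 25, 15, 16),
    ("SAL008", 30, 75, 15, 16),
    ("SAL009", 60, 50, 10, 12),
    ("SAL010", 90, 75, 5, 8),
    ("SAL011", 0, 50, 10, 12),
    ("SAL012", 30, 25, 5, 16),
    ("SAL013", 60, 50, 10, 12),
    ("SAL014", 30, 25, 15, 8),
    ("SAL015", 60, 50, 10, 12),
    ("SAL016", 60, 100, 10, 12),
    ("SAL017", 90, 75, 5, 16),
    ("SAL018", 30, 25, 15, 16),
    ("SAL019", 90, 25, 5, 8),
    ("SAL020", 90, 75, 15, 8),
    ("SAL021", 30, 75, 5, 16),
    ("SAL022", 30, 25, 5, 8),
    ("SAL023", 30, 75, 5, 8),
    ("SAL024", 90, 25, 15, 8),
    ("SAL025", 60, 50, 0, 12),
    ("SAL026", 90, 25, 5, 16),
    ("SAL027", 60, 0, 10, 12),
    ("SAL028", 60, 50, 10, 12),
    ("SAL029", 60, 50, 10, 12),
    ("SAL030", 30, 75, 15, 8),
)


def study_design_fixture(with_ids: bool = False):
    """The 30 central-composite-design compositions, in run order.

    Returns a list of :class:`Formulation`; with ``with_ids=True`` a list of
    ``(id, Formulation)`` pairs instead.
    """
    out = [
        (rid, Formulation(m, x, c, s)) for rid, m, x, c, s in _DESIGN_ROWS
    ]
    if with_ids:
        return out
    return [f for _, f in out]
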