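"""Domain types and CSV readers/writers for twin-pair survey tables.

A *twin pair* is one family with two same-aged twins. Tables come in two
layouts:

* **wide** -- one row per family, twin-specific columns suffixed ``_1``/``_2``;
* **long** -- one row per twin, twin order given by the ``ptyp`` column
  (1 or 2), family-level columns repeated on both rows.

Missing values are empty cells (``NA`` also accepted on read); no sentinel
numbers are ever used. Family-level variables (zygosity, parental education)
must agree across co-twin rows in the long layout -- disagreement raises
:class:`DataError` rather than being silently resolved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "TwinObservation",
    "TwinPairRecord",
    "TwinPairTable",
    "FormatError",
    "DataError",
    "read_twin_table",
    "write_twin_table",
]

#: per-twin survey columns, in canonical order
TWIN_COLUMNS = (
    "sex",
    "age",
    "school_type",
    "grade_math",
    "grade_german",
    "aspiration",
    "success_prob",
    "cft1",
    "cft2",
    "cft3",
    "cft4",
    "expectation_raw",
)
#: family-level columns
FAMILY_COLUMNS = ("family_id", "zygosity", "par_edu_years")

CFT_MAXIMA = (15.0, 15.0, 15.0, 11.0)

_NUMERIC_TWIN_COLUMNS = frozenset(TWIN_COLUMNS) - {"sex", "school_type"}


class FormatError(ValueError):
    """Malformed file structure (missing/unknown columns, bad layout)."""


class DataError(ValueError):
    """Structurally valid file with inconsistent or out-of-range content."""


def _is_missing(x) -> bool:
    if x is None:
        return True
    if isinstance(x, float) and math.isnan(x):
        return True
    if isinstance(x, str) and x.strip() in ("", "NA", "NaN", "nan"):
        return True
    return x is pd.NA or x is pd.NaT


@dataclass
class TwinObservation:
    """Raw survey variables for one twin. Any field may be missing (None)."""

    sex: Optional[str] = None  # "male" / "female"
    age: Optional[float] = None  # years at wave 1
    school_type: Optional[str] = None  # categorical code
    grade_math: Optional[float] = None  # 1-6, 1 = best
    grade_german: Optional[float] = None
    aspiration: Optional[int] = None  # 1 lower / 2 intermediate / 3 higher
    success_prob: Optional[float] = None  # percent, 0-100
    cft1: Optional[float] = None  # CFT subscale sum scores
    cft2: Optional[float] = None
    cft3: Optional[float] = None
    cft4: Optional[float] = None
    expectation_raw: Optional[float] = None  # optional precomputed score

    def __post_init__(self):
        # canonical numeric types so round trips compare cleanly
        for f in _NUMERIC_TWIN_COLUMNS:
            v = getattr(self, f)
            if v is not None:
                setattr(self, f, float(v))
        if self.aspiration is not None:
            self.aspiration = int(self.aspiration)

    @property
    def cft_subscales(self) -> tuple:
        return (self.cft1, self.cft2, self.cft3, self.cft4)

    def validate(self, label: str = "twin") -> None:
        if self.sex is not None and self.sex not in ("male", "female"):
            raise DataError(f"{label}: sex must be 'male'/'female', got {self.sex!r}")
        for name in ("grade_math", "grade_german"):
            g = getattr(self, name)
            if g is not None and not (1.0 <= g <= 6.0):
                raise DataError(f"{label}: {name}={g} outside [1, 6]")
        if self.aspiration is not None and self.aspiration not in (1, 2, 3):
            raise DataError(f"{label}: aspiration={self.aspiration} not in {{1,2,3}}")
        if self.success_prob is not None and not (0.0 <= self.success_prob <= 100.0):
            raise DataError(f"{label}: success_prob={self.success_prob} outside [0, 100]")
        for i, (v, vmax) in enumerate(zip(self.cft_subscales, CFT_MAXIMA), start=1):
            if v is not None and not (0.0 <= v <= vmax):
                raise DataError(f"{label}: cft{i}={v} outside [0, {vmax}]")


@dataclass
class TwinPairRecord:
    """One family: zygosity, both twins' raw variables, family-level moderator.

    Twin indices are exchangeable: swapping ``twin1`` and ``twin2`` yields an
    equally valid record.
    """

    family_id: str
    zygosity: str  # "MZ" / "DZ"
    twin1: TwinObservation = field(default_factory=TwinObservation)
    twin2: TwinObservation = field(default_factory=TwinObservation)
    par_edu_years: Optional[float] = None  # mean of both parents if they differ

    def validate(self) -> None:
        if self.zygosity not in ("MZ", "DZ"):
            raise DataError(
                f"family {self.family_id}: zygosity must be MZ or DZ, got {self.zygosity!r}"
            )
        self.twin1.validate(f"family {self.family_id} twin 1")
        self.twin2.validate(f"family {self.family_id} twin 2")

    def swapped(self) -> "TwinPairRecord":
        return replace(self, twin1=self.twin2, twin2=self.twin1)


@dataclass
class TwinPairTable:
    """Ordered collection of :class:`TwinPairRecord` with provenance metadata."""

    records: list
    source: Optional[str] = None
    layout: Optional[str] = None

    @property
    def n_pairs(self) -> int:
        return len(self.records)

    def validate(self) -> None:
        seen = set()
        for rec in self.records:
            if rec.family_id in seen:
                raise DataError(f"duplicate family_id {rec.family_id!r}")
            seen.add(rec.family_id)
            rec.validate()

    def to_wide_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            row = {
                "family_id": rec.family_id,
                "zygosity": rec.zygosity,
                "par_edu_years": rec.par_edu_years,
            }
            for t, obs in ((1, rec.twin1), (2, rec.twin2)):
                for col in TWIN_COLUMNS:
                    row[f"{col}_{t}"] = getattr(obs, col)
            rows.append(row)
        cols = list(FAMILY_COLUMNS) + [f"{c}_{t}" for t in (1, 2) for c in TWIN_COLUMNS]
        return pd.DataFrame(rows, columns=cols)

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            for t, obs in ((1, rec.twin1), (2, rec.twin2)):
                row = {
                    "family_id": rec.family_id,
                    "ptyp": t,
                    "zygosity": rec.zygosity,
                    "par_edu_years": rec.par_edu_years,
                }
                for col in TWIN_COLUMNS:
                    row[col] = getattr(obs, col)
                rows.append(row)
        cols = ["family_id", "ptyp", "zygosity", "par_edu_years"] + list(TWIN_COLUMNS)
        return pd.DataFrame(rows, columns=cols)


def _parse_value(col: str, raw):
    if _is_missing(raw):
        return None
    if col in ("sex", "school_type"):
        return str(raw).strip()
    try:
        val = float(raw)
    except (TypeError, ValueError) as exc:
        raise DataError(f"column {col!r}: cannot parse {raw!r} as a number") from exc
    if col == "aspiration":
        ival = int(round(val))
        if abs(val - ival) > 1e-9:
            raise DataError(f"column {col!r}: non-integer aspiration {raw!r}")
        return ival
    return val


def _obs_from_mapping(mapping, suffix: str = "") -> TwinObservation:
    kwargs = {}
    for col in TWIN_COLUMNS:
        key = f"{col}{suffix}"
        if key in mapping:
            kwargs[col] = _parse_value(col, mapping[key])
    return TwinObservation(**kwargs)


def _check_header(present: Sequence[str], required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in present]
    if missing:
        raise FormatError(f"{path}: missing required columns: {', '.join(missing)}")


def read_twin_table(path, layout: str = "wide") -> TwinPairTable:
    """Read a twin-pair table from CSV.

    Parameters
    ----------
    path : path-like
        CSV file to read.
    layout : {"wide", "long"}
        ``wide``: one row per pair; ``long``: one row per twin, paired by
        ``family_id`` with twin order from ``ptyp``. A singleton twin (no
        co-twin row) yields a record whose other twin is fully missing.
    """
    if layout not in ("wide", "long"):
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    records = []
    if layout == "wide":
        required = list(FAMILY_COLUMNS) + [f"{c}_{t}" for t in (1, 2) for c in TWIN_COLUMNS]
        _check_header(df.columns, required, path)
        for _, row in df.iterrows():
            mapping = row.to_dict()
            fid = str(mapping["family_id"]).strip()
            zyg = str(mapping["zygosity"]).strip()
            rec = TwinPairRecord(
                family_id=fid,
                zygosity=zyg,
                twin1=_obs_from_mapping(mapping, "_1"),
                twin2=_obs_from_mapping(mapping, "_2"),
                par_edu_years=_parse_value("par_edu_years", mapping["par_edu_years"])
                if not _is_missing(mapping["par_edu_years"])
                else None,
            )
            records.append(rec)
    else:
        required = ["family_id", "ptyp", "zygosity", "par_edu_years"] + list(TWIN_COLUMNS)
        _check_header(df.columns, required, path)
        by_family: dict = {}
        order: list = []
        for _, row in df.iterrows():
            mapping = row.to_dict()
            fid = str(mapping["family_id"]).strip()
            if fid not in by_family:
                by_family[fid] = []
                order.append(fid)
            by_family[fid].append(mapping)
        for fid in order:
            rows = by_family[fid]
            if len(rows) > 2:
                raise DataError(f"family {fid!r}: {len(rows)} rows in long layout (max 2)")
            zygs = {str(r["zygosity"]).strip() for r in rows}
            if len(zygs) > 1:
                raise DataError(f"family {fid!r}: co-twins disagree on zygosity {sorted(zygs)}")
            pes = {
                _parse_value("par_edu_years", r["par_edu_years"])
                for r in rows
                if not _is_missing(r["par_edu_years"])
            }
            if len(pes) > 1:
                raise DataError(
                    f"family {fid!r}: co-twins disagree on par_edu_years {sorted(pes)}"
                )
            obs = {1: TwinObservation(), 2: TwinObservation()}
            for r in rows:
                try:
                    t = int(float(r["ptyp"]))
                except (TypeError, ValueError) as exc:
                    raise DataError(f"family {fid!r}: unparseable ptyp {r['ptyp']!r}") from exc
                if t not in (1, 2):
                    raise DataError(f"family {fid!r}: ptyp must be 1 or 2, got {t}")
                obs[t] = _obs_from_mapping(r)
            records.append(
                TwinPairRecord(
                    family_id=fid,
                    zygosity=next(iter(zygs)),
                    twin1=obs[1],
                    twin2=obs[2],
                    par_edu_years=next(iter(pes)) if pes else None,
                )
            )
    table = TwinPairTable(records=records, source=str(path), layout=layout)
    table.validate()
    return table


def _fmt(value) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    if isinstance(value, float) and value.is_integer() and abs(value) < 1e15:
        return str(int(value))
    return str(value)


def write_twin_table(table: TwinPairTable, path, layout: str = "wide") -> None:
    """Write *table* to CSV at *path*; output is parseable by :func:`read_twin_table`.

    Layout conversion is lossless: a wide table written long and read back
    carries identical values (missing cells stay missing).
    """
    if layout not in ("wide", "long"):
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")
    table.validate()
    df = table.to_wide_frame() if layout == "wide" else table.to_long_frame()
    df = df.map(_fmt)
    df.to_csv(path, index=False)
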