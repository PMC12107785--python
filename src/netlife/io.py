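"""Readers and writers for the standard text formats, plus run configuration.

Life tables travel in the HMD-style 1×1 period layout (header lines, then
columns Year Age mx qx ax lx dx Lx Tx ex, radix 100 000 on disk, the
terminal age marked with a ``+``); cohorts travel as CSV with the fixed
header ``id,diagnosis_date,age_at_diagnosis,vital_status,outcome_date,
site,dco``.  Internally the radix is 1.0 and ``qx`` is authoritative: tables
are rebuilt from ``qx`` on read so the in-memory object always satisfies the
life-table identities regardless of rounding on disk.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import yaml

from .exceptions import InvalidInputError, ParseError
from .lifetables import LifeTable, MortalityCounts, build_lifetable_from_qx
from .netsurv import PatientRecord

__all__ = [
    "read_hmd_table",
    "write_hmd_table",
    "read_cohort_csv",
    "write_cohort_csv",
    "read_mortality_counts_csv",
    "write_mortality_counts_csv",
    "compare_published_estimates",
    "RunConfig",
]

COHORT_HEADER = ["id", "diagnosis_date", "age_at_diagnosis", "vital_status",
                 "outcome_date", "site", "dco"]

_HMD_COLUMNS = ("Year", "Age", "mx", "qx", "ax", "lx", "dx", "Lx", "Tx", "ex")


def read_hmd_table(path) -> dict[int, LifeTable]:
    """Parse an HMD 1×1 period life-table file into a per-year series.

    The survivorship radix is rescaled to 1.0 and the table is rebuilt from
    the ``qx`` column; an age token ending in ``+`` marks the open terminal
    age.
    """
    path = Path(path)
    rows: list[tuple[int, int, float, float]] = []  # year, age, mx, qx
    header_seen = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if not header_seen:
                if tokens[0] == "Year" and "Age" in tokens:
                    if "qx" not in tokens:
                        raise ParseError("header lacks a qx column", lineno)
                    header_seen = True
                continue
            if len(tokens) != len(_HMD_COLUMNS):
                raise ParseError(
                    f"expected {len(_HMD_COLUMNS)} columns, got {len(tokens)}",
                    lineno)
            try:
                year = int(tokens[0])
                age = int(tokens[1].rstrip("+"))
                mx = float(tokens[2])
                qx = float(tokens[3])
            except ValueError as exc:
                raise ParseError(f"malformed row: {exc}", lineno) from None
            if not 0.0 <= qx <= 1.0:
                raise ParseError(
                    f"qx={qx} outside [0,1] at year {year}, age {age}",
                    lineno)
            rows.append((year, age, mx, qx))
    if not header_seen:
        raise ParseError("no header row (Year Age mx qx ...) found")
    series: dict[int, LifeTable] = {}
    years = sorted({r[0] for r in rows})
    for y in years:
        sub = sorted((r for r in rows if r[0] == y), key=lambda r: r[1])
        ages = np.array([r[1] for r in sub])
        if ages[0] != 0 or np.any(np.diff(ages) != 1):
            raise ParseError(f"year {y}: ages not contiguous from 0")
        mx = np.array([r[2] for r in sub])
        qx = np.array([r[3] for r in sub])
        series[y] = build_lifetable_from_qx(qx, year=y, max_age=int(ages[-1]),
                                            mx=mx)
    return series


def write_hmd_table(path, series: dict[int, LifeTable] | LifeTable,
                    name: str = "Synthetic population") -> None:
    """Write a life-table series in the HMD 1×1 period layout."""
    if isinstance(series, LifeTable):
        series = {series.year: series}
    path = Path(path)
    lines = [f"{name}, Life tables (period 1x1)", ""]
    lines.append("  Year          Age         mx       qx       ax"
                 "          lx       dx       Lx        Tx     ex")
    for y in sorted(series):
        lt = series[y]
        radix = 100_000.0
        # quantize first so the file's derived columns are reproducible from
        # its own printed qx (write -> read -> write is byte-stable)
        q5 = np.round(lt.qx, 5)
        m5 = np.round(lt.mx, 5)
        n = lt.max_age + 1
        lx_q = np.empty(n)
        lx_q[0] = 1.0
        np.cumprod(1.0 - q5[:-1], out=lx_q[1:])
        lx_i = np.rint(lx_q * radix).astype(int)
        dx_i = np.rint(lx_q * q5 * radix).astype(int)
        Lx = np.empty(n)
        Lx[:-1] = lx_i[:-1] - 0.5 * (lx_i[:-1] - lx_i[1:])
        mterm = m5[-1]
        Lx[-1] = lx_i[-1] / mterm if mterm > 0 else lx_i[-1] / 2.0
        Tx = np.cumsum(Lx[::-1])[::-1]
        with np.errstate(divide="ignore", invalid="ignore"):
            ex = np.where(lx_i > 0, Tx / np.maximum(lx_i, 1), 0.0)
        for a in range(n):
            age_tok = f"{a}+" if a == lt.max_age else str(a)
            lines.append(
                f"  {y}    {age_tok:>9s}   {m5[a]:8.5f} {q5[a]:8.5f}"
                f"     0.50    {lx_i[a]:7d}  {dx_i[a]:7d}  {int(round(Lx[a])):7d}"
                f"  {int(round(Tx[a])):8d}  {ex[a]:6.2f}"
            )
    path.write_text("\n".join(lines) + "\n")


def read_cohort_csv(path) -> list[PatientRecord]:
    """Read a cohort file in the documented CSV dialect.

    Dates are ISO-8601; unknown vital-status tokens and malformed dates are
    parse errors carrying the row number.  A record whose death precedes
    diagnosis is loaded as-is — flagging it is the job of the exclusion
    step, not the parser.
    """
    path = Path(path)
    records: list[PatientRecord] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError("empty cohort file") from None
        if header != COHORT_HEADER:
            raise ParseError(
                f"unexpected header {header!r}; expected {COHORT_HEADER!r}",
                1)
        for rowno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(COHORT_HEADER):
                raise ParseError(f"expected {len(COHORT_HEADER)} fields, "
                                 f"got {len(row)}", rowno)
            rid, dx_s, age_s, status, out_s, site, dco_s = row
            try:
                dx = date.fromisoformat(dx_s)
                out = date.fromisoformat(out_s)
            except ValueError as exc:
                raise ParseError(f"bad date: {exc}", rowno) from None
            if status not in ("dead", "alive"):
                raise ParseError(f"unknown vital_status {status!r}", rowno)
            if dco_s not in ("0", "1"):
                raise ParseError(f"dco must be 0 or 1, got {dco_s!r}", rowno)
            try:
                age = float(age_s)
            except ValueError:
                raise ParseError(f"bad age {age_s!r}", rowno) from None
            records.append(PatientRecord(
                id=rid, diagnosis_date=dx, age_at_diagnosis=age,
                vital_status=status, outcome_date=out, site=site,
                dco=dco_s == "1"))
    return records


def write_cohort_csv(path, cohort) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(COHORT_HEADER)
        for p in cohort:
            writer.writerow([
                p.id, p.diagnosis_date.isoformat(),
                f"{p.age_at_diagnosis:.4f}", p.vital_status,
                p.outcome_date.isoformat(), p.site, int(p.dco)])


def read_mortality_counts_csv(path) -> dict[int, MortalityCounts]:
    """CSV with columns year,age,deaths,person_years -> per-year counts."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"year", "age", "deaths", "person_years"}
    if not required.issubset(df.columns):
        raise ParseError(f"mortality counts need columns {sorted(required)}")
    out = {}
    for y, sub in df.groupby("year"):
        sub = sub.sort_values("age")
        out[int(y)] = MortalityCounts(
            year=int(y), age=sub["age"].to_numpy(),
            deaths=sub["deaths"].to_numpy(dtype=float),
            person_years=sub["person_years"].to_numpy(dtype=float))
    return out


def write_mortality_counts_csv(path, counts: dict[int, MortalityCounts]):
    import pandas as pd

    frames = []
    for y in sorted(counts):
        c = counts[y]
        frames.append(pd.DataFrame({
            "year": c.year, "age": c.age, "deaths": c.deaths,
            "person_years": c.person_years}))
    pd.concat(frames).to_csv(path, index=False)


def compare_published_estimates(estimate_a: float, estimate_b: float) -> float:
    """Difference b − a in percentage points, rounded to one decimal.

    Both inputs on the percent scale; the reporting convention for
    cross-study comparison tables (second study minus first).
    """
    return round(float(estimate_b) - float(estimate_a), 1)


@dataclass
class RunConfig:
    """Configuration of one pipeline run; flags override file values."""

    cohort_path: str = ""
    lifetable_path: str = ""
    method: str = "hmd"  # hmd | hld | eurocare | mfm | ewbank
    knots: tuple = ()
    alpha: float = 0.0
    beta: float = 1.0
    kappa: float = 0.0
    lambda_: float = 0.0
    standard_path: str = ""
    sites: tuple = ()
    horizon: float = 5.0
    weights: str = "breast"
    output_dir: str = "results"
    seed: int = 12345

    def __post_init__(self):
        if self.horizon <= 0:
            raise InvalidInputError("horizon must be positive")
        if self.method not in ("hmd", "hld", "eurocare", "mfm", "ewbank"):
            raise InvalidInputError(f"unknown method {self.method!r}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "lambda" in data:
            data["lambda_"] = data.pop("lambda")
        data.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("knots", "sites"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)
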