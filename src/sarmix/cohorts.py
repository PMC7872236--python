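"""Ingest per-fish detection records and aggregate them to cohort lattices.

The raw material is one row per PIT-tagged smolt: the day-of-year and year
of its last juvenile detection at the downstream dam, its rearing type
(hatchery or wild), a watershed label, and whether it was later detected
as a returning adult.  After a fixed sequence of inclusion filters the
records are counted into a complete day-by-year lattice per rear type:
``n_jt`` smolts passed on day *j* of year *t*, of which ``k_jt`` returned.

Filters are applied in a fixed order and every excluded record is
attributed to exactly one rule (the first that matches), so the filter
report is a partition of the input.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DetectionRecord",
    "FilterConfig",
    "FilterReport",
    "CohortTable",
    "parse_detections",
    "apply_filters",
    "aggregate_cohorts",
]

REAR_TYPES = ("hatchery", "wild", "unknown")
RELEASE_SITES = ("above_confluence", "below_confluence")

#: Exclusion rules in the order they claim records.
FILTER_RULES = (
    "unknown_rear_type",
    "small_region",
    "below_confluence",
    "short_return",
    "barged",
    "day_window",
)

_TRUE = {"1", "true", "t", "yes", "y"}
_FALSE = {"0", "false", "f", "no", "n", ""}

#: Canonical column names; a schema maps these to the file's own headers.
DEFAULT_SCHEMA = {
    "tag_id": "tag_id",
    "year": "year",
    "day": "day",
    "rear_type": "rear_type",
    "region": "region",
    "adult_detected": "adult_detected",
    "barged": "barged",
    "return_interval_years": "return_interval_years",
    "release_site": "release_site",
}
REQUIRED_FIELDS = ("tag_id", "year", "day", "rear_type", "adult_detected")


@dataclass
class DetectionRecord:
    """One tagged fish: juvenile passage cell plus adult-return outcome."""

    tag_id: str
    year: int
    day: int
    rear_type: str
    adult_detected: bool
    region: str = ""
    barged: bool = False
    return_interval_years: float | None = None
    release_site: str = "above_confluence"

    def __post_init__(self) -> None:
        if not 1 <= self.day <= 366:
            raise ValueError(f"day {self.day} outside [1, 366]")
        if self.rear_type not in REAR_TYPES:
            raise ValueError(f"unknown rear_type {self.rear_type!r}")
        if self.release_site not in RELEASE_SITES:
            raise ValueError(f"unknown release_site {self.release_site!r}")
        if (
            self.adult_detected
            and self.return_interval_years is not None
            and self.return_interval_years <= 0
        ):
            raise ValueError(
                "adult_detected record with non-positive return interval"
            )


@dataclass
class FilterConfig:
    """Inclusion-filter settings.

    Defaults follow the study design this package targets: migration days
    100-190 (April 9 to July 8, ordinal days under the non-leap
    convention), 16 outmigration years, and a 200-fish minimum per
    watershed over the whole window.
    """

    day_min: int = 100
    day_max: int = 190
    years: tuple[int, ...] = tuple(range(2000, 2016))
    min_region_count: int = 200
    min_return_interval: float = 1.0

    @classmethod
    def from_mapping(cls, d: Mapping) -> "FilterConfig":
        kw = {k: d[k] for k in (
            "day_min", "day_max", "years", "min_region_count",
            "min_return_interval") if k in d}
        if "years" in kw:
            kw["years"] = tuple(int(y) for y in kw["years"])
        return cls(**kw)


@dataclass
class FilterReport:
    """Counts of records excluded per rule, plus the retained total.

    ``retained + sum(excluded.values()) == total`` always holds: the rules
    partition the input, each exclusion attributed to the first matching
    rule.
    """

    total: int
    retained: int
    excluded: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.retained + sum(self.excluded.values()) != self.total:
            raise ValueError("filter report does not partition the input")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {"total": self.total, "retained": self.retained,
             "excluded": dict(self.excluded)},
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


class CohortTable:
    """Complete day-by-year lattice of migrant counts and adult returns.

    Cells with no fish carry ``n = 0``; ``0 <= k <= n`` everywhere.
    """

    def __init__(
        self,
        rear_type: str,
        days: Sequence[int],
        years: Sequence[int],
        n: np.ndarray,
        k: np.ndarray,
    ) -> None:
        self.rear_type = rear_type
        self.days = np.asarray(days, dtype=int)
        self.years = np.asarray(years, dtype=int)
        self.n = np.asarray(n)
        self.k = np.asarray(k)
        if self.n.shape != (self.days.size, self.years.size):
            raise ValueError("n shape does not match (days, years)")
        if self.k.shape != self.n.shape:
            raise ValueError("k shape does not match n")
        if np.any(self.n < 0) or np.any(self.k < 0) or np.any(self.k > self.n):
            raise ValueError("need 0 <= k <= n in every cell")
        if np.any(np.diff(self.days) != 1):
            raise ValueError("day lattice must be contiguous")

    @property
    def shape(self) -> tuple[int, int]:
        return self.n.shape

    @property
    def n_total(self) -> int:
        return int(self.n.sum())

    @property
    def k_total(self) -> int:
        return int(self.k.sum())

    def observed_mask(self) -> np.ndarray:
        return self.n > 0

    def to_frame(self) -> pd.DataFrame:
        jj, tt = np.meshgrid(
            np.arange(self.days.size), np.arange(self.years.size),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "rear_type": self.rear_type,
                "year": self.years[tt.ravel()],
                "day": self.days[jj.ravel()],
                "n": self.n.ravel(),
                "k": self.k.ravel(),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, rear_type: str | None = None) -> "CohortTable":
        df = frame
        if rear_type is not None:
            df = df[df["rear_type"] == rear_type]
        elif df["rear_type"].nunique() != 1:
            raise ValueError("frame holds several rear types; pass rear_type")
        rt = df["rear_type"].iloc[0] if rear_type is None else rear_type
        days = np.sort(df["day"].unique())
        years = np.sort(df["year"].unique())
        n = np.zeros((days.size, years.size), dtype=int)
        k = np.zeros_like(n)
        jidx = df["day"].map({d: i for i, d in enumerate(days)}).to_numpy()
        tidx = df["year"].map({y: i for i, y in enumerate(years)}).to_numpy()
        n[jidx, tidx] = df["n"].to_numpy()
        k[jidx, tidx] = df["k"].to_numpy()
        return cls(rt, days, years, n, k)

    @classmethod
    def read_csv(cls, path: str | Path, rear_type: str | None = None) -> "CohortTable":
        return cls.from_frame(pd.read_csv(path), rear_type=rear_type)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"CohortTable({self.rear_type!r}, days {self.days[0]}-{self.days[-1]}, "
            f"years {self.years[0]}-{self.years[-1]}, n={self.n_total}, "
            f"k={self.k_total})"
        )


@dataclass
class ParseIssue:
    row: int
    column: str
    value: str
    message: str


def _parse_bool(raw, column: str) -> bool:
    s = str(raw).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"cannot interpret {column}={raw!r} as boolean")


def parse_detections(
    path: str | Path | io.TextIOBase,
    schema: Mapping[str, str] | None = None,
    *,
    delimiter: str | None = None,
) -> tuple[list[DetectionRecord], list[ParseIssue]]:
    """Read a delimited text file of per-fish detections.

    Parameters
    ----------
    path
        CSV/TSV file with a header row.
    schema
        Optional mapping from canonical field names (see
        :data:`DEFAULT_SCHEMA`) to the file's column names.
    delimiter
        Field separator; sniffed by pandas when ``None``.

    Returns
    -------
    records, issues
        One :class:`DetectionRecord` per cleanly parsed row, plus a list of
        :class:`ParseIssue` for rows whose required fields could not be
        interpreted.  Bad rows are reported, never silently dropped.
    """
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False,
                     engine="python" if delimiter is None else "c")
    missing = [colmap[f] for f in REQUIRED_FIELDS if colmap[f] not in df.columns]
    if missing:
        raise KeyError(f"required column(s) missing: {missing}")
    records: list[DetectionRecord] = []
    issues: list[ParseIssue] = []
    for i, row in enumerate(df.itertuples(index=False)):
        rowd = dict(zip(df.columns, row))
        try:
            rear = rowd.get(colmap["rear_type"], "").strip().lower()
            if rear in ("h",):
                rear = "hatchery"
            elif rear in ("w",):
                rear = "wild"
            elif rear not in ("hatchery", "wild"):
                rear = "unknown"
            interval_raw = rowd.get(colmap["return_interval_years"], "").strip()
            site = rowd.get(colmap["release_site"], "").strip() or "above_confluence"
            rec = DetectionRecord(
                tag_id=rowd[colmap["tag_id"]],
                year=int(rowd[colmap["year"]]),
                day=int(rowd[colmap["day"]]),
                rear_type=rear,
                adult_detected=_parse_bool(rowd[colmap["adult_detected"]],
                                           "adult_detected"),
                region=rowd.get(colmap["region"], "").strip(),
                barged=_parse_bool(rowd.get(colmap["barged"], "0"), "barged"),
                return_interval_years=(
                    float(interval_raw) if interval_raw else None
                ),
                release_site=site,
            )
        except (ValueError, KeyError) as exc:
            bad_col = colmap["day"]
            issues.append(ParseIssue(row=i, column=bad_col,
                                     value=str(rowd), message=str(exc)))
            continue
        records.append(rec)
    return records, issues


def apply_filters(
    records: Iterable[DetectionRecord], cfg: FilterConfig | None = None
) -> tuple[list[DetectionRecord], FilterReport]:
    """Apply the inclusion filters in their fixed order.

    Rules, in attribution order: unknown rear type; watershed with fewer
    than ``min_region_count`` known-rear-type fish over the study window;
    release below the Snake/Columbia confluence; adult return in under
    ``min_return_interval`` years; barge-transported; passage day outside
    ``[day_min, day_max]``.  Each excluded record is counted under the
    first rule it violates, so the report partitions the input.

    The small-region rule is evaluated on the input restricted to records
    of known rear type.
    """
    cfg = cfg or FilterConfig()
    records = list(records)
    region_counts: dict[str, int] = {}
    for r in records:
        if r.rear_type != "unknown":
            region_counts[r.region] = region_counts.get(r.region, 0) + 1

    def first_violation(r: DetectionRecord) -> str | None:
        if r.rear_type == "unknown":
            return "unknown_rear_type"
        if region_counts.get(r.region, 0) < cfg.min_region_count:
            return "small_region"
        if r.release_site == "below_confluence":
            return "below_confluence"
        if (
            r.adult_detected
            and r.return_interval_years is not None
            and r.return_interval_years < cfg.min_return_interval
        ):
            return "short_return"
        if r.barged:
            return "barged"
        if not cfg.day_min <= r.day <= cfg.day_max:
            return "day_window"
        return None

    retained: list[DetectionRecord] = []
    excluded = {rule: 0 for rule in FILTER_RULES}
    for r in records:
        rule = first_violation(r)
        if rule is None:
            retained.append(r)
        else:
            excluded[rule] += 1
    report = FilterReport(
        total=len(records),
        retained=len(retained),
        excluded={k: v for k, v in excluded.items()},
    )
    return retained, report


def aggregate_cohorts(
    records: Iterable[DetectionRecord],
    day_min: int = 100,
    day_max: int = 190,
    years: Sequence[int] = tuple(range(2000, 2016)),
) -> dict[str, CohortTable]:
    """Count filtered records into one complete lattice per rear type.

    Raises if any record falls outside the lattice: filters must already
    have run.
    """
    years = np.asarray(sorted(years), dtype=int)
    days = np.arange(day_min, day_max + 1)
    yindex = {int(y): i for i, y in enumerate(years)}
    by_type: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for r in records:
        if not day_min <= r.day <= day_max or r.year not in yindex:
            raise ValueError(
                f"record {r.tag_id} at (day={r.day}, year={r.year}) lies "
                "outside the lattice; run apply_filters first"
            )
        if r.rear_type not in by_type:
            by_type[r.rear_type] = (
                np.zeros((days.size, years.size), dtype=int),
                np.zeros((days.size, years.size), dtype=int),
            )
        n, k = by_type[r.rear_type]
        j = r.day - day_min
        t = yindex[r.year]
        n[j, t] += 1
        if r.adult_detected:
            k[j, t] += 1
    if not by_type:
        by_type["wild"] = (
            np.zeros((days.size, years.size), dtype=int),
            np.zeros((days.size, years.size), dtype=int),
        )
    return {
        rt: CohortTable(rt, days, years, n, k)
        for rt, (n, k) in sorted(by_type.items())
    }
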