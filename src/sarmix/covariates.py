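"""Year-level marine covariates from monthly environmental series.

Monthly index series (upwelling, SST anomalies, gyre/ENSO indices, river
flow...) are binned to three-month seasonal means, assembled into a
year-by-covariate table, standardised column-wise, and screened for
collinear pairs before entering the survival model.

Season conventions (for outmigration year *y*):

==========  =======================
``win``     Dec(y-1), Jan(y), Feb(y)
``spr``     Mar, Apr, May of y
``sum``     Jun, Jul, Aug of y
``aut``     Sep, Oct, Nov of y
==========  =======================

Winter spans the calendar boundary and is assigned to the outmigration
year using the *prior* December, i.e. the winter immediately before the
smolts enter the ocean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MonthlySeries",
    "CovariateMatrix",
    "seasonal_mean",
    "build_yearly_table",
    "standardize",
    "correlation_screen",
]

SEASONS = ("win", "spr", "sum", "aut")

#: (year offset, month) triples defining each season for outmigration year y.
SEASON_MONTHS = {
    "win": ((-1, 12), (0, 1), (0, 2)),
    "spr": ((0, 3), (0, 4), (0, 5)),
    "sum": ((0, 6), (0, 7), (0, 8)),
    "aut": ((0, 9), (0, 10), (0, 11)),
}


class MissingMonthError(KeyError):
    """A month needed for a seasonal mean is absent from the series."""


@dataclass
class MonthlySeries:
    """A named monthly environmental series: (year, month) -> value."""

    name: str
    values: dict[tuple[int, int], float] = field(default_factory=dict)
    units: str = ""

    def __post_init__(self) -> None:
        self.values = {(int(y), int(m)): float(v)
                       for (y, m), v in self.values.items()}
        for (_, m) in self.values:
            if not 1 <= m <= 12:
                raise ValueError(f"month {m} outside 1..12")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, name: str | None = None) -> "MonthlySeries":
        """Build from a long-format frame with columns variable/year/month/value."""
        df = frame
        if name is not None:
            df = df[df["variable"] == name]
        elif df["variable"].nunique() != 1:
            raise ValueError("frame holds several variables; pass name")
        nm = name if name is not None else df["variable"].iloc[0]
        vals = {(int(r.year), int(r.month)): float(r.value)
                for r in df.itertuples(index=False)}
        if len(vals) != len(df):
            raise ValueError(f"duplicate (year, month) entries in {nm!r}")
        return cls(nm, vals)


def seasonal_mean(series: MonthlySeries, season: str, year: int) -> float:
    """Arithmetic mean of the three monthly values in ``season`` of ``year``.

    ``win`` uses December of the previous calendar year.  A missing month
    raises :class:`MissingMonthError` naming it.
    """
    if season not in SEASON_MONTHS:
        raise ValueError(f"unknown season {season!r}; expected one of {SEASONS}")
    vals = []
    for dy, month in SEASON_MONTHS[season]:
        key = (year + dy, month)
        if key not in series.values:
            raise MissingMonthError(
                f"{series.name}: month {key[1]}/{key[0]} needed for "
                f"{season}({year}) is missing"
            )
        vals.append(series.values[key])
    return float(np.mean(vals))


def build_yearly_table(
    series: Iterable[MonthlySeries],
    seasons: Mapping[str, Sequence[str]] | Sequence[str],
    years: Sequence[int],
) -> pd.DataFrame:
    """Assemble a raw year-by-covariate table of seasonal means.

    ``seasons`` is either one list of seasons applied to every series, or a
    mapping from series name to its seasons.  Covariates are named
    ``"<variable>.<season>"``.
    """
    series = list(series)
    if not isinstance(seasons, Mapping):
        seasons = {s.name: list(seasons) for s in series}
    cols: dict[str, list[float]] = {}
    for s in series:
        for season in seasons.get(s.name, ()):
            cols[f"{s.name}.{season}"] = [
                seasonal_mean(s, season, int(y)) for y in years
            ]
    return pd.DataFrame(cols, index=pd.Index([int(y) for y in years], name="year"))


class CovariateMatrix:
    """Standardised year-level covariates: the model's X matrix.

    Each column is a z-score over the study years (sample standard
    deviation, n-1 denominator); the original means and standard
    deviations are stored for back-transformation.
    """

    def __init__(
        self,
        years: Sequence[int],
        names: Sequence[str],
        values: np.ndarray,
        means: np.ndarray | None = None,
        sds: np.ndarray | None = None,
    ) -> None:
        self.years = np.asarray(years, dtype=int)
        self.names = list(names)
        self.values = np.asarray(values, dtype=float)
        if self.values.shape != (self.years.size, len(self.names)):
            raise ValueError("values shape must be (n_years, n_covariates)")
        self.means = (np.zeros(len(self.names)) if means is None
                      else np.asarray(means, dtype=float))
        self.sds = (np.ones(len(self.names)) if sds is None
                    else np.asarray(sds, dtype=float))

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    def subset(self, names: Sequence[str]) -> np.ndarray:
        """(n_years, len(names)) slice in the given column order."""
        idx = [self.names.index(n) for n in names]
        return self.values[:, idx]

    def align(self, years: Sequence[int], names: Sequence[str]) -> np.ndarray:
        """Values for the requested years/columns (errors on missing years)."""
        pos = {int(y): i for i, y in enumerate(self.years)}
        try:
            rows = [pos[int(y)] for y in years]
        except KeyError as exc:
            raise KeyError(f"year {exc.args[0]} not in covariate matrix") from exc
        return self.subset(names)[rows, :]

    def back_transform(self) -> pd.DataFrame:
        raw = self.values * self.sds + self.means
        return pd.DataFrame(raw, index=pd.Index(self.years, name="year"),
                            columns=self.names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.years, name="year"),
                            columns=self.names)

    def to_csv(self, path: str | Path, scaling_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(path)
        if scaling_path is not None:
            Path(scaling_path).write_text(json.dumps(
                {"means": dict(zip(self.names, self.means)),
                 "sds": dict(zip(self.names, self.sds))}, indent=2))

    @classmethod
    def read_csv(cls, path: str | Path) -> "CovariateMatrix":
        df = pd.read_csv(path, index_col="year")
        return cls(df.index.to_numpy(), list(df.columns), df.to_numpy())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"CovariateMatrix({len(self.names)} covariates x "
                f"{self.years.size} years)")


def standardize(raw: pd.DataFrame) -> CovariateMatrix:
    """Column-wise z-scores of a raw year-by-covariate table.

    Uses the sample (n-1) standard deviation.  A zero-variance column is
    an error (it cannot inform survival and breaks the scaling).
    """
    if raw.isna().any().any():
        bad = raw.columns[raw.isna().any()].tolist()
        raise ValueError(f"missing cells in covariate column(s) {bad}")
    means = raw.mean(axis=0).to_numpy()
    sds = raw.std(axis=0, ddof=1).to_numpy()
    zero = np.flatnonzero(sds <= 0)
    if zero.size:
        raise ValueError(
            f"zero-variance covariate column(s): {[raw.columns[i] for i in zero]}"
        )
    z = (raw.to_numpy() - means) / sds
    return CovariateMatrix(raw.index.to_numpy(), list(raw.columns), z,
                           means=means, sds=sds)


def correlation_screen(
    X: CovariateMatrix, threshold: float = 0.7
) -> set[frozenset[str]]:
    """Pairs of covariates admissible in the same model.

    A pair (a, b) is admissible iff ``|Pearson r(a, b)| < threshold``
    (strict inequality).  Symmetric by construction.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    corr = np.corrcoef(X.values, rowvar=False)
    admissible: set[frozenset[str]] = set()
    for i in range(len(X.names)):
        for j in range(i + 1, len(X.names)):
            if abs(corr[i, j]) < threshold:
                admissible.add(frozenset({X.names[i], X.names[j]}))
    return admissible
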