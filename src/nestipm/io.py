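"""Reading, validating and deriving the tabular observation streams.

Three CSV dialects mirror the harmonized nestbox-study exchange format:

* ``nests.csv`` — one row per nesting attempt:
  ``site,year,box,first_egg_doy,clutch,fledged,female_id,female_age,replacement``
* ``captures.csv`` — long-format sightings:
  ``individual,ring_age,first_year,year_seen``
* ``weather.csv`` — daily series: ``date,tmin_c,rain_mm``

The module also constructs the breeding-season covariate windows (post-hatch
and post-fledging), aggregates daily weather inside them, z-standardizes
covariates, and derives the annual population-level count series the IPM uses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NestData",
    "CaptureHistories",
    "EnvSeries",
    "TableFormatError",
    "read_nest_table",
    "write_nest_table",
    "read_capture_table",
    "write_capture_table",
    "read_weather_table",
    "hatch_date",
    "posthatch_window",
    "postfledge_window",
    "aggregate_covariate",
    "zstandardize",
    "identified_proportion",
    "build_population_counts",
]

NEST_COLUMNS = ["site", "year", "box", "first_egg_doy", "clutch", "fledged",
                "female_id", "female_age", "replacement"]
CAPTURE_COLUMNS = ["individual", "ring_age", "first_year", "year_seen"]
WEATHER_COLUMNS = ["date", "tmin_c", "rain_mm"]

#: Days from hatching to fledging; fledge day = hatch day + 16 + 1.
NESTLING_PERIOD = 16
INCUBATION_DAYS = 14
POSTHATCH_HALFWIDTH = 8   # window spans the centre +/- 8 days (17 days)
POSTFLEDGE_DAYS = 7       # window spans fledge day .. fledge day + 7 (8 days)


class TableFormatError(ValueError):
    """Raised when an input table is structurally unusable."""


@dataclass
class NestData:
    """Validated nest records plus a row-numbered rejection report."""

    frame: pd.DataFrame
    rejected: pd.DataFrame  # columns: row, reason

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class CaptureHistories:
    """Detection matrices built from long-format sighting rows.

    ``detections[i, t]`` is 1 if individual i was seen in study year index t.
    Entries before an individual's first year are zero; the first-year entry
    is always 1. ``ring_age`` is "nestling" or "adult".
    """

    individuals: np.ndarray   # (n,) ids
    ring_age: np.ndarray      # (n,) str
    first_year: np.ndarray    # (n,) study-year index
    detections: np.ndarray    # (n, T) 0/1
    years: np.ndarray         # calendar years for the study axis

    def __len__(self) -> int:
        return len(self.individuals)


@dataclass
class EnvSeries:
    """Daily minimum temperature and precipitation keyed by calendar date."""

    frame: pd.DataFrame  # indexed by date, columns tmin_c, rain_mm
    standardization: dict = field(default_factory=dict)

    def year_values(self, year: int, variable: str) -> pd.Series:
        """Daily values for one calendar year, indexed by day-of-year."""
        sub = self.frame[self.frame.index.year == year]
        return pd.Series(sub[variable].values, index=sub.index.dayofyear)


def read_nest_table(path) -> NestData:
    """Read and validate a nest-record table.

    Rows violating ``fledged <= clutch`` or with negative counts are rejected
    with a row-numbered report (1-based data rows, excluding the header);
    missing mandatory columns raise :class:`TableFormatError`.
    """
    df = pd.read_csv(path)
    missing = [c for c in NEST_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"nest table missing mandatory columns: {missing}")
    df = df[NEST_COLUMNS].copy()
    df["first_egg_doy"] = pd.to_numeric(df["first_egg_doy"], errors="coerce")
    for col in ("clutch", "fledged"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["replacement"] = df["replacement"].astype(bool)
    df["female_age"] = df["female_age"].fillna("unknown")

    reasons = pd.Series("", index=df.index)
    bad = df["clutch"].isna() | df["fledged"].isna()
    reasons[bad] = "unparsable clutch/fledged"
    neg = ~bad & ((df["clutch"] < 0) | (df["fledged"] < 0))
    reasons[neg] = "negative count"
    over = ~bad & ~neg & (df["fledged"] > df["clutch"])
    reasons[over] = "fledged exceeds clutch size"
    bad_age = (reasons == "") & ~df["female_age"].isin(["yearling", "adult", "unknown"])
    reasons[bad_age] = "unknown female_age category"

    rej_mask = reasons != ""
    rejected = pd.DataFrame({
        "row": df.index[rej_mask] + 1,
        "reason": reasons[rej_mask].values,
    })
    good = df[~rej_mask].reset_index(drop=True)
    good["clutch"] = good["clutch"].astype(int)
    good["fledged"] = good["fledged"].astype(int)
    return NestData(frame=good, rejected=rejected)


def write_nest_table(nests: pd.DataFrame, path) -> None:
    nests.to_csv(path, index=False, columns=NEST_COLUMNS)


def read_capture_table(path, years=None) -> CaptureHistories:
    """Build capture histories from long-format (individual, year) sightings.

    Parameters
    ----------
    years : (int, int), optional
        Inclusive calendar-year range of the study. Defaults to the range
        spanned by ``first_year`` and ``year_seen`` in the file.

    Duplicate (individual, year) rows collapse to a single detection. A
    sighting before an individual's declared first year is a format error.
    """
    df = pd.read_csv(path)
    missing = [c for c in CAPTURE_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"capture table missing mandatory columns: {missing}")
    if len(df) == 0:
        years = years or (0, -1)
        yr = np.arange(years[0], years[1] + 1)
        return CaptureHistories(np.array([]), np.array([]), np.array([], int),
                                np.zeros((0, len(yr)), dtype=np.int8), yr)
    if (df["year_seen"] < df["first_year"]).any():
        bad = df[df["year_seen"] < df["first_year"]].iloc[0]
        raise TableFormatError(
            f"individual {bad['individual']!r} sighted in {int(bad['year_seen'])} "
            f"before its declared first year {int(bad['first_year'])}")
    if years is None:
        years = (int(df["first_year"].min()),
                 int(max(df["year_seen"].max(), df["first_year"].max())))
    year_axis = np.arange(years[0], years[1] + 1)
    T = len(year_axis)

    firsts = df.groupby("individual").agg(
        ring_age=("ring_age", "first"), first_year=("first_year", "first"))
    ids = firsts.index.to_numpy()
    idx = {ind: i for i, ind in enumerate(ids)}
    det = np.zeros((len(ids), T), dtype=np.int8)
    fy = firsts["first_year"].to_numpy()
    det[np.arange(len(ids)), fy - years[0]] = 1
    for ind, seen in zip(df["individual"], df["year_seen"]):
        t = int(seen) - years[0]
        if 0 <= t < T:
            det[idx[ind], t] = 1
    return CaptureHistories(
        individuals=ids,
        ring_age=firsts["ring_age"].to_numpy(),
        first_year=(fy - years[0]).astype(int),
        detections=det,
        years=year_axis,
    )


def write_capture_table(histories: CaptureHistories, path) -> None:
    rows = []
    for i in range(len(histories)):
        seen = np.nonzero(histories.detections[i])[0]
        for t in seen:
            rows.append({
                "individual": histories.individuals[i],
                "ring_age": histories.ring_age[i],
                "first_year": histories.years[histories.first_year[i]],
                "year_seen": histories.years[t],
            })
    pd.DataFrame(rows, columns=CAPTURE_COLUMNS).to_csv(path, index=False)


def read_weather_table(path) -> EnvSeries:
    df = pd.read_csv(path, parse_dates=["date"])
    missing = [c for c in WEATHER_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"weather table missing mandatory columns: {missing}")
    df = df.set_index("date").sort_index()
    return EnvSeries(frame=df)


def hatch_date(first_egg_doy, clutch):
    """Hatch day-of-year: first egg + laying days (one egg/day) + incubation.

    Missing first-egg dates propagate as NaN.
    """
    fe = np.asarray(first_egg_doy, dtype=float)
    cl = np.asarray(clutch, dtype=float)
    if np.any(cl[~np.isnan(cl)] < 1):
        raise ValueError("clutch must be >= 1 (one egg laid per day)")
    out = fe + cl + INCUBATION_DAYS
    return out if out.shape else float(out)


def _quantile_day(values: np.ndarray, q: float) -> int:
    """Linear-interpolation quantile rounded half-down to a whole day."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("no non-missing hatch dates")
    c = float(np.quantile(x, q))
    return int(math.ceil(c - 0.5))


def posthatch_window(hatch_dates) -> tuple[int, int]:
    """17-day window centred on the 0.25 quantile of annual hatch dates.

    Returns inclusive (start, end) day-of-year; requires at least one
    non-missing hatch date.
    """
    c = _quantile_day(hatch_dates, 0.25)
    return (c - POSTHATCH_HALFWIDTH, c + POSTHATCH_HALFWIDTH)


def postfledge_window(hatch_dates) -> tuple[int, int]:
    """8-day window from the assumed fledge day (centre hatch + 17), inclusive."""
    c = _quantile_day(hatch_dates, 0.25)
    fledge = c + NESTLING_PERIOD + 1
    return (fledge, fledge + POSTFLEDGE_DAYS)


def aggregate_covariate(env: EnvSeries, year: int, window: tuple[int, int],
                        variable: str):
    """Mean of a daily weather variable over an inclusive day-of-year window.

    Days with missing weather are excluded from the mean; returns
    ``(mean, n_days_used)`` with mean NaN when every day is missing.
    """
    daily = env.year_values(year, variable)
    sel = daily.loc[(daily.index >= window[0]) & (daily.index <= window[1])]
    vals = sel.to_numpy(dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return float("nan"), 0
    return float(vals.mean()), int(vals.size)


def zstandardize(values):
    """Z-standardize with the sample (n-1) SD; missing values stay missing.

    Returns ``(standardized, metadata)`` where metadata records the mean and
    SD used. A constant covariate (SD = 0) is an error: drop it instead.
    """
    x = np.asarray(values, dtype=float)
    obs = x[~np.isnan(x)]
    if obs.size < 2:
        raise ValueError("need at least two non-missing values to standardize")
    mean = float(obs.mean())
    sd = float(obs.std(ddof=1))
    if sd == 0.0:
        raise ValueError("constant covariate (SD = 0); drop it from the model")
    return (x - mean) / sd, {"mean": mean, "sd": sd}


def identified_proportion(nests: pd.DataFrame) -> pd.Series:
    """Per-year proportion of monitored nests with an identified female.

    This approximates the probability that a breeding female is captured and
    identified (pCapB). Years absent from the table are simply absent from the
    result (missing).
    """
    if len(nests) == 0:
        return pd.Series(dtype=float)
    ided = nests["female_id"].notna() & (nests["female_id"].astype(str) != "")
    return ided.groupby(nests["year"]).mean().astype(float)


def build_population_counts(nests: pd.DataFrame, captures: CaptureHistories,
                            years=None) -> pd.DataFrame:
    """Annual population-level count series for the IPM.

    Per year: ``first_clutches`` (non-replacement nests), ``eggs`` and
    ``fledglings`` (sums over all nests), ``newly_ringed_adults`` (capture
    histories with ring age "adult" first captured that year) and ``pCapB``
    (identified-female nest proportion; NaN in years with no nests).
    """
    if years is None:
        lo = int(min(nests["year"].min(), captures.years.min()))
        hi = int(max(nests["year"].max(), captures.years.max()))
        years = (lo, hi)
    axis = np.arange(years[0], years[1] + 1)
    out = pd.DataFrame(index=pd.Index(axis, name="year"))
    by_year = nests.groupby("year")
    out["first_clutches"] = (~nests["replacement"]).groupby(nests["year"]).sum()
    out["eggs"] = by_year["clutch"].sum()
    out["fledglings"] = by_year["fledged"].sum()
    out[["first_clutches", "eggs", "fledglings"]] = \
        out[["first_clutches", "eggs", "fledglings"]].fillna(0).astype(int)
    adult = captures.ring_age == "adult"
    newly = np.zeros(len(axis), dtype=int)
    for t in captures.first_year[adult]:
        yr = captures.years[t]
        if years[0] <= yr <= years[1]:
            newly[yr - years[0]] += 1
    out["newly_ringed_adults"] = newly
    out["pCapB"] = identified_proportion(nests).reindex(axis).astype(float)
    return out
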