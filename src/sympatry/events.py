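"""Camera-trap event tables: ingest, independence filtering, and RAI.

An *event* is a timestamped record of one species at one camera. Raw photo
records are collapsed into independent events with the 30-minute rule:
within each camera x species stream, a photo opens a new event iff it falls
at least ``window_minutes`` after the previous photo of the current event
(rolling window, so a burst of closely spaced photos extends the event).

The relative abundance index (RAI) is the number of independent events per
100 camera-trap days::

    RAI = n_events / trap_nights * 100

where a trap night is one camera active for any part of one calendar day,
summed over all cameras and clipped to the season window (summer = 1 Jul to
31 Aug, autumn = 1 Sep to 31 Oct).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Calendar months belonging to each season.
SEASON_MONTHS: dict[str, tuple[int, ...]] = {"summer": (7, 8), "autumn": (9, 10)}

EVENT_COLUMNS = ["camera_id", "species", "timestamp"]
DEPLOYMENT_COLUMNS = [
    "camera_id",
    "year",
    "start_date",
    "end_date",
    "habitat",
    "altitude_m",
    "slope_deg",
]
HABITAT_CLASSES = ("BF", "CF", "RF")


@dataclass(frozen=True)
class RaiResult:
    """Relative abundance index for one species, season and year.

    ``rai`` is computed on pooled effort; ``se`` is the among-camera
    standard error of the per-camera indices (sd / sqrt(n_cameras)).
    """

    species: str
    season: str
    year: int
    n_events: int
    trap_nights: int
    rai: float
    se: float

    def __post_init__(self) -> None:
        if self.trap_nights <= 0:
            raise ValueError("trap_nights must be positive")


def season_window(season: str, year: int) -> tuple[pd.Timestamp, pd.Timestamp]:
    """Inclusive [first day, last day] of a season in a given year."""
    try:
        months = SEASON_MONTHS[season]
    except KeyError:
        raise ValueError(f"unknown season {season!r}; expected one of {sorted(SEASON_MONTHS)}")
    first = pd.Timestamp(year=year, month=months[0], day=1)
    last = pd.Timestamp(year=year, month=months[-1], day=1) + pd.offsets.MonthEnd(0)
    return first, last


def read_events(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a delimited event file (camera_id, species, timestamp).

    Returns ``(events, report)``: parseable rows with ``timestamp`` as
    datetime, plus a per-row report of unparseable timestamps. Malformed
    structure (missing columns) raises.
    """
    raw = pd.read_csv(path, dtype=str)
    missing = [c for c in EVENT_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"event file {path!r} is missing columns {missing}")
    ts = pd.to_datetime(raw["timestamp"], errors="coerce", format="mixed")
    bad = ts.isna() & raw["timestamp"].notna()
    report = _report(raw[bad], "unparseable timestamp")
    events = raw.loc[~bad, EVENT_COLUMNS].copy()
    events["timestamp"] = ts[~bad]
    return events.reset_index(drop=True), report


def read_deployments(path) -> pd.DataFrame:
    """Read a delimited deployment file; one row per active interval."""
    dep = pd.read_csv(path, dtype={"camera_id": str, "habitat": str})
    missing = [c for c in DEPLOYMENT_COLUMNS if c not in dep.columns]
    if missing:
        raise ValueError(f"deployment file {path!r} is missing columns {missing}")
    dep["year"] = dep["year"].astype(int)
    for col in ("start_date", "end_date"):
        dep[col] = pd.to_datetime(dep[col])
    unknown = set(dep["habitat"]) - set(HABITAT_CLASSES)
    if unknown:
        raise ValueError(f"unknown habitat classes {sorted(unknown)}; expected {HABITAT_CLASSES}")
    if (dep["start_date"] > dep["end_date"]).any():
        raise ValueError("deployment with start_date after end_date")
    return dep.sort_values(["camera_id", "year", "start_date"]).reset_index(drop=True)


def validate_events(
    events: pd.DataFrame,
    deployments: pd.DataFrame,
    species_whitelist: list[str] | None = None,
) -> pd.DataFrame:
    """Per-row validation report; offending rows are reported, never dropped.

    Flags unknown camera ids, species outside the whitelist (when one is
    configured), and timestamps outside every active interval of the
    camera's deployment ("out-of-effort").
    """
    reports = []
    known = set(deployments["camera_id"])
    bad_cam = ~events["camera_id"].isin(known)
    reports.append(_report(events[bad_cam], "unknown camera id"))
    if species_whitelist is not None:
        bad_sp = ~events["species"].isin(species_whitelist)
        reports.append(_report(events[bad_sp], "unknown species label"))
    ok = events[~bad_cam]
    if len(ok):
        merged = ok.reset_index().merge(deployments, on="camera_id", how="left")
        inside = (merged["timestamp"] >= merged["start_date"]) & (
            merged["timestamp"] < merged["end_date"] + pd.Timedelta(days=1)
        )
        inside_any = inside.groupby(merged["index"]).any()
        out = ok.loc[inside_any.index[~inside_any]]
        reports.append(_report(out, "timestamp outside deployment interval"))
    return pd.concat(reports, ignore_index=True) if reports else _report(events.iloc[:0], "")


def _report(rows: pd.DataFrame, issue: str) -> pd.DataFrame:
    rep = rows.copy()
    rep["issue"] = issue
    return rep.reset_index(names="row")


def filter_independent(events: pd.DataFrame, window_minutes: float = 30) -> pd.DataFrame:
    """Collapse photo records into independent events (rolling window).

    Within each camera x species stream sorted by time, a photo whose gap
    from the previous photo of the current event is >= ``window_minutes``
    starts a new event; exactly 30:00 apart therefore splits. The first
    photo of each event is retained with its timestamp. Idempotent.
    """
    if window_minutes < 0:
        raise ValueError("window_minutes must be non-negative")
    if events.empty:
        return events.copy()
    window = pd.Timedelta(minutes=window_minutes)
    ordered = events.sort_values(["camera_id", "species", "timestamp"], kind="stable")
    keep_idx: list = []
    for _, grp in ordered.groupby(["camera_id", "species"], sort=False):
        last = None
        for idx, ts in zip(grp.index, grp["timestamp"]):
            if last is None or ts - last >= window:
                keep_idx.append(idx)
            last = ts  # rolling: gap measured from the latest photo seen
    return events.loc[keep_idx].sort_values(
        ["camera_id", "species", "timestamp"], kind="stable"
    ).reset_index(drop=True)


def trap_nights(deployments: pd.DataFrame, season: str, year: int) -> pd.Series:
    """Per-camera count of active calendar days within the season window.

    A day counts if the camera was active for any part of it; intervals are
    clipped to the season at day granularity.
    """
    first, last = season_window(season, year)
    dep = deployments[deployments["year"] == year]
    days = {}
    for cam, grp in dep.groupby("camera_id"):
        total = 0
        for _, row in grp.iterrows():
            lo = max(row["start_date"].normalize(), first)
            hi = min(row["end_date"].normalize(), last)
            if lo <= hi:
                total += (hi - lo).days + 1
        days[cam] = total
    return pd.Series(days, name="trap_nights", dtype=int)


def compute_rai(
    events: pd.DataFrame,
    deployments: pd.DataFrame,
    species: str,
    season: str,
    year: int,
) -> RaiResult:
    """RAI from an independence-filtered event table.

    Pooled index: events in the season window / total trap nights x 100.
    The SE is the standard deviation of per-camera indices divided by the
    square root of the number of cameras with effort.
    """
    effort = trap_nights(deployments, season, year)
    total_nights = int(effort.sum())
    if total_nights <= 0:
        raise ValueError(f"zero trapping effort for {season} {year}")
    first, last = season_window(season, year)
    in_window = (
        (events["species"] == species)
        & (events["timestamp"] >= first)
        & (events["timestamp"] < last + pd.Timedelta(days=1))
    )
    sel = events[in_window]
    per_cam_events = sel.groupby("camera_id").size()
    cams = effort[effort > 0]
    per_cam_rai = per_cam_events.reindex(cams.index, fill_value=0) / cams * 100.0
    se = float(per_cam_rai.std(ddof=1) / np.sqrt(len(cams))) if len(cams) > 1 else float("nan")
    n_events = int(len(sel))
    return RaiResult(
        species=species,
        season=season,
        year=year,
        n_events=n_events,
        trap_nights=total_nights,
        rai=n_events / total_nights * 100.0,
        se=se,
    )


def rai_table(
    events: pd.DataFrame,
    deployments: pd.DataFrame,
    species: list[str],
    seasons: list[str] | None = None,
) -> pd.DataFrame:
    """RAI for every species x season x year with any effort."""
    seasons = seasons or list(SEASON_MONTHS)
    rows = []
    for year in sorted(deployments["year"].unique()):
        for season in seasons:
            for sp in species:
                r = compute_rai(events, deployments, sp, season, int(year))
                rows.append(vars(r))
    return pd.DataFrame(rows)


def write_events(events: pd.DataFrame, path) -> None:
    out = events.copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%d %H:%M:%S")
    out.to_csv(path, index=False)


def write_deployments(deployments: pd.DataFrame, path) -> None:
    out = deployments.copy()
    for col in ("start_date", "end_date"):
        out[col] = out[col].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
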