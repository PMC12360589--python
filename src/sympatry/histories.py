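"""Site x occasion detection histories and the candidate covariate designs.

Each season is divided into six 10-day sampling occasions (early, middle
and late thirds of each of its two months); the 31st day of a month belongs
to no occasion, so every month contributes exactly 30 survey days. A site
is one camera-year deployment: data from the three study years are pooled
into a single-season design with year as a site covariate.

Cell coding follows the standard detection/non-detection convention:
1 = at least one independent event in the occasion, 0 = none although the
camera was active for at least one day of the occasion, missing = the
camera was not installed or malfunctioned for the whole occasion.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .events import SEASON_MONTHS, season_window

CATEGORICAL_COVARIATES = ("year", "habitat")
CONTINUOUS_COVARIATES = ("altitude", "slope")

#: continuous covariate name -> raw column in the site-covariate table
_RAW_COLUMN = {"altitude": "altitude_m", "slope": "slope_deg"}


def season_occasions(season: str) -> list[tuple[int, int, int]]:
    """Six (month, first_day, last_day) windows for a season."""
    return [
        (month, lo, lo + 9)
        for month in SEASON_MONTHS[season]
        for lo in (1, 11, 21)
    ]


def occasion_labels(season: str) -> list[str]:
    return [f"m{m:02d}d{lo:02d}-{hi:02d}" for m, lo, hi in season_occasions(season)]


@dataclass
class DetectionHistory:
    """Detection/non-detection matrix with site covariates.

    ``matrix`` is float with values in {0.0, 1.0, nan}; nan encodes a
    missing (unsurveyed) occasion. ``site_covariates`` is indexed by
    ``sites`` and carries year, habitat, altitude_m, slope_deg plus any
    standardized copies (altitude_z, slope_z) added by :func:`standardize`.
    """

    season: str
    sites: list[str]
    occasions: list[str]
    matrix: np.ndarray
    site_covariates: pd.DataFrame
    species: str | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.sites), len(self.occasions)):
            raise ValueError("matrix shape does not match sites x occasions")
        vals = self.matrix[~np.isnan(self.matrix)]
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError("matrix values must be 0, 1 or missing")
        if list(self.site_covariates.index) != list(self.sites):
            raise ValueError("site_covariates index must equal the site list")

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of surveyed site-occasions."""
        return ~np.isnan(self.matrix)

    def to_frame(self) -> pd.DataFrame:
        occ = pd.DataFrame(self.matrix, index=self.sites, columns=self.occasions)
        return pd.concat([self.site_covariates, occ], axis=1)

    def write(self, path) -> None:
        """Delimited text: one row per site, covariates then o1..o6 (NA = missing)."""
        frame = self.to_frame().reset_index(names="site_id")
        frame.to_csv(path, index=False, na_rep="NA")

    @classmethod
    def read(cls, path, season: str, species: str | None = None) -> "DetectionHistory":
        frame = pd.read_csv(path, dtype={"habitat": str}).set_index("site_id")
        occ = occasion_labels(season)
        covs = frame.drop(columns=occ)
        return cls(
            season=season,
            sites=list(frame.index),
            occasions=occ,
            matrix=frame[occ].to_numpy(dtype=float),
            site_covariates=covs,
            species=species,
        )


def site_id(camera_id: str, year: int) -> str:
    return f"{camera_id}:{year}"


def build_history(
    events: pd.DataFrame,
    deployments: pd.DataFrame,
    species: str,
    season: str,
) -> DetectionHistory:
    """Detection history for one species and season.

    ``events`` must already be independence-filtered. Sites are the
    camera-year deployments, in sorted order. Events at a camera with no
    deployment raise a validation error listing the offenders.
    """
    ev = events[events["species"] == species]
    known = set(deployments["camera_id"])
    orphans = sorted(set(ev["camera_id"]) - known)
    if orphans:
        raise ValueError(f"events at cameras with no deployment: {orphans}")

    pairs = deployments[["camera_id", "year"]].drop_duplicates().sort_values(
        ["year", "camera_id"]
    )
    sites = [site_id(c, y) for c, y in zip(pairs["camera_id"], pairs["year"])]
    windows = season_occasions(season)
    matrix = np.full((len(sites), len(windows)), np.nan)

    for i, (cam, year) in enumerate(zip(pairs["camera_id"], pairs["year"])):
        dep = deployments[(deployments["camera_id"] == cam) & (deployments["year"] == year)]
        cam_ev = ev[(ev["camera_id"] == cam) & (ev["timestamp"].dt.year == year)]
        for j, (month, lo, hi) in enumerate(windows):
            w0 = pd.Timestamp(year=year, month=month, day=lo)
            w1 = pd.Timestamp(year=year, month=month, day=hi)
            active = 0
            for _, row in dep.iterrows():
                a = max(row["start_date"].normalize(), w0)
                b = min(row["end_date"].normalize(), w1)
                if a <= b:
                    active += (b - a).days + 1
            if active == 0:
                continue  # not installed or malfunctioned: missing
            hit = (
                (cam_ev["timestamp"] >= w0)
                & (cam_ev["timestamp"] < w1 + pd.Timedelta(days=1))
            ).any()
            matrix[i, j] = 1.0 if hit else 0.0

    covs = (
        deployments.groupby(["camera_id", "year"], as_index=False)
        .first()[["camera_id", "year", "habitat", "altitude_m", "slope_deg"]]
        .sort_values(["year", "camera_id"])
    )
    covs.index = [site_id(c, y) for c, y in zip(covs["camera_id"], covs["year"])]
    covs = covs.loc[sites, ["year", "habitat", "altitude_m", "slope_deg"]]
    return DetectionHistory(
        season=season,
        sites=sites,
        occasions=occasion_labels(season),
        matrix=matrix,
        site_covariates=covs,
        species=species,
    )


def standardize(history: DetectionHistory) -> DetectionHistory:
    """Append z-scored copies of the continuous covariates.

    Uses the sample standard deviation (ddof=1). Recomputes from the raw
    columns, so the operation is idempotent on the z-columns. A covariate
    with zero variance raises, naming the covariate.
    """
    covs = history.site_covariates.copy()
    if len(covs) < 2:
        raise ValueError("standardization needs at least two sites")
    for name, raw in _RAW_COLUMN.items():
        x = covs[raw].astype(float)
        sd = x.std(ddof=1)
        if sd == 0 or np.isnan(sd):
            raise ValueError(f"covariate {name!r} has zero variance")
        covs[f"{name}_z"] = (x - x.mean()) / sd
    return replace(history, site_covariates=covs)


@dataclass(frozen=True)
class CovariateDesign:
    """Covariate structure of one candidate model.

    Each of occupancy and detection carries at most one categorical term
    (year or habitat) and at most one continuous term (altitude or slope);
    the small-sample design forbids anything richer.
    """

    occupancy_terms: tuple[str, ...] = ()
    detection_terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for terms in (self.occupancy_terms, self.detection_terms):
            _check_terms(terms)

    @property
    def name(self) -> str:
        return f"psi({_fmt(self.occupancy_terms)}),p({_fmt(self.detection_terms)})"


def _fmt(terms: tuple[str, ...]) -> str:
    return "+".join(t.capitalize() for t in terms) if terms else "."


def _check_terms(terms: tuple[str, ...]) -> None:
    known = CATEGORICAL_COVARIATES + CONTINUOUS_COVARIATES
    unknown = [t for t in terms if t not in known]
    if unknown:
        raise ValueError(f"unknown covariates {unknown}; expected subset of {known}")
    if len([t for t in terms if t in CATEGORICAL_COVARIATES]) > 1:
        raise ValueError("at most one categorical covariate (year or habitat) allowed")
    if len([t for t in terms if t in CONTINUOUS_COVARIATES]) > 1:
        raise ValueError("at most one continuous covariate (altitude or slope) allowed")
    if len(set(terms)) != len(terms):
        raise ValueError("duplicate covariate term")


def enumerate_model_set(
    categoricals: tuple[str, ...] = CATEGORICAL_COVARIATES,
    continuous: tuple[str, ...] = CONTINUOUS_COVARIATES,
) -> list[CovariateDesign]:
    """All admissible occupancy x detection designs, constant model first.

    With both categoricals and both continuous covariates available there
    are (1+2)x(1+2) = 9 structures per parameter, hence 81 models.
    Deterministic ordering: by term count, then lexicographic.
    """
    per_param = [
        tuple(t for t in (cat, cont) if t is not None)
        for cat in (None, *categoricals)
        for cont in (None, *continuous)
    ]
    per_param.sort(key=lambda t: (len(t), t))
    return [
        CovariateDesign(occupancy_terms=occ, detection_terms=det)
        for occ, det in itertools.product(per_param, per_param)
    ]


def design_matrix(
    covariates: pd.DataFrame, terms: tuple[str, ...]
) -> tuple[np.ndarray, list[str]]:
    """Intercept + dummy/linear columns for the given terms.

    Reference levels: habitat BF, the earliest year. Continuous terms use
    the standardized columns (altitude_z, slope_z), which must be present.
    """
    cols = [np.ones(len(covariates))]
    names = ["(Intercept)"]
    for term in terms:
        if term == "year":
            levels = sorted(covariates["year"].unique())
            for lev in levels[1:]:
                cols.append((covariates["year"] == lev).to_numpy(float))
                names.append(f"year{lev}")
        elif term == "habitat":
            for lev in [h for h in ("CF", "RF") if (covariates["habitat"] == h).any()]:
                cols.append((covariates["habitat"] == lev).to_numpy(float))
                names.append(f"habitat{lev}")
        else:
            zcol = f"{term}_z"
            if zcol not in covariates:
                raise ValueError(
                    f"standardized column {zcol!r} missing; call standardize() first"
                )
            cols.append(covariates[zcol].to_numpy(float))
            names.append(term)
    return np.column_stack(cols), names
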