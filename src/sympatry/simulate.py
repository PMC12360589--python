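"""Synthetic camera-trap studies with known ground truth.

Emulates the structure of a three-year (2015-2017) ungulate survey:
cameras deployed 1 July - 31 October each year in mountain forest (habitat
broad-leaved / conifer / riparian, altitude 600-1600 m, slope 2.2-37.1
degrees), two interacting species ("deer" dominant, "serow" subordinate),
six 10-day occasions per season, and event timestamps with realistic diel
structure (von Mises mixtures: deer crepuscular; serow cathemeral in
summer, nocturnal in autumn).

The forward model inverts the two-species occupancy parameterization:
latent states drawn per site with weights {psiA*psiBA, psiA*(1-psiBA),
(1-psiA)*psiBa, (1-psiA)*(1-psiBa)}; per occasion A is detected with rA
(both present) or pA (A only), and B with rBA / rBa / pB according to A's
presence and same-occasion detection. Year effects shift every detection
probability on the logit scale. Each detected site-occasion receives a
zero-truncated Poisson number of events.

Randomness is keyed: every (purpose, site, year) tuple gets its own
generator derived from the master seed, so enlarging the design leaves
existing sites' draws untouched, and identical configs give byte-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .events import SEASON_MONTHS
from .histories import DetectionHistory, occasion_labels, season_occasions, site_id
from .occu_two import TwoSpeciesParams

# stream tags keeping the keyed substreams disjoint
_S_DEPLOY, _S_LATENT, _S_DETECT, _S_EVENTS = 1, 2, 3, 4

#: Diel von Mises mixtures, (mean hour, concentration, weight) per component.
DEFAULT_DIEL_PROFILES: dict[tuple[str, str], tuple[tuple[float, float, float], ...]] = {
    ("deer", "summer"): ((5.0, 3.0, 0.30), (18.8, 3.0, 0.45), (12.0, 0.8, 0.25)),
    ("deer", "autumn"): ((5.5, 3.0, 0.45), (18.0, 3.0, 0.30), (12.0, 0.8, 0.25)),
    ("serow", "summer"): ((4.5, 2.0, 0.40), (14.0, 0.4, 0.30), (21.0, 1.0, 0.30)),
    ("serow", "autumn"): ((23.0, 1.5, 0.45), (2.5, 1.5, 0.35), (19.0, 2.0, 0.20)),
}

DEFAULT_PARAMS = TwoSpeciesParams(
    psiA=0.85, psiBA=0.78, psiBa=0.78, pA=0.12, pB=0.03, rA=0.14, rBA=0.23, rBa=0.29
)


@dataclass(frozen=True)
class SimConfig:
    """Study-design and generating-parameter configuration.

    Defaults emulate the reference design: 13 cameras per year over three
    years (39 camera-year sites), July-October deployments, detection
    rising across years on the logit scale, and the diel profiles above.
    """

    n_sites: int = 13
    years: tuple[int, ...] = (2015, 2016, 2017)
    season_months: dict = field(default_factory=lambda: dict(SEASON_MONTHS))
    occupancy_params: TwoSpeciesParams = DEFAULT_PARAMS
    detection_year_effects: dict = field(
        default_factory=lambda: {2015: 0.0, 2016: 0.9, 2017: 1.8}
    )
    diel_profiles: dict = field(default_factory=lambda: dict(DEFAULT_DIEL_PROFILES))
    events_per_detection: float = 1.5
    altitude_range: tuple[float, float] = (600.0, 1600.0)
    slope_range: tuple[float, float] = (2.2, 37.1)
    habitat_probs: dict = field(
        default_factory=lambda: {"BF": 0.6, "CF": 0.2, "RF": 0.2}
    )
    malfunction_prob: float = 0.1
    species_a: str = "deer"
    species_b: str = "serow"
    burst_photos: int = 1
    burst_spacing_minutes: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if not self.years:
            raise ValueError("years must be non-empty")
        for key, profile in self.diel_profiles.items():
            total = sum(w for _, _, w in profile)
            if abs(total - 1.0) > 1e-12:
                raise ValueError(f"diel mixture weights for {key} sum to {total}, not 1")
        for lo, hi in (self.altitude_range, self.slope_range):
            if not lo < hi:
                raise ValueError("covariate ranges must be ordered and non-degenerate")
        if abs(sum(self.habitat_probs.values()) - 1.0) > 1e-12:
            raise ValueError("habitat class probabilities must sum to 1")
        if self.events_per_detection <= 0:
            raise ValueError("events_per_detection must be positive")


@dataclass
class SimTruth:
    """Latent ground truth behind one simulated season."""

    season: str
    sites: list[str]
    site_table: pd.DataFrame  # camera_id, year per site
    present_a: np.ndarray
    present_b: np.ndarray
    detected_a: np.ndarray  # site x occasion, nan where unsurveyed
    detected_b: np.ndarray
    params: TwoSpeciesParams
    deployments: pd.DataFrame


def _rng(config: SimConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng([config.seed & 0x7FFFFFFF, *key])


def simulate_deployments(config: SimConfig) -> pd.DataFrame:
    """One deployment per camera x year, 1 Jul - 31 Oct, optional outage.

    With probability ``malfunction_prob`` a camera drops out for 10-40
    days starting at a uniform date, splitting its record into two active
    intervals (or truncating it at the boundary).
    """
    rows = []
    habitats = list(config.habitat_probs)
    probs = [config.habitat_probs[h] for h in habitats]
    for s in range(config.n_sites):
        for year in config.years:
            rng = _rng(config, _S_DEPLOY, s, year)
            cam = f"C{year}-{s + 1:02d}"
            habitat = rng.choice(habitats, p=probs)
            altitude = rng.uniform(*config.altitude_range)
            slope = rng.uniform(*config.slope_range)
            start = pd.Timestamp(year=year, month=7, day=1)
            end = pd.Timestamp(year=year, month=10, day=31)
            intervals = [(start, end)]
            if rng.random() < config.malfunction_prob:
                out_start = start + pd.Timedelta(days=int(rng.integers(0, 113)))
                out_len = int(rng.integers(10, 41))
                out_end = out_start + pd.Timedelta(days=out_len - 1)
                intervals = [
                    iv
                    for iv in [(start, out_start - pd.Timedelta(days=1)), (out_end + pd.Timedelta(days=1), end)]
                    if iv[0] <= iv[1]
                ]
            for a, b in intervals:
                rows.append(
                    {
                        "camera_id": cam,
                        "year": year,
                        "start_date": a,
                        "end_date": b,
                        "habitat": habitat,
                        "altitude_m": round(altitude, 1),
                        "slope_deg": round(slope, 1),
                    }
                )
    return pd.DataFrame(rows)


def _interval_index(deployments: pd.DataFrame) -> dict:
    """(camera_id, year) -> list of (start_ordinal, end_ordinal) day pairs."""
    idx: dict = {}
    for (cam, year), grp in deployments.groupby(["camera_id", "year"]):
        idx[(cam, int(year))] = [
            (a.toordinal(), b.toordinal())
            for a, b in zip(grp["start_date"].dt.normalize(), grp["end_date"].dt.normalize())
        ]
    return idx


def _active_days(intervals: list, year: int, month: int, lo: int, hi: int) -> list[int]:
    """Active day ordinals of the camera within one occasion window."""
    w0 = pd.Timestamp(year=year, month=month, day=lo).toordinal()
    w1 = w0 + (hi - lo)
    days = []
    for a, b in intervals:
        start, end = max(a, w0), min(b, w1)
        days.extend(range(start, end + 1))
    return sorted(set(days))


def simulate_two_species(
    config: SimConfig,
    season: str = "summer",
    deployments: pd.DataFrame | None = None,
) -> tuple[DetectionHistory, DetectionHistory, SimTruth]:
    """Latent occupancy states and detection histories for one season."""
    if deployments is None:
        deployments = simulate_deployments(config)
    params = config.occupancy_params
    windows = season_occasions(season)
    pairs = deployments[["camera_id", "year"]].drop_duplicates().sort_values(["year", "camera_id"])
    sites = [site_id(c, y) for c, y in zip(pairs["camera_id"], pairs["year"])]
    n, j = len(sites), len(windows)

    present_a = np.zeros(n, dtype=bool)
    present_b = np.zeros(n, dtype=bool)
    det_a = np.full((n, j), np.nan)
    det_b = np.full((n, j), np.nan)

    season_tag = 0 if season == "summer" else 1
    interval_idx = _interval_index(deployments)
    for i, (cam, year) in enumerate(zip(pairs["camera_id"], pairs["year"])):
        cam_idx = int(cam.split("-")[-1]) - 1
        rng = _rng(config, _S_LATENT, season_tag, cam_idx, year)
        a = rng.random() < params.psiA
        b = rng.random() < (params.psiBA if a else params.psiBa)
        present_a[i], present_b[i] = a, b
        off = config.detection_year_effects.get(year, 0.0)
        p = {
            name: float(expit(logit(getattr(params, name)) + off))
            for name in ("pA", "pB", "rA", "rBA", "rBa")
        }
        rng_d = _rng(config, _S_DETECT, season_tag, cam_idx, year)
        for k, (month, lo, hi) in enumerate(windows):
            if not _active_days(interval_idx[(cam, year)], year, month, lo, hi):
                continue  # occasion never surveyed -> missing
            ya = yb = 0
            if a:
                ya = int(rng_d.random() < (p["rA"] if b else p["pA"]))
            if b:
                if a:
                    pb = p["rBA"] if ya else p["rBa"]
                else:
                    pb = p["pB"]
                yb = int(rng_d.random() < pb)
            det_a[i, k], det_b[i, k] = ya, yb

    covs = (
        deployments.groupby(["camera_id", "year"], as_index=False)
        .first()[["camera_id", "year", "habitat", "altitude_m", "slope_deg"]]
        .sort_values(["year", "camera_id"])
    )
    covs.index = [site_id(c, y) for c, y in zip(covs["camera_id"], covs["year"])]
    covs = covs.loc[sites, ["year", "habitat", "altitude_m", "slope_deg"]]
    labels = occasion_labels(season)
    hist_a = DetectionHistory(season, sites, labels, det_a, covs.copy(), species=config.species_a)
    hist_b = DetectionHistory(season, sites, labels, det_b, covs.copy(), species=config.species_b)
    truth = SimTruth(
        season=season,
        sites=sites,
        site_table=pairs.reset_index(drop=True),
        present_a=present_a,
        present_b=present_b,
        detected_a=det_a,
        detected_b=det_b,
        params=params,
        deployments=deployments,
    )
    return hist_a, hist_b, truth


def _sample_mixture_times(rng: np.random.Generator, profile, n: int) -> np.ndarray:
    """Times of day (hours) from a von Mises mixture over the 24 h circle."""
    means = np.array([c[0] for c in profile]) / 24.0 * 2 * np.pi
    kappas = np.array([c[1] for c in profile])
    weights = np.array([c[2] for c in profile])
    comp = rng.choice(len(profile), size=n, p=weights)
    angles = rng.vonmises(means[comp], kappas[comp])
    return (angles % (2 * np.pi)) / (2 * np.pi) * 24.0


def simulate_events(config: SimConfig, truth: SimTruth) -> pd.DataFrame:
    """Event table consistent with the simulated detections.

    Every detected site-occasion-species yields a zero-truncated Poisson
    count of independent events; each event's day is uniform over the
    occasion's active days and its time of day follows the species+season
    diel mixture. ``burst_photos`` > 1 appends closely spaced duplicate
    photos after each event to exercise the independence filter.
    """
    windows = season_occasions(truth.season)
    rows = []
    interval_idx = _interval_index(truth.deployments)
    species_det = [(config.species_a, truth.detected_a), (config.species_b, truth.detected_b)]
    for i, (cam, year) in enumerate(
        zip(truth.site_table["camera_id"], truth.site_table["year"])
    ):
        cam_idx = int(cam.split("-")[-1]) - 1
        season_tag = 0 if truth.season == "summer" else 1
        rng = _rng(config, _S_EVENTS, season_tag, cam_idx, year)
        for k, (month, lo, hi) in enumerate(windows):
            active = None
            for sp_tag, (species, det) in enumerate(species_det):
                if not det[i, k] == 1.0:
                    continue
                if active is None:
                    active = _active_days(interval_idx[(cam, year)], year, month, lo, hi)
                n_events = _zt_poisson(rng, config.events_per_detection)
                profile = config.diel_profiles[(species, truth.season)]
                hours = _sample_mixture_times(rng, profile, n_events)
                days = rng.choice(len(active), size=n_events)
                for d, h in zip(days, hours):
                    ts = pd.Timestamp.fromordinal(active[d]) + pd.Timedelta(seconds=round(h * 3600))
                    for b in range(max(1, config.burst_photos)):
                        rows.append(
                            {
                                "camera_id": cam,
                                "species": species,
                                "timestamp": ts + pd.Timedelta(minutes=b * config.burst_spacing_minutes),
                            }
                        )
    events = pd.DataFrame(rows, columns=["camera_id", "species", "timestamp"])
    if len(events):
        events["timestamp"] = pd.to_datetime(events["timestamp"])
        events = events.sort_values(["camera_id", "species", "timestamp"]).reset_index(drop=True)
    return events


def _zt_poisson(rng: np.random.Generator, rate: float) -> int:
    """Zero-truncated Poisson draw (a detected occasion has >= 1 event)."""
    while True:
        n = rng.poisson(rate)
        if n > 0:
            return int(n)


def simulate_study(
    config: SimConfig, seasons: tuple[str, ...] = ("summer", "autumn")
) -> dict:
    """Full end-to-end dataset: deployments, per-season histories/truth/events.

    Returns a dict with keys ``deployments``, ``events`` (all seasons
    pooled) and per-season ``histories`` / ``truth``.
    """
    deployments = simulate_deployments(config)
    out = {"deployments": deployments, "histories": {}, "truth": {}}
    all_events = []
    for season in seasons:
        ha, hb, truth = simulate_two_species(config, season, deployments)
        out["histories"][season] = {config.species_a: ha, config.species_b: hb}
        out["truth"][season] = truth
        all_events.append(simulate_events(config, truth))
    events = pd.concat(all_events, ignore_index=True) if all_events else pd.DataFrame()
    if len(events):
        events = events.sort_values(["camera_id", "species", "timestamp"]).reset_index(drop=True)
    out["events"] = events
    return out
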