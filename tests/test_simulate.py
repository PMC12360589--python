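import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from sympatry.diel import times_to_radians
from sympatry.events import filter_independent
from sympatry.occu_two import TwoSpeciesParams
from sympatry.simulate import (
    SimConfig,
    simulate_deployments,
    simulate_events,
    simulate_study,
    simulate_two_species,
)


def flat_config(**kw):
    """Single-year, no-malfunction, no-year-effect configuration."""
    defaults = dict(
        years=(2015,),
        malfunction_prob=0.0,
        detection_year_effects={2015: 0.0},
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_sites=0)
        with pytest.raises(ValueError):
            SimConfig(years=())
        with pytest.raises(ValueError):
            SimConfig(altitude_range=(1600.0, 600.0))
        with pytest.raises(ValueError):
            SimConfig(habitat_probs={"BF": 0.5, "CF": 0.5, "RF": 0.5})
        with pytest.raises(ValueError):
            SimConfig(diel_profiles={("deer", "summer"): ((6.0, 2.0, 0.5),)})


class TestDeployments:
    def test_one_row_per_camera_year_without_malfunction(self):
        cfg = SimConfig(n_sites=39, years=(2015, 2016, 2017), malfunction_prob=0.0)
        dep = simulate_deployments(cfg)
        assert len(dep) == 117
        assert (dep["start_date"].dt.strftime("%m-%d") == "07-01").all()
        assert (dep["end_date"].dt.strftime("%m-%d") == "10-31").all()

    def test_deterministic_given_seed(self):
        cfg = SimConfig(seed=123, malfunction_prob=0.3)
        pd.testing.assert_frame_equal(simulate_deployments(cfg), simulate_deployments(cfg))

    def test_covariates_within_configured_ranges(self):
        dep = simulate_deployments(SimConfig(n_sites=40, seed=1))
        assert dep["altitude_m"].between(600, 1600).all()
        assert dep["slope_deg"].between(2.2, 37.1).all()
        assert set(dep["habitat"]) <= {"BF", "CF", "RF"}

    def test_adding_sites_preserves_existing_draws(self):
        small = simulate_deployments(SimConfig(n_sites=10, seed=9))
        big = simulate_deployments(SimConfig(n_sites=20, seed=9))
        merged = big[big["camera_id"].isin(small["camera_id"])].reset_index(drop=True)
        pd.testing.assert_frame_equal(merged, small.reset_index(drop=True))


class TestTwoSpecies:
    def test_latent_absence_means_zero_detections(self):
        cfg = flat_config(n_sites=300, seed=2)
        ha, hb, truth = simulate_two_species(cfg, "summer")
        assert np.nansum(ha.matrix[~truth.present_a]) == 0
        assert np.nansum(hb.matrix[~truth.present_b]) == 0

    def test_near_certain_parameters_give_all_ones(self):
        p = 1 - 1e-9
        cfg = flat_config(
            n_sites=30,
            occupancy_params=TwoSpeciesParams(p, p, p, p, p, p, p, p),
            seed=3,
        )
        ha, hb, _ = simulate_two_species(cfg, "summer")
        assert (ha.matrix == 1.0).all() and (hb.matrix == 1.0).all()

    def test_marginal_occupancy_of_b_matches_closed_form(self):
        # psiB = psiA*psiBA + (1-psiA)*psiBa = 0.5*0.8 + 0.5*0.2 = 0.5
        cfg = flat_config(
            n_sites=20_000,
            occupancy_params=TwoSpeciesParams(0.5, 0.8, 0.2, 0.4, 0.4, 0.4, 0.4, 0.4),
            seed=4,
        )
        _, _, truth = simulate_two_species(cfg, "summer")
        se = np.sqrt(0.5 * 0.5 / 20_000)
        assert abs(truth.present_b.mean() - 0.5) < 3 * se

    def test_no_interaction_means_independent_latent_states(self):
        cfg = flat_config(
            n_sites=5000,
            occupancy_params=TwoSpeciesParams(0.6, 0.5, 0.5, 0.4, 0.4, 0.4, 0.4, 0.4),
            seed=5,
        )
        _, _, truth = simulate_two_species(cfg, "summer")
        table = pd.crosstab(truth.present_a, truth.present_b)
        assert chi2_contingency(table).pvalue > 0.01

    def test_conditional_detection_frequencies_recover_generators(self):
        params = TwoSpeciesParams(0.6, 0.7, 0.4, 0.25, 0.45, 0.35, 0.2, 0.55)
        cfg = flat_config(n_sites=5000, occupancy_params=params, seed=6)
        ha, hb, truth = simulate_two_species(cfg, "summer")
        both = truth.present_a & truth.present_b
        surveyed = ~np.isnan(ha.matrix)

        # rBA: B-detections among both-present occasions where A was detected
        da = truth.detected_a[both] == 1.0
        db = truth.detected_b[both]
        for rate, sel in (
            (params.rBA, da),
            (params.rBa, (truth.detected_a[both] == 0.0)),
        ):
            obs = db[sel]
            freq = np.nanmean(obs)
            n = np.isfinite(obs).sum()
            assert abs(freq - rate) < 3 * np.sqrt(rate * (1 - rate) / n)
        # pB: B-only sites
        only_b = ~truth.present_a & truth.present_b
        obs = truth.detected_b[only_b]
        n = np.isfinite(obs).sum()
        assert abs(np.nanmean(obs) - params.pB) < 3 * np.sqrt(params.pB * (1 - params.pB) / n)
        assert surveyed.all()  # no malfunction configured

    def test_reproducible_histories(self):
        cfg = SimConfig(seed=7)
        a1, b1, _ = simulate_two_species(cfg, "autumn")
        a2, b2, _ = simulate_two_species(cfg, "autumn")
        np.testing.assert_array_equal(a1.matrix, a2.matrix)
        np.testing.assert_array_equal(b1.matrix, b2.matrix)


class TestEvents:
    def test_zero_detections_give_empty_event_table(self):
        eps = 1e-9
        cfg = flat_config(
            n_sites=10,
            occupancy_params=TwoSpeciesParams(eps, eps, eps, eps, eps, eps, eps, eps),
            seed=8,
        )
        _, _, truth = simulate_two_species(cfg, "summer")
        assert simulate_events(cfg, truth).empty

    def test_event_days_respect_detection_truth(self):
        cfg = SimConfig(seed=9)
        ha, hb, truth = simulate_two_species(cfg, "summer")
        events = simulate_events(cfg, truth)
        assert set(events["species"]) <= {"deer", "serow"}
        assert events["timestamp"].dt.month.isin([7, 8]).all()
        assert (events["timestamp"].dt.day <= 30).all()

    def test_circular_mean_of_single_von_mises_profile(self):
        # all events at a single 04:30-centered component, kappa=8
        profiles = {
            (sp, season): ((4.5, 8.0, 1.0),)
            for sp in ("deer", "serow")
            for season in ("summer", "autumn")
        }
        cfg = flat_config(
            n_sites=800,
            diel_profiles=profiles,
            occupancy_params=TwoSpeciesParams(0.9, 0.9, 0.9, 0.6, 0.6, 0.6, 0.6, 0.6),
            events_per_detection=2.0,
            seed=10,
        )
        _, _, truth = simulate_two_species(cfg, "summer")
        events = simulate_events(cfg, truth)
        assert len(events) >= 5000
        rad = times_to_radians(events["timestamp"])
        mean_angle = np.arctan2(np.sin(rad).mean(), np.cos(rad).mean()) % (2 * np.pi)
        mean_hour = mean_angle / (2 * np.pi) * 24
        assert abs(mean_hour - 4.5) < 0.25  # within 15 minutes

    def test_event_rate_recovers_configured_mean(self):
        rate = 1.5
        cfg = flat_config(
            n_sites=500,
            occupancy_params=TwoSpeciesParams(0.9, 0.9, 0.9, 0.5, 0.5, 0.5, 0.5, 0.5),
            events_per_detection=rate,
            seed=11,
        )
        _, _, truth = simulate_two_species(cfg, "summer")
        events = simulate_events(cfg, truth)
        n_detected = np.nansum(truth.detected_a) + np.nansum(truth.detected_b)
        mean_events = len(events) / n_detected
        # zero-truncated Poisson mean and variance
        zt_mean = rate / (1 - np.exp(-rate))
        zt_var = zt_mean * (1 + rate - zt_mean)
        assert abs(mean_events - zt_mean) < 3 * np.sqrt(zt_var / n_detected)

    def test_burst_photos_collapse_under_independence_filter(self):
        cfg = flat_config(n_sites=50, burst_photos=3, burst_spacing_minutes=5.0, seed=12)
        _, _, truth = simulate_two_species(cfg, "summer")
        events = simulate_events(cfg, truth)
        kept = filter_independent(events, 30)
        assert 0 < len(kept) < len(events)

    def test_byte_identical_event_tables(self, tmp_path):
        cfg = SimConfig(seed=13)
        study1 = simulate_study(cfg, seasons=("summer",))
        study2 = simulate_study(cfg, seasons=("summer",))
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        study1["events"].to_csv(p1, index=False)
        study2["events"].to_csv(p2, index=False)
        assert p1.read_bytes() == p2.read_bytes()
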