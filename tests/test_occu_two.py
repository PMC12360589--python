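import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import logit

from sympatry.occu_two import (
    ConstraintSpec,
    SifResult,
    TwoSpeciesOccupancy,
    TwoSpeciesParams,
    compute_sif,
    fit_two,
    loglik_two,
    sif_value,
    two_species_model_set,
)
from sympatry.occu_single import loglik_single
from sympatry.simulate import SimConfig, simulate_two_species

from conftest import make_history


def random_histories(rng, n_sites=12, n_occ=6, miss=0.1):
    def one():
        m = rng.integers(0, 2, (n_sites, n_occ)).astype(float)
        return m

    a, b = one(), one()
    holes = rng.random((n_sites, n_occ)) < miss
    a[holes] = np.nan
    b[holes] = np.nan
    return make_history(a), make_history(b)


prob = st.floats(min_value=0.01, max_value=0.99, allow_nan=False)


class TestParams:
    @settings(derandomize=True, max_examples=100)
    @given(vals=st.tuples(*([prob] * 8)))
    def test_latent_state_weights_sum_to_one(self, vals):
        p = TwoSpeciesParams(*vals)
        assert abs(p.latent_state_weights().sum() - 1.0) < 1e-12

    @settings(derandomize=True, max_examples=100)
    @given(psiA=prob, psiBA=prob, psiBa=prob)
    def test_sif_nonnegative_and_one_iff_equal(self, psiA, psiBA, psiBa):
        phi = sif_value(psiA, psiBA, psiBa)
        assert phi >= 0.0
        assert sif_value(psiA, psiBA, psiBA) == 1.0

    def test_probabilities_validated(self):
        with pytest.raises(ValueError, match="psiA"):
            TwoSpeciesParams(1.0, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5)


class TestLikelihood:
    def test_four_state_hand_enumeration(self):
        # one site, one occasion, A detected and B not, everything 0.5:
        # both-present contributes 0.25*0.5*0.5, A-only 0.25*0.5
        ha, hb = make_history([[1.0]]), make_history([[0.0]])
        p = TwoSpeciesParams(*[0.5] * 8)
        assert np.exp(loglik_two(p, ha, hb)) == pytest.approx(0.1875)

    @pytest.mark.parametrize("seed", range(5))
    def test_factorizes_into_single_species_under_no_interaction(self, seed):
        rng = np.random.default_rng(seed)
        ha, hb = random_histories(rng)
        psiA, psiB, pa, pb = rng.uniform(0.15, 0.85, 4)
        p = TwoSpeciesParams(psiA, psiB, psiB, pa, pb, pa, pb, pb)
        joint = loglik_two(p, ha, hb)
        factored = loglik_single([logit(psiA)], [logit(pa)], ha) + loglik_single(
            [logit(psiB)], [logit(pb)], hb
        )
        assert joint == pytest.approx(factored, abs=1e-10)

    def test_all_missing_site_contributes_zero_with_warning(self):
        ha = make_history([[1.0, 0.0], [np.nan, np.nan]])
        hb = make_history([[0.0, 0.0], [np.nan, np.nan]])
        p = TwoSpeciesParams(*[0.5] * 8)
        with pytest.warns(UserWarning, match="all-missing"):
            ll = loglik_two(p, ha, hb)
        ha1 = make_history([[1.0, 0.0]])
        hb1 = make_history([[0.0, 0.0]])
        assert ll == pytest.approx(loglik_two(p, ha1, hb1))

    def test_mismatched_structure_rejected(self):
        ha = make_history(np.zeros((3, 6)))
        hb = make_history(np.zeros((4, 6)))
        with pytest.raises(ValueError, match="share"):
            loglik_two(TwoSpeciesParams(*[0.5] * 8), ha, hb)

    def test_brute_force_state_enumeration_oracle(self):
        # independent oracle: enumerate the 4 latent states and every
        # occasion outcome explicitly for a 1-site, 2-occasion history
        rng = np.random.default_rng(42)
        for _ in range(10):
            vals = rng.uniform(0.1, 0.9, 8)
            p = TwoSpeciesParams(*vals)
            ya = rng.integers(0, 2, 2)
            yb = rng.integers(0, 2, 2)
            weights = p.latent_state_weights()
            lik = 0.0
            for state, w in zip(("both", "Aonly", "Bonly", "none"), weights):
                site = 1.0
                ok = True
                for j in range(2):
                    if state == "both":
                        pa = p.rA
                        site *= pa if ya[j] else 1 - pa
                        pb = p.rBA if ya[j] else p.rBa
                        site *= pb if yb[j] else 1 - pb
                    elif state == "Aonly":
                        site *= p.pA if ya[j] else 1 - p.pA
                        ok &= yb[j] == 0
                    elif state == "Bonly":
                        ok &= ya[j] == 0
                        site *= p.pB if yb[j] else 1 - p.pB
                    else:
                        ok &= ya[j] == 0 and yb[j] == 0
                lik += w * site if ok else 0.0
            ha = make_history([ya.astype(float)])
            hb = make_history([yb.astype(float)])
            assert loglik_two(p, ha, hb) == pytest.approx(np.log(lik), abs=1e-10)


class TestSif:
    def test_equal_conditional_occupancy_gives_exactly_one(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            psiA, psiB = rng.uniform(0.01, 0.99, 2)
            assert sif_value(psiA, psiB, psiB) == 1.0

    def test_hand_value(self):
        assert sif_value(0.5, 0.8, 0.2) == pytest.approx(1.6)

    def test_no_cooccurrence_gives_zero_limit(self):
        assert sif_value(0.5, 1e-12, 0.4) == pytest.approx(0.0, abs=1e-10)

    def test_matches_joint_over_marginal_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            p = TwoSpeciesParams(*rng.uniform(0.05, 0.95, 8))
            w = p.latent_state_weights()  # both, Aonly, Bonly, none
            psi_ab = w[0]
            psi_a = w[0] + w[1]
            psi_b = w[0] + w[2]
            assert sif_value(p.psiA, p.psiBA, p.psiBa) == pytest.approx(
                psi_ab / (psi_a * psi_b), abs=1e-12
            )

    def test_boundary_psiA_rejected(self):
        with pytest.raises(ValueError, match="boundary"):
            sif_value(0.0, 0.5, 0.5)

    def test_compute_sif_delta_method(self):
        p = TwoSpeciesParams(0.5, 0.8, 0.2, 0.5, 0.5, 0.5, 0.5, 0.5)
        res = compute_sif(p, cov=np.eye(3) * 1e-4)
        assert isinstance(res, SifResult)
        assert res.sif == pytest.approx(1.6)
        assert res.se > 0
        # numerical check of the analytic gradient
        eps = 1e-6
        g_num = np.array(
            [
                (sif_value(0.5 + eps, 0.8, 0.2) - sif_value(0.5 - eps, 0.8, 0.2)) / (2 * eps),
                (sif_value(0.5, 0.8 + eps, 0.2) - sif_value(0.5, 0.8 - eps, 0.2)) / (2 * eps),
                (sif_value(0.5, 0.8, 0.2 + eps) - sif_value(0.5, 0.8, 0.2 - eps)) / (2 * eps),
            ]
        )
        assert res.se == pytest.approx(np.sqrt(g_num @ (np.eye(3) * 1e-4) @ g_num), rel=1e-4)


class TestConstraints:
    def test_parameter_counts_match_structure_bookkeeping(self):
        cases = [
            (ConstraintSpec(True, False, ("year",)), 9),
            (ConstraintSpec(False, False, ("year",)), 10),
            (ConstraintSpec(True, True, ("year",)), 7),
            (ConstraintSpec(True, True, ("year", "altitude")), 8),
            (ConstraintSpec(False, True, ("year",)), 8),
        ]
        for spec, expected in cases:
            assert spec.n_params(n_years=3) == expected

    def test_model_set_is_the_constraint_grid(self):
        models = two_species_model_set()
        assert len(models) == 8
        combos = {(m.psi_equal, m.det_equal, m.detection_covariates) for m in models}
        assert len(combos) == 8

    def test_unknown_detection_covariate_rejected(self):
        with pytest.raises(ValueError):
            ConstraintSpec(detection_covariates=("slope",))


class TestFit:
    def test_constrained_fit_reports_sif_one_with_zero_se(self):
        cfg = SimConfig(seed=5)
        ha, hb, _ = simulate_two_species(cfg, "summer")
        est = TwoSpeciesOccupancy(
            psi_equal=True, det_equal=False, detection_covariates=("year",), n_starts=2
        ).fit(ha, hb)
        assert est.sif_ == 1.0
        assert est.sif_se_ == 0.0
        assert est.K_ == 9

    def test_recovers_generating_parameters_on_large_simulation(self):
        truth = TwoSpeciesParams(0.7, 0.5, 0.9, 0.4, 0.4, 0.4, 0.3, 0.5)
        cfg = SimConfig(
            n_sites=600,
            years=(2015,),
            malfunction_prob=0.0,
            detection_year_effects={2015: 0.0},
            occupancy_params=truth,
            seed=17,
        )
        ha, hb, _ = simulate_two_species(cfg, "summer")
        est = TwoSpeciesOccupancy(
            psi_equal=False, det_equal=False, detection_covariates=(), n_starts=2
        ).fit(ha, hb)
        assert est.converged_
        assert est.psiA_ == pytest.approx(truth.psiA, abs=0.1)
        assert est.psiBA_ == pytest.approx(truth.psiBA, abs=0.15)
        assert est.psiBa_ == pytest.approx(truth.psiBa, abs=0.15)

    def test_year_relabeling_permutes_per_year_estimates(self):
        cfg = SimConfig(seed=8, years=(2015, 2016))
        ha, hb, _ = simulate_two_species(cfg, "summer")
        est = TwoSpeciesOccupancy(n_starts=2).fit(ha, hb)
        # relabel years 2015<->2016: same likelihood, swapped year rows
        for h in (ha, hb):
            h.site_covariates["year"] = h.site_covariates["year"].map({2015: 2016, 2016: 2015})
        swapped = TwoSpeciesOccupancy(n_starts=2).fit(ha, hb)
        assert swapped.loglik_ == pytest.approx(est.loglik_, abs=1e-4)
        orig = est.real_scale_.loc["pA:2015", "estimate"]
        new = swapped.real_scale_.loc["pA:2016", "estimate"]
        assert new == pytest.approx(orig, abs=1e-3)

    def test_real_scale_table_layout(self):
        cfg = SimConfig(seed=5)
        ha, hb, _ = simulate_two_species(cfg, "summer")
        fit = fit_two(ha, hb, ConstraintSpec(True, False, ("year",)), n_starts=2)
        table = fit.extra["real_scale"]
        assert {"psiA", "psiBA", "psiBa"} <= set(table.index)
        for cls, year in itertools.product(("pA", "rA", "pB", "rBA", "rBa"), (2015, 2016, 2017)):
            assert f"{cls}:{year}" in table.index
        assert ((table["estimate"] > 0) & (table["estimate"] < 1)).all()
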