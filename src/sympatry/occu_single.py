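"""Single-season single-species occupancy model.

The zero-inflated detection likelihood for site i with detection history
y_i over its surveyed occasions:

    L_i = psi_i * prod_j p_ij^y_ij (1 - p_ij)^(1 - y_ij)
          + (1 - psi_i) * I(all observed y_ij = 0)

with logit links psi_i = expit(x_i' beta_psi), p_ij = expit(w_i' beta_p).
All covariates here are site-level, so p is constant across occasions
within a site. Missing occasions contribute no factor; sites with no
surveyed occasion are excluded (and counted out of the AICc sample size).

Maximization uses L-BFGS-B from several dispersed starting points;
standard errors come from the inverse of the numerically differentiated
observed information. Boundary estimates (psi or p driven to 0/1) are
reported as-is, not truncated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, log_expit
from sklearn.base import BaseEstimator
from statsmodels.tools.numdiff import approx_hess

from .histories import CovariateDesign, DetectionHistory, design_matrix
from .selection import aicc


@dataclass
class FitResult:
    """Maximum-likelihood fit of one candidate model."""

    name: str
    model: object
    beta: pd.Series
    se: pd.Series
    cov: np.ndarray | None
    loglik: float
    K: int
    aicc: float
    converged: bool
    n_sites_used: int
    extra: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        """Coefficients with z-based Wald statistics and two-sided p-values."""
        from scipy.stats import norm

        z = self.beta / self.se
        return pd.DataFrame(
            {
                "beta": self.beta,
                "se": self.se,
                "z": z,
                "p": 2 * norm.sf(np.abs(z)),
            }
        )


def _site_sufficient(history: DetectionHistory) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(detections, surveyed occasions, usable-site mask) per site."""
    obs = history.observed
    d = np.nansum(history.matrix, axis=1)
    o = obs.sum(axis=1)
    return d, o, o > 0


def loglik_single(
    beta_psi: np.ndarray,
    beta_p: np.ndarray,
    history: DetectionHistory,
    model: CovariateDesign = CovariateDesign(),
) -> float:
    """Log-likelihood at link-scale coefficients.

    Sites with every occasion missing are excluded (with a warning).
    """
    x_psi, _ = design_matrix(history.site_covariates, model.occupancy_terms)
    x_p, _ = design_matrix(history.site_covariates, model.detection_terms)
    d, o, use = _site_sufficient(history)
    if not use.all():
        warnings.warn(
            f"{int((~use).sum())} site(s) with no surveyed occasion excluded",
            stacklevel=2,
        )
    return _loglik_core(
        np.asarray(beta_psi, float),
        np.asarray(beta_p, float),
        x_psi[use],
        x_p[use],
        d[use],
        o[use],
    )


def _loglik_core(beta_psi, beta_p, x_psi, x_p, d, o) -> float:
    eta_psi = x_psi @ beta_psi
    eta_p = x_p @ beta_p
    # log[psi * p^d (1-p)^(o-d)] done entirely in log space
    log_det = log_expit(eta_psi) + d * log_expit(eta_p) + (o - d) * log_expit(-eta_p)
    never = d == 0
    site_ll = np.where(
        never, np.logaddexp(log_det, log_expit(-eta_psi)), log_det
    )
    return float(np.sum(site_ll))


class SingleSeasonOccupancy(BaseEstimator):
    """Scikit-learn-style estimator for the single-species model.

    Parameters
    ----------
    occupancy_terms, detection_terms : tuple of str
        Covariates on the logit of psi and p; each may hold at most one
        categorical (year/habitat) and one continuous (altitude/slope) term.
    n_starts : int
        Optimizer restarts from dispersed initial points (the likelihood
        can be multimodal near the boundary at small n).
    seed : int
        Seeds the restart dispersion.
    tol : float
        Convergence tolerance on the objective.
    """

    def __init__(
        self,
        occupancy_terms: tuple[str, ...] = (),
        detection_terms: tuple[str, ...] = (),
        n_starts: int = 5,
        seed: int = 0,
        tol: float = 1e-8,
    ):
        self.occupancy_terms = occupancy_terms
        self.detection_terms = detection_terms
        self.n_starts = n_starts
        self.seed = seed
        self.tol = tol

    @property
    def _design(self) -> CovariateDesign:
        return CovariateDesign(tuple(self.occupancy_terms), tuple(self.detection_terms))

    def fit(self, history: DetectionHistory, y=None) -> "SingleSeasonOccupancy":
        model = self._design
        x_psi, names_psi = design_matrix(history.site_covariates, model.occupancy_terms)
        x_p, names_p = design_matrix(history.site_covariates, model.detection_terms)
        d, o, use = _site_sufficient(history)
        x_psi, x_p, d, o = x_psi[use], x_p[use], d[use], o[use]
        k_psi = x_psi.shape[1]
        k = k_psi + x_p.shape[1]

        def nll(theta):
            return -_loglik_core(theta[:k_psi], theta[k_psi:], x_psi, x_p, d, o)

        theta, value, converged = _multistart(nll, k, self.n_starts, self.seed, self.tol)
        names = [f"psi:{n}" for n in names_psi] + [f"p:{n}" for n in names_p]
        se, cov = _wald_se(nll, theta)
        n_used = int(use.sum())
        self.names_ = names
        self.beta_ = pd.Series(theta, index=names)
        self.se_ = pd.Series(se, index=names)
        self.cov_ = cov
        self.loglik_ = -value
        self.K_ = k
        self.n_sites_used_ = n_used
        self.aicc_ = aicc(self.loglik_, k, n_used)
        self.converged_ = converged
        self.result_ = FitResult(
            name=model.name,
            model=model,
            beta=self.beta_,
            se=self.se_,
            cov=cov,
            loglik=self.loglik_,
            K=k,
            aicc=self.aicc_,
            converged=converged,
            n_sites_used=n_used,
            extra={"real_scale": self._real_scale(history, use)},
        )
        return self

    def predict_psi(self, history: DetectionHistory) -> np.ndarray:
        x, _ = design_matrix(history.site_covariates, self._design.occupancy_terms)
        k_psi = x.shape[1]
        return expit(x @ self.beta_.to_numpy()[:k_psi])

    def predict_p(self, history: DetectionHistory) -> np.ndarray:
        x, _ = design_matrix(history.site_covariates, self._design.detection_terms)
        k_p = x.shape[1]
        return expit(x @ self.beta_.to_numpy()[-k_p:])

    def _real_scale(self, history, use) -> pd.DataFrame:
        """psi and p at the reference site (all dummies 0, z-scores 0),
        with delta-method standard errors."""
        b = self.beta_.to_numpy()
        se = self.se_.to_numpy()
        k_psi = len([n for n in self.names_ if n.startswith("psi:")])
        rows = {}
        for label, idx in (("psi", 0), ("p", k_psi)):
            est = expit(b[idx])
            grad = est * (1 - est)
            rows[label] = {"estimate": est, "se": grad * se[idx]}
        return pd.DataFrame(rows).T


def _multistart(nll, k, n_starts, seed, tol):
    """Best optimum over dispersed starts; NaN-safe."""
    rng = np.random.default_rng(seed)
    best = None
    converged = False
    for s in range(max(1, n_starts)):
        x0 = np.zeros(k) if s == 0 else rng.normal(0.0, 1.5, size=k)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = minimize(nll, x0, method="L-BFGS-B", options={"ftol": tol, "maxiter": 500})
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun - 1e-12:
            best = res
            converged = bool(res.success)
        elif abs(res.fun - best.fun) <= 1e-8:
            converged = converged or bool(res.success)
    if best is None:
        raise RuntimeError("all optimizer starts failed")
    return best.x, best.fun, converged


def _wald_se(nll, theta):
    """SEs from the inverse observed information; NaN when singular."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            hess = approx_hess(theta, nll)
            cov = np.linalg.inv(hess)
            var = np.diag(cov)
            se = np.where(var > 0, np.sqrt(np.abs(var)), np.nan)
            if not np.isfinite(se).all():
                se = np.where(np.isfinite(se), se, np.nan)
            return se, cov
        except np.linalg.LinAlgError:
            return np.full(len(theta), np.nan), None


def fit_single(
    history: DetectionHistory,
    model: CovariateDesign = CovariateDesign(),
    n_starts: int = 5,
    seed: int = 0,
) -> FitResult:
    """Fit one candidate model; thin wrapper over SingleSeasonOccupancy."""
    est = SingleSeasonOccupancy(
        occupancy_terms=model.occupancy_terms,
        detection_terms=model.detection_terms,
        n_starts=n_starts,
        seed=seed,
    ).fit(history)
    return est.result_


def fit_model_set(
    history: DetectionHistory,
    models: list[CovariateDesign],
    n_starts: int = 5,
    seed: int = 0,
) -> list[FitResult]:
    """Fit every candidate design, skipping (and reporting) failures."""
    fits = []
    for m in models:
        try:
            fits.append(fit_single(history, m, n_starts=n_starts, seed=seed))
        except RuntimeError as err:  # pragma: no cover - defensive
            warnings.warn(f"model {m.name} failed to fit: {err}", stacklevel=2)
    return fits
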