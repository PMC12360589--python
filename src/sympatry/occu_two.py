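"""Single-season two-species co-occurrence occupancy model (psiBa/rBa form).

Species A is the dominant species, B the subordinate. Eight real-scale
parameters:

* psiA  — occupancy of A
* psiBA — occupancy of B given A present
* psiBa — occupancy of B given A absent
* pA    — detection of A given B absent
* pB    — detection of B given A absent
* rA    — detection of A given both present
* rBA   — detection of B given both present and A detected (that occasion)
* rBa   — detection of B given both present and A not detected

The site likelihood mixes four latent states with weights
{psiA*psiBA, psiA*(1-psiBA), (1-psiA)*psiBa, (1-psiA)*(1-psiBa)}; states
inconsistent with the data (a detection of an absent species) contribute
zero. Two constraint scenarios are fit per the study design: occupancy
interaction on/off (psiBA != psiBa vs =) and detection interaction on/off
(pB != rBA != rBa vs =). Occupancy carries no covariates; detection allows
year offsets and an altitude slope, shared across the five detection
classes (each class keeps its own intercept) and across the two species.

The species interaction factor is

    SIF (phi) = psiA*psiBA / (psiA * (psiA*psiBA + (1-psiA)*psiBa))
              = psiBA / (psiBa + psiA*(psiBA - psiBa)),

the ratio of joint occupancy to the product of marginals; 1 means
independent site use, < 1 spatial segregation, > 1 aggregation. The second
(cancelled) form is used so that psiBA == psiBa gives exactly 1.0 in
floating point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit, logit
from sklearn.base import BaseEstimator

from .histories import DetectionHistory
from .occu_single import FitResult, _multistart, _wald_se
from .selection import aicc

_NEG_INF = -np.inf


@dataclass(frozen=True)
class TwoSpeciesParams:
    """Real-scale parameter set; every probability must lie in (0, 1)."""

    psiA: float
    psiBA: float
    psiBa: float
    pA: float
    pB: float
    rA: float
    rBA: float
    rBa: float

    def __post_init__(self) -> None:
        for name, val in vars(self).items():
            if not 0.0 < val < 1.0:
                raise ValueError(f"{name}={val} outside (0, 1)")

    def latent_state_weights(self) -> np.ndarray:
        """P(both), P(A only), P(B only), P(neither); sums to 1."""
        return np.array(
            [
                self.psiA * self.psiBA,
                self.psiA * (1.0 - self.psiBA),
                (1.0 - self.psiA) * self.psiBa,
                (1.0 - self.psiA) * (1.0 - self.psiBa),
            ]
        )


@dataclass(frozen=True)
class SifResult:
    sif: float
    se: float


@dataclass(frozen=True)
class ConstraintSpec:
    """One candidate structure of the two-species family.

    ``psi_equal``: psiBA = psiBa (no occupancy interaction).
    ``det_equal``: pB = rBA = rBa (no detection interaction).
    ``detection_covariates``: subset of {year, altitude}; year enters as
    offsets shared across the five detection classes, altitude as one
    shared slope on standardized altitude.
    """

    psi_equal: bool = True
    det_equal: bool = False
    detection_covariates: tuple[str, ...] = ("year",)

    def __post_init__(self) -> None:
        bad = set(self.detection_covariates) - {"year", "altitude"}
        if bad:
            raise ValueError(f"unsupported detection covariates {sorted(bad)}")

    @property
    def name(self) -> str:
        psi = "psiBA=psiBa" if self.psi_equal else "psiBA!=psiBa"
        det = "pB=rBA=rBa" if self.det_equal else "pB!=rBA!=rBa"
        cov = "+".join(self.detection_covariates) or "."
        return f"{psi} | {det} | det({cov})"

    def n_params(self, n_years: int) -> int:
        k = 2 + (0 if self.psi_equal else 1)  # psiA, psiBA (, psiBa)
        k += 3 + (0 if self.det_equal else 2)  # pA, rA, pB (, rBA, rBa)
        if "year" in self.detection_covariates:
            k += n_years - 1
        if "altitude" in self.detection_covariates:
            k += 1
        return k


def two_species_model_set(
    covariate_sets: tuple[tuple[str, ...], ...] = (("year",), ("year", "altitude")),
) -> list[ConstraintSpec]:
    """The 2 x 2 constraint grid crossed with the detection covariate sets."""
    return [
        ConstraintSpec(psi_equal=pe, det_equal=de, detection_covariates=cov)
        for pe in (True, False)
        for de in (True, False)
        for cov in covariate_sets
    ]


def _check_aligned(historyA: DetectionHistory, historyB: DetectionHistory) -> None:
    if historyA.sites != historyB.sites or historyA.occasions != historyB.occasions:
        raise ValueError("histories must share site list and occasion structure")
    if not np.array_equal(historyA.observed, historyB.observed):
        raise ValueError("histories disagree on which site-occasions were surveyed")


def _loglik_two_core(
    lpsiA: float,
    lpsiBA: float,
    lpsiBa: float,
    eta_pA: np.ndarray,
    eta_pB: np.ndarray,
    eta_rA: np.ndarray,
    eta_rBA: np.ndarray,
    eta_rBa: np.ndarray,
    yA: np.ndarray,
    yB: np.ndarray,
    mask: np.ndarray,
) -> np.ndarray:
    """Per-site log-likelihood; detection etas are per-site, logit scale."""
    ya = np.where(mask, yA, 0.0)
    yb = np.where(mask, yB, 0.0)
    m = mask.astype(float)

    def bern(eta, y):
        # sum over occasions of the Bernoulli log-pmf, missing skipped
        return np.sum(m * (y * log_expit(eta)[:, None] + (1 - y) * log_expit(-eta)[:, None]), axis=1)

    lA_both = bern(eta_rA, ya)
    # B's factor in state "both" switches on A's same-occasion detection
    lB_both = np.sum(
        m
        * (
            ya * (yb * log_expit(eta_rBA)[:, None] + (1 - yb) * log_expit(-eta_rBA)[:, None])
            + (1 - ya) * (yb * log_expit(eta_rBa)[:, None] + (1 - yb) * log_expit(-eta_rBa)[:, None])
        ),
        axis=1,
    )
    lA_only = bern(eta_pA, ya)
    lB_only = bern(eta_pB, yb)
    a_never = np.sum(m * ya, axis=1) == 0
    b_never = np.sum(m * yb, axis=1) == 0

    lw = np.array(
        [
            log_expit(lpsiA) + log_expit(lpsiBA),
            log_expit(lpsiA) + log_expit(-lpsiBA),
            log_expit(-lpsiA) + log_expit(lpsiBa),
            log_expit(-lpsiA) + log_expit(-lpsiBa),
        ]
    )
    states = np.stack(
        [
            lw[0] + lA_both + lB_both,
            np.where(b_never, lw[1] + lA_only, _NEG_INF),
            np.where(a_never, lw[2] + lB_only, _NEG_INF),
            np.where(a_never & b_never, lw[3], _NEG_INF),
        ]
    )
    top = states.max(axis=0)
    return top + np.log(np.sum(np.exp(states - top), axis=0))


def loglik_two(
    params: TwoSpeciesParams,
    historyA: DetectionHistory,
    historyB: DetectionHistory,
) -> float:
    """Log-likelihood of a constant (covariate-free) parameter set.

    Sites with every occasion missing contribute zero and are reported
    with a warning.
    """
    _check_aligned(historyA, historyB)
    mask = historyA.observed
    n = len(historyA.sites)
    empty = mask.sum(axis=1) == 0
    if empty.any():
        warnings.warn(f"{int(empty.sum())} all-missing site(s) contribute nothing", stacklevel=2)
    ones = np.ones(n)
    site_ll = _loglik_two_core(
        logit(params.psiA),
        logit(params.psiBA),
        logit(params.psiBa),
        ones * logit(params.pA),
        ones * logit(params.pB),
        ones * logit(params.rA),
        ones * logit(params.rBA),
        ones * logit(params.rBa),
        historyA.matrix,
        historyB.matrix,
        mask,
    )
    return float(np.sum(site_ll[~empty]))


def sif_value(psiA: float, psiBA: float, psiBa: float) -> float:
    """Species interaction factor phi = psi_AB / (psi_A * psi_B)."""
    if not 0.0 < psiA < 1.0:
        raise ValueError(f"SIF undefined at boundary psiA={psiA}")
    denom = psiBa + psiA * (psiBA - psiBa)  # = marginal occupancy of B
    if denom <= 0.0:
        raise ValueError("SIF undefined: marginal occupancy of B is zero")
    return psiBA / denom


def _sif_gradient(psiA: float, psiBA: float, psiBa: float) -> np.ndarray:
    d = psiBa + psiA * (psiBA - psiBa)
    return np.array(
        [
            -psiBA * (psiBA - psiBa) / d**2,
            psiBa * (1.0 - psiA) / d**2,
            -psiBA * (1.0 - psiA) / d**2,
        ]
    )


def compute_sif(params: TwoSpeciesParams, cov: np.ndarray | None = None) -> SifResult:
    """SIF with a delta-method SE from the real-scale occupancy covariance.

    ``cov`` is the 3x3 covariance of (psiA, psiBA, psiBa); omit it for a
    point estimate (se = nan). With psiBA = psiBa the gradient components
    for psiBA and psiBa cancel, so a fit constrained that way reports
    SIF = 1.0 +/- 0.0.
    """
    phi = sif_value(params.psiA, params.psiBA, params.psiBa)
    if cov is None:
        return SifResult(sif=phi, se=float("nan"))
    g = _sif_gradient(params.psiA, params.psiBA, params.psiBa)
    return SifResult(sif=phi, se=float(np.sqrt(g @ cov @ g)))


class TwoSpeciesOccupancy(BaseEstimator):
    """Scikit-learn-style estimator for the co-occurrence model.

    Fit with ``fit(historyA, historyB)`` where history A belongs to the
    dominant species. Fitted attributes include link-scale ``beta_``/``se_``,
    real-scale ``params_`` (reference-year probabilities), ``sif_`` and
    ``sif_se_``, plus ``aicc_`` for model selection.
    """

    def __init__(
        self,
        psi_equal: bool = True,
        det_equal: bool = False,
        detection_covariates: tuple[str, ...] = ("year",),
        n_starts: int = 5,
        seed: int = 0,
        tol: float = 1e-8,
    ):
        self.psi_equal = psi_equal
        self.det_equal = det_equal
        self.detection_covariates = detection_covariates
        self.n_starts = n_starts
        self.seed = seed
        self.tol = tol

    @property
    def _constraint(self) -> ConstraintSpec:
        return ConstraintSpec(
            psi_equal=self.psi_equal,
            det_equal=self.det_equal,
            detection_covariates=tuple(self.detection_covariates),
        )

    # -- parameter vector layout ------------------------------------------
    def _layout(self, year_levels: list) -> list[str]:
        names = ["psiA", "psiBA"]
        if not self.psi_equal:
            names.append("psiBa")
        names += ["pA", "rA", "pB"]
        if not self.det_equal:
            names += ["rBA", "rBa"]
        if "year" in self.detection_covariates:
            names += [f"year{lev}" for lev in year_levels[1:]]
        if "altitude" in self.detection_covariates:
            names.append("altitude")
        return names

    def _unpack(self, theta: np.ndarray, names: list[str], year_dummies, alt_z):
        idx = {n: i for i, n in enumerate(names)}
        lpsiA = theta[idx["psiA"]]
        lpsiBA = theta[idx["psiBA"]]
        lpsiBa = theta[idx["psiBa"]] if "psiBa" in idx else lpsiBA
        shift = 0.0
        if year_dummies is not None:
            offs = np.array([theta[idx[n]] for n in names if n.startswith("year")])
            shift = year_dummies @ offs
        if "altitude" in idx:
            shift = shift + theta[idx["altitude"]] * alt_z
        eta = {}
        for cls in ("pA", "rA", "pB"):
            eta[cls] = theta[idx[cls]] + shift
        if self.det_equal:
            eta["rBA"] = eta["rBa"] = eta["pB"]
        else:
            eta["rBA"] = theta[idx["rBA"]] + shift
            eta["rBa"] = theta[idx["rBa"]] + shift
        return lpsiA, lpsiBA, lpsiBa, eta

    def fit(self, historyA: DetectionHistory, historyB: DetectionHistory) -> "TwoSpeciesOccupancy":
        _check_aligned(historyA, historyB)
        covs = historyA.site_covariates
        year_levels = sorted(covs["year"].unique())
        self.year_levels_ = year_levels
        names = self._layout(year_levels)
        k = len(names)

        mask = historyA.observed
        use = mask.sum(axis=1) > 0
        yA = historyA.matrix[use]
        yB = historyB.matrix[use]
        m = mask[use]
        year_dummies = None
        if "year" in self.detection_covariates:
            year_dummies = np.column_stack(
                [(covs["year"] == lev).to_numpy(float) for lev in year_levels[1:]]
            )[use]
        alt_z = None
        if "altitude" in self.detection_covariates:
            if "altitude_z" not in covs:
                raise ValueError("standardized altitude_z missing; call standardize() first")
            alt_z = covs["altitude_z"].to_numpy(float)[use]

        def nll(theta):
            lpsiA, lpsiBA, lpsiBa, eta = self._unpack(theta, names, year_dummies, alt_z)
            site_ll = _loglik_two_core(
                lpsiA, lpsiBA, lpsiBa,
                np.broadcast_to(eta["pA"], (use.sum(),)),
                np.broadcast_to(eta["pB"], (use.sum(),)),
                np.broadcast_to(eta["rA"], (use.sum(),)),
                np.broadcast_to(eta["rBA"], (use.sum(),)),
                np.broadcast_to(eta["rBa"], (use.sum(),)),
                yA, yB, m,
            )
            return -float(np.sum(site_ll))

        theta, value, converged = _multistart(nll, k, self.n_starts, self.seed, self.tol)
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
        self._finalize(theta, names)
        self.result_ = FitResult(
            name=self._constraint.name,
            model=self._constraint,
            beta=self.beta_,
            se=self.se_,
            cov=cov,
            loglik=self.loglik_,
            K=k,
            aicc=self.aicc_,
            converged=converged,
            n_sites_used=n_used,
            extra={"sif": self.sif_, "sif_se": self.sif_se_, "real_scale": self.real_scale_},
        )
        return self

    def _finalize(self, theta: np.ndarray, names: list[str]) -> None:
        idx = {n: i for i, n in enumerate(names)}
        psiA = float(expit(theta[idx["psiA"]]))
        psiBA = float(expit(theta[idx["psiBA"]]))
        psiBa = float(expit(theta[idx["psiBa"]])) if "psiBa" in idx else psiBA
        self.psiA_, self.psiBA_, self.psiBa_ = psiA, psiBA, psiBa
        # delta method through the link: d psi / d theta = psi (1 - psi)
        if self.cov_ is not None:
            g = np.zeros(len(theta))
            grad_real = _sif_gradient(psiA, psiBA, psiBa)
            g[idx["psiA"]] = grad_real[0] * psiA * (1 - psiA)
            if "psiBa" in idx:
                g[idx["psiBA"]] = grad_real[1] * psiBA * (1 - psiBA)
                g[idx["psiBa"]] = grad_real[2] * psiBa * (1 - psiBa)
            else:  # shared parameter: gradients add (and cancel exactly)
                g[idx["psiBA"]] = (grad_real[1] + grad_real[2]) * psiBA * (1 - psiBA)
            var = float(g @ self.cov_ @ g)
            self.sif_se_ = float(np.sqrt(max(var, 0.0)))
        else:
            self.sif_se_ = float("nan")
        self.sif_ = sif_value(psiA, psiBA, psiBa)
        self.real_scale_ = self._real_scale_table(theta, idx)

    def _real_scale_table(self, theta: np.ndarray, idx: dict) -> pd.DataFrame:
        """Real-scale estimates in the reporting layout: occupancy rows,
        then each detection class by year (delta-method SEs)."""
        rows = []
        def add(label, indices, coefs):
            eta = float(np.dot(coefs, theta[indices]))
            est = float(expit(eta))
            if self.cov_ is not None:
                g = np.zeros(len(theta))
                g[indices] = np.asarray(coefs, float) * est * (1 - est)
                se = float(np.sqrt(max(g @ self.cov_ @ g, 0.0)))
            else:
                se = float("nan")
            rows.append({"parameter": label, "estimate": est, "se": se})

        add("psiA", [idx["psiA"]], [1.0])
        add("psiBA", [idx["psiBA"]], [1.0])
        add("psiBa", [idx["psiBa"] if "psiBa" in idx else idx["psiBA"]], [1.0])
        classes = ["pA", "rA", "pB"] + ([] if self.det_equal else ["rBA", "rBa"])
        year_terms = [n for n in self.names_ if n.startswith("year")]
        for cls in classes:
            for j, lev in enumerate(self.year_levels_):
                indices = [idx[cls]]
                coefs = [1.0]
                if year_terms and j > 0:
                    indices.append(idx[year_terms[j - 1]])
                    coefs.append(1.0)
                add(f"{cls}:{lev}", indices, coefs)
        return pd.DataFrame(rows).set_index("parameter")


def fit_two(
    historyA: DetectionHistory,
    historyB: DetectionHistory,
    constraint: ConstraintSpec = ConstraintSpec(),
    n_starts: int = 5,
    seed: int = 0,
) -> FitResult:
    """Fit one constraint scenario; thin wrapper over TwoSpeciesOccupancy."""
    est = TwoSpeciesOccupancy(
        psi_equal=constraint.psi_equal,
        det_equal=constraint.det_equal,
        detection_covariates=constraint.detection_covariates,
        n_starts=n_starts,
        seed=seed,
    ).fit(historyA, historyB)
    return est.result_


def fit_two_model_set(
    historyA: DetectionHistory,
    historyB: DetectionHistory,
    models: list[ConstraintSpec] | None = None,
    n_starts: int = 5,
    seed: int = 0,
) -> list[FitResult]:
    models = models if models is not None else two_species_model_set()
    fits = []
    for m in models:
        try:
            fits.append(fit_two(historyA, historyB, m, n_starts=n_starts, seed=seed))
        except RuntimeError as err:  # pragma: no cover - defensive
            warnings.warn(f"model {m.name} failed to fit: {err}", stacklevel=2)
    return fits
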