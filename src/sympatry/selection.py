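"""Information-theoretic model selection and averaging.

AICc = -2 logL + 2K + 2K(K+1)/(n - K - 1), with n the number of sites
contributing at least one surveyed occasion. Models within 2 AICc of the
best are the *competitive set*; coefficient estimates are model-averaged
over the competitive models that contain the coefficient, with Akaike
weights renormalized within that subset (conditional averaging), and an
unconditional standard error combining within-model variance and
between-model spread:

    se_bar = sqrt( sum_m w_m * (se_m^2 + (beta_m - beta_bar)^2) ).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

COMPETITIVE_DELTA = 2.0


def aicc(loglik: float, K: int, n: int) -> float:
    """Small-sample Akaike information criterion."""
    if n <= K + 1:
        raise ValueError(f"AICc undefined: n={n} must exceed K+1={K + 1}")
    return -2.0 * loglik + 2.0 * K + 2.0 * K * (K + 1) / (n - K - 1)


@dataclass
class SelectionResult:
    """Ranked candidate set with Akaike weights and the competitive subset."""

    table: pd.DataFrame
    competitive: list  # FitResults with delta_aicc < 2, best first

    @property
    def best(self):
        return self.competitive[0]


def rank_and_weight(fits: list) -> SelectionResult:
    """Rank converged fits by AICc and attach Akaike weights.

    Weights w_m = exp(-delta_m/2) / sum_k exp(-delta_k/2) over the full
    converged candidate set. Stable sort by AICc; ties broken by smaller K
    then model name. Non-converged fits are dropped (reported in the table
    is only the converged set).
    """
    usable = [f for f in fits if f.converged]
    if not usable:
        raise ValueError("no converged fits to rank")
    usable = sorted(usable, key=lambda f: (f.aicc, f.K, f.name))
    a = np.array([f.aicc for f in usable])
    delta = a - a[0]
    w = np.exp(-delta / 2.0)
    w /= w.sum()
    table = pd.DataFrame(
        {
            "model": [f.name for f in usable],
            "K": [f.K for f in usable],
            "loglik": [f.loglik for f in usable],
            "aicc": a,
            "delta_aicc": delta,
            "weight": w,
        }
    )
    competitive = [f for f, d in zip(usable, delta) if d < COMPETITIVE_DELTA]
    return SelectionResult(table=table, competitive=competitive)


def model_average(selection: SelectionResult) -> pd.DataFrame:
    """Conditionally model-averaged coefficients over the competitive set.

    Each coefficient is averaged over the competitive models containing it,
    with weights renormalized within that subset; the unconditional SE adds
    the between-model spread to the within-model variance. Returns a frame
    indexed by coefficient with columns beta, se, n_models, and z-based
    two-sided Wald p-values.
    """
    from scipy.stats import norm

    comp = selection.competitive
    sub = selection.table[selection.table["delta_aicc"] < COMPETITIVE_DELTA]
    weights = dict(zip(sub["model"], sub["weight"]))
    terms: dict[str, list[tuple[float, float, float]]] = {}
    for f in comp:
        w = weights[f.name]
        for name, b in f.beta.items():
            terms.setdefault(name, []).append((w, b, f.se[name]))
    rows = {}
    for name, entries in terms.items():
        w = np.array([e[0] for e in entries])
        w = w / w.sum()
        b = np.array([e[1] for e in entries])
        s = np.array([e[2] for e in entries])
        bbar = float(np.sum(w * b))
        se = float(np.sqrt(np.sum(w * (s**2 + (b - bbar) ** 2))))
        rows[name] = {"beta": bbar, "se": se, "n_models": len(entries)}
    out = pd.DataFrame(rows).T
    out["n_models"] = out["n_models"].astype(int)
    z = out["beta"] / out["se"]
    out["p"] = 2 * norm.sf(np.abs(z))
    return out
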