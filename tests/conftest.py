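import numpy as np
import pandas as pd
import pytest

from sympatry.histories import DetectionHistory, occasion_labels


def make_history(matrix, years=None, habitats=None, altitudes=None, slopes=None,
                 season="summer", species=None):
    """DetectionHistory from a plain matrix (nan = missing occasion)."""
    matrix = np.asarray(matrix, dtype=float)
    n, j = matrix.shape
    sites = [f"s{i:03d}" for i in range(n)]
    covs = pd.DataFrame(
        {
            "year": years if years is not None else [2015] * n,
            "habitat": habitats if habitats is not None else ["BF"] * n,
            "altitude_m": altitudes if altitudes is not None else np.linspace(600, 1600, n),
            "slope_deg": slopes if slopes is not None else np.linspace(3, 30, n),
        },
        index=sites,
    )
    occ = occasion_labels(season)[:j] if j <= 6 else [f"o{k}" for k in range(j)]
    return DetectionHistory(season, sites, occ, matrix, covs, species=species)


@pytest.fixture
def history_factory():
    return make_history


def simulate_constant_history(n_sites, n_occasions, psi, p, rng):
    """Constant-parameter detection data for oracle checks."""
    z = rng.random(n_sites) < psi
    y = (rng.random((n_sites, n_occasions)) < p) & z[:, None]
    return make_history(y.astype(float))
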