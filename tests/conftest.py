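"""Shared fixtures: montage, synthetic rating data, small model datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from thetasync.montage import load_standard_montage


@pytest.fixture(scope="session")
def montage():
    return load_standard_montage()


@pytest.fixture(scope="session")
def beta_rows():
    """Beta-regression fixture: 6 subjects x 20 trials, planted interaction."""
    rng = np.random.default_rng(3)
    b = np.array([-0.85, 0.1, 0.1, 0.8])
    phi = 60.0
    rows = []
    for s in range(6):
        u = rng.normal(0, 0.2, 4)
        for t in range(20):
            most, old = t % 2, int(t < 10)
            x = np.array([1.0, most, old, most * old])
            mu = expit(x @ (b + u))
            rows.append(
                dict(
                    subject=f"S{s}",
                    ispc=float(rng.beta(mu * phi, (1 - mu) * phi)),
                    pleasantness_class="most" if most else "least",
                    familiarity_condition="old" if old else "new",
                )
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def pleasantness_table():
    """Student-t fixture: retained trials with a planted old-new shift."""
    rng = np.random.default_rng(11)
    rows = []
    for s in range(6):
        a = rng.normal(0, 0.25)
        for t in range(20):
            old = int(t < 10)
            rows.append(
                dict(
                    subject=f"S{s}",
                    familiarity_condition="old" if old else "new",
                    pleasantness_index=float(2.5 + a + 0.12 * old + rng.standard_t(8) * 0.35),
                    retained=True,
                )
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def familiarity_ratings():
    """Ordinal fixture: latent-normal ratings, old shifted +2 latent SD."""
    rng = np.random.default_rng(5)
    thresholds = np.array([0.8, 1.7, 2.9, 3.8, 4.6, 5.4])
    rows = []
    for s in range(6):
        dev = rng.normal(0, 0.3)
        for e in range(20):
            old = e < 10
            def rate(shift):
                lat = dev + shift + rng.standard_normal()
                return int(np.searchsorted(thresholds, lat) + 1)
            if old:
                rows.append(dict(subject=f"S{s}", condition="exposure", rating=rate(0.0)))
                rows.append(dict(subject=f"S{s}", condition="old", rating=rate(2.0)))
            else:
                rows.append(dict(subject=f"S{s}", condition="new", rating=rate(0.0)))
    return pd.DataFrame(rows)
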