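import datetime as dt

import numpy as np
import pytest

from oppqct import PhantomObservation, default_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture
def ict_model(registry):
    return registry["philips_ict_256"]


def make_observations(model, densities, scanner_id="scanner", date=dt.date(2020, 1, 1)):
    """Noiseless phantom points lying exactly on a scanner's conversion line."""
    return [
        PhantomObservation(
            scanner_id=scanner_id,
            acquisition_date=date,
            insert_id=f"rod_{d:g}",
            nominal_density=d,
            measured_hu=model.invert(d),
        )
        for d in densities
    ]


def ols_normal_equations(x, y):
    """Closed-form simple OLS oracle: (slope, intercept, see)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    sxx = ((x - x.mean()) ** 2).sum()
    slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - slope * x - intercept
    see = 0.0 if n <= 2 else np.sqrt((resid**2).sum() / (n - 2))
    return slope, intercept, see
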