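import numpy as np
import pandas as pd
import pytest

import rhythmarm as ra


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def make_series(x, y, start_hour=0, pid="p"):
    """Build an HourlySeries directly from X / Y arrays (NaN in x = missing)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    n = len(x)
    data = pd.DataFrame(
        {
            "t": np.arange(n),
            "hour_of_day": (start_hour + np.arange(n) + 1) % 24,
            "X": x,
            "Y": y,
            "imputed": False,
        }
    )
    return ra.HourlySeries(participant_id=pid, data=data, start_hour_epoch=start_hour)


@pytest.fixture(scope="session")
def default_params():
    """A plausible parameter set for oracle tests."""
    t1, t2 = ra.diurnal_templates()
    return ra.CTHMMParams(
        alpha1=np.log(0.3),
        beta1=0.4,
        alpha2=np.log(0.2),
        beta2=-0.3,
        b1=t1 * 0.7,
        b2=t2 * 0.7,
        sigma1_sq=0.49,
        sigma2_sq=0.49,
        mu_rest=0.05,
        mu_active=5.0,
        delta=np.array([0.6, 0.4]),
    )


@pytest.fixture(scope="session")
def fitted_participant():
    """One moderately rhythmic simulated participant fitted end to end.

    Session-scoped: several tests inspect different facets of the same fit.
    """
    truth = ra.make_truth(sigma_sq_total=2.0)
    series, states = ra.simulate_participant(truth, n_days=21, seed=777, participant_id="fix")
    fitted, imputed, imp_fit = ra.process_participant(series, hsmm_seed=5)
    return {
        "truth": truth,
        "series": series,
        "states": states,
        "fitted": fitted,
        "imputed": imputed,
        "imp_fit": imp_fit,
    }
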