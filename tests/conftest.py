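import numpy as np
import pandas as pd
import pytest

import oagsim as og


@pytest.fixture(scope="session")
def params():
    return og.default_params()


@pytest.fixture(scope="session")
def retro_cohort(params):
    """Default-scale retrospective cohort (67 cases / 1919 controls)."""
    return og.generate_cohort(params, seed=7, mode="retrospective")


def make_planted_cohort(seed, n_cases=67, n_controls=200, n_noise=5,
                        signal_sd=0.3):
    """Balanced-signal toy data: one variable tracks the label, rest is noise.

    Returns (cases, controls) frames with columns status, age, signal,
    noise0..noise{n_noise-1}.
    """
    rng = np.random.default_rng(seed)

    def group(n, status):
        df = pd.DataFrame({"status": np.full(n, status, dtype=np.int64),
                           "age": rng.normal(65.0, 8.0, n)})
        df["signal"] = status + rng.normal(0.0, signal_sd, n)
        for j in range(n_noise):
            df[f"noise{j}"] = rng.normal(size=n)
        return df

    return group(n_cases, 1), group(n_controls, 0)


@pytest.fixture()
def planted():
    return make_planted_cohort(seed=123)
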