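import numpy as np
import pytest

import spirlhgf as sp


@pytest.fixture(scope="session")
def design160():
    return sp.default_design()


@pytest.fixture(scope="session")
def design40():
    return sp.generate_design(
        [(10, 0.8, "stable"), (10, 0.2, "volatile"),
         (10, 0.5, "unpredictable"), (10, 0.8, "stable")]
    )


@pytest.fixture(scope="session")
def m1_priors():
    return sp.initial_priors("M1")


@pytest.fixture(scope="session")
def m1_subject(design40, m1_priors):
    """One synthetic subject drawn from the M1 priors on the small design."""
    truth, ds = sp.simulate_from_priors("M1", m1_priors, design40, n_sim=1, seed=11)
    return truth, ds[0]


def make_dataset(u, y_bin=None, y_rt=None, design=None, subject_id="s1",
                 ignored=None, irregular=None):
    """Assemble a Dataset from plain arrays (None entries stay missing)."""
    n = len(u)
    trials = []
    for k in range(n):
        ig = bool(ignored[k]) if ignored is not None else False
        ir = bool(irregular[k]) if irregular is not None else False
        yb = None if (y_bin is None or y_bin[k] is None or ig) else int(y_bin[k])
        yr = None if (y_rt is None or y_rt[k] is None or ig) else float(y_rt[k])
        trials.append(sp.TrialRecord(k + 1, int(u[k]), yb, yr, ig, ir))
    return sp.Dataset(subject_id, trials, design)
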