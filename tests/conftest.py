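import numpy as np
import pytest

from revcor.archive import TrialRecord
from revcor.experiment import StaircaseState, default_staircase, run_staircase
from revcor.observers import make_observer
from revcor.stimuli import DisplaySpec, spec_for

SIGMA2 = 0.16


@pytest.fixture(scope="session")
def display():
    return DisplaySpec()


@pytest.fixture(scope="session")
def small_spec():
    return spec_for("small_inducers")


@pytest.fixture(scope="session")
def large_spec():
    return spec_for("large_inducers")


def simulate_run(kind, condition, n_trials, seed, display,
                 store_fields=False, **observer_kw):
    spec = spec_for(condition)
    observer = make_observer(kind, spec, display, SIGMA2, **observer_kw)
    return run_staircase(observer, spec, display, n_trials, seed=seed,
                         sigma2=SIGMA2, store_fields=store_fields)


# -- heavyweight session runs shared by acceptance + property tests ---------

@pytest.fixture(scope="session")
def run_ideal_small_10k(display):
    return simulate_run("ideal", "small_inducers", 10_000, 101, display)


@pytest.fixture(scope="session")
def run_ideal_large_10k(display):
    return simulate_run("ideal", "large_inducers", 10_000, 102, display)


@pytest.fixture(scope="session")
def run_csf_small_10k(display):
    return simulate_run("csf_ideal", "small_inducers", 10_000, 103, display)


@pytest.fixture(scope="session")
def run_template_small_10k(display):
    return simulate_run("template", "small_inducers", 10_000, 104, display)


@pytest.fixture(scope="session")
def run_csf_large_10k(display):
    return simulate_run("csf_ideal", "large_inducers", 10_000, 107, display)


@pytest.fixture(scope="session")
def run_template_large_10k(display):
    return simulate_run("template", "large_inducers", 10_000, 108, display)


@pytest.fixture(scope="session")
def run_ideal_small_1k(display):
    return simulate_run("ideal", "small_inducers", 1_000, 108, display)


@pytest.fixture(scope="session")
def mini_archive(display):
    """600-trial ideal run with full noise fields stored."""
    return simulate_run("ideal", "small_inducers", 600, 106, display,
                        store_fields=True)


# -- synthetic psychometric sessions (no imaging) ---------------------------

def simulate_weibull_session(alpha, beta, n_trials, seed, gamma=0.5, lam=0.01,
                             start_level=None):
    """Staircase records from a direct Weibull responder (no rendering)."""
    rng = np.random.default_rng(seed)
    level = start_level if start_level is not None else 30.0 * alpha
    stair = StaircaseState(level=level)
    u = rng.random(n_trials)
    v = rng.random(n_trials)
    span = 1.0 - gamma - lam
    records = []
    for t in range(n_trials):
        e = stair.level
        p = gamma + span * (1.0 - np.exp(-((e / alpha) ** beta)))
        correct = bool(u[t] < p)
        present = bool(v[t] < 0.5)
        response = present if correct else not present
        records.append(TrialRecord(index=t, condition="small_inducers",
                                   present=present, energy=e, noise_ref=t,
                                   response=response, correct=correct))
        stair.update(correct)
    return records
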