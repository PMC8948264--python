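import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import rhythmlab as rl
from rhythmlab.simulate import BehaviorSimConfig, mouse_params

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ld_schedule():
    return rl.build_schedule("LD", days=14)


@pytest.fixture(scope="session")
def dd_schedule():
    return rl.build_schedule("DD", days=14)


@pytest.fixture(scope="session")
def chra_schedule():
    return rl.build_schedule("chronic_jetlag", days=28)


@pytest.fixture(scope="session")
def entrained_mouse(ld_schedule):
    """One mouse fully entrained to 12:12 LD."""
    cfg = BehaviorSimConfig(n_subjects=1, seed=21)
    return rl.simulate_activity(cfg, ld_schedule)[0]


@pytest.fixture(scope="session")
def dd_mouse_cohort(dd_schedule):
    """Five free-running mice, tau = 23.6 h, 14 days of DD."""
    cfg = BehaviorSimConfig(n_subjects=5, seed=22,
                            components=[(mouse_params(tau=23.6), 1.0)])
    return rl.simulate_activity(cfg, dd_schedule, return_truth=True)


def naive_chi_square_Q(counts, p_bins):
    """Double-loop folding oracle for the periodogram statistic."""
    x = np.asarray(counts, dtype=float)
    K = len(x) // p_bins
    n_used = K * p_bins
    xs = x[:n_used]
    m = xs.mean()
    col_means = []
    for h in range(p_bins):
        vals = [xs[k * p_bins + h] for k in range(K)]
        col_means.append(sum(vals) / K)
    num = sum((cm - m) ** 2 for cm in col_means)
    den = sum((v - m) ** 2 for v in xs)
    return K * n_used * num / den
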