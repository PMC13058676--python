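import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from drscreen import GeneratorConfig, generate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture(scope="session")
def study_cohort(default_config):
    """Synthetic cohort at the study's size and composition (n=1716)."""
    return generate_cohort(default_config)


@pytest.fixture(scope="session")
def large_cohort(default_config):
    """Large cohort (50k eyes) for convergence checks."""
    return generate_cohort(default_config, n_patients=25_000, seed=5)


def brute_force_roc(scores, labels, threshold):
    """Oracle: direct counting of the score > threshold rule."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    sens = float((s[y] > threshold).mean())
    spec = float((s[~y] <= threshold).mean())
    return sens, spec


def brute_force_best_j(scores, labels):
    """Oracle: max Youden J over every achievable operating point.

    J(t) is piecewise constant, changing only at observed score values, so
    scanning t over the distinct scores plus one value below the minimum
    enumerates every achievable (sens, spec) pair.
    """
    s = np.asarray(scores, dtype=float)
    cands = np.concatenate(([s.min() - 1.0], np.unique(s)))
    best = -2.0
    for t in cands:
        sens, spec = brute_force_roc(s, labels, t)
        best = max(best, sens + spec - 1.0)
    return best


def brute_force_auc(scores, labels):
    """Oracle: Mann–Whitney pair counting, P(pos > neg) + 0.5 P(tie)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    pos, neg = s[y], s[~y]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (pos.size * neg.size)
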