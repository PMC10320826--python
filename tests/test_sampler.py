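import numpy as np
import pytest

from metagaze.inference.diagnostics import ess_mean, max_split_rhat, split_rhat
from metagaze.inference.sampler import sample_nuts


def gaussian_target(mean, sd):
    mean = np.asarray(mean, float)
    var = np.asarray(sd, float) ** 2

    def logp_grad(theta):
        delta = theta - mean
        return -0.5 * float(delta @ (delta / var)), -delta / var

    return logp_grad


def test_nuts_recovers_gaussian_moments():
    """The sampler must reproduce the first two moments of a known
    anisotropic Gaussian."""
    mean = np.array([1.0, -2.0, 0.5, 0.0])
    sd = np.array([0.5, 3.0, 1.0, 0.1])
    rng = np.random.default_rng(0)
    draws, stats = sample_nuts(
        gaussian_target(mean, sd), np.zeros(4), n_tune=500, n_draws=2000, rng=rng
    )
    assert not stats.diverging.any()
    se = sd / np.sqrt(2000)
    assert np.all(np.abs(draws.mean(axis=0) - mean) < 8 * se)
    np.testing.assert_allclose(draws.std(axis=0), sd, rtol=0.15)


def test_nuts_seeded_determinism():
    target = gaussian_target([0.0], [1.0])
    d1, _ = sample_nuts(target, np.zeros(1), 100, 100, np.random.default_rng(5))
    d2, _ = sample_nuts(target, np.zeros(1), 100, 100, np.random.default_rng(5))
    np.testing.assert_array_equal(d1, d2)


def test_nuts_rejects_bad_start():
    def bad(theta):
        return -np.inf, np.zeros_like(theta)

    with pytest.raises(FloatingPointError):
        sample_nuts(bad, np.zeros(2), 10, 10, np.random.default_rng(0))


# -- diagnostics vs. independent textbook implementations ---------------------


def textbook_split_rhat(chains):
    """Direct implementation of the split potential-scale-reduction factor."""
    halves = []
    n = chains.shape[1] // 2
    for chain in chains:
        halves.append(chain[:n])
        halves.append(chain[n : 2 * n])
    halves = np.asarray(halves)
    m = len(halves)
    means = halves.mean(axis=1)
    variances = halves.var(axis=1, ddof=1)
    W = variances.mean()
    B = n * np.sum((means - means.mean()) ** 2) / (m - 1)
    var_plus = (n - 1) / n * W + B / n
    return np.sqrt(var_plus / W)


def textbook_ess(chains):
    """Geyer initial-monotone-sequence estimator, direct autocovariances."""
    n = chains.shape[1] // 2
    halves = []
    for chain in chains:
        halves.append(chain[:n])
        halves.append(chain[n : 2 * n])
    halves = np.asarray(halves, float)
    m = len(halves)
    acov = np.empty((m, n))
    for j, h in enumerate(halves):
        centered = h - h.mean()
        for lag in range(n):
            acov[j, lag] = np.sum(centered[: n - lag] * centered[lag:]) / n
    chain_var = acov[:, 0] * n / (n - 1)
    mean_var = chain_var.mean()
    var_plus = mean_var * (n - 1) / n + halves.mean(axis=1).var(ddof=1)
    rho = 1.0 - (mean_var - acov.mean(axis=0)) / var_plus
    rho[0] = 1.0
    tau = 1.0
    prev = np.inf
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        pair = min(pair, prev)
        prev = pair
        tau += 2 * pair
        t += 2
    return min(m * n / tau, m * n)


@pytest.fixture(scope="module")
def mock_chains():
    rng = np.random.default_rng(42)
    # AR(1) chains with distinct means to exercise both W and B terms
    chains = np.empty((2, 400))
    for c in range(2):
        x = 0.0
        for i in range(400):
            x = 0.7 * x + rng.standard_normal()
            chains[c, i] = x + 0.3 * c
    return chains


def test_split_rhat_matches_textbook(mock_chains):
    assert split_rhat(mock_chains) == pytest.approx(
        textbook_split_rhat(mock_chains), abs=1e-8
    )


def test_ess_matches_textbook(mock_chains):
    assert ess_mean(mock_chains) == pytest.approx(textbook_ess(mock_chains), abs=1e-8)


def test_split_rhat_detects_disagreeing_chains():
    rng = np.random.default_rng(1)
    good = rng.standard_normal((2, 500))
    bad = good.copy()
    bad[1] += 3.0
    assert split_rhat(good) < 1.05
    assert split_rhat(bad) > 1.5


def test_split_rhat_matches_arviz(mock_chains):
    import arviz as az

    theirs = float(az.rhat(mock_chains, method="split"))
    assert split_rhat(mock_chains) == pytest.approx(theirs, abs=1e-10)


def test_max_split_rhat_handles_vector_parameters(mock_chains):
    stacked = np.stack([mock_chains, mock_chains + 0.01], axis=-1)
    worst = max_split_rhat({"scalar": mock_chains, "vector": stacked})
    assert worst >= split_rhat(mock_chains)
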