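"""MCMC convergence diagnostics: split-R-hat and effective sample size.

Implemented directly from the standard definitions so the fitting code does
not depend on any one inference library's conventions; values are
cross-checkable against other implementations on the same draws.
"""

from __future__ import annotations

import numpy as np


def _split_chains(x: np.ndarray) -> np.ndarray:
    """Split each chain in half, dropping one draw from odd-length chains."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected draws with shape (chains, draws)")
    n = x.shape[1] // 2
    return np.concatenate([x[:, :n], x[:, n : 2 * n]], axis=0)


def split_rhat(x: np.ndarray) -> float:
    """Split-R-hat of one parameter from draws shaped (chains, draws).

    The potential scale reduction factor computed on half-chains:
    ``sqrt(((n-1)/n * W + B/n) / W)`` with within-chain variance ``W`` and
    between-chain variance ``B``.  Values near 1 indicate the half-chains
    agree in location and scale.
    """
    z = _split_chains(x)
    m, n = z.shape
    if n < 2:
        return np.nan
    chain_means = z.mean(axis=1)
    chain_vars = z.var(axis=1, ddof=1)
    w = chain_vars.mean()
    b = n * chain_means.var(ddof=1)
    if w == 0:
        return 1.0 if b == 0 else np.inf
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def _autocovariance(y: np.ndarray) -> np.ndarray:
    """Biased autocovariance function of a 1-d series (FFT-based)."""
    n = len(y)
    y = y - y.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(y, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    return acov


def ess_mean(x: np.ndarray) -> float:
    """Effective sample size for the posterior mean (Geyer's initial
    monotone positive sequence, combined over split chains)."""
    z = _split_chains(x)
    m, n = z.shape
    if n < 4:
        return np.nan
    acov = np.array([_autocovariance(z[j]) for j in range(m)])
    chain_var = acov[:, 0] * n / (n - 1.0)
    mean_var = chain_var.mean()
    var_plus = mean_var * (n - 1.0) / n + z.mean(axis=1).var(ddof=1)
    if var_plus == 0:
        return float(m * n)

    rho = np.ones(n)
    rho[1:] = 1.0 - (mean_var - acov[:, 1:].mean(axis=0)) / var_plus

    # Geyer: sum consecutive pairs while positive, enforce monotone decrease
    tau = 1.0
    prev_pair = np.inf
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        pair = min(pair, prev_pair)
        prev_pair = pair
        tau += 2.0 * pair
        t += 2
    ess = m * n / tau
    return float(min(ess, m * n))


def max_split_rhat(draws_by_param: dict[str, np.ndarray]) -> float:
    """Maximum split-R-hat over a dictionary of (chains, draws[, ...]) arrays."""
    worst = -np.inf
    for arr in draws_by_param.values():
        arr = np.asarray(arr)
        if arr.ndim == 2:
            worst = max(worst, split_rhat(arr))
        else:
            flat = arr.reshape(arr.shape[0], arr.shape[1], -1)
            for k in range(flat.shape[2]):
                worst = max(worst, split_rhat(flat[:, :, k]))
    return float(worst)
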