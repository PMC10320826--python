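"""Gradient-based MCMC: dynamic Hamiltonian Monte Carlo (no-U-turn).

A self-contained sampler for models exposing ``logp_grad(theta)``.  It
implements the dynamic-trajectory HMC scheme standard in modern Bayesian
software: multiplicative doubling of the leapfrog trajectory until a U-turn,
multinomial sampling of the proposal along the trajectory, dual-averaging
step-size adaptation to a target acceptance statistic, and diagonal
mass-matrix adaptation from warmup draws.  Divergences (energy errors above
a large threshold) terminate the doubling and are reported per draw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NutsStats", "sample_nuts"]

_DIVERGENCE_ENERGY = 1000.0


@dataclass
class NutsStats:
    """Per-draw sampler statistics for one chain."""

    lp: np.ndarray
    diverging: np.ndarray
    tree_depth: np.ndarray
    accept_rate: np.ndarray
    step_size: float


class _DualAveraging:
    """Nesterov dual averaging of log step size (standard constants)."""

    def __init__(self, eps0: float, target: float):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.log_eps = np.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.gamma = 0.05
        self.t0 = 10.0
        self.kappa = 0.75
        self.count = 0

    def update(self, accept_stat: float) -> float:
        self.count += 1
        m = self.count
        eta = 1.0 / (m + self.t0)
        self.h_bar = (1 - eta) * self.h_bar + eta * (self.target - accept_stat)
        self.log_eps = self.mu - np.sqrt(m) / self.gamma * self.h_bar
        w = m ** (-self.kappa)
        self.log_eps_bar = w * self.log_eps + (1 - w) * self.log_eps_bar
        return float(np.exp(self.log_eps))

    @property
    def adapted(self) -> float:
        return float(np.exp(self.log_eps_bar))


def _leapfrog(logp_grad, theta, r, eps, inv_mass, grad):
    r = r + 0.5 * eps * grad
    theta = theta + eps * inv_mass * r
    logp, grad_new = logp_grad(theta)
    r = r + 0.5 * eps * grad_new
    return theta, r, logp, grad_new


def _find_initial_step(logp_grad, theta0, inv_mass, rng):
    eps = 1.0
    logp0, grad0 = logp_grad(theta0)
    if not np.isfinite(logp0):
        raise FloatingPointError("log density not finite at the initial point")
    r0 = rng.standard_normal(len(theta0)) / np.sqrt(inv_mass)
    h0 = -logp0 + 0.5 * float(r0 * inv_mass @ r0)
    theta, r, logp, _ = _leapfrog(logp_grad, theta0, r0, eps, inv_mass, grad0)
    h = -logp + 0.5 * float(r * inv_mass @ r) if np.isfinite(logp) else np.inf
    direction = 1 if (h0 - h) > np.log(0.5) else -1
    for _ in range(50):
        eps *= 2.0**direction
        theta, r, logp, _ = _leapfrog(logp_grad, theta0, r0, eps, inv_mass, grad0)
        h = -logp + 0.5 * float(r * inv_mass @ r) if np.isfinite(logp) else np.inf
        crossed = (h0 - h) > np.log(0.5)
        if (direction == 1 and not crossed) or (direction == -1 and crossed):
            break
    return eps


class _Tree:
    __slots__ = (
        "theta_minus", "r_minus", "grad_minus",
        "theta_plus", "r_plus", "grad_plus",
        "theta_prop", "log_sum_weight", "n_leaves",
        "sum_accept", "diverging", "turning",
    )


def _is_turning(theta_minus, r_minus, theta_plus, r_plus, inv_mass):
    delta = theta_plus - theta_minus
    return (
        float(delta @ (inv_mass * r_minus)) < 0
        or float(delta @ (inv_mass * r_plus)) < 0
    )


def _build_tree(logp_grad, theta, r, grad, logp, direction, depth, eps, inv_mass, h0, rng):
    tree = _Tree()
    if depth == 0:
        theta1, r1, logp1, grad1 = _leapfrog(
            logp_grad, theta, r, direction * eps, inv_mass, grad
        )
        if np.isfinite(logp1):
            h1 = -logp1 + 0.5 * float(r1 * inv_mass @ r1)
        else:
            h1 = np.inf
        delta_h = h1 - h0
        tree.diverging = bool(delta_h > _DIVERGENCE_ENERGY or not np.isfinite(h1))
        tree.turning = False
        tree.theta_minus = tree.theta_plus = tree.theta_prop = theta1
        tree.r_minus = tree.r_plus = r1
        tree.grad_minus = tree.grad_plus = grad1
        tree.log_sum_weight = -delta_h if np.isfinite(delta_h) else -np.inf
        tree.n_leaves = 1
        tree.sum_accept = float(min(1.0, np.exp(-delta_h))) if np.isfinite(delta_h) else 0.0
        return tree

    first = _build_tree(logp_grad, theta, r, grad, logp, direction, depth - 1, eps, inv_mass, h0, rng)
    if first.diverging or first.turning:
        return first
    if direction == 1:
        theta_edge, r_edge, grad_edge = first.theta_plus, first.r_plus, first.grad_plus
    else:
        theta_edge, r_edge, grad_edge = first.theta_minus, first.r_minus, first.grad_minus
    second = _build_tree(
        logp_grad, theta_edge, r_edge, grad_edge, None, direction, depth - 1, eps, inv_mass, h0, rng
    )

    tree.diverging = second.diverging
    tree.n_leaves = first.n_leaves + second.n_leaves
    tree.sum_accept = first.sum_accept + second.sum_accept
    tree.log_sum_weight = np.logaddexp(first.log_sum_weight, second.log_sum_weight)
    if direction == 1:
        tree.theta_minus, tree.r_minus, tree.grad_minus = (
            first.theta_minus, first.r_minus, first.grad_minus,
        )
        tree.theta_plus, tree.r_plus, tree.grad_plus = (
            second.theta_plus, second.r_plus, second.grad_plus,
        )
    else:
        tree.theta_minus, tree.r_minus, tree.grad_minus = (
            second.theta_minus, second.r_minus, second.grad_minus,
        )
        tree.theta_plus, tree.r_plus, tree.grad_plus = (
            first.theta_plus, first.r_plus, first.grad_plus,
        )
    # multinomial (weight-proportional) choice between subtrees
    if second.log_sum_weight > -np.inf and np.log(rng.random()) < (
        second.log_sum_weight - tree.log_sum_weight
    ):
        tree.theta_prop = second.theta_prop
    else:
        tree.theta_prop = first.theta_prop
    tree.turning = second.turning or _is_turning(
        tree.theta_minus, tree.r_minus, tree.theta_plus, tree.r_plus, inv_mass
    )
    return tree


def _nuts_step(logp_grad, theta, logp, grad, eps, inv_mass, max_depth, rng):
    r0 = rng.standard_normal(len(theta)) / np.sqrt(inv_mass)
    h0 = -logp + 0.5 * float(r0 * inv_mass @ r0)
    theta_minus = theta_plus = theta
    r_minus = r_plus = r0
    grad_minus = grad_plus = grad
    theta_prop, logp_prop, grad_prop = theta, logp, grad
    log_sum_weight = 0.0
    sum_accept = 0.0
    n_leaves = 0
    diverging = False
    depth = 0
    while depth < max_depth:
        direction = 1 if rng.random() < 0.5 else -1
        if direction == 1:
            tree = _build_tree(
                logp_grad, theta_plus, r_plus, grad_plus, None, 1, depth, eps, inv_mass, h0, rng
            )
            theta_plus, r_plus, grad_plus = tree.theta_plus, tree.r_plus, tree.grad_plus
        else:
            tree = _build_tree(
                logp_grad, theta_minus, r_minus, grad_minus, None, -1, depth, eps, inv_mass, h0, rng
            )
            theta_minus, r_minus, grad_minus = tree.theta_minus, tree.r_minus, tree.grad_minus
        sum_accept += tree.sum_accept
        n_leaves += tree.n_leaves
        if tree.diverging:
            diverging = True
            break
        if tree.turning:
            break
        # biased progressive sampling toward the new subtree
        if np.log(rng.random()) < tree.log_sum_weight - log_sum_weight:
            theta_prop = tree.theta_prop
        log_sum_weight = np.logaddexp(log_sum_weight, tree.log_sum_weight)
        depth += 1
        if _is_turning(theta_minus, r_minus, theta_plus, r_plus, inv_mass):
            break
    logp_prop, grad_prop = logp_grad(theta_prop)
    accept_rate = sum_accept / max(n_leaves, 1)
    return theta_prop, logp_prop, grad_prop, depth, diverging, accept_rate


def sample_nuts(
    logp_grad,
    theta0: np.ndarray,
    n_tune: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.85,
    max_depth: int = 8,
) -> tuple[np.ndarray, NutsStats]:
    """Run one chain; returns draws ``(n_draws, dim)`` and statistics.

    Warmup schedule: the first 15% of tuning adapts only the step size; the
    middle 70% additionally accumulates draw variances used to set the
    diagonal mass matrix (updated twice, at 50% and 85% of tuning); the final
    15% re-adapts the step size under the final metric.  Warmup draws are
    discarded.
    """
    dim = len(theta0)
    inv_mass = np.ones(dim)
    theta = theta0.copy()
    logp, grad = logp_grad(theta)
    if not np.isfinite(logp):
        raise FloatingPointError("log density not finite at the initial point")

    eps = _find_initial_step(logp_grad, theta, inv_mass, rng)
    da = _DualAveraging(eps, target_accept)

    win_start = int(0.15 * n_tune)
    updates = {int(0.5 * n_tune), int(0.85 * n_tune)}
    welford_n = 0
    welford_mean = np.zeros(dim)
    welford_m2 = np.zeros(dim)

    for i in range(n_tune):
        theta, logp, grad, depth, div, acc = _nuts_step(
            logp_grad, theta, logp, grad, eps, inv_mass, max_depth, rng
        )
        eps = da.update(acc)
        if i >= win_start:
            welford_n += 1
            delta = theta - welford_mean
            welford_mean += delta / welford_n
            welford_m2 += delta * (theta - welford_mean)
        if i + 1 in updates and welford_n > 10:
            var = welford_m2 / (welford_n - 1)
            # regularize toward unit scale as in standard warmup schemes
            inv_mass = (welford_n / (welford_n + 5.0)) * var + (
                5.0 / (welford_n + 5.0)
            ) * 1e-3
            welford_n = 0
            welford_mean[:] = 0.0
            welford_m2[:] = 0.0
            eps = _find_initial_step(logp_grad, theta, inv_mass, rng)
            da = _DualAveraging(eps, target_accept)
    eps = da.adapted if n_tune > 0 else eps

    draws = np.empty((n_draws, dim))
    lp = np.empty(n_draws)
    diverging = np.zeros(n_draws, bool)
    tree_depth = np.zeros(n_draws, int)
    accept = np.empty(n_draws)
    for i in range(n_draws):
        theta, logp, grad, depth, div, acc = _nuts_step(
            logp_grad, theta, logp, grad, eps, inv_mass, max_depth, rng
        )
        draws[i] = theta
        lp[i] = logp
        diverging[i] = div
        tree_depth[i] = depth
        accept[i] = acc
    stats = NutsStats(
        lp=lp, diverging=diverging, tree_depth=tree_depth,
        accept_rate=accept, step_size=eps,
    )
    return draws, stats
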