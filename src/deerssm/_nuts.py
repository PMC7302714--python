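"""No-U-Turn sampler with diagonal mass-matrix and step-size adaptation.

A self-contained multinomial NUTS implementation for densities supplied as
``logp_grad(q) -> (float, ndarray)``.  Warmup follows the usual three-phase
scheme: an initial step-size-only buffer, a sequence of doubling windows in
which the diagonal inverse metric is estimated from the warmup draws, and a
terminal step-size buffer.  Step size is tuned by dual averaging towards a
target acceptance statistic.  Divergences (energy error > 1000) are counted
and reported, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

_MAX_DELTA_H = 1000.0

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]


@dataclass
class NutsDiagnostics:
    step_size: float
    divergences: int
    warmup_divergences: int
    mean_accept: float
    mean_treedepth: float
    inv_metric: np.ndarray = field(repr=False, default=None)


@dataclass
class _Tree:
    q_minus: np.ndarray
    p_minus: np.ndarray
    g_minus: np.ndarray
    lp_minus: float
    q_plus: np.ndarray
    p_plus: np.ndarray
    g_plus: np.ndarray
    lp_plus: float
    q_prop: np.ndarray
    lp_prop: float
    log_w: float
    sum_alpha: float
    n_alpha: int
    diverged: bool
    turning: bool


class _NutsKernel:
    def __init__(self, logp_grad: LogpGrad, inv_metric: np.ndarray):
        self.f = logp_grad
        self.inv_metric = inv_metric

    def kinetic(self, p: np.ndarray) -> float:
        # overflow here simply yields inf energy -> divergence; the sampler
        # runs inside one errstate block, so no warning spam
        return 0.5 * float(p @ (self.inv_metric * p))

    def leapfrog(self, q, p, grad, eps):
        p = p + 0.5 * eps * grad
        q = q + eps * self.inv_metric * p
        lp, grad = self.f(q)
        p = p + 0.5 * eps * grad
        return q, p, grad, lp

    def _turning(self, q_minus, q_plus, p_minus, p_plus) -> bool:
        dq = q_plus - q_minus
        return (
            float(dq @ (self.inv_metric * p_minus)) < 0.0
            or float(dq @ (self.inv_metric * p_plus)) < 0.0
        )

    def _leaf(self, q, p, grad, lp, v, eps, H0) -> _Tree:
        q1, p1, g1, lp1 = self.leapfrog(q, p, grad, v * eps)
        H1 = -lp1 + self.kinetic(p1) if np.isfinite(lp1) else np.inf
        dH = H0 - H1  # > 0 means the leaf is more probable than the start
        diverged = not np.isfinite(H1) or (-dH > _MAX_DELTA_H)
        alpha = 0.0 if diverged else float(min(1.0, np.exp(min(dH, 0.0))))
        log_w = -np.inf if diverged else dH
        return _Tree(q1, p1, g1, lp1, q1, p1, g1, lp1, q1, lp1,
                     log_w, alpha, 1, diverged, False)

    def build_tree(self, q, p, grad, lp, v, depth, eps, H0, rng) -> _Tree:
        if depth == 0:
            return self._leaf(q, p, grad, lp, v, eps, H0)
        first = self.build_tree(q, p, grad, lp, v, depth - 1, eps, H0, rng)
        if first.diverged or first.turning:
            return first
        if v > 0:
            second = self.build_tree(
                first.q_plus, first.p_plus, first.g_plus, first.lp_plus,
                v, depth - 1, eps, H0, rng,
            )
            first.q_plus, first.p_plus = second.q_plus, second.p_plus
            first.g_plus, first.lp_plus = second.g_plus, second.lp_plus
        else:
            second = self.build_tree(
                first.q_minus, first.p_minus, first.g_minus, first.lp_minus,
                v, depth - 1, eps, H0, rng,
            )
            first.q_minus, first.p_minus = second.q_minus, second.p_minus
            first.g_minus, first.lp_minus = second.g_minus, second.lp_minus
        first.sum_alpha += second.sum_alpha
        first.n_alpha += second.n_alpha
        if second.diverged or second.turning:
            # a stopped subtree is discarded wholesale: no proposal merge
            first.diverged = second.diverged
            first.turning = second.turning
            return first
        total = np.logaddexp(first.log_w, second.log_w)
        # multinomial sampling within the combined subtree
        if np.isfinite(second.log_w) and rng.random() < np.exp(second.log_w - total):
            first.q_prop, first.lp_prop = second.q_prop, second.lp_prop
        first.log_w = total
        first.turning = self._turning(
            first.q_minus, first.q_plus, first.p_minus, first.p_plus
        )
        return first


def _find_initial_step(kernel: _NutsKernel, q, lp, grad, rng) -> float:
    """Heuristic: double/halve until the one-step acceptance crosses 0.5."""
    eps = 1.0
    p0 = rng.standard_normal(q.shape) / np.sqrt(kernel.inv_metric)
    H0 = -lp + kernel.kinetic(p0)
    _, p1, _, lp1 = kernel.leapfrog(q, p0, grad, eps)
    H1 = -lp1 + kernel.kinetic(p1) if np.isfinite(lp1) else np.inf
    dH = H0 - H1
    direction = 1.0 if dH > np.log(0.5) else -1.0
    for _ in range(100):
        eps *= 2.0**direction
        _, p1, _, lp1 = kernel.leapfrog(q, p0, grad, eps)
        H1 = -lp1 + kernel.kinetic(p1) if np.isfinite(lp1) else np.inf
        dH = H0 - H1
        if direction > 0 and not dH > np.log(0.5):
            break
        if direction < 0 and not dH < np.log(0.5):
            break
    return max(eps, 1e-10)


def _adaptation_windows(n_warmup: int) -> list[tuple[int, int]]:
    """(start, end) iteration ranges of the metric-adaptation windows."""
    if n_warmup < 150:
        return []
    init_buf = max(25, int(0.15 * n_warmup))
    term_buf = max(25, int(0.10 * n_warmup))
    windows = []
    start, size = init_buf, 25
    while start < n_warmup - term_buf:
        end = min(start + size, n_warmup - term_buf)
        # absorb a final stub window into the previous one
        if n_warmup - term_buf - end < 25:
            end = n_warmup - term_buf
        windows.append((start, end))
        start, size = end, size * 2
    return windows


def nuts_sample(
    logp_grad: LogpGrad,
    q0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    max_treedepth: int = 10,
    inv_metric: np.ndarray | None = None,
    adapt_metric: bool = True,
) -> tuple[np.ndarray, NutsDiagnostics]:
    """Run one NUTS chain; returns ``(draws, diagnostics)``.

    ``draws`` has shape ``(n_draws, dim)``; warmup iterations are discarded.
    With ``adapt_metric=False`` the supplied ``inv_metric`` is kept fixed
    and warmup tunes the step size only.
    """
    with np.errstate(over="ignore", invalid="ignore"):
        return _nuts_sample_impl(
            logp_grad, q0, n_warmup, n_draws, rng, target_accept,
            max_treedepth, inv_metric, adapt_metric,
        )


def _nuts_sample_impl(
    logp_grad, q0, n_warmup, n_draws, rng, target_accept,
    max_treedepth, inv_metric, adapt_metric,
):
    q = np.ascontiguousarray(q0, dtype=float)
    dim = q.size
    if inv_metric is None:
        inv_metric = np.ones(dim)
    kernel = _NutsKernel(logp_grad, inv_metric.copy())
    lp, grad = logp_grad(q)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log density")

    eps = _find_initial_step(kernel, q, lp, grad, rng)
    # dual averaging state
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    da_count = 0

    windows = _adaptation_windows(n_warmup) if adapt_metric else []
    win_idx = 0
    welford_n = 0
    welford_mean = np.zeros(dim)
    welford_m2 = np.zeros(dim)

    draws = np.empty((n_draws, dim))
    divergences = warmup_div = 0
    accept_sum = 0.0
    depth_sum = 0
    n_total = n_warmup + n_draws

    for it in range(n_total):
        p0 = rng.standard_normal(dim) / np.sqrt(kernel.inv_metric)
        H0 = -lp + kernel.kinetic(p0)
        tree = _Tree(q, p0, grad, lp, q, p0, grad, lp, q, lp,
                     0.0, 0.0, 0, False, False)
        sum_alpha, n_alpha = 0.0, 0
        diverged = False
        depth = 0
        while depth < max_treedepth:
            v = 1 if rng.random() < 0.5 else -1
            if v > 0:
                sub = kernel.build_tree(
                    tree.q_plus, tree.p_plus, tree.g_plus, tree.lp_plus,
                    v, depth, eps, H0, rng,
                )
                tree.q_plus, tree.p_plus = sub.q_plus, sub.p_plus
                tree.g_plus, tree.lp_plus = sub.g_plus, sub.lp_plus
            else:
                sub = kernel.build_tree(
                    tree.q_minus, tree.p_minus, tree.g_minus, tree.lp_minus,
                    v, depth, eps, H0, rng,
                )
                tree.q_minus, tree.p_minus = sub.q_minus, sub.p_minus
                tree.g_minus, tree.lp_minus = sub.g_minus, sub.lp_minus
            sum_alpha += sub.sum_alpha
            n_alpha += sub.n_alpha
            if sub.diverged:
                diverged = True
                break
            if sub.turning:
                break
            # biased progressive sampling favouring the new subtree
            if np.isfinite(sub.log_w) and (
                sub.log_w >= tree.log_w
                or rng.random() < np.exp(sub.log_w - tree.log_w)
            ):
                tree.q_prop, tree.lp_prop = sub.q_prop, sub.lp_prop
            tree.log_w = np.logaddexp(tree.log_w, sub.log_w)
            if kernel._turning(
                tree.q_minus, tree.q_plus, tree.p_minus, tree.p_plus
            ):
                break
            depth += 1

        if not np.array_equal(tree.q_prop, q):
            q = tree.q_prop
            lp, grad = logp_grad(q)
        alpha_mean = sum_alpha / max(n_alpha, 1)

        if it < n_warmup:
            if diverged:
                warmup_div += 1
            # dual averaging update
            da_count += 1
            frac = 1.0 / (da_count + t0)
            h_bar = (1.0 - frac) * h_bar + frac * (target_accept - alpha_mean)
            log_eps = mu - np.sqrt(da_count) / gamma * h_bar
            w = da_count**-kappa
            log_eps_bar = w * log_eps + (1.0 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
            # metric adaptation
            if win_idx < len(windows):
                start, end = windows[win_idx]
                if start <= it < end:
                    welford_n += 1
                    delta = q - welford_mean
                    welford_mean += delta / welford_n
                    welford_m2 += delta * (q - welford_mean)
                if it == end - 1:
                    if welford_n > 4:
                        var = welford_m2 / (welford_n - 1)
                        n = welford_n
                        var = (n / (n + 5.0)) * var + (5.0 / (n + 5.0)) * 1e-3
                        kernel.inv_metric = np.maximum(var, 1e-10)
                    welford_n = 0
                    welford_mean[:] = 0.0
                    welford_m2[:] = 0.0
                    win_idx += 1
                    # restart step-size adaptation around the current value
                    eps = _find_initial_step(kernel, q, lp, grad, rng)
                    mu = np.log(10.0 * eps)
                    log_eps_bar, h_bar, da_count = 0.0, 0.0, 0
            if it == n_warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            if diverged:
                divergences += 1
            accept_sum += alpha_mean
            depth_sum += depth
            draws[it - n_warmup] = q

    diag = NutsDiagnostics(
        step_size=eps,
        divergences=divergences,
        warmup_divergences=warmup_div,
        mean_accept=accept_sum / max(n_draws, 1),
        mean_treedepth=depth_sum / max(n_draws, 1),
        inv_metric=kernel.inv_metric.copy(),
    )
    return draws, diag
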