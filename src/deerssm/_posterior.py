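"""Unconstrained parameterisation of the joint posterior for NUTS.

The sampler works on a real vector ``q`` holding:

* the structural coefficients hm, rho, b, a (unconstrained already);
* ``u_i = log(sigma_i)`` for the six scale parameters;
* logits of the observation rates R_A..R_E, bc, rD;
* the latent states NL, hl, dl, rsl *directly* (centred): the count data
  are strongly informative about these states, which is the regime where
  the centred parameterisation has the better geometry;
* standardised innovations ``z`` for the growth random walk ``rl`` only
  (non-centred): the walk's innovation scale sigma3 is small and weakly
  identified, so centring it would create a funnel.

``logp_grad`` returns the log density of ``q`` (the constrained-space
posterior plus the log Jacobian of the sigma / rate / rl transforms)
together with its exact gradient, derived analytically.  The gradient is
verified against finite differences, and the value against the centred
density plus Jacobian, in the test suite.  A numba translation of the same
computation (:mod:`deerssm._kernels`) is used when available; the NumPy
path below is the reference implementation.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, gammaln, xlogy

from .data import SurveyData
from .model import ModelConfig, ModelParams

try:
    from ._kernels import logp_grad_kernel as _compiled_kernel
except Exception:  # pragma: no cover - numba missing or compilation failure
    _compiled_kernel = None

_LOG_2PI = float(np.log(2.0 * np.pi))


def _reverse_cumsum(x: np.ndarray) -> np.ndarray:
    return x[::-1].cumsum()[::-1]


class _Layout:
    """Index layout of the unconstrained vector."""

    def __init__(self, M: int, T: int, W: int):
        self.M, self.T, self.W = M, T, W
        self.HM, self.RHO, self.B, self.A = 0, 1, 2, 3
        self.U = slice(4, 10)  # log sigma_1..6
        n_rates = M + 2
        self.RATES = slice(10, 10 + n_rates)  # logit R_m, bc, rD
        off = 10 + n_rates
        self.NL = slice(off, off + T)
        off += T
        self.ZRL = slice(off, off + T)
        off += T
        self.HL = slice(off, off + T - 1)
        off += T - 1
        self.DL = slice(off, off + W)
        off += W
        self.RSL = slice(off, off + T)
        off += T
        self.dim = off


class UnconstrainedPosterior:
    """Log density and gradient of the model posterior over a real vector."""

    def __init__(
        self,
        data: SurveyData,
        config: ModelConfig | None = None,
        engine: str = "auto",
    ):
        self.data = data
        self.config = config or ModelConfig()
        time = data.time
        self.T = time.T
        self.W = time.n_winters
        self.M = len(data.routes)
        self.layout = _Layout(self.M, self.T, self.W)
        self.dim = self.layout.dim

        self.widx = data.winter_index
        self.winter_mask = np.zeros(self.T, dtype=bool)
        self.winter_mask[self.widx] = True
        self.growth_mult = np.where(self.winter_mask, 2.0, 1.0)
        self.Sn = self.config.snow_series(data).astype(float)
        self.Ef = data.effort.astype(float)
        self.O = data.road_occasions.astype(float)
        self.road_mask = self.O > 0
        self.C = data.road_counts.astype(float)
        self.A_c = data.route_area_ratio.astype(float)
        self.H = data.harvest.astype(float)
        self.B_counts = data.block_counts.astype(float)
        self.A_b = data.block_area_ratio.astype(float)
        self.D = data.carcasses.astype(float)
        self.A_d = data.carcass_area_ratio.astype(float)
        # constant factorial terms of the enabled Poisson channels
        self._lgamma_const = 0.0
        if self.config.use_road:
            self._lgamma_const -= float(gammaln(self.C[self.road_mask] + 1).sum())
        if self.config.use_harvest:
            self._lgamma_const -= float(gammaln(self.H[1:] + 1).sum())
        if self.config.use_block:
            self._lgamma_const -= float(gammaln(self.B_counts + 1).sum())
        if self.config.use_carcass:
            self._lgamma_const -= float(gammaln(self.D + 1).sum())

        if engine not in ("auto", "numba", "numpy"):
            raise ValueError(f"unknown engine {engine!r}")
        self._use_kernel = (
            engine in ("auto", "numba") and _compiled_kernel is not None
        )
        if engine == "numba" and _compiled_kernel is None:
            raise RuntimeError("compiled kernel unavailable")
        cfg = self.config
        self._kernel_args = (
            self.T, self.W, self.M,
            self.widx.astype(np.int64), self.winter_mask,
            self.Ef, self.Sn,
            np.ascontiguousarray(self.O), np.ascontiguousarray(self.C),
            self.A_c, self.H, self.B_counts, self.A_b, self.D, self.A_d,
            cfg.use_road, cfg.use_harvest, cfg.use_block, cfg.use_carcass,
            float(cfg.nl1_prior_sd), float(cfg.rl1_prior_sd),
            float(cfg.rsl_init_sd) if cfg.rsl_init_sd is not None else -1.0,
            float(cfg.coef_prior_sd), float(cfg.sigma_prior_scale),
            self._lgamma_const,
        )

    # -- reconstruction -----------------------------------------------------

    def _rl(self, q: np.ndarray, sigma3: float) -> np.ndarray:
        z_rl = q[self.layout.ZRL]
        rl = np.empty(self.T)
        rl[0] = self.config.rl1_prior_sd * z_rl[0]
        rl[1:] = sigma3 * z_rl[1:]
        return np.cumsum(rl)

    def reconstruct(self, q: np.ndarray) -> ModelParams:
        """Map an unconstrained vector to constrained model parameters."""
        q = np.asarray(q, dtype=float)
        L = self.layout
        sigma = np.exp(q[L.U])
        rates = expit(q[L.RATES])
        return ModelParams(
            NL=q[L.NL].copy(), rl=self._rl(q, sigma[2]), hl=q[L.HL].copy(),
            dl=q[L.DL].copy(), rsl=q[L.RSL].copy(),
            hm=float(q[L.HM]), rho=float(q[L.RHO]),
            b=float(q[L.B]), a=float(q[L.A]),
            sigma=sigma, R=rates[: self.M],
            bc=float(rates[self.M]), rD=float(rates[self.M + 1]),
        )

    def unconstrain(self, params: ModelParams) -> np.ndarray:
        """Inverse of :meth:`reconstruct` (useful for tests and warm starts)."""
        L = self.layout
        q = np.empty(self.dim)
        q[L.HM], q[L.RHO] = params.hm, params.rho
        q[L.B], q[L.A] = params.b, params.a
        q[L.U] = np.log(params.sigma)
        rates = np.concatenate([params.R, [params.bc, params.rD]])
        q[L.RATES] = np.log(rates) - np.log1p(-rates)
        q[L.NL] = params.NL
        z = np.empty(self.T)
        z[0] = params.rl[0] / self.config.rl1_prior_sd
        z[1:] = np.diff(params.rl) / params.sigma[2]
        q[L.ZRL] = z
        q[L.HL] = params.hl
        q[L.DL] = params.dl
        q[L.RSL] = params.rsl
        return q

    def log_jacobian(self, q: np.ndarray) -> float:
        """log |d(constrained)/d(unconstrained)| of the sigma, rate and rl
        transforms (the other latent blocks are identity maps)."""
        L, cfg = self.layout, self.config
        q = np.asarray(q, dtype=float)
        u = q[L.U]
        rates = expit(q[L.RATES])
        return float(
            np.log(cfg.rl1_prior_sd) + (self.T - 1) * u[2]
            + np.sum(u)
            + np.sum(np.log(rates) + np.log1p(-rates))
        )

    # -- density and gradient ----------------------------------------------

    def logp(self, q: np.ndarray) -> float:
        return self.logp_grad(np.asarray(q, dtype=float))[0]

    def logp_grad(self, q: np.ndarray) -> tuple[float, np.ndarray]:
        if self._use_kernel:
            if not (isinstance(q, np.ndarray) and q.dtype == np.float64
                    and q.flags.c_contiguous):
                q = np.ascontiguousarray(q, dtype=float)
            return _compiled_kernel(q, *self._kernel_args)
        return self.logp_grad_numpy(q)

    def logp_grad_numpy(self, q: np.ndarray) -> tuple[float, np.ndarray]:
        q = np.asarray(q, dtype=float)
        L, cfg = self.layout, self.config
        T, W, M = self.T, self.W, self.M
        zeros = lambda: np.zeros(self.dim)  # noqa: E731
        with np.errstate(over="ignore", invalid="ignore"):
            sigma = np.exp(q[L.U])
            rates = expit(q[L.RATES])
            R, bc, rD = rates[:M], rates[M], rates[M + 1]
            hm, rho, b, a = q[:4]
            NL, hl, dl, rsl = q[L.NL], q[L.HL], q[L.DL], q[L.RSL]
            z_rl = q[L.ZRL]
            rl = self._rl(q, sigma[2])
            if NL.max() > 690.0:
                return -np.inf, zeros()
            N = np.exp(NL)
            h = expit(hl)
            d = expit(dl)
            rS = expit(rsl)
            s0 = cfg.rsl_init_sd if cfg.rsl_init_sd is not None else sigma[5]

            g = zeros()
            lp = 0.0

            # ---- priors
            lp += float(
                -0.5 * (NL[0] / cfg.nl1_prior_sd) ** 2
                - np.log(cfg.nl1_prior_sd) - 0.5 * _LOG_2PI
            )
            g[L.NL][0] += -NL[0] / cfg.nl1_prior_sd**2
            coefs = q[:4]
            lp += float(
                -0.5 * (coefs @ coefs) / cfg.coef_prior_sd**2
                - 4 * (np.log(cfg.coef_prior_sd) + 0.5 * _LOG_2PI)
            )
            g[:4] += -coefs / cfg.coef_prior_sd**2
            scale = cfg.sigma_prior_scale
            u = q[L.U]
            lp += float(np.sum(
                np.log(2.0 / np.pi) - np.log(scale)
                - np.log1p((sigma / scale) ** 2) + u
            ))
            g[L.U] += 1.0 - 2.0 * sigma**2 / (scale**2 + sigma**2)
            lp += float(np.sum(np.log(rates) + np.log1p(-rates)))
            g[L.RATES] += 1.0 - 2.0 * rates
            lp += float(-0.5 * (z_rl @ z_rl) - 0.5 * T * _LOG_2PI)
            g[L.ZRL] -= z_rl

            # ---- process terms (centred NL)
            log1mh = -np.logaddexp(0.0, hl)
            log1md = -np.logaddexp(0.0, dl)
            step_sd = np.where(self.winter_mask[1:], sigma[1], sigma[0])
            mu = NL[:-1] + self.growth_mult[1:] * rl[1:] + log1mh
            mu[self.widx - 1] += log1md
            resid = (NL[1:] - mu) / step_sd
            lp += float(np.sum(-0.5 * resid**2 - np.log(step_sd)
                               - 0.5 * _LOG_2PI))
            e = resid / step_sd  # d logp / d mu
            g[L.NL][1:] += -e
            g[L.NL][:-1] += e
            reg = ~self.winter_mask[1:]
            g[L.U][0] += float(np.sum(resid[reg] ** 2 - 1.0))
            g[L.U][1] += float(np.sum(resid[~reg] ** 2 - 1.0))
            g_rl = np.zeros(T)
            g_rl[1:] = e * self.growth_mult[1:]
            g[L.HL] += -e * h
            g[L.DL] += -e[self.widx - 1] * d

            # ---- rl random walk backprop (non-centred cumulative sum)
            rbar = _reverse_cumsum(g_rl)
            g[L.ZRL][0] += rbar[0] * cfg.rl1_prior_sd
            g[L.ZRL][1:] += rbar[1:] * sigma[2]
            g[L.U][2] += sigma[2] * float(rbar[1:] @ z_rl[1:])

            # ---- hunting submodel
            fh = (hl - (hm + rho * self.Ef[1:])) / sigma[3]
            lp += float(np.sum(-0.5 * fh**2 - np.log(sigma[3]) - 0.5 * _LOG_2PI))
            g[L.HL] += -fh / sigma[3]
            g[L.HM] += float(np.sum(fh)) / sigma[3]
            g[L.RHO] += float(fh @ self.Ef[1:]) / sigma[3]
            g[L.U][3] += float(np.sum(fh**2 - 1.0))

            # ---- winter mortality submodel
            fd = (dl - (b + a * self.Sn)) / sigma[4]
            lp += float(np.sum(-0.5 * fd**2 - np.log(sigma[4]) - 0.5 * _LOG_2PI))
            g[L.DL] += -fd / sigma[4]
            g[L.B] += float(np.sum(fd)) / sigma[4]
            g[L.A] += float(fd @ self.Sn) / sigma[4]
            g[L.U][4] += float(np.sum(fd**2 - 1.0))

            # ---- seasonal observability: init prior + sum-to-noise recursion
            lp += float(np.sum(-0.5 * (rsl[:3] / s0) ** 2 - np.log(s0)
                               - 0.5 * _LOG_2PI))
            g[L.RSL][:3] += -rsl[:3] / s0**2
            if cfg.rsl_init_sd is None:
                g[L.U][5] += float(np.sum((rsl[:3] / s0) ** 2 - 1.0))
            S = rsl[3:] + rsl[2:-1] + rsl[1:-2] + rsl[:-3]
            lp += float(np.sum(-0.5 * (S / sigma[5]) ** 2 - np.log(sigma[5])
                               - 0.5 * _LOG_2PI))
            w_res = S / sigma[5] ** 2
            gS = np.zeros(T)
            for k in range(4):  # rsl_j enters windows j..j+3
                gS[k : k + T - 3] += -w_res
            g[L.RSL] += gS
            g[L.U][5] += float(np.sum((S / sigma[5]) ** 2 - 1.0))

            # ---- observation channels
            if cfg.use_road:
                mu_r = N[:, None] * R[None, :] * rS[:, None] * self.O \
                    * self.A_c[None, :]
                mu_r = np.where(self.road_mask, mu_r, 0.0)
                if np.any((mu_r < 1e-12) & (self.C > 0) & self.road_mask):
                    return -np.inf, zeros()
                lp += float(np.sum(
                    xlogy(self.C[self.road_mask], mu_r[self.road_mask])
                    - mu_r[self.road_mask]
                ))
                res_r = np.where(self.road_mask, self.C - mu_r, 0.0)
                g[L.NL] += res_r.sum(axis=1)
                g[L.RSL] += res_r.sum(axis=1) * (1.0 - rS)
                g[L.RATES][:M] += res_r.sum(axis=0) * (1.0 - R)
            if cfg.use_harvest:
                lam = N[1:] * h
                if np.any((lam < 1e-12) & (self.H[1:] > 0)):
                    return -np.inf, zeros()
                lp += float(np.sum(xlogy(self.H[1:], lam) - lam))
                res_h = self.H[1:] - lam
                g[L.NL][1:] += res_h
                g[L.HL] += res_h * (1.0 - h)
            if cfg.use_block:
                theta = N[self.widx] * bc * self.A_b
                if np.any((theta < 1e-12) & (self.B_counts > 0)):
                    return -np.inf, zeros()
                lp += float(np.sum(xlogy(self.B_counts, theta) - theta))
                res_b = self.B_counts - theta
                g[L.NL][self.widx] += res_b
                g[L.RATES][M] += res_b.sum() * (1.0 - bc)
            if cfg.use_carcass:
                eta = N[self.widx] * d * rD * self.A_d
                if np.any((eta < 1e-12) & (self.D > 0)):
                    return -np.inf, zeros()
                lp += float(np.sum(xlogy(self.D, eta) - eta))
                res_d = self.D - eta
                g[L.NL][self.widx] += res_d
                g[L.DL] += res_d * (1.0 - d)
                g[L.RATES][M + 1] += res_d.sum() * (1.0 - rD)
            lp += self._lgamma_const

            if not (np.isfinite(lp) and np.all(np.isfinite(g))):
                return -np.inf, zeros()
            return float(lp), g

    # -- initial points ------------------------------------------------------

    def initial_point(self, rng: np.random.Generator, scale: float = 0.1) -> np.ndarray:
        """A random starting point with finite density.

        Latent abundances start near ``NL = 5`` (a few hundred animals),
        mortality/hunting logits near -3; everything else near zero.
        Redraws (shrinking the jitter) until the log density is finite.
        """
        L = self.layout
        base = np.zeros(self.dim)
        base[L.NL] = 5.0
        base[L.HL] = -3.0
        base[L.DL] = -2.0
        base[L.HM] = -3.0
        base[L.B] = -2.0
        for attempt in range(100):
            shrink = 0.5 ** (attempt // 10)
            q = base + scale * shrink * rng.standard_normal(self.dim)
            if np.isfinite(self.logp(q)):
                return q
        raise RuntimeError("could not find a finite starting point")

    def hessian_inv_metric(self, q: np.ndarray, h: float = 1e-4) -> np.ndarray:
        """Diagonal inverse metric from the local curvature at ``q``.

        Central finite differences of the analytic gradient give the
        diagonal of the negative Hessian; its inverse (floored away from
        zero and infinity) seeds the sampler's mass matrix, which matters
        because coordinate scales span several orders of magnitude.
        """
        q = np.asarray(q, dtype=float)
        diag = np.empty(self.dim)
        for i in range(self.dim):
            qp, qm = q.copy(), q.copy()
            qp[i] += h
            qm[i] -= h
            gp, gm = self.logp_grad(qp)[1], self.logp_grad(qm)[1]
            diag[i] = -(gp[i] - gm[i]) / (2.0 * h)
        diag = np.clip(diag, 1e-8, 1e8)
        return 1.0 / diag

    def map_point(self, rng: np.random.Generator, maxiter: int = 1000) -> np.ndarray:
        """Posterior mode (in the unconstrained space) found by L-BFGS.

        Used to initialise chains: starting near the mode shortens warmup
        considerably for this high-dimensional latent model.
        """
        from scipy.optimize import minimize

        def neg(qv):
            lp, gr = self.logp_grad(qv)
            if not np.isfinite(lp):
                return 1e12, np.zeros_like(qv)
            return -lp, -gr

        best = None
        for _ in range(3):
            res = minimize(
                neg, self.initial_point(rng), jac=True, method="L-BFGS-B",
                options={"maxiter": maxiter},
            )
            if best is None or res.fun < best.fun:
                best = res
        return np.asarray(best.x, dtype=float)
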