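"""Negative-binomial mixed-effects regression via the Laplace approximation.

Count model for regional c-Fos cell numbers::

    y_i ~ NegBin(mean μ_i, size k),   var = μ + μ²/k
    log μ_i = x_i'β + offset_i + u_litter(i) [+ v_subject(i)]
    u_l ~ N(0, σ_litter²),  v_s ~ N(0, σ_subject²)  (subjects nested in litters)

The marginal likelihood is approximated by Laplace integration of the random
effects, block-by-block over litters; β, log k and the log random-effect SDs
are then maximized with a quasi-Newton optimizer.  With a single aggregated
observation per subject (the per-region model) the subject intercept is not
identifiable from NB overdispersion and is omitted.

Inference on the treatment term is by likelihood-ratio chi-square with 1 df,
comparing fits with and without the treatment column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

__all__ = ["NBMMResult", "FitError", "fit_nb_mixed", "lr_test"]

ETA_CLIP = 30.0
LOG_SIGMA_MIN, LOG_SIGMA_MAX = -6.0, 3.0
LOG_K_MIN, LOG_K_MAX = -8.0, 12.0


class FitError(RuntimeError):
    """Raised when the marginal-likelihood optimization fails to converge."""


@dataclass
class NBMMResult:
    beta: np.ndarray
    beta_names: list[str]
    k: float
    sigma_litter: float
    sigma_subject: float | None
    loglik: float
    n_obs: int
    converged: bool

    def coef(self, name: str) -> float:
        return float(self.beta[self.beta_names.index(name)])


def _nb_logpmf(y: np.ndarray, mu: np.ndarray, k: float) -> np.ndarray:
    return (
        special.gammaln(y + k)
        - special.gammaln(k)
        - special.gammaln(y + 1.0)
        + k * (np.log(k) - np.log(k + mu))
        + y * (np.log(np.maximum(mu, 1e-300)) - np.log(k + mu))
    )


def _poisson_irls(y, X, offset, n_iter=15):
    """Cheap Poisson-GLM starting values for β."""
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(max(np.mean(y / np.exp(offset)), 1e-8))
    for _ in range(n_iter):
        eta = np.clip(X @ beta + offset, -ETA_CLIP, ETA_CLIP)
        mu = np.exp(eta)
        z = (eta - offset) + (y - mu) / np.maximum(mu, 1e-8)
        W = mu
        xtw = X.T * W
        try:
            new = np.linalg.solve(xtw @ X + 1e-8 * np.eye(X.shape[1]), xtw @ z)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(new)):
            break
        if np.max(np.abs(new - beta)) < 1e-10:
            beta = new
            break
        beta = new
    return beta


class _LaplaceNLL:
    """Negative Laplace marginal log-likelihood as a function of θ.

    θ = [β..., log k, log σ_litter (, log σ_subject)].  Random-effect modes
    are warm-started between calls.
    """

    def __init__(self, y, X, offset, litter_codes, subject_codes=None):
        order = np.argsort(litter_codes, kind="stable")
        self.y = np.asarray(y, dtype=float)[order]
        self.X = np.asarray(X, dtype=float)[order]
        self.offset = np.asarray(offset, dtype=float)[order]
        self.lit = np.asarray(litter_codes)[order]
        self.n_lit = int(self.lit.max()) + 1
        self.p = self.X.shape[1]
        self.with_subject = subject_codes is not None
        if self.with_subject:
            self.sub = np.asarray(subject_codes)[order]
            self.n_sub = int(self.sub.max()) + 1
            # map each subject to its litter (nested design)
            self.sub_lit = np.zeros(self.n_sub, dtype=int)
            self.sub_lit[self.sub] = self.lit
            self._v = np.zeros(self.n_sub)
        self._u = np.zeros(self.n_lit)

    @property
    def n_params(self) -> int:
        return self.p + 2 + (1 if self.with_subject else 0)

    def _eta_fixed(self, beta):
        return self.X @ beta + self.offset

    def __call__(self, theta: np.ndarray) -> float:
        beta = theta[: self.p]
        k = float(np.exp(np.clip(theta[self.p], LOG_K_MIN, LOG_K_MAX)))
        sig_l2 = float(np.exp(2 * np.clip(theta[self.p + 1], LOG_SIGMA_MIN, LOG_SIGMA_MAX)))
        eta0 = self._eta_fixed(beta)
        if self.with_subject:
            sig_s2 = float(
                np.exp(2 * np.clip(theta[self.p + 2], LOG_SIGMA_MIN, LOG_SIGMA_MAX))
            )
            return -self._loglik_subject(eta0, k, sig_l2, sig_s2)
        return -self._loglik_scalar(eta0, k, sig_l2)

    # -- one scalar random intercept per litter (vectorized Newton) ----------

    def _loglik_scalar(self, eta0, k, sig2) -> float:
        y, lit = self.y, self.lit
        u = self._u.copy()
        for _ in range(50):
            eta = np.clip(eta0 + u[lit], -ETA_CLIP, ETA_CLIP)
            mu = np.exp(eta)
            w1 = k * (y - mu) / (k + mu)
            w2 = k * mu * (k + y) / (k + mu) ** 2
            g = np.bincount(lit, w1, self.n_lit) - u / sig2
            h = np.bincount(lit, w2, self.n_lit) + 1.0 / sig2
            step = g / h
            u = u + step
            if np.max(np.abs(step)) < 1e-11:
                break
        self._u = u
        eta = np.clip(eta0 + u[lit], -ETA_CLIP, ETA_CLIP)
        mu = np.exp(eta)
        w2 = k * mu * (k + y) / (k + mu) ** 2
        h = np.bincount(lit, w2, self.n_lit) + 1.0 / sig2
        ll = (
            _nb_logpmf(y, mu, k).sum()
            - 0.5 * np.sum(u**2) / sig2
            - 0.5 * self.n_lit * np.log(sig2)
            - 0.5 * np.sum(np.log(h))
        )
        return float(ll)

    # -- litter + nested subject intercepts (small dense blocks) -------------

    def _loglik_subject(self, eta0, k, sig_l2, sig_s2) -> float:
        y, lit, sub = self.y, self.lit, self.sub
        u, v = self._u.copy(), self._v.copy()
        for _ in range(80):
            eta = np.clip(eta0 + u[lit] + v[sub], -ETA_CLIP, ETA_CLIP)
            mu = np.exp(eta)
            w1 = k * (y - mu) / (k + mu)
            w2 = k * mu * (k + y) / (k + mu) ** 2
            gu = np.bincount(lit, w1, self.n_lit) - u / sig_l2
            gv = np.bincount(sub, w1, self.n_sub) - v / sig_s2
            # block-diagonal Newton: per litter, solve the (1+m_l) system
            huu = np.bincount(lit, w2, self.n_lit) + 1.0 / sig_l2
            hvv = np.bincount(sub, w2, self.n_sub) + 1.0 / sig_s2
            huv = np.bincount(sub, w2, self.n_sub)  # coupling u_l — v_s, s in l
            max_step = 0.0
            for l in range(self.n_lit):
                subs = np.flatnonzero(self.sub_lit == l)
                m = len(subs)
                H = np.empty((1 + m, 1 + m))
                H[0, 0] = huu[l]
                H[0, 1:] = H[1:, 0] = huv[subs]
                H[1:, 1:] = np.diag(hvv[subs])
                g = np.concatenate(([gu[l]], gv[subs]))
                step = np.linalg.solve(H, g)
                u[l] += step[0]
                v[subs] += step[1:]
                max_step = max(max_step, float(np.max(np.abs(step))))
            if max_step < 1e-11:
                break
        self._u, self._v = u, v
        eta = np.clip(eta0 + u[lit] + v[sub], -ETA_CLIP, ETA_CLIP)
        mu = np.exp(eta)
        w2 = k * mu * (k + y) / (k + mu) ** 2
        huu = np.bincount(lit, w2, self.n_lit) + 1.0 / sig_l2
        hvv = np.bincount(sub, w2, self.n_sub) + 1.0 / sig_s2
        huv = np.bincount(sub, w2, self.n_sub)
        logdet_h = 0.0
        for l in range(self.n_lit):
            subs = np.flatnonzero(self.sub_lit == l)
            H = np.empty((1 + len(subs), 1 + len(subs)))
            H[0, 0] = huu[l]
            H[0, 1:] = H[1:, 0] = huv[subs]
            H[1:, 1:] = np.diag(hvv[subs])
            sign, ld = np.linalg.slogdet(H)
            logdet_h += ld
        ll = (
            _nb_logpmf(y, mu, k).sum()
            - 0.5 * np.sum(u**2) / sig_l2
            - 0.5 * self.n_lit * np.log(sig_l2)
            - 0.5 * np.sum(v**2) / sig_s2
            - 0.5 * self.n_sub * np.log(sig_s2)
            - 0.5 * logdet_h
        )
        return float(ll)


def fit_nb_mixed(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    litter_codes: np.ndarray,
    subject_codes: np.ndarray | None = None,
    beta_names: list[str] | None = None,
    label: str = "",
) -> NBMMResult:
    """Maximize the Laplace-approximated NB mixed-model likelihood."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    offset = np.asarray(offset, dtype=float)
    nll = _LaplaceNLL(y, X, offset, litter_codes, subject_codes)

    beta0 = _poisson_irls(y, X, offset)
    # moment start for k from Poisson-fit residual overdispersion
    eta = np.clip(X @ beta0 + offset, -ETA_CLIP, ETA_CLIP)
    mu = np.exp(eta)
    excess = float(np.sum((y - mu) ** 2 - mu) / max(np.sum(mu**2), 1e-12))
    k0 = float(np.clip(1.0 / excess if excess > 1e-4 else 100.0, 0.2, 500.0))
    theta0 = np.concatenate(
        [beta0, [np.log(k0), np.log(0.2)] + ([np.log(0.2)] if subject_codes is not None else [])]
    )
    bounds = (
        [(-25.0, 25.0)] * X.shape[1]
        + [(LOG_K_MIN, LOG_K_MAX)]
        + [(LOG_SIGMA_MIN, LOG_SIGMA_MAX)]
        * (2 if subject_codes is not None else 1)
    )
    res = optimize.minimize(
        nll, theta0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    if not res.success:
        res2 = optimize.minimize(
            nll, res.x, method="Nelder-Mead",
            options={"maxiter": 4000, "fatol": 1e-10, "xatol": 1e-8},
        )
        if res2.fun <= res.fun:
            res = res2
    if not np.all(np.isfinite(res.x)) or not np.isfinite(res.fun):
        raise FitError(f"NB mixed-model fit failed{': ' + label if label else ''}")
    p = X.shape[1]
    names = beta_names or [f"b{i}" for i in range(p)]
    return NBMMResult(
        beta=res.x[:p],
        beta_names=list(names),
        k=float(np.exp(res.x[p])),
        sigma_litter=float(np.exp(res.x[p + 1])),
        sigma_subject=(
            float(np.exp(res.x[p + 2])) if subject_codes is not None else None
        ),
        loglik=float(-res.fun),
        n_obs=len(y),
        converged=bool(res.success or np.isfinite(res.fun)),
    )


def lr_test(full: NBMMResult, reduced: NBMMResult, df: int = 1) -> tuple[float, float]:
    """Likelihood-ratio chi-square for nested Laplace fits."""
    chi2 = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    return chi2, float(stats.chi2.sf(chi2, df))
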