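"""Beta-mixture modelling of the VAF distribution.

The residue ("lees") of low-VAF artifact calls that survive the read-level
filters forms its own mode in the variant-allele-frequency distribution.  The
VAF sample is modelled as a finite mixture of beta distributions fitted by
EM; the number of components k is selected over k = 1..10 by the ICL-BIC
criterion (BIC plus twice the classification entropy).  A component whose
mean falls in a configured low-frequency band (default 1-3%) is treated as
the error distribution, and candidate calls are tested against it with a
beta-binomial upper-tail test on (alt count | depth): calls consistent with
the error component are removed.

The M-step maximises the weighted beta log-likelihood per component with a
safeguarded Newton update (step-halving until the EM objective does not
decrease), so the observed-data log-likelihood is monotone non-decreasing
across iterations.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
from scipy.special import betaln, digamma, polygamma
from scipy.stats import betabinom

_EPS = 1e-10


@dataclasses.dataclass
class BetaMixtureModel:
    k: int
    weights: np.ndarray
    alphas: np.ndarray
    betas: np.ndarray
    icl_bic: float
    loglik: float
    error_component: Optional[int]
    loglik_history: list = dataclasses.field(default_factory=list)

    def means(self) -> np.ndarray:
        return self.alphas / (self.alphas + self.betas)


def _log_beta_pdf(x: np.ndarray, a: float, b: float) -> np.ndarray:
    return (a - 1) * np.log(x) + (b - 1) * np.log1p(-x) - betaln(a, b)


def _component_loglik(x: np.ndarray, w: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """(n, k) matrix of log(w_j) + log Beta(x_i; a_j, b_j)."""
    return np.log(w)[None, :] + np.stack([_log_beta_pdf(x, a[j], b[j]) for j in range(len(w))], axis=1)


def _loglik(x: np.ndarray, w: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    m = _component_loglik(x, w, a, b)
    mx = m.max(axis=1)
    return float((mx + np.log(np.exp(m - mx[:, None]).sum(axis=1))).sum())


def _weighted_beta_mle(
    x: np.ndarray, w: np.ndarray, a0: float, b0: float, n_newton: int = 5
) -> tuple[float, float]:
    """Improve the weighted beta log-likelihood from (a0, b0).

    Damped Newton in (log a, log b); each step is halved until the weighted
    objective does not decrease, so the overall EM update is a valid GEM step.
    """
    W = w.sum()
    if W <= 0:
        return a0, b0
    slx = float((w * np.log(x)).sum())
    sl1x = float((w * np.log1p(-x)).sum())

    def obj(a: float, b: float) -> float:
        return (a - 1) * slx + (b - 1) * sl1x - W * betaln(a, b)

    a, b = a0, b0
    f = obj(a, b)
    for _ in range(n_newton):
        dga, dgb, dgab = digamma(a), digamma(b), digamma(a + b)
        ga = slx - W * (dga - dgab)
        gb = sl1x - W * (dgb - dgab)
        t_a, t_b, t_ab = polygamma(1, a), polygamma(1, b), polygamma(1, a + b)
        # Hessian of obj wrt (a, b)
        haa = -W * (t_a - t_ab)
        hbb = -W * (t_b - t_ab)
        hab = W * t_ab
        det = haa * hbb - hab * hab
        if not np.isfinite(det) or abs(det) < 1e-300:
            break
        da = -(hbb * ga - hab * gb) / det
        db = -(haa * gb - hab * ga) / det
        step = 1.0
        improved = False
        for _ in range(20):
            na = a + step * da
            nb = b + step * db
            if na > _EPS and nb > _EPS and na < 1e6 and nb < 1e6:
                nf = obj(na, nb)
                if nf >= f - 1e-12:
                    a, b, f = na, nb, nf
                    improved = True
                    break
            step *= 0.5
        if not improved or max(abs(ga), abs(gb)) < 1e-8:
            break
    return a, b


def _moment_init(x: np.ndarray, k: int, rng: np.random.Generator, jitter: float) -> tuple:
    """Quantile-block method-of-moments initialisation."""
    xs = np.sort(x)
    blocks = np.array_split(xs, k)
    a = np.empty(k)
    b = np.empty(k)
    w = np.empty(k)
    for j, blk in enumerate(blocks):
        m = float(np.clip(blk.mean(), 1e-4, 1 - 1e-4))
        v = float(blk.var())
        v = max(v, 1e-6)
        common = max(m * (1 - m) / v - 1, 0.5)
        if jitter:
            common *= float(np.exp(rng.normal(0, jitter)))
            m = float(np.clip(m * np.exp(rng.normal(0, jitter / 2)), 1e-4, 1 - 1e-4))
        a[j] = max(m * common, 1e-3)
        b[j] = max((1 - m) * common, 1e-3)
        w[j] = len(blk) / len(x)
    w = np.maximum(w, 1e-6)
    return w / w.sum(), a, b


def _fit_k(
    x: np.ndarray,
    k: int,
    rng: np.random.Generator,
    restarts: int,
    max_iter: int,
    tol: float,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray, list]:
    best = None
    for rep in range(restarts):
        w, a, b = _moment_init(x, k, rng, jitter=0.0 if rep == 0 else 0.5)
        history = []
        ll = _loglik(x, w, a, b)
        for _ in range(max_iter):
            history.append(ll)
            m = _component_loglik(x, w, a, b)
            mx = m.max(axis=1, keepdims=True)
            tau = np.exp(m - mx)
            tau /= tau.sum(axis=1, keepdims=True)
            w = tau.mean(axis=0)
            w = np.maximum(w, 1e-12)
            w /= w.sum()
            for j in range(k):
                a[j], b[j] = _weighted_beta_mle(x, tau[:, j], a[j], b[j])
            new_ll = _loglik(x, w, a, b)
            if new_ll - ll < tol:
                ll = max(new_ll, ll)
                break
            ll = new_ll
        history.append(ll)
        if best is None or ll > best[0] + 1e-9:
            best = (ll, w.copy(), a.copy(), b.copy(), history)
    return best


def icl_bic(loglik: float, tau: np.ndarray, n_params: int, n: int) -> float:
    """ICL-BIC = -2 logL + n_params log n + 2 * classification entropy."""
    ent = float(-(tau * np.log(np.maximum(tau, 1e-300))).sum())
    return -2.0 * loglik + n_params * np.log(n) + 2.0 * ent


def fit_beta_mixture(
    vafs: Sequence[float],
    k_max: int = 10,
    restarts: int = 5,
    seed: int = 0,
    min_obs: int = 20,
    error_band: tuple[float, float] = (0.01, 0.03),
    max_iter: int = 300,
    tol: float = 1e-8,
    early_stop: int = 2,
) -> Optional[BetaMixtureModel]:
    """Fit beta mixtures for k = 1..k_max and select by minimal ICL-BIC.

    Returns None (the lees filter is then disabled) when fewer than
    ``min_obs`` observations are available.  Ties in ICL-BIC are broken
    toward smaller k.  The search over k stops early once ICL-BIC has not
    improved for ``early_stop`` consecutive k (the criterion is convex-ish
    in practice; larger k only add penalty).  ``error_component`` is the
    index of the component whose mean lies inside ``error_band``, preferring
    the lowest mean.
    """
    x = np.clip(np.asarray(vafs, dtype=float), 1e-6, 1 - 1e-6)
    n = len(x)
    if n < min_obs:
        return None
    rng = np.random.default_rng(seed)
    best_model: Optional[BetaMixtureModel] = None
    since_best = 0
    for k in range(1, min(k_max, max(1, n // 2)) + 1):
        ll, w, a, b, history = _fit_k(x, k, rng, restarts, max_iter, tol)
        m = _component_loglik(x, w, a, b)
        mx = m.max(axis=1, keepdims=True)
        tau = np.exp(m - mx)
        tau /= tau.sum(axis=1, keepdims=True)
        crit = icl_bic(ll, tau, n_params=3 * k - 1, n=n)
        improved = best_model is None or crit < best_model.icl_bic - 1e-9
        if improved:
            since_best = 0
            means = a / (a + b)
            in_band = np.nonzero((means >= error_band[0]) & (means <= error_band[1]))[0]
            err = int(in_band[np.argmin(means[in_band])]) if in_band.size else None
            best_model = BetaMixtureModel(
                k=k, weights=w, alphas=a, betas=b, icl_bic=crit, loglik=ll,
                error_component=err, loglik_history=history,
            )
        else:
            since_best += 1
            if early_stop and since_best >= early_stop:
                break
    return best_model


def beta_binomial_sf(k: int, n: int, a: float, b: float) -> float:
    """Upper tail P(X >= k) for X ~ BetaBinomial(n, a, b)."""
    if k <= 0:
        return 1.0
    if k > n:
        return 0.0
    return float(betabinom.sf(k - 1, n, a, b))


__all__ = ["BetaMixtureModel", "fit_beta_mixture", "icl_bic", "beta_binomial_sf"]
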