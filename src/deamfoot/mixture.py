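"""Deaminase-attributable fraction via a two-normal mixture decomposition.

The distribution of weights (percent matching scores) of mutated sites is
decomposed into two normal components by EM; the mixing weight of the
component with the larger mean is taken as the fraction of mutations
attributable to the deaminase. The estimate is reported only when a binned
chi-square goodness-of-fit test does not reject the mixture (p >= 0.05).

Weights live on [0, 100] but the components are untruncated normals; a
boundary-pileup warning flags distributions whose last bin dwarfs its
neighbor, the known failure mode of this decomposition at the scale's edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import logsumexp

GOF_ALPHA = 0.05
SIGMA_FLOOR = 0.5  # weight units
N_FREE_PARAMS = 5  # mu1, sigma1, mu2, sigma2, pi


@dataclass
class MixtureFit:
    """Two-normal mixture fit of a weight distribution (mu2 > mu1)."""

    mu1: float
    sigma1: float
    pi1: float
    mu2: float
    sigma2: float
    pi2: float
    loglik: float
    n_iter: int
    converged: bool
    collapsed: bool = False  # sigma hit the floor even after a restart
    gof_chi2: float | None = None
    gof_df: int | None = None
    gof_p: float | None = None
    fraction: float | None = None
    boundary_pileup: bool = False
    loglik_path: list[float] = field(default_factory=list, repr=False)


def _em(
    x: np.ndarray,
    mu: np.ndarray,
    sigma: np.ndarray,
    pi: np.ndarray,
    tol: float,
    max_iter: int,
    sigma_floor: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, int, bool, bool, list[float]]:
    prev = -np.inf
    path: list[float] = []
    collapsed = False
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        logp = np.log(pi)[:, None] + stats.norm.logpdf(x[None, :], mu[:, None], sigma[:, None])
        ll = float(logsumexp(logp, axis=0).sum())
        path.append(ll)
        resp = np.exp(logp - logsumexp(logp, axis=0)[None, :])  # (2, n)
        nk = resp.sum(axis=1)
        pi = nk / len(x)
        mu = (resp @ x) / nk
        var = (resp @ (x**2)) / nk - mu**2
        sigma = np.sqrt(np.maximum(var, 0.0))
        if np.any(sigma < sigma_floor):
            collapsed = True
            sigma = np.maximum(sigma, sigma_floor)
        # convergence on the mean per-observation log-likelihood gain
        if (ll - prev) / len(x) < tol and n_iter > 1:
            converged = True
            break
        prev = ll
    return mu, sigma, pi, path[-1], n_iter, converged, collapsed, path


def fit_two_normal_mixture(
    weights,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 1000,
    sigma_floor: float = SIGMA_FLOOR,
    n_min: int = 100,
) -> MixtureFit:
    """EM maximum-likelihood fit of a two-normal mixture to weights in [0, 100].

    Initialization: component means at the 25th/75th percentiles, equal mixing
    weights, pooled variance. Convergence when the log-likelihood gain drops
    below ``tol``. If a component's sigma collapses below ``sigma_floor`` the
    fit restarts once from a perturbed initialization; a second collapse is
    flagged and the fraction is withheld downstream.
    """
    x = np.asarray(weights, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if len(x) < n_min:
        raise ValueError(f"need at least {n_min} weights, got {len(x)}")
    rng = np.random.default_rng(seed)
    mu0 = np.percentile(x, [25.0, 75.0])
    if mu0[1] - mu0[0] < 1e-9:
        mu0 = mu0 + np.array([-1.0, 1.0])
    sd = max(float(x.std()), sigma_floor)
    init = (mu0.copy(), np.array([sd, sd]), np.array([0.5, 0.5]))

    mu, sigma, pi, ll, n_iter, converged, collapsed, path = _em(
        x, *init, tol=tol, max_iter=max_iter, sigma_floor=sigma_floor
    )
    if collapsed:
        # one restart from a perturbed initialization
        jitter = rng.normal(0.0, 0.1 * sd, size=2)
        init2 = (mu0 + jitter, np.array([sd, sd]), np.array([0.5, 0.5]))
        mu, sigma, pi, ll, n_iter, converged, collapsed, path = _em(
            x, *init2, tol=tol, max_iter=max_iter, sigma_floor=sigma_floor
        )
    order = np.argsort(mu)
    mu, sigma, pi = mu[order], sigma[order], pi[order]
    return MixtureFit(
        mu1=float(mu[0]),
        sigma1=float(sigma[0]),
        pi1=float(pi[0]),
        mu2=float(mu[1]),
        sigma2=float(sigma[1]),
        pi2=float(pi[1]),
        loglik=ll,
        n_iter=n_iter,
        converged=converged,
        collapsed=collapsed,
        loglik_path=path,
    )


def _bin_counts(weights: np.ndarray, binwidth: float) -> tuple[np.ndarray, np.ndarray]:
    edges = np.arange(0.0, 100.0 + binwidth, binwidth)
    observed, _ = np.histogram(weights, bins=edges)  # last bin closed at 100
    return observed.astype(float), edges


def mixture_cdf(fit: MixtureFit, x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return fit.pi1 * stats.norm.cdf(x, fit.mu1, fit.sigma1) + fit.pi2 * stats.norm.cdf(
        x, fit.mu2, fit.sigma2
    )


def goodness_of_fit(
    fit: MixtureFit, weights, binwidth: float = 10.0
) -> tuple[float, int, float]:
    """Binned chi-square test of the fitted mixture against the observed weights.

    Bins are [0,10), [10,20), ..., [90,100]; expected counts come from the
    mixture CDF with the tails folded into the end bins. Adjacent bins are
    pooled until every expected count is >= 5. df = pooled bins - 1 - 5 (five
    free parameters), floored at 1.
    """
    x = np.asarray(weights, dtype=float)
    observed, edges = _bin_counts(x, binwidth)
    cdf = mixture_cdf(fit, edges)
    probs = np.diff(cdf)
    probs[0] += cdf[0]  # fold lower tail
    probs[-1] += 1.0 - cdf[-1]  # fold upper tail
    expected = probs * len(x)

    obs_pooled, exp_pooled = _pool_bins(observed, expected, min_expected=5.0)
    if len(obs_pooled) < 3:
        raise ValueError("distribution too narrow for a goodness-of-fit test")
    chi2 = float(((obs_pooled - exp_pooled) ** 2 / exp_pooled).sum())
    df = max(len(obs_pooled) - 1 - N_FREE_PARAMS, 1)
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def _pool_bins(
    observed: np.ndarray, expected: np.ndarray, min_expected: float
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy left-to-right pooling of adjacent bins until expected >= threshold."""
    obs_out: list[float] = []
    exp_out: list[float] = []
    acc_o = acc_e = 0.0
    for o, e in zip(observed, expected):
        acc_o += o
        acc_e += e
        if acc_e >= min_expected:
            obs_out.append(acc_o)
            exp_out.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0 and exp_out:
        obs_out[-1] += acc_o
        exp_out[-1] += acc_e
    elif acc_e > 0:
        obs_out.append(acc_o)
        exp_out.append(acc_e)
    return np.array(obs_out), np.array(exp_out)


def binned_distribution(weights, binwidth: float = 10.0):
    """Observed bin counts on the standard decade bins (for plotting/export)."""
    import pandas as pd

    observed, edges = _bin_counts(np.asarray(weights, dtype=float), binwidth)
    return pd.DataFrame(
        {
            "bin": np.arange(len(observed)),
            "low": edges[:-1],
            "high": edges[1:],
            "count": observed.astype(int),
        }
    )


def estimate_fraction(
    weights,
    seed: int = 0,
    gof_alpha: float = GOF_ALPHA,
    binwidth: float = 10.0,
    return_fit: bool = False,
    **fit_kwargs,
):
    """Deaminase-attributable fraction: pi of the higher-mean component, gated.

    Returns the fraction (float) when the fit converged and the chi-square
    goodness-of-fit test does not reject it (p >= ``gof_alpha``); otherwise
    None. With ``return_fit=True`` the full :class:`MixtureFit` is returned
    instead, carrying the GOF fields and the boundary-pileup flag.
    """
    x = np.asarray(weights, dtype=float)
    fit = fit_two_normal_mixture(x, seed=seed, **fit_kwargs)
    observed, _ = _bin_counts(x, binwidth)
    if len(observed) >= 2 and observed[-1] > 2.0 * observed[-2]:
        fit.boundary_pileup = True
        warnings.warn(
            "boundary pileup: last weight bin exceeds its neighbor by >2x; "
            "the mixture decomposition may be distorted at the scale boundary",
            stacklevel=2,
        )
    try:
        fit.gof_chi2, fit.gof_df, fit.gof_p = goodness_of_fit(fit, x, binwidth)
    except ValueError:
        fit.gof_chi2 = fit.gof_df = fit.gof_p = None
    usable = (
        fit.converged
        and not fit.collapsed
        and fit.gof_p is not None
        and fit.gof_p >= gof_alpha
    )
    fit.fraction = float(fit.pi2) if usable else None
    return fit if return_fit else fit.fraction
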