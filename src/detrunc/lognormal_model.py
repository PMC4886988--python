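"""The three-parameter (shifted) lognormal noise model.

Background counts in an annulus are modeled as draws from a lognormal
distribution with location μ and scale σ, shifted by τ so that its
support is (τ, ∞) and negative counts are admitted:

    f(x) = exp(−(ln(x−τ) − μ)² / (2σ²)) / ((x−τ) σ √(2π)),  x > τ
    F(x) = Φ((ln(x−τ) − μ) / σ)

Integer ADU counts are obtained by half-integer binning of the
continuous model, P(I) = F(I+½) − F(I−½), which telescopes exactly to
one over all integers.  An observed zero is censored — it may be a true
zero or any clamped negative count — so it contributes the whole left
tail F(½) to the likelihood:

    ℓ(μ, σ, τ) = N₀ ln F(½) + Σ_{I=1}^{I_max} N_I ln[F(I+½) − F(I−½)]
                 + N_over ln[1 − F(I_max+½)]

assuming pixels within the annulus are independent and identically
distributed.  The N_over pixels above the fit range I_max are treated
as right-censored — the mirror image of the left-censored zero bin —
which reduces to the plain per-bin sum when nothing overflows and keeps
the estimator consistent when the fit range clips a Bragg tail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .histogram import PixelHistogram


@dataclass(frozen=True)
class LognormalParams:
    """Parameters (μ, σ, τ) of the shifted lognormal model.

    ``mu`` is the location on the log-ADU scale, ``sigma > 0`` the
    scale, and ``tau`` (ADU, possibly negative) translates the support
    to (τ, ∞).
    """

    mu: float
    sigma: float
    tau: float = 0.0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")

    @property
    def mode(self) -> float:
        """Most probable count, τ + exp(μ − σ²)."""
        return self.tau + np.exp(self.mu - self.sigma**2)

    @property
    def mean(self) -> float:
        """E[X] = τ + exp(μ + σ²/2)."""
        return self.tau + np.exp(self.mu + self.sigma**2 / 2.0)

    @property
    def variance(self) -> float:
        """Var[X] = (exp(σ²) − 1) exp(2μ + σ²)."""
        return (np.exp(self.sigma**2) - 1.0) * np.exp(2.0 * self.mu + self.sigma**2)

    def frozen(self) -> stats.rv_continuous:
        """The scipy frozen distribution (s=σ, loc=τ, scale=e^μ)."""
        return stats.lognorm(s=self.sigma, loc=self.tau, scale=np.exp(self.mu))


def pdf(x, p: LognormalParams) -> np.ndarray:
    """Density of the shifted lognormal at ``x`` (0 for x ≤ τ)."""
    return p.frozen().pdf(x)


def cdf(x, p: LognormalParams) -> np.ndarray:
    """Cumulative distribution F(x) (0 for x ≤ τ)."""
    return p.frozen().cdf(x)


def discrete_prob(i, p: LognormalParams) -> np.ndarray:
    """Probability of integer count ``i``: F(i+½) − F(i−½)."""
    i = np.asarray(i, dtype=float)
    dist = p.frozen()
    return dist.cdf(i + 0.5) - dist.cdf(i - 0.5)


def prob_nonpositive(p: LognormalParams) -> float:
    """Model mass of all integer counts I ≤ 0, i.e. F(½)."""
    return float(p.frozen().cdf(0.5))


def _edge_cdf_and_grad(x: np.ndarray, p: LognormalParams):
    """F(x) and its partial derivatives w.r.t. (μ, σ, τ) at edges ``x``.

    With z = (ln(x−τ) − μ)/σ and φ the standard normal density:
        ∂F/∂μ = −φ(z)/σ,  ∂F/∂σ = −z φ(z)/σ,  ∂F/∂τ = −φ(z)/((x−τ) σ).
    All are 0 where x ≤ τ.
    """
    x = np.asarray(x, dtype=float)
    inside = x > p.tau
    f = np.zeros_like(x)
    d_mu = np.zeros_like(x)
    d_sigma = np.zeros_like(x)
    d_tau = np.zeros_like(x)
    if np.any(inside):
        gap = x[inside] - p.tau
        z = (np.log(gap) - p.mu) / p.sigma
        phi = np.exp(-0.5 * z**2) / np.sqrt(2.0 * np.pi)
        f[inside] = stats.norm.cdf(z)
        d_mu[inside] = -phi / p.sigma
        d_sigma[inside] = -z * phi / p.sigma
        d_tau[inside] = -phi / (gap * p.sigma)
    return f, np.stack([d_mu, d_sigma, d_tau])


def log_likelihood_grad(
    h: PixelHistogram, p: LognormalParams, conditional: bool = False
) -> tuple[float, np.ndarray]:
    """Censored log-likelihood and its gradient w.r.t. (μ, σ, τ).

    Returns (−∞, zeros) for infeasible parameters, matching
    :func:`log_likelihood`.
    """
    edges_x = np.arange(h.i_max + 1) + 0.5
    f, df = _edge_cdf_and_grad(edges_x, p)
    probs = np.diff(f)
    dprobs = np.diff(df, axis=1)
    n_pos = h.counts[1:]
    occupied = n_pos > 0

    ll = 0.0
    grad = np.zeros(3)
    if h.n_zero > 0:
        if f[0] <= 0.0:
            return -np.inf, np.zeros(3)
        ll += h.n_zero * np.log(f[0])
        grad += h.n_zero * df[:, 0] / f[0]
    if np.any(occupied):
        if np.any(probs[occupied] <= 0.0):
            return -np.inf, np.zeros(3)
        ll += float(np.sum(n_pos[occupied] * np.log(probs[occupied])))
        grad += (dprobs[:, occupied] * (n_pos[occupied] / probs[occupied])).sum(axis=1)
    if conditional:
        if f[-1] <= 0.0:
            return -np.inf, np.zeros(3)
        n_in_range = h.n_total - h.n_overflow
        ll -= n_in_range * np.log(f[-1])
        grad -= n_in_range * df[:, -1] / f[-1]
    elif h.n_overflow > 0:
        survival = 1.0 - f[-1]
        if survival <= 0.0:
            return -np.inf, np.zeros(3)
        ll += h.n_overflow * np.log(survival)
        grad -= h.n_overflow * df[:, -1] / survival
    return float(ll), grad


def log_likelihood(
    h: PixelHistogram, p: LognormalParams, conditional: bool = False
) -> float:
    """Censored log-likelihood of histogram ``h`` under ``p``.

    Returns −∞ for parameters that assign zero probability to any
    occupied bin (infeasible rather than erroneous).  With
    ``conditional=True`` the likelihood is renormalized to the mass
    below ``i_max + ½``, i.e. conditioned on the pixel falling inside
    the fit range; the default is the plain unconditional sum.
    """
    dist = p.frozen()
    edges = dist.cdf(np.arange(h.i_max + 1) + 0.5)  # F(½), F(1½), …
    probs = np.diff(edges)  # P(1) … P(i_max)
    n_pos = h.counts[1:]
    occupied = n_pos > 0

    with np.errstate(divide="ignore"):
        ll = 0.0
        if h.n_zero > 0:
            if edges[0] <= 0.0:
                return -np.inf
            ll += h.n_zero * np.log(edges[0])
        if np.any(occupied):
            if np.any(probs[occupied] <= 0.0):
                return -np.inf
            ll += float(np.sum(n_pos[occupied] * np.log(probs[occupied])))
        if conditional:
            total = edges[-1]
            if total <= 0.0:
                return -np.inf
            n_in_range = h.n_total - h.n_overflow
            ll -= n_in_range * np.log(total)
        elif h.n_overflow > 0:
            survival = 1.0 - edges[-1]
            if survival <= 0.0:
                return -np.inf
            ll += h.n_overflow * np.log(survival)
    return float(ll)
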