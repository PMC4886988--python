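"""Censored maximum-likelihood fitting of the shifted lognormal.

Each annulus is fitted independently with an unconstrained
quasi-Newton (BFGS) search over the reparameterized space

    θ = (μ, ln σ, t),   τ = U − exp(t),   U = min(½, I_min_pos − ½),

so that σ > 0 and every occupied bin keeps positive probability by
construction (the support bound τ < U guarantees mass below the first
occupied bin and below the censoring threshold when zeros are present).
The start point is a method-of-moments estimate from the positive bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .exceptions import InsufficientDataError
from .histogram import PixelHistogram
from .lognormal_model import (
    LognormalParams,
    log_likelihood,
    log_likelihood_grad,
    prob_nonpositive,
)

GRAD_TOL = 1e-6
REL_LL_TOL = 1e-10
MAX_ITER = 500
_MAX_RESTARTS = 3
# keep exp(t) finite and tau strictly inside the support bound
_MIN_GAP = 1e-6


@dataclass(frozen=True)
class FitResult:
    """Outcome of one per-annulus maximum-likelihood fit."""

    params: LognormalParams
    loglik: float
    converged: bool
    n_iter: int
    rmsd: float
    annulus: int


def _support_bound(h: PixelHistogram) -> float:
    """Upper bound U on τ so every observed bin has positive mass."""
    occupied = np.nonzero(h.counts[1:])[0]
    i_min_pos = occupied[0] + 1 if occupied.size else h.i_max
    bound = i_min_pos - 0.5
    if h.n_zero > 0:
        bound = min(0.5, bound)
    return bound


def initialize_params(h: PixelHistogram) -> LognormalParams:
    """Method-of-moments starting point from the positive bins.

    τ₀ is set to minus the weighted standard deviation of the positive
    bin values; μ₀ and σ₀ follow from the weighted mean and variance of
    ln(I − τ₀).  Requires at least 3 distinct occupied positive bins.
    """
    values = np.nonzero(h.counts[1:])[0] + 1.0
    weights = h.counts[1:][h.counts[1:] > 0].astype(float)
    if len(values) < 3:
        raise InsufficientDataError(
            f"annulus {h.annulus}: {len(values)} distinct positive bins, need >= 3"
        )
    mean = np.average(values, weights=weights)
    std = np.sqrt(np.average((values - mean) ** 2, weights=weights))
    tau0 = -std
    bound = _support_bound(h)
    tau0 = min(tau0, bound - _MIN_GAP)
    logs = np.log(values - tau0)
    mu0 = float(np.average(logs, weights=weights))
    var0 = float(np.average((logs - mu0) ** 2, weights=weights))
    sigma0 = float(np.sqrt(max(var0, 1e-8)))
    return LognormalParams(mu=mu0, sigma=sigma0, tau=float(tau0))


def fit_quality_rmsd(h: PixelHistogram, p: LognormalParams) -> float:
    """Root-mean-square deviation between N_I and model counts.

    Computed over I ∈ [0, i_max]; the predicted zero bin is the whole
    censored mass n_total · F(½).
    """
    dist = p.frozen()
    edges = dist.cdf(np.arange(h.i_max + 1) + 0.5)
    predicted = np.empty(h.i_max + 1)
    predicted[0] = h.n_total * edges[0]
    predicted[1:] = h.n_total * np.diff(edges)
    return float(np.sqrt(np.mean((h.counts - predicted) ** 2)))


def fit_annulus(
    h: PixelHistogram,
    init: LognormalParams | None = None,
    conditional: bool = False,
) -> FitResult:
    """Maximize the censored log-likelihood of one annulus histogram.

    Deterministic given ``(h, init)``.  Non-convergence within the
    iteration cap is reported through ``converged=False``, never
    silently.
    """
    if init is None:
        init = initialize_params(h)
    bound = _support_bound(h)

    def pack(p: LognormalParams) -> np.ndarray:
        gap = max(bound - p.tau, _MIN_GAP)
        return np.array([p.mu, np.log(p.sigma), np.log(gap)])

    def unpack(theta: np.ndarray) -> LognormalParams:
        mu, log_sigma, t = theta
        return LognormalParams(
            mu=float(mu),
            sigma=float(np.exp(np.clip(log_sigma, -30.0, 30.0))),
            tau=float(bound - np.exp(np.clip(t, -30.0, 30.0))),
        )

    def objective(theta: np.ndarray) -> tuple[float, np.ndarray]:
        p = unpack(theta)
        ll, grad = log_likelihood_grad(h, p, conditional=conditional)
        if not np.isfinite(ll):
            return 1e300, np.zeros(3)
        # chain rule through (μ, ln σ, t) with τ = U − exp(t)
        grad_theta = np.array(
            [grad[0], grad[1] * p.sigma, grad[2] * (p.tau - bound)]
        )
        return -ll, -grad_theta

    x0 = pack(init)
    n_iter = 0
    res = None
    for _ in range(1 + _MAX_RESTARTS):
        prev_fun = None if res is None else res.fun
        res = optimize.minimize(
            objective,
            x0,
            jac=True,
            method="BFGS",
            options={"gtol": GRAD_TOL, "maxiter": MAX_ITER},
        )
        n_iter += int(res.nit)
        x0 = res.x
        if res.success:
            break
        # BFGS may stop on line-search precision loss at the optimum:
        # accept a gradient small relative to the likelihood scale, or a
        # stalled restart (relative objective change below tolerance)
        if np.linalg.norm(res.jac, np.inf) <= GRAD_TOL * max(1.0, abs(res.fun)):
            break
        if prev_fun is not None and abs(prev_fun - res.fun) <= REL_LL_TOL * max(
            1.0, abs(res.fun)
        ):
            break
    converged = bool(res.success) or np.linalg.norm(res.jac, np.inf) <= GRAD_TOL * max(
        1.0, abs(res.fun)
    )
    params = unpack(res.x)
    loglik = log_likelihood(h, params, conditional=conditional)
    return FitResult(
        params=params,
        loglik=float(loglik),
        converged=converged,
        n_iter=n_iter,
        rmsd=fit_quality_rmsd(h, params),
        annulus=h.annulus,
    )


def write_fit_report(results: list[FitResult], path) -> None:
    """Tab-separated per-annulus fit report."""
    with open(path, "w") as fh:
        fh.write("annulus\tmu\tsigma\ttau\tloglik\trmsd\tconverged\tn_iter\n")
        for r in results:
            fh.write(
                f"{r.annulus}\t{r.params.mu:.6g}\t{r.params.sigma:.6g}\t"
                f"{r.params.tau:.6g}\t{r.loglik:.8g}\t{r.rmsd:.6g}\t"
                f"{int(r.converged)}\t{r.n_iter}\n"
            )


def plot_fit(h: PixelHistogram, p: LognormalParams, path) -> None:
    """Diagnostic plot of the histogram with the fitted curve."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .lognormal_model import discrete_prob

    i = h.values()
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(i, h.counts, width=1.0, color="0.7", label="observed")
    model = h.n_total * discrete_prob(i, p)
    model[0] = h.n_total * prob_nonpositive(p)
    ax.plot(i, model, "k-", label="fitted lognormal")
    ax.set_xlabel("pixel value (ADU)")
    ax.set_ylabel("count")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
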