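"""Beta-binomial background-noise model and statistical filtering.

Background junction noise is modeled hierarchically:

    pi ~ Beta(alpha, beta)
    X | pi ~ Binomial(n, pi)

where X is the number of breakpoint-supporting reads among the n = s + w
reads informative for a junction. Candidates with heteroplasmy below the
noise threshold (default 1%) are treated as artifacts and used to fit
(alpha, beta) by the method of moments on their observed frequencies:

    c = mu (1 - mu) / sigma^2 - 1,   alpha = mu c,   beta = (1 - mu) c

with mu the mean and sigma^2 the (unbiased) variance of the noise
frequencies. Under-dispersed noise (c <= 0) falls back to a plain
binomial with p = mu. Surviving candidates get an upper-tail p-value,
Benjamini-Hochberg correction across the tested set, and pass when
q < fdr (strict).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import betaln, gammaln
from scipy.stats import binom

from .caller import DeletionCandidate

DEFAULT_NOISE_THRESHOLD = 0.01
DEFAULT_MIN_NOISE = 10
DEFAULT_FDR = 0.05
DEFAULT_MIN_SUPPORT = 2
DEFAULT_MIN_WILDTYPE = 1


class ModelFitError(ValueError):
    """Raised when the background model cannot be fitted."""


@dataclass(frozen=True)
class ErrorModel:
    """Fitted beta-binomial background model (or binomial fallback)."""

    alpha: float
    beta: float
    mu: float
    sigma2: float
    n_noise: int
    fallback: bool = False

    def tail_p(self, x: int, n: int) -> float:
        return betabin_tail_p(x, n, self)


def select_noise_set(
    candidates: Iterable[DeletionCandidate],
    threshold: float = DEFAULT_NOISE_THRESHOLD,
) -> list[DeletionCandidate]:
    """Candidates with heteroplasmy strictly below ``threshold``."""
    return [c for c in candidates if c.f < threshold]


def fit_beta_binomial_mom(
    noise_frequencies: Sequence[float],
    min_noise: int = DEFAULT_MIN_NOISE,
) -> ErrorModel:
    """Method-of-moments fit of Beta(alpha, beta) to noise frequencies."""
    freqs = np.asarray(list(noise_frequencies), dtype=float)
    if freqs.size < min_noise:
        raise ModelFitError(
            f"only {freqs.size} noise variants (< {min_noise}); "
            "cannot fit background model"
        )
    mu = float(freqs.mean())
    sigma2 = float(freqs.var(ddof=1))
    if sigma2 <= 0:
        raise ModelFitError("zero variance in noise frequencies")
    c = mu * (1.0 - mu) / sigma2 - 1.0
    if c <= 0:
        # under-dispersed: beta-binomial shapes would be non-positive
        return ErrorModel(
            alpha=float("nan"), beta=float("nan"), mu=mu, sigma2=sigma2,
            n_noise=int(freqs.size), fallback=True,
        )
    return ErrorModel(
        alpha=mu * c, beta=(1.0 - mu) * c, mu=mu, sigma2=sigma2,
        n_noise=int(freqs.size), fallback=False,
    )


def fit_from_candidates(
    candidates: Iterable[DeletionCandidate],
    threshold: float = DEFAULT_NOISE_THRESHOLD,
    min_noise: int = DEFAULT_MIN_NOISE,
) -> ErrorModel:
    noise = select_noise_set(candidates, threshold)
    return fit_beta_binomial_mom([c.f for c in noise], min_noise=min_noise)


def betabin_logpmf(x: np.ndarray, n: int, alpha: float, beta: float) -> np.ndarray:
    """Log pmf of the beta-binomial via log-gamma (numerically stable)."""
    x = np.asarray(x, dtype=float)
    return (
        gammaln(n + 1) - gammaln(x + 1) - gammaln(n - x + 1)
        + betaln(x + alpha, n - x + beta) - betaln(alpha, beta)
    )


def betabin_tail_p(x: int, n: int, model: ErrorModel) -> float:
    """Upper tail P(X >= x) under the fitted background model.

    Sums the shorter side of the pmf; under the binomial fallback the
    binomial survival function with p = mu is used.
    """
    if n < 1 or not 0 <= x <= n:
        raise ValueError(f"invalid tail arguments x={x}, n={n}")
    if x == 0:
        return 1.0
    if model.fallback:
        return float(binom.sf(x - 1, n, model.mu))
    a, b = model.alpha, model.beta
    if x <= n - x + 1:
        lower = np.exp(betabin_logpmf(np.arange(0, x), n, a, b)).sum()
        return float(min(1.0, max(0.0, 1.0 - lower)))
    upper = np.exp(betabin_logpmf(np.arange(x, n + 1), n, a, b)).sum()
    return float(min(1.0, upper))


def apply_prefilters(
    candidates: Iterable[DeletionCandidate],
    min_support: int = DEFAULT_MIN_SUPPORT,
    min_wildtype: int = DEFAULT_MIN_WILDTYPE,
) -> list[DeletionCandidate]:
    """Keep candidates with s >= min_support and w >= min_wildtype.

    Excluded candidates are not returned but are annotated in place with
    ``passed=False`` and a reason, so they stay in the written table.
    """
    kept = []
    for c in candidates:
        if c.s < min_support:
            c.passed, c.reason = False, "single_read_support"
        elif c.w < min_wildtype:
            c.passed, c.reason = False, "no_wildtype_reads"
        else:
            kept.append(c)
    return kept


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values, in input order.

    q_(i) = min_{j >= i} (m p_(j) / j), clipped to 1; ties handled by a
    stable sort.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


def filter_calls(
    candidates: list[DeletionCandidate],
    model: ErrorModel | None = None,
    fdr: float = DEFAULT_FDR,
    noise_threshold: float = DEFAULT_NOISE_THRESHOLD,
    min_support: int = DEFAULT_MIN_SUPPORT,
    min_wildtype: int = DEFAULT_MIN_WILDTYPE,
    min_noise: int = DEFAULT_MIN_NOISE,
) -> tuple[list[DeletionCandidate], ErrorModel]:
    """Full filtering stage, in fixed order.

    (1) fit the background model on the sub-threshold noise stratum of ALL
    raw candidates (unless a fitted ``model`` is supplied); (2) apply
    pre-filters; (3) compute tail p-values with n = s + w, x = s for the
    survivors (the noise stratum is itself tested, not exempted); (4) BH
    across survivors; (5) pass = (q < fdr), strict. All candidates retain
    their status for the written table; returns (passing calls, model).
    """
    if model is None:
        model = fit_from_candidates(candidates, noise_threshold, min_noise)
    tested = apply_prefilters(candidates, min_support, min_wildtype)
    if not tested:
        return [], model
    pvals = [betabin_tail_p(c.s, c.s + c.w, model) for c in tested]
    qvals = benjamini_hochberg(pvals)
    passing = []
    for c, p, q in zip(tested, pvals, qvals):
        c.p, c.q = float(p), float(q)
        c.passed = bool(q < fdr)
        if not c.passed:
            c.reason = "q_above_fdr"
        else:
            passing.append(c)
    return passing, model
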