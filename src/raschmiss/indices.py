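"""Scalability (Loevinger H) and reliability (PSI) indices.

Loevinger's H measures how close a set of dichotomous items comes to a
perfect Guttman scale: it is the ratio of summed inter-item covariances to
the summed maxima those covariances could reach given the marginal positive
rates. H = 1 for perfect Guttman data, ~0 for independent items. On
incomplete data every pair is evaluated on the persons observing both items
(pairwise handling), so no case deletion is involved.

The Person Separation Index (PSI) contrasts the dispersion of the latent
trait with the person-estimation error, playing the role Cronbach's alpha
plays in classical test theory. Two forms are provided: the model-variance
form sigma2 / (sigma2 + mean(se^2)), which uses the fitted latent variance
and is the form whose behaviour under imputation matches the reference
simulation study, and the empirical separation form (V - mean(se^2)) / V
with V the sample variance of the person estimates.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np

from .types import (
    PersonEstimates,
    ReliabilityResult,
    ResponseData,
    ScalabilityResult,
    UndefinedIndexError,
)

__all__ = ["loevinger_h", "psi"]


def loevinger_h(data: ResponseData) -> ScalabilityResult:
    """Overall Loevinger H by the pairwise technique.

    H = sum_{j<k} Cov(X_j, X_k) / sum_{j<k} Cov0(X_j, X_k), where
    Cov0 = min(p_j, p_k) - p_j * p_k is the maximum covariance compatible
    with the marginals, both computed on the subsample jointly observing the
    pair. Pairs with fewer than 2 joint observations or a constant item in
    the joint subsample are dropped from both sums.
    """
    J = data.n_items
    vals = data.values
    obs = ~np.isnan(vals)
    n_pairs = J * (J - 1) // 2
    cov = np.full(n_pairs, np.nan)
    cov0 = np.full(n_pairs, np.nan)
    pair_n = np.zeros(n_pairs, dtype=int)
    dropped = []

    for idx, (j, k) in enumerate(combinations(range(J), 2)):
        both = obs[:, j] & obs[:, k]
        n = int(both.sum())
        pair_n[idx] = n
        if n < 2:
            dropped.append((j, k))
            continue
        xj = vals[both, j]
        xk = vals[both, k]
        pj, pk = xj.mean(), xk.mean()
        if pj in (0.0, 1.0) or pk in (0.0, 1.0):
            dropped.append((j, k))
            continue
        cov[idx] = np.mean(xj * xk) - pj * pk
        cov0[idx] = min(pj, pk) - pj * pk

    valid = ~np.isnan(cov)
    if not valid.any():
        raise UndefinedIndexError("all item pairs are degenerate; H is undefined")
    if dropped:
        warnings.warn(f"dropped degenerate item pairs: {dropped}", stacklevel=2)
    h = float(cov[valid].sum() / cov0[valid].sum())
    return ScalabilityResult(
        h=h, pair_cov=cov, pair_cov_max=cov0, pair_n=pair_n, dropped_pairs=dropped
    )


def psi(persons: PersonEstimates, sigma2: float | None = None) -> ReliabilityResult:
    """Person Separation Index from trait estimates and standard errors.

    With ``sigma2`` given (the fitted latent variance), uses the
    model-variance form PSI = sigma2 / (sigma2 + mean(se^2)) — the default
    in the study layer. Without it, uses the empirical separation form
    PSI = (V - mean(se^2)) / V with V the sample variance (denominator n-1)
    of the finite person estimates; that form equals 1 when estimation is
    error-free and 0 when the error variance matches the observed
    dispersion.
    """
    ok = ~np.isnan(persons.theta_hat)
    th = persons.theta_hat[ok]
    se = persons.se[ok]
    if th.size < 2:
        raise UndefinedIndexError("PSI needs at least 2 persons with estimates")
    v = float(np.var(th, ddof=1))
    mean_se2 = float(np.mean(se**2))
    if sigma2 is not None:
        if sigma2 <= 0:
            raise UndefinedIndexError("model variance must be positive")
        value = sigma2 / (sigma2 + mean_se2)
    else:
        if v == 0.0:
            raise UndefinedIndexError("person estimates have zero variance")
        value = (v - mean_se2) / v
    return ReliabilityResult(psi=value, var_theta=v, mean_se2=mean_se2)
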