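"""Simulation of complete Rasch response data and (non)informative missingness.

The generator follows the simulation design of the underlying study: person
abilities ``theta`` and a non-response propensity ``xi`` are jointly standard
normal with correlation ``rho <= 0``; responses come from the dichotomous
Rasch model; each cell is then independently deleted with a probability
centred on the target rate ``pi``, driven by ``xi`` (informative when
``rho != 0``) and optionally by item difficulty (``w = 1``).

The per-cell deletion probability uses the calibrated linear-clip form

    pi_nj = clip(pi * (1 + 0.4 * xi_n) + w * 0.4 * pi * delta_j, 0.01, 1)

whose person slope was calibrated so that the expected number of persons with
3+ missing responses out of 5 matches the study's reported counts at
pi = 10/20/30%.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .types import (
    ItemBank,
    LatentSample,
    MissingnessDesign,
    ResponseData,
    SimulationConfig,
)

__all__ = [
    "draw_latents",
    "simulate_responses",
    "missingness_probabilities",
    "apply_missingness",
    "replication_streams",
    "simulate_incomplete",
]

# Stable stage indices: adding a stream never perturbs existing ones.
_STAGES = {"latents": 0, "responses": 1, "mask": 2}
# Randomized methods get fixed stream slots starting at 10.
_METHOD_STREAMS = {
    "PMS-R": 10,
    "IMS-R": 11,
    "CIM-R": 12,
    "LOG-R": 13,
    "MOK": 14,
    "RAS-R": 15,
    "RAI": 16,
    "LOG": 17,
}


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def replication_streams(master_seed: int, rep_index: int) -> dict[str, np.random.Generator]:
    """Independent child generators for one replication.

    Each stage (latents, responses, mask, and each randomized imputation
    method) draws from its own stream, so every method sees the same
    incomplete dataset and adding a method never changes another's draws.
    """
    streams = {}
    for name, idx in {**_STAGES, **_METHOD_STREAMS}.items():
        ss = np.random.SeedSequence(master_seed, spawn_key=(rep_index, idx))
        streams[name] = np.random.default_rng(ss)
    return streams


def draw_latents(
    n: int,
    rho: float,
    mu: float = 0.0,
    sigma2: float = 1.0,
    seed=None,
) -> LatentSample:
    """Draw N jointly normal (theta, xi) pairs with Corr(theta, xi) = rho.

    theta ~ N(mu, sigma2); xi ~ N(0, 1). The pair is constructed as
    xi = rho * z_theta + sqrt(1 - rho^2) * z_perp so the joint law is exactly
    bivariate normal.
    """
    if sigma2 <= 0:
        raise ValueError(f"sigma2 must be positive, got {sigma2}")
    if abs(rho) > 1:
        raise ValueError(f"|rho| must be <= 1, got {rho}")
    rng = _as_rng(seed)
    z_theta = rng.standard_normal(n)
    z_perp = rng.standard_normal(n)
    theta = mu + np.sqrt(sigma2) * z_theta
    xi = rho * z_theta + np.sqrt(1.0 - rho**2) * z_perp
    return LatentSample(theta=theta, xi=xi, rho=rho, mu=mu, sigma2=sigma2)


def simulate_responses(latents: LatentSample, bank: ItemBank, seed=None) -> ResponseData:
    """Simulate a complete N x J response matrix from the Rasch model.

    Each cell is an independent Bernoulli draw with
    P(X_nj = 1) = expit(theta_n - delta_j).
    """
    rng = _as_rng(seed)
    p = expit(latents.theta[:, None] - bank.difficulties[None, :])
    values = (rng.random(p.shape) < p).astype(float)
    return ResponseData(values, labels=bank.labels)


def missingness_probabilities(
    latents: LatentSample, bank: ItemBank, design: MissingnessDesign
) -> np.ndarray:
    """Per-cell probability of non-response, centred on pi and floored.

    Returns the N x J matrix
    clip(pi * (1 + 0.4 * xi_n) + w * 0.4 * pi * delta_j, floor, 1).
    With rho = 0 and w = 0 the mechanism is MCAR; w = 1 links non-response to
    item difficulty (MAR); rho != 0 links it to the latent trait (MNAR).
    """
    pi = design.pi
    if pi == 0.0:
        return np.zeros((latents.n, bank.n_items))
    base = pi * (1.0 + 0.4 * latents.xi)[:, None]
    if design.w:
        base = base + 0.4 * pi * bank.difficulties[None, :]
    else:
        base = np.broadcast_to(base, (latents.n, bank.n_items)).copy()
    return np.clip(base, design.floor, 1.0)


def apply_missingness(
    complete: ResponseData, probs: np.ndarray, seed=None
) -> ResponseData:
    """Delete cells independently with the given per-cell probabilities.

    The input must be complete; the returned object is a new matrix with nan
    in the deleted cells, leaving ``complete`` untouched so paired
    complete-vs-incomplete comparisons remain possible.
    """
    if probs.shape != complete.values.shape:
        raise ValueError(
            f"shape mismatch: data {complete.values.shape} vs probs {probs.shape}"
        )
    if not complete.is_complete:
        raise ValueError("apply_missingness expects a complete dataset")
    rng = _as_rng(seed)
    values = complete.values.copy()
    values[rng.random(probs.shape) < probs] = np.nan
    return ResponseData(values, labels=complete.labels)


def simulate_incomplete(
    config: SimulationConfig, rep_index: int = 0
) -> tuple[ResponseData, ResponseData, LatentSample, dict[str, np.random.Generator]]:
    """One replication: complete data, incomplete data, latents, and streams."""
    streams = replication_streams(config.seed, rep_index)
    latents = draw_latents(
        config.n_persons, config.rho, config.mu, config.sigma2, streams["latents"]
    )
    complete = simulate_responses(latents, config.bank, streams["responses"])
    design = MissingnessDesign(pi=config.pi, w=config.w)
    probs = missingness_probabilities(latents, config.bank, design)
    incomplete = apply_missingness(complete, probs, streams["mask"])
    return complete, incomplete, latents, streams
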