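"""Core containers shared across the package.

Responses are stored as float arrays with ``numpy.nan`` marking a missing
cell; the observation mask is derived, never stored separately, so the two
can never disagree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class DegenerateItemError(ValueError):
    """An item has no observed 0s or no observed 1s, so its difficulty diverges."""


class UndefinedIndexError(ValueError):
    """An index (H, PSI) is undefined on this input (degenerate variance)."""


@dataclass(frozen=True)
class ItemBank:
    """A set of dichotomous items located on the logit scale.

    Parameters
    ----------
    difficulties
        Item difficulty parameters ``delta_j``; a higher value lowers the
        positive-response probability.
    labels
        Optional item labels; defaults to ``item1..itemJ``.
    """

    difficulties: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        d = np.asarray(self.difficulties, dtype=float)
        if d.ndim != 1 or d.size < 2:
            raise ValueError("an item bank needs at least 2 items")
        object.__setattr__(self, "difficulties", d)
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(f"item{j + 1}" for j in range(d.size))
            )
        elif len(self.labels) != d.size:
            raise ValueError("labels length must match difficulties")

    @property
    def n_items(self) -> int:
        return self.difficulties.size


#: The five-item bank used throughout the simulation study; its population
#: variance (divisor J) is exactly 0.5.
DEFAULT_BANK = ItemBank(np.array([-1.0, -0.5, 0.0, 0.5, 1.0]))


@dataclass(frozen=True)
class LatentSample:
    """Joint draws of ability ``theta`` and non-response propensity ``xi``.

    ``rho = Corr(theta, xi)`` controls the informativity of missingness:
    rho = 0 gives ignorable mechanisms, rho < 0 means low-ability persons
    skip more items (MNAR).
    """

    theta: np.ndarray
    xi: np.ndarray
    rho: float
    mu: float
    sigma2: float

    def __post_init__(self) -> None:
        if self.theta.shape != self.xi.shape or self.theta.ndim != 1:
            raise ValueError("theta and xi must be 1-d arrays of equal length")

    @property
    def n(self) -> int:
        return self.theta.size


@dataclass(frozen=True)
class MissingnessDesign:
    """Target item-level missingness rate and its link to item difficulty.

    ``pi`` is the expected per-item missingness rate; ``w`` = 1 makes harder
    items more frequently skipped (MAR component); ``floor`` bounds every
    per-cell probability from below.
    """

    pi: float
    w: int = 0
    floor: float = 0.01

    def __post_init__(self) -> None:
        if self.pi != 0.0 and not (self.floor <= self.pi < 1.0):
            raise ValueError(f"need floor <= pi < 1 (or pi = 0), got pi={self.pi}")
        if self.w not in (0, 1):
            raise ValueError("w must be 0 or 1")


class ResponseData:
    """An N x J matrix of dichotomous responses with missing cells.

    Values are 0.0, 1.0 or nan. The mask (1 = observed) and all margins are
    derived properties.
    """

    def __init__(self, values: np.ndarray, labels: tuple[str, ...] = ()):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be 2-d (persons x items)")
        obs = ~np.isnan(values)
        if not np.isin(values[obs], (0.0, 1.0)).all():
            raise ValueError("observed responses must be 0 or 1")
        self.values = values
        self.labels = labels or tuple(f"item{j + 1}" for j in range(values.shape[1]))

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    @property
    def mask(self) -> np.ndarray:
        """D_nj: 1 where the response is observed."""
        return (~np.isnan(self.values)).astype(np.int8)

    @property
    def person_observed(self) -> np.ndarray:
        """Number of observed responses per person."""
        return self.mask.sum(axis=1)

    @property
    def person_scores(self) -> np.ndarray:
        """S_n: number of positive observed responses per person."""
        return np.nansum(self.values, axis=1).astype(int)

    @property
    def item_observed(self) -> np.ndarray:
        """Number of observed responses per item."""
        return self.mask.sum(axis=0)

    @property
    def item_positive(self) -> np.ndarray:
        """R_j: number of positive observed responses per item."""
        return np.nansum(self.values, axis=0).astype(int)

    @property
    def is_complete(self) -> bool:
        return not np.isnan(self.values).any()

    def complete_rows(self) -> np.ndarray:
        """Boolean index of fully observed persons."""
        return ~np.isnan(self.values).any(axis=1)

    def copy(self) -> "ResponseData":
        return ResponseData(self.values.copy(), self.labels)

    def __repr__(self) -> str:  # pragma: no cover
        nmiss = int(np.isnan(self.values).sum())
        return (
            f"ResponseData(N={self.n_persons}, J={self.n_items}, "
            f"missing={nmiss})"
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Full generating configuration for one simulation study cell."""

    n_persons: int = 500
    bank: ItemBank = field(default_factory=lambda: DEFAULT_BANK)
    mu: float = 0.0
    sigma2: float = 1.0
    rho: float = 0.0
    w: int = 0
    pi: float = 0.1
    replications: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_persons < 1 or self.replications < 1:
            raise ValueError("n_persons and replications must be >= 1")


@dataclass
class ImputedData:
    """Result of one imputation method applied to an incomplete matrix.

    ``data`` holds the (possibly still partially missing) completed matrix;
    observed input cells are never altered. ``imputed_mask`` marks cells the
    method filled, ``residual_missing`` cells that remain missing (ineligible
    rows, missing donors, unusable covariates). ``probabilities`` holds the
    per-cell fill probability for methods that produce one.
    """

    data: ResponseData
    imputed_mask: np.ndarray
    method: str
    probabilities: np.ndarray | None = None
    n_iterations: int | None = None

    @property
    def residual_missing(self) -> np.ndarray:
        return np.isnan(self.data.values)


@dataclass
class RaschFit:
    """Marginal-maximum-likelihood estimates of the Rasch model.

    The latent mean is fixed at ``mu_hat`` by the identifiability constraint
    (``mu0``: mu = 0 with free difficulties; ``sumdelta``: sum of difficulties
    = 0 with free mu). ``nu_hat = mean(delta_hat) - mu_hat`` is constraint
    invariant.
    """

    delta_hat: np.ndarray
    sigma2_hat: float
    mu_hat: float
    loglik: float
    converged: bool
    n_iter: int
    grad_norm: float
    quad_order: int
    constraint: str = "mu0"

    @property
    def nu_hat(self) -> float:
        return float(np.mean(self.delta_hat) - self.mu_hat)

    @property
    def var_delta_hat(self) -> float:
        """Population variance (divisor J) of the estimated difficulties."""
        return float(np.var(self.delta_hat))


@dataclass
class PersonEstimates:
    """Latent-trait point estimates and standard errors per person.

    Persons with zero observed responses carry nan entries and are excluded
    from downstream indices.
    """

    theta_hat: np.ndarray
    se: np.ndarray
    estimator: str


@dataclass
class FitTestResult:
    """Q1 goodness-of-fit test on score groups of complete response rows."""

    statistic: float
    df: int
    p_value: float
    observed: np.ndarray
    expected: np.ndarray
    group_sizes: np.ndarray

    @property
    def reject_at_5pct(self) -> bool:
        return self.p_value < 0.05


@dataclass
class ScalabilityResult:
    """Pairwise Loevinger H with per-pair detail."""

    h: float
    pair_cov: np.ndarray
    pair_cov_max: np.ndarray
    pair_n: np.ndarray
    dropped_pairs: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class ReliabilityResult:
    """Person Separation Index and its components."""

    psi: float
    var_theta: float
    mean_se2: float
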