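"""Single-imputation strategies for incomplete dichotomous questionnaires.

Fourteen imputation methods plus two non-imputation strategies, as compared
in the simulation study this package reproduces:

========  =============================================================
NOIMP     available-case analysis: no imputation at all
LD        listwise deletion: drop persons with any missing response
WORST     fill every missing cell with the worst response (0)
PMS(-R)   personal mean score, rounded (or Bernoulli-drawn)
IMS(-R)   item mean score, rounded (or Bernoulli-drawn)
CIM(-R)   corrected item mean: item mean weighted by the person's level
ICS       response to the most correlated item (donor item)
LOG(-R)   stepwise logistic model on the other items
MOK       Mokken/Guttman five-rule imputation on difficulty-sorted items
RAS(-R)   Rasch-model predicted probability, rounded (or drawn)
RAI       iterative Rasch imputation (refit and re-impute, max 10 passes)
========  =============================================================

All imputation methods obey the 50% eligibility rule: a person's missing
cells are filled only if they observed a strict majority of the items
(at least 3 of 5); ineligible persons keep their observed responses and
remain partially missing. Observed cells are never altered by any method.

Rounding of fill probabilities is half-up (0.5 -> 1) everywhere.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import chi2

from . import rasch_mml
from .types import ImputedData, ResponseData

__all__ = [
    "METHOD_NAMES",
    "RANDOMIZED_METHODS",
    "eligible_rows",
    "listwise_delete",
    "impute_noimp",
    "impute_worst",
    "impute_pms",
    "impute_ims",
    "impute_cim",
    "impute_ics",
    "impute_log",
    "impute_mok",
    "impute_rasch",
    "impute_rasch_iterative",
    "apply_method",
]

METHOD_NAMES = (
    "NOIMP", "LD", "WORST", "PMS", "PMS-R", "IMS", "IMS-R", "CIM", "CIM-R",
    "ICS", "LOG", "LOG-R", "MOK", "RAS", "RAS-R", "RAI",
)
RANDOMIZED_METHODS = frozenset({"PMS-R", "IMS-R", "CIM-R", "LOG-R", "RAS-R", "MOK"})


class ImputationError(RuntimeError):
    """A method could not be applied to this dataset (e.g. fit failure)."""


def _round_half_up(p: np.ndarray) -> np.ndarray:
    """Round probabilities to {0,1} with 0.5 going to 1 (ties away from zero)."""
    return (np.asarray(p, dtype=float) >= 0.5).astype(float)


def eligible_rows(data: ResponseData) -> np.ndarray:
    """Persons observing a strict majority of items (> J/2 observed).

    Only these persons' missing cells may be imputed; the rest contribute
    their observed responses to the analysis unchanged.
    """
    return data.person_observed > data.n_items / 2


def _fillable(data: ResponseData) -> np.ndarray:
    """Cells that are missing and belong to an eligible row."""
    return np.isnan(data.values) & eligible_rows(data)[:, None]


def _build(
    data: ResponseData,
    prob: np.ndarray,
    cells: np.ndarray,
    method: str,
    randomized: bool,
    rng: np.random.Generator | None,
) -> ImputedData:
    """Fill `cells` from per-cell probabilities, rounding or drawing."""
    values = data.values.copy()
    if randomized:
        if rng is None:
            rng = np.random.default_rng()
        fills = (rng.random(data.values.shape) < prob).astype(float)
    else:
        fills = _round_half_up(prob)
    values[cells] = fills[cells]
    probabilities = np.where(cells, prob, np.nan)
    return ImputedData(
        data=ResponseData(values, data.labels),
        imputed_mask=cells.astype(np.int8),
        method=method,
        probabilities=probabilities,
    )


def impute_noimp(data: ResponseData) -> ImputedData:
    """Available-case analysis: return the data untouched."""
    return ImputedData(
        data=data.copy(),
        imputed_mask=np.zeros(data.values.shape, dtype=np.int8),
        method="NOIMP",
    )


def listwise_delete(data: ResponseData) -> ResponseData:
    """Drop every person with one or more missing responses."""
    keep = data.complete_rows()
    if not keep.any():
        raise ImputationError("listwise deletion leaves an empty dataset")
    return ResponseData(data.values[keep].copy(), data.labels)


def impute_worst(data: ResponseData) -> ImputedData:
    """Fill every eligible missing cell with the worst response, 0."""
    cells = _fillable(data)
    return _build(data, np.zeros(data.values.shape), cells, "WORST", False, None)


def impute_pms(
    data: ResponseData, randomized: bool = False, rng=None
) -> ImputedData:
    """Personal mean score: fill with the person's observed positive rate."""
    with np.errstate(invalid="ignore"):
        p_n = data.person_scores / data.person_observed
    prob = np.broadcast_to(p_n[:, None], data.values.shape)
    name = "PMS-R" if randomized else "PMS"
    return _build(data, prob, _fillable(data), name, randomized, rng)


def impute_ims(
    data: ResponseData, randomized: bool = False, rng=None
) -> ImputedData:
    """Item mean score: fill with the item's observed positive rate."""
    obs = data.item_observed
    with np.errstate(invalid="ignore", divide="ignore"):
        p_j = np.where(obs > 0, data.item_positive / np.maximum(obs, 1), np.nan)
    cells = _fillable(data) & (obs > 0)[None, :]
    if (obs == 0).any():
        warnings.warn(
            f"items with no observed responses left missing: "
            f"{[data.labels[j] for j in np.flatnonzero(obs == 0)]}",
            stacklevel=2,
        )
    prob = np.broadcast_to(np.nan_to_num(p_j)[None, :], data.values.shape)
    name = "IMS-R" if randomized else "IMS"
    return _build(data, prob, cells, name, randomized, rng)


def impute_cim(
    data: ResponseData, randomized: bool = False, rng=None
) -> ImputedData:
    """Corrected item mean: item mean weighted by the person's relative level.

    q_nj = (S_n / sum_{k in O_n} p_k) * p_j with p_k the observed item
    means, clipped to [0, 1].
    """
    obs = data.item_observed
    with np.errstate(invalid="ignore", divide="ignore"):
        p_j = np.where(obs > 0, data.item_positive / np.maximum(obs, 1), 0.0)
    mask = data.mask.astype(float)
    denom = mask @ p_j  # sum of observed items' means per person
    ok = denom > 0
    if not ok.all():
        warnings.warn("persons with zero expected score left missing", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        weight = np.where(ok, data.person_scores / np.where(ok, denom, 1.0), np.nan)
    prob = np.clip(weight[:, None] * p_j[None, :], 0.0, 1.0)
    cells = _fillable(data) & ok[:, None] & (obs > 0)[None, :]
    name = "CIM-R" if randomized else "CIM"
    return _build(data, np.nan_to_num(prob), cells, name, randomized, rng)


def item_correlations(data: ResponseData) -> np.ndarray:
    """Pairwise Pearson correlations on jointly observed persons (nan if undefined)."""
    J = data.n_items
    corr = np.full((J, J), np.nan)
    vals = data.values
    obs = ~np.isnan(vals)
    for j, k in combinations(range(J), 2):
        both = obs[:, j] & obs[:, k]
        if both.sum() < 2:
            continue
        xj, xk = vals[both, j], vals[both, k]
        if xj.std() == 0 or xk.std() == 0:
            continue
        r = np.corrcoef(xj, xk)[0, 1]
        corr[j, k] = corr[k, j] = r
    return corr


def impute_ics(data: ResponseData) -> ImputedData:
    """Item-correlation substitution: copy the response to the donor item.

    The donor of item j is the item most (signed) correlated with j over
    jointly observed persons, ties broken by lowest index; a cell stays
    missing when the donor response is itself missing or when no pair
    involving j has a defined correlation.
    """
    corr = item_correlations(data)
    J = data.n_items
    values = data.values.copy()
    imputed = np.zeros(values.shape, dtype=np.int8)
    fillable = _fillable(data)
    for j in range(J):
        col = corr[j]
        if np.isnan(col).all():
            continue
        donor = int(np.nanargmax(col))
        rows = np.flatnonzero(fillable[:, j] & ~np.isnan(data.values[:, donor]))
        values[rows, j] = data.values[rows, donor]
        imputed[rows, j] = 1
    return ImputedData(
        data=ResponseData(values, data.labels),
        imputed_mask=imputed,
        method="ICS",
    )


def _fit_logit(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Fit a logistic regression, falling back to a ridge fit on separation.

    Returns (coefficients incl. intercept, log-likelihood).
    """
    Xc = sm.add_constant(X, has_constant="add")
    model = sm.Logit(y, Xc)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, method="lbfgs", maxiter=200)
            if np.isfinite(res.llf) and np.all(np.isfinite(res.params)):
                return np.asarray(res.params), float(res.llf)
        except Exception:
            pass
        res = model.fit_regularized(disp=0, alpha=1e-4, maxiter=500)
    params = np.asarray(res.params)
    llf = float(model.loglike(params))
    return params, llf


def impute_log(
    data: ResponseData,
    randomized: bool = False,
    alpha: float = 0.05,
    rng=None,
) -> ImputedData:
    """Stepwise logistic-model imputation.

    For each item with missing values, the other items enter a forward
    stepwise logistic regression (likelihood-ratio entry test at level
    ``alpha``, candidate and incumbent models refitted on the rows complete
    for the candidate set). Missing cells whose selected covariates are all
    observed are filled from the predicted probability; others stay missing.
    """
    J = data.n_items
    values = data.values.copy()
    imputed = np.zeros(values.shape, dtype=np.int8)
    prob_out = np.full(values.shape, np.nan)
    fillable = _fillable(data)
    if rng is None:
        rng = np.random.default_rng()
    obs = ~np.isnan(data.values)

    for j in range(J):
        if not fillable[:, j].any():
            continue
        selected: list[int] = []
        candidates = [k for k in range(J) if k != j]
        while candidates:
            best_p, best_k = None, None
            for k in candidates:
                rows = obs[:, j] & obs[:, selected + [k]].all(axis=1)
                y = data.values[rows, j]
                if y.size < 3 or y.min() == y.max():
                    continue
                _, ll_full = _fit_logit(y, data.values[np.ix_(np.flatnonzero(rows), selected + [k])])
                if selected:
                    _, ll_null = _fit_logit(y, data.values[np.ix_(np.flatnonzero(rows), selected)])
                else:
                    p0 = y.mean()
                    ll_null = float(
                        y.sum() * np.log(p0) + (y.size - y.sum()) * np.log(1 - p0)
                    )
                p_val = float(chi2.sf(max(2.0 * (ll_full - ll_null), 0.0), 1))
                if best_p is None or p_val < best_p:
                    best_p, best_k = p_val, k
            if best_p is not None and best_p < alpha:
                selected.append(best_k)
                candidates.remove(best_k)
            else:
                break

        rows_fit = obs[:, j] & (obs[:, selected].all(axis=1) if selected else True)
        y = data.values[rows_fit, j]
        if selected and y.size >= 3 and y.min() != y.max():
            params, _ = _fit_logit(y, data.values[np.ix_(np.flatnonzero(rows_fit), selected)])
            can_fill = fillable[:, j] & obs[:, selected].all(axis=1)
            Xp = data.values[np.ix_(np.flatnonzero(can_fill), selected)]
            eta = params[0] + Xp @ params[1:]
            p_fill = expit(eta)
        else:
            # intercept-only model: predict the item's observed mean
            y_all = data.values[obs[:, j], j]
            if y_all.size == 0:
                continue
            can_fill = fillable[:, j]
            p_fill = np.full(int(can_fill.sum()), y_all.mean())
        idx = np.flatnonzero(can_fill)
        if randomized:
            values[idx, j] = (rng.random(idx.size) < p_fill).astype(float)
        else:
            values[idx, j] = _round_half_up(p_fill)
        prob_out[idx, j] = p_fill
        imputed[idx, j] = 1

    return ImputedData(
        data=ResponseData(values, data.labels),
        imputed_mask=imputed,
        method="LOG-R" if randomized else "LOG",
        probabilities=prob_out,
    )


def impute_mok(data: ResponseData, rng=None) -> ImputedData:
    """Mokken-style imputation minimizing Guttman errors.

    Items are sorted from easiest (most observed positives) to hardest,
    stable in the original order. Per missing cell, in sorted coordinates:

    a. any observed positive response at a harder position -> 1;
    b. else any observed negative response at an easier position -> 0;
    c. else 0 if the count of observed negatives at easier positions is at
       least the count of positives there;
    d. else 1 if the count of observed negatives at harder positions is at
       most the count of positives there;
    e. else a Bernoulli draw with the item's observed positive proportion.

    Rules read only originally observed responses.
    """
    if rng is None:
        rng = np.random.default_rng()
    order = np.argsort(-data.item_positive, kind="stable")
    vals = data.values[:, order]
    obs = ~np.isnan(vals)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_sorted = np.where(
            data.item_observed[order] > 0,
            data.item_positive[order] / np.maximum(data.item_observed[order], 1),
            0.5,
        )
    fillable = _fillable(data)[:, order]
    filled = vals.copy()
    for n, pos in zip(*np.nonzero(fillable)):
        row, ob = vals[n], obs[n]
        after = ob & (np.arange(row.size) > pos)
        before = ob & (np.arange(row.size) < pos)
        if (row[after] == 1).any():                      # (a)
            filled[n, pos] = 1.0
        elif (row[before] == 0).any():                   # (b)
            filled[n, pos] = 0.0
        else:
            a00 = int((row[before] == 0).sum())
            a01 = int((row[before] == 1).sum())
            if a00 >= a01:                               # (c)
                filled[n, pos] = 0.0
            else:
                a10 = int((row[after] == 0).sum())
                a11 = int((row[after] == 1).sum())
                if a10 <= a11:                           # (d)
                    filled[n, pos] = 1.0
                else:                                    # (e)
                    filled[n, pos] = float(rng.random() < p_sorted[pos])
    values = np.empty_like(filled)
    values[:, order] = filled
    imputed = np.zeros(values.shape, dtype=np.int8)
    imputed[:, order] = fillable.astype(np.int8)
    return ImputedData(
        data=ResponseData(values, data.labels),
        imputed_mask=imputed,
        method="MOK",
    )


def rasch_fill_probabilities(
    data: ResponseData, estimator: str = "eap", quad_order: int = 30
):
    """Fit the Rasch model on observed data and return per-cell P(X=1).

    Person estimates default to EAP (posterior mean under the fitted latent
    distribution): the shrinkage keeps fill probabilities conservative,
    which is the behaviour the reference simulation results exhibit. WLE is
    available as a switch.
    """
    fit = rasch_mml.fit_mml(data, quad_order=quad_order)
    if not fit.converged:
        raise ImputationError("Rasch MML fit did not converge")
    persons = rasch_mml.estimate_persons(fit, data, estimator=estimator)
    prob = expit(persons.theta_hat[:, None] - fit.delta_hat[None, :])
    return prob, fit, persons


def impute_rasch(
    data: ResponseData,
    randomized: bool = False,
    rng=None,
    estimator: str = "eap",
    quad_order: int = 30,
) -> ImputedData:
    """Rasch-model imputation: fill from the model-predicted probability.

    p_nj = expit(theta_hat_n - delta_hat_j) with difficulties from the MML
    fit on observed data and person estimates (EAP by default) from observed
    responses.
    """
    prob, _, _ = rasch_fill_probabilities(data, estimator, quad_order)
    cells = _fillable(data) & np.isfinite(prob)
    name = "RAS-R" if randomized else "RAS"
    return _build(data, np.nan_to_num(prob, nan=0.5), cells, name, randomized, rng)


def impute_rasch_iterative(
    data: ResponseData,
    max_iter: int = 10,
    rng=None,
    estimator: str = "eap",
    quad_order: int = 30,
) -> ImputedData:
    """Iterative Rasch imputation (RAI).

    A first deterministic Rasch imputation is followed by refits on the
    completed matrix and deterministic re-imputation of the originally
    missing cells, until two successive passes agree or ``max_iter`` (10,
    matching the reference procedure) passes have run.
    """
    first = impute_rasch(data, randomized=False, estimator=estimator,
                         quad_order=quad_order)
    cells = first.imputed_mask.astype(bool)
    current = first.data
    n_iter = 1
    last_prob = first.probabilities
    while n_iter < max_iter:
        try:
            fit = rasch_mml.fit_mml(current, quad_order=quad_order)
            persons = rasch_mml.estimate_persons(fit, current, estimator=estimator)
        except Exception:
            warnings.warn("RAI inner fit failed; returning last completed state",
                          stacklevel=2)
            break
        prob = expit(persons.theta_hat[:, None] - fit.delta_hat[None, :])
        new_fill = _round_half_up(prob)
        values = current.values.copy()
        changed = (values[cells] != new_fill[cells]).any()
        values[cells] = new_fill[cells]
        current = ResponseData(values, data.labels)
        last_prob = np.where(cells, prob, np.nan)
        n_iter += 1
        if not changed:
            break
    return ImputedData(
        data=current,
        imputed_mask=cells.astype(np.int8),
        method="RAI",
        probabilities=last_prob,
        n_iterations=n_iter,
    )


def apply_method(
    name: str, data: ResponseData, rng=None, **options
) -> ImputedData:
    """Apply a strategy by name, returning an ImputedData wrapper.

    NOIMP returns the data unchanged; LD returns the listwise-deleted matrix
    (with an all-zero imputation mask over the retained rows).
    """
    if name not in METHOD_NAMES:
        raise ValueError(f"unknown method {name!r}; choose from {METHOD_NAMES}")
    if name == "NOIMP":
        return impute_noimp(data)
    if name == "LD":
        reduced = listwise_delete(data)
        return ImputedData(
            data=reduced,
            imputed_mask=np.zeros(reduced.values.shape, dtype=np.int8),
            method="LD",
        )
    if name == "WORST":
        return impute_worst(data)
    if name in ("PMS", "PMS-R"):
        return impute_pms(data, randomized=name.endswith("-R"), rng=rng)
    if name in ("IMS", "IMS-R"):
        return impute_ims(data, randomized=name.endswith("-R"), rng=rng)
    if name in ("CIM", "CIM-R"):
        return impute_cim(data, randomized=name.endswith("-R"), rng=rng)
    if name == "ICS":
        return impute_ics(data)
    if name in ("LOG", "LOG-R"):
        return impute_log(data, randomized=name.endswith("-R"), rng=rng, **options)
    if name == "MOK":
        return impute_mok(data, rng=rng)
    if name in ("RAS", "RAS-R"):
        return impute_rasch(data, randomized=name.endswith("-R"), rng=rng, **options)
    return impute_rasch_iterative(data, rng=rng, **options)
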