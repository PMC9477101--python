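"""Maximum-likelihood estimation of the loglinear Bradley-Terry pattern model.

The Bradley-Terry model assigns each item j a worth pi_j on the unit
simplex; the probability of preferring j over k is pi_j / (pi_j + pi_k).
On the log scale pi_j = exp(2 lambda_j) / sum_k exp(2 lambda_k), and a whole
ranking pattern y (a vector of J(J-1)/2 signed decisions) has probability

    p(y | lambda) = exp(lambda . x(y)) / Z(lambda),

where x(y) is the item score vector (signed pairwise win counts) and Z sums
the weights over all J! transitive patterns.  This is a regular exponential
family in the J-1 free coordinates of lambda (sum-to-zero constraint), so
the log-likelihood over a pattern count table is concave and a Newton
iteration with analytic gradient and Hessian converges quadratically.  The
equivalent Poisson loglinear formulation (log link over the subject-expanded
pattern design, nuisance intercepts absorbing the normalization) is asserted
against this fit in the test suite rather than maintained as a second
production path.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit, logsumexp
from scipy.stats import norm

from .rankings import (
    ItemSet,
    PatternTable,
    PCPattern,
    enumerate_patterns,
    item_scores,
    score_matrix,
)

__all__ = [
    "ItemParams",
    "WorthVector",
    "GroupSpec",
    "LLBTFit",
    "SeparationWarning",
    "worth_from_lambda",
    "lambda_from_worth",
    "preference_prob",
    "pattern_probability",
    "pattern_distribution",
    "fit_llbt",
    "fit_llbt_grouped",
    "worth_ci",
    "loglik_and_scores",
    "fit_to_dict",
    "fit_from_dict",
]

#: |lambda| beyond which the likelihood is treated as separated (an item is
#: essentially always first or always last); the unpenalized MLE diverges.
SEPARATION_BOUND = 15.0
#: Ridge penalty applied to a separated fit so a finite, near-degenerate
#: worth vector is still reported (flagged on the fit record).
RIDGE_PENALTY = 1e-4
GRAD_TOL = 1e-8
MAX_ITER = 200


class SeparationWarning(UserWarning):
    """The likelihood is (quasi-)separated; a ridge-penalized fit is returned."""


ItemParams = np.ndarray  # length-J lambda vector, sum-to-zero
WorthVector = np.ndarray  # length-J pi vector on the open simplex


@dataclass(frozen=True)
class GroupSpec:
    """A focal grouping of subjects (e.g. expert vs. novice).

    The group enters every node model as an item-by-group interaction and is
    never a splitting candidate.
    """

    group_of_subject: dict[str, str]
    reference_group: str

    def __post_init__(self) -> None:
        labels = set(self.group_of_subject.values())
        if self.reference_group not in labels:
            raise ValueError(
                f"reference group {self.reference_group!r} not among {sorted(labels)}"
            )

    @property
    def labels(self) -> list[str]:
        out = [self.reference_group]
        for g in sorted(set(self.group_of_subject.values())):
            if g != self.reference_group:
                out.append(g)
        return out


@dataclass
class LLBTFit:
    """A fitted loglinear Bradley-Terry pattern model.

    ``lambda_`` holds the sum-to-zero item parameters of the reference fit;
    ``pi`` the worth vector.  For grouped fits, ``group_lambda`` maps each
    group label to its full lambda vector and ``group_terms`` to the offset
    from the reference group (zero for the reference group itself);
    ``group_pi`` holds per-group worths.  ``cov_lambda`` is the covariance
    of the full lambda vector from the observed information (singular by
    construction along the constant direction).  ``normalization`` stores
    -log Z, the absorbed loglinear intercept.
    """

    items: ItemSet
    lambda_: np.ndarray
    pi: np.ndarray
    loglik: float
    n: int
    n_params: int
    cov_lambda: np.ndarray
    converged: bool
    separated: bool
    normalization: float
    group_terms: dict[str, np.ndarray] | None = None
    group_lambda: dict[str, np.ndarray] | None = None
    group_pi: dict[str, np.ndarray] | None = None
    group_n: dict[str, int] | None = None
    group_cov: dict[str, np.ndarray] | None = None
    reference_group: str | None = None

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params


def worth_from_lambda(lambda_: np.ndarray) -> WorthVector:
    """Map item parameters to worths: pi_j = exp(2 lambda_j) / sum exp(2 lambda_k).

    Invariant under adding a constant to all lambda; overflow is guarded by
    max-subtraction.
    """
    lam = np.asarray(lambda_, dtype=float)
    if not np.all(np.isfinite(lam)):
        raise ValueError("lambda must be finite")
    z = 2.0 * lam
    z -= z.max()
    w = np.exp(z)
    return w / w.sum()


def lambda_from_worth(pi: np.ndarray) -> ItemParams:
    """Inverse worth transform: lambda_j = ln(pi_j)/2, recentred to sum zero."""
    p = np.asarray(pi, dtype=float)
    if np.any(p <= 0):
        raise ValueError("worths must be strictly positive")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError(f"worths must sum to 1 (got {p.sum():.10f})")
    lam = 0.5 * np.log(p)
    return lam - lam.mean()


def preference_prob(pi: np.ndarray, j: int, k: int) -> float:
    """P(item j preferred over item k) = pi_j / (pi_j + pi_k)."""
    if j == k:
        raise ValueError("j and k must be distinct items")
    p = np.asarray(pi, dtype=float)
    return float(p[j] / (p[j] + p[k]))


def pattern_distribution(lambda_: np.ndarray) -> np.ndarray:
    """Probabilities of all J! patterns (enumeration order) under lambda."""
    lam = np.asarray(lambda_, dtype=float)
    X = score_matrix(lam.size)
    eta = X @ lam
    eta -= eta.max()
    w = np.exp(eta)
    return w / w.sum()


def pattern_probability(lambda_: np.ndarray, pattern: PCPattern) -> float:
    """Probability of one ranking pattern under the pattern model."""
    lam = np.asarray(lambda_, dtype=float)
    X = score_matrix(lam.size)
    eta = X @ lam
    x = np.asarray(item_scores(tuple(pattern), lam.size), dtype=float)
    return float(np.exp(x @ lam - logsumexp(eta)))


def _reduced_stats(n_items: int) -> np.ndarray:
    """(J!, J-1) reduced score matrix u_p = x_p[:-1] - x_p[-1]."""
    X = score_matrix(n_items)
    return X[:, :-1] - X[:, -1:]


def _theta_to_lambda(theta: np.ndarray) -> np.ndarray:
    lam = np.append(theta, -theta.sum())
    return lam - lam.mean()


_STATS_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _design(n_items: int) -> tuple[np.ndarray, np.ndarray]:
    if n_items not in _STATS_CACHE:
        _STATS_CACHE[n_items] = (score_matrix(n_items), _reduced_stats(n_items))
    return _STATS_CACHE[n_items]


def _fit_core(
    counts: np.ndarray, n_items: int, *, ridge: float = 0.0
) -> tuple[np.ndarray, float, np.ndarray, bool, bool]:
    """Newton iteration on the reduced (J-1)-parameter concave loglik.

    Returns (lambda, loglik, cov_lambda, converged, separated).  ``loglik``
    is always the *unpenalized* multinomial log-likelihood at the returned
    parameters, including the multinomial coefficient-free form
    sum_p n_p log p_p.
    """
    X, U = _design(n_items)
    n = counts.sum()
    t_u = counts @ U  # reduced sufficient statistic
    theta = np.zeros(n_items - 1)
    tol = max(GRAD_TOL, 1e-12 * n)
    converged = False
    separated = False

    def penalized_ll(th: np.ndarray) -> float:
        eta = U @ th
        ll = th @ t_u - n * logsumexp(eta)
        if ridge:
            lam = _theta_to_lambda(th)
            ll -= ridge * (lam @ lam)
        return ll

    ll = penalized_ll(theta)
    for _ in range(MAX_ITER):
        eta = U @ theta
        p = np.exp(eta - logsumexp(eta))
        mean_u = p @ U
        grad = t_u - n * mean_u
        cov_u = (U * p[:, None]).T @ U - np.outer(mean_u, mean_u)
        hess = -n * cov_u
        if ridge:
            lam = _theta_to_lambda(theta)
            # d lam / d theta: rows for items 1..J-1 are e_i, last row is -1.
            A = np.vstack([np.eye(n_items - 1), -np.ones(n_items - 1)])
            # centring drops out of the quadratic penalty gradient only up
            # to the mean; use the exact chain rule.
            Ac = A - A.mean(axis=0, keepdims=True)
            grad = grad - 2.0 * ridge * (Ac.T @ lam)
            hess = hess - 2.0 * ridge * (Ac.T @ Ac)
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError:
            step = -np.linalg.pinv(hess) @ grad
        # step halving on the (penalized) objective keeps the ascent honest
        new_ll = None
        for _h in range(40):
            cand = theta + step
            new_ll = penalized_ll(cand)
            if new_ll >= ll - 1e-12:
                theta = cand
                ll = new_ll
                break
            step *= 0.5
        else:  # pragma: no cover - concave objective, should not happen
            break
        if np.max(np.abs(_theta_to_lambda(theta))) > SEPARATION_BOUND:
            separated = True
            break

    lam = _theta_to_lambda(theta)
    eta = U @ theta
    logZ = logsumexp(eta)
    loglik = float(theta @ t_u - n * logZ)
    # observed information for theta at the optimum (unpenalized model part)
    p = np.exp(eta - logZ)
    mean_u = p @ U
    cov_u = (U * p[:, None]).T @ U - np.outer(mean_u, mean_u)
    info = n * cov_u
    if ridge:
        A = np.vstack([np.eye(n_items - 1), -np.ones(n_items - 1)])
        Ac = A - A.mean(axis=0, keepdims=True)
        info = info + 2.0 * ridge * (Ac.T @ Ac)
    try:
        cov_theta = np.linalg.inv(info)
    except np.linalg.LinAlgError:  # pragma: no cover
        cov_theta = np.linalg.pinv(info)
    A = np.vstack([np.eye(n_items - 1), -np.ones(n_items - 1)])
    Ac = A - A.mean(axis=0, keepdims=True)
    cov_lambda = Ac @ cov_theta @ Ac.T
    return lam, loglik, cov_lambda, converged, separated


def fit_llbt(table: PatternTable) -> LLBTFit:
    """MLE of the Bradley-Terry pattern model over a pattern count table.

    Identical (up to numerical tolerance) to the multinomial MLE over the
    J!-cell table, and to the Poisson loglinear fit with per-comparison
    nuisance intercepts.  Separation — some item effectively always first
    or always last, driving |lambda| beyond :data:`SEPARATION_BOUND` — is
    detected during iteration; a ridge-penalized fit is returned with
    ``separated=True`` and a :class:`SeparationWarning`.
    """
    counts = table.count_vector()
    n = counts.sum()
    if n < 1:
        raise ValueError("pattern table needs total count >= 1")
    n = int(n) if float(n).is_integer() else n
    n_items = table.items.n_items
    lam, ll, cov, converged, separated = _fit_core(counts, n_items)
    if separated:
        warnings.warn(
            "separated likelihood (an item is always ranked first or last); "
            "returning a ridge-penalized fit",
            SeparationWarning,
            stacklevel=2,
        )
        lam, ll, cov, converged, _ = _fit_core(
            counts, n_items, ridge=RIDGE_PENALTY * n
        )
    X, _ = _design(n_items)
    logZ = float(logsumexp(X @ lam))
    return LLBTFit(
        items=table.items,
        lambda_=lam,
        pi=worth_from_lambda(lam),
        loglik=ll,
        n=n,
        n_params=n_items - 1,
        cov_lambda=cov,
        converged=converged,
        separated=separated,
        normalization=-logZ,
    )


def fit_llbt_grouped(
    tables_by_group: dict[str, PatternTable], groups: GroupSpec
) -> LLBTFit:
    """Grouped LLBT fit with a saturated item-by-group interaction.

    Each group g gets item parameters lambda_j(g) = lambda_j + lambda_js(g),
    with the reference group's offsets fixed at zero.  With the interaction
    saturated the grouped likelihood factorizes, so each group's parameters
    are the MLE of its own table and the total log-likelihood is the sum of
    the per-group log-likelihoods (an identity asserted in the tests).
    """
    labels = groups.labels
    missing = [g for g in labels if g not in tables_by_group]
    if missing:
        raise ValueError(f"no pattern table for group(s) {missing}")
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    fits: dict[str, LLBTFit] = {}
    for g in labels:
        tab = tables_by_group[g]
        if tab.n < 1:
            raise ValueError(f"group {g!r} is empty")
        fits[g] = fit_llbt(tab)
    ref = groups.reference_group
    items = tables_by_group[ref].items
    n_items = items.n_items
    lam_ref = fits[ref].lambda_
    return LLBTFit(
        items=items,
        lambda_=lam_ref,
        pi=fits[ref].pi,
        loglik=sum(f.loglik for f in fits.values()),
        n=sum(f.n for f in fits.values()),
        n_params=len(labels) * (n_items - 1),
        cov_lambda=fits[ref].cov_lambda,
        converged=all(f.converged for f in fits.values()),
        separated=any(f.separated for f in fits.values()),
        normalization=fits[ref].normalization,
        group_terms={g: fits[g].lambda_ - lam_ref for g in labels},
        group_lambda={g: fits[g].lambda_ for g in labels},
        group_pi={g: fits[g].pi for g in labels},
        group_n={g: fits[g].n for g in labels},
        group_cov={g: fits[g].cov_lambda for g in labels},
        reference_group=ref,
    )


def worth_ci(fit: LLBTFit, level: float = 0.95) -> np.ndarray:
    """Delta-method confidence intervals for the worth parameters.

    The normal approximation is applied on the log-odds scale of each
    pi_j and back-transformed, so bounds stay inside (0, 1) and always
    contain the point estimate.  Returns an array of shape (J, 2).
    """
    if not fit.converged:
        raise ValueError("cannot compute intervals for a non-converged fit")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    pi = fit.pi
    # d pi / d lambda = 2 (diag(pi) - pi pi')
    J_mat = 2.0 * (np.diag(pi) - np.outer(pi, pi))
    var_pi = np.einsum("ij,jk,ik->i", J_mat, fit.cov_lambda, J_mat)
    var_pi = np.maximum(var_pi, 0.0)
    se_logit = np.sqrt(var_pi) / np.maximum(pi * (1.0 - pi), 1e-300)
    z = norm.ppf(0.5 + level / 2.0)
    lo = expit(logit(pi) - z * se_logit)
    hi = expit(logit(pi) + z * se_logit)
    return np.column_stack([lo, hi])


def loglik_and_scores(
    fit: LLBTFit, patterns: list[PCPattern] | PatternTable
) -> tuple[float, np.ndarray]:
    """Total log-likelihood and per-subject score contributions.

    The score of a subject with pattern y is x(y) - E_lambda[x], the
    gradient of that subject's log-likelihood in the full lambda
    coordinates.  At the node MLE the scores sum to (numerically) zero in
    every coordinate.  For a :class:`PatternTable` input, subjects are
    expanded in pattern enumeration order.
    """
    if isinstance(patterns, PatternTable):
        pats: list[PCPattern] = []
        for p in enumerate_patterns(patterns.items.n_items):
            pats.extend([p] * patterns.counts[p])
    else:
        pats = [tuple(p) for p in patterns]
    n_items = fit.items.n_items
    X, _ = _design(n_items)
    dist = pattern_distribution(fit.lambda_)
    mean_x = dist @ X
    index = {p: i for i, p in enumerate(enumerate_patterns(n_items))}
    rows = np.array([index[p] for p in pats], dtype=int)
    if rows.size and rows.max() >= X.shape[0]:  # pragma: no cover
        raise ValueError("pattern/items dimension mismatch")
    scores = X[rows] - mean_x
    eta = X @ fit.lambda_
    logZ = logsumexp(eta)
    loglik = float(np.sum(eta[rows]) - len(rows) * logZ)
    return loglik, scores


# ---------------------------------------------------------------------------
# JSON serialization

def fit_to_dict(fit: LLBTFit, level: float = 0.95) -> dict:
    d = {
        "items": list(fit.items.labels),
        "attribute": fit.items.attribute_name,
        "lambda": fit.lambda_.tolist(),
        "pi": fit.pi.tolist(),
        "loglik": fit.loglik,
        "aic": fit.aic,
        "n": fit.n,
        "n_params": fit.n_params,
        "converged": bool(fit.converged),
        "separated": bool(fit.separated),
        "normalization": fit.normalization,
        "cov_lambda": fit.cov_lambda.tolist(),
    }
    if fit.converged:
        d["ci"] = {"level": level, "bounds": worth_ci(fit, level).tolist()}
    if fit.group_pi is not None:
        d["reference_group"] = fit.reference_group
        d["group_pi"] = {g: v.tolist() for g, v in fit.group_pi.items()}
        d["group_lambda"] = {g: v.tolist() for g, v in fit.group_lambda.items()}
        d["group_terms"] = {g: v.tolist() for g, v in fit.group_terms.items()}
        d["group_n"] = dict(fit.group_n)
    return d


def fit_from_dict(d: dict) -> LLBTFit:
    items = ItemSet(tuple(d["items"]), d.get("attribute", ""))
    return LLBTFit(
        items=items,
        lambda_=np.array(d["lambda"]),
        pi=np.array(d["pi"]),
        loglik=float(d["loglik"]),
        n=int(d["n"]),
        n_params=int(d["n_params"]),
        cov_lambda=np.array(d["cov_lambda"]),
        converged=bool(d["converged"]),
        separated=bool(d["separated"]),
        normalization=float(d["normalization"]),
        group_terms={g: np.array(v) for g, v in d["group_terms"].items()}
        if "group_terms" in d
        else None,
        group_lambda={g: np.array(v) for g, v in d["group_lambda"].items()}
        if "group_lambda" in d
        else None,
        group_pi={g: np.array(v) for g, v in d["group_pi"].items()}
        if "group_pi" in d
        else None,
        group_n=dict(d["group_n"]) if "group_n" in d else None,
        reference_group=d.get("reference_group"),
    )


def save_fit(fit: LLBTFit, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(fit_to_dict(fit), fh, indent=2)


def load_fit(path) -> LLBTFit:
    with open(path, encoding="utf-8") as fh:
        return fit_from_dict(json.load(fh))
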