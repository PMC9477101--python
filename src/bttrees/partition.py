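"""Model-based recursive partitioning of Bradley-Terry pattern fits.

Subjects are recursively split on covariates wherever the fitted item
parameters are unstable.  At each node:

1. fit the LLBT pattern model (grouped when a focal group is supplied);
2. for every candidate covariate, test parameter instability using the
   per-subject score contributions — a supLM score-fluctuation test for
   numeric/ordinal covariates, a chi-square aggregation for nominal ones;
3. Bonferroni-correct across candidates; if the smallest adjusted p-value
   is below alpha, split on that covariate at the cutpoint maximizing the
   sum of the two children's log-likelihoods, and recurse.

Trees are optionally post-pruned bottom-up by AIC: a split whose subtree
does not lower the AIC relative to its parent node's own fit is collapsed.

The supLM null distribution (sup over t in [trim, 1-trim] of
||B(t)||^2 / (t(1-t)) for a k-dimensional Brownian bridge B) is obtained by
Monte-Carlo simulation with a fixed internal seed, cached per (k, trim).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .llbt import GroupSpec, LLBTFit, fit_llbt, fit_llbt_grouped, loglik_and_scores
from .rankings import (
    ItemSet,
    PatternTable,
    Ranking,
    enumerate_patterns,
    ranking_to_pattern,
    score_matrix,
)

__all__ = [
    "Covariate",
    "InstabilityResult",
    "SplitRule",
    "TreeNode",
    "TreeConfig",
    "PartitionTree",
    "instability_test",
    "select_split_variable",
    "search_cutpoint",
    "grow_tree",
    "prune_aic",
    "predict_node",
    "tree_to_dict",
    "tree_to_json",
    "tree_to_dot",
    "read_covariates_csv",
]

_NULL_SIM_SEED = 20220810  # fixed: the null distribution is not data-dependent
_NULL_SIM_REPS = 20000
_NULL_SIM_GRID = 200
_suplm_null_cache: dict[tuple[int, float], np.ndarray] = {}


@dataclass
class Covariate:
    """A subject-level splitting candidate.

    ``kind`` is one of ``numeric``, ``ordinal``, ``nominal``; Likert-scale
    items are ordinal (threshold splits like "IP <= 2").  ``levels`` gives
    the declared level order for ordinal covariates and the category set
    for nominal ones.
    """

    name: str
    kind: str
    values: dict[str, object]
    levels: tuple | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("numeric", "ordinal", "nominal"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.kind in ("ordinal", "nominal") and self.levels is None:
            levels = sorted(set(self.values.values()))
            self.levels = tuple(levels)
        if self.levels is not None:
            self.levels = tuple(self.levels)

    def numeric_codes(self, subject_ids: Sequence[str]) -> np.ndarray:
        """Values as floats (ordinal: index into the declared level order)."""
        if self.kind == "ordinal":
            code = {lv: i for i, lv in enumerate(self.levels)}
            return np.array([code[self.values[s]] for s in subject_ids], float)
        return np.array([float(self.values[s]) for s in subject_ids])

    def raw(self, subject_ids: Sequence[str]) -> list:
        return [self.values[s] for s in subject_ids]


@dataclass(frozen=True)
class InstabilityResult:
    covariate: str
    statistic: float
    p_value: float
    p_adjusted: float
    test: str  # "supLM" | "chisq" | "none"
    no_variation: bool = False


@dataclass(frozen=True)
class SplitRule:
    """Binary split rule: numeric/ordinal send ``value <= cutpoint`` left;
    nominal send ``value in left_categories`` left.  The cutpoint is the
    left child's largest observed value, so rules print as "age <= 15"."""

    covariate: str
    kind: str
    cutpoint: Optional[float] = None
    left_categories: Optional[tuple] = None

    def goes_left(self, value) -> bool:
        if self.kind == "nominal":
            return value in self.left_categories
        return float(value) <= self.cutpoint

    def describe(self, invert: bool = False) -> str:
        if self.kind == "nominal":
            cats = ",".join(map(str, self.left_categories))
            return f"{self.covariate} not in {{{cats}}}" if invert else (
                f"{self.covariate} in {{{cats}}}"
            )
        c = self.cutpoint
        c_str = f"{c:g}"
        return f"{self.covariate} > {c_str}" if invert else f"{self.covariate} <= {c_str}"


@dataclass
class TreeConfig:
    """Growth and pruning controls.

    ``alpha`` is the significance level for the (Bonferroni-adjusted)
    instability tests; ``minsize`` the minimum number of subjects per node
    (the study design used 40 for the large student sample and 4 for the
    small expert/novice sample); ``prune`` is ``"aic"`` or ``"none"``.
    """

    alpha: float = 0.05
    minsize: int = 40
    max_depth: int = 10
    prune: str = "aic"
    bonferroni: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.minsize < 1:
            raise ValueError("minsize must be >= 1")
        if self.prune not in ("aic", "none"):
            raise ValueError("prune must be 'aic' or 'none'")


@dataclass
class TreeNode:
    id: int
    depth: int
    subject_ids: list[str]
    fit: LLBTFit
    instability: list[InstabilityResult] = field(default_factory=list)
    split: Optional[SplitRule] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None
    fit_failed: bool = False
    weights: Optional[list[float]] = None  # case weights per subject id

    @property
    def is_terminal(self) -> bool:
        return self.split is None

    @property
    def n(self) -> int:
        if self.weights is not None:
            return int(round(sum(self.weights)))
        return len(self.subject_ids)


@dataclass
class PartitionTree:
    root: TreeNode
    items: ItemSet
    covariate_names: list[str]
    config: TreeConfig
    groups: Optional[GroupSpec] = None
    n_dropped_missing: int = 0

    def nodes(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def rec(nd: TreeNode) -> None:
            out.append(nd)
            if nd.left is not None:
                rec(nd.left)
                rec(nd.right)

        rec(self.root)
        return out

    def terminal_nodes(self) -> list[TreeNode]:
        return [nd for nd in self.nodes() if nd.is_terminal]

    def split_rules(self) -> list[SplitRule]:
        return [nd.split for nd in self.nodes() if nd.split is not None]


# ---------------------------------------------------------------------------
# Parameter-instability tests

def _suplm_null(k: int, trim: float) -> np.ndarray:
    """Sorted Monte-Carlo sample of the supLM limit distribution.

    sup over t in [trim, 1-trim] of ||B(t)||^2 / (t(1-t)), B a k-dim
    Brownian bridge, simulated on a fixed grid with a fixed seed so the
    test is deterministic across runs and processes.
    """
    key = (k, round(trim, 4))
    if key not in _suplm_null_cache:
        rng = np.random.default_rng(_NULL_SIM_SEED + 1000 * k)
        m = _NULL_SIM_GRID
        t = np.arange(1, m) / m
        mask = (t >= trim) & (t <= 1.0 - trim)
        sups = np.empty(_NULL_SIM_REPS)
        block = 250
        for start in range(0, _NULL_SIM_REPS, block):
            b = min(block, _NULL_SIM_REPS - start)
            incr = rng.standard_normal((b, m - 1, k)) / np.sqrt(m)
            w = np.cumsum(incr, axis=1)
            bridge = w - t[None, :, None] * w[:, -1:, :]
            stat = (bridge**2).sum(axis=2) / (t * (1.0 - t))[None, :]
            sups[start : start + b] = stat[:, mask].max(axis=1)
        _suplm_null_cache[key] = np.sort(sups)
    return _suplm_null_cache[key]


def _decorrelate(scores: np.ndarray) -> np.ndarray:
    """Whiten score rows with the inverse square root of the empirical info."""
    n = scores.shape[0]
    info = scores.T @ scores / n
    vals, vecs = np.linalg.eigh(info)
    tol = max(vals.max(), 0.0) * 1e-10 + 1e-300
    inv_sqrt = np.where(vals > tol, 1.0 / np.sqrt(np.maximum(vals, tol)), 0.0)
    return scores @ (vecs * inv_sqrt) @ vecs.T


def instability_test(
    scores: np.ndarray,
    covariate: Covariate,
    subject_ids: Sequence[str],
    minsize: int,
    n_tests: int = 1,
) -> InstabilityResult:
    """Score-fluctuation test of parameter stability along one covariate.

    ``scores`` is the (n, k) matrix of per-subject score contributions
    evaluated at the node MLE (rows sum to ~0 per column).  Numeric and
    ordinal covariates use the supLM statistic over the cumulative sums of
    covariate-ordered, decorrelated scores with trimming
    ``max(0.1, minsize/n)``; nominal covariates aggregate scores within
    categories into a chi-square statistic with (C-1)*k degrees of freedom.
    ``n_tests`` is the Bonferroni multiplicity (number of covariates tested
    at the node).
    """
    n, k = scores.shape
    if n < 2 * minsize:
        raise ValueError(f"need at least 2*minsize={2 * minsize} subjects, got {n}")
    raw = covariate.raw(subject_ids)
    if len(set(raw)) <= 1:
        return InstabilityResult(covariate.name, 0.0, 1.0, 1.0, "none", True)
    E = _decorrelate(scores)

    if covariate.kind == "nominal":
        cats = covariate.levels
        stat = 0.0
        for c in cats:
            idx = [i for i, v in enumerate(raw) if v == c]
            if not idx:
                continue
            s = E[idx].sum(axis=0)
            stat += float(s @ s) / len(idx)
        df = (len(cats) - 1) * k
        p = float(chi2.sf(stat, df))
        test = "chisq"
    else:
        vals = covariate.numeric_codes(subject_ids)
        # stable sort: by value, ties broken by input (subject) order
        order = np.argsort(vals, kind="stable")
        csum = np.cumsum(E[order], axis=0) / np.sqrt(n)
        t = np.arange(1, n + 1) / n
        trim = max(0.1, minsize / n)
        mask = (t >= trim) & (t <= 1.0 - trim)
        mask[-1] = False  # t = 1 is not a cut
        if not mask.any():
            return InstabilityResult(covariate.name, 0.0, 1.0, 1.0, "supLM", True)
        proc = (csum[mask] ** 2).sum(axis=1) / (t[mask] * (1.0 - t[mask]))
        stat = float(proc.max())
        null = _suplm_null(k, trim)
        p = float((1 + np.sum(null >= stat)) / (1 + null.size))
        test = "supLM"

    p_adj = min(1.0, p * n_tests)
    return InstabilityResult(covariate.name, stat, p, p_adj, test)


def select_split_variable(
    results: Sequence[InstabilityResult], alpha: float
) -> Optional[str]:
    """The covariate with smallest adjusted p-value, if it beats alpha.

    Ties break by position in ``results`` (covariate declaration order).
    """
    if not results:
        raise ValueError("no instability results")
    best = min(range(len(results)), key=lambda i: results[i].p_adjusted)
    if results[best].p_adjusted < alpha:
        return results[best].covariate
    return None


# ---------------------------------------------------------------------------
# Cutpoint search

def _maximize_reduced(
    t_u: np.ndarray, n: float, U: np.ndarray, theta0: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Quick Newton maximization of the reduced loglik for a child node.

    ``theta0`` warm-starts the iteration; during a cutpoint sweep each
    candidate differs from its neighbour by one subject, so a warm start
    converges in one or two steps.
    """
    from scipy.special import logsumexp

    k = U.shape[1]
    theta = np.zeros(k) if theta0 is None else theta0.copy()
    eta = U @ theta
    ll = float(theta @ t_u - n * logsumexp(eta))
    for _ in range(60):
        eta = U @ theta
        lz = logsumexp(eta)
        p = np.exp(eta - lz)
        mean_u = p @ U
        grad = t_u - n * mean_u
        if np.max(np.abs(grad)) < 1e-6 * max(1.0, n):
            break
        cov_u = (U * p[:, None]).T @ U - np.outer(mean_u, mean_u)
        try:
            step = np.linalg.solve(n * cov_u, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.pinv(n * cov_u) @ grad
        for _h in range(30):
            cand = theta + step
            eta_c = U @ cand
            ll_c = cand @ t_u - n * logsumexp(eta_c)
            if ll_c >= ll - 1e-12:
                theta, ll = cand, ll_c
                break
            step *= 0.5
        else:
            break
        if np.max(np.abs(theta)) > 40:  # separated child: loglik has plateaued
            break
    eta = U @ theta
    return float(theta @ t_u - n * logsumexp(eta)), theta


def search_cutpoint(
    pattern_rows: np.ndarray,
    covariate: Covariate,
    subject_ids: Sequence[str],
    minsize: int,
    items: ItemSet,
    group_codes: np.ndarray | None = None,
    n_groups: int = 1,
    weights: np.ndarray | None = None,
) -> SplitRule:
    """Best admissible binary split on one covariate.

    Maximizes the sum of the two children's maximized log-likelihoods
    (summed over focal groups when present).  ``pattern_rows`` holds each
    subject's pattern index into the enumeration order; optional case
    ``weights`` (e.g. bootstrap multiplicities) scale each subject's
    contribution and the minsize admissibility check.  Numeric/ordinal
    cutpoints are reported as the left child's maximum observed value;
    nominal splits enumerate all binary partitions of the (<= 10) levels.
    """
    n_items = items.n_items
    X = score_matrix(n_items)
    U_full = X[:, :-1] - X[:, -1:]
    n = len(subject_ids)
    if group_codes is None:
        group_codes = np.zeros(n, dtype=int)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)

    Usub = U_full[pattern_rows] * w[:, None]  # weighted per-subject stats

    def children_loglik(left_mask: np.ndarray) -> float | None:
        nl = w[left_mask].sum()
        nr = w.sum() - nl
        if nl < minsize or nr < minsize:
            return None
        total = 0.0
        for g in range(n_groups):
            gm = group_codes == g
            for mask in (left_mask & gm, (~left_mask) & gm):
                ng = w[mask].sum()
                if ng == 0:
                    continue
                t_u = Usub[mask].sum(axis=0)
                total += _maximize_reduced(t_u, float(ng), U_full)[0]
        return total

    if covariate.kind == "nominal":
        levels = covariate.levels
        if len(levels) > 10:
            raise ValueError(
                f"nominal covariate {covariate.name!r} has more than 10 levels"
            )
        raw = covariate.raw(subject_ids)
        best_ll, best_subset = -np.inf, None
        # fix the first level's side to avoid mirrored duplicates
        rest = levels[1:]
        for bits in range(2 ** len(rest)):
            subset = (levels[0],) + tuple(
                lv for i, lv in enumerate(rest) if bits >> i & 1
            )
            if len(subset) == len(levels):
                continue
            left_mask = np.array([v in subset for v in raw])
            ll = children_loglik(left_mask)
            if ll is not None and ll > best_ll:
                best_ll, best_subset = ll, subset
        if best_subset is None:
            raise ValueError(f"node unsplittable on {covariate.name!r}")
        return SplitRule(covariate.name, "nominal", left_categories=best_subset)

    vals = covariate.numeric_codes(subject_ids)
    order = np.argsort(vals, kind="stable")
    sorted_vals = vals[order]
    wsort = w[order]
    cumw = np.concatenate([[0.0], np.cumsum(wsort)])
    W = cumw[-1]
    # candidate boundaries: between distinct consecutive sorted values,
    # with both (weighted) children at least minsize
    boundaries = [
        i
        for i in range(n - 1)
        if sorted_vals[i] < sorted_vals[i + 1]
        and cumw[i + 1] >= minsize
        and W - cumw[i + 1] >= minsize
    ]
    if not boundaries:
        raise ValueError(f"node unsplittable on {covariate.name!r}")
    # prefix sums over sorted subjects make each candidate's sufficient
    # statistics O(1); warm-started Newton makes each child fit ~1 step
    Usort = Usub[order]
    gsort = group_codes[order]
    k = U_full.shape[1]
    prefix = {}
    for g in range(n_groups):
        gm = (gsort == g)[:, None] * Usort
        prefix[g] = (
            np.vstack([np.zeros(k), np.cumsum(gm, axis=0)]),
            np.concatenate([[0.0], np.cumsum(wsort * (gsort == g))]),
        )
    warm: dict[tuple[int, str], np.ndarray] = {}
    best_ll, best_i = -np.inf, None
    for i in boundaries:
        total = 0.0
        for g in range(n_groups):
            psum, pcnt = prefix[g]
            for side, t_u, ng in (
                ("L", psum[i + 1], pcnt[i + 1]),
                ("R", psum[-1] - psum[i + 1], pcnt[-1] - pcnt[i + 1]),
            ):
                if ng == 0:
                    continue
                ll, theta = _maximize_reduced(
                    t_u, float(ng), U_full, warm.get((g, side))
                )
                warm[(g, side)] = theta
                total += ll
        if total > best_ll:
            best_ll, best_i = total, i
    cut_code = sorted_vals[best_i]
    if covariate.kind == "ordinal":
        # report the level itself (codes index the declared order)
        cutpoint = float(cut_code)
        try:
            lvl = covariate.levels[int(cut_code)]
            cutpoint = float(lvl)
        except (TypeError, ValueError):
            cutpoint = float(cut_code)
    else:
        cutpoint = float(cut_code)
    return SplitRule(covariate.name, covariate.kind, cutpoint=cutpoint)


# ---------------------------------------------------------------------------
# Tree growth

def _node_scores(
    fit: LLBTFit,
    pats: list,
    subject_ids: Sequence[str],
    groups: Optional[GroupSpec],
) -> np.ndarray:
    """Reduced per-subject scores (n, k) for the instability tests.

    Ungrouped: k = J-1 (reduced coordinates u = x[:-1] - x[-1], centred).
    Grouped: block-sparse over G blocks of J-1 — each subject contributes
    only to its own group's block, centred at that group's MLE.
    """
    n_items = fit.items.n_items
    if groups is None:
        _, s_full = loglik_and_scores(fit, pats)
        return s_full[:, :-1] - s_full[:, -1:]
    labels = groups.labels
    k = (n_items - 1) * len(labels)
    out = np.zeros((len(subject_ids), k))
    for gi, g in enumerate(labels):
        idx = [i for i, s in enumerate(subject_ids) if groups.group_of_subject[s] == g]
        if not idx:
            continue
        gfit = LLBTFit(
            items=fit.items,
            lambda_=fit.group_lambda[g],
            pi=fit.group_pi[g],
            loglik=0.0,
            n=len(idx),
            n_params=n_items - 1,
            cov_lambda=np.zeros((n_items, n_items)),
            converged=True,
            separated=False,
            normalization=0.0,
        )
        _, s_full = loglik_and_scores(gfit, [pats[i] for i in idx])
        out[np.ix_(idx, range(gi * (n_items - 1), (gi + 1) * (n_items - 1)))] = (
            s_full[:, :-1] - s_full[:, -1:]
        )
    return out


def _fit_node(
    pats: list,
    subject_ids: Sequence[str],
    items: ItemSet,
    groups: Optional[GroupSpec],
    weights: np.ndarray,
) -> LLBTFit:
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        if groups is None:
            counts: dict = {}
            for p, wi in zip(pats, weights):
                counts[p] = counts.get(p, 0) + wi
            return fit_llbt(PatternTable(items, counts))
        tables: dict[str, dict] = {g: {} for g in groups.labels}
        for p, s, wi in zip(pats, subject_ids, weights):
            g = groups.group_of_subject[s]
            tables[g][p] = tables[g].get(p, 0) + wi
        return fit_llbt_grouped(
            {g: PatternTable(items, c) for g, c in tables.items()}, groups
        )


def grow_tree(
    rankings: Sequence[Ranking],
    covariates: Sequence[Covariate],
    items: ItemSet,
    config: TreeConfig,
    groups: Optional[GroupSpec] = None,
    weights: Optional[dict[str, float]] = None,
) -> PartitionTree:
    """Grow (and per config AIC-prune) a Bradley-Terry partition tree.

    Subjects missing any candidate covariate value (or, when grouped, a
    group assignment) are dropped at entry; the count is recorded on the
    returned tree.  The focal group variable is never a splitting
    candidate.  A node whose fit does not converge becomes terminal with
    ``fit_failed`` set.

    ``weights`` maps subject ids to non-negative case weights (bootstrap
    multiplicities); node sizes, fits, instability tests and cutpoint
    admissibility all operate on weighted counts, with each unique subject
    a single exchangeable unit in the fluctuation tests.
    """
    cov_names = [c.name for c in covariates]
    if len(set(cov_names)) != len(cov_names):
        raise ValueError("duplicate covariate names")

    usable: list[Ranking] = []
    dropped = 0
    for r in rankings:
        sid = r.subject_id
        ok = all(
            sid in c.values and not _is_missing(c.values[sid]) for c in covariates
        )
        if groups is not None:
            ok = ok and sid in groups.group_of_subject
        if weights is not None:
            ok = ok and weights.get(sid, 0) > 0
        if ok:
            usable.append(r)
        else:
            dropped += 1
    if not usable:
        raise ValueError("no subjects with complete covariates")

    pattern_index = {p: i for i, p in enumerate(enumerate_patterns(items.n_items))}
    pats_all = [ranking_to_pattern(r, items) for r in usable]
    sid_all = [r.subject_id for r in usable]
    w_all = np.array(
        [1.0 if weights is None else float(weights[s]) for s in sid_all]
    )

    counter = {"next_id": 1}

    def build(idx: list[int], depth: int) -> TreeNode:
        node_id = counter["next_id"]
        counter["next_id"] += 1
        sids = [sid_all[i] for i in idx]
        pats = [pats_all[i] for i in idx]
        w = w_all[idx]
        fit = _fit_node(pats, sids, items, groups, w)
        node = TreeNode(node_id, depth, sids, fit, weights=w.tolist())
        if not fit.converged:
            node.fit_failed = True
            return node
        if w.sum() < 2 * config.minsize or depth >= config.max_depth:
            return node
        scores = _node_scores(fit, pats, sids, groups) * w[:, None]
        n_tests = len(covariates) if config.bonferroni else 1
        try:
            results = [
                instability_test(scores, c, sids, config.minsize, n_tests)
                for c in covariates
            ]
        except ValueError:
            return node  # too few unique subjects to order
        node.instability = results
        chosen = select_split_variable(results, config.alpha)
        if chosen is None:
            return node
        cov = next(c for c in covariates if c.name == chosen)
        rows = np.array([pattern_index[p] for p in pats], dtype=int)
        gcodes, n_groups = None, 1
        if groups is not None:
            glabels = groups.labels
            gmap = {g: i for i, g in enumerate(glabels)}
            gcodes = np.array([gmap[groups.group_of_subject[s]] for s in sids])
            n_groups = len(glabels)
        try:
            rule = search_cutpoint(
                rows, cov, sids, config.minsize, items, gcodes, n_groups, w
            )
        except ValueError:
            return node
        if cov.kind == "ordinal":
            code = {lv: i for i, lv in enumerate(cov.levels)}
            go_left = [
                code[cov.values[s]] <= _ordinal_cut_code(rule, cov) for s in sids
            ]
        else:
            go_left = [rule.goes_left(cov.values[s]) for s in sids]
        left_idx = [i for i, gl in zip(idx, go_left) if gl]
        right_idx = [i for i, gl in zip(idx, go_left) if not gl]
        if w_all[left_idx].sum() < config.minsize or (
            w_all[right_idx].sum() < config.minsize
        ):
            return node  # pragma: no cover - search guarantees admissibility
        node.split = rule
        node.left = build(left_idx, depth + 1)
        node.right = build(right_idx, depth + 1)
        return node

    root = build(list(range(len(usable))), 0)
    tree = PartitionTree(root, items, cov_names, config, groups, dropped)
    if config.prune == "aic":
        tree = prune_aic(tree)
    return tree


def _ordinal_cut_code(rule: SplitRule, cov: Covariate) -> float:
    """Cut threshold in code space for an ordinal rule (levels may be numeric)."""
    for i, lv in enumerate(cov.levels):
        try:
            if float(lv) == rule.cutpoint:
                return i
        except (TypeError, ValueError):
            continue
    return rule.cutpoint


def _is_missing(v) -> bool:
    try:
        return v is None or (isinstance(v, float) and np.isnan(v))
    except TypeError:  # pragma: no cover
        return False


# ---------------------------------------------------------------------------
# AIC post-pruning

def _subtree_aic(node: TreeNode) -> float:
    """Total AIC of the subtree's terminal fits: -2 sum loglik + 2 sum params."""
    if node.is_terminal:
        return node.fit.aic
    return _subtree_aic(node.left) + _subtree_aic(node.right)


def prune_aic(tree: PartitionTree) -> PartitionTree:
    """Collapse, bottom-up, every split whose subtree does not lower the AIC.

    A split survives only if the combined AIC of its (pruned) descendants
    is strictly lower than the parent node's own fit AIC.  Idempotent; the
    total AIC of the terminal fits never increases.
    """

    def rec(node: TreeNode) -> None:
        if node.is_terminal:
            return
        rec(node.left)
        rec(node.right)
        if _subtree_aic(node.left) + _subtree_aic(node.right) >= node.fit.aic:
            node.split = None
            node.left = None
            node.right = None

    rec(tree.root)
    return tree


# ---------------------------------------------------------------------------
# Prediction & serialization

def predict_node(tree: PartitionTree, values: dict[str, object]):
    """Route one subject's covariate values to a terminal node.

    Returns ``(node_id, worth)`` where ``worth`` is that node's worth
    vector (a dict of per-group worths for grouped trees).  Values equal
    to a cutpoint go left (the <= convention).
    """
    node = tree.root
    while not node.is_terminal:
        rule = node.split
        if rule.covariate not in values or _is_missing(values[rule.covariate]):
            raise KeyError(
                f"missing value for covariate {rule.covariate!r} used in a rule"
            )
        node = node.left if rule.goes_left(values[rule.covariate]) else node.right
    worth = node.fit.group_pi if node.fit.group_pi is not None else node.fit.pi
    return node.id, worth


SCHEMA_VERSION = 1


def _node_dict(node: TreeNode, path: list[str], level: float = 0.95) -> list[dict]:
    from .llbt import worth_ci

    d: dict = {
        "id": node.id,
        "depth": node.depth,
        "n": node.n,
        "terminal": node.is_terminal,
        "path": list(path),
        "pi": node.fit.pi.tolist(),
        "loglik": node.fit.loglik,
        "aic": node.fit.aic,
        "converged": bool(node.fit.converged),
        "separated": bool(node.fit.separated),
        "instability": [
            {
                "covariate": r.covariate,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "p_adjusted": r.p_adjusted,
                "test": r.test,
            }
            for r in node.instability
        ],
    }
    if node.fit.converged:
        d["ci"] = {"level": level, "bounds": worth_ci(node.fit, level).tolist()}
    if node.fit.group_pi is not None:
        d["group_pi"] = {g: v.tolist() for g, v in node.fit.group_pi.items()}
    if node.split is not None:
        d["split"] = {
            "covariate": node.split.covariate,
            "kind": node.split.kind,
            "cutpoint": node.split.cutpoint,
            "left_categories": list(node.split.left_categories)
            if node.split.left_categories
            else None,
        }
        out = [d]
        out += _node_dict(node.left, path + [node.split.describe(False)], level)
        out += _node_dict(node.right, path + [node.split.describe(True)], level)
        return out
    return [d]


def tree_to_dict(tree: PartitionTree, level: float = 0.95) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "items": list(tree.items.labels),
        "attribute": tree.items.attribute_name,
        "covariates": list(tree.covariate_names),
        "config": {
            "alpha": tree.config.alpha,
            "minsize": tree.config.minsize,
            "max_depth": tree.config.max_depth,
            "prune": tree.config.prune,
        },
        "n_dropped_missing": tree.n_dropped_missing,
        "nodes": _node_dict(tree.root, [], level),
    }


def tree_to_json(tree: PartitionTree, path, level: float = 0.95) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(tree_to_dict(tree, level), fh, indent=2)


def tree_to_dot(tree: PartitionTree, log_scale: bool = False) -> str:
    """DOT rendering: inner nodes show the split, leaves a worth profile.

    ``log_scale`` prints log10 worths, which separates near-degenerate
    profiles visually.
    """
    lines = [
        "digraph bttree {",
        '  node [shape=box, fontname="Helvetica"];',
    ]

    def fmt(p: float) -> str:
        if log_scale:
            return f"{np.log10(max(p, 1e-300)):.2f}"
        return f"{p:.3g}" if p >= 1e-3 else f"{p:.2e}"

    def rec(node: TreeNode) -> None:
        if node.is_terminal:
            rows = "\\n".join(
                f"{lab}: {fmt(p)}" for lab, p in zip(tree.items.labels, node.fit.pi)
            )
            title = "log10 worth" if log_scale else "worth"
            lines.append(
                f'  n{node.id} [label="node {node.id} (n={node.n})\\n{title}\\n{rows}"];'
            )
        else:
            lines.append(
                f'  n{node.id} [label="node {node.id} (n={node.n})\\n'
                f'{node.split.covariate}"];'
            )
            lines.append(
                f'  n{node.id} -> n{node.left.id} [label="{node.split.describe(False)}"];'
            )
            lines.append(
                f'  n{node.id} -> n{node.right.id} [label="{node.split.describe(True)}"];'
            )
            rec(node.left)
            rec(node.right)

    rec(tree.root)
    lines.append("}")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Covariates CSV

def read_covariates_csv(
    path, declarations: Sequence[tuple[str, str]], *, delimiter: str = ","
) -> list[Covariate]:
    """Read a covariates table; ``declarations`` is [(name, kind), ...].

    Kinds are declared, never inferred: Likert columns are ordinal even
    though their cells look numeric.
    """
    df = pd.read_csv(path, sep=delimiter, encoding="utf-8")
    if "subject_id" not in df.columns:
        raise ValueError("covariates file needs a 'subject_id' column")
    df["subject_id"] = df["subject_id"].astype(str)
    out = []
    for name, kind in declarations:
        if name not in df.columns:
            raise ValueError(f"declared covariate {name!r} not in file")
        col = df.set_index("subject_id")[name]
        if kind == "numeric":
            values = {s: float(v) for s, v in col.items()}
        else:
            values = {s: v for s, v in col.items()}
        out.append(Covariate(name, kind, values))
    return out
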