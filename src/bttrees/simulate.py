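"""Synthetic ranking studies with covariate-driven preference subgroups.

The generator emulates the structure the partitioning analysis assumes: a
population partitioned by covariate rules into leaves, each leaf holding
its own Bradley-Terry worth vector (optionally per focal group), with
every subject's complete ranking drawn from the *pattern* distribution
p(y | lambda(pi)) by exact enumeration of the J! transitive patterns and a
categorical draw.  Sampling from the pattern distribution — rather than a
Plackett-Luce sequential scheme, which induces a different law on rankings
for J >= 3 — means generator and estimator share one probability model, so
parameter- and split-recovery tests are meaningful.

Covariates are sampled independently per subject: rounded/truncated
normals and log-normals for numeric columns, categorical draws for
ordinal (Likert) and nominal ones.  The bundled study-emulation design
(see ``data/study_emulation.yaml``) mirrors the marginals of the study
this package models: ~987 students, age ~ N(15.35, 2.96^2) rounded and
truncated at 13, a log-normal task time, gender, art grade, ten Likert
columns, and four leaves defined by task time and interest in visual
puzzles with distinct worth vectors.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .llbt import lambda_from_worth, pattern_distribution
from .partition import Covariate
from .rankings import ItemSet, Ranking, enumerate_patterns, pattern_to_ranking

__all__ = [
    "CovariateSpec",
    "LeafSpec",
    "GroupDesign",
    "SimDesign",
    "sample_covariates",
    "sample_ranking",
    "simulate_study",
    "covariates_from_frame",
    "design_from_yaml",
    "design_to_yaml",
    "load_design_file",
    "study_emulation_design",
    "write_covariates_csv",
]


@dataclass
class CovariateSpec:
    """Distributional spec for one covariate column.

    numeric: ``mean``/``sd`` (optionally ``lognormal: true``, in which case
    they are the mean/sd on the *natural* scale and are converted to
    log-scale parameters), with optional ``round`` (to integers) and
    ``minimum``/``maximum`` truncation by rejection.
    ordinal / nominal: ``levels`` plus ``probs`` summing to 1.
    """

    name: str
    kind: str
    mean: Optional[float] = None
    sd: Optional[float] = None
    lognormal: bool = False
    round: bool = False
    minimum: Optional[float] = None
    maximum: Optional[float] = None
    levels: Optional[tuple] = None
    probs: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if self.kind not in ("numeric", "ordinal", "nominal"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.kind == "numeric":
            if self.mean is None or self.sd is None or self.sd <= 0:
                raise ValueError(f"{self.name}: numeric spec needs mean and sd > 0")
        else:
            if not self.levels or not self.probs:
                raise ValueError(f"{self.name}: categorical spec needs levels+probs")
            if len(self.levels) != len(self.probs):
                raise ValueError(f"{self.name}: levels/probs length mismatch")
            if abs(sum(self.probs) - 1.0) > 1e-8:
                raise ValueError(f"{self.name}: probs must sum to 1")
            self.levels = tuple(self.levels)
            self.probs = tuple(float(p) for p in self.probs)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind != "numeric":
            idx = rng.choice(len(self.levels), size=n, p=self.probs)
            return np.array([self.levels[i] for i in idx], dtype=object)
        if self.lognormal:
            # natural-scale mean/sd -> log-scale mu/sigma
            cv2 = (self.sd / self.mean) ** 2
            sigma = np.sqrt(np.log1p(cv2))
            mu = np.log(self.mean) - 0.5 * sigma**2

            def draw(m: int) -> np.ndarray:
                return rng.lognormal(mu, sigma, size=m)

        else:

            def draw(m: int) -> np.ndarray:
                return rng.normal(self.mean, self.sd, size=m)

        out = draw(n)
        if self.round:
            out = np.round(out)
        lo = -np.inf if self.minimum is None else self.minimum
        hi = np.inf if self.maximum is None else self.maximum
        bad = (out < lo) | (out > hi)
        # rejection keeps the in-range shape intact (no boundary atom)
        for _ in range(1000):
            if not bad.any():
                break
            repl = draw(int(bad.sum()))
            if self.round:
                repl = np.round(repl)
            out[bad] = repl
            bad = (out < lo) | (out > hi)
        else:  # pragma: no cover
            raise RuntimeError(f"{self.name}: truncation bounds too tight")
        return out


_OPS = {"<=", ">", "in", "not_in"}


@dataclass
class LeafSpec:
    """One subgroup: a conjunction of covariate conditions and its worths.

    ``conditions`` is a list of (covariate, op, value) with op in
    {"<=", ">", "in", "not_in"}.  ``group_worths`` optionally overrides the
    worth vector per focal-group label.
    """

    conditions: list[tuple[str, str, object]]
    worth: np.ndarray
    group_worths: Optional[dict[str, np.ndarray]] = None

    def __post_init__(self) -> None:
        self.worth = np.asarray(self.worth, dtype=float)
        if np.any(self.worth <= 0) or abs(self.worth.sum() - 1.0) > 1e-8:
            raise ValueError("leaf worth must be positive and sum to 1")
        for c in self.conditions:
            if len(c) != 3 or c[1] not in _OPS:
                raise ValueError(f"bad leaf condition {c!r}")
        if self.group_worths is not None:
            self.group_worths = {
                g: np.asarray(w, dtype=float) for g, w in self.group_worths.items()
            }
            for g, w in self.group_worths.items():
                if np.any(w <= 0) or abs(w.sum() - 1.0) > 1e-8:
                    raise ValueError(f"group {g!r} worth must be on the open simplex")

    def matches(self, row: dict) -> bool:
        for cov, op, val in self.conditions:
            v = row[cov]
            if op == "<=" and not float(v) <= val:
                return False
            if op == ">" and not float(v) > val:
                return False
            if op == "in" and v not in val:
                return False
            if op == "not_in" and v in val:
                return False
        return True


@dataclass
class GroupDesign:
    """Focal-group spec: labels with sampling proportions; first label is
    the reference group."""

    name: str
    labels: tuple[str, ...]
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.probs) or abs(sum(self.probs) - 1) > 1e-8:
            raise ValueError("group labels/probs mismatch or probs not summing to 1")


@dataclass
class SimDesign:
    """A complete synthetic study: items, covariate distributions, leaf
    rules with worth vectors, sample size and seed."""

    items: ItemSet
    covariates: list[CovariateSpec]
    leaves: list[LeafSpec]
    n: int
    seed: int = 0
    groups: Optional[GroupDesign] = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not self.leaves:
            raise ValueError("need at least one leaf")
        j = self.items.n_items
        for leaf in self.leaves:
            if leaf.worth.size != j:
                raise ValueError("leaf worth length != number of items")


def sample_covariates(design: SimDesign, rng=None) -> pd.DataFrame:
    """Sample the covariates table (n rows, indexed by subject_id)."""
    rng = np.random.default_rng(design.seed) if rng is None else rng
    n = design.n
    sids = [f"s{i + 1:05d}" for i in range(n)]
    data = {"subject_id": sids}
    for spec in design.covariates:
        data[spec.name] = spec.sample(n, rng)
    df = pd.DataFrame(data)
    if design.groups is not None:
        idx = rng.choice(len(design.groups.labels), size=n, p=design.groups.probs)
        df[design.groups.name] = [design.groups.labels[i] for i in idx]
    return df


_PATTERN_CACHE: dict[int, list] = {}


def _patterns(n_items: int) -> list:
    if n_items not in _PATTERN_CACHE:
        _PATTERN_CACHE[n_items] = enumerate_patterns(n_items)
    return _PATTERN_CACHE[n_items]


def sample_ranking(
    worth: np.ndarray, rng: np.random.Generator, items: ItemSet, subject_id: str = ""
) -> Ranking:
    """Draw one ranking from the exact pattern distribution of a worth vector."""
    lam = lambda_from_worth(np.asarray(worth, dtype=float))
    probs = pattern_distribution(lam)
    idx = rng.choice(probs.size, p=probs)
    return pattern_to_ranking(_patterns(items.n_items)[idx], items, subject_id)


def _leaf_of(design: SimDesign, row: dict) -> LeafSpec:
    hits = [leaf for leaf in design.leaves if leaf.matches(row)]
    if len(hits) != 1:
        raise ValueError(
            f"design leaves are not mutually exclusive and exhaustive: covariate "
            f"row {row!r} matches {len(hits)} leaves"
        )
    return hits[0]


def simulate_study(design: SimDesign) -> tuple[list[Ranking], pd.DataFrame]:
    """Sample covariates, route each subject to its leaf, draw its ranking.

    Returns the rankings and the covariates table (including the focal
    group column when the design has one).  Fully reproducible from
    ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    cov_df = sample_covariates(design, rng)
    # exhaustiveness check up front, before any ranking is drawn
    leaves = [
        _leaf_of(design, row) for row in cov_df.to_dict("records")
    ]
    # vectorized draw: group subjects by (leaf, group label) and sample
    # each block from its pattern distribution in one categorical call
    rankings: list[Optional[Ranking]] = [None] * design.n
    pats = _patterns(design.items.n_items)
    blocks: dict[tuple[int, Optional[str]], list[int]] = {}
    leaf_ids = {id(leaf): k for k, leaf in enumerate(design.leaves)}
    for i, leaf in enumerate(leaves):
        glabel = (
            cov_df[design.groups.name].iloc[i] if design.groups is not None else None
        )
        blocks.setdefault((leaf_ids[id(leaf)], glabel), []).append(i)
    for (leaf_k, glabel), idxs in sorted(
        blocks.items(), key=lambda kv: (kv[0][0], str(kv[0][1]))
    ):
        leaf = design.leaves[leaf_k]
        worth = leaf.worth
        if glabel is not None and leaf.group_worths is not None:
            worth = leaf.group_worths.get(glabel, leaf.worth)
        probs = pattern_distribution(lambda_from_worth(worth))
        draws = rng.choice(probs.size, size=len(idxs), p=probs)
        for i, d in zip(idxs, draws):
            sid = cov_df["subject_id"].iloc[i]
            rankings[i] = pattern_to_ranking(pats[d], design.items, sid)
    return list(rankings), cov_df


def covariates_from_frame(
    df: pd.DataFrame, declarations: Sequence[tuple[str, str]]
) -> list[Covariate]:
    """Build Covariate objects from a covariates table + (name, kind) pairs."""
    out = []
    for name, kind in declarations:
        col = df.set_index("subject_id")[name]
        values = {str(s): v for s, v in col.items()}
        out.append(Covariate(name, kind, values))
    return out


def write_covariates_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# YAML design configs

def design_from_yaml(text: str) -> SimDesign:
    d = yaml.safe_load(text)
    items = ItemSet(
        tuple(d["items"]["labels"]),
        d["items"].get("attribute", ""),
        tuple(d["items"]["intended_order"]) if d["items"].get("intended_order") else None,
    )
    covs = []
    for c in d["covariates"]:
        covs.append(
            CovariateSpec(
                name=c["name"],
                kind=c["kind"],
                mean=c.get("mean"),
                sd=c.get("sd"),
                lognormal=bool(c.get("lognormal", False)),
                round=bool(c.get("round", False)),
                minimum=c.get("minimum"),
                maximum=c.get("maximum"),
                levels=tuple(c["levels"]) if "levels" in c else None,
                probs=tuple(c["probs"]) if "probs" in c else None,
            )
        )
    leaves = []
    for lf in d["leaves"]:
        conditions = []
        for cond in lf.get("conditions", []):
            val = cond["value"]
            if cond["op"] in ("in", "not_in"):
                val = tuple(val) if isinstance(val, (list, tuple)) else (val,)
            conditions.append((cond["covariate"], cond["op"], val))
        leaves.append(
            LeafSpec(
                conditions,
                np.asarray(lf["worth"], dtype=float),
                {g: np.asarray(w, dtype=float) for g, w in lf["group_worths"].items()}
                if "group_worths" in lf
                else None,
            )
        )
    groups = None
    if "groups" in d and d["groups"]:
        g = d["groups"]
        groups = GroupDesign(g["name"], tuple(g["labels"]), tuple(g["probs"]))
    return SimDesign(
        items=items,
        covariates=covs,
        leaves=leaves,
        n=int(d["n"]),
        seed=int(d.get("seed", 0)),
        groups=groups,
    )


def design_to_yaml(design: SimDesign) -> str:
    d: dict = {
        "items": {
            "labels": list(design.items.labels),
            "attribute": design.items.attribute_name,
            "intended_order": list(design.items.intended_order)
            if design.items.intended_order
            else None,
        },
        "n": design.n,
        "seed": design.seed,
        "covariates": [],
        "leaves": [],
    }
    for c in design.covariates:
        cd: dict = {"name": c.name, "kind": c.kind}
        if c.kind == "numeric":
            cd.update(mean=c.mean, sd=c.sd)
            if c.lognormal:
                cd["lognormal"] = True
            if c.round:
                cd["round"] = True
            if c.minimum is not None:
                cd["minimum"] = c.minimum
            if c.maximum is not None:
                cd["maximum"] = c.maximum
        else:
            cd["levels"] = list(c.levels)
            cd["probs"] = list(c.probs)
        d["covariates"].append(cd)
    for lf in design.leaves:
        ld: dict = {
            "conditions": [
                {
                    "covariate": cov,
                    "op": op,
                    "value": list(val) if isinstance(val, tuple) else val,
                }
                for cov, op, val in lf.conditions
            ],
            "worth": [float(x) for x in lf.worth],
        }
        if lf.group_worths is not None:
            ld["group_worths"] = {
                g: [float(x) for x in w] for g, w in lf.group_worths.items()
            }
        d["leaves"].append(ld)
    if design.groups is not None:
        d["groups"] = {
            "name": design.groups.name,
            "labels": list(design.groups.labels),
            "probs": list(design.groups.probs),
        }
    return yaml.safe_dump(d, sort_keys=False)


def load_design_file(path) -> SimDesign:
    with open(path, encoding="utf-8") as fh:
        return design_from_yaml(fh.read())


def study_emulation_design(n: Optional[int] = None, seed: int = 0) -> SimDesign:
    """The bundled study-emulation design (see module docstring).

    ``n`` overrides the design's sample size (default 987); ``seed`` sets
    the generator seed.
    """
    ref = importlib.resources.files("bttrees").joinpath("data/study_emulation.yaml")
    design = design_from_yaml(ref.read_text(encoding="utf-8"))
    if n is not None:
        design.n = n
    design.seed = seed
    return design
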