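"""Family-aware splits, Hungarian demographic matching, lifestyle composites."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "SplitPlan",
    "MatchedPairs",
    "family_kfold",
    "replicated_family_kfold",
    "hungarian_match",
    "lifestyle_composite",
    "DEFAULT_MATCH_COVARIATES",
]

DEFAULT_MATCH_COVARIATES = ("age", "sex", "rms")


@dataclass
class SplitPlan:
    """Fold assignment keeping members of a family together."""

    n_folds: int
    assignments: pd.Series  # subject_id -> fold (0-based)
    seed: int
    replicate_id: int = 0

    def fold_ids(self, fold: int) -> list[str]:
        return list(self.assignments.index[self.assignments == fold])


@dataclass
class MatchedPairs:
    """Optimal demographic matching of group A to a subset of group B."""

    pairs: list[tuple[str, str]] = field(default_factory=list)
    cost: float = 0.0


def family_kfold(cohort: pd.DataFrame, n_folds: int = 5, seed: int = 0) -> SplitPlan:
    """Deal families to folds, largest first, balancing fold sizes greedily.

    Families are shuffled with ``seed`` (deciding ties among equal-sized
    families), then assigned in decreasing size order to the currently
    smallest fold, so all members of a family share a fold and fold sizes
    differ by at most the largest family size.
    """
    families = cohort.groupby("family_id")["subject_id"].apply(list)
    if n_folds > len(families):
        raise ValueError(f"n_folds={n_folds} exceeds the {len(families)} families")
    rng = np.random.default_rng(seed)
    order = families.index.to_numpy()[rng.permutation(len(families))]
    order = sorted(order, key=lambda f: -len(families[f]))
    fold_sizes = np.zeros(n_folds, dtype=int)
    assign: dict[str, int] = {}
    for fam in order:
        fold = int(np.argmin(fold_sizes))
        for sid in families[fam]:
            assign[sid] = fold
        fold_sizes[fold] += len(families[fam])
    series = pd.Series(assign, name="fold").loc[cohort["subject_id"]]
    return SplitPlan(n_folds=n_folds, assignments=series, seed=seed)


def replicated_family_kfold(
    cohort: pd.DataFrame, n_folds: int = 5, n_replicates: int = 40, seed: int = 0
) -> list[SplitPlan]:
    """Seeded replicate splits (counter-derived seeds), deduplicating exact
    assignment repeats."""
    plans: list[SplitPlan] = []
    seen: set[tuple] = set()
    counter = 0
    while len(plans) < n_replicates and counter < 50 * n_replicates:
        plan = family_kfold(cohort, n_folds, seed=(seed * 1000 + counter) & 0x7FFFFFFF)
        key = tuple(plan.assignments.to_numpy())
        counter += 1
        if key in seen:
            continue
        seen.add(key)
        plan.replicate_id = len(plans)
        plans.append(plan)
    if len(plans) < n_replicates:
        raise RuntimeError("could not generate enough distinct splits")
    return plans


def hungarian_match(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_MATCH_COVARIATES,
) -> MatchedPairs:
    """Optimal A-B pairing by Euclidean distance of z-scored covariates.

    Covariates are z-scored over the union of both groups (binary covariates
    such as sex enter as 0/1 before scaling); the assignment minimizing the
    total cost over all |A| pairings is found by the Hungarian algorithm.
    Requires |B| >= |A|; every A subject is paired with a distinct B subject.
    """
    if len(group_b) < len(group_a):
        raise ValueError("group B must be at least as large as group A")
    for c in covariates:
        if c not in group_a.columns or c not in group_b.columns:
            raise KeyError(f"missing covariate {c!r}")
    xa = group_a.loc[:, list(covariates)].to_numpy(dtype=float)
    xb = group_b.loc[:, list(covariates)].to_numpy(dtype=float)
    pooled = np.vstack([xa, xb])
    mu, sd = pooled.mean(axis=0), pooled.std(axis=0)
    sd[sd == 0] = 1.0
    za, zb = (xa - mu) / sd, (xb - mu) / sd
    cost = np.sqrt(((za[:, None, :] - zb[None, :, :]) ** 2).sum(axis=-1))
    rows, cols = linear_sum_assignment(cost)
    ids_a = group_a["subject_id"].to_numpy()
    ids_b = group_b["subject_id"].to_numpy()
    pairs = [(ids_a[i], ids_b[j]) for i, j in zip(rows, cols)]
    return MatchedPairs(pairs=pairs, cost=float(cost[rows, cols].sum()))


def matched_classification_split(
    cohort: pd.DataFrame,
    n_folds: int = 5,
    seed: int = 0,
    covariates: tuple[str, ...] = DEFAULT_MATCH_COVARIATES,
) -> tuple[MatchedPairs, pd.Series]:
    """Family-aware fold split of group A with per-fold Hungarian matching.

    Group A subjects (group == 1) are split into family-respecting folds;
    within each fold, A members are optimally matched against the still
    unused group-B pool, so every B subject appears in at most one pair.
    Both members of a pair share the A member's fold.

    Returns ``(pairs, fold_assignments)`` where fold_assignments covers the
    matched subjects only.
    """
    grp_a = cohort[cohort["group"] == 1]
    grp_b = cohort[cohort["group"] == 0]
    plan = family_kfold(grp_a, n_folds, seed)
    all_pairs: list[tuple[str, str]] = []
    total_cost = 0.0
    fold_of: dict[str, int] = {}
    used_b: set[str] = set()
    for fold in range(n_folds):
        ids_a = plan.fold_ids(fold)
        sub_a = grp_a[grp_a["subject_id"].isin(ids_a)]
        avail_b = grp_b[~grp_b["subject_id"].isin(used_b)]
        matched = hungarian_match(sub_a, avail_b, covariates)
        total_cost += matched.cost
        for sid_a, sid_b in matched.pairs:
            all_pairs.append((sid_a, sid_b))
            used_b.add(sid_b)
            fold_of[sid_a] = fold
            fold_of[sid_b] = fold
    return MatchedPairs(pairs=all_pairs, cost=total_cost), pd.Series(fold_of, name="fold")


def lifestyle_composite(
    measures: pd.DataFrame, factor_map: dict[str, str]
) -> pd.DataFrame:
    """Per-factor mean of available (non-missing) item scores per subject.

    ``factor_map`` maps item column names to factor names. A factor is
    missing for a subject only when all its items are missing.
    """
    unknown = [item for item in factor_map if item not in measures.columns]
    if unknown:
        raise KeyError(f"unknown item(s) in factor_map: {unknown}")
    factors = sorted(set(factor_map.values()))
    out = {}
    for factor in factors:
        items = [i for i, f in factor_map.items() if f == factor]
        out[factor] = measures[items].mean(axis=1, skipna=True)
    return pd.DataFrame(out, index=measures.index)
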