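"""Variable selection and validation procedures layered over the GDM fit:
category-wise forward selection, permutation importance, backward selection,
locality jackknife of spline fits, locality cross-validation and a
whole-model permutation significance test.

All locality-level randomization moves every sample of a locality together:
environmental values are attributes of localities, and train/test and
jackknife partitions are drawn over localities, not samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gdmcore import (GEO, GDMModel, SitePairTable, fit_gdm, predict_gdm)

__all__ = [
    "SelectionTrace",
    "SplineEnvelope",
    "forward_select",
    "permutation_importance",
    "backward_select",
    "jackknife_splines",
    "cross_validate",
    "model_significance",
    "train_pair_share",
    "limiting_train_share",
]


@dataclass
class SelectionTrace:
    """Ordered record of selection steps."""

    steps: list[dict] = field(default_factory=list)

    def add(self, **kwargs) -> None:
        self.steps.append(dict(step=len(self.steps), **kwargs))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)


@dataclass
class SplineEnvelope:
    """Full-data spline curves plus jackknife-replicate curves per predictor."""

    grids: dict[str, np.ndarray]
    full: dict[str, np.ndarray]
    replicates: dict[str, np.ndarray]  # (n_reps, n_grid), NaN rows = skipped
    n_skipped: int = 0
    full_intercept: float = 0.0
    intercepts: np.ndarray | None = None  # (n_reps,), NaN = skipped


def _set_env_values(pairs: SitePairTable, variable: str,
                    mapping: dict) -> SitePairTable:
    """Return a copy of the pair table with one variable's endpoint columns
    rebuilt from a locality -> value mapping."""
    df = pairs.df.copy()
    df[f"{variable}_s1"] = df["loc1"].map(mapping).to_numpy()
    df[f"{variable}_s2"] = df["loc2"].map(mapping).to_numpy()
    return SitePairTable(df, list(pairs.predictors), pairs.scale, pairs.min_geo_km)


def _env_locality_values(env: pd.DataFrame, variable: str) -> pd.Series:
    sub = env[env["variable"] == variable]
    return sub.set_index("locality")["value"]


def forward_select(pairs: SitePairTable, env: pd.DataFrame,
                   threshold_pct: float = 1.0,
                   base_predictors: tuple[str, ...] = (GEO,),
                   within_category_base: str = "growing",
                   **fit_kwargs) -> tuple[SelectionTrace, list[str]]:
    """Greedy forward selection of environmental variables within each
    category.

    Starting from the geography-only model, each category is searched
    independently: at every step the variable giving the largest gain in
    deviance explained (percentage points) is added; the search stops when
    the best gain drops below ``threshold_pct``. With
    ``within_category_base="base"`` every candidate is instead evaluated
    against the geography-only model alone. The union of per-category
    selections is returned as the candidate variable set.
    """
    if within_category_base not in ("growing", "base"):
        raise ValueError("within_category_base must be 'growing' or 'base'")
    base_model = fit_gdm(pairs, list(base_predictors), **fit_kwargs)
    base_de = base_model.deviance_explained
    trace = SelectionTrace()
    trace.add(action="base", variable=None, category=None,
              deviance_explained=base_de, gain=None)
    candidates: list[str] = []
    cat_map = env.groupby("category")["variable"].unique().to_dict()
    for category in sorted(cat_map):
        selected: list[str] = []
        remaining = sorted(set(cat_map[category]))
        current_de = base_de
        while remaining:
            gains = {}
            for var in remaining:
                preds = list(base_predictors) + (selected if within_category_base == "growing" else []) + [var]
                m = fit_gdm(pairs, preds, **fit_kwargs)
                ref = current_de if within_category_base == "growing" else base_de
                gains[var] = m.deviance_explained - ref
            best_var = max(sorted(gains), key=lambda v: gains[v])
            if gains[best_var] < threshold_pct:
                break
            selected.append(best_var)
            current_de += gains[best_var]
            trace.add(action="add", variable=best_var, category=category,
                      deviance_explained=current_de, gain=gains[best_var])
            remaining.remove(best_var)
        candidates.extend(selected)
    return trace, candidates


def permutation_importance(pairs: SitePairTable, env: pd.DataFrame,
                           predictors: list[str], variable: str,
                           n_perm: int = 100, seed: int | None = None,
                           **fit_kwargs) -> tuple[float | None, float]:
    """Locality-permutation importance of one variable in a fitted model.

    Each replicate shuffles the variable's values across localities (all
    other predictors and geography untouched), rebuilds the endpoint columns
    and refits. Importance is ``100 * (DE_full - mean DE_perm) / DE_full``
    (None when DE_full <= 0); p is the upper-tail permutation probability.
    """
    if variable not in predictors:
        raise ValueError(f"{variable!r} is not in the model predictors")
    rng = np.random.default_rng(seed)
    full = fit_gdm(pairs, predictors, **fit_kwargs)
    de_full = full.deviance_explained
    values = _env_locality_values(env, variable)
    localities = values.index.to_numpy()
    de_perm = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(len(localities))
        mapping = dict(zip(localities, values.to_numpy()[perm]))
        p_pairs = _set_env_values(pairs, variable, mapping)
        de_perm[b] = fit_gdm(p_pairs, predictors, **fit_kwargs).deviance_explained
    p = (1.0 + np.sum(de_perm >= de_full - 1e-12)) / (n_perm + 1.0)
    if de_full <= 0:
        return None, float(p)
    importance = 100.0 * (de_full - de_perm.mean()) / de_full
    return float(importance), float(p)


def backward_select(pairs: SitePairTable, env: pd.DataFrame,
                    candidate_vars: list[str], n_perm: int = 100,
                    target_size: int | None = None, seed: int | None = None,
                    base_predictors: tuple[str, ...] = (GEO,),
                    **fit_kwargs) -> tuple[SelectionTrace, GDMModel, int | None]:
    """Backward elimination from a candidate variable set.

    At each step the variable whose removal costs the least deviance explained
    is dropped (ties broken by lower permutation importance, then
    lexicographically). With ``target_size`` the process stops there;
    otherwise it runs down to the geography-only model and the returned
    suggested size is the point of largest second difference ("inflection")
    in the deviance-explained trajectory — reported, never silently applied.

    Returns (trace, model refitted at target/suggested size, suggested size).
    """
    rng = np.random.default_rng(seed)
    current = list(candidate_vars)
    trace = SelectionTrace()
    de_path = []
    model = full_model = fit_gdm(pairs, list(base_predictors) + current, **fit_kwargs)
    trace.add(action="full", variable=None,
              deviance_explained=model.deviance_explained, n_vars=len(current),
              p_value=None)
    de_path.append((len(current), model.deviance_explained))
    sizes_models = {len(current): list(current)}
    while current and (target_size is None or len(current) > target_size):
        losses = {}
        for var in current:
            preds = list(base_predictors) + [v for v in current if v != var]
            m = fit_gdm(pairs, preds, **fit_kwargs)
            losses[var] = model.deviance_explained - m.deviance_explained
        min_loss = min(losses.values())
        tied = sorted(v for v in losses if abs(losses[v] - min_loss) < 1e-9)
        if len(tied) > 1 and n_perm > 0:
            imps = {}
            for v in tied:
                imp, _ = permutation_importance(
                    pairs, env, list(base_predictors) + current, v,
                    n_perm=n_perm, seed=int(rng.integers(2**31)), **fit_kwargs)
                imps[v] = -math.inf if imp is None else imp
            drop = min(tied, key=lambda v: (imps[v], v))
        else:
            drop = tied[0]
        current.remove(drop)
        model = fit_gdm(pairs, list(base_predictors) + current, **fit_kwargs)
        trace.add(action="drop", variable=drop,
                  deviance_explained=model.deviance_explained,
                  n_vars=len(current), p_value=None)
        de_path.append((len(current), model.deviance_explained))
        sizes_models[len(current)] = list(current)

    suggested = None
    if target_size is None:
        if len(de_path) >= 3:
            # de_path runs from largest size down to 0; second difference of
            # DE versus size flags where one more removal starts to hurt
            sizes = [s for s, _ in de_path][::-1]
            des = [d for _, d in de_path][::-1]
            d2 = np.diff(des, 2)
            suggested = sizes[int(np.argmax(d2)) + 1]
        # the suggestion is reported, not applied: return the full candidate
        # model so callers decide the cut themselves
        model = full_model
    return trace, model, suggested


def jackknife_splines(pairs: SitePairTable, predictors: list[str],
                      drop_fraction: float = 0.1, n_reps: int = 100,
                      seed: int | None = None, n_grid: int = 200,
                      min_pairs: int = 10, reuse_knots: bool = True,
                      **fit_kwargs) -> SplineEnvelope:
    """Locality-deletion jackknife of spline fits.

    Each replicate removes all samples from ``ceil(drop_fraction * L)``
    randomly chosen localities, refits on the surviving pairs, and evaluates
    every predictor's spline on a common grid (the full-data knot range).
    With ``reuse_knots`` (default) replicates share the full-data knots so
    their curves are directly comparable; otherwise each replicate recomputes
    quantile knots from its own pairs. Replicates left with fewer than
    ``min_pairs`` pairs are skipped and counted.
    """
    localities = np.unique(np.concatenate([pairs.df["loc1"], pairs.df["loc2"]]))
    n_loc = len(localities)
    n_drop = math.ceil(drop_fraction * n_loc)
    if n_loc < math.ceil(1.0 / drop_fraction):
        raise ValueError(f"need >= {math.ceil(1/drop_fraction)} localities, have {n_loc}")
    rng = np.random.default_rng(seed)
    full = fit_gdm(pairs, predictors, **fit_kwargs)
    grids = {p: np.linspace(b.knots[0], b.knots[-1], n_grid)
             for p, b in full.bases.items()}
    full_curves = {p: full.spline(p, grids[p]) for p in grids}
    reps = {p: np.full((n_reps, n_grid), np.nan) for p in grids}
    intercepts = np.full(n_reps, np.nan)
    n_skipped = 0
    for b in range(n_reps):
        dropped = set(rng.choice(localities, size=n_drop, replace=False))
        mask = (~pairs.df["loc1"].isin(dropped)
                & ~pairs.df["loc2"].isin(dropped)).to_numpy()
        sub = pairs.subset(mask)
        if sub.n_pairs < min_pairs:
            n_skipped += 1
            continue
        m = fit_gdm(sub, predictors,
                    bases=full.bases if reuse_knots else None, **fit_kwargs)
        intercepts[b] = m.intercept
        for p in grids:
            if p in m.bases:
                reps[p][b] = m.spline(p, grids[p])
    return SplineEnvelope(grids, full_curves, reps, n_skipped,
                          full_intercept=full.intercept, intercepts=intercepts)


def cross_validate(pairs: SitePairTable, predictors: list[str],
                   test_fraction: float = 0.1, n_reps: int = 100,
                   seed: int | None = None, min_pairs: int = 10,
                   **fit_kwargs) -> pd.DataFrame:
    """Locality-partition cross-validation.

    Localities are split (1 - test_fraction) : test_fraction. Training pairs
    have both endpoints in training localities; test pairs have at least one
    endpoint in a test locality, so with a 90/10 locality split the pair
    ratio tends to 81:19 as the number of localities grows. Each replicate
    reports the squared Pearson correlation between predicted and observed
    test dissimilarities.
    """
    localities = np.unique(np.concatenate([pairs.df["loc1"], pairs.df["loc2"]]))
    n_loc = len(localities)
    if n_loc < 10:
        raise ValueError("need >= 10 localities for locality cross-validation")
    n_test = max(1, round(test_fraction * n_loc))
    rng = np.random.default_rng(seed)
    rows = []
    for b in range(n_reps):
        test_loc = set(rng.choice(localities, size=n_test, replace=False))
        in_test1 = pairs.df["loc1"].isin(test_loc).to_numpy()
        in_test2 = pairs.df["loc2"].isin(test_loc).to_numpy()
        train = pairs.subset(~in_test1 & ~in_test2)
        test = pairs.subset(in_test1 | in_test2)
        if test.n_pairs == 0 or train.n_pairs < min_pairs:
            rows.append({"replicate": b, "r2": np.nan, "n_train": train.n_pairs,
                         "n_test": test.n_pairs, "status": "skipped"})
            continue
        model = fit_gdm(train, predictors, **fit_kwargs)
        pred = predict_gdm(model, test)
        obs = test.df["distance"].to_numpy()
        if np.std(pred) == 0 or np.std(obs) == 0:
            r2 = np.nan
            status = "degenerate"
        else:
            r2 = float(np.corrcoef(pred, obs)[0, 1] ** 2)
            status = "ok"
        rows.append({"replicate": b, "r2": r2, "n_train": train.n_pairs,
                     "n_test": test.n_pairs, "status": status})
    return pd.DataFrame(rows)


def model_significance(pairs: SitePairTable, env: pd.DataFrame,
                       predictors: list[str], n_perm: int = 100,
                       seed: int | None = None, **fit_kwargs) -> float:
    """Whole-model permutation test of the environmental signal.

    All environmental variables' locality assignments are permuted jointly
    (one shared locality permutation; geography intact), the model refitted,
    and ``p = (1 + #{DE_perm >= DE_full}) / (n_perm + 1)`` returned.
    """
    env_vars = [p for p in predictors if p != GEO]
    if not env_vars:
        raise ValueError("model has no environmental variables to permute")
    rng = np.random.default_rng(seed)
    de_full = fit_gdm(pairs, predictors, **fit_kwargs).deviance_explained
    loc_values = {v: _env_locality_values(env, v) for v in env_vars}
    localities = loc_values[env_vars[0]].index.to_numpy()
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(localities))
        p_pairs = pairs
        for v in env_vars:
            mapping = dict(zip(localities, loc_values[v].to_numpy()[perm]))
            p_pairs = _set_env_values(p_pairs, v, mapping)
        de = fit_gdm(p_pairs, predictors, **fit_kwargs).deviance_explained
        if de >= de_full - 1e-12:
            count += 1
    return (1.0 + count) / (n_perm + 1.0)


def train_pair_share(n_localities: int, train_fraction: float = 0.9) -> float:
    """Fraction of all locality pairs with both members in the training
    partition: C(t,2)/C(L,2) with t = ceil(train_fraction * L)."""
    L = n_localities
    if L < 2:
        raise ValueError("need >= 2 localities")
    t = math.ceil(train_fraction * L)
    return (t * (t - 1)) / (L * (L - 1))


def limiting_train_share(train_fraction: float = 0.9,
                         n_localities: int = 10**9) -> float:
    """Large-L limit of :func:`train_pair_share`, as a percentage."""
    return 100.0 * train_pair_share(n_localities, train_fraction)
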