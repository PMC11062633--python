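"""Binding statistics for probed peptide arrays.

Four readouts summarize a probed array:

* the single-mark binding profile — mean +/- SEM intensity over spots
  carrying exactly one modification;
* duplicate reproducibility — Pearson correlation of spot intensities
  between the two subarray replicates;
* the specificity factor per mark — mean intensity of spots carrying the
  mark divided by the mean of spots lacking it (>1 means preferential
  binding);
* combinatorial co-mark interaction effects — the ratio of mean binding
  to target-mark spots with vs. without a co-occurring second mark,
  with a permutation test on the difference of stratum means and
  Benjamini-Hochberg correction across all tested pairs.

Statistics pool (spot, subarray) observations rather than pre-averaging
duplicates, which preserves within-spot variance for the SEM.  Because
every spot contributes the same number of replicate values, pooled stratum
means coincide with means of per-spot means; permutations therefore
relabel spots, keeping a spot's replicates together.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from itertools import combinations
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .array_model import ArrayLayout, ModificationTag, as_tag, spots_with
from .array_quantify import ArrayResult
from .errors import CorrelationError, StratificationError

DIRECTION_ENHANCING = "enhancing"
DIRECTION_INHIBITING = "inhibiting"
DIRECTION_NEUTRAL = "neutral"


def _spot_values(result: ArrayResult, column: str = "normalized") -> pd.DataFrame:
    """Non-control observations: one row per (spot, subarray)."""
    obs = result.observations()
    return obs.loc[:, ["spot_id", "subarray", column]].rename(columns={column: "value"})


def single_mod_profile(result: ArrayResult, column: str = "normalized") -> pd.DataFrame:
    """Mean +/- SEM binding per mark over spots carrying exactly that mark.

    Returns a frame indexed by mark name with columns mean, sem, n
    (n counts pooled (spot, subarray) observations), sorted by descending
    mean with alphabetical tie-break.
    """
    obs = _spot_values(result, column)
    peptides = result.layout.peptides()
    mark_of = {
        sid: str(next(iter(spec.mods)))
        for sid, spec in peptides.items()
        if len(spec.mods) == 1
    }
    single = obs[obs["spot_id"].isin(mark_of)].copy()
    if single.empty:
        raise StratificationError("layout has no single-mark spots")
    single["mark"] = single["spot_id"].map(mark_of)
    grouped = single.groupby("mark")["value"]
    prof = pd.DataFrame(
        {
            "mean": grouped.mean(),
            "sem": grouped.apply(
                lambda v: float(v.std(ddof=1) / math.sqrt(len(v))) if len(v) > 1 else 0.0
            ),
            "n": grouped.size(),
        }
    )
    prof = prof.reset_index().sort_values(
        ["mean", "mark"], ascending=[False, True], ignore_index=True
    )
    return prof.set_index("mark")


def duplicate_correlation(result: ArrayResult, column: str = "corrected") -> float:
    """Pearson r between spot-matched intensities of the two subarrays."""
    if result.layout.n_subarrays != 2:
        raise StratificationError(
            f"duplicate correlation needs exactly 2 subarrays, got {result.layout.n_subarrays}"
        )
    obs = _spot_values(result, column)
    wide = obs.pivot(index="spot_id", columns="subarray", values="value").dropna()
    if len(wide) < 3:
        raise CorrelationError("need at least 3 paired spots")
    a, b = wide[1].to_numpy(), wide[2].to_numpy()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise CorrelationError("correlation undefined: constant subarray")
    return float(stats.pearsonr(a, b).statistic)


def specificity_factor(
    result: ArrayResult,
    mark: Union[str, ModificationTag],
    column: str = "normalized",
) -> float:
    """Mean intensity of spots carrying ``mark`` over the mean of spots lacking it.

    Controls are excluded from both strata; observations pool subarrays.
    """
    mark = as_tag(mark)
    with_ids = set(spots_with(result.layout, include={mark}))
    without_ids = set(result.layout.spot_ids()) - with_ids
    if not with_ids or not without_ids:
        raise StratificationError(f"mark {mark}: with/without stratum is empty")
    obs = _spot_values(result, column)
    mean_with = obs.loc[obs["spot_id"].isin(with_ids), "value"].mean()
    mean_without = obs.loc[obs["spot_id"].isin(without_ids), "value"].mean()
    if mean_without <= 0:
        raise StratificationError(f"mark {mark}: without-mark mean is not positive")
    return float(mean_with / mean_without)


def specificity_ranking(
    result: ArrayResult,
    top_n: int | None = None,
    column: str = "normalized",
) -> pd.DataFrame:
    """Per-mark specificity factors, descending, alphabetical tie-break.

    Marks with an empty stratum or a non-positive denominator are skipped
    with a warning.  Columns: mark, factor, n_with, n_without.
    """
    rows = []
    layout = result.layout
    all_ids = set(layout.spot_ids())
    for mark in sorted(layout.marks(), key=str):
        try:
            factor = specificity_factor(result, mark, column=column)
        except StratificationError as exc:
            warnings.warn(f"skipping {mark}: {exc}", stacklevel=2)
            continue
        n_with = len(spots_with(layout, include={mark}))
        rows.append((str(mark), factor, n_with, len(all_ids) - n_with))
    if not rows:
        raise StratificationError("no mark could be evaluated")
    table = pd.DataFrame(rows, columns=["mark", "factor", "n_with", "n_without"])
    table = table.sort_values(
        ["factor", "mark"], ascending=[False, True], ignore_index=True
    )
    if top_n is not None:
        table = table.head(top_n).reset_index(drop=True)
    return table


@dataclass(frozen=True)
class InteractionEffect:
    """Effect of a co-occurring mark on binding to a target mark."""

    target: str
    co_mark: str
    effect_ratio: float
    n_with: int
    n_without: int
    p_value: float
    q_value: float
    direction: str


def _direction(ratio: float, q: float, alpha: float) -> str:
    if q <= alpha and ratio < 1:
        return DIRECTION_INHIBITING
    if q <= alpha and ratio > 1:
        return DIRECTION_ENHANCING
    return DIRECTION_NEUTRAL


def _perm_pvalue(
    with_means: np.ndarray,
    without_means: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
) -> float:
    """Two-sided permutation p for a difference of stratum means.

    Relabels co-mark membership among the pooled spots.  When the number
    of distinct relabelings C(n, k) does not exceed ``n_perm`` the test
    enumerates all of them and the p-value is exact; otherwise it samples
    ``n_perm`` random relabelings with the add-one estimator.
    """
    pooled = np.concatenate([with_means, without_means])
    n, k = len(pooled), len(with_means)
    observed = abs(with_means.mean() - without_means.mean())
    tol = 1e-12 * max(1.0, observed)

    if math.comb(n, k) <= n_perm:
        total = extreme = 0
        for idx in combinations(range(n), k):
            sel = np.zeros(n, dtype=bool)
            sel[list(idx)] = True
            diff = abs(pooled[sel].mean() - pooled[~sel].mean())
            extreme += diff >= observed - tol
            total += 1
        return extreme / total

    extreme = 0
    for _ in range(n_perm):
        sel = np.zeros(n, dtype=bool)
        sel[rng.choice(n, size=k, replace=False)] = True
        diff = abs(pooled[sel].mean() - pooled[~sel].mean())
        extreme += diff >= observed - tol
    return (1 + extreme) / (n_perm + 1)


def interaction_effect(
    result: ArrayResult,
    target: Union[str, ModificationTag],
    co: Union[str, ModificationTag],
    n_perm: int = 9999,
    seed: int = 0,
    alpha: float = 0.05,
    column: str = "normalized",
) -> InteractionEffect:
    """Quantify how co-mark ``co`` modulates binding to ``target`` spots.

    ``effect_ratio`` is mean(target AND co spots) / mean(target without co
    spots); a ratio below 1 with q <= alpha is called inhibiting, above 1
    enhancing.  Other marks on the peptides vary freely.  The reported
    q equals p for a single test; use :func:`interaction_matrix` for a
    family-wise corrected scan.
    """
    target, co = as_tag(target), as_tag(co)
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    with_ids = spots_with(result.layout, include={target, co})
    without_ids = spots_with(result.layout, include={target}, exclude={co})
    if len(with_ids) < 2 or len(without_ids) < 2:
        raise StratificationError(
            f"({target}, {co}): strata too small "
            f"({len(with_ids)} with, {len(without_ids)} without; need >=2 each)"
        )
    obs = _spot_values(result, column)
    spot_means = obs.groupby("spot_id")["value"].mean()
    with_means = spot_means.loc[with_ids].to_numpy()
    without_means = spot_means.loc[without_ids].to_numpy()
    if without_means.mean() <= 0:
        raise StratificationError(f"({target}, {co}): without-co stratum mean not positive")

    ratio = float(with_means.mean() / without_means.mean())
    rng = np.random.default_rng(seed)
    p = _perm_pvalue(with_means, without_means, n_perm, rng)
    return InteractionEffect(
        target=str(target),
        co_mark=str(co),
        effect_ratio=ratio,
        n_with=len(with_ids),
        n_without=len(without_ids),
        p_value=p,
        q_value=p,
        direction=_direction(ratio, p, alpha),
    )


def interaction_matrix(
    result: ArrayResult,
    targets: Iterable[Union[str, ModificationTag]] | None = None,
    co_marks: Iterable[Union[str, ModificationTag]] | None = None,
    n_perm: int = 9999,
    seed: int = 0,
    alpha: float = 0.05,
    column: str = "normalized",
) -> pd.DataFrame:
    """Scan ordered (target, co-mark) pairs with BH-corrected significance.

    Pairs whose strata are too small are skipped with a warning.  q-values
    are Benjamini-Hochberg over all computed p-values; per-pair seeds are
    derived deterministically from ``seed``.
    """
    marks = sorted(result.layout.marks(), key=str)
    targets = [as_tag(m) for m in targets] if targets is not None else marks
    co_marks = [as_tag(m) for m in co_marks] if co_marks is not None else marks

    effects: list[InteractionEffect] = []
    pair_index = 0
    for target in targets:
        for co in co_marks:
            if target == co:
                continue
            pair_seed = np.random.SeedSequence(seed, spawn_key=(pair_index,))
            pair_index += 1
            try:
                eff = interaction_effect(
                    result, target, co,
                    n_perm=n_perm,
                    seed=pair_seed,
                    alpha=alpha,
                    column=column,
                )
            except StratificationError as exc:
                warnings.warn(str(exc), stacklevel=2)
                continue
            effects.append(eff)
    if not effects:
        raise StratificationError("no testable (target, co-mark) pair")

    pvals = np.array([e.p_value for e in effects])
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    effects = [
        replace(e, q_value=float(q), direction=_direction(e.effect_ratio, float(q), alpha))
        for e, q in zip(effects, qvals)
    ]
    return pd.DataFrame(
        {
            "target": [e.target for e in effects],
            "co_mark": [e.co_mark for e in effects],
            "effect_ratio": [e.effect_ratio for e in effects],
            "n_with": [e.n_with for e in effects],
            "n_without": [e.n_without for e in effects],
            "p_value": [e.p_value for e in effects],
            "q_value": [e.q_value for e in effects],
            "direction": [e.direction for e in effects],
        }
    )
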