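"""Validity evidence: rater agreement, item–ability correlations, construct
alignment, Wright map banding, and subgroup fairness (DIF) analysis."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import (
    DegenerateDataError,
    InvalidArgumentError,
    UndefinedStatisticError,
)
from .rasch import RaschFit, fit_rasch_mml
from .scoring import ItemResponseMatrix, RubricConfig


def percent_agreement(r1: np.ndarray, r2: np.ndarray) -> float:
    """Raw agreement between two paired rating vectors, as a percentage."""
    r1 = np.asarray(r1)
    r2 = np.asarray(r2)
    if r1.size == 0 or r1.shape != r2.shape:
        raise InvalidArgumentError("ratings must be non-empty and equal length")
    return 100.0 * float(np.mean(r1 == r2))


def cohens_kappa(r1: np.ndarray, r2: np.ndarray) -> float:
    """Chance-corrected agreement, expected agreement from marginal products."""
    r1 = np.asarray(r1)
    r2 = np.asarray(r2)
    if r1.size == 0 or r1.shape != r2.shape:
        raise InvalidArgumentError("ratings must be non-empty and equal length")
    p_o = float(np.mean(r1 == r2))
    cats = np.union1d(r1, r2)
    p_e = float(sum(np.mean(r1 == c) * np.mean(r2 == c) for c in cats))
    if p_e >= 1.0:
        raise UndefinedStatisticError("chance agreement is 1; kappa undefined")
    return (p_o - p_e) / (1.0 - p_e)


def item_ability_biserial(
    matrix: ItemResponseMatrix | np.ndarray,
    abilities: np.ndarray,
    levels: list[str] | None = None,
    biserial_correction: bool = False,
) -> dict:
    """Point-biserial correlation of each binary item with person ability.

    With ``biserial_correction`` the classic biserial rescaling
    ``r_pb * sqrt(p q) / φ(Φ⁻¹(q))`` is applied. When per-person level
    labels are given, per-level mean abilities and the rank agreement
    between level order and mean ability are also reported.
    """
    x = matrix.scores if isinstance(matrix, ItemResponseMatrix) else np.asarray(matrix)
    theta = np.asarray(abilities, dtype=float)
    if theta.shape[0] != x.shape[0]:
        raise InvalidArgumentError("abilities must align with matrix rows")
    per_item = np.full(x.shape[1], np.nan)
    for i in range(x.shape[1]):
        col = x[:, i].astype(float)
        if col.std() == 0 or theta.std() == 0:
            warnings.warn(f"item {i}: zero variance, correlation undefined", RuntimeWarning)
            continue
        r = float(np.corrcoef(col, theta)[0, 1])
        if biserial_correction:
            p = col.mean()
            q = 1.0 - p
            ordinate = stats.norm.pdf(stats.norm.ppf(q))
            r = r * np.sqrt(p * q) / ordinate
        per_item[i] = r
    out: dict = {"per_item": per_item}
    if levels is not None:
        order = ["below_completion", "completion", "safety", "economy", "optimized"]
        present = [lv for lv in order if lv in levels]
        means = {
            lv: float(theta[[l == lv for l in levels]].mean()) for lv in present
        }
        vals = [means[lv] for lv in present]
        out["level_mean_ability"] = means
        out["level_order_monotone"] = bool(np.all(np.diff(vals) > 0)) if len(vals) > 1 else True
    return out


def construct_alignment_rho(item_levels: np.ndarray, delta: np.ndarray) -> float:
    """Spearman rank correlation (average ranks for ties) between the
    construct level rank of each item and its fitted difficulty."""
    ranks = np.asarray(item_levels, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if ranks.shape != delta.shape:
        raise InvalidArgumentError("item_levels must align with delta")
    finite = np.isfinite(delta)
    ranks, delta = ranks[finite], delta[finite]
    if ranks.size < 2 or np.ptp(delta) == 0 or np.ptp(ranks) == 0:
        raise UndefinedStatisticError("Spearman rho undefined for constant input")
    rho, _ = stats.spearmanr(ranks, delta)
    return float(rho)


@dataclass
class WrightMap:
    """Joint person/item locations on the logit scale, with level labels."""

    person_locations: np.ndarray
    item_locations: list[tuple[int, str, float]]  # (1-based item id, level, logit)
    level_summaries: dict[str, dict[str, float]]


@dataclass
class FairnessResult:
    item_subset: list[int]  # 1-based ids actually analysed
    dropped_items: list[int]
    group_labels: tuple[str, str]
    group_a_locations: np.ndarray
    group_b_locations: np.ndarray
    group_a_se: np.ndarray
    group_b_se: np.ndarray
    pearson_r: float
    ci_overlap: np.ndarray
    score_profile_r: float | None = None

    def __post_init__(self) -> None:
        if not self.item_subset:
            raise InvalidArgumentError("item subset is empty")
        if not -1.0 <= self.pearson_r <= 1.0:
            raise InvalidArgumentError("pearson_r out of range")


def build_wright_map(fit: RaschFit, rubric: RubricConfig | None = None) -> WrightMap:
    """Pair person ability locations with item difficulty locations."""
    rubric = rubric or RubricConfig()
    persons = fit.theta_wle if fit.theta_wle is not None else fit.theta_eap
    if persons is None:
        raise InvalidArgumentError("fit carries no person estimates")
    items = [
        (i + 1, rubric.level_of_item(i + 1), float(fit.delta[i]))
        for i in range(len(fit.delta))
        if np.isfinite(fit.delta[i])
    ]
    summaries: dict[str, dict[str, float]] = {}
    for _, level, loc in items:
        summaries.setdefault(level, {"locs": []})["locs"].append(loc)  # type: ignore[arg-type]
    summaries = {
        lv: {
            "mean": float(np.mean(d["locs"])),
            "min": float(np.min(d["locs"])),
            "max": float(np.max(d["locs"])),
        }
        for lv, d in summaries.items()
    }
    return WrightMap(
        person_locations=np.asarray(persons, dtype=float),
        item_locations=items,
        level_summaries=summaries,
    )


def banding_check(wmap: WrightMap) -> dict:
    """Per-level difficulty bands: are means increasing, do ranges overlap?"""
    order = [lv for lv in ("completion", "safety", "economy", "optimized") if lv in wmap.level_summaries]
    means = [wmap.level_summaries[lv]["mean"] for lv in order]
    overlaps = []
    for a, b in zip(order, order[1:]):
        overlaps.append(
            wmap.level_summaries[a]["max"] >= wmap.level_summaries[b]["min"]
        )
    return {
        "level_order": order,
        "level_means": dict(zip(order, means)),
        "means_strictly_increasing": bool(np.all(np.diff(means) > 0)) if len(means) > 1 else True,
        "adjacent_overlap": dict(zip([f"{a}|{b}" for a, b in zip(order, order[1:])], overlaps)),
        "any_overlap": bool(any(overlaps)),
    }


def fairness_dif(
    matrix: ItemResponseMatrix,
    group_labels: tuple[str, str],
    item_subset: list[int] | None = None,
    z_crit: float = 1.96,
    **fit_kwargs,
) -> FairnessResult:
    """Subgroup DIF check via separate per-group Rasch refits.

    Both groups are anchored to a latent mean of 0; difficulty vectors are
    mean-centered before the cross-group Pearson correlation. Items with
    zero variance in either group are auto-dropped (with a warning). CI
    overlap uses Wald intervals on the centered difficulty estimates.
    """
    if matrix.group is None:
        raise InvalidArgumentError("matrix carries no group labels")
    la, lb = group_labels
    groups = np.asarray(matrix.group)
    rows_a = np.flatnonzero(groups == la)
    rows_b = np.flatnonzero(groups == lb)
    if rows_a.size < 2 or rows_b.size < 2:
        raise InvalidArgumentError("each group needs at least 2 persons")
    items = item_subset or list(range(1, matrix.n_items + 1))
    cols = [i - 1 for i in items]
    xa = matrix.scores[np.ix_(rows_a, cols)]
    xb = matrix.scores[np.ix_(rows_b, cols)]
    keep, dropped = [], []
    for j, item in enumerate(items):
        if 0 < xa[:, j].sum() < xa.shape[0] and 0 < xb[:, j].sum() < xb.shape[0]:
            keep.append(j)
        else:
            dropped.append(item)
    if dropped:
        warnings.warn(
            f"items {dropped} dropped from fairness subset (zero variance in a group)",
            RuntimeWarning,
        )
    if len(keep) < 2:
        raise DegenerateDataError("fewer than 2 analysable items across both groups")
    kept_items = [items[j] for j in keep]
    xa, xb = xa[:, keep], xb[:, keep]
    fit_a = fit_rasch_mml(xa, **fit_kwargs)
    fit_b = fit_rasch_mml(xb, **fit_kwargs)
    da = fit_a.delta - fit_a.delta.mean()
    db = fit_b.delta - fit_b.delta.mean()
    if np.array_equal(da, db):
        r = 1.0  # same data, same fit path
    else:
        r = float(np.clip(np.corrcoef(da, db)[0, 1], -1.0, 1.0))
    lo_a, hi_a = da - z_crit * fit_a.delta_se, da + z_crit * fit_a.delta_se
    lo_b, hi_b = db - z_crit * fit_b.delta_se, db + z_crit * fit_b.delta_se
    overlap = (lo_a <= hi_b) & (lo_b <= hi_a)
    pa, pb = xa.mean(axis=0), xb.mean(axis=0)
    profile_r = (
        float(np.clip(np.corrcoef(pa, pb)[0, 1], -1.0, 1.0))
        if pa.std() > 0 and pb.std() > 0
        else None
    )
    return FairnessResult(
        item_subset=kept_items,
        dropped_items=dropped,
        group_labels=group_labels,
        group_a_locations=da,
        group_b_locations=db,
        group_a_se=fit_a.delta_se,
        group_b_se=fit_b.delta_se,
        pearson_r=r,
        ci_overlap=overlap,
        score_profile_r=profile_r,
    )
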