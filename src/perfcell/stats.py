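"""Voxelwise perfusion-cell correlation statistics and group comparisons.

Within an animal, every perfusion map is compared with the cell-density map
voxel by voxel under a named analysis mask (whole brain, or the cell
accumulation region): Spearman's rank correlation (rho, with the
t-approximation p-value) quantifies monotone association, and the adjusted
R-squared of a simple ordinary-least-squares regression
``density ~ map`` quantifies the fraction of cell-density variance linearly
predictable from perfusion.  Voxels are the correlation unit within an
animal; animals are the unit for the between-group Mann-Whitney comparison
(exact enumeration for small groups) with Benjamini-Hochberg FDR across the
eight maps.

Significance filtering (alpha = 0.05) is recorded as flags on every result
row, never by silently deleting rows.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, asdict
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import mannwhitneyu, rankdata, spearmanr
from statsmodels.stats.multitest import multipletests

from .perfusion import MAP_NAMES, PerfusionMapSet

__all__ = [
    "CorrelationResult",
    "GroupComparisonResult",
    "voxelwise_spearman",
    "ols_adj_r2",
    "analyze_animal",
    "mann_whitney_exact",
    "group_compare",
    "cohort_summary",
    "results_to_frame",
    "ALPHA",
]

ALPHA = 0.05
MASK_NAMES = ("whole_brain", "accumulation")
EXACT_MAX_N = 8  # exact Mann-Whitney enumeration up to this per-group size


@dataclass
class CorrelationResult:
    """One perfusion map vs. cell density under one analysis mask."""

    animal_id: str
    map_name: str
    mask_name: str
    rho: float
    rho_p: float
    adj_r2: float
    ols_p: float
    n_voxels: int
    significant: bool
    excluded: bool


@dataclass
class GroupComparisonResult:
    """Intact-vs-stroke comparison of one per-animal statistic, per map."""

    map_name: str
    statistic: float
    p_raw: float
    p_fdr: float
    significant: bool


def voxelwise_spearman(
    map_values: np.ndarray, density: np.ndarray, mask: np.ndarray
) -> tuple[float, float, int]:
    """Spearman rho between a perfusion map and cell density inside a mask.

    NaN pairs are dropped pairwise; needs at least 3 valid pairs.  A constant
    vector yields NaN rho with a warning.
    """
    x, y, n = _paired(map_values, density, mask)
    if n < 3:
        raise ValueError(f"need >= 3 paired voxels, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: Spearman rho undefined", stacklevel=2)
        return float("nan"), float("nan"), n
    rho, p = spearmanr(x, y)
    return float(rho), float(p), n


def ols_adj_r2(
    map_values: np.ndarray, density: np.ndarray, mask: np.ndarray
) -> tuple[float, float, int]:
    """Adjusted R-squared and overall F-test p of ``density ~ map`` in a mask.

    adj R^2 = 1 - (1 - R^2)(n - 1)/(n - 2) for the single-regressor model;
    needs at least 4 valid pairs so the adjustment is defined.
    """
    x, y, n = _paired(map_values, density, mask)
    if n < 4:
        raise ValueError(f"need >= 4 paired voxels, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance regressor")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return float(model.rsquared_adj), float(model.f_pvalue), n


def _paired(x: np.ndarray, y: np.ndarray, mask: np.ndarray):
    m = np.asarray(mask, bool)
    xv = np.asarray(x, float)[m]
    yv = np.asarray(y, float)[m]
    ok = np.isfinite(xv) & np.isfinite(yv)
    return xv[ok], yv[ok], int(ok.sum())


def analyze_animal(
    maps: PerfusionMapSet,
    density: np.ndarray,
    brain_mask: np.ndarray,
    accumulation_mask: np.ndarray,
    animal_id: str = "animal",
    alpha: float = ALPHA,
) -> List[CorrelationResult]:
    """All 8 maps x {whole-brain, accumulation} correlation results (16 rows).

    The accumulation mask is forced to be a subset of the brain mask.
    Degenerate map/mask combinations are recorded as NaN rows with
    ``excluded=True`` rather than dropped.
    """
    brain = np.asarray(brain_mask, bool)
    accum = np.asarray(accumulation_mask, bool) & brain
    dens = np.asarray(density, float)

    out: List[CorrelationResult] = []
    for map_name in MAP_NAMES:
        arr = getattr(maps, map_name)
        if arr is None:
            raise ValueError(f"map {map_name!r} missing from the map set")
        for mask_name, mask in (("whole_brain", brain), ("accumulation", accum)):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rho, rho_p, n = voxelwise_spearman(arr, dens, mask)
                    r2, ols_p, _ = ols_adj_r2(arr, dens, mask)
                excluded = not (np.isfinite(rho) and np.isfinite(r2))
                significant = (
                    not excluded and rho_p < alpha and ols_p < alpha
                )
            except ValueError:
                rho = rho_p = r2 = ols_p = float("nan")
                n = int(np.count_nonzero(mask))
                excluded, significant = True, False
            out.append(
                CorrelationResult(
                    animal_id=animal_id,
                    map_name=map_name,
                    mask_name=mask_name,
                    rho=rho,
                    rho_p=rho_p,
                    adj_r2=r2,
                    ols_p=ols_p,
                    n_voxels=n,
                    significant=bool(significant),
                    excluded=bool(excluded),
                )
            )
    return out


def mann_whitney_exact(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U by exhaustive enumeration of rank assignments.

    Uses midranks, so ties (including identical groups) are handled exactly;
    the p-value is P(|U - n1*n2/2| >= |u_obs - n1*n2/2|) over all
    C(n1+n2, n1) assignments of the pooled ranks to group 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("empty group")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    mid = n1 * n2 / 2.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    dev_obs = abs(u_obs - mid)
    count = 0
    total = 0
    for combo in itertools.combinations(range(n1 + n2), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2.0
        if abs(u - mid) >= dev_obs - 1e-12:
            count += 1
        total += 1
    return float(u_obs), count / total


def group_compare(
    results_intact: Dict[str, Sequence[float]],
    results_stroke: Dict[str, Sequence[float]],
    alpha: float = ALPHA,
) -> List[GroupComparisonResult]:
    """Per-map intact-vs-stroke Mann-Whitney U with Benjamini-Hochberg FDR.

    Inputs map each perfusion-map name to the per-animal values of the
    compared statistic (e.g. whole-brain Spearman rho).  Exact enumeration is
    used when both groups have <= 8 animals, the normal approximation (with
    tie correction) otherwise.
    """
    maps = [m for m in MAP_NAMES if m in results_intact and m in results_stroke]
    if not maps:
        raise ValueError("no common maps between the two groups")
    stats_, praw = [], []
    for m in maps:
        xi = np.asarray(results_intact[m], float)
        ys = np.asarray(results_stroke[m], float)
        if len(xi) == 0 or len(ys) == 0:
            raise ValueError(f"empty group for map {m!r}")
        if len(xi) < 2 or len(ys) < 2:
            raise ValueError(f"need >= 2 animals per group for map {m!r}")
        xi = xi[np.isfinite(xi)]
        ys = ys[np.isfinite(ys)]
        if len(xi) < 2 or len(ys) < 2:
            # a degenerate map (e.g. constant over the brain) yields NaN rho
            # for most animals; record an untestable row rather than aborting
            warnings.warn(f"map {m!r}: too few finite values, comparison undefined",
                          stacklevel=2)
            stats_.append(float("nan"))
            praw.append(float("nan"))
            continue
        if len(xi) <= EXACT_MAX_N and len(ys) <= EXACT_MAX_N:
            u, p = mann_whitney_exact(xi, ys)
        else:
            res = mannwhitneyu(xi, ys, alternative="two-sided", method="asymptotic")
            u, p = float(res.statistic), float(res.pvalue)
        stats_.append(u)
        praw.append(p)
    praw_arr = np.asarray(praw, float)
    testable = np.isfinite(praw_arr)
    p_fdr = np.full_like(praw_arr, np.nan)
    reject = np.zeros_like(praw_arr, dtype=bool)
    if testable.any():
        rej_t, fdr_t, _, _ = multipletests(praw_arr[testable], alpha=alpha, method="fdr_bh")
        p_fdr[testable] = fdr_t
        reject[testable] = rej_t
    return [
        GroupComparisonResult(
            map_name=m,
            statistic=s,
            p_raw=float(p),
            p_fdr=float(q),
            significant=bool(r),
        )
        for m, s, p, q, r in zip(maps, stats_, praw_arr, p_fdr, reject)
    ]


def pooled_correlation(
    animals: Sequence[dict],
    alpha: float = ALPHA,
) -> List[CorrelationResult]:
    """Pooled-voxel variant: concatenate voxels across animals per map x mask.

    Each entry of ``animals`` is a dict with keys ``maps`` (PerfusionMapSet),
    ``density``, ``brain_mask``, ``accumulation_mask``.  Treats the pooled
    voxels as one sample (the alternative reading of a cohort-level
    correlation); per-animal correlation is the default elsewhere.
    """
    if not animals:
        raise ValueError("no animals to pool")
    out: List[CorrelationResult] = []
    for map_name in MAP_NAMES:
        for mask_name in MASK_NAMES:
            xs, ys = [], []
            for a in animals:
                brain = np.asarray(a["brain_mask"], bool)
                mask = brain if mask_name == "whole_brain" else (
                    np.asarray(a["accumulation_mask"], bool) & brain
                )
                arr = getattr(a["maps"], map_name)
                x, y, _ = _paired(arr, a["density"], mask)
                xs.append(x)
                ys.append(y)
            x = np.concatenate(xs)
            y = np.concatenate(ys)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rho, rho_p, n = voxelwise_spearman(x, y, np.ones_like(x, bool))
                    r2, ols_p, _ = ols_adj_r2(x, y, np.ones_like(x, bool))
                excluded = not (np.isfinite(rho) and np.isfinite(r2))
                significant = not excluded and rho_p < alpha and ols_p < alpha
            except ValueError:
                rho = rho_p = r2 = ols_p = float("nan")
                n, excluded, significant = len(x), True, False
            out.append(
                CorrelationResult(
                    animal_id="pooled",
                    map_name=map_name,
                    mask_name=mask_name,
                    rho=rho,
                    rho_p=rho_p,
                    adj_r2=r2,
                    ols_p=ols_p,
                    n_voxels=n,
                    significant=bool(significant),
                    excluded=bool(excluded),
                )
            )
    return out


def results_to_frame(results: Iterable[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in results])


def cohort_summary(
    results: Iterable[CorrelationResult],
    only_significant: bool = True,
) -> pd.DataFrame:
    """Per map x mask mean and SD of rho and adjusted R^2 over animals.

    Excluded (degenerate) rows are always dropped; with
    ``only_significant=True`` non-significant rows are additionally dropped
    before averaging, mirroring the "only significant parameters included"
    reporting rule.  SD uses the sample convention (ddof=1), reported as 0.0
    for a single animal and flagged via ``n_animals``.
    """
    df = results_to_frame(results)
    if df.empty:
        raise ValueError("no results to summarize")
    df = df[~df["excluded"]]
    if only_significant:
        df = df[df["significant"]]
    rows = []
    for (map_name, mask_name), grp in df.groupby(["map_name", "mask_name"], sort=True):
        n = len(grp)
        rows.append(
            {
                "map_name": map_name,
                "mask_name": mask_name,
                "n_animals": n,
                "rho_mean": grp["rho"].mean(),
                "rho_sd": grp["rho"].std(ddof=1) if n > 1 else 0.0,
                "adj_r2_mean": grp["adj_r2"].mean(),
                "adj_r2_sd": grp["adj_r2"].std(ddof=1) if n > 1 else 0.0,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "map_name",
            "mask_name",
            "n_animals",
            "rho_mean",
            "rho_sd",
            "adj_r2_mean",
            "adj_r2_sd",
        ],
    )
    return out.sort_values(["map_name", "mask_name"]).reset_index(drop=True)
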