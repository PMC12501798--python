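"""Two-proportion power analysis on the arcsine scale, and sample-mass planning.

Proportions are compared on the variance-stabilising arcsine-square-root
scale (Cohen 1988): phi = 2*arcsin(sqrt(p)), effect size
h = |phi_1 - phi_2|. With n_1 and n_2 total objects behind the two
proportions the non-centrality is delta = h * sqrt(n_1*n_2/(n_1+n_2)) and
the two-sided power of the z-test at level alpha is

    P = Phi(delta - z_{1-alpha/2}) + Phi(-delta - z_{1-alpha/2}),

the same computation as R's ``pwr::pwr.2p2n.test``. On top of this the
module provides the breeding-oriented planners: all-pairs power within
sample-mass groups with a target-zone summary, minimum-detectable-difference
curves for proportion pairs centred at a chosen value (0.5 is the
worst case, centres near 0 or 1 the best case), and the minimum pod sample
mass needed to detect a target PE difference given an objects-per-gram rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm


@dataclass(frozen=True)
class PowerTestSpec:
    """Two-sided test configuration: level, target power, derived critical z."""

    alpha: float = 0.05
    target_power: float = 0.8
    max_diff: float = 0.25  # breeding-relevant PE difference bound

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0,1), got {self.alpha}")
        if not 0 < self.target_power < 1:
            raise ValueError(f"target_power must lie in (0,1), got {self.target_power}")

    @property
    def z_crit(self) -> float:
        return float(norm.ppf(1.0 - self.alpha / 2.0))


def arcsine_phi(p: float) -> float:
    """phi = 2*arcsin(sqrt(p)), in [0, pi]."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"proportion must lie in [0,1], got {p}")
    return 2.0 * math.asin(math.sqrt(p))


def cohens_h(p_i, p_j):
    """Absolute arcsine effect size h = |phi_i - phi_j|; symmetric, vectorised."""
    p_i, p_j = np.asarray(p_i, dtype=float), np.asarray(p_j, dtype=float)
    if np.any((p_i < 0) | (p_i > 1) | (p_j < 0) | (p_j > 1)):
        raise ValueError("proportions must lie in [0,1]")
    h = np.abs(2.0 * np.arcsin(np.sqrt(p_i)) - 2.0 * np.arcsin(np.sqrt(p_j)))
    return float(h) if h.ndim == 0 else h


def noncentrality(h, n_i, n_j):
    """delta = h * sqrt(n_i*n_j / (n_i + n_j)) — the unequal-n effective size."""
    h = np.asarray(h, dtype=float)
    n_i, n_j = np.asarray(n_i, dtype=float), np.asarray(n_j, dtype=float)
    d = h * np.sqrt(n_i * n_j / (n_i + n_j))
    return float(d) if d.ndim == 0 else d


def two_prop_power(h, n_i, n_j, spec: PowerTestSpec = PowerTestSpec()):
    """Power of the two-sided arcsine two-proportion z-test.

    Exactly alpha at h = 0; monotone increasing in h and in each n.
    Vectorised over h and the n's.
    """
    delta = noncentrality(h, n_i, n_j)
    z = spec.z_crit
    p = norm.cdf(delta - z) + norm.cdf(-delta - z)
    return float(p) if np.ndim(p) == 0 else p


@dataclass
class PairwisePowerResult:
    sample_i: str
    sample_j: str
    pe_diff: float
    h: float
    power: float
    in_target: bool


def pairwise_power_analysis(
    traits: pd.DataFrame,
    spec: PowerTestSpec = PowerTestSpec(),
    group_col: str = "nominal_mass_g",
    pe_col: str = "pe",
    n_col: str = "total_objects",
    id_col: str = "sample_id",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All unordered pairwise power tests within each sample-mass group.

    For every pair (i, j) in a group: h from the two PE values, delta from
    the two samples' (unrounded) effective object totals, power from the
    two-sided test. A pair is in the target zone when power >= the target
    and |PE_i - PE_j| <= the breeding-relevant bound.

    Returns (per-pair table, per-group summary). Groups with fewer than two
    usable samples are skipped with a warning in the summary. The summary's
    ``mean_diff_powered`` is the mean |PE| difference over pairs at or
    above the power target — the detection limit actually achieved;
    ``mean_diff_target`` averages only pairs inside the target zone.
    """
    rows = []
    summaries = []
    for group, gdf in traits.groupby(group_col, sort=True):
        gdf = gdf.dropna(subset=[pe_col, n_col])
        m = len(gdf)
        if m < 2:
            summaries.append(
                {group_col: group, "n_samples": m, "n_pairs": 0, "skipped": True}
            )
            continue
        ids = gdf[id_col].to_numpy()
        pe = gdf[pe_col].to_numpy(dtype=float)
        nn = gdf[n_col].to_numpy(dtype=float)
        ii, jj = map(np.array, zip(*combinations(range(m), 2)))
        h = cohens_h(pe[ii], pe[jj])
        power = two_prop_power(h, nn[ii], nn[jj], spec)
        diff = np.abs(pe[ii] - pe[jj])
        in_target = (power >= spec.target_power) & (diff <= spec.max_diff)
        for k in range(len(ii)):
            rows.append(
                {
                    group_col: group,
                    "sample_i": ids[ii[k]],
                    "sample_j": ids[jj[k]],
                    "pe_diff": diff[k],
                    "h": h[k],
                    "power": power[k],
                    "in_target": bool(in_target[k]),
                }
            )
        powered = power >= spec.target_power
        summaries.append(
            {
                group_col: group,
                "n_samples": m,
                "n_pairs": len(ii),
                "frac_powered": float(powered.mean()),
                "n_target_zone": int(in_target.sum()),
                "mean_diff_powered": float(diff[powered].mean()) if powered.any() else math.nan,
                "mean_diff_target": float(diff[in_target].mean()) if in_target.any() else math.nan,
                "skipped": False,
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(summaries)


def min_detectable_difference(
    n: float,
    center: float = 0.5,
    spec: PowerTestSpec = PowerTestSpec(),
    tol: float = 1e-6,
) -> float:
    """Smallest |p1 - p2| centred at ``center`` detectable with target power.

    Solves power(h(center + d/2, center - d/2), n, n) = target_power for d
    by bisection (brentq) on the feasible bracket
    (0, 2*min(center, 1-center)]. Raises if even the maximal feasible
    difference is under-powered.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0.0 < center < 1.0:
        raise ValueError(f"center must lie in (0,1), got {center}")
    d_max = 2.0 * min(center, 1.0 - center)

    def gap(d: float) -> float:
        h = cohens_h(center + d / 2.0, center - d / 2.0)
        return two_prop_power(h, n, n, spec) - spec.target_power

    if gap(d_max) < 0:
        raise ValueError(
            f"under-powered: even d={d_max:.4f} at n={n} gives power below "
            f"{spec.target_power} (center={center})"
        )
    return float(brentq(gap, 0.0, d_max, xtol=tol))


@dataclass
class DetectableDiffCurve:
    """min_detectable_difference over a grid of equal per-sample totals."""

    center: float
    n_grid: np.ndarray
    min_diff: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"n": self.n_grid, "center": self.center, "min_diff": self.min_diff}
        )


def detectable_diff_curve(
    n_max: int = 300,
    center: float = 0.5,
    spec: PowerTestSpec = PowerTestSpec(),
    n_min: int = 1,
) -> DetectableDiffCurve:
    """Theoretical minimum-detectable-difference curve for n = n_min..n_max.

    Grid points where even the maximal feasible difference is under-powered
    (tiny n) are reported as NaN.
    """
    grid = np.arange(n_min, n_max + 1)
    vals = np.full(grid.shape, np.nan)
    for k, n in enumerate(grid):
        try:
            vals[k] = min_detectable_difference(int(n), center, spec)
        except ValueError:
            pass
    return DetectableDiffCurve(center=center, n_grid=grid, min_diff=vals)


@dataclass
class SampleMassPlan:
    objects_per_gram: float
    target_diff: float
    center: float
    recommended_grams: int | None  # None when infeasible within max_grams
    per_gram: pd.DataFrame  # grams, n, min_diff, meets_target
    curve: DetectableDiffCurve


def plan_sample_mass(
    objects_per_gram: float = 46.0,
    target_diff: float = 0.25,
    center: float = 0.5,
    spec: PowerTestSpec = PowerTestSpec(),
    max_grams: int = 10,
) -> SampleMassPlan:
    """Minimum integer pod sample mass to detect ``target_diff`` in PE.

    Each candidate mass g provides n = round(g * objects_per_gram) objects
    per sample; the smallest g whose minimum detectable difference (at
    ``center``, default worst case 0.5) does not exceed the target is
    recommended. Also returns the full detectable-difference curve up to
    the largest candidate n, with per-gram markers.
    """
    if objects_per_gram <= 0:
        raise ValueError("objects_per_gram must be positive")
    if not 0.0 < target_diff < 1.0:
        raise ValueError("target_diff must lie in (0,1)")
    rows = []
    recommended = None
    for g in range(1, max_grams + 1):
        n = round(g * objects_per_gram)
        try:
            d = min_detectable_difference(n, center, spec)
        except ValueError:
            d = math.nan
        ok = (not math.isnan(d)) and d <= target_diff
        rows.append({"grams": g, "n_objects": n, "min_diff": d, "meets_target": ok})
        if ok and recommended is None:
            recommended = g
    n_max = max(1, round(max_grams * objects_per_gram))
    curve = detectable_diff_curve(n_max=n_max, center=center, spec=spec)
    return SampleMassPlan(
        objects_per_gram=objects_per_gram,
        target_diff=target_diff,
        center=center,
        recommended_grams=recommended,
        per_gram=pd.DataFrame(rows),
        curve=curve,
    )
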