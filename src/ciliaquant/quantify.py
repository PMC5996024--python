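"""Intensity-ratio quantification, per-cell normalisations, outlier handling
and group statistics.

Actin enrichment at the centriolar patch is quantified as the ratio of mean
phalloidin intensity inside the patch mask to the mean over the remaining cell
surface, measured on a 6-slice sum projection centred on a reference z-plane
(the Cep164 plane for the apical band, the Akap450 plane for the subapical
band).  Centriole counts and intensities are made comparable across animals
and fields by fold-change normalisation against a reference population
(contralateral hemisphere, surrounding non-transfected cells, or littermate
controls) or against the three closest non-transfected neighbour cells.

Statistical contract: two groups are compared with the Mann-Whitney rank test;
more than two with a Kruskal-Wallis omnibus followed by Dunn's pairwise
z-comparisons with Bonferroni adjustment; binned nearest-neighbour distance
distributions with the chi-squared test for trend (Cochran-Armitage).
Automatic counts are cleaned with a ROUT-style outlier rule (robust
location/scale fit + FDR on standardised residuals at rate Q).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .detection import VoxelGrid

__all__ = [
    "CellRecord",
    "ZBandSpec",
    "band_projection",
    "patch_ratio",
    "neighbour_normalised_intensity",
    "select_nearest_neighbours",
    "fold_change_counts",
    "remove_outliers_rout",
    "compare_groups",
    "dunn_posthoc",
    "chi2_trend",
]


@dataclass
class CellRecord:
    """One row of the per-cell results table."""

    cell_id: int
    group: str
    transfected: bool = False
    centriole_count: int | None = None
    patch_area_um2: float | None = None
    apical_ratio: float | None = None
    subapical_ratio: float | None = None
    normalised_count: float | None = None
    neighbour_ids: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        for name in ("apical_ratio", "subapical_ratio", "normalised_count"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")


@dataclass
class ZBandSpec:
    """A z-band for sum projection: ``n_slices`` planes around a marker plane."""

    marker: str = "cep164"  # reference staining defining the anchor plane
    n_slices: int = 6
    projection: str = "sum"

    def __post_init__(self) -> None:
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.projection != "sum":
            raise ValueError("only sum projection is supported")


def band_projection(
    grid: VoxelGrid,
    band: ZBandSpec,
    anchor_z_um: float,
) -> tuple[np.ndarray, bool]:
    """Sum projection of ``n_slices`` z-planes centred on the anchor plane.

    The anchor plane is the voxel plane containing ``anchor_z_um``.  For an
    even slice count the window is asymmetric by one plane: the anchor plus
    the 3 planes above and 2 below for the default of 6 (documented rounding).
    If the window is truncated by the stack edge the available planes are
    summed and the result flagged.  Returns ``(projection, truncated)``.
    """
    nz = grid.shape[0]
    dz = grid.voxel_size[0]
    anchor = int(np.floor(anchor_z_um / dz))
    if not (0 <= anchor < nz):
        raise ValueError(f"anchor plane {anchor_z_um} um is outside the stack")
    n = band.n_slices
    below = (n - 1) // 2 if n % 2 == 1 else n // 2 - 1
    above = n - 1 - below
    lo, hi = anchor - below, anchor + above + 1
    truncated = lo < 0 or hi > nz
    lo, hi = max(lo, 0), min(hi, nz)
    return grid.data[lo:hi].sum(axis=0), truncated


def patch_ratio(
    projection: np.ndarray,
    patch_mask: np.ndarray,
    cell_mask: np.ndarray,
) -> float:
    """Mean intensity in the patch over mean intensity in the rest of the cell.

    ``patch_mask`` must be a subset of ``cell_mask``; border pixels must
    already be excluded from both masks by the caller (masks are authoritative
    here).  An empty rest-region makes the ratio undefined (NaN, with a
    warning).
    """
    projection = np.asarray(projection, dtype=float)
    patch_mask = np.asarray(patch_mask, dtype=bool)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if patch_mask.shape != projection.shape or cell_mask.shape != projection.shape:
        raise ValueError("masks must match the projection shape")
    if np.any(patch_mask & ~cell_mask):
        raise ValueError("patch_mask must be contained in cell_mask")
    if not patch_mask.any():
        raise ValueError("patch_mask is empty")
    rest = cell_mask & ~patch_mask
    if not rest.any():
        warnings.warn("rest-of-cell region is empty; ratio undefined", stacklevel=2)
        return float("nan")
    return float(projection[patch_mask].mean() / projection[rest].mean())


def select_nearest_neighbours(
    cell_id: int,
    centroids: Mapping[int, tuple[float, float]],
    transfected: Mapping[int, bool],
    k: int = 3,
) -> tuple[list[int], bool]:
    """The ``k`` closest non-transfected cells by centroid distance.

    Ties are broken by cell id.  Returns ``(neighbour_ids, flagged)`` where
    ``flagged`` indicates fewer than ``k`` eligible neighbours were available.
    """
    cx, cy = centroids[cell_id]
    candidates = [
        (np.hypot(x - cx, y - cy), cid)
        for cid, (x, y) in centroids.items()
        if cid != cell_id and not transfected.get(cid, False)
    ]
    candidates.sort()
    chosen = [cid for _, cid in candidates[:k]]
    return chosen, len(chosen) < k


def neighbour_normalised_intensity(
    cell_value: float,
    neighbour_values: Sequence[float],
) -> tuple[float, bool]:
    """Cell mean intensity divided by the mean of its neighbour cells' means.

    Returns ``(fold_change, flagged)``; flagged when fewer than 3 neighbours
    were supplied (the available ones are still used).
    """
    values = np.asarray(neighbour_values, dtype=float)
    if len(values) == 0:
        raise ValueError("at least one neighbour value is required")
    flagged = len(values) < 3
    if flagged:
        warnings.warn(f"only {len(values)} neighbour(s) available; using them", stacklevel=2)
    ref = float(values.mean())
    if ref == 0:
        raise ValueError("neighbour mean intensity is zero; fold change undefined")
    return float(cell_value) / ref, flagged


def fold_change_counts(
    treated: Sequence[float],
    reference: Sequence[float],
    mode: str = "contralateral",
) -> np.ndarray:
    """Per-cell centriole counts normalised by the mean reference count.

    ``mode`` documents the reference population (``contralateral`` hemisphere,
    ``surrounding`` non-transfected cells, or ``littermate`` controls); the
    arithmetic is the same for all three.  Returns the distribution of
    per-cell fold changes.
    """
    if mode not in {"contralateral", "surrounding", "littermate"}:
        raise ValueError(f"unknown normalisation mode {mode!r}")
    treated = np.asarray(treated, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if len(reference) == 0:
        raise ValueError("reference counts must be non-empty")
    ref_mean = float(reference.mean())
    if ref_mean == 0:
        raise ValueError("reference mean count is zero; fold change undefined")
    return treated / ref_mean


# ---------------------------------------------------------------------------
# ROUT-style outlier removal
# ---------------------------------------------------------------------------

def remove_outliers_rout(
    values: Sequence[float],
    q_percent: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Robust outlier identification with an FDR cut at rate Q (percent).

    Location-model form of the ROUT procedure for univariate samples: the
    centre is the median and the scale the normal-consistent MAD; standardised
    residuals are converted to two-sided t p-values (n-1 df) and a
    Benjamini-Hochberg step-up at rate Q/100 marks the outliers.  Removed
    points are returned, never silently dropped.  Samples with n < 10, zero
    robust scale (e.g. constant data) or Q = 0 are left untouched.

    Returns ``(kept, removed)`` as arrays of values.
    """
    x = np.asarray(values, dtype=float)
    if q_percent < 0:
        raise ValueError("Q must be >= 0")
    n = len(x)
    if n < 10:
        if n > 0:
            warnings.warn(f"n={n} < 10: outlier removal skipped", stacklevel=2)
        return x.copy(), np.empty(0)
    if q_percent == 0:
        return x.copy(), np.empty(0)
    centre = float(np.median(x))
    scale = 1.4826 * float(np.median(np.abs(x - centre)))
    if scale == 0:
        return x.copy(), np.empty(0)
    z = (x - centre) / scale
    pvals = 2.0 * stats.t.sf(np.abs(z), df=n - 1)
    order = np.argsort(pvals)
    q = q_percent / 100.0
    thresh = q * (np.arange(1, n + 1)) / n
    passed = pvals[order] <= thresh
    k = int(np.max(np.nonzero(passed)[0])) + 1 if passed.any() else 0
    outlier_idx = order[:k]
    mask = np.ones(n, dtype=bool)
    mask[outlier_idx] = False
    return x[mask], x[~mask]


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

def dunn_posthoc(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Dunn's rank-based pairwise comparisons with Bonferroni adjustment.

    Pools all observations, ranks them (average ranks at ties), and for each
    pair of groups computes z = (Rbar_i - Rbar_j) / SE with the tie-corrected
    variance N(N+1)/12 - T/(12(N-1)).  Two-sided normal p-values are
    Bonferroni-adjusted over all pairwise contrasts.
    """
    names = list(groups)
    data = [np.asarray(groups[g], dtype=float) for g in names]
    pooled = np.concatenate(data)
    N = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for name, arr in zip(names, data):
        mean_ranks[name] = ranks[start : start + len(arr)].mean()
        start += len(arr)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term
    n_pairs = len(names) * (len(names) - 1) // 2
    rows = []
    for a, b in combinations(names, 2):
        na, nb = len(groups[a]), len(groups[b])
        se = np.sqrt(var_base * (1.0 / na + 1.0 / nb))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append(
            {"group_a": a, "group_b": b, "n_a": na, "n_b": nb,
             "z": z, "p_value": p, "p_adjusted": min(1.0, p * n_pairs)}
        )
    return pd.DataFrame(rows)


def chi2_trend(table: np.ndarray, scores: Sequence[float] | None = None) -> dict:
    """Cochran-Armitage chi-squared test for trend on a 2 x k count table.

    Row 0 holds the "event" counts and row 1 the complementary counts across k
    ordered bins (e.g. binned nearest-neighbour distances for two conditions);
    ``scores`` default to 0..k-1.  Returns statistic (1 df), z and p.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != 2:
        raise ValueError("table must be 2 x k")
    k = t.shape[1]
    s = np.asarray(scores if scores is not None else np.arange(k), dtype=float)
    n_col = t.sum(axis=0)
    N = t.sum()
    if N == 0 or np.any(n_col == 0):
        raise ValueError("table has empty columns or no data")
    p_bar = t[0].sum() / N
    T = float(np.sum(s * (t[0] - n_col * p_bar)))
    var = p_bar * (1 - p_bar) * (np.sum(s**2 * n_col) - np.sum(s * n_col) ** 2 / N)
    if var <= 0:
        return {"statistic": 0.0, "z": 0.0, "p_value": 1.0}
    z = T / np.sqrt(var)
    return {"statistic": z**2, "z": float(z), "p_value": float(2.0 * stats.norm.sf(abs(z)))}


def compare_groups(groups: Mapping[str, Sequence[float]]) -> dict:
    """Compare group distributions per the study's statistical contract.

    Two groups: two-sided Mann-Whitney U.  More than two: Kruskal-Wallis
    omnibus followed by Dunn's pairwise comparisons with Bonferroni
    adjustment.  Groups with fewer than 3 observations are flagged degenerate
    (tests still run where mathematically possible).
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    degenerate = [g for g in names if len(groups[g]) < 3]
    if degenerate:
        warnings.warn(f"groups with n < 3: {degenerate}", stacklevel=2)
    data = [np.asarray(groups[g], dtype=float) for g in names]
    if len(names) == 2:
        res = stats.mannwhitneyu(data[0], data[1], alternative="two-sided")
        return {
            "test": "mann-whitney",
            "statistic": float(res.statistic),
            "p_value": float(res.pvalue),
            "degenerate_groups": degenerate,
        }
    omnibus = stats.kruskal(*data)
    return {
        "test": "kruskal-dunn",
        "statistic": float(omnibus.statistic),
        "p_value": float(omnibus.pvalue),
        "pairwise": dunn_posthoc(groups),
        "degenerate_groups": degenerate,
    }
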