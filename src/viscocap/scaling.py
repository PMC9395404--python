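"""Population-level analyses of capsule fit results.

Cells, not individual indentations, are the replication unit: per-cell
means of the fitted (sigma0, KA0, beta) feed the scaling analyses.  The
central object is the empirical line beta = a - m * log10(KA0): conditions
that exhaust excess surface area shift this line almost in parallel toward
larger apparent stiffness, and the horizontal offset of a shared-slope
refit measures the area-reduction factor xi^-1.  Helper routines cover
normalized per-cell condition changes, Mann-Whitney rank-sum tests with
Bonferroni correction, substrate strain from fiducial bead displacements,
and ellipse-equivalent shape descriptors from segmentation masks.

Records are plain pandas DataFrames with columns ``cell``, ``beta``,
``KA0`` (and optionally ``sigma0``, ``condition``); one row per cell or per
indentation.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import mannwhitneyu
from skimage.measure import label as sk_label
from skimage.measure import regionprops

__all__ = [
    "ScalingFit",
    "XiEstimate",
    "StrainField",
    "aggregate_cells",
    "binned_scaling_fit",
    "xi_from_parallel_shift",
    "normalized_change",
    "rank_sum_tests",
    "strain_from_beads",
    "shape_descriptors",
]

logger = logging.getLogger(__name__)

SIGNIFICANCE_CODES = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


@dataclass
class ScalingFit:
    """Line beta = a - m log10(KA0) fitted to binned means."""

    slope: float  # m (positive for the usual downward beta-vs-logK trend)
    intercept: float  # a
    bin_x: np.ndarray  # mean log10(KA0) per occupied bin
    bin_means: np.ndarray  # mean beta per occupied bin
    bin_sds: np.ndarray
    bin_counts: np.ndarray
    n: int  # number of records
    mode: str


@dataclass
class XiEstimate:
    """Horizontal shift of two scaling lines expressed as an area factor."""

    xi_inv: float
    shared_slope: float
    slope_ratio: float  # unconstrained condition/reference slopes (parallelism)


@dataclass
class StrainField:
    """Substrate strain from matched fiducial beads."""

    pre: np.ndarray
    during: np.ndarray
    longitudinal: float
    lateral: float
    n_matched: int


def aggregate_cells(fits: pd.DataFrame) -> pd.DataFrame:
    """Per-cell means over repeated indentations (cells are the unit)."""
    cols = [c for c in ("sigma0", "KA0", "beta") if c in fits.columns]
    keys = [c for c in ("cell", "condition") if c in fits.columns]
    return fits.groupby(keys, as_index=False)[cols].mean()


def binned_scaling_fit(
    records: pd.DataFrame,
    nbins: int = 8,
    mode: str = "1d",
) -> ScalingFit:
    """Fit beta = a - m log10(KA0) through binned averages.

    1d mode bins on log10(KA0) and averages beta per bin; 2d mode bins on
    both axes and uses the mean of every occupied 2D cell, which
    de-weights dense regions of the scatter.  Ordinary least squares on
    the bin means yields (a, m); empty bins are skipped and at least three
    occupied bins are required.
    """
    if len(records) < 3 * nbins:
        raise ValueError(f"need at least {3 * nbins} records for {nbins} bins")
    x = np.log10(records["KA0"].to_numpy(dtype=float))
    y = records["beta"].to_numpy(dtype=float)

    if mode == "1d":
        edges = np.linspace(x.min(), x.max(), nbins + 1)
        which = np.clip(np.digitize(x, edges) - 1, 0, nbins - 1)
        bx, by, bs, bc = [], [], [], []
        for b in range(nbins):
            sel = which == b
            if sel.sum() == 0:
                continue
            bx.append(x[sel].mean())
            by.append(y[sel].mean())
            bs.append(y[sel].std(ddof=0))
            bc.append(int(sel.sum()))
    elif mode == "2d":
        ex = np.linspace(x.min(), x.max(), nbins + 1)
        ey = np.linspace(y.min(), y.max(), nbins + 1)
        ix = np.clip(np.digitize(x, ex) - 1, 0, nbins - 1)
        iy = np.clip(np.digitize(y, ey) - 1, 0, nbins - 1)
        bx, by, bs, bc = [], [], [], []
        for bxi, byi in {(a, b) for a, b in zip(ix, iy)}:
            sel = (ix == bxi) & (iy == byi)
            bx.append(x[sel].mean())
            by.append(y[sel].mean())
            bs.append(y[sel].std(ddof=0))
            bc.append(int(sel.sum()))
    else:
        raise ValueError("mode must be '1d' or '2d'")

    if len(bx) < 3:
        raise ValueError(f"only {len(bx)} occupied bins; need at least 3")
    bx, by = np.asarray(bx), np.asarray(by)
    order = np.argsort(bx)
    bx, by = bx[order], by[order]
    bs = np.asarray(bs)[order]
    bc = np.asarray(bc)[order]
    slope, intercept = np.polyfit(bx, by, 1)
    return ScalingFit(
        slope=-float(slope), intercept=float(intercept),
        bin_x=bx, bin_means=by, bin_sds=bs, bin_counts=bc,
        n=len(records), mode=mode,
    )


def xi_from_parallel_shift(fit_ref: ScalingFit, fit_cond: ScalingFit) -> XiEstimate:
    """Area-reduction factor xi^-1 from the shift between two scaling lines.

    Both sets of bin means are refit with a shared slope and separate
    intercepts; the horizontal log10 offset at matched beta gives
    xi^-1 = 10^(da / m).  The ratio of the two unconstrained slopes is
    reported as a parallelism diagnostic (near 1 when the premise holds).
    Being a ratio of KA0 values, xi^-1 does not depend on the log base.
    """
    x = np.concatenate([fit_ref.bin_x, fit_cond.bin_x])
    y = np.concatenate([fit_ref.bin_means, fit_cond.bin_means])
    is_cond = np.concatenate(
        [np.zeros_like(fit_ref.bin_x), np.ones_like(fit_cond.bin_x)]
    )
    # y = a_ref + da*is_cond - m*x
    design = np.column_stack([np.ones_like(x), is_cond, -x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    _, da, m = coef
    if abs(m) < 1e-3:
        raise ValueError("shared slope is ~0; horizontal shift undefined")
    xi_inv = float(10.0 ** (da / m))
    ratio = (
        fit_cond.slope / fit_ref.slope if fit_ref.slope != 0 else np.inf
    )
    return XiEstimate(xi_inv=xi_inv, shared_slope=float(m), slope_ratio=float(ratio))


def normalized_change(
    records_cond: pd.DataFrame,
    records_ref: pd.DataFrame,
    parameter: str,
) -> tuple[pd.DataFrame, dict]:
    """Per-cell % change of a fitted parameter relative to a reference state.

    Cells are matched by id; unmatched cells are dropped (count logged) and
    cells with non-positive reference values excluded with a warning.
    Returns the per-cell table and a median/quartile summary.
    """
    ref = aggregate_cells(records_ref).set_index("cell")[parameter]
    cond = aggregate_cells(records_cond).set_index("cell")[parameter]
    common = ref.index.intersection(cond.index)
    dropped = len(set(ref.index) ^ set(cond.index))
    if dropped:
        logger.info("normalized_change: dropped %d unmatched cells", dropped)
    ref, cond = ref.loc[common], cond.loc[common]
    bad = ref <= 0
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} cells excluded: non-positive reference {parameter}"
        )
        ref, cond = ref[~bad], cond[~bad]
    change = 100.0 * (cond - ref) / ref
    table = pd.DataFrame({"cell": change.index, "change_percent": change.to_numpy()})
    q1, med, q3 = np.percentile(change, [25, 50, 75])
    return table, {"median": float(med), "q1": float(q1), "q3": float(q3)}


def rank_sum_tests(
    groups: dict[str, np.ndarray],
    exact_max_n: int = 20,
) -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney U tests with Bonferroni correction.

    The exact null distribution is used for combined samples up to
    ``exact_max_n`` without ties; larger (or tied) samples use the normal
    approximation with tie correction.  Adjusted p-values are multiplied by
    the number of comparisons and clipped at 1; significance codes follow
    the usual thresholds (ns, *, **, ***, ****).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for name, vals in groups.items():
        if len(vals) < 3:
            raise ValueError(f"group {name!r} has n < 3")
    pairs = list(itertools.combinations(groups, 2))
    n_comp = len(pairs)
    rows = []
    for g1, g2 in pairs:
        a = np.asarray(groups[g1], dtype=float)
        b = np.asarray(groups[g2], dtype=float)
        has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
        method = "exact" if (a.size + b.size <= exact_max_n and not has_ties) else "asymptotic"
        res = mannwhitneyu(a, b, alternative="two-sided", method=method)
        p_adj = min(res.pvalue * n_comp, 1.0)
        code = "ns"
        for thr, c in SIGNIFICANCE_CODES:
            if p_adj < thr:
                code = c
                break
        rows.append(
            {"group1": g1, "group2": g2, "U": float(res.statistic),
             "p_raw": float(res.pvalue), "p_adjusted": float(p_adj),
             "method": method, "code": code}
        )
    return pd.DataFrame(rows)


def strain_from_beads(
    pre: np.ndarray,
    during: np.ndarray,
    strain_axis: str = "x",
    min_separation_frac: float = 0.05,
) -> StrainField:
    """Substrate strain from fiducial bead displacements.

    Coarse drift and the bulk stretch are removed by per-axis
    standardisation (centroid alignment plus spread normalisation), beads
    are matched by nearest neighbour in that space, and the strain along
    each axis is the mean over bead pairs of the projected-distance ratio
    minus one.  Pairs whose pre-stretch projected separation is below
    ``min_separation_frac`` of the field span are excluded (their ratios
    are jitter-dominated).
    """
    pre = np.asarray(pre, dtype=float)
    during = np.asarray(during, dtype=float)
    if pre.shape[0] < 2 or during.shape[0] < 2:
        raise ValueError("need at least two beads in each image")
    if strain_axis not in ("x", "y"):
        raise ValueError("strain_axis must be 'x' or 'y'")

    def standardize(pts: np.ndarray) -> np.ndarray:
        spread = pts.std(axis=0)
        spread[spread == 0] = 1.0
        return (pts - pts.mean(axis=0)) / spread

    tree = cKDTree(standardize(during))
    _, idx = tree.query(standardize(pre))
    counts = np.bincount(idx, minlength=during.shape[0])
    if np.any(counts > 1):
        offenders = np.flatnonzero(counts > 1).tolist()
        raise ValueError(f"ambiguous bead matching: during-beads {offenders} claimed twice")
    matched = during[idx]

    ax = 0 if strain_axis == "x" else 1

    def axis_strain(axis: int) -> float:
        dp = np.abs(pre[:, None, axis] - pre[None, :, axis])
        dd = np.abs(matched[:, None, axis] - matched[None, :, axis])
        iu = np.triu_indices(pre.shape[0], k=1)
        dp, dd = dp[iu], dd[iu]
        span = np.ptp(pre[:, axis])
        if span <= 0:
            raise ValueError("beads do not span the axis")
        keep = dp >= min_separation_frac * span
        if keep.sum() < 1:
            raise ValueError("no bead pairs with usable separation")
        return float(np.mean(dd[keep] / dp[keep]) - 1.0)

    return StrainField(
        pre=pre, during=matched,
        longitudinal=axis_strain(ax), lateral=axis_strain(1 - ax),
        n_matched=pre.shape[0],
    )


def shape_descriptors(
    mask: np.ndarray,
    strain_axis: str = "x",
    pixel_size: float = 1.0,
) -> tuple[float, float, float]:
    """(area, eccentricity, orientation) of a cell mask.

    The cell outline is summarised by the ellipse with the same second
    moments as the mask.  Area is pixel count times ``pixel_size**2``;
    orientation is the angle of the major axis to the axis perpendicular
    to the strain axis, folded into [0, 90] degrees (90 = aligned with the
    strain direction).
    """
    mask = np.asarray(mask) > 0
    if not mask.any():
        raise ValueError("empty mask")
    labeled = sk_label(mask)
    props = regionprops(labeled)
    if len(props) > 1:
        warnings.warn(f"mask has {len(props)} components; using the largest")
        props = [max(props, key=lambda r: r.area)]
    region = props[0]
    area = float(region.area) * pixel_size**2
    ecc = float(region.eccentricity)
    # regionprops orientation: angle between the row (y) axis and the major
    # axis, in (-pi/2, pi/2].  Rows are perpendicular to an x strain axis.
    ang = abs(np.degrees(region.orientation))
    if strain_axis == "x":
        orientation = ang
    elif strain_axis == "y":
        orientation = 90.0 - ang
    else:
        raise ValueError("strain_axis must be 'x' or 'y'")
    return area, ecc, orientation
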