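"""Choriocapillaris reflectivity and flow-void quantification.

The choriocapillaris is characterized by (i) the mean and standard deviation
of the normalized en-face signal (reflectivity), and (ii) the dark "flow
voids" (flow deficits) of the Phansalkar-binarized image: their number, mean
size, and the log-log linear regression of per-size-bin counts on size,

    log10(count per bin) = intercept + slope * log10(size),

as proposed by Spaide for choriocapillaris flow-deficit analysis. Group
differences in that regression's intercept are tested with an equal-slopes
analysis of covariance over the pooled per-eye binned points, and group
differences in void-count dispersion with a Brown-Forsythe-type test on
absolute deviations from each group's median.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import ndimage, stats

from .exceptions import InsufficientDataError, LayerError, OctavascError
from .images import BinaryMap, EnFaceAngiogram
from .thresholding import PHANSALKAR_DEFAULTS, phansalkar_binarize

DEFAULT_N_BINS = 10


@dataclass
class ReflectivityStats:
    """Whole-scan mean and population SD of normalized choriocapillaris signal."""

    mean: float
    sd: float


@dataclass
class FlowVoidSet:
    """Labelled dark components of a binarized choriocapillaris scan."""

    sizes_px: np.ndarray
    px_size_um: float
    image_id: str = ""

    def __post_init__(self) -> None:
        self.sizes_px = np.asarray(self.sizes_px, dtype=float)

    @property
    def n_voids(self) -> int:
        return int(self.sizes_px.size)

    @property
    def sizes_um2(self) -> np.ndarray:
        return self.sizes_px * self.px_size_um**2

    @property
    def mean_size_um2(self) -> float:
        return float(self.sizes_um2.mean()) if self.n_voids else float("nan")


@dataclass
class VoidDistributionFit:
    """OLS fit of log10 bin count on log10 bin-center size."""

    slope: float
    intercept: float
    r_squared: float
    bin_edges: np.ndarray
    bin_counts: np.ndarray


@dataclass
class InterceptComparison:
    """Equal-slopes ANCOVA of pooled log-log points with a group indicator."""

    common_slope: float
    intercept_difference: float
    ci95: tuple[float, float]
    p: float
    n_a: int = 0
    n_b: int = 0


def reflectivity_stats(image: EnFaceAngiogram) -> ReflectivityStats:
    """Per-scan pixel mean and population standard deviation of the signal."""
    if image.layer != "choriocapillaris":
        raise LayerError(f"reflectivity is a choriocapillaris metric, got {image.layer!r}")
    px = image.pixels
    return ReflectivityStats(mean=float(px.mean()), sd=float(px.std()))


def detect_flow_voids(
    image: EnFaceAngiogram,
    min_size_um2: float = 0.0,
    connectivity: int = 8,
    phansalkar_params: dict | None = None,
) -> FlowVoidSet:
    """Detect flow voids: Phansalkar dark-foreground components above a size floor.

    The image is binarized with the Phansalkar local threshold keeping the
    dark phase, connected components are labelled (8-connectivity by default,
    so diagonally touching deficits merge), and components smaller than
    ``min_size_um2`` are dropped (no floor by default).
    """
    if image.layer != "choriocapillaris":
        raise LayerError(f"flow voids are a choriocapillaris metric, got {image.layer!r}")
    if connectivity not in (4, 8):
        raise OctavascError("connectivity must be 4 or 8")
    params = dict(PHANSALKAR_DEFAULTS)
    params.update(phansalkar_params or {})
    dark = phansalkar_binarize(image, polarity="dark_fg", **params)
    structure = ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)
    labels, n = ndimage.label(dark.pixels, structure=structure)
    if n == 0:
        sizes = np.array([], dtype=float)
    else:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    sizes_um2 = sizes * image.px_size_um**2
    sizes = sizes[sizes_um2 >= min_size_um2]
    return FlowVoidSet(sizes_px=sizes, px_size_um=image.px_size_um)


def _log_bin(sizes: np.ndarray, n_bins: int, bin_edges: np.ndarray | None):
    """Histogram sizes into log10-spaced bins; return (log10 centers, counts, edges)."""
    sizes = np.asarray(sizes, dtype=float)
    if bin_edges is None:
        lo, hi = sizes.min(), sizes.max()
        if lo <= 0:
            raise OctavascError("sizes must be positive for logarithmic binning")
        if lo == hi:
            raise InsufficientDataError(
                "insufficient distribution support: all sizes identical"
            )
        bin_edges = np.logspace(np.log10(lo), np.log10(hi), n_bins + 1)
    bin_edges = np.asarray(bin_edges, dtype=float)
    counts, _ = np.histogram(sizes, bins=bin_edges)
    log_centers = 0.5 * (np.log10(bin_edges[:-1]) + np.log10(bin_edges[1:]))
    return log_centers, counts, bin_edges


def fit_powerlaw_sizes(
    sizes,
    n_bins: int = DEFAULT_N_BINS,
    bin_edges: np.ndarray | None = None,
) -> VoidDistributionFit:
    """Fit ``log10(count) = intercept + slope * log10(size)`` on binned sizes.

    Sizes are binned into ``n_bins`` log10-spaced bins spanning the observed
    range (or explicit ``bin_edges``); empty bins are dropped and at least
    three non-empty bins are required. Bin centers are geometric midpoints.
    """
    sizes = np.asarray(sizes, dtype=float)
    if sizes.size == 0:
        raise InsufficientDataError("insufficient distribution support: no voids")
    log_centers, counts, bin_edges = _log_bin(sizes, n_bins, bin_edges)
    keep = counts > 0
    if keep.sum() < 3:
        raise InsufficientDataError(
            f"insufficient distribution support: {int(keep.sum())} non-empty bins (< 3)"
        )
    res = stats.linregress(log_centers[keep], np.log10(counts[keep]))
    return VoidDistributionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        bin_edges=bin_edges,
        bin_counts=counts,
    )


def fit_void_size_distribution(voids: FlowVoidSet, n_bins: int = DEFAULT_N_BINS) -> VoidDistributionFit:
    """Spaide-style size-distribution fit on a detected void set (sizes in um^2)."""
    return fit_powerlaw_sizes(voids.sizes_um2, n_bins=n_bins)


def _pooled_points(groups: list[FlowVoidSet], n_bins: int):
    xs, ys = [], []
    for voids in groups:
        log_centers, counts, _ = _log_bin(np.asarray(voids.sizes_um2), n_bins, None)
        keep = counts > 0
        if keep.sum() < 3:
            raise InsufficientDataError(
                "insufficient distribution support in one eye (< 3 non-empty bins)"
            )
        xs.append(log_centers[keep])
        ys.append(np.log10(counts[keep]))
    return xs, ys


def compare_void_intercepts(
    group_a: list[FlowVoidSet],
    group_b: list[FlowVoidSet],
    n_bins: int = DEFAULT_N_BINS,
) -> InterceptComparison:
    """Test for a group difference in the size-distribution intercept.

    Pools the per-eye binned (log10 size, log10 count) points of both groups
    and fits an equal-slopes model ``log_count ~ log_size + group``; the group
    indicator's coefficient estimates the intercept difference (B minus A) at
    common slope. Because bin points from one eye share that eye's
    realization, standard errors are cluster-robust over void sets (t
    reference distribution), which keeps the test's size at the nominal
    level.
    """
    if len(group_a) < 3 or len(group_b) < 3:
        raise InsufficientDataError("each group needs at least 3 void sets")
    xa, ya = _pooled_points(group_a, n_bins)
    xb, yb = _pooled_points(group_b, n_bins)
    clusters = np.concatenate(
        [np.full(len(v), i) for i, v in enumerate(ya + yb)]
    )
    x = np.concatenate(xa + xb)
    y = np.concatenate(ya + yb)
    g = np.concatenate([np.zeros(sum(len(v) for v in ya)), np.ones(sum(len(v) for v in yb))])
    design = sm.add_constant(np.column_stack([x, g]))
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise OctavascError("degenerate pooled design (collinear log-size and group)")
    fit = sm.OLS(y, design).fit(
        cov_type="cluster", cov_kwds={"groups": clusters}, use_t=True
    )
    ci = fit.conf_int()[2]
    return InterceptComparison(
        common_slope=float(fit.params[1]),
        intercept_difference=float(fit.params[2]),
        ci95=(float(ci[0]), float(ci[1])),
        p=float(fit.pvalues[2]),
        n_a=len(group_a),
        n_b=len(group_b),
    )


def void_count_dispersion_test(counts_a, counts_b) -> float:
    """Brown-Forsythe-type dispersion test on per-participant void counts.

    Tests whether the spread (not the location) of void counts differs between
    groups, via the Levene statistic on absolute deviations from each group's
    median. Captures "noticeably high or low" counts in one group.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise InsufficientDataError("each group needs at least 3 counts")
    dev_a = np.abs(a - np.median(a))
    dev_b = np.abs(b - np.median(b))
    if dev_a.max() == 0 and dev_b.max() == 0:
        warnings.warn("no within-group variability in either group; p = 1", stacklevel=2)
        return 1.0
    stat, p = stats.levene(a, b, center="median")
    return float(p)
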