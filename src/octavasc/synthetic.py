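"""Synthetic inputs with known ground truth for every pipeline stage.

Four generators emulate the study's three input classes:

* :func:`generate_vessel_image` — en-face plexus angiograms: random seeded
  walkers with branching grow a connected vessel network of configurable
  width; the drawn mask and centerlines are the exact truth against which
  binarization/skeletonization recovery is tested.
* :func:`generate_choriocap_image` — choriocapillaris scans: a bright
  speckled background with implanted disjoint dark flow voids whose
  per-log-bin counts follow ``count = 10**intercept * size**slope``.
* :func:`generate_lesion_volume` — 3-D white-matter lesion masks with a known
  number of disjoint lesions and accompanying tissue-class volumes.
* :func:`generate_cohort` — full participant tables parameterized by the
  study's group means/SDs, with a structural effect model: OCT-A metrics
  decline with age and with a shared latent microvascular factor, lesion
  count (NOL) depends on age and on one driver OCT-A metric with a
  configurable negative slope, and the (log-normal) white-matter lesion
  index correlates with age and NOL.

Every generator is a pure function of its seed, and all truth quantities are
measured on the generated objects themselves rather than echoed from the
request.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import truncnorm

from .choriocap import fit_powerlaw_sizes
from .exceptions import GenerationError, InsufficientDataError, OctavascError
from .images import BinaryMap, EnFaceAngiogram, SkeletonMap
from .mri import MriSummary
from .records import ParticipantRecord

try:  # skimage.filters.gaussian is the only smoothing we need
    from skimage.filters import gaussian as _gaussian_blur
except ImportError:  # pragma: no cover
    _gaussian_blur = None


# --------------------------------------------------------------------------
# truth containers
# --------------------------------------------------------------------------

@dataclass
class VesselImageTruth:
    """A synthetic plexus angiogram plus its exact vessel-mask ground truth."""

    image: EnFaceAngiogram
    true_mask: BinaryMap
    true_vessel_fraction: float
    true_centerlines: SkeletonMap
    mean_width_px: float


@dataclass
class ChoriocapTruth:
    """A synthetic choriocapillaris scan plus its implanted flow-void sizes."""

    image: EnFaceAngiogram
    true_void_sizes: np.ndarray  # exact pixel counts of implanted voids
    slope: float
    intercept: float
    background_mean: float
    background_sd: float


@dataclass
class LesionVolumeTruth:
    """A synthetic 3-D lesion mask plus its exact lesion count."""

    mask: np.ndarray
    voxel_dims_mm: tuple[float, float, float]
    true_n_lesions: int
    tissue_volumes_ml: tuple[float, float, float]


# --------------------------------------------------------------------------
# vessel-network angiograms
# --------------------------------------------------------------------------

def _disk_offsets(width: int) -> np.ndarray:
    r = width // 2
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy * yy + xx * xx) <= r * r + max(r // 2, 0)


def _walk(rng, shape, n_steps, branch_prob=0.03):
    """One reflecting random walker; returns centerline coords and branch seeds."""
    H, W = shape
    y = rng.uniform(1.0, H - 1.0)
    x = rng.uniform(1.0, W - 1.0)
    angle = rng.uniform(0.0, 2 * np.pi)
    pts, branches = [], []
    for _ in range(n_steps):
        y += math.sin(angle)
        x += math.cos(angle)
        if y < 1:
            y, angle = 1.0, -angle
        elif y > H - 2:
            y, angle = H - 2.0, -angle
        if x < 1:
            x, angle = 1.0, math.pi - angle
        elif x > W - 2:
            x, angle = W - 2.0, math.pi - angle
        pts.append((int(round(y)), int(round(x))))
        angle += rng.normal(0.0, 0.2)
        if rng.random() < branch_prob:
            branches.append((y, x, angle + rng.choice([-1.0, 1.0]) * rng.uniform(0.6, 1.2)))
    return pts, branches


def generate_vessel_image(
    seed: int,
    shape: tuple[int, int] = (256, 256),
    target_fraction: float = 0.278,
    width_range: tuple[int, int] = (2, 6),
    noise_sd: float = 0.05,
    layer: str = "superficial",
    blur_sigma: float = 0.5,
    vessel_intensity: float = 0.85,
    background_intensity: float = 0.2,
    px_size_um: float = 6.0,
) -> VesselImageTruth:
    """Grow a random vessel network until the mask hits ``target_fraction``.

    Random walkers of per-stroke width (uniform over ``width_range``) are
    stamped onto the canvas until the vessel-pixel fraction reaches the
    target; near the target the stroke length and width are reduced so the
    achieved fraction lands within +-0.02. The returned truth fraction and
    mean width are measured on the drawn mask and centerlines.
    """
    if not 0.0 < target_fraction < 0.6:
        raise GenerationError(f"target_fraction must be in (0, 0.6), got {target_fraction}")
    wlo, whi = int(width_range[0]), int(width_range[1])
    if wlo < 1 or whi > 15 or wlo > whi:
        raise GenerationError(f"width_range must lie within [1, 15], got {width_range}")

    rng = np.random.default_rng(seed)
    H, W = shape
    size = H * W
    mask = np.zeros(shape, dtype=bool)
    centerlines = np.zeros(shape, dtype=bool)
    target_px = target_fraction * size

    max_strokes = 20000
    strokes = 0
    while mask.sum() < target_px:
        strokes += 1
        if strokes > max_strokes:
            raise GenerationError(
                f"target fraction {target_fraction} unreachable on shape {shape} "
                f"with widths {width_range} after {max_strokes} strokes"
            )
        deficit = target_px - mask.sum()
        width = wlo if deficit < 0.01 * size else int(rng.integers(wlo, whi + 1))
        w_eff = 2 * (width // 2) + 1
        base_len = int(rng.integers(max(H // 4, 8), max(H // 2, 16) + 1))
        # total point budget (main walk + branches) keeps the final overshoot
        # below the +-0.02 fraction tolerance
        budget = min(2 * base_len, max(6, int(1.2 * deficit / w_eff)))
        pts, branches = _walk(rng, shape, min(base_len, budget))
        for by, bx, bangle in branches[:2]:
            if len(pts) >= budget:
                break
            sub, _ = _walk(rng, shape, min(max(len(pts) // 2, 4), budget - len(pts)))
            pts.extend(sub)
        stroke = np.zeros(shape, dtype=bool)
        ys, xs = zip(*pts)
        stroke[list(ys), list(xs)] = True
        centerlines |= stroke
        if width >= 2:
            stroke = ndimage.binary_dilation(stroke, structure=_disk_offsets(width))
        mask |= stroke

    fraction = float(mask.sum()) / size
    if abs(fraction - target_fraction) > 0.02:
        raise GenerationError(
            f"achieved fraction {fraction:.4f} outside +-0.02 of target {target_fraction}"
        )

    # the truth centerline is the medial axis of the drawn network: where
    # strokes overlap, the drawn walk pixels double-count length, so the
    # medial line is the meaningful 1-px ground truth for skeleton metrics
    from skimage.morphology import skeletonize as _thin

    medial = _thin(mask)

    img = np.where(mask, vessel_intensity, background_intensity).astype(float)
    if blur_sigma > 0:
        img = _gaussian_blur(img, sigma=blur_sigma, preserve_range=True)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, shape)
    img = np.clip(img, 0.0, 1.0)

    return VesselImageTruth(
        image=EnFaceAngiogram(img, px_size_um=px_size_um, layer=layer),
        true_mask=BinaryMap(mask, provenance={"algorithm": "synthetic_truth"}),
        true_vessel_fraction=fraction,
        true_centerlines=SkeletonMap(medial),
        mean_width_px=float(mask.sum()) / float(medial.sum()),
    )


# --------------------------------------------------------------------------
# choriocapillaris scans with power-law flow voids
# --------------------------------------------------------------------------

def _powerlaw_bin_plan(slope, intercept, size_range, n_bins):
    lo, hi = float(size_range[0]), float(size_range[1])
    edges = np.logspace(np.log10(lo), np.log10(hi), n_bins + 1)
    centers = np.sqrt(edges[:-1] * edges[1:])
    expected = 10.0**intercept * centers**slope
    return edges, centers, expected


def sample_void_sizes(
    seed,
    slope: float = -1.5,
    intercept: float = 3.2,
    size_range: tuple[float, float] = (4.0, 300.0),
    n_bins: int = 10,
) -> np.ndarray:
    """Draw a void-size sample from the per-log-bin power law.

    Per-bin counts are Poisson around ``10**intercept * center**slope`` and
    sizes are log-uniform within their bin. This is the fast, image-free
    route used for statistical simulations; ``seed`` may be an integer or a
    ``numpy.random.Generator``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    edges, _, expected = _powerlaw_bin_plan(slope, intercept, size_range, n_bins)
    sizes = []
    for k, lam in enumerate(expected):
        n_k = rng.poisson(lam)
        if n_k:
            u = rng.uniform(np.log10(edges[k]), np.log10(edges[k + 1]), n_k)
            sizes.append(10.0**u)
    return np.concatenate(sizes) if sizes else np.array([])


def generate_choriocap_image(
    seed: int,
    shape: tuple[int, int] = (512, 512),
    slope: float = -1.5,
    intercept: float | None = 3.2,
    size_range: tuple[float, float] = (4.0, 300.0),
    background_mean: float = 0.9,
    background_sd: float = 0.05,
    n_bins: int = 10,
    void_intensity: float = 0.45,
    margin_px: int = 4,
    px_size_um: float = 6.0,
) -> ChoriocapTruth:
    """Implant disjoint dark flow voids following a size power law.

    Per-log-bin void counts are ``round(10**intercept * center**slope)``;
    target sizes sit at log-uniform quantiles within their bin (so the truth
    histogram deviates from the law only by integer rounding) and are
    rasterized as disks,
    placed largest-first by rejection sampling with a ``margin_px`` gap so
    implanted voids are pairwise disjoint (and stay disjoint after
    binarization). The recorded truth sizes are the exact rasterized pixel
    counts. ``intercept=None`` requests a background-only scan with no
    implanted voids.
    """
    if slope >= 0:
        raise GenerationError("slope must be negative (fewer large voids)")
    if size_range[0] < 4:
        raise GenerationError("minimum void size must be >= 4 px")
    rng = np.random.default_rng(seed)
    H, W = shape
    if intercept is None:
        edges = _powerlaw_bin_plan(slope, 0.0, size_range, n_bins)[0]
        counts = np.zeros(n_bins, dtype=int)
    else:
        edges, _, expected = _powerlaw_bin_plan(slope, intercept, size_range, n_bins)
        counts = np.round(expected).astype(int)
        if counts.sum() == 0:
            raise GenerationError("no voids generated: expected count < 1 in every bin")

    # deterministic log-uniform quantile placement within each bin: the truth
    # histogram then deviates from the law only by integer rounding
    targets = []
    for k, n_k in enumerate(counts):
        if n_k:
            lo_k, hi_k = np.log10(edges[k]), np.log10(edges[k + 1])
            u = lo_k + (np.arange(n_k) + 0.5) / n_k * (hi_k - lo_k)
            targets.extend(10.0**u)
    targets = sorted(targets, reverse=True)
    if sum(targets) > 0.5 * H * W:
        raise GenerationError(
            f"requested void area {sum(targets):.0f} px exceeds 50% of the image"
        )

    occupied = np.zeros(shape, dtype=bool)
    void_mask = np.zeros(shape, dtype=bool)
    true_sizes = []
    for s in targets:
        r = max(1.2, math.sqrt(s / math.pi))
        ri = int(math.ceil(r))
        placed = False
        for _ in range(300):
            cy = rng.integers(ri + margin_px, H - ri - margin_px)
            cx = rng.integers(ri + margin_px, W - ri - margin_px)
            R = ri + margin_px
            yy, xx = np.ogrid[-R : R + 1, -R : R + 1]
            guard = (yy * yy + xx * xx) <= R * R
            window = occupied[cy - R : cy + R + 1, cx - R : cx + R + 1]
            if np.any(window & guard):
                continue
            dd = (yy * yy + xx * xx) <= r * r
            void_mask[cy - R : cy + R + 1, cx - R : cx + R + 1] |= dd
            occupied[cy - R : cy + R + 1, cx - R : cx + R + 1] |= guard
            true_sizes.append(int(dd.sum()))
            placed = True
            break
        if not placed:
            raise GenerationError(
                "could not place all voids without overlap; use a larger image"
            )

    img = np.full(shape, background_mean, dtype=float)
    img[void_mask] = void_intensity
    if background_sd > 0:
        img = img + rng.normal(0.0, background_sd, shape)
    img = np.clip(img, 0.0, 1.0)
    return ChoriocapTruth(
        image=EnFaceAngiogram(img, px_size_um=px_size_um, layer="choriocapillaris"),
        true_void_sizes=np.array(true_sizes, dtype=float),
        slope=slope,
        intercept=intercept,
        background_mean=background_mean,
        background_sd=background_sd,
    )


# --------------------------------------------------------------------------
# 3-D lesion volumes
# --------------------------------------------------------------------------

def generate_lesion_volume(
    seed: int,
    grid: tuple[int, int, int] = (64, 64, 64),
    n_lesions: int = 16,
    lesion_radius_range: tuple[int, int] = (1, 4),
    tissue_volumes_ml: tuple[float, float, float] = (700.0, 600.0, 200.0),
    voxel_dims_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> LesionVolumeTruth:
    """Place ``n_lesions`` disjoint quasi-spherical lesions in a voxel grid.

    Spheres are placed largest-first by rejection sampling with a 2-voxel gap
    so they remain distinct under 26-connectivity; exceeding the retry cap
    raises with a suggestion to enlarge the grid. The returned lesion count
    is measured on the mask itself.
    """
    rng = np.random.default_rng(seed)
    mask = np.zeros(grid, dtype=bool)
    rlo, rhi = lesion_radius_range
    if rlo < 1 or rhi < rlo:
        raise GenerationError(f"invalid lesion_radius_range {lesion_radius_range}")
    placed: list[tuple[np.ndarray, int]] = []
    radii = sorted((int(rng.integers(rlo, rhi + 1)) for _ in range(n_lesions)), reverse=True)
    for r in radii:
        ok = False
        for _ in range(1000):
            c = np.array([rng.integers(r + 1, g - r - 1) for g in grid])
            if all(np.linalg.norm(c - pc) > r + pr + 2 for pc, pr in placed):
                zz, yy, xx = np.ogrid[-r : r + 1, -r : r + 1, -r : r + 1]
                sphere = (zz * zz + yy * yy + xx * xx) <= r * r
                mask[
                    c[0] - r : c[0] + r + 1,
                    c[1] - r : c[1] + r + 1,
                    c[2] - r : c[2] + r + 1,
                ] |= sphere
                placed.append((c, r))
                ok = True
                break
        if not ok:
            raise GenerationError(
                f"could not place {n_lesions} disjoint lesions in grid {grid}; "
                "use a larger grid or fewer/smaller lesions"
            )
    structure = ndimage.generate_binary_structure(3, 3)
    _, n_found = ndimage.label(mask, structure=structure)
    return LesionVolumeTruth(
        mask=mask,
        voxel_dims_mm=tuple(voxel_dims_mm),
        true_n_lesions=int(n_found),
        tissue_volumes_ml=tuple(tissue_volumes_ml),
    )


# --------------------------------------------------------------------------
# cohort tables
# --------------------------------------------------------------------------

#: Group means and SDs of the study sample (controls / all CSVD cases).
STUDY_CONTROLS = {
    "age": (58.0, 5.0),
    "moca": (25.0, 3.0),
    "vd_sup": (0.281, 0.015),
    "vdi_sup": (1_979_802.0, 30_639.0),
    "vd_deep": (0.245, 0.013),
    "vdi_deep": (1_571_945.0, 59_464.0),
    "cc_mean": (0.918, 0.050),
    "cc_sd": (0.247, 0.011),
    "nol": (6.0, 6.0),
    "wmi": (2.58e-4, 2.57e-4),
}

STUDY_CASES = {
    "age": (63.0, 11.0),
    "moca": (25.0, 4.0),
    "vd_sup": (0.276, 0.020),
    "vdi_sup": (1_944_182.0, 78_558.0),
    "vd_deep": (0.240, 0.019),
    "vdi_deep": (1_544_999.0, 65_947.0),
    "cc_mean": (0.899, 0.052),
    "cc_sd": (0.237, 0.011),
    "nol": (16.0, 8.0),
    "wmi": (39.71e-4, 50.50e-4),
}

#: Gaussian copula-free structural age slopes (units of the metric per year).
DEFAULT_AGE_SLOPES = {
    "vd_sup": -0.0008,
    "vd_deep": -0.0008,
    "vdi_sup": -1500.0,
    "vdi_deep": -1500.0,
    "cc_mean": -0.002,
    "cc_sd": -0.0003,
}

_EYE_METRICS = ("vd_sup", "vdi_sup", "vd_deep", "vdi_deep", "cc_mean", "cc_sd")
_METRIC_BOUNDS = {
    "vd_sup": (1e-4, 0.9999),
    "vd_deep": (1e-4, 0.9999),
    "cc_mean": (1e-4, 0.9999),
    "cc_sd": (1e-4, 0.9999),
    "vdi_sup": (1.0, np.inf),
    "vdi_deep": (1.0, np.inf),
}


@dataclass
class CohortParams:
    """Parameters of the synthetic cohort generator.

    Group marginals (``cases``/``controls``) are mean/SD pairs per variable;
    the effect structure couples age, a shared microvascular latent factor,
    the driver OCT-A metric, lesion count and lesion index. The configured
    SDs describe participant-level (eye-averaged) values; the two eyes of a
    participant are generated symmetrically around that value with
    within-participant correlation ``rho_eye``.
    """

    n_cases: int = 20
    n_controls: int = 10
    cases: dict = field(default_factory=lambda: dict(STUDY_CASES))
    controls: dict = field(default_factory=lambda: dict(STUDY_CONTROLS))
    age_slopes: dict = field(default_factory=lambda: dict(DEFAULT_AGE_SLOPES))
    factor_loading: float = 0.3  # fraction of each metric SD on the shared factor
    nol_driver: str = "vd_deep"
    nol_metric_slope: float = -200.0  # lesions per unit of driver metric
    nol_age_slope: float = 0.4  # lesions per year
    wmi_age_rho: float = 0.45
    wmi_nol_rho: float = 0.3
    rho_eye: float = 0.8
    mean_width_sup: tuple[float, float] = (4.2, 0.2)  # px, for skeleton density
    mean_width_deep: tuple[float, float] = (3.6, 0.2)
    fazekas_probs: tuple[float, float, float] = (0.55, 0.30, 0.15)
    female_frac: float = 0.6
    tissue_volumes_ml: tuple[float, float, float] = (700.0, 600.0, 200.0)
    tissue_jitter_ml: tuple[float, float, float] = (30.0, 30.0, 15.0)
    include_flow_voids: bool = True
    void_slope: float = -1.5
    void_intercepts: dict = field(default_factory=lambda: {"control": 2.8, "case": 2.6})
    void_intercept_sd: dict = field(default_factory=lambda: {"control": 0.06, "case": 0.18})
    void_size_range: tuple[float, float] = (4.0, 300.0)
    px_size_um: float = 6.0
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 2 or self.n_controls < 2:
            raise GenerationError("n_cases and n_controls must both be >= 2")
        for name, params in (("cases", self.cases), ("controls", self.controls)):
            for key, (mean, sd) in params.items():
                if sd < 0:
                    raise GenerationError(f"{name}[{key}] has negative SD {sd}")
            if params["wmi"][0] <= 0:
                raise GenerationError(f"{name} WMI mean must be > 0 (log-transformable)")
        if not 0.0 <= self.rho_eye < 1.0:
            raise GenerationError("rho_eye must be in [0, 1)")
        if self.wmi_age_rho**2 + self.wmi_nol_rho**2 >= 1.0:
            raise GenerationError(
                "implied covariance not positive definite for pair (wmi_age_rho, wmi_nol_rho)"
            )


def _trunc_normal(rng, mean, sd, lo, hi, size=None):
    if sd == 0:
        return np.full(size, mean) if size else mean
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _metric_residual_sd(name, sd, age_slope, age_sd, loading):
    var = sd**2 - (age_slope * age_sd) ** 2 - (loading * sd) ** 2
    if var <= 0:
        raise GenerationError(
            f"implied covariance not positive definite for pair ({name}, age): "
            f"age slope {age_slope} with age SD {age_sd} exceeds metric SD {sd}"
        )
    return math.sqrt(var)


def _lognormal_params(mean, sd):
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def generate_cohort(params: CohortParams, seed: int | None = None) -> list[ParticipantRecord]:
    """Draw a synthetic participant cohort under the structural effect model.

    See :class:`CohortParams`. Deterministic given ``params.rng_seed`` (or the
    ``seed`` override).
    """
    params.validate()
    rng = np.random.default_rng(params.rng_seed if seed is None else seed)
    records: list[ParticipantRecord] = []
    specs = [("case", params.cases, params.n_cases), ("control", params.controls, params.n_controls)]
    idx = 0
    for group, gp, n in specs:
        age_mean, age_sd = gp["age"]
        a, b = (18.0 - age_mean) / age_sd, (100.0 - age_mean) / age_sd
        age_center = truncnorm.mean(a, b, loc=age_mean, scale=age_sd)
        resid_sd = {
            m: _metric_residual_sd(
                m, gp[m][1], params.age_slopes[m], age_sd, params.factor_loading
            )
            for m in _EYE_METRICS
        }
        # NOL latent residual so its marginal SD matches the configured value
        d_mean, d_sd = gp[params.nol_driver]
        d_gamma = params.age_slopes[params.nol_driver]
        nol_mean, nol_sd = gp["nol"]
        struct_var = (
            (params.nol_age_slope * age_sd) ** 2
            + (params.nol_metric_slope * d_sd) ** 2
            + 2.0 * params.nol_age_slope * params.nol_metric_slope * d_gamma * age_sd**2
        )
        if struct_var >= nol_sd**2:
            raise GenerationError(
                "implied covariance not positive definite for pair (nol, "
                f"{params.nol_driver}): structural variance {struct_var:.3g} exceeds "
                f"NOL variance {nol_sd**2:.3g}"
            )
        nol_resid_sd = math.sqrt(nol_sd**2 - struct_var)
        lw_mu, lw_sigma = _lognormal_params(*gp["wmi"])

        for _ in range(n):
            idx += 1
            age = float(_trunc_normal(rng, age_mean, age_sd, 18.0, 100.0))
            d_age = age - age_center
            u = rng.normal()
            values = {}
            for m in _EYE_METRICS:
                mean_m, sd_m = gp[m]
                values[m] = (
                    mean_m
                    + params.age_slopes[m] * d_age
                    - params.factor_loading * sd_m * u
                    + rng.normal(0.0, resid_sd[m])
                )
                lo, hi = _METRIC_BOUNDS[m]
                values[m] = float(np.clip(values[m], lo, hi))
            nol_eps = rng.normal(0.0, nol_resid_sd)
            nol_latent = (
                nol_mean
                + params.nol_age_slope * d_age
                + params.nol_metric_slope * (values[params.nol_driver] - d_mean)
                + nol_eps
            )
            nol = int(max(0, round(nol_latent)))
            z_eps = nol_eps / nol_resid_sd if nol_resid_sd > 0 else 0.0
            z_res = math.sqrt(max(0.0, 1.0 - params.wmi_age_rho**2 - params.wmi_nol_rho**2))
            z_lw = (
                params.wmi_age_rho * (d_age / age_sd)
                + params.wmi_nol_rho * z_eps
                + z_res * rng.normal()
            )
            wmi = float(np.exp(lw_mu + lw_sigma * z_lw))

            moca = float(np.round(_trunc_normal(rng, *gp["moca"], 0.0, 30.0)))
            sex = "f" if rng.random() < params.female_frac else "m"
            fazekas = 0 if group == "control" else int(
                rng.choice([1, 2, 3], p=params.fazekas_probs)
            )

            # two eyes symmetric about the participant value: corr(OD, OS) = rho_eye
            eyes: dict[str, dict[str, float]] = {"OD": {}, "OS": {}}
            for m in _EYE_METRICS:
                sd_m = gp[m][1]
                tau = sd_m * math.sqrt((1.0 - params.rho_eye) / (1.0 + params.rho_eye))
                d = rng.normal(0.0, tau)
                lo, hi = _METRIC_BOUNDS[m]
                eyes["OD"][m] = float(np.clip(values[m] + d, lo, hi))
                eyes["OS"][m] = float(np.clip(values[m] - d, lo, hi))
            w_sup = max(1.5, rng.normal(*params.mean_width_sup))
            w_deep = max(1.5, rng.normal(*params.mean_width_deep))
            for eye in ("OD", "OS"):
                eyes[eye]["sd_sup"] = eyes[eye]["vd_sup"] / w_sup
                eyes[eye]["sd_deep"] = eyes[eye]["vd_deep"] / w_deep

            if params.include_flow_voids:
                icpt = params.void_intercepts[group] + rng.normal(
                    0.0, params.void_intercept_sd[group]
                )
                for eye in ("OD", "OS"):
                    sizes_px = sample_void_sizes(
                        rng, params.void_slope, icpt, params.void_size_range
                    )
                    sizes_um2 = sizes_px * params.px_size_um**2
                    eyes[eye]["fv_n"] = float(sizes_px.size)
                    eyes[eye]["fv_mean_um2"] = (
                        float(sizes_um2.mean()) if sizes_px.size else np.nan
                    )
                    try:
                        fit = fit_powerlaw_sizes(sizes_um2)
                        eyes[eye]["fv_slope"] = fit.slope
                        eyes[eye]["fv_intercept"] = fit.intercept
                    except (InsufficientDataError, OctavascError):
                        eyes[eye]["fv_slope"] = np.nan
                        eyes[eye]["fv_intercept"] = np.nan

            tissues = tuple(
                float(max(t + rng.normal(0.0, j), 1.0))
                for t, j in zip(params.tissue_volumes_ml, params.tissue_jitter_ml)
            )
            tiv = float(sum(tissues))
            mri = MriSummary(
                nol=nol,
                lesion_volume_ml=wmi * tiv / 100.0,
                tiv_ml=tiv,
                wmi=wmi,
                log_wmi=math.log(wmi),
            )
            records.append(
                ParticipantRecord(
                    id=f"P{idx:04d}",
                    age=age,
                    sex=sex,
                    fazekas=fazekas,
                    moca=moca,
                    eyes=eyes,
                    eye_quality={"OD": 10, "OS": 10},
                    mri=mri,
                )
            )
    return records


def make_screening_roster(
    seed: int = 0,
    n_ocular: int = 18,
    n_quality: int = 9,
    n_neuro: int = 5,
    fazekas_counts: tuple[int, int, int, int] = (10, 11, 6, 3),
) -> list[ParticipantRecord]:
    """Build a screening roster with the study's exclusion and grade structure.

    The included participants carry the given Fazekas composition
    (default 10 grade-0 controls and 20 graded cases); the remainder are
    flagged with one exclusion reason each (disjoint flags).
    """
    rng = np.random.default_rng(seed)
    records = []
    idx = 0
    for grade, n in zip((0, 1, 2, 3), fazekas_counts):
        for _ in range(n):
            idx += 1
            mean_age = 58.0 if grade == 0 else 63.0
            records.append(
                ParticipantRecord(
                    id=f"S{idx:04d}",
                    age=float(_trunc_normal(rng, mean_age, 8.0, 18.0, 100.0)),
                    sex="f" if rng.random() < 0.6 else "m",
                    fazekas=grade,
                )
            )
    for reason, n in (
        ("ocular_disease", n_ocular),
        ("poor_image_quality", n_quality),
        ("neurologic_abnormality", n_neuro),
    ):
        for _ in range(n):
            idx += 1
            records.append(
                ParticipantRecord(
                    id=f"S{idx:04d}",
                    age=float(_trunc_normal(rng, 61.0, 10.0, 18.0, 100.0)),
                    sex="f" if rng.random() < 0.6 else "m",
                    fazekas=int(rng.integers(0, 4)),
                    exclusion_flags={reason},
                )
            )
    rng.shuffle(records)
    return records
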