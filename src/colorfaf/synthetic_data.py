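"""Synthetic color-FAF images and synthetic cohorts with known ground truth.

No raw study data are available, so every pipeline stage is exercised on
synthetic inputs whose true parameters are known:

* :func:`generate_eye_image` paints sector-wise constant GEFC/REFC means
  (plus truncated Gaussian noise) into an RGB raster, overlays dark
  vessel random-walk curves and focal lesions (small dark
  microaneurysms, dark hemorrhages, bright hard exudates), and returns
  the matching ground-truth exclusion mask.

* :func:`generate_cohort` draws one-row-per-eye cohorts with the group
  structure of the study population (18 controls + 193 diabetic eyes
  across four DR grades, 41 of them with center-involving DME) and
  sector intensity marginals set to the published mean ± SD values by
  DME status.  Foveal GEFC/REFC are coupled to central retinal thickness
  through a Gaussian copula calibrated so that the *pooled* Pearson
  correlation over the diabetic eyes equals the configured value
  (defaults 0.37 and 0.42; inner-nasal GEFC 0.49).

Marginals are Gaussians truncated at zero whose parent parameters are
moment-matched, so the truncated distribution has *exactly* the
configured mean and SD.  A printed summary whose SD is too large
relative to its mean for any non-negative truncated normal (this occurs
for two published sector summaries) falls back to a gamma marginal with
the exact configured moments.

Because DME eyes have higher foveal intensity *and* higher thickness,
the DME/no-DME mixture alone already induces a pooled correlation close
to the target; the calibration solves (via a Hermite-series expansion of
the covariance under the Gaussian copula) for the within-status latent
correlation — possibly slightly negative — that makes the pooled
population correlation land exactly on the configured value.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from scipy import stats as sps
from skimage.draw import disk as draw_disk

from .etdrs_grid import ETDRSGrid, all_sector_masks, grid_from_metadata
from .imaging_io import (
    COHORT_COLUMNS,
    ExclusionMask,
    FundusImage,
    ImageMetadata,
    SECTORS,
    default_disc_side,
)
from .spectral import estimate_wavelength

# ---------------------------------------------------------------------------
# published cohort constants (mean, sd) used as generator defaults
# ---------------------------------------------------------------------------

#: Sector intensity summaries by DME status: {sector: {component: {status: (mean, sd)}}}
SECTOR_INTENSITY: dict[str, dict[str, dict[str, tuple[float, float]]]] = {
    "fovea": {
        "gefc": {"no_dme": (17.4, 14.1), "dme": (43.3, 21.2)},
        "refc": {"no_dme": (18.5, 12.6), "dme": (47.1, 21.4)},
    },
    "inner_nasal": {
        "gefc": {"no_dme": (52.2, 25.9), "dme": (54.7, 21.2)},
        "refc": {"no_dme": (62.0, 23.3), "dme": (62.7, 21.1)},
    },
    "outer_nasal": {
        "gefc": {"no_dme": (74.9, 23.5), "dme": (68.5, 15.4)},
        "refc": {"no_dme": (96.4, 25.3), "dme": (88.6, 17.3)},
    },
    "inner_superior": {
        "gefc": {"no_dme": (53.2, 19.3), "dme": (52.0, 21.6)},
        "refc": {"no_dme": (64.2, 19.7), "dme": (61.0, 21.7)},
    },
    "outer_superior": {
        "gefc": {"no_dme": (87.9, 21.9), "dme": (75.2, 25.3)},
        "refc": {"no_dme": (111.7, 26.7), "dme": (89.2, 23.7)},
    },
    "inner_inferior": {
        "gefc": {"no_dme": (55.2, 18.4), "dme": (53.7, 15.2)},
        "refc": {"no_dme": (73.5, 79.8), "dme": (62.5, 16.5)},
    },
    "outer_inferior": {
        "gefc": {"no_dme": (78.5, 20.6), "dme": (74.7, 20.7)},
        "refc": {"no_dme": (104.4, 88.9), "dme": (93.2, 6.1)},
    },
    "inner_temporal": {
        "gefc": {"no_dme": (55.9, 19.7), "dme": (50.7, 19.4)},
        "refc": {"no_dme": (65.9, 19.8), "dme": (60.3, 19.4)},
    },
    "outer_temporal": {
        "gefc": {"no_dme": (78.4, 21.8), "dme": (64.9, 23.6)},
        "refc": {"no_dme": (95.0, 23.1), "dme": (79.4, 26.3)},
    },
}

#: Healthy-control foveal intensities (mean, sd).
CONTROL_FOVEA: dict[str, tuple[float, float]] = {"gefc": (9.1, 6.1), "refc": (10.0, 6.6)}

#: Study group sizes.
GROUP_SIZES: dict[str, int] = {
    "control": 18,
    "noDR": 39,
    "mildDR": 22,
    "moderateDR": 100,
    "sightThreateningDR": 32,
}

#: Per-group HbA1c %, DM duration (years), BCVA (ETDRS letters): (mean, sd).
GROUP_HBA1C = {"noDR": (6.7, 1.3), "mildDR": (7.2, 0.9),
               "moderateDR": (7.6, 1.3), "sightThreateningDR": (7.4, 1.5)}
GROUP_DURATION = {"noDR": (9.5, 7.1), "mildDR": (18.0, 9.6),
                  "moderateDR": (15.2, 9.2), "sightThreateningDR": (16.6, 8.5)}
GROUP_BCVA = {"control": (85.0, 0.0), "noDR": (83.8, 2.2), "mildDR": (82.3, 4.9),
              "moderateDR": (75.4, 11.4), "sightThreateningDR": (76.3, 9.8)}


class SimConfigError(ValueError):
    """Raised when a simulation configuration is invalid or infeasible."""


# ---------------------------------------------------------------------------
# marginal distributions (exact configured moments, non-negative support)
# ---------------------------------------------------------------------------

_ZGRID = np.linspace(-8.0, 8.0, 4001)
_PHI = sps.norm.pdf(_ZGRID)
_UGRID = np.clip(sps.norm.cdf(_ZGRID), 1e-16, 1 - 1e-16)


class _Marginal:
    """A 1-D marginal reachable from a standard-normal latent via its quantile map."""

    mean: float
    sd: float

    def from_z(self, z: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def hermite_coeffs(self, order: int = 12) -> np.ndarray:
        """Coefficients c_k = E[h(Z) He_k(Z)] / k! of the quantile map h.

        Under a Gaussian copula with latent correlation rho,
        Cov(h1(Z1), h2(Z2)) = sum_k k! c1_k c2_k rho^k.
        """
        cache = getattr(self, "_hermite_cache", None)
        if cache is not None and cache[0] == order:
            return cache[1]
        h = self.from_z(_ZGRID)
        he_prev = np.ones_like(_ZGRID)  # He_0
        he = _ZGRID.copy()  # He_1
        coeffs = np.empty(order)
        kfact = 1.0
        for k in range(1, order + 1):
            kfact *= k
            coeffs[k - 1] = np.trapezoid(h * he * _PHI, _ZGRID) / kfact
            he, he_prev = _ZGRID * he - k * he_prev, he
        self._hermite_cache = (order, coeffs)
        return coeffs


@dataclass
class NormalMarginal(_Marginal):
    mean: float
    sd: float

    def from_z(self, z):
        return self.mean + self.sd * np.asarray(z, dtype=float)


@dataclass
class GammaMarginal(_Marginal):
    """Gamma marginal with exact (mean, sd); fallback for summaries whose
    SD is too large for any normal truncated at the lower bound."""

    mean: float
    sd: float
    lower: float = 0.0

    def __post_init__(self) -> None:
        m = self.mean - self.lower
        if m <= 0 or self.sd <= 0:
            raise SimConfigError("gamma marginal needs mean > lower and sd > 0")
        self._shape = (m / self.sd) ** 2
        self._scale = self.sd**2 / m

    def from_z(self, z):
        u = np.clip(sps.norm.cdf(np.asarray(z, dtype=float)), 1e-16, 1 - 1e-16)
        return self.lower + sps.gamma.ppf(u, self._shape, scale=self._scale)


@dataclass
class TruncatedNormalMarginal(_Marginal):
    """Normal truncated below at ``lower``, moment-matched so that the
    *truncated* distribution has exactly the configured mean and SD."""

    mean: float
    sd: float
    lower: float = 0.0

    def __post_init__(self) -> None:
        m = self.mean - self.lower
        if m <= 0 or self.sd <= 0:
            raise SimConfigError("truncated normal needs mean > lower and sd > 0")
        ratio = self.sd / m
        if ratio >= 0.99:
            raise SimConfigError(
                f"no truncated normal has mean {self.mean} and sd {self.sd} "
                f"above {self.lower} (sd/(mean-lower) = {ratio:.2f} >= 1)"
            )
        if ratio <= 0.12:
            # truncation mass < 1e-15: parent = configured
            self._alpha = -np.inf
            self._loc, self._scale = self.mean, self.sd
            return
        alpha = optimize.brentq(lambda a: _truncated_ratio(a) - ratio, -8.1, 40.0)
        lam = _mills(alpha)
        scale = self.sd / math.sqrt(1.0 + alpha * lam - lam**2)
        self._alpha = alpha
        self._scale = scale
        self._loc = self.lower - alpha * scale

    def from_z(self, z):
        u = np.clip(sps.norm.cdf(np.asarray(z, dtype=float)), 1e-16, 1 - 1e-16)
        if not np.isfinite(self._alpha):
            return self._loc + self._scale * sps.norm.ppf(u)
        return sps.truncnorm.ppf(u, self._alpha, np.inf, loc=self._loc, scale=self._scale)


def _mills(alpha: float) -> float:
    """Inverse Mills ratio phi(a) / (1 - Phi(a)), computed in log space."""
    return math.exp(sps.norm.logpdf(alpha) - sps.norm.logsf(alpha))


def _truncated_ratio(alpha: float) -> float:
    """sd/mean of a standard normal truncated below at alpha, shifted to start at 0."""
    lam = _mills(alpha)
    var = 1.0 + alpha * lam - lam**2
    return math.sqrt(max(var, 0.0)) / (lam - alpha)


@functools.lru_cache(maxsize=512)
def nonnegative_marginal(mean: float, sd: float, lower: float = 0.0) -> _Marginal:
    """Best-effort marginal with exact (mean, sd) supported on [lower, inf).

    Instances are cached by parameters (they are immutable in use), so
    repeated cohort draws share the moment-matching and Hermite work.
    """
    try:
        return TruncatedNormalMarginal(mean, sd, lower)
    except SimConfigError:
        return GammaMarginal(mean, sd, lower)


# ---------------------------------------------------------------------------
# pooled-correlation calibration
# ---------------------------------------------------------------------------

def calibrate_latent_rho(
    target_r: float,
    strata: list[tuple[float, _Marginal, _Marginal]],
    order: int = 12,
) -> float:
    """Latent Gaussian-copula correlation giving a pooled Pearson ``target_r``.

    ``strata`` holds ``(weight, intensity_marginal, thickness_marginal)``
    per stratum; weights must sum to 1.  The pooled covariance is the
    weighted within-stratum covariance (a polynomial in the latent rho
    via the Hermite expansion) plus the between-stratum term; brentq
    solves for the latent rho.  Raises when no latent correlation in
    (-1, 1) can achieve the target.
    """
    if not -1.0 < target_r < 1.0:
        raise SimConfigError(f"target correlation must be in (-1, 1), got {target_r}")
    ws = np.array([w for w, _, _ in strata])
    if abs(ws.sum() - 1.0) > 1e-9:
        raise SimConfigError("stratum weights must sum to 1")
    mi = np.array([im.mean for _, im, _ in strata])
    mt = np.array([tm.mean for _, _, tm in strata])
    vi = np.array([im.sd**2 for _, im, _ in strata])
    vt = np.array([tm.sd**2 for _, _, tm in strata])
    mbar_i, mbar_t = ws @ mi, ws @ mt
    pooled_sd_i = math.sqrt(ws @ (vi + (mi - mbar_i) ** 2))
    pooled_sd_t = math.sqrt(ws @ (vt + (mt - mbar_t) ** 2))
    between = ws @ ((mi - mbar_i) * (mt - mbar_t))
    kfact = np.cumprod(np.arange(1, order + 1)).astype(float)
    coeffs = [
        kfact * im.hermite_coeffs(order) * tm.hermite_coeffs(order)
        for _, im, tm in strata
    ]
    powers = np.arange(1, order + 1)

    def pooled_cov(rho: float) -> float:
        rp = rho**powers
        return float(sum(w * (c @ rp) for (w, _, _), c in zip(strata, coeffs)) + between)

    target_cov = target_r * pooled_sd_i * pooled_sd_t
    lo, hi = -0.999, 0.999
    if not (pooled_cov(lo) - target_cov) * (pooled_cov(hi) - target_cov) < 0:
        raise SimConfigError(
            f"pooled correlation {target_r} infeasible for the configured marginals"
        )
    return float(optimize.brentq(lambda r: pooled_cov(r) - target_cov, lo, hi))


# ---------------------------------------------------------------------------
# image simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VesselSpec:
    count: int = 4
    width_um: float = 60.0
    darkness: float = 0.35  # multiplicative factor on R and G under the vessel

    def __post_init__(self) -> None:
        if self.count < 0 or self.width_um <= 0 or not 0 <= self.darkness <= 1:
            raise SimConfigError("invalid vessel spec")


@dataclass(frozen=True)
class LesionSpec:
    kind: str  # microaneurysm | hemorrhage | exudate
    count: int
    radius_um: float

    def __post_init__(self) -> None:
        if self.kind not in ("microaneurysm", "hemorrhage", "exudate"):
            raise SimConfigError(f"unknown lesion kind {self.kind!r}")
        if self.count < 0 or self.radius_um <= 0:
            raise SimConfigError("invalid lesion spec")


#: Multiplicative channel factors per lesion kind (hemorrhages dark in both
#: channels, exudates bright, microaneurysms small and dark).
_LESION_FACTOR = {"microaneurysm": 0.3, "hemorrhage": 0.25, "exudate": 1.7}

DEFAULT_LESIONS: tuple[LesionSpec, ...] = (
    LesionSpec("microaneurysm", 4, 30.0),
    LesionSpec("hemorrhage", 1, 150.0),
    LesionSpec("exudate", 2, 80.0),
)

#: Foveal uplift applied under DME: difference of the published DME vs
#: no-DME foveal means.
DME_UPLIFT = {
    "gefc": SECTOR_INTENSITY["fovea"]["gefc"]["dme"][0]
    - SECTOR_INTENSITY["fovea"]["gefc"]["no_dme"][0],
    "refc": SECTOR_INTENSITY["fovea"]["refc"]["dme"][0]
    - SECTOR_INTENSITY["fovea"]["refc"]["no_dme"][0],
}


def _default_sector_means(component: str) -> dict[str, float]:
    return {s: SECTOR_INTENSITY[s][component]["no_dme"][0] for s in SECTORS}


@dataclass
class ImageSimConfig:
    """Configuration of one synthetic color-FAF image.

    Sector means default to the published no-DME sector intensities; the
    ``dme`` flag adds the published DME-minus-no-DME foveal uplift.
    """

    shape: tuple[int, int] = (1300, 1300)
    um_per_pixel: float = 5.0
    eye_id: str = "synthetic"
    laterality: str = "OD"
    fovea_center: tuple[float, float] | None = None
    sector_gefc: dict[str, float] = field(default_factory=lambda: _default_sector_means("gefc"))
    sector_refc: dict[str, float] = field(default_factory=lambda: _default_sector_means("refc"))
    background: tuple[float, float] | None = None  # (gefc, refc) outside the grid
    blue_level: int = 10
    noise_sd: float = 4.0
    vessels: VesselSpec = VesselSpec()
    lesions: tuple[LesionSpec, ...] = DEFAULT_LESIONS
    dme: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for d in (self.sector_gefc, self.sector_refc):
            missing = set(SECTORS) - d.keys()
            if missing:
                raise SimConfigError(f"sector means missing: {sorted(missing)}")
            for s, m in d.items():
                if not 0 <= m <= 255:
                    raise SimConfigError(f"sector mean out of [0, 255]: {s} = {m}")
        if self.noise_sd < 0:
            raise SimConfigError("noise_sd must be >= 0")


def _truth_means(config: ImageSimConfig) -> dict[str, dict[str, float]]:
    truth: dict[str, dict[str, float]] = {}
    for s in SECTORS:
        g = config.sector_gefc[s]
        r = config.sector_refc[s]
        if config.dme and s == "fovea":
            g = min(255.0, g + DME_UPLIFT["gefc"])
            r = min(255.0, r + DME_UPLIFT["refc"])
        total = g + r
        wav = estimate_wavelength(g / total) if total > 0 else float("nan")
        truth[s] = {"gefc": g, "refc": r, "wavelength": wav}
    return truth


def _add_truncated_noise(
    field_arr: np.ndarray, region: np.ndarray, mean: float, sd: float, rng
) -> None:
    """Fill ``region`` with N(mean, sd) truncated to [0, 255]."""
    n = int(region.sum())
    if n == 0:
        return
    if sd == 0:
        field_arr[region] = mean
        return
    a, b = (0.0 - mean) / sd, (255.0 - mean) / sd
    field_arr[region] = sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _draw_vessels(spec: VesselSpec, shape: tuple[int, int], um_per_pixel: float, rng) -> np.ndarray:
    """Dark vessel footprints as smooth random-walk curves crossing the image."""
    footprint = np.zeros(shape, dtype=bool)
    h, w = shape
    radius = max(1, int(round(spec.width_um / 2.0 / um_per_pixel)))
    max_steps = int(2.5 * max(h, w))
    for _ in range(spec.count):
        edge = rng.integers(4)
        if edge == 0:
            pos = np.array([0.0, rng.uniform(0, w - 1)])
        elif edge == 1:
            pos = np.array([h - 1.0, rng.uniform(0, w - 1)])
        elif edge == 2:
            pos = np.array([rng.uniform(0, h - 1), 0.0])
        else:
            pos = np.array([rng.uniform(0, h - 1), w - 1.0])
        # head toward the image center, then meander
        heading = math.atan2(h / 2 - pos[0], w / 2 - pos[1]) + rng.normal(0, 0.4)
        step = 2.0
        for _ in range(max_steps):
            rr, cc = draw_disk((pos[0], pos[1]), radius, shape=shape)
            footprint[rr, cc] = True
            heading += rng.normal(0.0, 0.15)
            pos += step * np.array([math.sin(heading), math.cos(heading)])
            if not (0 <= pos[0] < h and 0 <= pos[1] < w):
                break
    return footprint


def generate_eye_image(
    config: ImageSimConfig, seed: int | None = None
) -> tuple[FundusImage, ExclusionMask, dict]:
    """Render one synthetic eye: image, ground-truth exclusion mask, truth record.

    The R/G channels hold the per-sector programmed means plus additive
    truncated Gaussian noise; vessels and lesions darken/brighten their
    footprints, and the exclusion mask is the union of those footprints
    dilated by one pixel.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    h, w = config.shape
    fovea = config.fovea_center or ((h - 1) / 2.0, (w - 1) / 2.0)
    meta = ImageMetadata(
        eye_id=config.eye_id,
        fovea_center=fovea,
        um_per_pixel=config.um_per_pixel,
        laterality=config.laterality,
        disc_side=default_disc_side(config.laterality),
    )
    grid = grid_from_metadata(meta)
    masks = all_sector_masks(grid, config.shape)
    truth = _truth_means(config)

    gefc = np.zeros(config.shape, dtype=float)
    refc = np.zeros(config.shape, dtype=float)
    in_grid = np.zeros(config.shape, dtype=bool)
    for s in SECTORS:
        in_grid |= masks[s]
    if config.background is None:
        bg_g = float(np.mean([truth[s]["gefc"] for s in SECTORS if s.startswith("outer")]))
        bg_r = float(np.mean([truth[s]["refc"] for s in SECTORS if s.startswith("outer")]))
    else:
        bg_g, bg_r = config.background
    _add_truncated_noise(gefc, ~in_grid, bg_g, config.noise_sd, rng)
    _add_truncated_noise(refc, ~in_grid, bg_r, config.noise_sd, rng)
    for s in SECTORS:
        _add_truncated_noise(gefc, masks[s], truth[s]["gefc"], config.noise_sd, rng)
        _add_truncated_noise(refc, masks[s], truth[s]["refc"], config.noise_sd, rng)

    vessel_fp = _draw_vessels(config.vessels, config.shape, config.um_per_pixel, rng)
    lesion_fp = np.zeros(config.shape, dtype=bool)
    grid_rad_px = grid.radius_px
    for spec in config.lesions:
        factor = _LESION_FACTOR[spec.kind]
        r_px = max(1, int(round(spec.radius_um / config.um_per_pixel)))
        for _ in range(spec.count):
            ang = rng.uniform(0, 2 * math.pi)
            rad = grid_rad_px * math.sqrt(rng.uniform())
            center = (fovea[0] + rad * math.sin(ang), fovea[1] + rad * math.cos(ang))
            rr, cc = draw_disk(center, r_px, shape=config.shape)
            lesion_fp[rr, cc] = True
            gefc[rr, cc] *= factor
            refc[rr, cc] *= factor
    gefc[vessel_fp] *= config.vessels.darkness
    refc[vessel_fp] *= config.vessels.darkness

    exclusion_px = ndimage.binary_dilation(vessel_fp | lesion_fp, iterations=1)
    for s in SECTORS:
        if not (masks[s] & ~exclusion_px).any():
            raise SimConfigError(f"vessel/lesion coverage leaves sector {s} with no clean area")

    pixels = np.zeros((h, w, 3), dtype=np.uint8)
    pixels[:, :, 0] = np.clip(np.rint(refc), 0, 255).astype(np.uint8)
    pixels[:, :, 1] = np.clip(np.rint(gefc), 0, 255).astype(np.uint8)
    pixels[:, :, 2] = config.blue_level
    image = FundusImage(pixels=pixels, metadata=meta)
    mask = ExclusionMask(pixels=exclusion_px)
    record = {
        "eye_id": config.eye_id,
        "dme": config.dme,
        "noise_sd": config.noise_sd,
        "sectors": truth,
    }
    return image, mask, record


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class CohortSimConfig:
    """Configuration of a synthetic cohort.

    Defaults reproduce the study population: 18 controls plus 193
    diabetic eyes (39 no DR, 22 mild, 100 moderate, 32 sight-threatening
    DR), 41 with center-involving DME; sector intensity marginals from
    the published DME-stratified summaries; foveal intensity-thickness
    coupling 0.37 (GEFC) and 0.42 (REFC), inner-nasal GEFC 0.49.
    """

    group_sizes: dict[str, int] = field(default_factory=lambda: dict(GROUP_SIZES))
    n_dme: int = 41
    sector_intensity: dict = field(default_factory=lambda: SECTOR_INTENSITY)
    control_fovea: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(CONTROL_FOVEA)
    )
    rho_fovea_gefc: float = 0.37
    rho_fovea_refc: float = 0.42
    rho_inner_nasal_gefc: float = 0.49
    #: central retinal thickness (µm): mean, sd by DME status; DME floored at 300
    crt_no_dme: tuple[float, float] = (275.0, 25.0)
    crt_dme: tuple[float, float] = (360.0, 55.0)
    crt_dme_floor: float = 300.0
    inner_thickness_no_dme: tuple[float, float] = (330.0, 25.0)
    inner_thickness_dme: tuple[float, float] = (400.0, 60.0)
    outer_thickness_no_dme: tuple[float, float] = (285.0, 20.0)
    outer_thickness_dme: tuple[float, float] = (305.0, 35.0)
    irf_prob_dme: float = 0.2
    irf_prob_no_dme: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if n <= 0:
                raise SimConfigError(f"group size must be positive: {g} = {n}")
        for rho in (self.rho_fovea_gefc, self.rho_fovea_refc, self.rho_inner_nasal_gefc):
            if not -1.0 < rho < 1.0:
                raise SimConfigError(f"correlation out of (-1, 1): {rho}")
        n_dr = sum(
            n for g, n in self.group_sizes.items()
            if g not in ("control", "noDR")
        )
        if self.n_dme > n_dr:
            raise SimConfigError(
                f"n_dme = {self.n_dme} exceeds the {n_dr} eyes with retinopathy"
            )

    @property
    def n_diabetic(self) -> int:
        return sum(n for g, n in self.group_sizes.items() if g != "control")


def _intensity_marginal(config: CohortSimConfig, sector: str, component: str, status: str) -> _Marginal:
    if status == "control":
        if sector == "fovea":
            mean, sd = config.control_fovea[component]
        else:
            # control non-foveal summaries are unpublished; reuse the
            # no-DME diabetic values
            mean, sd = config.sector_intensity[sector][component]["no_dme"]
    else:
        mean, sd = config.sector_intensity[sector][component][status]
    return nonnegative_marginal(mean, sd)


def _crt_marginal(config: CohortSimConfig, status: str) -> _Marginal:
    if status == "dme":
        m, s = config.crt_dme
        return nonnegative_marginal(m, s, lower=config.crt_dme_floor)
    m, s = config.crt_no_dme
    return NormalMarginal(m, s)


def _diabetic_strata(
    config: CohortSimConfig, sector: str, component: str
) -> list[tuple[float, _Marginal, _Marginal]]:
    n_dia = config.n_diabetic
    w_dme = config.n_dme / n_dia
    if sector == "fovea":
        thick = {"no_dme": _crt_marginal(config, "no_dme"), "dme": _crt_marginal(config, "dme")}
    else:
        thick = {
            "no_dme": NormalMarginal(*config.inner_thickness_no_dme),
            "dme": NormalMarginal(*config.inner_thickness_dme),
        }
    return [
        (1.0 - w_dme, _intensity_marginal(config, sector, component, "no_dme"), thick["no_dme"]),
        (w_dme, _intensity_marginal(config, sector, component, "dme"), thick["dme"]),
    ]


_RHO_CACHE: dict[tuple, tuple[float, float, float]] = {}


def _calibrated_rhos(config: CohortSimConfig) -> tuple[float, float, float]:
    """The three latent copula correlations, memoized per configuration."""
    key = (
        config.rho_fovea_gefc, config.rho_fovea_refc, config.rho_inner_nasal_gefc,
        config.n_dme, config.n_diabetic,
        config.crt_no_dme, config.crt_dme, config.crt_dme_floor,
        config.inner_thickness_no_dme, config.inner_thickness_dme,
        config.sector_intensity["fovea"]["gefc"]["no_dme"],
        config.sector_intensity["fovea"]["gefc"]["dme"],
        config.sector_intensity["fovea"]["refc"]["no_dme"],
        config.sector_intensity["fovea"]["refc"]["dme"],
        config.sector_intensity["inner_nasal"]["gefc"]["no_dme"],
        config.sector_intensity["inner_nasal"]["gefc"]["dme"],
    )
    if key not in _RHO_CACHE:
        _RHO_CACHE[key] = (
            calibrate_latent_rho(
                config.rho_fovea_gefc, _diabetic_strata(config, "fovea", "gefc")
            ),
            calibrate_latent_rho(
                config.rho_fovea_refc, _diabetic_strata(config, "fovea", "refc")
            ),
            calibrate_latent_rho(
                config.rho_inner_nasal_gefc, _diabetic_strata(config, "inner_nasal", "gefc")
            ),
        )
    return _RHO_CACHE[key]


def _from_z_by_status(
    z: np.ndarray, status: np.ndarray, marginals: dict[str, _Marginal]
) -> np.ndarray:
    out = np.empty_like(z)
    for s, marg in marginals.items():
        sel = status == s
        if sel.any():
            out[sel] = marg.from_z(z[sel])
    return out


def generate_cohort(config: CohortSimConfig | None = None, seed: int | None = None):
    """Draw one synthetic cohort as a cohort-CSV-shaped DataFrame.

    Deterministic under ``seed`` (falls back to ``config.seed``).  DME
    eyes are assigned among eyes with retinopathy; their central
    thickness marginal is floored at 300 µm.  Foveal GEFC/REFC and
    inner-nasal GEFC are coupled to the matching sector thickness via
    the calibrated Gaussian copula; all other sector values are drawn
    independently.
    """
    import pandas as pd

    config = config or CohortSimConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    groups = [g for g in GROUP_SIZES if g in config.group_sizes]
    group_col = np.concatenate(
        [np.full(config.group_sizes[g], g) for g in groups]
    )
    n = len(group_col)
    order = rng.permutation(n)  # interleave groups in the id ordering
    group_col = group_col[order]
    eye_ids = np.array([f"eye_{i:04d}" for i in range(n)])

    dr_idx = np.flatnonzero(~np.isin(group_col, ("control", "noDR")))
    dme = np.zeros(n, dtype=bool)
    dme[rng.choice(dr_idx, size=config.n_dme, replace=False)] = True
    diabetic = group_col != "control"
    status = np.where(~diabetic, "control", np.where(dme, "dme", "no_dme"))

    # latent copula correlations calibrated on the diabetic strata
    rho_g, rho_r, rho_in = _calibrated_rhos(config)

    def couple(z_t: np.ndarray, rho: float) -> np.ndarray:
        eps = rng.standard_normal(n)
        z = rho * z_t + math.sqrt(1.0 - rho**2) * eps
        return np.where(diabetic, z, eps)  # controls: uncoupled

    cols: dict[str, np.ndarray] = {}

    # --- fovea: (thickness, gefc, refc) coupled for diabetic eyes
    z_t_fovea = rng.standard_normal(n)
    z_g_fovea = couple(z_t_fovea, rho_g)
    z_r_fovea = couple(z_t_fovea, rho_r)
    crt_marg = {
        "control": _crt_marginal(config, "no_dme"),
        "no_dme": _crt_marginal(config, "no_dme"),
        "dme": _crt_marginal(config, "dme"),
    }
    cols["thickness_fovea"] = _from_z_by_status(z_t_fovea, status, crt_marg)
    for comp, z in (("gefc", z_g_fovea), ("refc", z_r_fovea)):
        marg = {s: _intensity_marginal(config, "fovea", comp, s)
                for s in ("control", "no_dme", "dme")}
        cols[f"{comp}_fovea"] = _from_z_by_status(z, status, marg)

    # --- inner nasal: (thickness, gefc) coupled
    z_t_in = rng.standard_normal(n)
    z_g_in = couple(z_t_in, rho_in)
    inner_marg = {
        "control": NormalMarginal(*config.inner_thickness_no_dme),
        "no_dme": NormalMarginal(*config.inner_thickness_no_dme),
        "dme": NormalMarginal(*config.inner_thickness_dme),
    }
    outer_marg = {
        "control": NormalMarginal(*config.outer_thickness_no_dme),
        "no_dme": NormalMarginal(*config.outer_thickness_no_dme),
        "dme": NormalMarginal(*config.outer_thickness_dme),
    }
    cols["thickness_inner_nasal"] = _from_z_by_status(z_t_in, status, inner_marg)
    marg = {s: _intensity_marginal(config, "inner_nasal", "gefc", s)
            for s in ("control", "no_dme", "dme")}
    cols["gefc_inner_nasal"] = _from_z_by_status(z_g_in, status, marg)

    # --- every remaining sector x component: independent draws
    for sector in SECTORS:
        for comp in ("gefc", "refc"):
            key = f"{comp}_{sector}"
            if key in cols:
                continue
            marg = {s: _intensity_marginal(config, sector, comp, s)
                    for s in ("control", "no_dme", "dme")}
            cols[key] = _from_z_by_status(rng.standard_normal(n), status, marg)
        tkey = f"thickness_{sector}"
        if tkey not in cols:
            ring = inner_marg if sector.startswith("inner") else outer_marg
            cols[tkey] = _from_z_by_status(rng.standard_normal(n), status, ring)

    # --- wavelengths from each eye's own sector intensities
    for sector in SECTORS:
        g, r = cols[f"gefc_{sector}"], cols[f"refc_{sector}"]
        total = g + r
        frac = np.where(total > 0, g / np.where(total > 0, total, 1.0), np.nan)
        cols[f"wavelength_{sector}"] = estimate_wavelength(frac)

    # --- IRF flags: foveal IRF accompanies center-involving DME
    cols["irf_fovea"] = dme.astype(int)
    for sector in SECTORS:
        if sector == "fovea":
            continue
        p = np.where(dme, config.irf_prob_dme, config.irf_prob_no_dme)
        p = np.where(diabetic, p, 0.0)
        cols[f"irf_{sector}"] = (rng.uniform(size=n) < p).astype(int)

    # --- clinical covariates by group
    hba1c = np.full(n, np.nan)
    duration = np.full(n, np.nan)
    bcva = np.empty(n)
    for g in groups:
        sel = group_col == g
        k = int(sel.sum())
        if g in GROUP_HBA1C:
            m, s = GROUP_HBA1C[g]
            hba1c[sel] = np.clip(rng.normal(m, s, size=k), 3.5, None)
            m, s = GROUP_DURATION[g]
            duration[sel] = np.clip(rng.normal(m, s, size=k), 0.2, None)
        m, s = GROUP_BCVA[g]
        bcva[sel] = np.clip(rng.normal(m, s, size=k), 0, 100) if s > 0 else m

    frame = {
        "eye_id": eye_ids,
        "group": group_col,
        "dme": dme.astype(int),
        **{f"irf_{s}": cols[f"irf_{s}"] for s in SECTORS},
        **{f"thickness_{s}": cols[f"thickness_{s}"] for s in SECTORS},
        **{f"gefc_{s}": cols[f"gefc_{s}"] for s in SECTORS},
        **{f"refc_{s}": cols[f"refc_{s}"] for s in SECTORS},
        **{f"wavelength_{s}": cols[f"wavelength_{s}"] for s in SECTORS},
        "hba1c": hba1c,
        "dm_duration_y": duration,
        "bcva": bcva,
    }
    return pd.DataFrame(frame, columns=list(COHORT_COLUMNS))
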