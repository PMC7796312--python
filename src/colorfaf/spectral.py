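"""Per-pixel spectral decomposition of color-FAF images.

A 450 nm-excitation color-FAF image records the emission spectrum with a
color sensor, so each pixel carries only two emission components: the
green band (500-560 nm, GEFC) on the sensor's G channel and the red band
(560-700 nm, REFC) on the R channel.  This module turns the raw raster
into per-pixel maps of

* ``gefc`` and ``refc`` — the two components as floats (0-255 counts),
* ``intensity`` — their average, (REFC + GEFC) / 2,
* ``green_fraction`` — GEFC / (GEFC + REFC), undefined (NaN) at
  zero-signal pixels,
* ``wavelength`` — an estimated overall emission wavelength obtained by
  exponential (geometric) interpolation between the band centers.

The wavelength model is a package assumption, not a measured calibration:
λ(f) = λ_R · (λ_G / λ_R)^f with band centers λ_G = 530 nm, λ_R = 630 nm,
so λ(0) = λ_R, λ(1) = λ_G, strictly decreasing in the green fraction f
and exponential in it.  The constants are overridable via
:class:`SpectralConstants`.

Two diagnostic scatter plots are supported as plain point lists: the
*segment graph* (wavelength vs intensity) and the *RG graph* (REFC vs
GEFC), each with one point per defined pixel in row-major order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging_io import FundusImage


@dataclass(frozen=True)
class SpectralConstants:
    """Emission band definitions of the color-FAF device."""

    green_band: tuple[float, float] = (500.0, 560.0)
    red_band: tuple[float, float] = (560.0, 700.0)
    lambda_g: float = 530.0  # green band center, nm
    lambda_r: float = 630.0  # red band center, nm
    excitation_peak: float = 450.0

    def __post_init__(self) -> None:
        if self.green_band[1] != self.red_band[0]:
            raise ValueError("green band max must equal red band min")
        if not (self.green_band[0] < self.lambda_g < self.green_band[1]):
            raise ValueError("lambda_g must lie strictly inside the green band")
        if not (self.red_band[0] < self.lambda_r < self.red_band[1]):
            raise ValueError("lambda_r must lie strictly inside the red band")


DEFAULT_CONSTANTS = SpectralConstants()


@dataclass(frozen=True)
class SpectralMap:
    """Per-pixel spectral quantities of one color-FAF image.

    Undefined pixels (GEFC + REFC = 0) carry NaN in ``green_fraction``
    and ``wavelength``; they are excluded from region statistics rather
    than imputed.
    """

    gefc: np.ndarray
    refc: np.ndarray
    intensity: np.ndarray
    green_fraction: np.ndarray
    wavelength: np.ndarray
    constants: SpectralConstants = DEFAULT_CONSTANTS

    @property
    def shape(self) -> tuple[int, int]:
        return self.gefc.shape

    @property
    def defined(self) -> np.ndarray:
        """Boolean raster of pixels with nonzero total signal."""
        return ~np.isnan(self.green_fraction)


def estimate_wavelength(
    green_fraction, constants: SpectralConstants = DEFAULT_CONSTANTS
):
    """Estimated overall emission wavelength from the green fraction.

    Exponential interpolation between the band centers:
    ``λ(f) = λ_R * (λ_G / λ_R) ** f``.  Accepts scalars or arrays; NaN
    propagates (undefined pixels stay undefined).

    Raises
    ------
    ValueError
        If any finite input lies outside [0, 1].
    """
    f = np.asarray(green_fraction, dtype=float)
    finite = np.isfinite(f)
    if np.any((f[finite] < 0) | (f[finite] > 1)):
        raise ValueError("green_fraction must lie in [0, 1]")
    lam = constants.lambda_r * (constants.lambda_g / constants.lambda_r) ** f
    if np.isscalar(green_fraction) or np.ndim(green_fraction) == 0:
        return float(lam)
    return lam


def decompose(
    image: FundusImage, constants: SpectralConstants = DEFAULT_CONSTANTS
) -> SpectralMap:
    """Split a color-FAF image into its per-pixel spectral quantities.

    GEFC is the sensor's G channel and REFC its R channel, taken as
    floats; the blue channel lies below the 500 nm emission cut-on and
    is ignored for quantification.
    """
    px = image.pixels
    refc = px[:, :, 0].astype(float)
    gefc = px[:, :, 1].astype(float)
    total = refc + gefc
    intensity = total / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        green_fraction = np.where(total > 0, gefc / total, np.nan)
    wavelength = estimate_wavelength(green_fraction, constants)
    return SpectralMap(
        gefc=gefc,
        refc=refc,
        intensity=intensity,
        green_fraction=green_fraction,
        wavelength=wavelength,
        constants=constants,
    )


def _region_points(smap: SpectralMap, region_mask: np.ndarray) -> np.ndarray:
    region = np.asarray(region_mask, dtype=bool)
    if region.shape != smap.shape:
        raise ValueError(f"region shape {region.shape} != map shape {smap.shape}")
    if not region.any():
        raise ValueError("empty region")
    sel = region & smap.defined
    if not sel.any():
        raise ValueError("no defined pixels in region")
    return sel


def segment_graph_data(smap: SpectralMap, region_mask: np.ndarray) -> np.ndarray:
    """Points of the segment graph: (wavelength nm, intensity) per defined pixel.

    Row-major pixel order; one point per defined pixel in the region.
    """
    sel = _region_points(smap, region_mask)
    return np.column_stack((smap.wavelength[sel], smap.intensity[sel]))


def rg_graph_data(smap: SpectralMap, region_mask: np.ndarray) -> np.ndarray:
    """Points of the RG graph: (REFC, GEFC) per defined pixel, row-major."""
    sel = _region_points(smap, region_mask)
    return np.column_stack((smap.refc[sel], smap.gefc[sel]))
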