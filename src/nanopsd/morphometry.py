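"""Shape and size measurement: FWHM line profiles, manual two-axis diameters,
second-moment ellipse fitting, and PSD subtype classification.

The full width at half maximum (FWHM) of a fitted Gaussian is the package's
standard size measure for individual structures, mirroring the classic manual
line-profile protocol; mask-based morphometry (circle-equivalent diameters,
ellipse axes) serves the automated pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .core import FWHM_PER_SIGMA, RenderedImage

__all__ = [
    "LineProfile",
    "FWHMMeasure",
    "fwhm_from_profile",
    "manual_diameter",
    "ellipse_axes",
    "classify_subtype",
]


@dataclass
class LineProfile:
    """Ordered intensity samples along a straight line."""

    samples: np.ndarray
    spacing: float  # nm per sample
    endpoints: tuple[tuple[float, float], tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 5:
            raise ValueError("profile needs >= 5 samples")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")


@dataclass
class FWHMMeasure:
    fwhm: float          # nm
    fit_centre: float    # nm along the profile
    fit_amplitude: float
    fit_offset: float
    r_squared: float
    valid: bool


def _gaussian(x: np.ndarray, amp: float, centre: float, sigma: float,
              offset: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((x - centre) / sigma) ** 2) + offset


def fwhm_from_profile(profile: LineProfile, min_r_squared: float = 0.5) -> FWHMMeasure:
    """Least-squares Gaussian-plus-offset fit of a line profile.

    ``fwhm = 2 sqrt(2 ln 2) * sigma`` of the fitted Gaussian, in nm.  A
    non-convergent fit or one explaining less than ``min_r_squared`` of the
    variance is flagged invalid.
    """
    y = profile.samples
    x = np.arange(y.size) * profile.spacing
    offset0 = float(np.min(y))
    amp0 = float(np.max(y) - offset0)
    invalid = FWHMMeasure(fwhm=np.nan, fit_centre=np.nan, fit_amplitude=np.nan,
                          fit_offset=np.nan, r_squared=0.0, valid=False)
    if amp0 <= 0:
        return invalid
    w = np.clip(y - offset0, 0, None)
    centre0 = float(np.sum(x * w) / np.sum(w))
    var0 = float(np.sum(w * (x - centre0) ** 2) / np.sum(w))
    sigma0 = max(np.sqrt(var0), profile.spacing / 2.0)
    try:
        popt, _ = optimize.curve_fit(
            _gaussian, x, y, p0=[amp0, centre0, sigma0, offset0], maxfev=5000)
    except (RuntimeError, optimize.OptimizeWarning):
        return invalid
    amp, centre, sigma, offset = popt
    sigma = abs(float(sigma))
    resid = y - _gaussian(x, *popt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 0.0
    if not np.isfinite(sigma) or sigma <= 0 or amp <= 0 or r2 < min_r_squared:
        return FWHMMeasure(np.nan, np.nan, np.nan, np.nan, max(r2, 0.0), False)
    return FWHMMeasure(fwhm=sigma * FWHM_PER_SIGMA, fit_centre=float(centre),
                       fit_amplitude=float(amp), fit_offset=float(offset),
                       r_squared=r2, valid=True)


# --------------------------------------------------------------------------
# manual two-axis diameter
# --------------------------------------------------------------------------

def _sample_profile(image: RenderedImage, centre: tuple[float, float],
                    direction: tuple[float, float], half_length: float,
                    spacing: float) -> LineProfile:
    """Bilinear profile through ``centre`` along ``direction`` (unit vector)."""
    n = int(np.ceil(2 * half_length / spacing)) + 1
    t = (np.arange(n) - (n - 1) / 2.0) * spacing
    xs = centre[0] + t * direction[0]
    ys = centre[1] + t * direction[1]
    cols = xs / image.pixel_size - 0.5
    rows = ys / image.pixel_size - 0.5
    vals = ndimage.map_coordinates(image.data.astype(np.float64),
                                   [rows, cols], order=1, mode="constant")
    return LineProfile(samples=vals, spacing=spacing,
                       endpoints=((float(xs[0]), float(ys[0])),
                                  (float(xs[-1]), float(ys[-1]))))


def _principal_direction(image: RenderedImage, centre: tuple[float, float],
                         window_nm: float) -> tuple[float, float]:
    """Principal axis of the local intensity second-moment matrix."""
    px = image.pixel_size
    half = window_nm / 2.0
    r0 = max(0, int((centre[1] - half) / px))
    r1 = min(image.data.shape[0], int(np.ceil((centre[1] + half) / px)))
    c0 = max(0, int((centre[0] - half) / px))
    c1 = min(image.data.shape[1], int(np.ceil((centre[0] + half) / px)))
    patch = np.clip(image.data[r0:r1, c0:c1].astype(np.float64), 0, None)
    if patch.size == 0 or patch.sum() == 0:
        return (1.0, 0.0)
    ys, xs = np.mgrid[r0:r1, c0:c1]
    xs = (xs + 0.5) * px - centre[0]
    ys = (ys + 0.5) * px - centre[1]
    w = patch / patch.sum()
    cxx = np.sum(w * xs * xs)
    cyy = np.sum(w * ys * ys)
    cxy = np.sum(w * xs * ys)
    cov = np.array([[cxx, cxy], [cxy, cyy]])
    vals, vecs = np.linalg.eigh(cov)
    v = vecs[:, np.argmax(vals)]
    return (float(v[0]), float(v[1]))


def manual_diameter(image: RenderedImage, centre: tuple[float, float],
                    expected_size_nm: float = 300.0) -> float:
    """Mean of two perpendicular FWHM measurements through a structure centre.

    The first profile follows the structure's long axis (principal axis of the
    local second-moment matrix in a window 3x the expected size), the second
    is perpendicular; the diameter is the arithmetic mean of both FWHMs.
    Returns NaN when either profile's fit is invalid.
    """
    direction = _principal_direction(image, centre, 3.0 * expected_size_nm)
    perp = (-direction[1], direction[0])
    half = 1.5 * expected_size_nm
    spacing = image.pixel_size / 2.0
    fwhms = []
    for d in (direction, perp):
        prof = _sample_profile(image, centre, d, half, spacing)
        m = fwhm_from_profile(prof)
        if not m.valid:
            return float("nan")
        fwhms.append(m.fwhm)
    return float(np.mean(fwhms))


# --------------------------------------------------------------------------
# mask morphometry
# --------------------------------------------------------------------------

def ellipse_axes(mask: np.ndarray, pixel_size: float,
                 intensities: np.ndarray | None = None,
                 ) -> tuple[float, float, float]:
    """Second-moment ellipse of a binary mask: (long, short, aspect) in nm.

    Axis lengths follow the normalised-second-moment convention (the axes of
    the ellipse with the same second moments as the mask).  Degenerate
    (collinear) masks have the short axis floored at one pixel, so the aspect
    ratio stays in (0, 1].
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 5:
        raise ValueError("need >= 5 pixels for a second-moment ellipse")
    ys, xs = np.nonzero(mask)
    if intensities is not None:
        w = np.clip(np.asarray(intensities, dtype=np.float64)[ys, xs], 0, None)
        if w.sum() == 0:
            w = np.ones_like(w)
    else:
        w = np.ones(len(xs))
    w = w / w.sum()
    mx, my = np.sum(w * xs), np.sum(w * ys)
    # + 1/12: variance of the uniform pixel footprint
    cxx = np.sum(w * (xs - mx) ** 2) + 1.0 / 12.0
    cyy = np.sum(w * (ys - my) ** 2) + 1.0 / 12.0
    cxy = np.sum(w * (xs - mx) * (ys - my))
    vals = np.linalg.eigvalsh(np.array([[cxx, cxy], [cxy, cyy]]))
    vals = np.clip(vals, 0, None)
    long_px = 4.0 * np.sqrt(vals[1])
    short_px = 4.0 * np.sqrt(vals[0])
    long_px = max(long_px, 1.0)
    short_px = max(short_px, 1.0)
    long_nm = long_px * pixel_size
    short_nm = short_px * pixel_size
    return long_nm, short_nm, float(min(short_nm / long_nm, 1.0))


def classify_subtype(nc_count: int) -> str:
    """Map an NC count to the synapse subtype label: 1NC, 2NC or 3+NC."""
    if nc_count < 1:
        raise ValueError("a retained PSD must contain at least one nanocluster")
    if nc_count == 1:
        return "1NC"
    if nc_count == 2:
        return "2NC"
    return "3+NC"
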