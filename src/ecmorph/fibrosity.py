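"""Fibrosity index: an FFT angular-anisotropy statistic for AFM topographies.

Actin stress fibers show up in AFM height images of endothelial cells as
parallel ridges. Their degree of alignment is summarized by a single scalar:
after scan-line leveling, band-pass filtering (with suppression of
scan-direction stripes), edge enhancement and an isotropic radial taper, the
2-D Fourier magnitude spectrum is averaged over angle bins on [0°, 180°).
An isotropic texture gives a flat angular profile; oriented fibers
concentrate spectral energy at one angle. The standard deviation of the
per-angle means — with the cardinal directions excluded, because the raster
scan itself imprints energy at 0°/90° — is the *fibrosity index*.

The processing chain is deliberately positively homogeneous of degree one in
the input heights (linear filters, gradient magnitude, FFT magnitude), so
scaling all heights by c > 0 scales the index by exactly c.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage

from .containers import HeightMap

__all__ = [
    "FibrosityParams",
    "AngularSpectrum",
    "FibrosityResult",
    "level_lines",
    "angular_profile",
    "fibrosity_pipeline",
]

MIN_IMAGE_DIM = 64


@dataclass
class FibrosityParams:
    """Tunable parameters of the fibrosity pipeline.

    All length-like values are in pixels. ``bandpass_large`` /
    ``bandpass_small`` bound the spatial scales kept by the Fourier bandpass
    (structures larger than the former and smaller than the latter are
    suppressed). ``stripe_axis`` selects which scan-artifact stripes to
    attenuate: ``"horizontal"`` stripes (constant along a row) carry their
    spectral energy on the vertical frequency axis and vice versa.
    ``radial_band`` restricts the angular average to an annulus in the
    centered spectrum; ``None`` defaults to (3, min(shape)//2 - 1).
    """

    bandpass_large: float = 40.0
    bandpass_small: float = 3.0
    stripe_axis: Literal["horizontal", "vertical", "none"] = "horizontal"
    stripe_halfwidth: float = 2.0
    gauss_sigma_pre: float = 1.0
    gauss_sigma_post: float = 1.0
    spectrum_smooth_sigma: float = 1.0
    radial_band: tuple[float, float] | None = None
    angle_bin: float = 2.0
    cardinal_exclusion: float = 5.0
    window: Literal["radial-hann", "separable-hann"] = "radial-hann"
    spectrum_scale: Literal["magnitude", "power", "log"] = "magnitude"
    sd_ddof: int = 0

    def __post_init__(self) -> None:
        if not self.bandpass_small < self.bandpass_large:
            raise ValueError("bandpass_small must be < bandpass_large")
        if not (0 < self.angle_bin <= 10):
            raise ValueError("angle_bin must be in (0, 10] degrees")
        if abs(round(180.0 / self.angle_bin) * self.angle_bin - 180.0) > 1e-9:
            raise ValueError("angle_bin must divide 180 evenly")
        if not (0 <= self.cardinal_exclusion < 45):
            raise ValueError("cardinal_exclusion must be in [0, 45) degrees")
        if self.radial_band is not None:
            r_min, r_max = self.radial_band
            if r_min < 1:
                raise ValueError("radial_band r_min must be >= 1")
            if r_max <= r_min:
                raise ValueError("radial_band r_max must exceed r_min")


@dataclass
class AngularSpectrum:
    """Per-angle mean spectral magnitude over [0°, 180°).

    ``mean_intensity`` is NaN for bins with no pixel support; ``excluded``
    flags bins within the cardinal exclusion zone, which carry no weight in
    the index.
    """

    angles: np.ndarray  # bin centers, degrees
    mean_intensity: np.ndarray
    excluded: np.ndarray  # bool

    def included_values(self) -> np.ndarray:
        vals = self.mean_intensity[~self.excluded]
        return vals[np.isfinite(vals)]


@dataclass
class FibrosityResult:
    index: float
    spectrum: AngularSpectrum
    params: FibrosityParams
    intermediates: dict[str, np.ndarray] = field(default_factory=dict)


def level_lines(hmap: HeightMap) -> HeightMap:
    """Subtract the median of every fast-scan row (scan-line leveling).

    Constant per-row offsets — the dominant AFM raster artifact — are
    removed exactly; all output row medians are zero.
    """
    h = hmap.heights
    return hmap.with_heights(h - np.median(h, axis=1, keepdims=True))


def _bandpass_stripe_filter(img: np.ndarray, params: FibrosityParams) -> np.ndarray:
    """Fourier-domain bandpass with a Gaussian notch over stripe frequencies.

    Gaussian transfer functions (soft cutoffs at spatial scales
    ``bandpass_large`` and ``bandpass_small``) avoid ringing; the stripe
    notch attenuates >= 99% on-axis but leaves the DC sample untouched
    (DC is later discarded by the radial band).
    """
    rows, cols = img.shape
    fy = np.fft.fftfreq(rows)[:, None]  # cycles / pixel
    fx = np.fft.fftfreq(cols)[None, :]
    r = np.hypot(fy, fx)
    # pass structures between bandpass_small and bandpass_large pixels
    highpass = 1.0 - np.exp(-2.0 * (r * params.bandpass_large) ** 2)
    lowpass = np.exp(-2.0 * (r * params.bandpass_small) ** 2)
    transfer = highpass * lowpass

    if params.stripe_axis != "none":
        # horizontal stripes vary only along rows -> energy at fx == 0
        axis_dist_px = np.abs(fx) * cols if params.stripe_axis == "horizontal" else np.abs(fy) * rows
        notch = 1.0 - 0.995 * np.exp(-0.5 * (axis_dist_px / params.stripe_halfwidth) ** 2)
        notch = np.broadcast_to(notch, (rows, cols)).copy()
        notch[0, 0] = 1.0  # keep DC
        transfer = transfer * notch

    return np.fft.ifft2(np.fft.fft2(img) * transfer).real


def _radial_hann(shape: tuple[int, int]) -> np.ndarray:
    """Radial taper w(n) = 0.5 - 0.5*cos(pi*(1 - n/N)): 1 at the image
    center, 0 at the inscribed-circle edge (n = N = half the smaller
    dimension), clamped to 0 beyond."""
    rows, cols = shape
    cy, cx = rows // 2, cols // 2
    n = np.hypot(np.arange(rows)[:, None] - cy, np.arange(cols)[None, :] - cx)
    big_n = min(rows, cols) / 2.0
    w = 0.5 - 0.5 * np.cos(np.pi * (1.0 - n / big_n))
    w[n > big_n] = 0.0
    return w


def _separable_hann(shape: tuple[int, int]) -> np.ndarray:
    return np.outer(np.hanning(shape[0]), np.hanning(shape[1]))


def angular_profile(
    spectrum_image: np.ndarray,
    radial_band: tuple[float, float],
    angle_bin: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Angular mean of a center-shifted spectrum over an annulus.

    Each bin's value is the mean of pixels whose polar angle about the
    spectrum center (taken mod 180°, folding the point-symmetric
    half-planes) falls in the bin and whose radius lies in
    ``radial_band`` (inclusive). The center is at index (rows//2, cols//2),
    the FFT-shift convention. Bins without support are NaN.

    Returns ``(bin_centers_deg, mean_intensity)``.
    """
    spectrum_image = np.asarray(spectrum_image, dtype=float)
    rows, cols = spectrum_image.shape
    r_min, r_max = radial_band
    if r_max > np.hypot(rows // 2, cols // 2):
        raise ValueError("radial_band extends outside the spectrum image")
    n_bins = int(round(180.0 / angle_bin))

    dy = np.arange(rows)[:, None] - rows // 2
    dx = np.arange(cols)[None, :] - cols // 2
    r = np.hypot(dy, dx)
    in_band = (r >= r_min) & (r <= r_max)
    ang = np.degrees(np.arctan2(dy, dx)) % 180.0
    bins = np.minimum((ang[in_band] / angle_bin).astype(int), n_bins - 1)
    vals = spectrum_image[in_band]

    sums = np.bincount(bins, weights=vals, minlength=n_bins)
    counts = np.bincount(bins, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = (np.arange(n_bins) + 0.5) * angle_bin
    return centers, means


def _cardinal_excluded(centers: np.ndarray, halfwidth: float) -> np.ndarray:
    d = np.minimum.reduce([np.abs(centers), np.abs(centers - 90.0), np.abs(centers - 180.0)])
    return d <= halfwidth


def fibrosity_pipeline(
    hmap: HeightMap,
    params: FibrosityParams | None = None,
    keep_intermediates: bool = False,
) -> FibrosityResult:
    """Run the full fibrosity-index pipeline on a height map.

    Steps, in order: scan-line leveling; Fourier bandpass with stripe
    notch; Gaussian pre-smoothing; Sobel gradient magnitude; Gaussian
    post-smoothing; radial Hann taper; centered FFT magnitude spectrum;
    Gaussian spectrum smoothing; angular profile over the radial band;
    cardinal exclusion; standard deviation of the included angular means.

    Raises
    ------
    ValueError
        If the map is smaller than 64x64, every angular bin is excluded,
        or filtering produced non-finite values.
    """
    params = params or FibrosityParams()
    rows, cols = hmap.shape
    if min(rows, cols) < MIN_IMAGE_DIM:
        raise ValueError(f"height map must be at least {MIN_IMAGE_DIM}x{MIN_IMAGE_DIM}")

    leveled = level_lines(hmap).heights
    filtered = _bandpass_stripe_filter(leveled, params)
    if params.gauss_sigma_pre > 0:
        filtered = ndimage.gaussian_filter(filtered, params.gauss_sigma_pre)
    if not np.all(np.isfinite(filtered)):
        raise ValueError("non-finite values after filtering")

    edge = np.hypot(ndimage.sobel(filtered, axis=0), ndimage.sobel(filtered, axis=1))
    if params.gauss_sigma_post > 0:
        edge = ndimage.gaussian_filter(edge, params.gauss_sigma_post)

    window = _radial_hann((rows, cols)) if params.window == "radial-hann" else _separable_hann((rows, cols))
    windowed = edge * window

    spec = np.abs(np.fft.fftshift(np.fft.fft2(windowed)))
    if params.spectrum_scale == "power":
        spec = spec**2
    elif params.spectrum_scale == "log":
        spec = np.log1p(spec)
    if params.spectrum_smooth_sigma > 0:
        spec = ndimage.gaussian_filter(spec, params.spectrum_smooth_sigma)

    band = params.radial_band or (3.0, min(rows, cols) // 2 - 1.0)
    centers, means = angular_profile(spec, band, params.angle_bin)
    excluded = _cardinal_excluded(centers, params.cardinal_exclusion)
    spectrum = AngularSpectrum(centers, means, excluded)

    vals = spectrum.included_values()
    if vals.size == 0:
        raise ValueError("all angular bins excluded; widen radial_band or reduce cardinal_exclusion")
    index = float(np.std(vals, ddof=params.sd_ddof))

    intermediates = {}
    if keep_intermediates:
        intermediates = {
            "leveled": leveled,
            "filtered": filtered,
            "edge": edge,
            "windowed": windowed,
            "spectrum": spec,
        }
    return FibrosityResult(index, spectrum, params, intermediates)
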