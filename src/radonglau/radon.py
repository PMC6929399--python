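"""Multi-angle Radon projection and unified-length signal resampling.

The Radon transform integrates the image intensity f(x, y) along straight
lines rho = x*cos(theta) + y*sin(theta), with theta measured from the
horizontal and rho the signed distance of the line from the image center.
Collecting the projections for a set of angles gives the sinogram R(rho,
theta); each column is a 1-D signal in which radial structure of the optic
nerve head (cup enlargement, rim loss, a peripapillary crescent) shows up as
a characteristic profile.

Discretization: every pixel is treated as a point mass at its center and
splatted onto the two nearest bins of a unit-spaced rho grid with linear
weights.  This preserves the total mass of the image in every column
exactly, which is the discrete analogue of the line-integral normalisation.

Coordinate convention (fixed once): x increases with the column index, y
increases with the row index, both measured from the image center.  At
theta = 0 the integration lines are vertical (x = rho), so the projection
equals the column sums of the raster; at theta = 90 deg it equals the row
sums.  Angles are canonicalized modulo 180 deg.

Because source images come in many resolutions, the per-angle projection
signals are resampled to a common unified length (default 690 samples) by
cubic interpolation before feature extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

#: Named angle sets.  "9-even" is the default: the nine even multiples of
#: 20 degrees (n * 20 for n = 1..9, with 180 identified with 0).  "9-odd" is
#: the complementary reading, the nine odd multiples of 10 degrees.  "6" and
#: "18" are the uniform 30- and 10-degree families.
ANGLE_PRESETS: dict[str, tuple[float, ...]] = {
    "6": tuple(float(n * 30 % 180) for n in range(1, 7)),
    "9-even": tuple(float(n * 20 % 180) for n in range(1, 10)),
    "9-odd": tuple(float(10 + n * 20) for n in range(0, 9)),
    "18": tuple(float(n * 10 % 180) for n in range(1, 19)),
}

#: Default unified projection-signal length.
DEFAULT_UNIFIED_LENGTH = 690


def resolve_angles(angles: str | list[float] | tuple[float, ...]) -> tuple[float, ...]:
    """Resolve a preset name or an explicit list into a canonical angle set.

    Angles are reduced modulo 180 degrees; the resulting set must be
    non-empty and free of duplicates.  Order is preserved.
    """
    if isinstance(angles, str):
        try:
            return ANGLE_PRESETS[angles]
        except KeyError:
            raise ValueError(
                f"unknown angle preset {angles!r}; choose from {sorted(ANGLE_PRESETS)}"
            ) from None
    canon = tuple(float(a) % 180.0 for a in angles)
    if not canon:
        raise ValueError("angle set must be non-empty")
    if len(set(canon)) != len(canon):
        raise ValueError(f"duplicate angles after reduction mod 180: {canon}")
    return canon


@dataclass(frozen=True)
class Sinogram:
    """Radon-domain matrix R(rho, theta).

    ``values`` has one row per rho bin and one column per angle;
    ``rho_offsets`` is the unit-spaced rho grid in pixels, symmetric about
    the image center; ``angles_deg`` matches the column order.
    """

    values: np.ndarray
    rho_offsets: np.ndarray = field(repr=False)
    angles_deg: tuple[float, ...]

    @property
    def n_angles(self) -> int:
        return self.values.shape[1]


def projection_length(height: int, width: int) -> int:
    """Number of unit-spaced rho bins spanning the image diagonal.

    Convention: ``ceil(hypot(height, width))``, so a 300 x 400 image yields
    exactly 500 bins.  The grid is symmetric about rho = 0; since the
    outermost pixel centers sit at radius hypot(h-1, w-1)/2 <
    (ceil(hypot(h, w)) - 1)/2, every pixel projects inside the grid at any
    angle.  Degenerate 1 x 1 images yield 2 bins under this convention.
    """
    if height < 1 or width < 1:
        raise ValueError("image dimensions must be positive")
    return int(np.ceil(np.hypot(height, width)))


def radon_project(image: np.ndarray, angles: str | list[float] | tuple[float, ...]) -> Sinogram:
    """Project a grayscale image onto a set of angles.

    Each pixel's intensity is distributed between the two nearest rho bins
    by linear interpolation, so every column sums to the total image
    intensity (mass conservation).

    Parameters
    ----------
    image:
        2-D intensity raster (any numeric dtype; converted to float64).
    angles:
        Preset name or explicit list of angles in degrees from horizontal.
    """
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("radon_project expects a non-empty 2-D image")
    angles_deg = resolve_angles(angles)
    h, w = arr.shape
    n_rho = projection_length(h, w)
    rho_offsets = np.arange(n_rho, dtype=np.float64) - (n_rho - 1) / 2.0

    y = np.arange(h, dtype=np.float64) - (h - 1) / 2.0
    x = np.arange(w, dtype=np.float64) - (w - 1) / 2.0
    xx, yy = np.meshgrid(x, y)
    xx = xx.ravel()
    yy = yy.ravel()
    v = arr.ravel()

    values = np.empty((n_rho, len(angles_deg)), dtype=np.float64)
    for j, ang in enumerate(angles_deg):
        t = np.deg2rad(ang)
        pos = xx * np.cos(t) + yy * np.sin(t) - rho_offsets[0]
        lo = np.floor(pos).astype(np.intp)
        frac = pos - lo
        col = np.bincount(lo, weights=v * (1.0 - frac), minlength=n_rho + 1)
        col += np.bincount(lo + 1, weights=v * frac, minlength=n_rho + 1)
        values[:, j] = col[:n_rho]
    return Sinogram(values=values, rho_offsets=rho_offsets, angles_deg=angles_deg)


def resample_signal(signal: np.ndarray, target_len: int = DEFAULT_UNIFIED_LENGTH) -> np.ndarray:
    """Resample a 1-D projection signal to ``target_len`` samples.

    A not-a-knot cubic spline is fitted to the samples on a normalized
    support [0, 1] and evaluated at ``target_len`` evenly spaced positions,
    so endpoints map to endpoints exactly and polynomials of degree <= 3 are
    reproduced.  Both the input and target length must be at least 4 (the
    spline needs four points).
    """
    sig = np.asarray(signal, dtype=np.float64)
    if sig.ndim != 1:
        raise ValueError("resample_signal expects a 1-D signal")
    if sig.size < 4 or target_len < 4:
        raise ValueError("signal and target length must both be >= 4")
    if sig.size == target_len:
        return sig.copy()
    src = np.linspace(0.0, 1.0, sig.size)
    dst = np.linspace(0.0, 1.0, target_len)
    return CubicSpline(src, sig)(dst)


def unified_signals(sinogram: Sinogram, target_len: int = DEFAULT_UNIFIED_LENGTH) -> np.ndarray:
    """Resample every sinogram column; returns an (n_angles, target_len) array."""
    return np.stack(
        [resample_signal(sinogram.values[:, j], target_len) for j in range(sinogram.n_angles)]
    )


def fbp_reconstruct(sinogram: Sinogram, shape: tuple[int, int]) -> np.ndarray:
    """Filtered back-projection of a sinogram produced by :func:`radon_project`.

    Each column is ramp-filtered in the frequency domain and smeared back
    along its projection lines under the same rho/angle convention the
    forward transform uses.  With a dense angle set this recovers the input
    up to discretization error; it exists to demonstrate that the sinogram
    preserves the image information, not as a production reconstructor.
    """
    vals = sinogram.values
    n_rho, n_ang = vals.shape
    nfft = 1 << int(np.ceil(np.log2(2 * n_rho)))
    ramp = np.abs(np.fft.rfftfreq(nfft))
    filtered = np.fft.irfft(np.fft.rfft(vals, n=nfft, axis=0) * ramp[:, None], axis=0)[
        :n_rho
    ]

    h, w = shape
    y = np.arange(h, dtype=np.float64) - (h - 1) / 2.0
    x = np.arange(w, dtype=np.float64) - (w - 1) / 2.0
    xx, yy = np.meshgrid(x, y)
    out = np.zeros((h, w))
    for j, ang in enumerate(sinogram.angles_deg):
        t = np.deg2rad(ang)
        rho = xx * np.cos(t) + yy * np.sin(t)
        out += np.interp(rho, sinogram.rho_offsets, filtered[:, j])
    return out * (np.pi / (2.0 * n_ang))
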