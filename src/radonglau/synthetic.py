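"""Synthetic fundus-like images with controllable optic-nerve-head morphology.

The generator emulates the structure that matters to the downstream
pipeline rather than photorealism: a smoothly illuminated background, a
bright elliptical optic disc, an inner brighter optic cup whose vertical
cup-to-disc ratio (CDR) is drawn from a class-conditional truncated normal
distribution, a darker neuro-retinal rim (the disc annulus outside the
cup), dark curvilinear vessels converging on the disc, an optional pale
temporal peripapillary-atrophy (PPA) crescent for glaucomatous images, and
additive sensor noise.  Glaucoma is simulated as cup enlargement (higher
CDR, hence a thinner rim) plus a higher PPA probability — the radial
signatures the Radon-domain features are designed to pick up.

All randomness flows through a single generator seeded per image, so
identical parameters and seed give bit-identical PNGs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.stats import truncnorm

#: CDR samples are truncated to this open interval so the cup always fits
#: strictly inside the disc.
CDR_BOUNDS = (0.05, 0.95)

LABELS = ("normal", "glaucoma")


@dataclass(frozen=True)
class SynthParams:
    """Generator configuration.

    Parameters
    ----------
    image_size:
        (height, width) in pixels, at least (64, 64).
    disc_radius_frac:
        Disc vertical semi-axis as a fraction of the smaller image
        dimension.
    cdr_normal_mean, cdr_normal_sd, cdr_glaucoma_mean, cdr_glaucoma_sd:
        Class-conditional truncated-normal parameters of the vertical CDR.
        Defaults (0.35, 0.05) and (0.70, 0.08) give overlapping but
        separable classes.
    ppa_prob_glaucoma:
        Probability that a glaucomatous image carries a temporal PPA
        crescent.
    n_vessels:
        Number of vessel curves entering the disc.
    illum_gradient_strength:
        Peak-to-trough fractional intensity variation of the background
        illumination ramp, in [0, 1].
    noise_sd:
        Standard deviation of additive Gaussian sensor noise in 8-bit
        intensity units.
    seed:
        Base seed for dataset generation.
    """

    image_size: tuple[int, int] = (128, 128)
    disc_radius_frac: float = 0.22
    cdr_normal_mean: float = 0.35
    cdr_normal_sd: float = 0.05
    cdr_glaucoma_mean: float = 0.70
    cdr_glaucoma_sd: float = 0.08
    ppa_prob_glaucoma: float = 0.5
    n_vessels: int = 6
    illum_gradient_strength: float = 0.15
    noise_sd: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size[0] < 64 or self.image_size[1] < 64:
            raise ValueError("image_size must be at least (64, 64)")
        for m in (self.cdr_normal_mean, self.cdr_glaucoma_mean):
            if not 0.0 < m < 1.0:
                raise ValueError("CDR means must lie in (0, 1)")
        for s in (self.cdr_normal_sd, self.cdr_glaucoma_sd):
            if s <= 0:
                raise ValueError("CDR standard deviations must be positive")
        if not 0.0 <= self.ppa_prob_glaucoma <= 1.0:
            raise ValueError("ppa_prob_glaucoma must lie in [0, 1]")
        if not 0.0 <= self.illum_gradient_strength <= 1.0:
            raise ValueError("illum_gradient_strength must lie in [0, 1]")
        if self.noise_sd < 0 or self.n_vessels < 0:
            raise ValueError("noise_sd and n_vessels must be non-negative")
        if not 0.0 < self.disc_radius_frac < 0.5:
            raise ValueError("disc_radius_frac must lie in (0, 0.5)")


@dataclass(frozen=True)
class GroundTruth:
    """Per-image generation record."""

    label: str
    cdr_true: float
    ppa_present: bool
    disc_center: tuple[float, float]  # (row, col) px


def sample_cdr(
    params: SynthParams, label: str, rng: np.random.Generator
) -> float:
    """Draw a vertical CDR from the class-conditional truncated normal."""
    if label == "normal":
        mean, sd = params.cdr_normal_mean, params.cdr_normal_sd
    elif label == "glaucoma":
        mean, sd = params.cdr_glaucoma_mean, params.cdr_glaucoma_sd
    else:
        raise ValueError(f"label must be one of {LABELS}, got {label!r}")
    lo, hi = CDR_BOUNDS
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _soft_ellipse(d2: np.ndarray, softness: float = 0.08) -> np.ndarray:
    """Smooth indicator of d2 <= 1 where d2 is a normalized ellipse metric."""
    return 1.0 / (1.0 + np.exp(np.clip((d2 - 1.0) / softness, -60.0, 60.0)))


def _stamp_curve(
    mask: np.ndarray, pts: np.ndarray, radius: float
) -> None:
    """Mark a disk of the given radius around each curve sample point."""
    h, w = mask.shape
    r = int(np.ceil(radius))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    foot = (dy**2 + dx**2) <= radius**2
    fy, fx = np.nonzero(foot)
    fy, fx = fy - r, fx - r
    for py, px in np.rint(pts).astype(int):
        yy = py + fy
        xx = px + fx
        ok = (yy >= 0) & (yy < h) & (xx >= 0) & (xx < w)
        mask[yy[ok], xx[ok]] = True


def generate_image(
    params: SynthParams, label: str, draw_seed: int
) -> tuple[np.ndarray, GroundTruth]:
    """Render one labeled RGB fundus-like image.

    Returns the (H, W, 3) uint8 image and the :class:`GroundTruth` holding
    the sampled CDR, PPA flag and disc center.  Identical arguments give a
    bit-identical array.
    """
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}, got {label!r}")
    rng = np.random.default_rng(draw_seed)
    h, w = params.image_size
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)

    # Background with a linear illumination ramp in a random direction.
    phi = rng.uniform(0.0, 2.0 * np.pi)
    proj = (xx / (w - 1)) * np.cos(phi) + (yy / (h - 1)) * np.sin(phi)
    proj = (proj - proj.min()) / max(proj.max() - proj.min(), 1e-12)
    field = 110.0 * (1.0 + params.illum_gradient_strength * (proj - 0.5))

    # Disc: bright ellipse near the image center, slight anisotropy/jitter.
    jitter = 0.05 * min(h, w)
    cy = (h - 1) / 2.0 + rng.uniform(-jitter, jitter)
    cx = (w - 1) / 2.0 + rng.uniform(-jitter, jitter)
    b_disc = params.disc_radius_frac * min(h, w)
    a_disc = b_disc * rng.uniform(0.85, 1.0)
    d2_disc = ((xx - cx) / a_disc) ** 2 + ((yy - cy) / b_disc) ** 2
    field += 70.0 * _soft_ellipse(d2_disc)

    # Cup: concentric brighter ellipse, vertical semi-axis = CDR * disc's.
    cdr = sample_cdr(params, label, rng)
    b_cup = cdr * b_disc
    a_cup = cdr * a_disc * rng.uniform(0.9, 1.05)
    d2_cup = ((xx - cx) / a_cup) ** 2 + ((yy - cy) / b_cup) ** 2
    field += 55.0 * _soft_ellipse(d2_cup, softness=0.12)

    # Optional temporal PPA crescent: pale half-annulus just outside the disc.
    ppa_draw = rng.random()
    ppa_present = label == "glaucoma" and ppa_draw < params.ppa_prob_glaucoma
    if ppa_present:
        d2_outer = ((xx - cx) / (1.45 * a_disc)) ** 2 + ((yy - cy) / (1.45 * b_disc)) ** 2
        annulus = _soft_ellipse(d2_outer, 0.1) * (1.0 - _soft_ellipse(d2_disc, 0.05))
        temporal = np.cos(np.arctan2(yy - cy, xx - cx))  # weight toward +x side
        field += 30.0 * annulus * np.clip(temporal, 0.0, None)

    # Vessels: quadratic Bezier strips from the border into the disc.
    if params.n_vessels > 0:
        vmask = np.zeros((h, w), dtype=bool)
        t = np.linspace(0.0, 1.0, 256)[:, None]
        for _ in range(params.n_vessels):
            side = rng.integers(0, 4)
            edge = rng.uniform(0.0, 1.0)
            p0 = {
                0: (0.0, edge * (w - 1)),
                1: (h - 1.0, edge * (w - 1)),
                2: (edge * (h - 1), 0.0),
                3: (edge * (h - 1), w - 1.0),
            }[int(side)]
            p2 = (
                cy + rng.uniform(-0.3, 0.3) * b_disc,
                cx + rng.uniform(-0.3, 0.3) * a_disc,
            )
            mid = ((p0[0] + p2[0]) / 2.0, (p0[1] + p2[1]) / 2.0)
            p1 = (
                mid[0] + rng.uniform(-0.15, 0.15) * h,
                mid[1] + rng.uniform(-0.15, 0.15) * w,
            )
            pts = (
                (1 - t) ** 2 * np.array(p0)
                + 2 * (1 - t) * t * np.array(p1)
                + t**2 * np.array(p2)
            )
            _stamp_curve(vmask, pts, radius=1.4 + rng.uniform(0.0, 0.8))
        field = np.where(vmask, field - 45.0, field)

    field += rng.normal(0.0, params.noise_sd, size=(h, w)) if params.noise_sd > 0 else 0.0

    # Fundus-like coloration: strong red, moderate green, weak blue channel.
    rgb = np.stack(
        [
            np.clip(field * 1.0 + 30.0, 0, 255),
            np.clip(field * 0.72, 0, 255),
            np.clip(field * 0.45, 0, 255),
        ],
        axis=-1,
    )
    image = np.rint(rgb).astype(np.uint8)
    truth = GroundTruth(
        label=label, cdr_true=cdr, ppa_present=ppa_present, disc_center=(cy, cx)
    )
    return image, truth


def generate_dataset(
    n_normal: int,
    n_glaucoma: int,
    params: SynthParams,
    out_dir: str | Path,
) -> tuple[pd.DataFrame, Path]:
    """Write a labeled PNG dataset and its CSV manifest.

    Images are named ``<label>_<index>.png``; the manifest
    (``manifest.csv`` in ``out_dir``) has columns
    ``path,label,cdr_true,ppa_present`` with paths relative to the
    manifest.  Per-image seeds are derived from ``params.seed`` through a
    :class:`numpy.random.SeedSequence`, so re-running with the same
    arguments reproduces every file byte for byte.

    Returns the manifest frame and the manifest path.
    """
    if n_normal < 0 or n_glaucoma < 0:
        raise ValueError("counts must be non-negative")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_total = n_normal + n_glaucoma
    child_seeds = np.random.SeedSequence(params.seed).generate_state(max(n_total, 1))

    rows = []
    labels = ["normal"] * n_normal + ["glaucoma"] * n_glaucoma
    for i, label in enumerate(labels):
        image, truth = generate_image(params, label, int(child_seeds[i]))
        name = f"{label}_{i:04d}.png"
        Image.fromarray(image).save(out_dir / name)
        rows.append(
            {
                "path": name,
                "label": label,
                "cdr_true": truth.cdr_true,
                "ppa_present": truth.ppa_present,
            }
        )
    manifest = pd.DataFrame(rows, columns=["path", "label", "cdr_true", "ppa_present"])
    manifest_path = out_dir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest, manifest_path
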