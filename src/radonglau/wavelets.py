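"""Single-level biorthogonal wavelet features for projection signals.

Each unified projection signal is decomposed once into approximation
coefficients (low-pass analysis filter + dyadic downsampling) and detail
coefficients (high-pass analysis filter + dyadic downsampling).  No scalar
summaries (energy, mean, entropy) are taken: the full coefficient vectors
of every angle are concatenated, so with periodization boundary handling
and an even signal length L the feature vector of an image has exactly
|angles| * L entries — e.g. nine angles at L = 690 give 6210 features.

Periodization is used because it is the only standard extension mode under
which coefficient count equals signal length, which the dimension
arithmetic of the pipeline requires; symmetric padding would inflate the
count by the filter length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pywt

#: The supported biorthogonal analysis families.
BIOR_FAMILIES: tuple[str, ...] = (
    "bior1.1",
    "bior1.3",
    "bior1.5",
    "bior2.2",
    "bior2.4",
    "bior2.6",
    "bior3.3",
    "bior3.5",
    "bior3.7",
)


@dataclass(frozen=True)
class WaveletConfig:
    """Wavelet decomposition parameters.

    ``family`` must be one of :data:`BIOR_FAMILIES` (default ``bior1.5``,
    the best-performing family; ``bior1.1`` is the Haar wavelet).
    ``levels`` is the decomposition depth (the pipeline uses exactly one
    level).  ``extension_mode`` is the boundary handling passed to
    PyWavelets; ``periodization`` keeps the coefficient count equal to the
    signal length.
    """

    family: str = "bior1.5"
    levels: int = 1
    extension_mode: str = "periodization"

    def __post_init__(self) -> None:
        if self.family not in BIOR_FAMILIES:
            raise ValueError(
                f"unknown wavelet {self.family!r}; supported: {BIOR_FAMILIES}"
            )
        if self.levels < 1:
            raise ValueError("levels must be >= 1")


def dwt_coeffs(
    signal: np.ndarray, config: WaveletConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """One-level DWT of a 1-D signal.

    Returns ``(cA, cD)``: approximation and detail coefficients.  With
    periodization and an even input length L, both have length L/2.

    Raises
    ------
    ValueError
        If the signal is shorter than the analysis filter support.
    """
    config = config or WaveletConfig()
    sig = np.asarray(signal, dtype=np.float64)
    if sig.ndim != 1:
        raise ValueError("dwt_coeffs expects a 1-D signal")
    wavelet = pywt.Wavelet(config.family)
    if sig.size < wavelet.dec_len:
        raise ValueError(
            f"signal length {sig.size} shorter than {config.family} "
            f"filter support {wavelet.dec_len}"
        )
    cA, cD = pywt.dwt(sig, wavelet, mode=config.extension_mode)
    return cA, cD


def build_feature_vector(
    signals: Sequence[np.ndarray], config: WaveletConfig | None = None
) -> np.ndarray:
    """Concatenate per-angle [cA || cD] blocks into one feature vector.

    ``signals`` holds one unified projection signal per angle, all of the
    same length; the block order follows the angle order.
    """
    config = config or WaveletConfig()
    if len(signals) == 0:
        raise ValueError("need at least one signal")
    lengths = {np.asarray(s).shape[-1] for s in signals}
    if len(lengths) != 1:
        raise ValueError(f"mixed signal lengths: {sorted(lengths)}")
    blocks = []
    for sig in signals:
        cA, cD = dwt_coeffs(np.asarray(sig), config)
        blocks.append(cA)
        blocks.append(cD)
    return np.concatenate(blocks)


def feature_names(n_angles: int, signal_len: int, config: WaveletConfig | None = None) -> list[str]:
    """Column names for a persisted feature matrix: angle/block/index."""
    config = config or WaveletConfig()
    probe = np.zeros(signal_len)
    cA, cD = dwt_coeffs(probe, config)
    names = []
    for a in range(n_angles):
        names.extend(f"a{a}_cA_{i}" for i in range(cA.size))
        names.extend(f"a{a}_cD_{i}" for i in range(cD.size))
    return names
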