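"""Time-frequency features: wavelet band energies and wavelet entropy.

A 10-level discrete Meyer wavelet decomposition splits the signal into 11
coefficient bands ``[a10, d10, d9, ..., d1]`` (a10 the coarsest).  Features
are the relative energy (percent of total coefficient energy) of each band,
a fixed per-axis subset of retained low-frequency bands, and the Shannon
entropy of the full 11-band energy distribution.

The fixed retained-band lists (A-P: a10..d7, five bands; S-I: a10..d6, six
bands) keep the 30-feature vector identical across datasets; the data-driven
95%-cumulative-energy rule that originally produced those lists is available
separately as a calibration tool for new data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pywt

from .core import DegenerateInputError
from .wavelets import get_wavelet

logger = logging.getLogger(__name__)

#: band labels from lowest to highest frequency
BAND_NAMES = ("a10", "d10", "d9", "d8", "d7", "d6", "d5", "d4", "d3", "d2", "d1")

#: fixed retained bands per axis for the 30-feature vector
DEFAULT_RETAINED = {
    "ap": ("a10", "d10", "d9", "d8", "d7"),
    "si": ("a10", "d10", "d9", "d8", "d7", "d6"),
}


@dataclass
class WaveletDecomposition:
    """Coefficient bands of a 10-level DWT, coarsest first."""

    wavelet: str
    bands: list[np.ndarray]  # [a10, d10, ..., d1]

    def band(self, name: str) -> np.ndarray:
        return self.bands[BAND_NAMES.index(name)]


def dwt10(x: np.ndarray, wavelet: str = "dmey") -> WaveletDecomposition:
    """10-level discrete wavelet decomposition (periodized).

    The depth is fixed at 10 so the 11-band structure (and hence feature
    identity) is stable.  Periodization keeps the per-band coefficient
    counts dyadic and conserves energy exactly, which the relative-energy
    features rely on; the denoising transform, where band bookkeeping does
    not matter, uses symmetric extension instead for better edge behaviour.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    wav = get_wavelet(wavelet)
    if len(x) < 2 ** 10:
        logger.debug("n=%d below 2^10: coarse bands are boundary-dominated", len(x))
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Level value of .* is too high")
        coeffs = pywt.wavedec(x, wav, mode="periodization", level=10)
    return WaveletDecomposition(wavelet, list(coeffs))


def relative_energies(dec: WaveletDecomposition) -> np.ndarray:
    """Relative energy per band in percent, ordered ``[a10, d10, ..., d1]``.

    Band energy is the squared Euclidean norm of its coefficients; shares sum
    to 100.
    """
    energies = np.array([float(np.sum(np.square(c))) for c in dec.bands])
    total = energies.sum()
    if total == 0:
        raise DegenerateInputError("all-zero signal has no energy distribution")
    return 100.0 * energies / total


def truncate_bands(mean_energies: np.ndarray, threshold: float = 95.0,
                   ) -> list[str]:
    """Retained-band list by the cumulative-energy rule.

    Walk from the lowest spectral band (a10) upward in frequency, accumulate
    the mean relative energies, and retain every band up to and including the
    first at which the running sum reaches ``threshold`` percent.
    """
    e = np.asarray(mean_energies, dtype=float)
    if e.shape != (11,):
        raise ValueError("expected 11 band energies")
    csum = np.cumsum(e)
    cut = int(np.argmax(csum >= threshold)) if (csum >= threshold).any() else 10
    return list(BAND_NAMES[: cut + 1])


def default_band_convention(axis: str) -> list[str]:
    """Fixed retained bands: ``ap`` -> a10..d7 (5), ``si`` -> a10..d6 (6)."""
    key = axis.lower().replace("-", "").replace("_", "")
    if key in ("ap", "anteriorposterior"):
        return list(DEFAULT_RETAINED["ap"])
    if key in ("si", "superiorinferior"):
        return list(DEFAULT_RETAINED["si"])
    raise ValueError(f"unknown axis label {axis!r}")


def wavelet_entropy(rel_energies: np.ndarray) -> float:
    """Shannon entropy (nats) of the full 11-band energy distribution.

    ``WE = -sum_k p_k ln p_k`` with ``p_k`` the relative share / 100;
    zero-energy bands contribute nothing.  Bounded by ``ln 11``.
    """
    p = np.asarray(rel_energies, dtype=float) / 100.0
    if not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValueError("relative energies must sum to 100")
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())
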