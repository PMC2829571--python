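"""Swallow segmentation and two-stage signal conditioning.

Pipeline order (fixed): segment the sequence recording into individual
swallows, filter each segment through an axis-specific inverse FIR filter that
undoes the acquisition chain, then denoise with a 10-level discrete Meyer
wavelet decomposition and soft thresholding.

The segmenter is a simplified envelope-based fuzzy c-means: a windowed RMS
envelope of the summed squared channels is partitioned into an active and a
rest cluster (2-cluster FCM, fuzziness m), adjacent active windows are merged,
boundaries are snapped to window edges, and segments shorter than a minimum
duration are dropped.  Externally supplied boundaries can replace it, so real
annotations slot in unchanged.

The inverse filters come from modified-covariance AR models of noise-only
baseline recordings: if the chain is modelled as an AR(P) coloration, the FIR
whitening filter is simply ``[1, -a_1, ..., -a_P]``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal as sps

from .core import DegenerateInputError, DualAxisRecording, SwallowSegment
from .wavelets import get_wavelet

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _fuzzy_cmeans_1d(x: np.ndarray, m: float = 2.0, n_iter: int = 200,
                     tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Two-cluster fuzzy c-means on a 1-D array.

    Returns (memberships to the high-valued cluster, cluster centers sorted
    ascending).  Standard alternating optimisation with fuzzifier ``m``.
    """
    lo, hi = np.percentile(x, [10, 90])
    if hi <= lo:
        hi = lo + 1.0
    centers = np.array([lo, hi], dtype=float)
    expo = 2.0 / (m - 1.0)
    u = np.full((len(x), 2), 0.5)
    for _ in range(n_iter):
        d = np.abs(x[:, None] - centers[None, :])
        d = np.maximum(d, 1e-12)
        inv = d ** (-expo)
        u_new = inv / inv.sum(axis=1, keepdims=True)
        w = u_new ** m
        new_centers = (w * x[:, None]).sum(axis=0) / w.sum(axis=0)
        shift = np.max(np.abs(new_centers - centers))
        centers, u = new_centers, u_new
        if shift < tol:
            break
    order = np.argsort(centers)
    return u[:, order[1]], centers[order]


def segment_swallows(recording: DualAxisRecording, expected_count: int = 4,
                     window_s: float = 0.1, fuzziness: float = 2.0,
                     overlap: float = 0.5, min_duration_s: float = 0.3,
                     ) -> list[tuple[int, int]]:
    """Locate swallow intervals in a sequence recording.

    Returns up to ``expected_count`` disjoint, sorted, 0-based half-open
    ``(start, end)`` sample intervals.  If fewer segments are found, a warning
    is issued and whatever was found is returned (mirroring the exclusion of
    unsegmentable swallows).  If more are found, the ``expected_count``
    highest-energy ones are kept.
    """
    if expected_count < 1:
        raise ValueError("expected_count must be >= 1")
    fs = recording.sampling_rate
    energy = recording.ap ** 2 + recording.si ** 2
    w = max(2, int(round(window_s * fs)))
    hop = max(1, int(round(w * (1.0 - overlap))))
    n = recording.n
    if n < w:
        w = n
        hop = max(1, w // 2)
    starts = np.arange(0, n - w + 1, hop)
    env = np.sqrt(np.array([energy[s:s + w].mean() for s in starts]))

    if env.max() <= 0 or np.ptp(env) == 0:
        warnings.warn("no activity found: envelope is flat", stacklevel=2)
        return []

    member_hi, centers = _fuzzy_cmeans_1d(np.log10(env + 1e-12 * env.max() + 1e-300),
                                          m=fuzziness)
    active = member_hi > 0.5

    # merge runs of active windows into sample intervals
    intervals: list[tuple[int, int, float]] = []
    i = 0
    while i < len(active):
        if active[i]:
            j = i
            while j + 1 < len(active) and active[j + 1]:
                j += 1
            start = int(starts[i])
            end = int(min(starts[j] + w, n))
            peak = float(env[i:j + 1].max())
            intervals.append((start, end, peak))
            i = j + 1
        else:
            i += 1

    intervals = [(s, e, p) for s, e, p in intervals
                 if (e - s) / fs >= min_duration_s]
    if len(intervals) > expected_count:
        keep = sorted(intervals, key=lambda t: t[2], reverse=True)[:expected_count]
        intervals = sorted(keep)
    if len(intervals) < expected_count:
        warnings.warn(
            f"found {len(intervals)} segment(s), expected {expected_count}; "
            "returning what was found", stacklevel=2)
    return [(s, e) for s, e, _ in intervals]


# ---------------------------------------------------------------------------
# inverse filtering of the acquisition chain
# ---------------------------------------------------------------------------

def fit_ar_modified_covariance(baseline: np.ndarray, order: int) -> np.ndarray:
    """Fit AR(P) coefficients by the modified covariance (forward-backward
    least squares) method.

    The returned ``a`` satisfy ``x[t] ~= sum_k a[k-1] * x[t-k]`` and minimise
    the combined forward and backward prediction error.
    """
    x = np.asarray(baseline, dtype=float)
    if order < 1:
        raise ValueError("order must be >= 1")
    if len(x) <= 10 * order:
        raise ValueError("baseline too short for requested order (need > 10*order)")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant baseline: AR model undefined")
    n = len(x)
    win = np.lib.stride_tricks.sliding_window_view(x, order)
    # forward: predict x[t] from x[t-1..t-P]
    A_f = win[: n - order][:, ::-1]
    b_f = x[order:]
    # backward: predict x[t] from x[t+1..t+P]
    A_b = win[1:]
    b_b = x[: n - order]
    A = np.vstack([A_f, A_b])
    b = np.concatenate([b_f, b_b])
    coeffs, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < order:
        raise DegenerateInputError("near-singular normal equations in AR fit")
    return coeffs


def build_inverse_fir(ar_coeffs: np.ndarray) -> np.ndarray:
    """Whitening FIR taps ``[1, -a_1, ..., -a_P]`` for a fitted AR model.

    An empty coefficient array yields the identity filter ``[1]``.
    """
    a = np.asarray(ar_coeffs, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("AR coefficients must be finite")
    return np.concatenate([[1.0], -a])


@dataclass
class InverseFilterSpec:
    """Axis-specific whitening filters estimated from one baseline recording."""

    ar_order: int
    ar_coeffs_ap: np.ndarray
    ar_coeffs_si: np.ndarray

    @property
    def fir_taps_ap(self) -> np.ndarray:
        return build_inverse_fir(self.ar_coeffs_ap)

    @property
    def fir_taps_si(self) -> np.ndarray:
        return build_inverse_fir(self.ar_coeffs_si)

    @classmethod
    def identity(cls) -> "InverseFilterSpec":
        return cls(0, np.array([]), np.array([]))

    @classmethod
    def from_baseline(cls, baseline: DualAxisRecording, order: int = 10,
                      ) -> "InverseFilterSpec":
        return cls(order,
                   fit_ar_modified_covariance(baseline.ap, order),
                   fit_ar_modified_covariance(baseline.si, order))


def apply_inverse_fir(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    return sps.lfilter(taps, [1.0], np.asarray(x, dtype=float))


# ---------------------------------------------------------------------------
# wavelet denoising
# ---------------------------------------------------------------------------

@dataclass
class DenoiseSpec:
    """Discrete Meyer wavelet soft-threshold denoising parameters.

    ``t_den=None`` computes the threshold per signal from its first-level
    detail coefficients (robust MAD noise estimate times the universal
    factor sqrt(2 ln n)); ``t_den=0`` disables shrinkage (pass-through)."""

    wavelet: str = "dmey"
    levels: int = 10
    threshold_mode: str = "soft"
    t_den: float | None = None


def denoise_threshold(d1_coeffs: np.ndarray, n: int) -> float:
    """Universal soft threshold with a robust noise estimate.

    ``T = (median(|d1|) / 0.6745) * sqrt(2 ln n)`` where ``d1`` holds the
    first-level detail coefficients and ``n`` is the signal length.  The
    0.6745 constant is the median of |N(0,1)|, making median(|d1|)/0.6745 a
    consistent estimate of the noise standard deviation.
    """
    d1 = np.asarray(d1_coeffs, dtype=float)
    if d1.size == 0:
        raise ValueError("d1 must be non-empty")
    if n < 2:
        raise ValueError("signal length must be >= 2")
    sigma = np.median(np.abs(d1)) / 0.6745
    return float(sigma * np.sqrt(2.0 * np.log(n)))


def _wavedec(x: np.ndarray, wavelet, level: int) -> list[np.ndarray]:
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Level value of .* is too high")
        return pywt.wavedec(x, wavelet, mode="periodization", level=level)


def wavelet_denoise(samples: np.ndarray, spec: DenoiseSpec | None = None) -> np.ndarray:
    """Soft-threshold wavelet denoising; output length equals input length.

    All detail bands are shrunk with one global threshold; the approximation
    band is left untouched.  For signals too short for the requested depth
    the feasible maximum level (one level per signal-length octave, minus
    one) is used — band identity does not matter here.
    """
    spec = spec or DenoiseSpec()
    x = np.asarray(samples, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    wav = get_wavelet(spec.wavelet)
    level = min(spec.levels, max(1, int(np.log2(len(x))) - 1))
    if level < spec.levels:
        logger.debug("short signal (n=%d): using %d decomposition levels", len(x), level)
    coeffs = _wavedec(x, wav, level)
    t = spec.t_den
    if t is None:
        t = denoise_threshold(coeffs[-1], len(x))
    if t > 0:
        coeffs = [coeffs[0]] + [pywt.threshold(c, t, mode=spec.threshold_mode)
                                for c in coeffs[1:]]
    rec = pywt.waverec(coeffs, wav, mode="periodization")
    return rec[: len(x)]


# ---------------------------------------------------------------------------
# full per-recording preprocessing
# ---------------------------------------------------------------------------

def preprocess_recording(recording: DualAxisRecording,
                         inverse: InverseFilterSpec | None = None,
                         denoise: DenoiseSpec | None = None,
                         boundaries: list[tuple[int, int]] | None = None,
                         expected_count: int = 4,
                         **segment_kwargs) -> list[SwallowSegment]:
    """Segment a recording and condition each swallow.

    Stage order: segmentation (or externally supplied ``boundaries``), then
    per-axis inverse FIR filtering, then per-axis wavelet denoising.  Returns
    one :class:`SwallowSegment` per retained swallow.
    """
    inverse = inverse or InverseFilterSpec.identity()
    denoise = denoise or DenoiseSpec()
    if boundaries is None:
        boundaries = segment_swallows(recording, expected_count=expected_count,
                                      **segment_kwargs)
    meta = recording.meta
    segments: list[SwallowSegment] = []
    for idx, (start, end) in enumerate(boundaries):
        try:
            x = apply_inverse_fir(recording.ap[start:end], inverse.fir_taps_ap)
            y = apply_inverse_fir(recording.si[start:end], inverse.fir_taps_si)
            x = wavelet_denoise(x, denoise)
            y = wavelet_denoise(y, denoise)
        except Exception as exc:  # attach segment identity to stage errors
            raise RuntimeError(
                f"preprocessing failed for swallow {idx} [{start}, {end}): {exc}"
            ) from exc
        segments.append(SwallowSegment(
            x, y, recording.sampling_rate,
            participant=meta.participant if meta else "",
            stimulus=meta.stimulus if meta else "",
            task=meta.task if meta else "",
            repetition=meta.repetition if meta else 0,
            swallow_index=idx))
    return segments
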