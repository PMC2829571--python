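"""Time-domain features of a preprocessed swallow.

Each swallow contributes, per axis: mean, unbiased variance, skewness,
kurtosis (non-excess), entropy rate (Porta-style regularity index rho),
memory (1/e autocorrelation width) and normalized Lempel-Ziv complexity;
plus three cross/shared features: duration, cross-entropy rate (a
synchronization index lambda) and the zero-lag cross-correlation.

Conventions adopted where the originals leave latitude, each documented on
its function: entropies use natural logarithms (rho and lambda are entropy
ratios, so the base cancels); pattern identity is exact symbol-tuple
equality, equivalent to the injective base-Q integer coding but without
10^30-scale arithmetic; the autocorrelation estimator is biased (divisor n),
which keeps |r| <= 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import DegenerateInputError

logger = logging.getLogger(__name__)

#: L range over which the conditional-entropy minimum is searched
L_MIN, L_MAX = 10, 30


# ---------------------------------------------------------------------------
# moments
# ---------------------------------------------------------------------------

def moments(x: np.ndarray) -> tuple[float, float, float, float]:
    """(mean, unbiased variance, skewness, kurtosis) of the amplitude
    distribution.

    Skewness is ``m3 / m2^(3/2)`` and kurtosis ``m4 / m2^2`` with central
    sample moments ``m_k = sum((x-mu)^k)/n`` — kurtosis is non-excess, so a
    Gaussian scores 3.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 samples")
    mu = x.mean()
    var = x.var(ddof=1)
    c = x - mu
    m2 = np.mean(c ** 2)
    if m2 == 0:
        raise DegenerateInputError("zero variance: skewness/kurtosis undefined")
    skew = np.mean(c ** 3) / m2 ** 1.5
    kurt = np.mean(c ** 4) / m2 ** 2
    return float(mu), float(var), float(skew), float(kurt)


# ---------------------------------------------------------------------------
# quantization and pattern statistics
# ---------------------------------------------------------------------------

@dataclass
class QuantizedSequence:
    """Integer symbols in ``[0, Q-1]`` plus the normalisation stats used."""

    symbols: np.ndarray
    Q: int
    source_stats: tuple[float, float]


def quantize(x: np.ndarray, Q: int, normalize: bool = True) -> QuantizedSequence:
    """Quantize into ``Q`` equally spaced levels spanning min..max.

    With ``normalize`` the signal is first standardised to zero mean and unit
    variance (the min-max binning that follows makes the symbols invariant to
    positive affine transforms either way).  The maximum maps to level Q-1.
    """
    x = np.asarray(x, dtype=float)
    mu, sd = float(x.mean()), float(x.std())
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant signal cannot be quantized")
    if normalize:
        x = (x - mu) / sd
    lo, hi = x.min(), x.max()
    width = (hi - lo) / Q
    sym = np.floor((x - lo) / width).astype(np.int64)
    np.clip(sym, 0, Q - 1, out=sym)
    return QuantizedSequence(sym.astype(np.uint8 if Q <= 256 else np.int64),
                             Q, (mu, sd))


@dataclass
class PatternDistribution:
    """Counts of the overlapping length-L windows of a symbol sequence."""

    L: int
    counts: np.ndarray
    SE: float       # Shannon entropy, nats
    perc: float     # fraction of patterns occurring exactly once

    @property
    def n_patterns(self) -> int:
        return int(self.counts.sum())


def _window_counts(arr2d: np.ndarray) -> np.ndarray:
    """Multiplicities of the distinct rows of a 2-D uint8 array."""
    a = np.ascontiguousarray(arr2d)
    void = a.view(np.dtype((np.void, a.dtype.itemsize * a.shape[1]))).ravel()
    _, counts = np.unique(void, return_counts=True)
    return counts


def _entropy_perc(counts: np.ndarray) -> tuple[float, float]:
    total = counts.sum()
    p = counts / total
    se = float(-(p * np.log(p)).sum())
    perc = float((counts == 1).sum() / total)
    return se, perc


def pattern_distribution(q: QuantizedSequence | np.ndarray, L: int) -> PatternDistribution:
    """Distribution of the ``n-L+1`` overlapping length-L symbol patterns.

    SE is the Shannon entropy (nats) under sample-frequency probabilities;
    ``perc`` is the fraction of patterns occurring exactly once.  Pattern
    identity is exact symbol-sequence equality.
    """
    sym = q.symbols if isinstance(q, QuantizedSequence) else np.asarray(q)
    n = len(sym)
    if L < 1 or L > n:
        raise ValueError(f"need 1 <= L <= n, got L={L}, n={n}")
    windows = sliding_window_view(sym, L)
    counts = _window_counts(windows)
    se, perc = _entropy_perc(counts)
    return PatternDistribution(L, counts, se, perc)


# ---------------------------------------------------------------------------
# entropy rate (regularity index rho)
# ---------------------------------------------------------------------------

def entropy_rate(x: np.ndarray, Q: int = 10,
                 l_min: int = L_MIN, l_max: int = L_MAX) -> float:
    """Regularity index rho in [0, 1]; 1 = maximally regular.

    The signal is standardised and quantized to ``Q`` levels.  For each
    pattern length L in ``[l_min, l_max]`` the corrected conditional entropy
    is ``CCE(L) = SE(L) - SE(L-1) + perc(L) * SE(1)`` — the conditional
    entropy plus a correction that charges patterns observed only once with
    the full single-symbol entropy, which removes the spurious decrease of
    the raw conditional entropy at large L.  rho = 1 - min_L CCE(L)/SE(1),
    clipped to [0, 1].

    A constant signal returns rho = 1 by convention (maximum regularity).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if np.ptp(x) == 0:
        logger.debug("constant signal: rho = 1 by convention")
        return 1.0
    if n < l_max + 1:
        raise ValueError(f"need n >= {l_max + 1} samples, got {n}")
    q = quantize(x, Q, normalize=True)
    pds = {L: pattern_distribution(q, L) for L in range(l_min - 1, l_max + 1)}
    se1 = pattern_distribution(q, 1).SE
    if se1 == 0:
        return 1.0
    best = np.inf
    for L in range(l_min, l_max + 1):
        cce = pds[L].SE - pds[L - 1].SE + pds[L].perc * se1
        best = min(best, cce / se1)
    return float(np.clip(1.0 - best, 0.0, 1.0))


# ---------------------------------------------------------------------------
# cross-entropy rate (synchronization index lambda)
# ---------------------------------------------------------------------------

def _mixed_counts(target: np.ndarray, source: np.ndarray, L: int) -> np.ndarray:
    """Counts of the mixed patterns pairing one current target symbol with
    the L-1 current-and-past source symbols."""
    n = len(target)
    cols = [target[L - 1:][:, None]]
    if L > 1:
        cols.append(sliding_window_view(source, L - 1)[: n - L + 1])
    return _window_counts(np.hstack(cols))


def cross_entropy_rate(x: np.ndarray, y: np.ndarray, Q: int = 10,
                       l_min: int = L_MIN, l_max: int = L_MAX) -> float:
    """Synchronization index lambda in [0, 1]; 1 = perfect synchronization.

    Both channels are standardised and quantized separately.  For each L the
    directional corrected cross-conditional entropy of X given Y is
    ``SE_{X/Y}(L) - SE_Y(L-1) + perc_{X/Y}(L) * SE_X(1)`` normalised by
    ``SE_X(1)``, where the mixed pattern joins one current X symbol with the
    L-1 current-and-past Y symbols; the mirror direction swaps the roles.
    The uncoupling function is the pointwise minimum of the two directions,
    and lambda = 1 - min_L UF(L), clipped to [0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("constant channel: lambda undefined")
    if n < l_max + 1:
        raise ValueError(f"need n >= {l_max + 1} samples, got {n}")
    qx = quantize(x, Q).symbols
    qy = quantize(y, Q).symbols
    se_x = {L: pattern_distribution(qx, L).SE for L in range(l_min - 1, l_max)}
    se_y = {L: pattern_distribution(qy, L).SE for L in range(l_min - 1, l_max)}
    se1_x = pattern_distribution(qx, 1).SE
    se1_y = pattern_distribution(qy, 1).SE
    if se1_x == 0 or se1_y == 0:
        raise DegenerateInputError("degenerate quantized channel")
    best = np.inf
    for L in range(l_min, l_max + 1):
        cxy = _mixed_counts(qx, qy, L)
        se_xy, perc_xy = _entropy_perc(cxy)
        ncce_xy = (se_xy - se_y[L - 1] + perc_xy * se1_x) / se1_x
        cyx = _mixed_counts(qy, qx, L)
        se_yx, perc_yx = _entropy_perc(cyx)
        ncce_yx = (se_yx - se_x[L - 1] + perc_yx * se1_y) / se1_y
        best = min(best, min(ncce_xy, ncce_yx))
    return float(np.clip(1.0 - best, 0.0, 1.0))


# ---------------------------------------------------------------------------
# memory, Lempel-Ziv complexity, duration, cross-correlation
# ---------------------------------------------------------------------------

def autocorrelation(x: np.ndarray) -> np.ndarray:
    """Biased sample autocorrelation (divisor n), normalised to r(0)=1,
    for lags 0..n-1, computed via FFT."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    c = x - x.mean()
    if np.all(c == 0):
        raise DegenerateInputError("constant signal has no autocorrelation")
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(c, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n]
    return acov / acov[0]


def memory_1e(x: np.ndarray, sampling_rate: float) -> float:
    """Signal memory in seconds: the 1/e autocorrelation width.

    The smallest lag tau with r(tau) <= 1/e (~0.3679), divided by the
    sampling rate; no interpolation.  If the autocorrelation never crosses
    1/e, the maximum lag ``(n-1)/fs`` is returned (logged).
    """
    r = autocorrelation(x)
    thresh = 1.0 / np.e
    below = r <= thresh
    if not below.any():
        logger.debug("autocorrelation never reached 1/e; returning max lag")
        return (len(r) - 1) / sampling_rate
    tau = int(np.argmax(below))
    return tau / sampling_rate


def lz76_block_count(symbols: np.ndarray) -> int:
    """Number of blocks in the exhaustive-history Lempel-Ziv parsing.

    The first block is the first symbol; each subsequent block is the
    shortest continuation that does not occur earlier in the sequence
    (occurrences may overlap into the block under construction, i.e. the
    search window for a candidate ending at position ``i+l`` is
    ``s[0 : i+l-1]``).  A final block left incomplete at the end of the
    sequence still counts, so a constant sequence parses into 2 blocks.
    """
    s = np.asarray(symbols)
    if s.size == 0:
        raise ValueError("empty sequence")
    if s.max(initial=0) > 255 or s.min(initial=0) < 0:
        raise ValueError("symbols must fit in a byte")
    buf = s.astype(np.uint8).tobytes()
    n = len(buf)
    k = 1
    i = 1
    while i < n:
        l = 1
        while i + l <= n and buf[: i + l - 1].find(buf[i: i + l]) != -1:
            l += 1
        k += 1
        i += l
    return k


def lz_complexity(x: np.ndarray, Q: int = 100) -> float:
    """Normalized Lempel-Ziv complexity ``C = k * log_Q(n) / n``.

    The raw signal is quantized into ``Q`` equally spaced levels spanning its
    min..max (no standardisation — min-max binning already makes the symbols
    scale invariant), parsed into ``k`` exhaustive-history blocks, and
    normalised with logarithm base ``Q``.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 samples")
    if np.ptp(x) == 0:
        # the parsing rule gives k=2 for any constant sequence
        return 2.0 * (np.log(n) / np.log(Q)) / n
    sym = quantize(x, Q, normalize=False).symbols
    k = lz76_block_count(sym)
    return float(k * (np.log(n) / np.log(Q)) / n)


def duration(n: int, sampling_rate: float) -> float:
    """Temporal swallow duration in seconds: ``(n - 1) / sampling_rate``
    (0.0001*(n-1) at the study's 10 kHz rate)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return (n - 1) / sampling_rate


def crosscorr_zero_lag(x: np.ndarray, y: np.ndarray) -> float:
    """Normalized zero-lag cross-correlation in [-1, 1] (Pearson form)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    cx = x - x.mean()
    cy = y - y.mean()
    denom = np.sqrt((cx ** 2).sum() * (cy ** 2).sum())
    if denom == 0:
        raise DegenerateInputError("constant channel: cross-correlation undefined")
    return float(np.dot(cx, cy) / denom)
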