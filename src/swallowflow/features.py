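"""The 30-feature per-swallow vector and tidy feature tables.

Composition: 7 time-domain features per axis (mean, variance, skewness,
kurtosis, entropy rate, memory, Lempel-Ziv complexity) plus wavelet entropy
per axis = 16 per-axis features; duration, cross-entropy rate and zero-lag
cross-correlation shared between axes = 3; and 11 retained wavelet band
energies (5 on A-P, 6 on S-I) = 30 features in total.

A feature whose computation is undefined for a given swallow (e.g. a constant
channel) is recorded as missing (NaN); the statistical stage's per-cell
medians ignore missing values.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core import DegenerateInputError, SwallowSegment
from . import features_time as ft
from . import features_wavelet as fw

logger = logging.getLogger(__name__)

_TIME_PER_AXIS = ("mean", "variance", "skewness", "kurtosis",
                  "entropy_rate", "memory", "lz")
_SHARED = ("duration", "cross_entropy_rate", "crosscorr0")

#: the canonical ordered names of the 30 per-swallow features
FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"{f}_{axis}" for axis in ("ap", "si") for f in _TIME_PER_AXIS]
    + [f"wavelet_entropy_{axis}" for axis in ("ap", "si")]
    + list(_SHARED)
    + [f"wen_{band}_ap" for band in fw.DEFAULT_RETAINED["ap"]]
    + [f"wen_{band}_si" for band in fw.DEFAULT_RETAINED["si"]]
)

ID_COLUMNS = ("participant", "stimulus", "task", "repetition", "swallow_index")


def _axis_time_features(x: np.ndarray, fs: float, out: dict, axis: str,
                        wanted: set[str]) -> None:
    if wanted & {f"{m}_{axis}" for m in ("mean", "variance", "skewness", "kurtosis")}:
        try:
            mu, var, skew, kurt = ft.moments(x)
            out[f"mean_{axis}"] = mu
            out[f"variance_{axis}"] = var
            out[f"skewness_{axis}"] = skew
            out[f"kurtosis_{axis}"] = kurt
        except DegenerateInputError:
            out[f"mean_{axis}"] = float(np.mean(x))
            out[f"variance_{axis}"] = float(np.var(x, ddof=1))
            logger.debug("constant %s channel: skewness/kurtosis missing", axis)
    for name, fn in (("entropy_rate", lambda: ft.entropy_rate(x)),
                     ("memory", lambda: ft.memory_1e(x, fs)),
                     ("lz", lambda: ft.lz_complexity(x))):
        if f"{name}_{axis}" in wanted:
            try:
                out[f"{name}_{axis}"] = fn()
            except (DegenerateInputError, ValueError) as exc:
                logger.debug("%s_%s missing: %s", name, axis, exc)


def _axis_wavelet_features(x: np.ndarray, out: dict, axis: str) -> None:
    try:
        rel = fw.relative_energies(fw.dwt10(x))
    except DegenerateInputError as exc:
        logger.debug("wavelet features missing on %s: %s", axis, exc)
        return
    out[f"wavelet_entropy_{axis}"] = fw.wavelet_entropy(rel)
    for band in fw.DEFAULT_RETAINED[axis]:
        out[f"wen_{band}_{axis}"] = float(rel[fw.BAND_NAMES.index(band)])


def extract_features(segment: SwallowSegment,
                     names: tuple[str, ...] | None = None) -> dict[str, float]:
    """Compute the per-swallow feature vector.

    Returns a dict keyed by feature name; undefined features are NaN.  With
    ``names`` only the feature groups needed for those names are computed
    (useful for large simulation studies).
    """
    wanted = set(names) if names is not None else set(FEATURE_NAMES)
    out: dict[str, float] = {name: float("nan") for name in wanted}
    fs = segment.sampling_rate

    for axis, sig in (("ap", segment.X), ("si", segment.Y)):
        if any(w.endswith(f"_{axis}") and not w.startswith(("wen_", "wavelet_"))
               for w in wanted):
            tmp: dict[str, float] = {}
            _axis_time_features(sig, fs, tmp, axis, wanted)
            out.update({k: v for k, v in tmp.items() if k in wanted})
        if any(w.endswith(f"_{axis}") and w.startswith(("wen_", "wavelet_"))
               for w in wanted):
            tmp = {}
            _axis_wavelet_features(sig, tmp, axis)
            out.update({k: v for k, v in tmp.items() if k in wanted})

    if "duration" in wanted:
        out["duration"] = ft.duration(segment.n, fs)
    if "cross_entropy_rate" in wanted:
        try:
            out["cross_entropy_rate"] = ft.cross_entropy_rate(segment.X, segment.Y)
        except (DegenerateInputError, ValueError) as exc:
            logger.debug("cross_entropy_rate missing: %s", exc)
    if "crosscorr0" in wanted:
        try:
            out["crosscorr0"] = ft.crosscorr_zero_lag(segment.X, segment.Y)
        except DegenerateInputError as exc:
            logger.debug("crosscorr0 missing: %s", exc)
    return out


def build_feature_table(segments: list[SwallowSegment],
                        names: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Tidy long-format table: one row per (swallow, feature).

    Columns: participant, stimulus, task, repetition, swallow_index,
    feature_name, value.
    """
    rows = []
    for seg in segments:
        feats = extract_features(seg, names)
        for fname, value in feats.items():
            rows.append({
                "participant": seg.participant,
                "stimulus": seg.stimulus,
                "task": seg.task,
                "repetition": seg.repetition,
                "swallow_index": seg.swallow_index,
                "feature_name": fname,
                "value": value,
            })
    return pd.DataFrame(rows, columns=list(ID_COLUMNS) + ["feature_name", "value"])
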