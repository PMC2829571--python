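"""Feature-level study simulation.

Power and calibration studies of the statistical stage do not need the full
recording round trip (assemble sequence -> acquisition chain -> segmentation
-> inverse filter -> denoise): the acquisition chain and its inverse cancel
in expectation, and ground-truth boundaries make segmentation exact.  This
module therefore generates swallows directly from the stimulus profiles and
extracts the requested features, producing the same tidy table the full
pipeline emits — at a fraction of the cost.  The full pipeline path is
exercised separately by :mod:`swallowflow.pipeline`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import SwallowSegment, STIMULI
from .features import build_feature_table, FEATURE_NAMES
from .synthgen import (SyntheticConfig, default_session_plan,
                       draw_participant_effects, draw_duration,
                       generate_swallow, _participant_rng)


def simulate_feature_table(config: SyntheticConfig,
                           features: tuple[str, ...] | None = None,
                           ) -> pd.DataFrame:
    """Simulate the whole study protocol at the swallow level.

    Every participant follows the default 17-entry session plan with four
    swallows per entry; each swallow is generated from its stimulus profile
    (with the participant's random effects) and reduced to the requested
    ``features`` (default: all 30).  Returns the tidy long-format table.
    """
    segments: list[SwallowSegment] = []
    for idx in range(config.n_participants):
        rng = _participant_rng(config, idx)
        pid = f"P{idx:02d}"
        eff = draw_participant_effects(config, rng)
        plan = default_session_plan(pid)
        for stimulus, task, rep in plan.entries:
            profile = config.profiles[stimulus]
            for k in range(4):
                ap, si, _ = generate_swallow(
                    profile, task, rng, sampling_rate=config.sampling_rate,
                    coupling=config.coupling, effects=eff,
                    within_sd=config.within_sd_duration)
                segments.append(SwallowSegment(
                    ap, si, config.sampling_rate, participant=pid,
                    stimulus=stimulus, task=task, repetition=rep,
                    swallow_index=k))
    return build_feature_table(segments, features)


def simulate_null_duration_matrix(config: SyntheticConfig,
                                  rng: np.random.Generator) -> np.ndarray:
    """One participants x 4-stimuli matrix of cell-median durations under the
    null that all four stimuli share one profile (the water profile).

    Used to calibrate the type-I error of the blocked Friedman test without
    synthesising waveforms: each cell is the median of the durations of the
    swallows that the discrete-task protocol assigns to that cell.
    """
    profile = config.profiles["water"]
    reps_per_cell = {s: (3 if s == "water" else 2) for s in STIMULI}
    mat = np.empty((config.n_participants, len(STIMULI)))
    for i in range(config.n_participants):
        offset = rng.normal(0.0, config.participant_sd_duration)
        for j, stim in enumerate(STIMULI):
            draws = [draw_duration(profile, "discrete", rng,
                                   within_sd=config.within_sd_duration,
                                   offset=offset)
                     for _ in range(4 * reps_per_cell[stim])]
            mat[i, j] = np.median(draws)
    return mat
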