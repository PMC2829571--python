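"""Simulate one participant's recording session.

Generates the 17-sequence protocol (every stimulus x task combination twice,
water-discrete three times), each sequence holding four swallows, plus a
noise-only baseline recording, and prints the protocol bookkeeping.
"""

import numpy as np

import swallowflow as sf

cfg = sf.SyntheticConfig(n_participants=1, sampling_rate=1000.0, seed=42)
recordings, baseline = sf.generate_session(cfg, participant_index=0)

print(f"{len(recordings)} sequence recordings; baseline of {baseline.n} samples")
for rec, truth in recordings[:5]:
    durs = ", ".join(f"{d:.2f}" for d in truth.latent_durations)
    print(f"  {rec.meta.stimulus:>6} / {rec.meta.task:<10} rep {rec.meta.repetition}"
          f"  {rec.duration_s:6.1f} s, swallow durations [{durs}] s")
print("  ...")

counts = {}
for rec, _ in recordings:
    key = (rec.meta.stimulus, rec.meta.task)
    counts[key] = counts.get(key, 0) + 1
print("repetitions per condition:", dict(sorted(counts.items())))
# water-discrete appears 3x, every other combination 2x: 17 sequences total,
# each with exactly 4 ground-truth swallows.
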