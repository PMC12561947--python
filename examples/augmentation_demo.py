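"""Sequence-consistent augmentation on an RDM sequence.

Shows the two training-time transforms — range translation and random
erasing — and verifies the properties that make them safe for radar data:
the same displacement and the same erase rectangle on every frame, fill
values inside the data's own range, labels untouched.
"""

import numpy as np

from radarcough import (AugmentationConfig, augment, preprocess,
                        sample_motion_profile, synthesize_cube)
from radarcough.augment import sample_erase_rect, sample_shift

rng = np.random.default_rng(1)
profile = sample_motion_profile("cough", "bed", rng)
seq = preprocess(synthesize_cube(profile, snr_db=20, rng=rng))

cfg = AugmentationConfig()  # max shift 12 bins, erase 5-20% area
shift = sample_shift(cfg, rng)
rect = sample_erase_rect(seq.data.shape[-2:], cfg, rng)
print(f"sampled range shift: {shift:+d} bins "
      f"({'away from' if shift > 0 else 'toward'} the radar)")
print(f"sampled erase rect: {rect.height}x{rect.width} px at "
      f"({rect.row0}, {rect.col0}) = "
      f"{100 * rect.area / (48 * 125):.1f}% of the frame")

out = augment(seq, AugmentationConfig(p_translate=1.0, p_erase=1.0),
              np.random.default_rng(2))
changed = (out.data != seq.data)[:, 0]
same_mask_everywhere = all(
    np.array_equal(changed[t], changed[0]) for t in range(seq.num_frames)
)
print(f"\naugmented shape {out.data.shape} (unchanged)")
print(f"identical change mask on all {seq.num_frames} frames: "
      f"{same_mask_everywhere}")
print(f"fill values within original range "
      f"[{seq.data.min():.2f}, {seq.data.max():.2f}]: "
      f"{seq.data.min() <= out.data.min() and out.data.max() <= seq.data.max()}")
print(f"label preserved: {out.label == seq.label} (label={out.label})")
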