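"""Sequence-consistent augmentation of RDM sequences.

Both transforms are drawn once per sequence and applied identically to every
frame, so the temporal structure of the recording is preserved:

* range translation — every frame shifts by the same number of range bins
  (simulating a subject at a different distance); vacated rows are filled
  with the sequence minimum (the post-log noise floor);
* random erasing — one rectangle (area 5-20% of the frame, aspect ratio
  0.3-3.33) is masked on every frame with uniform random values drawn from
  the sequence's own value range.

Augmentation is a training-time regularizer only; it never touches labels
or metadata.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .config import AugmentationConfig
from .pipeline import RDMSequence


@dataclass(frozen=True)
class EraseRect:
    row0: int
    col0: int
    height: int
    width: int

    @property
    def area(self) -> int:
        return self.height * self.width


def sample_shift(cfg: AugmentationConfig, rng: np.random.Generator) -> int:
    """Uniform integer displacement in [-max_shift, +max_shift] range bins."""
    return int(rng.integers(-cfg.max_shift, cfg.max_shift + 1))


def translate_array(data: np.ndarray, shift: int) -> np.ndarray:
    """Shift every frame along the range axis; positive = away from radar.

    ``data`` is (T, C, B, W); vacated rows are filled with the sequence
    minimum.  The Doppler axis is untouched.
    """
    n_rows = data.shape[-2]
    if abs(shift) >= n_rows:
        raise ValueError(f"|shift| {abs(shift)} must be < band height {n_rows}")
    if shift == 0:
        return data.copy()
    out = np.full_like(data, data.min())
    if shift > 0:
        out[..., shift:, :] = data[..., :-shift, :]
    else:
        out[..., :shift, :] = data[..., -shift:, :]
    return out


def translate_sequence(seq: RDMSequence, shift: int) -> RDMSequence:
    return dataclasses.replace(seq, data=translate_array(seq.data, shift))


def sample_erase_rect(frame_shape: tuple[int, int], cfg: AugmentationConfig,
                      rng: np.random.Generator, max_attempts: int = 100) -> EraseRect:
    """Rejection-sample an erase rectangle on a (height, width) frame grid.

    The target area fraction and the aspect ratio (width/height) are drawn
    uniformly from their configured ranges; the rectangle sides are
    ``h = round(sqrt(area/aspect))``, ``w = round(sqrt(area*aspect))`` and a
    draw is rejected if the rounded rectangle does not fit inside the frame.
    """
    n_rows, n_cols = frame_shape
    total = n_rows * n_cols
    for _ in range(max_attempts):
        area = rng.uniform(*cfg.erase_area_range) * total
        aspect = rng.uniform(*cfg.erase_aspect_range)
        height = int(round(np.sqrt(area / aspect)))
        width = int(round(np.sqrt(area * aspect)))
        if height < 1 or width < 1 or height > n_rows or width > n_cols:
            continue
        row0 = int(rng.integers(0, n_rows - height + 1))
        col0 = int(rng.integers(0, n_cols - width + 1))
        return EraseRect(row0, col0, height, width)
    raise RuntimeError(
        f"no feasible erase rectangle on a {n_rows}x{n_cols} frame "
        f"after {max_attempts} attempts"
    )


def erase_array(data: np.ndarray, rect: EraseRect,
                rng: np.random.Generator) -> np.ndarray:
    """Mask the same rectangle on every frame with fresh uniform draws.

    Fill values are uniform over [min, max] of the original sequence, drawn
    independently per pixel per frame; pixels outside the rectangle are
    bit-identical to the input.
    """
    n_rows, n_cols = data.shape[-2], data.shape[-1]
    if not (0 <= rect.row0 and rect.row0 + rect.height <= n_rows
            and 0 <= rect.col0 and rect.col0 + rect.width <= n_cols
            and rect.height >= 1 and rect.width >= 1):
        raise ValueError(f"rect {rect} invalid for frame {n_rows}x{n_cols}")
    lo, hi = float(data.min()), float(data.max())
    out = data.copy()
    fill_shape = data.shape[:-2] + (rect.height, rect.width)
    out[..., rect.row0:rect.row0 + rect.height,
        rect.col0:rect.col0 + rect.width] = rng.uniform(
        lo, hi, size=fill_shape
    ).astype(data.dtype)
    return out


def erase_sequence(seq: RDMSequence, rect: EraseRect,
                   rng: np.random.Generator) -> RDMSequence:
    return dataclasses.replace(seq, data=erase_array(seq.data, rect, rng))


def augment_array(data: np.ndarray, cfg: AugmentationConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Translation (prob. p_translate) then erasing (prob. p_erase)."""
    if rng.random() < cfg.p_translate:
        data = translate_array(data, sample_shift(cfg, rng))
    if rng.random() < cfg.p_erase:
        rect = sample_erase_rect(data.shape[-2:], cfg, rng)
        data = erase_array(data, rect, rng)
    return data


def augment(seq: RDMSequence, cfg: AugmentationConfig,
            rng: np.random.Generator) -> RDMSequence:
    """Randomized training-time augmentation; deterministic given ``rng``."""
    return dataclasses.replace(seq, data=augment_array(seq.data, cfg, rng))
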