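"""Inter-frame differencing with an ambient-compensated threshold.

A pixel is flagged as moving when its absolute inter-frame difference
exceeds T = T_c + T_r, where T_c is a fixed sensitivity and T_r — the
ambient complementary factor — is the mean absolute difference over all ROI
pixels.  A spatially uniform illumination change of magnitude g raises T_r
by exactly g, so the threshold tracks the change and the motion mask stays
empty: this is what makes the fused detector robust to light steps, and it
also drives the per-pixel learning rate of the background model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class DiffResult:
    diff: np.ndarray          # D_t, absolute differences (int32)
    threshold: float          # T = T_c + T_r
    ambient_term: float       # T_r, mean of D_t over the ROI
    motion_mask: np.ndarray   # bool, True where D_t > T


def frame_difference(f_prev: np.ndarray, f_cur: np.ndarray, Tc: float = 10.0) -> DiffResult:
    """Absolute difference of two frames thresholded at T_c + mean(|diff|).

    Differences are computed in a widened integer domain (no 8-bit
    wrap-around); flagging is strict (> T), so ties go to background.
    """
    f_prev = np.asarray(f_prev)
    f_cur = np.asarray(f_cur)
    if f_prev.shape != f_cur.shape:
        raise ValueError(f"shape mismatch: {f_prev.shape} vs {f_cur.shape}")
    if Tc < 0:
        raise ValueError("Tc must be >= 0")
    diff = np.abs(f_cur.astype(np.int32) - f_prev.astype(np.int32))
    ambient = float(diff.mean())
    threshold = float(Tc) + ambient
    return DiffResult(diff=diff, threshold=threshold, ambient_term=ambient,
                      motion_mask=diff > threshold)
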