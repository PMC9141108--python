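"""Quantitative evaluation of the detector and of whole-bottle inspection.

Three families of statistics:

* **Pixel metrics** — precision Pa = M/(M+N), recall Pb = M/(M+L) and the
  comprehensive index Pc = 2 Pa Pb / (Pa + Pb) (the harmonic mean), from the
  pixelwise contingency of a predicted foreground mask against ground truth
  (M true-positive, N false-positive, L false-negative pixels).
* **Recognition rate** — eta = (n1 + n2) / (m n3) over m experiment rounds of
  n3 detections each, with n1 correctly flagged impure samples and n2
  correctly passed clean samples.
* **Knapp-Kushner quality factors** — per-sample FQ = q/N * 10 from q
  rejections in N repeated tests; the efficiency ratio R compares machine to
  manual inspection as the ratio of the FQ sums restricted to the [7, 10]
  band (inclusive), R = FQB(7,10) / FQA(7,10) * 100%.

Degenerate denominators: both masks empty -> Pa = Pb = Pc = 1 (perfect
agreement); empty prediction against nonempty truth -> Pa = 0; nonempty
prediction against empty truth -> Pb = 1 (nothing to recall) and Pc = 0
through Pa = 0.  Reported percentages round half-up to one decimal place.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, List, Sequence, Tuple

import numpy as np


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round half away from zero at the given number of decimals."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class PixelEvalResult:
    M: int  # true-positive pixels
    N: int  # false-positive pixels
    L: int  # false-negative pixels
    Pa: float
    Pb: float
    Pc: float

    def as_percentages(self, decimals: int = 1) -> Tuple[float, float, float]:
        return tuple(round_half_up(100.0 * v, decimals) for v in (self.Pa, self.Pb, self.Pc))


def _rates_from_counts(M: int, N: int, L: int) -> Tuple[float, float, float]:
    if M + N + L == 0:
        return 1.0, 1.0, 1.0
    Pa = M / (M + N) if (M + N) > 0 else 0.0
    Pb = M / (M + L) if (M + L) > 0 else 1.0
    Pc = 2.0 * Pa * Pb / (Pa + Pb) if (Pa + Pb) > 0 else 0.0
    return Pa, Pb, Pc


def pixel_metrics(pred: np.ndarray, truth: np.ndarray) -> PixelEvalResult:
    """Pixelwise precision/recall/comprehensive index of one mask pair."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    M = int(np.sum(pred & truth))
    N = int(np.sum(pred & ~truth))
    L = int(np.sum(~pred & truth))
    Pa, Pb, Pc = _rates_from_counts(M, N, L)
    return PixelEvalResult(M=M, N=N, L=L, Pa=Pa, Pb=Pb, Pc=Pc)


def aggregate_pixel_metrics(pairs: Iterable[Tuple[np.ndarray, np.ndarray]]) -> PixelEvalResult:
    """Pooled metrics over (pred, truth) mask pairs: counts sum across frames."""
    M = N = L = 0
    for pred, truth in pairs:
        r = pixel_metrics(pred, truth)
        M, N, L = M + r.M, N + r.N, L + r.L
    Pa, Pb, Pc = _rates_from_counts(M, N, L)
    return PixelEvalResult(M=M, N=N, L=L, Pa=Pa, Pb=Pb, Pc=Pc)


def comprehensive_index(Pa: float, Pb: float) -> float:
    """Harmonic mean 2 Pa Pb / (Pa + Pb); 0 when both rates are 0."""
    return 2.0 * Pa * Pb / (Pa + Pb) if (Pa + Pb) > 0 else 0.0


def recognition_rate(m: int, n1: int, n2: int, n3: int) -> float:
    """Average recognition rate eta = (n1 + n2) / (m n3), as a fraction in [0, 1]."""
    if m <= 0 or n3 <= 0:
        raise ValueError("m and n3 must be positive")
    if n1 < 0 or n2 < 0 or n1 + n2 > m * n3:
        raise ValueError("need 0 <= n1 + n2 <= m * n3")
    return (n1 + n2) / (m * n3)


def quality_factor(q: int, N_tests: int) -> float:
    """FQ = q / N * 10 from q rejections in N repeated tests; in [0, 10]."""
    if N_tests <= 0:
        raise ValueError("N_tests must be positive")
    if not (0 <= q <= N_tests):
        raise ValueError("need 0 <= q <= N_tests")
    return q / N_tests * 10.0


def kk_ratio(fq_manual: Sequence[float], fq_machine: Sequence[float],
             band: Tuple[float, float] = (7.0, 10.0)) -> float:
    """Knapp-Kushner efficiency ratio R = FQB(7,10)/FQA(7,10) * 100%.

    Each sum runs over the samples whose quality factor lies inside the band
    (inclusive on both ends) for the respective inspector.
    """
    lo, hi = band
    fqa = sum(v for v in fq_manual if lo <= v <= hi)
    fqb = sum(v for v in fq_machine if lo <= v <= hi)
    if fqa == 0:
        raise ValueError("manual quality-factor sum in the band is zero; R undefined")
    return fqb / fqa * 100.0


def rejection_table_quality_factors(rows: Sequence[Tuple[str, int, int]]) -> List[Tuple[str, float]]:
    """(sample_id, q, N) rows -> (sample_id, FQ) records."""
    return [(sid, quality_factor(q, n)) for sid, q, n in rows]
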