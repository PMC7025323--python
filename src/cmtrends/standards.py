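"""Reference standard populations for age-standardisation.

The WHO World Standard population (Ahmad et al., GPE Discussion Paper 31,
WHO 2001) is shipped as the five-year weight table below (percent of total
population; the 85+ entry pools 85-89, 90-94, 95-99 and 100+).  For
age-standardising adult estimates the five-year weights are collapsed onto
the modelled age bands and renormalised over the adult range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .bands import AgeBand, validate_bands

# (age_lo, age_hi or None, percent) — WHO World Standard 2000-2025
WHO_WORLD_STANDARD_5Y: tuple[tuple[int, int | None, float], ...] = (
    (0, 5, 8.86), (5, 10, 8.69), (10, 15, 8.60), (15, 20, 8.47),
    (20, 25, 8.22), (25, 30, 7.93), (30, 35, 7.61), (35, 40, 7.15),
    (40, 45, 6.59), (45, 50, 6.04), (50, 55, 5.37), (55, 60, 4.55),
    (60, 65, 3.72), (65, 70, 2.96), (70, 75, 2.21), (75, 80, 1.52),
    (80, 85, 0.91), (85, None, 0.635),
)


@dataclass(frozen=True)
class StandardPopulation:
    """Ordered age bands with nonnegative weights summing to one."""

    bands: tuple[AgeBand, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        validate_bands(self.bands)
        w = np.asarray(self.weights, dtype=float)
        if len(w) != len(self.bands):
            raise ValueError("one weight per band required")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError(f"weights must sum to 1 (got {w.sum()!r})")

    def weight_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)


def _overlap(lo: int, hi: int | None, b_lo: int, b_hi: int | None) -> float:
    """Years of overlap between [lo, hi) and [b_lo, b_hi); None = +inf."""
    hi_f = np.inf if hi is None else hi
    b_hi_f = np.inf if b_hi is None else b_hi
    ov = min(hi_f, b_hi_f) - max(lo, b_lo)
    if not np.isfinite(ov):
        # both open-ended: treat the shared tail as full overlap of the 5y row
        ov = 5.0
    return max(ov, 0.0)


def who_standard(bands: Sequence[AgeBand]) -> StandardPopulation:
    """Collapse the WHO five-year weights onto ``bands`` and renormalise.

    Five-year rows straddling a band edge are split proportionally to the
    years of overlap (uniform-within-row assumption); the open-ended model
    band absorbs all older rows.
    """
    bands = validate_bands(bands)
    raw = np.zeros(len(bands))
    for lo, hi, pct in WHO_WORLD_STANDARD_5Y:
        span = 5.0 if hi is not None else 5.0
        for j, b in enumerate(bands):
            frac = _overlap(lo, hi, b.lo, b.hi) / span
            if b.hi is None and lo >= b.lo:
                frac = 1.0  # open-ended band absorbs the whole older row
            elif b.hi is None and hi is not None and hi > b.lo:
                frac = _overlap(lo, hi, b.lo, None) / span
            raw[j] += pct * min(frac, 1.0)
    if raw.sum() <= 0:
        raise ValueError("bands do not overlap the standard population")
    raw /= raw.sum()
    return StandardPopulation(bands, tuple(float(x) for x in raw))
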