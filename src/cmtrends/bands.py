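"""Age bands used throughout the pipeline.

Bands are closed-open intervals ``[lo, hi)`` except the final open-ended
band (``hi is None``), whose midpoint is defined as ``lo + 5``.  The adult
grid starts at 18 (20 for BMI outcomes, which are reported for ages 20+).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence


@dataclass(frozen=True, order=True)
class AgeBand:
    """A closed-open age interval ``[lo, hi)``; ``hi=None`` means open-ended."""

    lo: int
    hi: int | None = None

    def __post_init__(self) -> None:
        if self.lo < 0:
            raise ValueError(f"age band lower bound must be >= 0, got {self.lo}")
        if self.hi is not None and self.hi <= self.lo:
            raise ValueError(f"age band [{self.lo}, {self.hi}) is empty or inverted")

    @property
    def midpoint(self) -> float:
        if self.hi is None:
            return float(self.lo + 5)
        return (self.lo + self.hi) / 2.0

    @property
    def label(self) -> str:
        return f"{self.lo}-{self.hi}" if self.hi is not None else f"{self.lo}+"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def validate_bands(bands: Sequence[AgeBand]) -> tuple[AgeBand, ...]:
    """Check that bands are non-empty, ordered, disjoint and contiguous enough.

    Raises ``ValueError`` naming the offending bands on overlap or disorder.
    Only the final band may be open-ended.
    """
    if not bands:
        raise ValueError("at least one age band is required")
    bands = tuple(bands)
    for a, b in zip(bands, bands[1:]):
        if a.hi is None:
            raise ValueError(f"open-ended band {a.label} must be last")
        if b.lo < a.hi:
            raise ValueError(f"age bands {a.label} and {b.label} overlap or are unordered")
    return bands


def default_bands(min_age: int = 18) -> tuple[AgeBand, ...]:
    """Decadal adult bands: 18-20 (omitted when min_age=20), 20-30, ..., 70-80, 80+."""
    bands: list[AgeBand] = []
    if min_age < 20:
        bands.append(AgeBand(min_age, 20))
    bands.extend(AgeBand(lo, lo + 10) for lo in range(20, 80, 10))
    bands.append(AgeBand(80, None))
    return validate_bands(bands)


def bands_from_edges(pairs: Iterable[tuple[int, int | None]]) -> tuple[AgeBand, ...]:
    return validate_bands([AgeBand(lo, hi) for lo, hi in pairs])
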