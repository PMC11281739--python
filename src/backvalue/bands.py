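"""Age-band labels and helpers.

Bands are strings of the form ``"15-19"`` (inclusive bounds) or ``"90+"``
(open-ended).  The helpers here parse labels, validate an ordered
non-overlapping set covering adult ages (18+), and assign integer ages to
bands vectorially.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .errors import ConfigurationError, InputError

#: Upper age used when sampling inside an open-ended band such as "90+".
OPEN_BAND_TOP = 94


def parse_band(label: str) -> tuple[int, int | None]:
    """Return (low, high) for a band label; high is None for open bands."""
    label = label.strip()
    try:
        if label.endswith("+"):
            return int(label[:-1]), None
        lo_s, hi_s = label.split("-")
        return int(lo_s), int(hi_s)
    except ValueError as exc:  # pragma: no cover - message matters, not path
        raise InputError(f"unparseable age band label: {label!r}") from exc


def validate_bands(bands: Sequence[str]) -> None:
    """Check bands are ordered, non-overlapping, contiguous and cover 18+."""
    if not bands:
        raise ConfigurationError("age_bands: empty band list")
    parsed = [parse_band(b) for b in bands]
    lo0, _ = parsed[0]
    if lo0 > 18:
        raise ConfigurationError(
            f"age_bands: first band {bands[0]!r} starts above age 18"
        )
    for (a_lo, a_hi), (b_lo, _), lab in zip(parsed, parsed[1:], bands):
        if a_hi is None:
            raise ConfigurationError(
                f"age_bands: open-ended band {lab!r} must come last"
            )
        if b_lo != a_hi + 1:
            raise ConfigurationError(
                f"age_bands: bands {lab!r} and next are not contiguous"
            )
    if parsed[-1][1] is not None:
        raise ConfigurationError(
            f"age_bands: last band {bands[-1]!r} must be open-ended (e.g. '90+')"
        )


def band_lower_edges(bands: Sequence[str]) -> np.ndarray:
    return np.array([parse_band(b)[0] for b in bands], dtype=int)


def assign_bands(ages: np.ndarray, bands: Sequence[str]) -> np.ndarray:
    """Map integer ages to band labels (object array)."""
    edges = band_lower_edges(bands)
    ages = np.asarray(ages, dtype=int)
    if ages.size and ages.min() < edges[0]:
        raise InputError(
            f"age {int(ages.min())} is below the first age band {bands[0]!r}"
        )
    idx = np.searchsorted(edges, ages, side="right") - 1
    return np.asarray(bands, dtype=object)[idx]


def sampling_bounds(label: str, adult_min: int = 18) -> tuple[int, int]:
    """Inclusive integer age range used when drawing an age inside a band."""
    lo, hi = parse_band(label)
    return max(lo, adult_min), OPEN_BAND_TOP if hi is None else hi


def band_midpoint(label: str) -> float:
    lo, hi = sampling_bounds(label)
    return (lo + hi) / 2.0
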