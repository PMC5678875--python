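"""Clock-time conventions shared across the pipeline.

All times are minutes since midnight.  Intervals are half-open
``[start, end)`` and a minute is labelled by its start time, so the common
analysis window 08:30-19:30 contains exactly 660 one-minute epochs
(labels 510, 511, ..., 1169) and the wear-time window 07:00-22:00 contains
900 minutes.
"""

from __future__ import annotations

import numpy as np

#: Common analysis window (08:30-19:30), minutes since midnight.
COMMON_START = 510
COMMON_END = 1170
#: Number of one-minute epochs in the common window.
N_GRID = COMMON_END - COMMON_START  # 660

#: Wear-time accounting window (07:00-22:00).
WEAR_START = 420
WEAR_END = 1320
#: Minimum worn minutes inside the wear window for a day to be kept.
MIN_WEAR_MINUTES = 600

#: The shared 660-point minute grid (start times of the minutes).
MINUTE_GRID = np.arange(COMMON_START, COMMON_END, dtype=float)

#: The four reporting windows used for time-window-averaged coefficients,
#: plus the full day.
DEFAULT_WINDOWS = {
    "08:30-09:30": (510, 570),
    "09:30-12:00": (570, 720),
    "12:00-13:30": (720, 810),
    "17:30-19:30": (1050, 1170),
}
FULL_DAY_WINDOW = (COMMON_START, COMMON_END)


def parse_clock(text: str) -> int:
    """Parse ``"HH:MM"`` or ``"HH:MM:SS"`` to whole minutes since midnight."""
    parts = text.strip().split(":")
    if len(parts) not in (2, 3):
        raise ValueError(f"cannot parse clock time {text!r}")
    h, m = int(parts[0]), int(parts[1])
    s = int(parts[2]) if len(parts) == 3 else 0
    if not (0 <= h < 24 and 0 <= m < 60 and 0 <= s < 60):
        raise ValueError(f"clock time out of range: {text!r}")
    if s:
        raise ValueError(f"expected a whole minute, got {text!r}")
    return 60 * h + m


def parse_window(text: str) -> tuple[int, int]:
    """Parse ``"HH:MM-HH:MM"`` into a (start, end) minute pair."""
    try:
        a, b = text.split("-")
    except ValueError as exc:
        raise ValueError(f"cannot parse window {text!r}") from exc
    start, end = parse_clock(a), parse_clock(b)
    if end <= start:
        raise ValueError(f"empty or reversed window {text!r}")
    return start, end


def format_clock(minutes: float) -> str:
    m = int(round(minutes))
    return f"{m // 60:02d}:{m % 60:02d}"
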