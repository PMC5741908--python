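"""Duration parsing for minimum retest intervals.

Rule configs express intervals as strings like ``"24h"``, ``"3d"`` or
``"6mo"``.  Internally every interval is a number of hours.  Calendar
months are deliberately fixed at 30 days (720 h) so that interval
boundaries are deterministic and testable; clinical retest guidance of
the "not before 3 months" kind does not hinge on calendar-month length.
"""

from __future__ import annotations

import re

HOURS_PER_DAY = 24.0
HOURS_PER_MONTH = 30.0 * HOURS_PER_DAY  # fixed 30-day month

_DURATION_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*(h|d|mo)\s*$", re.IGNORECASE)

_UNIT_HOURS = {"h": 1.0, "d": HOURS_PER_DAY, "mo": HOURS_PER_MONTH}


class DurationError(ValueError):
    """Raised for a malformed duration string."""


def parse_duration_hours(text: str | int | float) -> float:
    """Parse a duration like ``"24h"``, ``"3d"``, ``"6mo"`` into hours.

    Bare numbers are taken as hours already.
    """
    if isinstance(text, (int, float)) and not isinstance(text, bool):
        value = float(text)
        if value <= 0:
            raise DurationError(f"duration must be positive, got {value!r}")
        return value
    m = _DURATION_RE.match(str(text))
    if not m:
        raise DurationError(
            f"cannot parse duration {text!r}; expected e.g. '24h', '3d', '6mo'"
        )
    value = float(m.group(1)) * _UNIT_HOURS[m.group(2).lower()]
    if value <= 0:
        raise DurationError(f"duration must be positive, got {text!r}")
    return value


def format_duration(hours: float) -> str:
    """Render hours back into the most compact config spelling."""
    if hours % HOURS_PER_MONTH == 0 and hours >= HOURS_PER_MONTH:
        return f"{int(hours // HOURS_PER_MONTH)}mo"
    if hours % HOURS_PER_DAY == 0 and hours > HOURS_PER_DAY:
        return f"{int(hours // HOURS_PER_DAY)}d"
    if hours == int(hours):
        return f"{int(hours)}h"
    return f"{hours}h"
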