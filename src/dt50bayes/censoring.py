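"""Censoring classification for reported biodegradation half-lives.

Reported DT50 values may lie beyond the range in which a standard soil
incubation study can quantify a half-life reliably.  Values extrapolated
past the global thresholds (default 0.1 d and 1000 d, motivated by OECD 307
sampling intervals and incubation times) are treated as left- or
right-censored at the global threshold.  In addition, a report comment may
state a bound explicitly (e.g. ">365 days"); such a bound becomes a *local*
censoring threshold.

All thresholds and values are handled on the log10(days) scale downstream;
this module converts once, at classification time.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from enum import Enum

logger = logging.getLogger(__name__)


class Censoring(str, Enum):
    """Censoring status of a single reported half-life."""

    NONE = "none"
    LEFT = "left"
    RIGHT = "right"


@dataclass(frozen=True)
class Observation:
    """One reported half-life on the log10(days) scale.

    ``value_log10`` is absent for purely threshold-reported values (the lab
    only stated a bound).  ``threshold_log10`` is defined iff the
    observation is censored; the likelihood of a censored observation uses
    only the threshold, never the point value.
    """

    source_record_id: str
    value_log10: float | None
    censoring: Censoring = Censoring.NONE
    threshold_log10: float | None = None

    def __post_init__(self) -> None:
        if self.censoring is Censoring.NONE:
            if self.threshold_log10 is not None:
                raise ValueError("uncensored observation must not carry a threshold")
            if self.value_log10 is None:
                raise ValueError("uncensored observation requires a point value")
        elif self.threshold_log10 is None:
            raise ValueError("censored observation requires a threshold")


# Bound expressions tolerated in report comments: ">365", "> 365 days",
# ">= 100 d", "≤0.5", "< 0.5" ...  The first match in the comment wins.
_BOUND_RE = re.compile(
    r"(?P<op>>=|<=|≥|≤|>|<)\s*(?P<num>[0-9]*\.?[0-9]+(?:[eE][-+]?[0-9]+)?)"
    r"\s*(?:days|day|d\b)?",
    re.IGNORECASE,
)

_RIGHT_OPS = {">", ">=", "≥"}
_LEFT_OPS = {"<", "<=", "≤"}


@dataclass(frozen=True)
class CensoringConfig:
    """Global censoring thresholds and comment-grammar extensions.

    ``extra_patterns`` are additional regexes with named groups ``op`` and
    ``num``, tried after the default grammar; real exports have
    heterogeneous comment dialects.
    """

    global_low_days: float = 0.1
    global_high_days: float = 1000.0
    extra_patterns: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0 < self.global_low_days < self.global_high_days):
            raise ValueError("require 0 < global_low_days < global_high_days")


def parse_comment_bound(comment: str) -> tuple[Censoring, float | None]:
    """Extract a censoring bound from a free-text comment.

    Returns ``(direction, bound_days)``; ``(Censoring.NONE, None)`` when no
    bound expression is found or the numeric part is malformed.
    """
    if not comment:
        return Censoring.NONE, None
    m = _BOUND_RE.search(comment)
    if m is None:
        return Censoring.NONE, None
    try:
        bound = float(m.group("num"))
    except ValueError:  # pragma: no cover - regex admits only valid floats
        logger.warning("malformed bound in comment %r; ignored", comment)
        return Censoring.NONE, None
    if not math.isfinite(bound) or bound <= 0:
        logger.warning("nonpositive bound in comment %r; ignored", comment)
        return Censoring.NONE, None
    direction = Censoring.RIGHT if m.group("op") in _RIGHT_OPS else Censoring.LEFT
    return direction, bound


def classify(
    value_days: float | None,
    comment: str = "",
    config: CensoringConfig | None = None,
    source_record_id: str = "",
) -> Observation:
    """Classify one reported half-life as uncensored / left- / right-censored.

    Rules (value and comment are combined; both may imply censoring):

    * value <= global low  -> LEFT at the global low threshold;
    * value >= global high -> RIGHT at the global high threshold;
    * a comment bound inside the global range -> censored at that local
      bound; outside the range it is clipped to the global threshold;
    * when value and comment imply the same direction, the more informative
      bound wins (larger for RIGHT, smaller for LEFT);
    * conflicting directions fall back to the value-based rule (logged).

    Raises ``ValueError`` when neither a value nor a comment bound is
    available.
    """
    config = config or CensoringConfig()
    low, high = config.global_low_days, config.global_high_days
    direction, bound = parse_comment_bound(comment)
    if direction is Censoring.NONE and comment:
        for pat in config.extra_patterns:
            m = re.search(pat, comment, re.IGNORECASE)
            if m:
                try:
                    bound = float(m.group("num"))
                except (ValueError, IndexError):
                    continue
                direction = (
                    Censoring.RIGHT if m.group("op") in _RIGHT_OPS else Censoring.LEFT
                )
                break

    if value_days is None and direction is Censoring.NONE:
        raise ValueError(
            f"record {source_record_id!r}: neither a half-life value nor a "
            "comment bound is available"
        )
    if value_days is not None and value_days <= 0:
        raise ValueError(f"record {source_record_id!r}: nonpositive half-life")

    value_log10 = math.log10(value_days) if value_days is not None else None

    # Candidate censorings in days: (direction, threshold)
    from_value: tuple[Censoring, float] | None = None
    if value_days is not None:
        if value_days <= low:
            from_value = (Censoring.LEFT, low)
        elif value_days >= high:
            from_value = (Censoring.RIGHT, high)
    from_comment: tuple[Censoring, float] | None = None
    if direction is not Censoring.NONE:
        assert bound is not None
        from_comment = (direction, min(max(bound, low), high))

    if from_value and from_comment:
        if from_value[0] is from_comment[0]:
            direction = from_value[0]
            if direction is Censoring.RIGHT:
                threshold = max(from_value[1], from_comment[1])
            else:
                threshold = min(from_value[1], from_comment[1])
        else:
            logger.warning(
                "record %r: comment bound contradicts value-based censoring; "
                "using the global rule",
                source_record_id,
            )
            direction, threshold = from_value
    elif from_value:
        direction, threshold = from_value
    elif from_comment:
        direction, threshold = from_comment
    else:
        return Observation(
            source_record_id=source_record_id,
            value_log10=value_log10,
            censoring=Censoring.NONE,
        )

    return Observation(
        source_record_id=source_record_id,
        value_log10=value_log10,
        censoring=direction,
        threshold_log10=math.log10(threshold),
    )
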