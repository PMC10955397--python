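"""Independent reference implementations used only by the tests.

The brute-force LOT checker enumerates every partition of a patient's event
sequence into contiguous segments and keeps those consistent with the two
line-boundary rules.  It shares no code with the production derivation; the
rules are re-stated declaratively so the two can disagree.
"""

from __future__ import annotations

from itertools import combinations
from typing import List, Sequence, Tuple

Pair = Tuple[int, str]  # (day offset, drug)


def _segment_ok(segment: Sequence[Pair], window: int, gap: int) -> bool:
    start = segment[0][0]
    first_seen = {}
    for day, drug in segment:
        first_seen.setdefault(drug, day)
    if any(day - start >= window for day in first_seen.values()):
        return False
    for (a, _), (b, _) in zip(segment, segment[1:]):
        if b - a >= gap:
            return False
    return True


def _boundary_ok(prev: Sequence[Pair], nxt: Sequence[Pair], window: int, gap: int) -> bool:
    day, drug = nxt[0]
    if day - prev[-1][0] >= gap:
        return True
    prev_drugs = {d for _, d in prev}
    prev_start = prev[0][0]
    return drug not in prev_drugs and day - prev_start >= window


def brute_force_lots(
    pairs: Sequence[Pair], window: int = 28, gap: int = 120
) -> List[List[Tuple[int, int, frozenset]]]:
    """All rule-consistent partitions of sorted (day, drug) events.

    Each partition is a list of (start, end, regimen) per line.  The rules
    admit exactly one valid partition; returning them all lets the test
    assert uniqueness instead of assuming it.
    """
    pairs = sorted(pairs)
    n = len(pairs)
    if n == 0:
        return [[]]
    valid = []
    for k in range(n):  # k = number of boundaries
        for cuts in combinations(range(1, n), k):
            bounds = (0,) + cuts + (n,)
            segments = [pairs[a:b] for a, b in zip(bounds, bounds[1:])]
            if not all(_segment_ok(s, window, gap) for s in segments):
                continue
            if not all(
                _boundary_ok(a, b, window, gap) for a, b in zip(segments, segments[1:])
            ):
                continue
            valid.append(
                [
                    (s[0][0], s[-1][0], frozenset(d for _, d in s))
                    for s in segments
                ]
            )
    return valid


def hand_kaplan_meier(
    times: Sequence[float], events: Sequence[bool]
) -> List[Tuple[float, int, int, float]]:
    """Product-limit estimate computed step by step from first principles.

    Returns (time, at_risk, n_events, survival) at each distinct event or
    censoring time.
    """
    subjects = sorted(zip(times, events))
    distinct = sorted({t for t, _ in subjects})
    survival = 1.0
    out = []
    for t in distinct:
        at_risk = sum(1 for time, _ in subjects if time >= t)
        d = sum(1 for time, e in subjects if time == t and e)
        if at_risk > 0 and d > 0:
            survival *= 1.0 - d / at_risk
        out.append((t, at_risk, d, survival))
    return out
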