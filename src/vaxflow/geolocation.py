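"""Resolving free-text user locations to countries.

Matching is deliberately simple and auditable: exact match of the whole
normalized string against the gazetteer first, then the longest
comma-separated token. Strings containing any word from a curated exclusion
list (words commonly used as non-locations, e.g. "worldwide") never resolve.

Two mis-geolocation filters are applied downstream of matching: users whose
resolved country changes across periods are dropped, and users responsible
for more than half of the retweets on some country pair in a period are
flagged for review (their cross-border contributions are suspect).
"""

from __future__ import annotations

import re
import string
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping

_PUNCT_TABLE = str.maketrans({c: " " for c in string.punctuation})
_WS = re.compile(r"\s+")


def normalize_location(text: str) -> str:
    """Lowercase, strip punctuation, collapse whitespace."""
    return _WS.sub(" ", text.lower().translate(_PUNCT_TABLE)).strip()


@dataclass(frozen=True)
class Gazetteer:
    """Map from normalized location string to ISO-like country code."""

    entries: Mapping[str, str]

    @classmethod
    def from_entries(cls, entries: Mapping[str, str]) -> "Gazetteer":
        return cls({normalize_location(k): v for k, v in entries.items()})

    def lookup(self, normalized: str) -> str | None:
        return self.entries.get(normalized)

    def __len__(self) -> int:
        return len(self.entries)


def resolve_country(
    raw_location: str | None,
    gazetteer: Gazetteer,
    exclusion: Iterable[str] = (),
) -> str | None:
    """Resolve a free-text location to a country code, or None.

    Returns None when the normalized string is empty, contains an excluded
    word, or matches nothing. Pure function of its arguments; never raises on
    unresolvable input.
    """
    if not raw_location:
        return None
    exclusion_set = set(exclusion)
    full = normalize_location(raw_location)
    if not full:
        return None
    if exclusion_set and any(w in exclusion_set for w in full.split()):
        return None
    hit = gazetteer.lookup(full)
    if hit is not None:
        return hit
    tokens = [normalize_location(t) for t in raw_location.split(",")]
    for token in sorted(tokens, key=len, reverse=True):
        if token and token != full:
            hit = gazetteer.lookup(token)
            if hit is not None:
                return hit
    return None


def drop_country_changers(
    assignments: Mapping[str, Iterable[str]],
) -> set[str]:
    """Retain users with a single distinct resolved country across periods.

    `assignments` maps user id to their per-period country codes (one or
    more). Users seen in more than one distinct country are removed; users
    seen in a single period are always retained.
    """
    retained = set()
    for user, countries in assignments.items():
        distinct = {c for c in countries if c is not None}
        if len(distinct) <= 1:
            retained.add(user)
    return retained


def flag_bridge_users(
    rt_events: Iterable[tuple],
    country_map: Mapping[str, str],
    threshold: float = 0.5,
) -> set[str]:
    """Flag users dominating the retweet traffic on some country pair.

    `rt_events` yields (retweeter, retweeted_author, period[, ...]) tuples.
    For each ordered pair of distinct countries and each period, a user (at
    either endpoint) is flagged when their retweets account for strictly more
    than `threshold` of all retweets on that pair. Flags are advisory: the
    pipeline excludes flagged users from cross-border matrices but keeps them
    in national networks.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold={threshold} outside (0, 1]")
    totals: dict[tuple, int] = defaultdict(int)
    per_user: dict[tuple, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for event in rt_events:
        src, dst, period = event[0], event[1], event[2]
        ci = country_map.get(src)
        cj = country_map.get(dst)
        if ci is None or cj is None or ci == cj:
            continue
        key = (ci, cj, period)
        totals[key] += 1
        per_user[key][src] += 1
        per_user[key][dst] += 1
    flagged: set[str] = set()
    for key, total in totals.items():
        for user, cnt in per_user[key].items():
            if cnt > threshold * total:
                flagged.add(user)
    return flagged
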