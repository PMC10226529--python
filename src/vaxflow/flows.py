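"""Country-by-country information-flow matrices.

All matrices follow the orientation "i_retweets_j": cell (i, j) is computed
from retweets by users in country i of users in country j, so information
flows from j to i. Statistics: raw retweet counts, the strength-normalized
retweet volume n_ij = a_ij * W / (s_i_out * s_j_in) (>1 means more
interaction than a random strength-preserving baseline), per-country net
information flow, the no-vax / other cross-border density ratio, and
low-credibility retweet fractions. Masked cells carry machine-readable
reasons and are written as empty values, never NaN.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence
from urllib.parse import urlparse

import numpy as np
import pandas as pd

from .networks import RTEvent
from .synthetic import TweetRecord, YOUTUBE_DOMAINS

logger = logging.getLogger(__name__)


@dataclass
class FlowMatrix:
    """Country x country statistic with an explicit orientation convention."""

    countries: list[str]
    values: np.ndarray
    mask: dict = field(default_factory=dict)  # (i_code, j_code) -> reason
    orientation: str = "i_retweets_j"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def index(self, country: str) -> int:
        return self.countries.index(country)

    def cell(self, i: str, j: str) -> float | None:
        if (i, j) in self.mask:
            return None
        return float(self.values[self.index(i), self.index(j)])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.countries, columns=self.countries)
        for (i, j) in self.mask:
            df.loc[i, j] = np.nan
        return df

    def to_csv(self, path) -> None:
        # masked cells written empty; no NaN leaks into output
        self.to_dataframe().to_csv(path, na_rep="")


@dataclass
class GroupSets:
    """Per-country user sets: V_A (users in no-vax communities) and V_O (the
    rest). Countries lacking a no-vax community have an empty V_A and are
    flagged."""

    novax: Mapping[str, set]
    other: Mapping[str, set]

    def __post_init__(self) -> None:
        for c in set(self.novax) & set(self.other):
            overlap = set(self.novax[c]) & set(self.other[c])
            if overlap:
                raise ValueError(f"user(s) in both groups for {c}: {sorted(overlap)[:3]}")

    def countries_without_novax(self) -> set[str]:
        return {c for c, users in self.novax.items() if not users}


# ---------------------------------------------------------------------------
# Domains


def extract_domain(url: str) -> str | None:
    """Lowercased hostname with any leading "www." removed; None when the URL
    has no parseable hostname."""
    try:
        host = urlparse(url.strip()).hostname
    except ValueError:
        logger.warning("unparseable URL: %r", url)
        return None
    if not host:
        logger.warning("URL without hostname: %r", url)
        return None
    host = host.lower()
    if host.startswith("www."):
        host = host[4:]
    return host or None


def domain_matches(domain: str, listed: set[str]) -> bool:
    """Suffix-at-label-boundary matching: "news.example.com" matches a list
    entry "example.com" but "notexample.com" does not."""
    parts = domain.split(".")
    return any(".".join(parts[i:]) in listed for i in range(len(parts)))


def is_lowcred_url(url: str, lowcred: set[str]) -> bool:
    dom = extract_domain(url)
    return dom is not None and domain_matches(dom, lowcred)


def is_youtube_url(url: str) -> bool:
    dom = extract_domain(url)
    return dom is not None and domain_matches(dom, set(YOUTUBE_DOMAINS))


def load_domain_list(path) -> set[str]:
    """Plain-text domain list, one lowercase domain per line; blank lines and
    '#' comments ignored."""
    out = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip().lower()
            if line and not line.startswith("#"):
                out.add(line)
    return out


# ---------------------------------------------------------------------------
# Matrices


def _geolocated(
    rt_events: Iterable[RTEvent],
    country_map: Mapping[str, str],
    period: str | None,
    exclude_users: set | None = None,
):
    exclude_users = exclude_users or set()
    for e in rt_events:
        if period is not None and e.period != period:
            continue
        if e.src in exclude_users or e.dst in exclude_users:
            continue
        ci, cj = country_map.get(e.src), country_map.get(e.dst)
        if ci is None or cj is None:
            continue
        yield e, ci, cj


def rt_count_matrix(
    rt_events: Iterable[RTEvent],
    country_map: Mapping[str, str],
    period: str | None = None,
    countries: Sequence[str] | None = None,
    exclude_users: set | None = None,
) -> FlowMatrix:
    """Raw counts a_ij = retweets by users in i of users in j (diagonal =
    within-country retweets, kept at this stage)."""
    events = list(_geolocated(rt_events, country_map, period, exclude_users))
    if countries is None:
        countries = sorted({c for _, ci, cj in events for c in (ci, cj)})
    countries = list(countries)
    idx = {c: k for k, c in enumerate(countries)}
    a = np.zeros((len(countries), len(countries)))
    for _, ci, cj in events:
        if ci in idx and cj in idx:
            a[idx[ci], idx[cj]] += 1
    return FlowMatrix(countries, a)


def normalized_rt_volume(counts: FlowMatrix) -> FlowMatrix:
    """n_ij = a_ij * W / (s_i_out * s_j_in) off-diagonal; n_ii = 0.

    Marginals (and W) include within-country retweets; cells with a zero
    marginal are masked rather than raising.
    """
    a = counts.values
    s_out = a.sum(axis=1)
    s_in = a.sum(axis=0)
    w_total = a.sum()
    n = np.zeros_like(a)
    mask: dict = {}
    for i, ci in enumerate(counts.countries):
        for j, cj in enumerate(counts.countries):
            if i == j:
                continue  # diagonal fixed at 0 by convention
            if s_out[i] == 0 or s_in[j] == 0:
                mask[(ci, cj)] = "zero_marginal"
                continue
            n[i, j] = a[i, j] * w_total / (s_out[i] * s_in[j])
    return FlowMatrix(counts.countries, n, mask, counts.orientation)


def net_information_flow(counts: FlowMatrix) -> dict[str, float]:
    """Per-country net flow: cross-border retweets of the country's content
    by others minus cross-border retweets by the country's users. Positive
    means net exporter; the values sum to zero."""
    a = counts.values
    off = a - np.diag(np.diag(a))
    exported = off.sum(axis=0)  # others retweeting country j
    imported = off.sum(axis=1)  # country i retweeting others
    return {
        c: float(exported[k] - imported[k]) for k, c in enumerate(counts.countries)
    }


def novax_density_ratio(
    rt_events: Iterable[RTEvent],
    groups: GroupSets,
    country_map: Mapping[str, str],
    period: str | None = None,
    countries: Sequence[str] | None = None,
    exclude_users: set | None = None,
) -> FlowMatrix:
    """Cross-border cohesion of no-vax communities.

    cell (i, j) = rho_A / rho_O where rho_K = W_ij_K / (|V_i_K| * |V_j_K|) is
    the per-pair retweet density between the stance-K user sets of the two
    countries. Cells are masked when a country lacks a no-vax community or
    when rho_O = 0; the diagonal is masked.
    """
    if countries is None:
        countries = sorted(set(groups.novax) | set(groups.other))
    countries = list(countries)
    idx = {c: k for k, c in enumerate(countries)}
    w_a = np.zeros((len(countries), len(countries)))
    w_o = np.zeros_like(w_a)
    nov = {c: set(groups.novax.get(c, set())) for c in countries}
    oth = {c: set(groups.other.get(c, set())) for c in countries}
    for e, ci, cj in _geolocated(rt_events, country_map, period, exclude_users):
        if ci == cj or ci not in idx or cj not in idx:
            continue
        if e.src in nov[ci] and e.dst in nov[cj]:
            w_a[idx[ci], idx[cj]] += 1
        elif e.src in oth[ci] and e.dst in oth[cj]:
            w_o[idx[ci], idx[cj]] += 1
    vals = np.zeros_like(w_a)
    mask: dict = {}
    for i, ci in enumerate(countries):
        for j, cj in enumerate(countries):
            if i == j:
                mask[(ci, cj)] = "diagonal"
                continue
            if not nov[ci] or not nov[cj]:
                mask[(ci, cj)] = "no_novax_community"
                continue
            if not oth[ci] or not oth[cj]:
                mask[(ci, cj)] = "no_other_users"
                continue
            rho_o = w_o[i, j] / (len(oth[ci]) * len(oth[cj]))
            if rho_o == 0:
                mask[(ci, cj)] = "zero_other_density"
                continue
            rho_a = w_a[i, j] / (len(nov[ci]) * len(nov[cj]))
            vals[i, j] = rho_a / rho_o
    return FlowMatrix(countries, vals, mask)


def lowcred_flow_matrix(
    rt_events: Iterable[RTEvent],
    tweets: Iterable[TweetRecord],
    lowcred: set[str],
    country_map: Mapping[str, str],
    period: str | None = None,
    countries: Sequence[str] | None = None,
    mask_cutoff: int = 10,
    exclude_users: set | None = None,
) -> FlowMatrix:
    """Fraction of cross-border retweets pointing to low-credibility URLs.

    cell (i, j) = (# retweets by users of i of tweets by users of j carrying
    at least one low-credibility URL) / (# retweets by users of i of users of
    j). Rows of countries importing <= `mask_cutoff` low-credibility URLs in
    total are masked, as is the diagonal and any zero-denominator cell.
    """
    lowcred_tweets = {
        t.tweet_id
        for t in tweets
        if t.kind == "original" and any(is_lowcred_url(u, lowcred) for u in t.urls)
    }
    events = list(_geolocated(rt_events, country_map, period, exclude_users))
    if countries is None:
        countries = sorted({c for _, ci, cj in events for c in (ci, cj)})
    countries = list(countries)
    idx = {c: k for k, c in enumerate(countries)}
    total = np.zeros((len(countries), len(countries)))
    low = np.zeros_like(total)
    for e, ci, cj in events:
        if ci == cj or ci not in idx or cj not in idx:
            continue
        total[idx[ci], idx[cj]] += 1
        if e.retweeted_tweet_id in lowcred_tweets:
            low[idx[ci], idx[cj]] += 1
    imports = low.sum(axis=1)  # low-cred RTs imported by row country
    vals = np.zeros_like(total)
    mask: dict = {}
    for i, ci in enumerate(countries):
        for j, cj in enumerate(countries):
            if i == j:
                mask[(ci, cj)] = "diagonal"
                continue
            if imports[i] <= mask_cutoff:
                mask[(ci, cj)] = "importer_lowcred_leq_cutoff"
                continue
            if total[i, j] == 0:
                mask[(ci, cj)] = "zero_denominator"
                continue
            vals[i, j] = low[i, j] / total[i, j]
    return FlowMatrix(countries, vals, mask)


def lowcred_export_share(
    rt_events: Iterable[RTEvent],
    tweets: Iterable[TweetRecord],
    lowcred: set[str],
    country_map: Mapping[str, str],
    period: str | None = None,
    exclude_users: set | None = None,
) -> dict[str, float]:
    """Each source country's share of all cross-border low-credibility
    retweets (shares sum to 1). Raises when there are none."""
    lowcred_tweets = {
        t.tweet_id
        for t in tweets
        if t.kind == "original" and any(is_lowcred_url(u, lowcred) for u in t.urls)
    }
    counts: Counter = Counter()
    for e, ci, cj in _geolocated(rt_events, country_map, period, exclude_users):
        if ci == cj:
            continue
        if e.retweeted_tweet_id in lowcred_tweets:
            counts[cj] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no cross-border low-credibility retweets")
    return {c: counts[c] / total for c in sorted(counts)}
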