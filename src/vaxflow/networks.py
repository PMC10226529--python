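"""Per-country retweet (RT) and URL-cosharing (CO) network construction.

The RT network is a weighted digraph: edge i->j counts the retweets by user
i of user j (endorsement of j by i). The CO network is a weighted undirected
graph: edge (u, v) counts the distinct normalized URLs posted by both users.
Tweets for a country are restricted to its dominant language, limiting
geolocation mismatch. Networks over 200k nodes have weight-1 edges pruned,
and analysis focuses on the giant connected component.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping, NamedTuple, Sequence

import networkx as nx

from .synthetic import TweetRecord


class RTEvent(NamedTuple):
    """One retweet event (retweeter endorses retweeted author)."""

    src: str  # the retweeter
    dst: str  # the retweeted author
    period: str
    tweet_id: str
    retweeted_tweet_id: str


def extract_rt_events(tweets: Iterable[TweetRecord]) -> list[RTEvent]:
    return [
        RTEvent(t.author_id, t.retweeted_author, t.period, t.tweet_id,
                t.retweeted_tweet_id)
        for t in tweets
        if t.kind == "retweet"
    ]


def normalize_url(url: str) -> str:
    """URL identity for cosharing: trimmed, lowercased full URL."""
    return url.strip().lower()


def _qualifying(
    tweets: Iterable[TweetRecord],
    resolved_countries: Mapping[str, str],
    country: str,
    period: str,
    language: str,
) -> list[TweetRecord]:
    return [
        t
        for t in tweets
        if t.period == period
        and t.language == language
        and resolved_countries.get(t.author_id) == country
    ]


def build_rt_network(
    tweets: Iterable[TweetRecord],
    resolved_countries: Mapping[str, str],
    country: str,
    period: str,
    language: str,
) -> nx.DiGraph:
    """Weighted retweet digraph for one country and period.

    Nodes are the country's users active (authoring any qualifying tweet) in
    the period and dominant language; edge i->j weight counts retweets by i
    of j where both endpoints belong to the country. Self-retweets are
    dropped. No qualifying tweets gives an empty graph.
    """
    qualifying = _qualifying(tweets, resolved_countries, country, period, language)
    g = nx.DiGraph()
    g.add_nodes_from(t.author_id for t in qualifying)
    for t in qualifying:
        if t.kind != "retweet":
            continue
        j = t.retweeted_author
        if resolved_countries.get(j) != country or j == t.author_id:
            continue
        i = t.author_id
        if g.has_edge(i, j):
            g[i][j]["weight"] += 1
        else:
            g.add_edge(i, j, weight=1)
    return g


def build_co_network(
    tweets: Iterable[TweetRecord],
    resolved_countries: Mapping[str, str],
    country: str,
    period: str,
    language: str,
) -> nx.Graph:
    """Weighted URL-cosharing graph for one country and period.

    Edge (u, v) weight is the number of unique normalized URLs posted by both
    u and v in original tweets. Users who coshare nothing remain as isolated
    nodes.
    """
    qualifying = _qualifying(tweets, resolved_countries, country, period, language)
    g = nx.Graph()
    g.add_nodes_from(t.author_id for t in qualifying)
    urls_of: dict[str, set[str]] = defaultdict(set)
    for t in qualifying:
        if t.kind != "original":
            continue
        for url in t.urls:
            urls_of[t.author_id].add(normalize_url(url))
    by_url: dict[str, set[str]] = defaultdict(set)
    for user, urls in urls_of.items():
        for url in urls:
            by_url[url].add(user)
    pairs: set[tuple[str, str]] = set()
    for sharers in by_url.values():
        ordered = sorted(sharers)
        for a in range(len(ordered)):
            for b in range(a + 1, len(ordered)):
                pairs.add((ordered[a], ordered[b]))
    for u, v in pairs:
        w = len(urls_of[u] & urls_of[v])
        if w > 0:
            g.add_edge(u, v, weight=w)
    return g


def prune_weight1(graph: nx.Graph | nx.DiGraph, node_threshold: int = 200_000):
    """Remove weight-1 edges from networks larger than `node_threshold` nodes
    (computational-cost filter); smaller networks pass through unchanged.
    Isolated nodes left behind by pruning are retained."""
    if graph.number_of_nodes() <= node_threshold:
        return graph
    pruned = graph.copy()
    drop = [(u, v) for u, v, w in pruned.edges(data="weight") if w <= 1]
    pruned.remove_edges_from(drop)
    return pruned


def giant_component(graph: nx.Graph | nx.DiGraph):
    """Subgraph induced by the largest (weakly) connected component.

    Ties are broken by the lexicographically smallest sorted node-id list.
    An empty graph is returned unchanged.
    """
    if graph.number_of_nodes() == 0:
        return graph.copy()
    if graph.is_directed():
        comps = list(nx.weakly_connected_components(graph))
    else:
        comps = list(nx.connected_components(graph))
    size = max(len(c) for c in comps)
    best = min(
        (c for c in comps if len(c) == size),
        key=lambda c: sorted(str(x) for x in c),
    )
    return graph.subgraph(best).copy()


def overlap_coefficient(a: set, b: set) -> float:
    """Overlap coefficient |A n B| / min(|A|, |B|)."""
    if not a or not b:
        raise ValueError("overlap coefficient undefined for empty sets")
    return len(set(a) & set(b)) / min(len(set(a)), len(set(b)))
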