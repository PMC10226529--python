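"""Echo-chamber and user-group metrics.

The Random Walk Controversy (RWC) score of a two-sided network is
P_XX * P_YY - P_XY * P_YX, where P_ST is the probability that a random walk
started on side S is absorbed at an endpoint of side T. Endpoints are the k
highest in-strength nodes of each side; walks start at a uniformly random
non-endpoint node of the starting side, follow out-edges proportionally to
weight, and restart (at a new random start of the same side) from dangling
nodes. A score of 1 marks two fully segregated groups; 0 a fully mixed
debate. The exact method solves the absorbing Markov chain; the Monte Carlo
method simulates walks.

NMI between the retweet and cosharing partitions quantifies information
siloing; suspension and behavior statistics contrast no-vax-community users
with everyone else.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from typing import Hashable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.metrics import normalized_mutual_info_score

from .communities import Partition
from .flows import is_lowcred_url, is_youtube_url
from .synthetic import TweetRecord, UserRecord

SIDES = ("X", "Y")


def _in_strength(graph: nx.Graph | nx.DiGraph) -> dict:
    if graph.is_directed():
        return {n: s for n, s in graph.in_degree(weight="weight")}
    return {n: s for n, s in graph.degree(weight="weight")}


def top_endpoints(
    graph: nx.Graph | nx.DiGraph,
    sides: Mapping[Hashable, str],
    k_endpoints: int | None = None,
) -> dict[str, list]:
    """The k highest in-strength nodes per side (absorbing endpoints).

    Default k is max(1, ceil(1% of the side's size)); ties break by node id.
    """
    strength = _in_strength(graph)
    out: dict[str, list] = {}
    for side in SIDES:
        members = sorted((n for n in graph.nodes if sides[n] == side), key=str)
        if not members:
            raise ValueError(f"side {side} is empty")
        k = k_endpoints if k_endpoints is not None else max(1, math.ceil(0.01 * len(members)))
        k = min(k, len(members))
        members.sort(key=lambda n: (-strength.get(n, 0), str(n)))
        out[side] = members[:k]
    return out


def _absorption_exact(
    graph: nx.DiGraph | nx.Graph,
    sides: Mapping[Hashable, str],
    endpoints: dict[str, list],
    start_side: str,
) -> dict[str, float]:
    """Absorption probabilities {X: P_SX, Y: P_SY} by dense linear solve.

    Dangling transient nodes restart the walk at a new uniformly random
    non-endpoint start node of `start_side`, which couples the system through
    a rank-one term: (I - P - d b^T) h = r_T.
    """
    endpoint_set = set(endpoints["X"]) | set(endpoints["Y"])
    nodes = sorted(graph.nodes, key=str)
    transient = [n for n in nodes if n not in endpoint_set]
    starts = [n for n in transient if sides[n] == start_side]
    if not starts:
        # every node of the side is an endpoint: absorbed at its start
        return {"X": 1.0 if start_side == "X" else 0.0,
                "Y": 1.0 if start_side == "Y" else 0.0}
    t_index = {n: i for i, n in enumerate(transient)}
    m = len(transient)
    p = np.zeros((m, m))
    r = {"X": np.zeros(m), "Y": np.zeros(m)}
    dangling = np.zeros(m)
    out_edges = (
        (lambda n: graph.out_edges(n, data="weight", default=1))
        if graph.is_directed()
        else (lambda n: graph.edges(n, data="weight", default=1))
    )
    for n in transient:
        i = t_index[n]
        edges = [(v, w) for _, v, w in out_edges(n) if v != n]
        total = sum(w for _, w in edges)
        if total <= 0:
            dangling[i] = 1.0
            continue
        for v, w in edges:
            q = w / total
            if v in endpoint_set:
                r[sides[v]][i] += q
            else:
                p[i, t_index[v]] += q
    b = np.zeros(m)
    for n in starts:
        b[t_index[n]] = 1.0 / len(starts)

    # Some transient states (e.g. isolated retweet 2-cycles) can never reach
    # an endpoint; their absorption probability is exactly 0 and including
    # them makes the linear system singular. Restrict the solve to states
    # from which an endpoint is reachable (through dangling restarts too).
    trans = p + np.outer(dangling, b)
    direct = (r["X"] + r["Y"]) > 0
    reach = direct.copy()
    frontier = np.flatnonzero(direct)
    while frontier.size:
        preds = np.flatnonzero((trans[:, frontier] > 0).any(axis=1) & ~reach)
        reach[preds] = True
        frontier = preds
    idx = np.flatnonzero(reach)
    probs = {}
    if idx.size == 0:
        probs = {"X": 0.0, "Y": 0.0}
    else:
        system = np.eye(idx.size) - trans[np.ix_(idx, idx)]
        for side in SIDES:
            h = np.zeros(m)
            h[idx] = np.linalg.solve(system, r[side][idx])
            probs[side] = float(b @ h)
    tot = probs["X"] + probs["Y"]
    if tot < 1 - 1e-9:
        warnings.warn(
            f"walks from side {start_side} reach endpoints with probability "
            f"{tot:.4f} < 1; renormalizing over reachable endpoints"
        )
        if tot > 0:
            probs = {s: v / tot for s, v in probs.items()}
    return probs


def _absorption_montecarlo(
    graph: nx.DiGraph | nx.Graph,
    sides: Mapping[Hashable, str],
    endpoints: dict[str, list],
    start_side: str,
    n_walks: int,
    rng: np.random.Generator,
    max_steps: int | None = None,
) -> dict[str, float]:
    endpoint_side = {n: s for s in SIDES for n in endpoints[s]}
    nodes = sorted(graph.nodes, key=str)
    starts = [n for n in nodes if sides[n] == start_side and n not in endpoint_side]
    if not starts:
        return {"X": 1.0 if start_side == "X" else 0.0,
                "Y": 1.0 if start_side == "Y" else 0.0}
    # precompute transition tables
    nbrs: dict = {}
    cum: dict = {}
    out_edges = (
        (lambda n: graph.out_edges(n, data="weight", default=1))
        if graph.is_directed()
        else (lambda n: graph.edges(n, data="weight", default=1))
    )
    for n in nodes:
        edges = [(v, w) for _, v, w in out_edges(n) if v != n]
        if edges:
            vs, ws = zip(*edges)
            nbrs[n] = list(vs)
            cum[n] = np.cumsum(ws) / np.sum(ws)
    if max_steps is None:
        max_steps = 100 * graph.number_of_nodes()
    counts = {"X": 0, "Y": 0}
    absorbed = 0
    for _ in range(n_walks):
        node = starts[int(rng.integers(len(starts)))]
        for _ in range(max_steps):
            if node in endpoint_side:
                counts[endpoint_side[node]] += 1
                absorbed += 1
                break
            if node not in nbrs:  # dangling: restart on the original side
                node = starts[int(rng.integers(len(starts)))]
                continue
            u = rng.random()
            node = nbrs[node][int(np.searchsorted(cum[node], u))]
    if absorbed == 0:
        raise RuntimeError("no walk was absorbed; check endpoint reachability")
    return {s: counts[s] / absorbed for s in SIDES}


def rwc_probabilities(
    graph: nx.DiGraph | nx.Graph,
    sides: Mapping[Hashable, str],
    k_endpoints: int | None = None,
    method: str = "exact",
    n_walks: int = 10_000,
    seed: int = 0,
) -> dict[tuple[str, str], float]:
    """The four absorption probabilities P_ST as {(S, T): prob}."""
    missing = set(graph.nodes) - set(sides)
    if missing:
        raise ValueError(f"side map does not cover nodes: {sorted(missing, key=str)[:5]}")
    for side in SIDES:
        if not any(sides[n] == side for n in graph.nodes):
            raise ValueError(f"side {side} is empty")
    endpoints = top_endpoints(graph, sides, k_endpoints)
    rng = np.random.default_rng([seed, 13])
    out: dict[tuple[str, str], float] = {}
    for start in SIDES:
        if method == "exact":
            probs = _absorption_exact(graph, sides, endpoints, start)
        elif method == "montecarlo":
            probs = _absorption_montecarlo(
                graph, sides, endpoints, start, n_walks, rng
            )
        else:
            raise ValueError(f"unknown method {method!r}")
        for target in SIDES:
            out[(start, target)] = probs[target]
    return out


def rwc(
    graph: nx.DiGraph | nx.Graph,
    sides: Mapping[Hashable, str],
    k_endpoints: int | None = None,
    method: str = "exact",
    n_walks: int = 10_000,
    seed: int = 0,
) -> float:
    """Random Walk Controversy score P_XX * P_YY - P_XY * P_YX."""
    p = rwc_probabilities(graph, sides, k_endpoints, method, n_walks, seed)
    return p[("X", "X")] * p[("Y", "Y")] - p[("X", "Y")] * p[("Y", "X")]


def nmi(partition_a: Partition, partition_b: Partition) -> float:
    """Normalized mutual information between two partitions, on the
    intersection of their user sets, normalized by the arithmetic mean of the
    entropies. 1 iff identical up to relabeling; 0 for independent structure."""
    common = sorted(
        set(partition_a.membership) & set(partition_b.membership), key=str
    )
    if not common:
        raise ValueError("partitions share no users")
    la = [partition_a.membership[u] for u in common]
    lb = [partition_b.membership[u] for u in common]
    return float(normalized_mutual_info_score(la, lb, average_method="arithmetic"))


def suspended_share(
    users: Iterable[UserRecord], group_map: Mapping[str, str]
) -> dict[str, float]:
    """Fraction of suspended accounts per group (novax / other)."""
    counts: Counter = Counter()
    susp: Counter = Counter()
    for u in users:
        g = group_map.get(u.user_id)
        if g is None:
            continue
        counts[g] += 1
        if u.suspended:
            susp[g] += 1
    return {g: susp[g] / counts[g] for g in counts}


def suspension_timeline(
    users: Iterable[UserRecord],
    country_map: Mapping[str, str] | None = None,
) -> pd.Series:
    """Counts of suspended accounts by (last_tweet_date, country); the total
    equals the number of suspended users with a known country."""
    rows = []
    for u in users:
        if not u.suspended:
            continue
        country = (
            country_map.get(u.user_id) if country_map is not None else u.country_truth
        )
        if country is None:
            continue
        rows.append((u.last_tweet_date, country))
    if not rows:
        return pd.Series(dtype=int, name="suspended")
    df = pd.DataFrame(rows, columns=["last_tweet_date", "country"])
    return (
        df.groupby(["last_tweet_date", "country"]).size().rename("suspended")
    )


def behavior_stats(
    tweets: Iterable[TweetRecord],
    group_map: Mapping[str, str],
    lowcred: set[str],
) -> pd.DataFrame:
    """Per-group behavior averages.

    Rows are groups; columns: retweets per user, URL posts per user, YouTube
    URL posts per user (all averaged over the group's users, zero-activity
    users included) and the group's pooled low-credibility share of URL posts
    (NaN when the group posted no URLs). URL statistics count original posts
    only, so they reflect the group's own sharing behavior rather than
    retweeted content.
    """
    users_by_group: dict[str, set] = {}
    for u, g in group_map.items():
        users_by_group.setdefault(g, set()).add(u)
    rt_count: Counter = Counter()
    url_count: Counter = Counter()
    yt_count: Counter = Counter()
    low_posts: Counter = Counter()
    url_posts: Counter = Counter()
    for t in tweets:
        g = group_map.get(t.author_id)
        if g is None:
            continue
        if t.kind == "retweet":
            rt_count[g] += 1
            continue
        for url in t.urls:
            url_count[g] += 1
            url_posts[g] += 1
            if is_youtube_url(url):
                yt_count[g] += 1
            if is_lowcred_url(url, lowcred):
                low_posts[g] += 1
    rows = {}
    for g, members in sorted(users_by_group.items()):
        n = len(members)
        rows[g] = {
            "rt_per_user": rt_count[g] / n,
            "urls_per_user": url_count[g] / n,
            "youtube_per_user": yt_count[g] / n,
            "lowcred_share": (
                low_posts[g] / url_posts[g] if url_posts[g] else np.nan
            ),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
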