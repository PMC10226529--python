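import networkx as nx
import numpy as np
import pytest

import vaxflow as vf
from vaxflow.synthetic import default_periods


@pytest.fixture(scope="session")
def world_small():
    """Default-parameter world, one period: marginal-statistics checks."""
    cfg = vf.WorldConfig(
        users_per_country=250, periods=default_periods()[:1], seed=11
    )
    users, tweets, truth = vf.generate_world(cfg)
    return cfg, users, tweets, truth


@pytest.fixture(scope="session")
def world_recovery():
    """Fully geolocatable world with strong planted contrast, one period:
    community-recovery and end-to-end checks."""
    cfg = vf.WorldConfig(
        users_per_country=400,
        periods=default_periods()[:1],
        location_noise=0.0,
        seed=21,
    )
    users, tweets, truth = vf.generate_world(cfg)
    country_map = {u.user_id: u.country_truth for u in users}
    return cfg, users, tweets, truth, country_map


@pytest.fixture(scope="session")
def two_cliques():
    """Two 5-cliques joined by a single weight-1 bridge edge."""
    g = nx.Graph()
    for base in (0, 5):
        for i in range(5):
            for j in range(i + 1, 5):
                g.add_edge(base + i, base + j, weight=1)
    g.add_edge(0, 5, weight=1)
    return g


@pytest.fixture(scope="session")
def rwc_fixture():
    """8-node weighted digraph with two loosely coupled halves."""
    g = nx.DiGraph()
    edges = [
        (0, 1, 3), (1, 2, 1), (2, 0, 2), (0, 3, 1),
        (3, 4, 2), (4, 5, 3), (5, 3, 1), (5, 6, 2),
        (6, 7, 1), (7, 4, 2), (2, 5, 1), (6, 1, 1),
    ]
    for u, v, w in edges:
        g.add_edge(u, v, weight=w)
    sides = {n: "X" if n < 4 else "Y" for n in g.nodes}
    return g, sides


def detect_novax_users(tweets, graph, seed=1, flip_prob=0.1):
    """Run the clustering + two-round labeling path on one network and
    return (partition, set of users in communities classified no-vax)."""
    import vaxflow.labeling as lab

    dend = vf.paris_dendrogram(graph)
    part = vf.cut_dendrogram(dend, graph)
    net_tweets = [t for t in tweets if t.author_id in part.membership]
    eligible = lab.eligible_communities(part)
    s1 = lab.sample_round1(net_tweets, part, eligible, 20, seed=seed)
    tc1 = {t.tweet_id: cid for cid, ts in s1.items() for t in ts}
    flat1 = [t for ts in s1.values() for t in ts]
    anns = vf.simulate_annotations(flat1, flip_prob, seed=seed + 1)
    tallies = lab.tally_annotations(anns, tc1, "round1")
    round2 = [c for c, t in sorted(tallies.items()) if lab.majority_novax(t)]
    s2 = lab.sample_round2(net_tweets, part, round2)
    tc2 = {t.tweet_id: cid for cid, ts in s2.items() for t in ts}
    flat2 = [t for ts in s2.values() for t in ts]
    if flat2:
        lab.tally_annotations(
            vf.simulate_annotations(flat2, flip_prob, seed=seed + 2), tc2,
            "round2", tallies,
        )
    novax_comms = {
        c for c, t in tallies.items() if lab.classify_novax(t) == "novax"
    }
    novax_users = {
        n for n, c in part.membership.items() if c in novax_comms
    }
    return part, novax_users
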