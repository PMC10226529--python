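"""RWC, NMI, suspension and behavior statistics."""

import math
import warnings

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import vaxflow as vf
from vaxflow.communities import Partition
from vaxflow.polarization import rwc_probabilities
from vaxflow.synthetic import default_periods


def _two_components():
    g = nx.DiGraph()
    for base in (0, 10):
        for i in range(10):
            g.add_edge(base + i, base + (i + 1) % 10, weight=1)
    sides = {n: "X" if n < 10 else "Y" for n in g.nodes}
    return g, sides


def _complete_symmetric(n=20):
    g = nx.complete_graph(n, nx.DiGraph())
    for u, v in g.edges:
        g[u][v]["weight"] = 1
    sides = {i: "X" if i < n // 2 else "Y" for i in g.nodes}
    return g, sides


class TestRWC:
    def test_two_components_score_one(self):
        g, sides = _two_components()
        assert vf.rwc(g, sides, k_endpoints=2) == pytest.approx(1.0, abs=1e-10)

    def test_complete_symmetric_score_zero(self):
        g, sides = _complete_symmetric()
        assert vf.rwc(g, sides, k_endpoints=2) == pytest.approx(0.0, abs=1e-10)

    def test_exact_probabilities_row_stochastic(self, rwc_fixture):
        g, sides = rwc_fixture
        p = rwc_probabilities(g, sides, k_endpoints=1)
        assert p[("X", "X")] + p[("X", "Y")] == pytest.approx(1.0, abs=1e-10)
        assert p[("Y", "X")] + p[("Y", "Y")] == pytest.approx(1.0, abs=1e-10)

    def test_montecarlo_matches_exact(self, rwc_fixture):
        g, sides = rwc_fixture
        exact = vf.rwc(g, sides, k_endpoints=1, method="exact")
        n_walks = 20_000
        mc = vf.rwc(g, sides, k_endpoints=1, method="montecarlo",
                    n_walks=n_walks, seed=1)
        # each P_ST has binomial SE <= 0.5/sqrt(n); the score combines four
        se = 2 * 0.5 / math.sqrt(n_walks)
        assert abs(mc - exact) < 3 * se

    def test_score_in_unit_interval_of_magnitude(self, rwc_fixture):
        g, sides = rwc_fixture
        assert -1.0 <= vf.rwc(g, sides, k_endpoints=1) <= 1.0

    def test_empty_side_rejected(self):
        g, _ = _two_components()
        with pytest.raises(ValueError):
            vf.rwc(g, {n: "X" for n in g.nodes})

    def test_unreachable_endpoints_renormalized_with_warning(self):
        # Y contains an isolated 2-cycle that can never reach an endpoint
        g = nx.DiGraph()
        g.add_edge(0, 1, weight=1)
        g.add_edge(1, 0, weight=1)
        g.add_edge(2, 3, weight=5)  # main X mass absorbed at 3
        g.add_edge(4, 5, weight=1)
        g.add_edge(5, 4, weight=1)
        g.add_edge(6, 3, weight=1)
        sides = {0: "X", 1: "X", 2: "X", 3: "X", 4: "Y", 5: "Y", 6: "Y"}
        with pytest.warns(UserWarning, match="renormaliz"):
            score = vf.rwc(g, sides, k_endpoints=1)
        assert -1.0 <= score <= 1.0

    def test_decreases_with_between_community_mixing(self):
        scores = []
        for p_between in (0.02, 0.1, 0.4):
            cfg = vf.WorldConfig(
                users_per_country=300,
                periods=default_periods()[:1],
                p_between=p_between,
                location_noise=0.0,
                seed=9,
            )
            users, tweets, truth = vf.generate_world(cfg)
            cmap = {u.user_id: u.country_truth for u in users}
            g = vf.giant_component(
                vf.build_rt_network(tweets, cmap, "US", "pre_covid", "en")
            )
            sides = {
                n: "X" if truth.group_of[n] == "novax" else "Y" for n in g.nodes
            }
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                scores.append(vf.rwc(g, sides))
        assert scores[0] > scores[1] > scores[2]


class TestNMI:
    def test_identical_partitions_one(self):
        part = Partition({f"u{i}": i % 4 for i in range(100)})
        relabeled = Partition({u: (c + 2) % 4 for u, c in part.membership.items()})
        assert vf.nmi(part, relabeled) == pytest.approx(1.0)

    def test_singletons_vs_lump_zero(self):
        a = Partition({f"u{i}": i for i in range(10)})
        b = Partition({f"u{i}": 0 for i in range(10)})
        assert vf.nmi(a, b) == pytest.approx(0.0)

    def test_six_element_contingency_fixture(self):
        # contingency {{2,1},{1,2}}: evaluate I and H by hand
        a = Partition(dict(zip("abcdef", [0, 0, 0, 1, 1, 1])))
        b = Partition(dict(zip("abcdef", [0, 0, 1, 0, 1, 1])))
        n = 6.0
        p = np.array([[2, 1], [1, 2]]) / n
        px = p.sum(axis=1)
        py = p.sum(axis=0)
        mi = sum(
            p[i, j] * np.log(p[i, j] / (px[i] * py[j]))
            for i in range(2)
            for j in range(2)
        )
        h = -sum(q * np.log(q) for q in px) / 2 - sum(q * np.log(q) for q in py) / 2
        assert vf.nmi(a, b) == pytest.approx(mi / h)

    def test_symmetric_and_relabel_invariant(self):
        rng = np.random.default_rng(2)
        a = Partition({f"u{i}": int(rng.integers(3)) for i in range(60)})
        b = Partition({f"u{i}": int(rng.integers(4)) for i in range(60)})
        assert vf.nmi(a, b) == pytest.approx(vf.nmi(b, a))

    def test_intersection_used_and_empty_rejected(self):
        a = Partition({"u1": 0, "u2": 1, "x": 0})
        b = Partition({"u1": 0, "u2": 1, "y": 0})
        assert vf.nmi(a, b) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            vf.nmi(Partition({"a": 0}), Partition({"b": 0}))


class TestSuspension:
    def test_extreme_shares(self):
        users = [
            vf.UserRecord(f"u{i}", "US", "", "novax", 0, True,
                          pd.Timestamp("2021-01-05").date())
            for i in range(5)
        ]
        share = vf.suspended_share(users, {u.user_id: "novax" for u in users})
        assert share["novax"] == 1.0

    def test_shares_match_planted(self, world_small):
        cfg, users, _, truth = world_small
        shares = vf.suspended_share(users, truth.group_of)
        for group, p in (
            ("novax", cfg.p_suspend_novax),
            ("other", cfg.p_suspend_other),
        ):
            n = sum(1 for u in users if truth.group_of[u.user_id] == group)
            se = np.sqrt(p * (1 - p) / n)
            assert abs(shares[group] - p) < 3 * se

    def test_timeline_conserves_totals_and_peaks_in_spike(self, world_small):
        cfg, users, _, _ = world_small
        timeline = vf.suspension_timeline(users)
        assert timeline.sum() == sum(u.suspended for u in users)
        by_date = timeline.groupby(level="last_tweet_date").sum()
        mode = by_date.idxmax()
        lo, hi = cfg.suspension_spike
        assert lo <= mode <= hi

    def test_no_suspended_users(self):
        users = [
            vf.UserRecord("u0", "US", "", "other", 0, False,
                          pd.Timestamp("2021-01-05").date())
        ]
        assert len(vf.suspension_timeline(users)) == 0


class TestBehaviorStats:
    def test_all_lowcred_group(self):
        tweets = [
            vf.TweetRecord("t1", "u0", "p", "en", "original", "",
                           ("https://bad.net/a",), "novax")
        ]
        stats = vf.behavior_stats(tweets, {"u0": "novax"}, {"bad.net"})
        assert stats.loc["novax", "lowcred_share"] == 1.0

    def test_matches_planted_and_brute_force(self, world_small):
        cfg, users, tweets, truth = world_small
        low = set(vf.lowcred_domains(cfg))
        stats = vf.behavior_stats(tweets, truth.group_of, low)
        # low-credibility share within 3 binomial SE of the planted values
        for group, p in (
            ("novax", cfg.p_lowcred_novax),
            ("other", cfg.p_lowcred_other),
        ):
            n_urls = sum(
                len(t.urls)
                for t in tweets
                if t.kind == "original" and truth.group_of[t.author_id] == group
            )
            se = np.sqrt(p * (1 - p) / n_urls)
            assert abs(stats.loc[group, "lowcred_share"] - p) < 3 * se
        # retweets per user equals a brute-force recount
        for group in ("novax", "other"):
            members = [u.user_id for u in users if u.group_truth == group]
            rt = sum(
                1
                for t in tweets
                if t.kind == "retweet" and truth.group_of[t.author_id] == group
            )
            assert stats.loc[group, "rt_per_user"] == pytest.approx(
                rt / len(members)
            )

    def test_novax_group_shares_more_youtube(self, world_small):
        cfg, _, tweets, truth = world_small
        stats = vf.behavior_stats(tweets, truth.group_of, set())
        assert (
            stats.loc["novax", "youtube_per_user"]
            > stats.loc["other", "youtube_per_user"]
        )
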