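"""Two-round community annotation and the no-vax classification rules.

Round 1 samples 20 random tweets from every community holding more than 1%
of the network's users. Communities whose round-1 sample has a plurality of
no-vax labels get a second round: their 10 most popular tweets (by in-corpus
retweet count, excluding the 50 most popular tweets network-wide). A
community is classified no-vax under the main rule when the total number of
no-vax labels across both rounds exceeds 10; majority / strict rules are
robustness alternatives.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.metrics import cohen_kappa_score

from .communities import Partition
from .synthetic import Annotation, TweetRecord

LABELS = ("novax", "provax", "other")


@dataclass
class LabelTally:
    """Per-community annotation counts with round provenance."""

    community: int
    round1: Counter = field(default_factory=Counter)
    round2: Counter = field(default_factory=Counter)

    @property
    def novax(self) -> int:
        return self.round1["novax"] + self.round2["novax"]

    @property
    def provax(self) -> int:
        return self.round1["provax"] + self.round2["provax"]

    @property
    def other(self) -> int:
        return self.round1["other"] + self.round2["other"]

    def total(self) -> int:
        return sum(self.round1.values()) + sum(self.round2.values())


def eligible_communities(partition: Partition, min_frac: float = 0.01) -> set[int]:
    """Communities holding strictly more than `min_frac` of the network's users."""
    n = len(partition)
    return {
        cid
        for cid, size in enumerate(map(len, partition.communities()))
        if size > min_frac * n
    }


def _tweets_by_community(
    tweets: Iterable[TweetRecord], partition: Partition
) -> dict[int, list[TweetRecord]]:
    out: dict[int, list[TweetRecord]] = {}
    for t in tweets:
        cid = partition.membership.get(t.author_id)
        if cid is not None:
            out.setdefault(cid, []).append(t)
    return out


def sample_round1(
    tweets: Iterable[TweetRecord],
    partition: Partition,
    communities: Iterable[int] | None = None,
    n: int = 20,
    seed: int = 0,
) -> dict[int, list[TweetRecord]]:
    """Uniform seeded sample of up to `n` tweets per community, without
    replacement. Communities with no tweets yield an empty sample with a
    warning."""
    by_comm = _tweets_by_community(tweets, partition)
    if communities is None:
        communities = sorted(set(partition.membership.values()))
    rng = np.random.default_rng([seed, 11])
    out: dict[int, list[TweetRecord]] = {}
    for cid in sorted(communities):
        pool = sorted(by_comm.get(cid, []), key=lambda t: t.tweet_id)
        if not pool:
            warnings.warn(f"community {cid} has no tweets to sample")
            out[cid] = []
            continue
        take = min(n, len(pool))
        idx = rng.choice(len(pool), size=take, replace=False)
        out[cid] = [pool[i] for i in sorted(idx)]
    return out


def popularity(tweets: Iterable[TweetRecord]) -> Counter:
    """Retweet count per original tweet id (the only popularity signal in the
    corpus schema)."""
    pops: Counter = Counter()
    for t in tweets:
        if t.kind == "retweet" and t.retweeted_tweet_id:
            pops[t.retweeted_tweet_id] += 1
    return pops


def sample_round2(
    tweets: Sequence[TweetRecord],
    partition: Partition,
    communities: Iterable[int],
    n: int = 10,
    exclude_top: int = 50,
) -> dict[int, list[TweetRecord]]:
    """The `n` most popular original tweets per community, after excluding the
    `exclude_top` most popular tweets network-wide. Ties break by tweet id."""
    pops = popularity(tweets)
    originals = [t for t in tweets if t.kind == "original"]
    ranked = sorted(originals, key=lambda t: (-pops[t.tweet_id], t.tweet_id))
    excluded = {t.tweet_id for t in ranked[:exclude_top]}
    by_comm = _tweets_by_community(originals, partition)
    out: dict[int, list[TweetRecord]] = {}
    for cid in sorted(communities):
        pool = [t for t in by_comm.get(cid, []) if t.tweet_id not in excluded]
        pool.sort(key=lambda t: (-pops[t.tweet_id], t.tweet_id))
        out[cid] = pool[:n]
    return out


def tally_annotations(
    annotations: Iterable[Annotation],
    tweet_community: Mapping[str, int],
    round_name: str,
    tallies: dict[int, LabelTally] | None = None,
) -> dict[int, LabelTally]:
    """Aggregate annotations into per-community tallies for one round."""
    if round_name not in ("round1", "round2"):
        raise ValueError(f"unknown round {round_name!r}")
    tallies = tallies if tallies is not None else {}
    for ann in annotations:
        cid = tweet_community.get(ann.tweet_id)
        if cid is None:
            continue
        tally = tallies.setdefault(cid, LabelTally(cid))
        getattr(tally, round_name)[ann.label] += 1
    return tallies


def majority_novax(tally: LabelTally) -> bool:
    """Round-1 gate for the second annotation round: no-vax labels form a
    plurality (strictly exceed both pro-vax and other counts)."""
    r1 = tally.round1
    return r1["novax"] > r1["provax"] and r1["novax"] > r1["other"]


def classify_novax(tally: LabelTally, rule: str = "main") -> str:
    """Classify a community as 'novax' or 'other'.

    main: total no-vax labels over both rounds > 10;
    majority: no-vax labels outnumber pro-vax labels;
    strict: no-vax labels exceed both pro-vax and other labels.
    """
    if rule == "main":
        return "novax" if tally.novax > 10 else "other"
    if rule == "majority":
        return "novax" if tally.novax > tally.provax else "other"
    if rule == "strict":
        return (
            "novax"
            if (tally.novax > tally.provax and tally.novax > tally.other)
            else "other"
        )
    raise ValueError(f"unknown classification rule {rule!r}")


def cohen_kappa(labels_a: Sequence[str], labels_b: Sequence[str]) -> float:
    """Cohen's kappa, (p_o - p_e) / (1 - p_e), with chance agreement from
    marginal label frequencies. Defined as 1.0 when both annotators are
    constant and identical (p_e = 1)."""
    if len(labels_a) != len(labels_b):
        raise ValueError("label sequences differ in length")
    if len(labels_a) < 2:
        raise ValueError("kappa requires at least 2 items")
    if list(labels_a) == list(labels_b) and len(set(labels_a)) == 1:
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kappa = cohen_kappa_score(list(labels_a), list(labels_b))
    if np.isnan(kappa):
        return 1.0 if list(labels_a) == list(labels_b) else 0.0
    return float(kappa)
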