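"""Synthetic multi-country vaccine-discourse worlds.

Generates tweet/user populations with planted structure that the downstream
estimators are designed to recover: per-country retweet communities (at most
one "no-vax" community per country), elevated low-credibility URL sharing and
account-suspension rates inside no-vax communities, elevated cross-border
retweet coupling between no-vax communities, and URL cosharing correlated
with retweet-community membership.

The generator is a stand-in for a real (non-redistributable) Twitter corpus;
it emulates the marginal statistics of such a corpus, not its text, temporal
bursts, or bot behavior.
"""

from __future__ import annotations

import dataclasses
import math
from collections import defaultdict
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Iterable, Mapping, Sequence

import numpy as np

from .geolocation import Gazetteer

STANCES = ("novax", "provax", "other")
GROUPS = ("novax", "other")

#: Non-location words filtered out during geolocation (fixture stand-in for
#: the ~500-word curated exclusion list).
EXCLUSION_WORDS = (
    "worldwide",
    "everywhere",
    "global",
    "earth",
    "moon",
    "internet",
    "online",
    "nowhere",
    "cyberspace",
    "metaverse",
)

#: Domains treated as YouTube regardless of any credibility list.
YOUTUBE_DOMAINS = ("youtube.com", "youtu.be")


class ConfigurationError(ValueError):
    """Raised when a WorldConfig is internally inconsistent."""


@dataclass(frozen=True)
class Period:
    """A labeled, closed time window."""

    label: str
    start: date
    end: date

    def contains(self, d: date) -> bool:
        return self.start <= d <= self.end


def default_periods() -> tuple[Period, ...]:
    """Four 3-month analysis windows: pre-pandemic baseline, pre-vaccine,
    vaccine development, and vaccine rollout."""
    return (
        Period("pre_covid", date(2019, 10, 1), date(2019, 12, 31)),
        Period("prevaccine", date(2020, 7, 1), date(2020, 9, 30)),
        Period("vaccine_development", date(2020, 10, 1), date(2020, 12, 31)),
        Period("vaccine_rollout", date(2021, 1, 1), date(2021, 3, 31)),
    )


@dataclass(frozen=True)
class WorldConfig:
    """Parameters of the planted world.

    The group-level defaults are the marginal statistics the analysis is
    expected to recover: 26% vs 2.4% low-credibility URL shares and 13.3% vs
    1.8% suspension rates for users inside vs outside no-vax communities, and
    a 48.7% geolocation yield (``location_noise = 0.513``).
    """

    countries: tuple[str, ...] = ("US", "FR", "IT")
    users_per_country: Mapping[str, int] | int = 300
    country_language: Mapping[str, str] = field(
        default_factory=lambda: {"US": "en", "FR": "fr", "IT": "it"}
    )
    periods: tuple[Period, ...] = field(default_factory=default_periods)
    communities_per_country: int = 3
    novax_countries: tuple[str, ...] = ("US", "FR")
    novax_fraction: float = 0.25
    # Relative retweet propensities (arbitrary units; only ratios matter).
    p_within: float = 1.0
    p_between: float = 0.05
    epsilon_crossborder: float = 0.01
    r_novax_coupling: float = 5.0
    # Per-group URL / moderation marginals.
    p_lowcred_novax: float = 0.26
    p_lowcred_other: float = 0.024
    p_suspend_novax: float = 0.133
    p_suspend_other: float = 0.018
    p_youtube_novax: float = 0.30
    p_youtube_other: float = 0.10
    stance_emission: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "novax": {"novax": 0.60, "provax": 0.05, "other": 0.35},
            "other": {"novax": 0.05, "provax": 0.30, "other": 0.65},
        }
    )
    url_rate: float = 4.0
    rt_rate: float = 8.0
    # Cosharing: probability a URL is drawn from the author community's
    # shared pool (vs a globally unique URL), and the pool size.
    url_pool_prob: float = 0.7
    url_pool_size: int = 25
    # Geolocation fixture: fraction of users with unresolvable locations.
    # 0.513 calibrates the resolvable share to 48.7%.
    location_noise: float = 0.513
    # Account-suspension burst window (content-moderation wave).
    suspension_spike: tuple[date, date] = (date(2021, 1, 1), date(2021, 1, 12))
    suspension_spike_prob: float = 0.6
    seed: int = 0

    def users_in(self, country: str) -> int:
        if isinstance(self.users_per_country, Mapping):
            return int(self.users_per_country[country])
        return int(self.users_per_country)

    def validate(self) -> None:
        probs = {
            "p_between": self.p_between,
            "novax_fraction": self.novax_fraction,
            "p_lowcred_novax": self.p_lowcred_novax,
            "p_lowcred_other": self.p_lowcred_other,
            "p_suspend_novax": self.p_suspend_novax,
            "p_suspend_other": self.p_suspend_other,
            "p_youtube_novax": self.p_youtube_novax,
            "p_youtube_other": self.p_youtube_other,
            "url_pool_prob": self.url_pool_prob,
            "location_noise": self.location_noise,
            "suspension_spike_prob": self.suspension_spike_prob,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name}={p} outside [0, 1]")
        if self.p_within <= self.p_between:
            raise ConfigurationError(
                f"p_within ({self.p_within}) must exceed p_between ({self.p_between})"
            )
        if self.p_within < 0 or self.epsilon_crossborder < 0:
            raise ConfigurationError("propensities must be non-negative")
        if self.r_novax_coupling < 0:
            raise ConfigurationError("r_novax_coupling must be >= 0")
        if self.communities_per_country < 2:
            raise ConfigurationError("communities_per_country must be >= 2")
        if not set(self.novax_countries) <= set(self.countries):
            raise ConfigurationError("novax_countries must be a subset of countries")
        for c in self.countries:
            if c not in self.country_language:
                raise ConfigurationError(f"no language configured for {c}")
            if self.users_in(c) <= 0:
                raise ConfigurationError(f"users_per_country for {c} must be positive")
        for c in self.novax_countries:
            if self.novax_fraction * self.users_in(c) < 1:
                raise ConfigurationError(
                    f"novax_fraction * users_per_country < 1 for no-vax country {c}"
                )
        if not self.periods:
            raise ConfigurationError("at least one period is required")
        spans = sorted((p.start, p.end, p.label) for p in self.periods)
        for (s1, e1, l1), (s2, e2, l2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ConfigurationError(f"periods {l1} and {l2} overlap")
        for s, e, l in spans:
            if e < s:
                raise ConfigurationError(f"period {l} ends before it starts")


@dataclass
class UserRecord:
    user_id: str
    country_truth: str
    raw_location: str
    group_truth: str  # novax | other
    community_truth: int
    suspended: bool
    last_tweet_date: date

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["last_tweet_date"] = self.last_tweet_date.isoformat()
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "UserRecord":
        d = dict(d)
        d["last_tweet_date"] = date.fromisoformat(d["last_tweet_date"])
        d["suspended"] = bool(d["suspended"])
        d["community_truth"] = int(d["community_truth"])
        return cls(**d)


@dataclass
class TweetRecord:
    tweet_id: str
    author_id: str
    period: str
    language: str
    kind: str  # original | retweet
    retweeted_author: str  # empty for originals
    urls: tuple[str, ...]
    stance_truth: str  # novax | provax | other
    retweeted_tweet_id: str = ""  # empty for originals

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["urls"] = list(self.urls)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "TweetRecord":
        d = dict(d)
        d["urls"] = tuple(d["urls"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted structure echoed back for recovery tests."""

    community_of: dict  # user_id -> (country, community index)
    group_of: dict  # user_id -> novax | other
    memberships: dict  # country -> {community index -> list of user ids}
    parameters: dict  # the WorldConfig as a plain dict
    expected: dict  # per-group expected marginal statistics

    def to_dict(self) -> dict:
        return {
            "community_of": {u: list(v) for u, v in self.community_of.items()},
            "group_of": dict(self.group_of),
            "memberships": {
                c: {str(k): v for k, v in comms.items()}
                for c, comms in self.memberships.items()
            },
            "parameters": self.parameters,
            "expected": self.expected,
        }


@dataclass(frozen=True)
class Annotation:
    tweet_id: str
    annotator: str
    label: str


@dataclass
class GazetteerFixture:
    gazetteer: Gazetteer
    exclusion_words: tuple[str, ...]
    resolvable_fraction: float


# ---------------------------------------------------------------------------
# URL universe


def lowcred_domains(config: WorldConfig) -> list[str]:
    """Fixture list of low-credibility domains, per language (stand-in for a
    curated multi-language list)."""
    langs = sorted(set(config.country_language[c] for c in config.countries))
    return [f"{lang}-lowcred-{i}.net" for lang in langs for i in range(8)]


def _other_domains(lang: str) -> list[str]:
    return [f"{lang}-news-{i}.com" for i in range(12)]


def _lowcred_domains_lang(lang: str) -> list[str]:
    return [f"{lang}-lowcred-{i}.net" for i in range(8)]


def _draw_url(rng: np.random.Generator, lang: str, group: str, cfg: WorldConfig,
              tag: str) -> tuple[str, bool]:
    """Draw one URL for a user of `group` in language `lang`.

    Returns (url, is_lowcred). The low-credibility indicator is an
    independent Bernoulli draw per URL instance so group-level shares are
    exactly binomial.
    """
    p_low = cfg.p_lowcred_novax if group == "novax" else cfg.p_lowcred_other
    p_yt = cfg.p_youtube_novax if group == "novax" else cfg.p_youtube_other
    if rng.random() < p_low:
        dom = _lowcred_domains_lang(lang)[rng.integers(8)]
        return f"https://{dom}/{tag}", True
    if rng.random() < p_yt:
        dom = YOUTUBE_DOMAINS[int(rng.integers(2))]
        return f"https://{dom}/watch{tag}", False
    dom = _other_domains(lang)[rng.integers(12)]
    return f"https://{dom}/{tag}", False


# ---------------------------------------------------------------------------
# Population layout


def _community_layout(config: WorldConfig) -> dict[str, list[int]]:
    """Community index for each user slot of each country.

    In no-vax countries, community 0 is the planted no-vax community holding
    round(novax_fraction * n) users; the remainder (all users, in other
    countries) is split as evenly as possible over the other communities.
    """
    layout: dict[str, list[int]] = {}
    k = config.communities_per_country
    for country in config.countries:
        n = config.users_in(country)
        comms: list[int] = []
        if country in config.novax_countries:
            n_novax = max(1, round(config.novax_fraction * n))
            comms.extend([0] * n_novax)
            rest, others = n - n_novax, list(range(1, k))
        else:
            rest, others = n, list(range(k))
        for i in range(rest):
            comms.append(others[i % len(others)])
        layout[country] = comms
    return layout


def _user_id(country: str, i: int) -> str:
    return f"{country}_u{i:05d}"


def _location_names(config: WorldConfig, country: str) -> list[str]:
    base = country.lower()
    return [base] + [f"{base} city {i}" for i in range(4)]


def _assign_locations(
    config: WorldConfig, noise_frac: float, rng: np.random.Generator
) -> tuple[list[str], int]:
    """Draw a raw_location per user slot (country-major, index-minor order).

    Returns the locations and the count of resolvable ones. Replayed by
    :func:`emit_gazetteer` to report the resolvable fraction.
    """
    raw: list[str] = []
    resolvable = 0
    for country in config.countries:
        names = _location_names(config, country)
        for _ in range(config.users_in(country)):
            if rng.random() < noise_frac:
                if rng.random() < 0.5:
                    raw.append(str(rng.choice(EXCLUSION_WORDS)))
                else:
                    raw.append(f"zz{rng.integers(10**6)}")
            else:
                name = names[int(rng.integers(len(names)))]
                if rng.random() < 0.3:
                    raw.append(f"{name}, lovely place")
                else:
                    raw.append(name)
                resolvable += 1
    return raw, resolvable


def emit_gazetteer(
    config: WorldConfig,
    noise_frac: float | None = None,
    seed: int | None = None,
) -> GazetteerFixture:
    """Fixture gazetteer + exclusion word list for the configured world.

    The gazetteer covers every location string :func:`generate_world` can
    assign; `resolvable_fraction` is computed by replaying the seeded
    location draw (the same stream generate_world uses), so it matches the
    generated world exactly when called with the config's own noise/seed.
    """
    if noise_frac is None:
        noise_frac = config.location_noise
    if not 0.0 <= noise_frac <= 1.0:
        raise ConfigurationError(f"noise_frac={noise_frac} outside [0, 1]")
    if seed is None:
        seed = config.seed
    entries = {}
    for country in config.countries:
        for name in _location_names(config, country):
            entries[name] = country
    gaz = Gazetteer.from_entries(entries)
    rng = np.random.default_rng([seed, 2])
    _, resolvable = _assign_locations(config, noise_frac, rng)
    total = sum(config.users_in(c) for c in config.countries)
    return GazetteerFixture(gaz, EXCLUSION_WORDS, resolvable / total)


# ---------------------------------------------------------------------------
# World generation


def _rand_date(rng: np.random.Generator, start: date, end: date) -> date:
    return start + timedelta(days=int(rng.integers((end - start).days + 1)))


def generate_world(
    config: WorldConfig,
) -> tuple[list[UserRecord], list[TweetRecord], GroundTruth]:
    """Generate users and tweet events with the planted structure.

    Retweet counts are drawn independently per ordered user pair as
    Poisson(c * propensity(u, v)), with the global constant c calibrated so
    the mean number of retweets per user per period equals ``rt_rate``. This
    makes every planted density contrast (within/between community,
    cross-border, no-vax coupling) hold exactly in expectation, which the
    per-user multinomial alternative does not.

    Deterministic: identical config (including seed) gives identical output.
    """
    config.validate()
    seed = config.seed
    layout = _community_layout(config)

    # --- users -----------------------------------------------------------
    rng_u = np.random.default_rng([seed, 1])
    rng_loc = np.random.default_rng([seed, 2])
    raw_locations, _ = _assign_locations(config, config.location_noise, rng_loc)

    users: list[UserRecord] = []
    community_of: dict[str, tuple[str, int]] = {}
    group_of: dict[str, str] = {}
    memberships: dict[str, dict[int, list[str]]] = {}
    span_start = min(p.start for p in config.periods)
    span_end = max(p.end for p in config.periods)
    last_period = max(config.periods, key=lambda p: p.end)
    spike_lo, spike_hi = config.suspension_spike
    loc_iter = iter(raw_locations)
    for country in config.countries:
        memberships[country] = defaultdict(list)
        for i, comm in enumerate(layout[country]):
            uid = _user_id(country, i)
            group = (
                "novax"
                if (country in config.novax_countries and comm == 0)
                else "other"
            )
            p_susp = (
                config.p_suspend_novax if group == "novax" else config.p_suspend_other
            )
            suspended = bool(rng_u.random() < p_susp)
            if suspended:
                if rng_u.random() < config.suspension_spike_prob:
                    last = _rand_date(rng_u, spike_lo, spike_hi)
                else:
                    last = _rand_date(rng_u, span_start, span_end)
            else:
                last = _rand_date(rng_u, last_period.start, last_period.end)
            users.append(
                UserRecord(
                    user_id=uid,
                    country_truth=country,
                    raw_location=next(loc_iter),
                    group_truth=group,
                    community_truth=comm,
                    suspended=suspended,
                    last_tweet_date=last,
                )
            )
            community_of[uid] = (country, comm)
            group_of[uid] = group
            memberships[country][comm].append(uid)

    # --- URL pools (cosharing structure) ---------------------------------
    rng_t = np.random.default_rng([seed, 3])
    pools: dict[tuple[str, int, bool], list[str]] = {}
    for country in config.countries:
        lang = config.country_language[country]
        for comm in sorted(memberships[country]):
            group = (
                "novax"
                if (country in config.novax_countries and comm == 0)
                else "other"
            )
            for is_low in (False, True):
                urls = []
                for j in range(config.url_pool_size):
                    tag = f"{country}c{comm}p{j}"
                    if is_low:
                        dom = _lowcred_domains_lang(lang)[rng_t.integers(8)]
                        urls.append(f"https://{dom}/{tag}")
                    else:
                        p_yt = (
                            config.p_youtube_novax
                            if group == "novax"
                            else config.p_youtube_other
                        )
                        if rng_t.random() < p_yt:
                            dom = YOUTUBE_DOMAINS[int(rng_t.integers(2))]
                            urls.append(f"https://{dom}/watch{tag}")
                        else:
                            dom = _other_domains(lang)[rng_t.integers(12)]
                            urls.append(f"https://{dom}/{tag}")
                pools[(country, comm, is_low)] = urls

    # --- original tweets --------------------------------------------------
    tweets: list[TweetRecord] = []
    originals_by_user: dict[str, dict[str, list[int]]] = defaultdict(dict)
    stance_probs = {
        g: np.array([config.stance_emission[g][s] for s in STANCES])
        for g in GROUPS
    }
    counter = 0
    unique_counter = 0
    for period in config.periods:
        for user in users:
            lang = config.country_language[user.country_truth]
            group = user.group_truth
            country, comm = community_of[user.user_id]
            idxs: list[int] = []
            n_url_tweets = int(rng_t.poisson(config.url_rate))
            for j in range(1 + n_url_tweets):
                if j == 0:
                    urls: tuple[str, ...] = ()
                else:
                    p_low = (
                        config.p_lowcred_novax
                        if group == "novax"
                        else config.p_lowcred_other
                    )
                    is_low = bool(rng_t.random() < p_low)
                    if rng_t.random() < config.url_pool_prob:
                        pool = pools[(country, comm, is_low)]
                        urls = (pool[int(rng_t.integers(len(pool)))],)
                    else:
                        unique_counter += 1
                        if is_low:
                            dom = _lowcred_domains_lang(lang)[rng_t.integers(8)]
                            urls = (f"https://{dom}/u{unique_counter}",)
                        else:
                            p_yt = (
                                config.p_youtube_novax
                                if group == "novax"
                                else config.p_youtube_other
                            )
                            if rng_t.random() < p_yt:
                                dom = YOUTUBE_DOMAINS[int(rng_t.integers(2))]
                                urls = (f"https://{dom}/watchu{unique_counter}",)
                            else:
                                dom = _other_domains(lang)[rng_t.integers(12)]
                                urls = (f"https://{dom}/u{unique_counter}",)
                stance = STANCES[int(rng_t.choice(3, p=stance_probs[group]))]
                tid = f"t{counter:08d}"
                counter += 1
                idxs.append(len(tweets))
                tweets.append(
                    TweetRecord(
                        tweet_id=tid,
                        author_id=user.user_id,
                        period=period.label,
                        language=lang,
                        kind="original",
                        retweeted_author="",
                        urls=urls,
                        stance_truth=stance,
                    )
                )
            originals_by_user[user.user_id][period.label] = idxs

    # --- retweets ---------------------------------------------------------
    rng_r = np.random.default_rng([seed, 4])
    blocks: list[tuple[str, int, list[str]]] = []
    for country in config.countries:
        for comm in sorted(memberships[country]):
            blocks.append((country, comm, memberships[country][comm]))

    def propensity(b1, b2) -> float:
        c1, k1, _ = b1
        c2, k2, _ = b2
        if c1 == c2:
            return config.p_within if k1 == k2 else config.p_between
        g1 = c1 in config.novax_countries and k1 == 0
        g2 = c2 in config.novax_countries and k2 == 0
        if g1 and g2:
            return config.epsilon_crossborder * config.r_novax_coupling
        return config.epsilon_crossborder

    n_total = len(users)
    total_propensity = 0.0
    for b1 in blocks:
        for b2 in blocks:
            m = len(b1[2]) * len(b2[2])
            if b1 is b2:
                m -= len(b1[2])
            total_propensity += propensity(b1, b2) * m
    if total_propensity <= 0:
        c_rate = 0.0
    else:
        c_rate = config.rt_rate * n_total / total_propensity

    rt_counter = 0
    for period in config.periods:
        for b1 in blocks:
            for b2 in blocks:
                m = len(b1[2]) * len(b2[2])
                same = b1 is b2
                if same:
                    m -= len(b1[2])
                if m <= 0:
                    continue
                lam = c_rate * propensity(b1, b2) * m
                if lam <= 0:
                    continue
                n_events = int(rng_r.poisson(lam))
                if n_events == 0:
                    continue
                src = rng_r.integers(len(b1[2]), size=n_events)
                dst = rng_r.integers(len(b2[2]), size=n_events)
                if same:
                    bad = src == dst
                    while bad.any():
                        dst[bad] = rng_r.integers(len(b2[2]), size=int(bad.sum()))
                        bad = src == dst
                for si, di in zip(src, dst):
                    u = b1[2][int(si)]
                    v = b2[2][int(di)]
                    origs = originals_by_user[v][period.label]
                    orig = tweets[origs[int(rng_r.integers(len(origs)))]]
                    tid = f"r{rt_counter:08d}"
                    rt_counter += 1
                    tweets.append(
                        TweetRecord(
                            tweet_id=tid,
                            author_id=u,
                            period=period.label,
                            language=orig.language,
                            kind="retweet",
                            retweeted_author=v,
                            urls=orig.urls,
                            stance_truth=orig.stance_truth,
                            retweeted_tweet_id=orig.tweet_id,
                        )
                    )

    params = dataclasses.asdict(config)
    params["periods"] = [
        {"label": p.label, "start": p.start.isoformat(), "end": p.end.isoformat()}
        for p in config.periods
    ]
    params["suspension_spike"] = [d.isoformat() for d in config.suspension_spike]
    if isinstance(config.users_per_country, Mapping):
        params["users_per_country"] = dict(config.users_per_country)
    params["country_language"] = dict(config.country_language)
    params["stance_emission"] = {
        g: dict(v) for g, v in config.stance_emission.items()
    }
    truth = GroundTruth(
        community_of=community_of,
        group_of=group_of,
        memberships={c: dict(m) for c, m in memberships.items()},
        parameters=params,
        expected={
            "lowcred_share": {
                "novax": config.p_lowcred_novax,
                "other": config.p_lowcred_other,
            },
            "suspended_share": {
                "novax": config.p_suspend_novax,
                "other": config.p_suspend_other,
            },
            "stance_emission": {
                g: dict(config.stance_emission[g]) for g in GROUPS
            },
            "density_ratio": config.r_novax_coupling,
            "resolvable_fraction": 1.0 - config.location_noise,
        },
    )
    return users, tweets, truth


# ---------------------------------------------------------------------------
# Simulated annotators


def simulate_annotations(
    tweets: Sequence[TweetRecord],
    flip_prob: float,
    seed: int,
    annotators: tuple[str, str] = ("ann1", "ann2"),
) -> list[Annotation]:
    """Two simulated annotators labeling sampled tweets.

    Each annotator reports the tweet's true stance with probability
    ``1 - flip_prob`` and otherwise a uniformly chosen different class.
    """
    if not 0.0 <= flip_prob <= 1.0:
        raise ConfigurationError(f"flip_prob={flip_prob} outside [0, 1]")
    tweets = list(tweets)
    if not tweets:
        raise ValueError("cannot annotate an empty tweet sample")
    rng = np.random.default_rng([seed, 5])
    out: list[Annotation] = []
    for tweet in tweets:
        for ann in annotators:
            if rng.random() < flip_prob:
                others = [s for s in STANCES if s != tweet.stance_truth]
                label = others[int(rng.integers(len(others)))]
            else:
                label = tweet.stance_truth
            out.append(Annotation(tweet.tweet_id, ann, label))
    return out
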