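# Methods

## The analysis in brief

The package measures how antivaccination ("no-vax") discourse is organized
within countries and coupled across them, using only network structure and
URL metadata — no text models. Users are geolocated, per-country retweet (RT)
and URL-cosharing (CO) networks are built, communities are detected and
annotated, and a set of estimators quantifies polarization, information
siloing, and cross-border flows. Everything runs on synthetic worlds with
planted structure, since real multi-country Twitter corpora cannot be
redistributed.

## Synthetic world model

`WorldConfig` states the world; `generate_world` realizes it deterministically
from a seed.

**Population.** Each country has a fixed number of users split into
`communities_per_country` retweet communities. In no-vax countries, community
0 holds `round(novax_fraction * n)` users and is the planted no-vax
community; everyone else belongs to the "other" group.

**Retweets.** The retweet count of every ordered user pair (u, v) is an
independent Poisson draw with mean c·p(u, v), where the relative propensity
p is `p_within` inside a community, `p_between` across communities of one
country, `epsilon_crossborder` across countries, and
`epsilon_crossborder * r_novax_coupling` between two no-vax communities of
different countries. The constant c is calibrated so the mean number of
retweets per user per period equals `rt_rate`. Independent per-pair draws
(rather than per-user multinomial target sampling) are used deliberately:
they make every planted density contrast exact in expectation, so the
cross-border density ratio ρ^A/ρ^O recovers `r_novax_coupling` without a
composition bias from unequal per-user normalizers. Each retweet event points
at a uniformly chosen original tweet of the target user and carries its URLs
and stance.

**Content.** Each user posts one plain original plus Poisson(`url_rate`)
URL-carrying originals per period. Each URL is independently low-credibility
with probability `p_lowcred_novax` = 0.26 or `p_lowcred_other` = 0.024 (the
group-level shares the analysis is expected to recover); non-low-credibility
URLs are YouTube links with per-group probability (0.30 / 0.10, a modest
planted contrast). With probability `url_pool_prob` = 0.7 the URL string is
drawn from the author community's shared pool (25 URLs per community and
credibility class), which makes cosharing correlate with retweet-community
membership; otherwise it is globally unique. Pools are split by credibility
class so group-level low-credibility shares stay exactly binomial.
Tweet stances are drawn from per-group categorical distributions
(`stance_emission`; defaults put 60% no-vax mass in the no-vax group and a
35–65% "other" floor everywhere, matching the observation that most
vaccine-debate content carries no clear stance).

**Moderation.** Users are suspended independently with per-group probability
13.3% / 1.8%. Suspended users' last-tweet dates fall in a configurable spike
window (default January 1–12, 2021, probability 0.6) to emulate a platform
moderation wave; others are uniform over the observation span.

**Geolocation fixture.** Each user's free-text location is, with probability
`location_noise`, junk (half excluded non-location words, half unresolvable
strings) and otherwise a gazetteer-resolvable name of their true country
(sometimes with a benign ", lovely place" suffix to exercise token matching).
The default `location_noise = 0.513` calibrates the resolvable share to the
48.7% geolocation yield typical of such corpora. `emit_gazetteer` reports the
resolvable fraction by replaying the same seeded draw the generator uses.

**What the generator does not emulate** — and hence what a green test does
not establish: tweet text, temporal bursts around news events, bot behavior,
degree heterogeneity beyond Poisson mixing, country-specific activity levels,
or multilingual users. Tests passing on this world show the estimators
recover planted marginals and structure, not that the real-world effect sizes
are correct.

## Estimators and numerical choices

**Geolocation.** Matching is exact on the normalized (lowercase,
punctuation-stripped) full string, then on the longest comma-separated token;
any excluded word anywhere in the string blocks resolution. Bridge flagging
counts both endpoints of a cross-border retweet as "responsible" for it and
flags a user when they account for strictly more than the threshold (default
0.5) of a (country pair, period) cell; flagged users are excluded from
cross-border matrices but kept in national networks.

**Networks.** Self-retweets are dropped (no endorsement signal; the metrics
do not define self-loops). URL identity for cosharing is the trimmed,
lowercased full URL. Directed GCC uses weak connectivity (RT graphs are
sparse and nearly acyclic; strong components would be degenerate). Pruning
precedes GCC extraction, and isolated nodes survive pruning.

**Paris clustering.** Implemented natively (no suitable installed library):
nearest-neighbor-chain agglomeration with cluster distance
d(a,b) = s_a·s_b / (W·w_ab). The distance is reducible, so the chain
produces a valid dendrogram; merges are re-sorted by height (stable, so
children always precede parents) into scipy-linkage layout. Directed input is
symmetrized by summing reciprocal weights. Ties in the nearest-neighbor
search break toward the smaller cluster id, making the dendrogram
deterministic for a fixed node ordering (nodes are pre-sorted).

**Windowed cut.** Candidate partitions are the cuts with k communities for k
in {2..5}, then {6..10}, {11..15}, … ("cutoff heights" are community counts).
Within a window the maximum-modularity candidate wins; ties go to fewer
communities (automatic, since candidates are enumerated in ascending k and
replaced only on strict improvement). The window advances while the largest
community holds more than 90% of nodes; on exhaustion the last window's best
is returned. Modularity is standard weighted Newman–Girvan on the symmetrized
graph (networkx).

**Labeling.** "Majority of no-vax tweets" is read as plurality over the three
classes, so other-heavy samples do not qualify for round 2. Popularity is the
in-corpus retweet count of a tweet (the only popularity signal in the
schema), with ties broken by tweet id. The main rule aggregates both rounds.
Cohen's κ comes from scikit-learn, with the degenerate
constant-and-identical case defined as 1.

**RWC.** Endpoints are the k highest in-strength nodes per side
(k = max(1, ⌈1% of side⌉) by default, configurable); walks follow out-edges
(retweeter → retweeted, i.e. toward endorsed accounts) with probability
proportional to weight; dangling nodes restart at a fresh random non-endpoint
start of the original side. The exact method solves
(I − P − d·bᵀ) h = r_T, where the rank-one term implements the restart.
Transient states that cannot reach any endpoint (e.g. isolated retweet
2-cycles) have absorption probability exactly zero and would make the system
singular; they are removed by reverse reachability before solving, and if
total absorption falls below 1 the probabilities are renormalized over
reachable endpoints with a warning. The Monte Carlo method simulates walks
(cap 100·n steps) and renormalizes over absorbed walks, matching the exact
semantics. On the synthetic worlds the absolute RWC values are well below the
0.73–0.94 range seen on real national debates — the small planted graphs mix
faster — so tests assert the analytic limits, exact/Monte-Carlo agreement,
and monotonicity in `p_between`, not absolute levels.

**NMI.** scikit-learn's `normalized_mutual_info_score` with arithmetic-mean
normalization, computed on the intersection of the two partitions' user sets
(the RT and CO networks cover different users).

**Behavior statistics.** URL-based statistics (URLs per user, YouTube URLs,
low-credibility share) count original posts only, so they measure the group's
own sharing behavior rather than retweeted content; retweets per user counts
retweet events. Low-credibility attribution is at the retweet level in flow
matrices: a retweet counts as low-credibility when the retweeted original
carries at least one listed URL. Domain matching is suffix-at-label-boundary
("news.example.com" matches list entry "example.com").

**Flow matrices.** All matrices are oriented "i retweets j" (information
flows j → i). Normalized volume keeps within-country retweets in the
marginals and total (the diagonal is zeroed only at output); an
exclude-diagonal variant would change only the overall scale of the
baseline. Masked cells (zero marginals, missing no-vax communities, zero
reference density, importers with ≤10 low-credibility retweets, diagonals)
carry machine-readable reasons and are written as empty CSV cells, never NaN.

## Pipeline

Stages communicate via plain-text artifacts (JSON-lines, CSV, TSV) in the
output directory, so each stage can be rerun or tested in isolation;
`vaxflow run-all` executes generate → geolocate → networks → communities →
label → metrics → flows → report. All randomness is routed through the world
seed, and a rerun with the same configuration is byte-identical. Default
periods are four labeled three-month windows (pre-COVID, prevaccine, vaccine
development, vaccine rollout).

## Known limitations

- The Paris implementation is pure Python (dict-based nearest-neighbor
  chain); it is comfortable to a few thousand nodes but not engineered for
  the 10⁵–10⁶-node networks of a production corpus.
- RWC on very sparse directed graphs relies on the renormalization rule when
  parts of a side cannot reach any endpoint; the warning should be heeded
  when comparing scores across networks of very different density.
- The generator's stance/URL/suspension draws are independent given group
  membership; real corpora exhibit user-level burstiness and cascades that
  would widen all sampling distributions.
- Low-credibility lists are synthetic fixtures; export-share magnitudes on
  synthetic worlds reflect the planted group contrasts, not any real
  country's media ecosystem.
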