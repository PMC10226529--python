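"""End-to-end orchestration: synthetic world -> geolocation -> networks ->
communities -> labeling -> polarization metrics -> cross-border flow matrices.

Stages communicate through plain-text files (JSON-lines, CSV, TSV) under an
output directory, so each stage can be run, inspected, and tested on its own,
and a run with a fixed seed reproduces byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import communities as comm_mod
from . import flows as flows_mod
from . import geolocation as geo_mod
from . import labeling as label_mod
from . import networks as net_mod
from . import polarization as pol_mod
from . import synthetic as syn_mod
from .synthetic import Period, TweetRecord, UserRecord, WorldConfig

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Full pipeline configuration; every analysis threshold is exposed with
    its standard value as the default."""

    world: WorldConfig = field(default_factory=WorldConfig)
    min_community_frac: float = 0.01
    classify_rule: str = "main"
    prune_node_threshold: int = 200_000
    bridge_threshold: float = 0.5
    exclude_bridge_users: bool = True
    lowcred_mask_cutoff: int = 10
    max_community_share: float = 0.9
    rwc_method: str = "exact"
    rwc_n_walks: int = 10_000
    rwc_k_endpoints: int | None = None
    round1_n: int = 20
    round2_n: int = 10
    round2_exclude_top: int = 50
    annotator_flip_prob: float = 0.1

    def validate(self) -> None:
        self.world.validate()
        if self.classify_rule not in ("main", "majority", "strict"):
            raise syn_mod.ConfigurationError(
                f"unknown classify_rule {self.classify_rule!r}"
            )
        if not 0 < self.bridge_threshold <= 1:
            raise syn_mod.ConfigurationError("bridge_threshold outside (0, 1]")

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RunConfig":
        data = dict(data)
        world_data = dict(data.pop("world", {}))
        if "periods" in world_data:
            world_data["periods"] = tuple(
                Period(
                    p["label"],
                    date.fromisoformat(p["start"]),
                    date.fromisoformat(p["end"]),
                )
                for p in world_data["periods"]
            )
        for key in ("countries", "novax_countries"):
            if key in world_data:
                world_data[key] = tuple(world_data[key])
        if "suspension_spike" in world_data:
            world_data["suspension_spike"] = tuple(
                date.fromisoformat(d) for d in world_data["suspension_spike"]
            )
        return cls(world=WorldConfig(**world_data), **data)


# ---------------------------------------------------------------------------
# Artifact IO


def write_jsonl(path: Path, records) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(json.dumps(r.to_dict(), sort_keys=True) + "\n")


def read_users(outdir: Path) -> list[UserRecord]:
    with open(outdir / "users.jsonl") as fh:
        return [UserRecord.from_dict(json.loads(line)) for line in fh]


def read_tweets(outdir: Path) -> list[TweetRecord]:
    with open(outdir / "tweets.jsonl") as fh:
        return [TweetRecord.from_dict(json.loads(line)) for line in fh]


def _read_gazetteer(outdir: Path):
    entries = {}
    with open(outdir / "gazetteer.tsv") as fh:
        for line in fh:
            name, country = line.rstrip("\n").split("\t")
            entries[name] = country
    with open(outdir / "exclusion.tsv") as fh:
        exclusion = [line.strip() for line in fh if line.strip()]
    return geo_mod.Gazetteer.from_entries(entries), exclusion


def _net_path(outdir: Path, country: str, period: str, kind: str) -> Path:
    return outdir / "networks" / f"{country}_{period}_{kind}.tsv"


def _write_network(graph, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("source\ttarget\tweight\n")
        for u, v, w in sorted(graph.edges(data="weight", default=1)):
            fh.write(f"{u}\t{v}\t{w}\n")
    meta = {
        "nodes": sorted(graph.nodes),
        "directed": graph.is_directed(),
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, sort_keys=True)


def _read_network(path: Path):
    import networkx as nx

    meta = json.loads(path.with_suffix(".json").read_text())
    g = nx.DiGraph() if meta["directed"] else nx.Graph()
    g.add_nodes_from(meta["nodes"])
    with open(path) as fh:
        next(fh)
        for line in fh:
            u, v, w = line.rstrip("\n").split("\t")
            g.add_edge(u, v, weight=int(w))
    return g


# ---------------------------------------------------------------------------
# Stages


def stage_generate(config: RunConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    users, tweets, truth = syn_mod.generate_world(config.world)
    write_jsonl(outdir / "users.jsonl", users)
    write_jsonl(outdir / "tweets.jsonl", tweets)
    pd.DataFrame([u.to_dict() for u in users]).to_csv(
        outdir / "users.csv", index=False
    )
    tw = pd.DataFrame([t.to_dict() for t in tweets])
    tw["urls"] = tw["urls"].map(lambda urls: " ".join(urls))
    tw.to_csv(outdir / "tweets.csv", index=False)
    fixture = syn_mod.emit_gazetteer(config.world)
    with open(outdir / "gazetteer.tsv", "w") as fh:
        for name, country in sorted(fixture.gazetteer.entries.items()):
            fh.write(f"{name}\t{country}\n")
    with open(outdir / "exclusion.tsv", "w") as fh:
        for word in fixture.exclusion_words:
            fh.write(word + "\n")
    with open(outdir / "lowcred_domains.txt", "w") as fh:
        for dom in syn_mod.lowcred_domains(config.world):
            fh.write(dom + "\n")
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth.to_dict(), fh, sort_keys=True, default=str)
    logger.info(
        "generated %d users, %d tweets (resolvable location fraction %.3f)",
        len(users),
        len(tweets),
        fixture.resolvable_fraction,
    )


def stage_geolocate(config: RunConfig, outdir: Path) -> None:
    users = read_users(outdir)
    tweets = read_tweets(outdir)
    gazetteer, exclusion = _read_gazetteer(outdir)
    periods = [p.label for p in config.world.periods]
    resolved = {
        u.user_id: geo_mod.resolve_country(u.raw_location, gazetteer, exclusion)
        for u in users
    }
    assignments = {
        u: [c] * len(periods) for u, c in resolved.items() if c is not None
    }
    retained = geo_mod.drop_country_changers(assignments)
    country_map = {u: resolved[u] for u in retained}
    rt_events = net_mod.extract_rt_events(tweets)
    flagged = geo_mod.flag_bridge_users(
        rt_events, country_map, config.bridge_threshold
    )
    rows = [
        {"user_id": u, "period": p, "country": country_map[u]}
        for u in sorted(country_map)
        for p in periods
    ]
    pd.DataFrame(rows).to_csv(outdir / "geolocation.csv", index=False)
    with open(outdir / "flagged_users.json", "w") as fh:
        json.dump(sorted(flagged), fh)
    logger.info(
        "geolocated %d/%d users (%.1f%%); flagged %d bridge users",
        len(country_map),
        len(users),
        100 * len(country_map) / len(users),
        len(flagged),
    )


def read_country_map(outdir: Path) -> dict[str, str]:
    df = pd.read_csv(outdir / "geolocation.csv")
    return dict(df.drop_duplicates("user_id")[["user_id", "country"]].values)


def stage_networks(config: RunConfig, outdir: Path) -> None:
    tweets = read_tweets(outdir)
    country_map = read_country_map(outdir)
    oc_rows = []
    for country in config.world.countries:
        language = config.world.country_language[country]
        for period in config.world.periods:
            rt = net_mod.build_rt_network(
                tweets, country_map, country, period.label, language
            )
            co = net_mod.build_co_network(
                tweets, country_map, country, period.label, language
            )
            rt = net_mod.prune_weight1(rt, config.prune_node_threshold)
            co = net_mod.prune_weight1(co, config.prune_node_threshold)
            rt_gcc = net_mod.giant_component(rt)
            co_gcc = net_mod.giant_component(co)
            _write_network(rt_gcc, _net_path(outdir, country, period.label, "rt"))
            _write_network(co_gcc, _net_path(outdir, country, period.label, "co"))
            oc = (
                net_mod.overlap_coefficient(set(rt_gcc.nodes), set(co_gcc.nodes))
                if rt_gcc.number_of_nodes() and co_gcc.number_of_nodes()
                else float("nan")
            )
            oc_rows.append(
                {
                    "country": country,
                    "period": period.label,
                    "rt_nodes": rt_gcc.number_of_nodes(),
                    "rt_edges": rt_gcc.number_of_edges(),
                    "co_nodes": co_gcc.number_of_nodes(),
                    "co_edges": co_gcc.number_of_edges(),
                    "overlap_coefficient": oc,
                }
            )
            logger.info(
                "%s/%s: RT GCC %d nodes, CO GCC %d nodes, OC %.3f",
                country,
                period.label,
                rt_gcc.number_of_nodes(),
                co_gcc.number_of_nodes(),
                oc,
            )
    pd.DataFrame(oc_rows).to_csv(outdir / "network_summary.csv", index=False)


def _partition_path(outdir: Path, country: str, period: str, kind: str) -> Path:
    return outdir / "communities" / f"{country}_{period}_{kind}_partition.csv"


def read_partition(path: Path) -> comm_mod.Partition:
    df = pd.read_csv(path)
    return comm_mod.Partition(dict(zip(df["user_id"], df["community_id"])))


def stage_communities(config: RunConfig, outdir: Path) -> None:
    (outdir / "communities").mkdir(parents=True, exist_ok=True)
    cut_rows = []
    for country in config.world.countries:
        for period in config.world.periods:
            for kind in ("rt", "co"):
                g = _read_network(_net_path(outdir, country, period.label, kind))
                if g.number_of_nodes() == 0:
                    continue
                dend = comm_mod.paris_dendrogram(g)
                part, info = comm_mod.cut_dendrogram(
                    dend, g, config.max_community_share, return_info=True
                )
                pd.DataFrame(
                    sorted(part.membership.items()),
                    columns=["user_id", "community_id"],
                ).to_csv(
                    _partition_path(outdir, country, period.label, kind), index=False
                )
                merges_path = (
                    outdir
                    / "communities"
                    / f"{country}_{period.label}_{kind}_dendrogram.json"
                )
                with open(merges_path, "w") as fh:
                    json.dump(
                        {"nodes": dend.nodes, "merges": dend.merges.tolist()},
                        fh,
                        sort_keys=True,
                    )
                cut_rows.append(
                    {
                        "country": country,
                        "period": period.label,
                        "network": kind,
                        "n_communities": part.n_communities(),
                        "largest_share": info.largest_share,
                        "modularity": info.modularity,
                        "window": info.window,
                        "terminated_by": info.terminated_by,
                    }
                )
                logger.info(
                    "%s/%s %s: %d communities (largest share %.2f, Q=%.3f)",
                    country,
                    period.label,
                    kind,
                    part.n_communities(),
                    info.largest_share,
                    info.modularity,
                )
    pd.DataFrame(cut_rows).to_csv(outdir / "communities" / "summary.csv", index=False)


def stage_label(config: RunConfig, outdir: Path) -> None:
    tweets = read_tweets(outdir)
    (outdir / "labels").mkdir(parents=True, exist_ok=True)
    seed = config.world.seed
    ann_rows = []
    class_rows = []
    for country in config.world.countries:
        for period in config.world.periods:
            ppath = _partition_path(outdir, country, period.label, "rt")
            if not ppath.exists():
                continue
            part = read_partition(ppath)
            net_tweets = [
                t
                for t in tweets
                if t.period == period.label and t.author_id in part.membership
            ]
            eligible = label_mod.eligible_communities(part, config.min_community_frac)
            sample1 = label_mod.sample_round1(
                net_tweets, part, eligible, config.round1_n, seed
            )
            tweet_comm = {
                t.tweet_id: cid for cid, ts in sample1.items() for t in ts
            }
            flat1 = [t for ts in sample1.values() for t in ts]
            if not flat1:
                continue
            ann1 = syn_mod.simulate_annotations(
                flat1, config.annotator_flip_prob, seed
            )
            tallies = label_mod.tally_annotations(ann1, tweet_comm, "round1")
            round2_comms = [
                cid for cid, tly in sorted(tallies.items())
                if label_mod.majority_novax(tly)
            ]
            sample2 = label_mod.sample_round2(
                net_tweets,
                part,
                round2_comms,
                config.round2_n,
                config.round2_exclude_top,
            )
            tweet_comm2 = {
                t.tweet_id: cid for cid, ts in sample2.items() for t in ts
            }
            flat2 = [t for ts in sample2.values() for t in ts]
            if flat2:
                ann2 = syn_mod.simulate_annotations(
                    flat2, config.annotator_flip_prob, seed + 1
                )
                label_mod.tally_annotations(ann2, tweet_comm2, "round2", tallies)
            else:
                ann2 = []
            for ann, rnd, tc in ((ann1, 1, tweet_comm), (ann2, 2, tweet_comm2)):
                for a in ann:
                    ann_rows.append(
                        {
                            "country": country,
                            "period": period.label,
                            "round": rnd,
                            "tweet_id": a.tweet_id,
                            "community": tc[a.tweet_id],
                            "annotator": a.annotator,
                            "label": a.label,
                        }
                    )
            for cid, tally in sorted(tallies.items()):
                class_rows.append(
                    {
                        "country": country,
                        "period": period.label,
                        "community": cid,
                        "novax": tally.novax,
                        "provax": tally.provax,
                        "other": tally.other,
                        "classification": label_mod.classify_novax(
                            tally, config.classify_rule
                        ),
                    }
                )
    pd.DataFrame(ann_rows).to_csv(outdir / "labels" / "annotations.csv", index=False)
    pd.DataFrame(class_rows).to_csv(
        outdir / "labels" / "classifications.csv", index=False
    )
    n_novax = sum(1 for r in class_rows if r["classification"] == "novax")
    logger.info(
        "labeled %d communities; %d classified no-vax", len(class_rows), n_novax
    )


def _novax_users(outdir: Path, country: str, period: str) -> set[str]:
    """Users in communities classified no-vax for one network."""
    cpath = outdir / "labels" / "classifications.csv"
    cls = pd.read_csv(cpath)
    sel = cls[
        (cls["country"] == country)
        & (cls["period"] == period)
        & (cls["classification"] == "novax")
    ]
    if sel.empty:
        return set()
    part = read_partition(_partition_path(outdir, country, period, "rt"))
    novax_comms = set(sel["community"])
    return {u for u, c in part.membership.items() if c in novax_comms}


def stage_metrics(config: RunConfig, outdir: Path) -> None:
    users = read_users(outdir)
    tweets = read_tweets(outdir)
    lowcred = flows_mod.load_domain_list(outdir / "lowcred_domains.txt")
    annotations = pd.read_csv(outdir / "labels" / "annotations.csv")
    (outdir / "metrics").mkdir(parents=True, exist_ok=True)
    metric_rows = []
    behavior_frames = []
    users_by_id = {u.user_id: u for u in users}
    for country in config.world.countries:
        for period in config.world.periods:
            rt_path = _net_path(outdir, country, period.label, "rt")
            if not rt_path.exists():
                continue
            rt = _read_network(rt_path)
            co = _read_network(_net_path(outdir, country, period.label, "co"))
            part_rt = read_partition(
                _partition_path(outdir, country, period.label, "rt")
            )
            part_co = read_partition(
                _partition_path(outdir, country, period.label, "co")
            )
            novax = _novax_users(outdir, country, period.label)
            row: dict[str, Any] = {"country": country, "period": period.label}
            row["n_users"] = rt.number_of_nodes()
            row["has_novax_community"] = bool(novax)
            row["novax_user_share"] = (
                len(novax & set(rt.nodes)) / rt.number_of_nodes()
                if rt.number_of_nodes()
                else np.nan
            )
            ann = annotations[
                (annotations["country"] == country)
                & (annotations["period"] == period.label)
            ]
            row["novax_tweet_share"] = (
                float((ann["label"] == "novax").mean()) if len(ann) else np.nan
            )
            if novax and len(novax & set(rt.nodes)) < rt.number_of_nodes():
                sides = {
                    n: ("X" if n in novax else "Y") for n in rt.nodes
                }
                row["rwc"] = pol_mod.rwc(
                    rt,
                    sides,
                    config.rwc_k_endpoints,
                    config.rwc_method,
                    config.rwc_n_walks,
                    config.world.seed,
                )
            else:
                row["rwc"] = np.nan
            try:
                row["nmi"] = pol_mod.nmi(part_rt, part_co)
            except ValueError:
                row["nmi"] = np.nan
            group_map = {
                n: ("novax" if n in novax else "other") for n in rt.nodes
            }
            susp = pol_mod.suspended_share(
                [users_by_id[n] for n in rt.nodes if n in users_by_id], group_map
            )
            row["suspended_share_novax"] = susp.get("novax", np.nan)
            row["suspended_share_other"] = susp.get("other", np.nan)
            metric_rows.append(row)
            net_tweets = [t for t in tweets if t.period == period.label]
            bstats = pol_mod.behavior_stats(net_tweets, group_map, lowcred)
            bstats.insert(0, "country", country)
            bstats.insert(1, "period", period.label)
            bstats.insert(2, "group", bstats.index)
            behavior_frames.append(bstats.reset_index(drop=True))
    pd.DataFrame(metric_rows).to_csv(outdir / "metrics" / "metrics.csv", index=False)
    if behavior_frames:
        pd.concat(behavior_frames, ignore_index=True).to_csv(
            outdir / "metrics" / "behavior.csv", index=False
        )
    timeline = pol_mod.suspension_timeline(users)
    timeline.reset_index().to_csv(
        outdir / "metrics" / "suspension_timeline.csv", index=False
    )
    logger.info("wrote metrics for %d networks", len(metric_rows))


def stage_flows(config: RunConfig, outdir: Path) -> None:
    tweets = read_tweets(outdir)
    country_map = read_country_map(outdir)
    lowcred = flows_mod.load_domain_list(outdir / "lowcred_domains.txt")
    rt_events = net_mod.extract_rt_events(tweets)
    flagged = set(json.loads((outdir / "flagged_users.json").read_text()))
    exclude = flagged if config.exclude_bridge_users else set()
    (outdir / "flows").mkdir(parents=True, exist_ok=True)
    countries = list(config.world.countries)
    summary = {}
    for period in config.world.periods:
        p = period.label
        counts = flows_mod.rt_count_matrix(
            rt_events, country_map, p, countries, exclude
        )
        norm = flows_mod.normalized_rt_volume(counts)
        net = flows_mod.net_information_flow(counts)
        groups = flows_mod.GroupSets(
            novax={c: _novax_users(outdir, c, p) for c in countries},
            other={
                c: {
                    u
                    for u, cc in country_map.items()
                    if cc == c and u not in _novax_users(outdir, c, p)
                }
                for c in countries
            },
        )
        density = flows_mod.novax_density_ratio(
            rt_events, groups, country_map, p, countries, exclude
        )
        lc = flows_mod.lowcred_flow_matrix(
            rt_events,
            tweets,
            lowcred,
            country_map,
            p,
            countries,
            config.lowcred_mask_cutoff,
            exclude,
        )
        try:
            export = flows_mod.lowcred_export_share(
                rt_events, tweets, lowcred, country_map, p, exclude
            )
        except ValueError:
            export = {}
        for name, matrix in (
            ("counts", counts),
            ("normalized", norm),
            ("density_ratio", density),
            ("lowcred", lc),
        ):
            matrix.to_csv(outdir / "flows" / f"{p}_{name}.csv")
            with open(outdir / "flows" / f"{p}_{name}_masks.json", "w") as fh:
                json.dump(
                    {f"{i}->{j}": reason for (i, j), reason in sorted(matrix.mask.items())},
                    fh,
                    sort_keys=True,
                )
        summary[p] = {
            "net_information_flow": net,
            "lowcred_export_share": export,
        }
    with open(outdir / "flows" / "summary.json", "w") as fh:
        json.dump(summary, fh, sort_keys=True)
    logger.info("wrote flow matrices for %d periods", len(config.world.periods))


def stage_report(config: RunConfig, outdir: Path) -> dict:
    metrics = pd.read_csv(outdir / "metrics" / "metrics.csv")
    flows_summary = json.loads((outdir / "flows" / "summary.json").read_text())
    report = {
        "config_seed": config.world.seed,
        "n_networks": int(len(metrics)),
        "per_network": metrics.to_dict(orient="records"),
        "flows": flows_summary,
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, sort_keys=True, default=str)
    return report


STAGES = (
    ("generate", stage_generate),
    ("geolocate", stage_geolocate),
    ("networks", stage_networks),
    ("communities", stage_communities),
    ("label", stage_label),
    ("metrics", stage_metrics),
    ("flows", stage_flows),
)


def run_pipeline(config: RunConfig, outdir: Path | str) -> dict:
    """Run every stage in order and return the summary report."""
    config.validate()
    outdir = Path(outdir)
    for name, stage in STAGES:
        logger.info("=== stage %s ===", name)
        stage(config, outdir)
    return stage_report(config, outdir)
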