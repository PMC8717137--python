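"""End-to-end analysis pipeline: load or simulate, clean, analyze, report.

Stages run in dependency order (load/synth -> clean -> network ->
netstats/distfit/temporal -> phrases -> wkn).  Every stochastic stage gets
its own seed derived from the single top-level seed by stable hashing, so
enabling or disabling one stage never perturbs another's randomness.  A
stage failure is recorded in the report and independent stages still run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import yaml

from . import distfit, io, netstats, network, phrases, temporal, wkn
from ._util import stage_seed
from .synth import ForumDataset, SynthConfig, config_from_dict, generate_forum

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "load_config"]

_ALL_STAGES = ("network", "netstats", "distfit", "temporal", "phrases", "wkn")


@dataclass
class RunConfig:
    output_dir: str = "ohcnet-out"
    posts_path: str | None = None
    users_path: str | None = None
    input_format: str = "csv"
    synth: dict | None = None
    stages: tuple[str, ...] = _ALL_STAGES
    bot_author_patterns: tuple[str, ...] = ()
    alpha: float = 0.05
    top_k: int = 200
    min_frequency: int = 2
    n_replicates: int = 50
    sigma_max_nodes: int = 3000
    cut_date: datetime = datetime(2020, 1, 1)
    degree_thresholds: dict = field(
        default_factory=lambda: {"exact": 1, "high": 100, "low": 5}
    )
    lexicon_path: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.posts_path is None and self.synth is None:
            raise ValueError("config needs either posts_path or a synth block")
        unknown = set(self.stages) - set(_ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


@dataclass
class RunReport:
    config: dict
    sections: dict = field(default_factory=dict)
    failures: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.failures

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "sections": self.sections,
                    "failures": self.failures,
                    "artifacts": self.artifacts,
                },
                fh,
                indent=2,
                default=str,
            )


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = dict(raw)
    if "cut_date" in kwargs and not isinstance(kwargs["cut_date"], datetime):
        kwargs["cut_date"] = datetime.fromisoformat(str(kwargs["cut_date"]))
    if "stages" in kwargs:
        kwargs["stages"] = tuple(kwargs["stages"])
    if "bot_author_patterns" in kwargs:
        kwargs["bot_author_patterns"] = tuple(kwargs["bot_author_patterns"])
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(kwargs) - known
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    return RunConfig(**kwargs)


def _acquire(config: RunConfig, outdir: Path) -> ForumDataset:
    if config.synth is not None:
        synth_kwargs = dict(config.synth)
        synth_kwargs.setdefault("seed", stage_seed(config.seed, "synth"))
        scfg = config_from_dict(synth_kwargs)
        dataset = generate_forum(scfg)
        io.write_dataset(dataset, outdir / "data")
        return dataset
    return io.load_dataset(
        config.posts_path, config.users_path, fmt=config.input_format
    )


def run_pipeline(config: RunConfig) -> RunReport:
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    resolved = dataclasses.asdict(config)
    logger.info("resolved config: %s", resolved)
    report = RunReport(config=resolved)

    dataset = _acquire(config, outdir)
    dataset, cleaning = io.clean_posts(
        dataset, bot_author_patterns=config.bot_author_patterns
    )
    report.sections["cleaning"] = dataclasses.asdict(cleaning)
    report.sections["dataset"] = {
        "forum": dataset.forum_name,
        "n_posts": len(dataset.posts),
        "n_threads": len(dataset.thread_roots()),
        "n_replies": len(dataset.replies()),
        "n_users": len(dataset.users),
    }

    graph = None
    if "network" in config.stages:
        try:
            graph = network.build_reply_graph(dataset)
            summary = network.degree_summary(graph)
            shares = network.degree_shares(summary, **config.degree_thresholds)
            _, evolution = network.yearly_snapshots(dataset)
            network.write_graphml(graph, outdir / "reply_graph.graphml")
            network.write_edgelist_csv(graph, outdir / "reply_edges.csv")
            report.sections["network"] = {
                "n_nodes": graph.number_of_nodes(),
                "n_edges": graph.number_of_edges(),
                "n_reply_rejects": len(graph.graph.get("rejects", [])),
                "degree_shares_percent": shares,
                "yearly_activity": evolution.counts.reset_index().to_dict("records"),
            }
            report.artifacts["reply_graph"] = str(outdir / "reply_graph.graphml")
        except Exception as exc:  # noqa: BLE001 - stage isolation
            report.failures["network"] = repr(exc)
            graph = None

    if "netstats" in config.stages:
        if graph is None:
            report.failures.setdefault("netstats", "network stage unavailable")
        else:
            try:
                metrics = netstats.network_metrics(graph)
                section = {"metrics": metrics.as_dict()}
                if graph.number_of_nodes() <= config.sigma_max_nodes:
                    sw = netstats.small_world_sigma(
                        graph,
                        n_replicates=config.n_replicates,
                        seed=stage_seed(config.seed, "sigma"),
                    )
                    section["small_world"] = {
                        "c_obs": sw.c_obs,
                        "l_obs": sw.l_obs,
                        "c_null_mean": sw.c_null_mean,
                        "l_null_mean": sw.l_null_mean,
                        "sigma_mean": sw.sigma_mean,
                        "sigma_sd": sw.sigma_sd,
                        "n_replicates": sw.n_replicates,
                    }
                report.sections["netstats"] = section
            except Exception as exc:  # noqa: BLE001
                report.failures["netstats"] = repr(exc)

    if "distfit" in config.stages:
        try:
            roots = dataset.thread_roots()
            reads = [p.n_reads for p in roots if p.n_reads is not None]
            replies = [p.n_replies for p in roots if p.n_replies is not None]
            section = {
                "reads": dataclasses.asdict(distfit.describe(reads)),
                "replies": dataclasses.asdict(distfit.describe(replies)),
                "reads_gamma": dataclasses.asdict(
                    distfit.fit_gamma_ks(reads, alpha=config.alpha)
                ),
            }
            users = dataset.users_frame()
            if (users["n_followers"] > 0).sum() >= 10:
                fit = distfit.fit_power_law(users["n_followers"].to_numpy())
                section["followers_power_law"] = dataclasses.asdict(fit)
            if graph is not None:
                summary = network.degree_summary(graph)
                fit = distfit.fit_power_law(summary.frame["total_degree"].to_numpy())
                section["degree_power_law"] = dataclasses.asdict(fit)
            report.sections["distfit"] = section
        except Exception as exc:  # noqa: BLE001
            report.failures["distfit"] = repr(exc)

    if "temporal" in config.stages:
        try:
            weekday = temporal.activity_profile(dataset.posts, "weekday", "all_posts")
            hour_threads = temporal.activity_profile(dataset.posts, "hour", "threads")
            hour_replies = temporal.activity_profile(dataset.posts, "hour", "replies")
            corr = temporal.correlate_profiles(hour_threads, hour_replies)
            report.sections["temporal"] = {
                "weekday_all_posts": list(weekday.percentages),
                "hour_threads": list(hour_threads.percentages),
                "hour_replies": list(hour_replies.percentages),
                "threads_vs_replies_spearman": {
                    "rho": corr.rho,
                    "p_value": corr.p_value,
                    "n": corr.n,
                },
            }
        except Exception as exc:  # noqa: BLE001
            report.failures["temporal"] = repr(exc)

    ranked = None
    if "phrases" in config.stages:
        try:
            ranked = phrases.extract_key_phrases(
                dataset.posts,
                top_k=config.top_k,
                min_frequency=config.min_frequency,
            )
            frame = phrases.phrases_to_frame(ranked)
            frame.to_csv(outdir / "key_phrases.csv", index=False)
            report.sections["phrases"] = {
                "n_phrases": len(ranked),
                "n_keywords": len({w for c in ranked for w in c.pair}),
                "top10": [
                    {"pair": list(c.pair), "score": c.score, "frequency": c.frequency}
                    for c in ranked[:10]
                ],
            }
            report.artifacts["key_phrases"] = str(outdir / "key_phrases.csv")
        except Exception as exc:  # noqa: BLE001
            report.failures["phrases"] = repr(exc)

    if "wkn" in config.stages:
        if ranked is None:
            report.failures.setdefault("wkn", "phrases stage unavailable")
        else:
            try:
                lexicon = (
                    wkn.load_lexicon(config.lexicon_path)
                    if config.lexicon_path
                    else {}
                )
                graph_wkn = wkn.build_wkn(ranked, forum=dataset.forum_name)
                topics = wkn.classify_topics(graph_wkn, lexicon)
                before, after = wkn.split_periods(dataset.posts, config.cut_date)
                section = {
                    "n_keywords": graph_wkn.number_of_nodes(),
                    "n_edges": graph_wkn.number_of_edges(),
                    "topic_shares": topics.reset_index().to_dict("records"),
                    "period_split": {
                        "cut": config.cut_date.isoformat(),
                        "n_before": len(before),
                        "n_after": len(after),
                    },
                }
                for label, subset in (("before", before), ("after", after)):
                    sub = phrases.extract_key_phrases(
                        subset, top_k=config.top_k, min_frequency=config.min_frequency
                    )
                    if sub:
                        sub_wkn = wkn.build_wkn(sub, forum=dataset.forum_name)
                        path = outdir / f"wkn_{label}.graphml"
                        wkn.write_wkn_graphml(sub_wkn, path)
                        report.artifacts[f"wkn_{label}"] = str(path)
                        section[f"n_keywords_{label}"] = sub_wkn.number_of_nodes()
                wkn.write_wkn_graphml(graph_wkn, outdir / "wkn.graphml")
                nodes, edges = wkn.wkn_tables(graph_wkn)
                nodes.to_csv(outdir / "wkn_nodes.csv", index=False)
                edges.to_csv(outdir / "wkn_edges.csv", index=False)
                report.artifacts["wkn"] = str(outdir / "wkn.graphml")
                report.sections["wkn"] = section
            except Exception as exc:  # noqa: BLE001
                report.failures["wkn"] = repr(exc)

    report.to_json(outdir / "report.json")
    return report
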