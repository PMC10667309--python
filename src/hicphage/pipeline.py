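"""End-to-end orchestration: catalogue -> detection -> linkage -> networks -> stats.

``run_pipeline`` reads a dataset directory (simulator output or real
tables in the same layout), runs every stage, and writes a report bundle:
the candidate table with all intermediate quantities and filter flags,
the collapsed infection-pair table, per-host VPH, per-sample detection
summaries, network edge lists and centrality tables, the statistical
comparisons, and a machine-readable manifest of thresholds and seeds.
The bundle is a pure function of (inputs, configuration, seed); re-running
produces byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from . import __version__
from .catalog import ToolVote, greedy_centroid_cluster, vote_viral_contigs
from .coverage import abundance_table, summarize_sample, transcript_activity
from .io import Dataset, load_dataset, write_tsv
from .linkage import (
    build_candidates,
    candidates_to_frame,
    collapse_to_pairs,
    promiscuity_adjust,
    relative_count_filter,
    roc_threshold,
    round1_filter,
    vph_per_host,
)
from .networks import (
    build_infection_network,
    centrality,
    clr_network,
    cross_reference_hosts,
    pearson_network,
    rf_importance_network,
)
from .stats import two_group_ttest, vph_abundance_regression
from .synthetic import truth_pair_set

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Thresholds and knobs of the full pipeline (field-standard defaults)."""

    data_dir: str = "."
    outdir: str = "results"
    seed: int = 0
    breadth_cut: float = 0.5
    min_links: int = 2
    min_ratio: float = 0.1
    min_intra: int = 10
    roc_score: str = "r_prime"  # or "L"
    relative_frac: float = 0.8
    max_host_fraction: float = 0.2
    remove_promiscuous: bool = True
    votu_ani: float = 95.0
    votu_af: float = 85.0
    derep_ani: float = 99.0
    min_support: int = 2
    pearson_cutoff: float = 0.8
    clr_top_edges: int = 200
    rf_top_fraction: float = 0.05
    regression_transform: str = "log10"
    ttest_equal_var: bool = False


def _stage(name: str):
    """Decorator: re-raise stage failures tagged with the stage name."""

    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as err:
                raise RuntimeError(f"pipeline stage '{name}' failed: {err}") from err

        inner.__name__ = fn.__name__
        return inner

    return wrap


@_stage("catalog")
def catalog_stage(ds: Dataset, cfg: PipelineConfig):
    types = ds.entity_types()
    phage_ids = sorted(e for e, t in types.items() if t == "phage")
    if ds.votes is not None:
        votes = [
            ToolVote(
                contig_id=str(r.contig_id),
                virsorter=bool(r.virsorter),
                vibrant=bool(r.vibrant),
                deepvirfinder=bool(r.deepvirfinder),
                checkv_quality=str(r.checkv_quality),
            )
            for r in ds.votes.itertuples(index=False)
        ]
        viral = vote_viral_contigs(votes) & set(phage_ids)
    else:
        viral = set(phage_ids)
    lengths = ds.lengths()
    votu_clusters = greedy_centroid_cluster(
        [(v, lengths[v]) for v in sorted(viral)],
        ds.votu_sims,
        ani_cut=cfg.votu_ani,
        af_cut=cfg.votu_af,
        level="votu_95_85",
    )
    mag_ids = sorted(e for e, t in types.items() if t == "mag")
    mag_derep = greedy_centroid_cluster(
        [(m, lengths[m]) for m in mag_ids],
        ds.mag_sims,
        ani_cut=cfg.derep_ani,
        af_cut=0.0,
        level="mag_derep_99",
    )
    return sorted(viral), votu_clusters, mag_derep


@_stage("detect")
def detect_stage(ds: Dataset, cfg: PipelineConfig):
    abundance: dict[str, pd.DataFrame] = {}
    activity: dict[str, pd.DataFrame] = {}
    for sid, cov in sorted(ds.metagenome_coverage.items()):
        abundance[sid] = abundance_table(cov, breadth_cut=cfg.breadth_cut)
    for sid, cov in sorted(ds.metatranscriptome_coverage.items()):
        if sid not in abundance:
            raise ValueError(f"metatranscriptome sample {sid} has no metagenome")
        activity[sid] = transcript_activity(cov, abundance[sid])
    return abundance, activity


@_stage("link")
def link_stage(ds: Dataset, cfg: PipelineConfig, viral, abundance, votu_clusters,
               mag_derep):
    types = ds.entity_types()
    viral = set(viral)
    types = {
        e: (t if (t != "phage" or e in viral) else "nonviral")
        for e, t in types.items()
    }
    n_mags = sum(1 for t in types.values() if t == "mag")

    all_cands, all_rejected = [], []
    for (cond, rep), table in sorted(ds.link_tables.items()):
        sid = f"{cond}_{rep}"
        if sid not in abundance:
            raise ValueError(f"link table {cond}/{rep} has no coverage sample {sid}")
        ab = dict(
            zip(abundance[sid]["entity_id"], abundance[sid]["abundance"])
        )
        cands, rejected = build_candidates(table, ab, types)
        all_cands.extend(cands)
        all_rejected.extend(rejected)

    round1 = round1_filter(
        all_cands, min_links=cfg.min_links, min_ratio=cfg.min_ratio,
        min_intra=cfg.min_intra,
    )
    # One ROC curve per Hi-C library (condition x replicate). Pooling the
    # replicates would count each biological link once per replicate in the
    # links-removed term while phage retention needs only one copy, biasing
    # the scan toward discarding replicate duplicates of true links.
    score = "L" if cfg.roc_score == "L" else "r_prime"
    roc_survivors, thresholds = [], {}
    for cond, rep in sorted(ds.link_tables):
        grp = [c for c in round1 if c.condition == cond and c.replicate_id == rep]
        if not grp:
            continue
        t, surv = roc_threshold(grp, score=score)
        thresholds[f"{cond}_{rep}"] = t
        roc_survivors.extend(surv)
    rel = relative_count_filter(roc_survivors, frac=cfg.relative_frac)
    final, promiscuity_report = promiscuity_adjust(
        rel, n_mags, max_host_fraction=cfg.max_host_fraction,
        remove=cfg.remove_promiscuous,
    )
    pairs = collapse_to_pairs(final, votu_clusters, mag_derep)
    per_host = vph_per_host(final, mag_derep)
    audit = {
        "n_candidates": len(all_cands),
        "n_rejected_undefined": len(all_rejected),
        "n_after_round1": len(round1),
        "roc_thresholds": thresholds,
        "roc_score": score,
        "n_after_roc": len(roc_survivors),
        "n_after_relative": len(rel),
        "n_final": len(final),
        "n_pairs": len(pairs),
    }
    return final, all_rejected, pairs, per_host, promiscuity_report, audit


@_stage("network")
def network_stage(ds: Dataset, cfg: PipelineConfig, pairs, host_mags):
    infection = build_infection_network(pairs, min_support=cfg.min_support)
    out = {"infection": infection, "cooccurrence": {}, "centrality": {},
           "cross_reference": {}}
    if ds.transcripts is None or ds.transcripts.shape[1] < 3:
        return out

    def node_mag(node: str) -> str:
        # argS_<mag> or argS_<mag>.2 for duplicated proxies
        return node.removeprefix("argS_").split(".")[0]

    host_nodes_of = lambda nodes: [n for n in nodes if node_mag(n) in host_mags]
    nets = {
        "pearson": pearson_network(ds.transcripts, cutoff=cfg.pearson_cutoff),
        "clr": clr_network(ds.transcripts, top_edges=cfg.clr_top_edges),
        "rf_importance": rf_importance_network(
            ds.transcripts, top_fraction=cfg.rf_top_fraction, seed=cfg.seed
        ),
    }
    for name, net in nets.items():
        cent = centrality(net)
        out["cooccurrence"][name] = net
        out["centrality"][name] = cent
        out["cross_reference"][name] = cross_reference_hosts(
            cent, host_nodes_of(cent["node"])
        )
    return out


@_stage("stats")
def stats_stage(ds: Dataset, cfg: PipelineConfig, viral, abundance, activity,
                final_cands, pairs, per_host, votu_clusters):
    conditions = ds.conditions
    viral = set(viral)

    host_assoc_by_cond: dict[str, set] = {c: set() for c in conditions}
    for c in final_cands:
        host_assoc_by_cond[c.condition].add(c.phage_id)
    # member phages inherit their vOTU's host-range class per condition
    votu_of = {m: cl.representative_id for cl in votu_clusters for m in cl.member_ids}
    class_of_votu = {(p.votu_id, p.condition): p.host_range_class for p in pairs}
    class_by_cond: dict[str, dict] = {c: {} for c in conditions}
    for c in final_cands:
        cls = class_of_votu.get((votu_of.get(c.phage_id), c.condition))
        if cls:
            class_by_cond[c.condition][c.phage_id] = cls

    summaries = []
    for sid in sorted(abundance):
        cond = sid.rsplit("_", 1)[0]
        ab = abundance[sid]
        viral_ab = ab[ab["entity_id"].isin(viral)]
        act = activity.get(sid)
        viral_act = act[act["entity_id"].isin(viral)] if act is not None else None
        detected = set(viral_ab.loc[viral_ab["present"], "entity_id"])
        # a vOTU host-associated in this condition counts for this sample
        # only when it is also detected in the sample's own metagenome
        host_assoc = host_assoc_by_cond.get(cond, set()) & detected
        summaries.append(
            summarize_sample(
                viral_ab, viral_ab, viral_act, host_assoc,
                host_range_class=class_by_cond.get(cond, {}),
            )
        )
    summary_df = pd.DataFrame([s.as_dict() for s in summaries])
    summary_df["condition"] = [s.rsplit("_", 1)[0] for s in summary_df["sample_id"]]

    comparisons = []
    if len(conditions) == 2:
        pre, post = conditions
        for metric in (
            "relative_richness",
            "relative_abundance",
            "active_fraction_host_associated",
            "transcript_fraction_host_associated",
            "relative_richness_multi",
            "relative_richness_one",
            "relative_abundance_multi",
            "relative_abundance_one",
        ):
            comparisons.append(
                two_group_ttest(
                    summary_df.loc[summary_df["condition"] == pre, metric],
                    summary_df.loc[summary_df["condition"] == post, metric],
                    metric=metric,
                    equal_var=cfg.ttest_equal_var,
                )
            )
        if len(per_host):
            comparisons.append(
                two_group_ttest(
                    per_host.loc[per_host["condition"] == pre, "total_vph"],
                    per_host.loc[per_host["condition"] == post, "total_vph"],
                    metric="vph_per_host",
                    equal_var=cfg.ttest_equal_var,
                )
            )

    regressions = {}
    for cond in conditions:
        sub = per_host[per_host["condition"] == cond]
        if not len(sub):
            continue
        # one point per host population: VPH and host abundance averaged
        # over the condition's replicates
        mean_vph = sub.groupby("population_id")["total_vph"].mean()
        host_ab = {}
        for sid, ab in abundance.items():
            if sid.rsplit("_", 1)[0] != cond:
                continue
            m = ab.set_index("entity_id")["abundance"]
            for pop in mean_vph.index:
                host_ab.setdefault(pop, []).append(float(m.get(pop, 0.0)))
        tbl = pd.DataFrame(
            {
                "vph": mean_vph,
                "host_abundance": [np.mean(host_ab[p]) for p in mean_vph.index],
            }
        )
        if len(tbl) >= 3:
            try:
                regressions[cond] = vph_abundance_regression(
                    tbl, transform=cfg.regression_transform
                )
            except ValueError:
                pass
    return summary_df, comparisons, regressions


def evaluate_against_truth(ds: Dataset, final_cands) -> dict:
    """Precision/recall and VPH recovery of the pipeline vs ground truth."""
    truth = ds.truth
    detected: dict[str, set] = {}
    est_vph: dict[tuple, list] = {}
    for c in final_cands:
        detected.setdefault(c.condition, set()).add((c.phage_id, c.mag_id))
        est_vph.setdefault((c.phage_id, c.mag_id, c.condition), []).append(c.vph)
    tp = fp = fn = 0
    true_map = truth.true_vph_map()
    spearman_pairs = []
    for cond in ds.conditions:
        truth_set = truth_pair_set(truth, cond)
        det = detected.get(cond, set())
        tp += len(det & truth_set)
        fp += len(det - truth_set)
        fn += len(truth_set - det)
        for pair in det & truth_set:
            key = (pair[0], pair[1], cond)
            spearman_pairs.append(
                (float(np.mean(est_vph[key])), true_map[key])
            )
    precision = tp / (tp + fp) if tp + fp else math.nan
    recall = tp / (tp + fn) if tp + fn else math.nan
    if len(spearman_pairs) >= 3:
        est, true = zip(*spearman_pairs)
        rho = float(sps.spearmanr(est, true).statistic)
    else:
        rho = math.nan
    return {
        "true_positives": tp,
        "false_positives": fp,
        "false_negatives": fn,
        "precision": precision,
        "recall": recall,
        "spearman_vph": rho,
        "n_true_positive_pairs": len(spearman_pairs),
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (set, frozenset)):
        return [_jsonable(v) for v in sorted(obj)]
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (bool, np.bool_)):
        return bool(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        return None if isinstance(obj, float) and math.isnan(obj) else float(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on a dataset directory and write the report bundle.

    Returns the in-memory report; writes TSVs, a ``report.json`` and a
    ``manifest.json`` under ``config.outdir``. Any stage failure aborts
    with the stage name and the offending records in the error message.
    """
    cfg = config
    ds = load_dataset(cfg.data_dir)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    viral, votu_clusters, mag_derep = catalog_stage(ds, cfg)
    abundance, activity = detect_stage(ds, cfg)
    final, rejected, pairs, per_host, prom_report, audit = link_stage(
        ds, cfg, viral, abundance, votu_clusters, mag_derep
    )
    host_mags = sorted(
        {m for cl in mag_derep for m in cl.member_ids
         if any(p.population_id == cl.representative_id for p in pairs)}
    )
    nets = network_stage(ds, cfg, pairs, set(host_mags))
    summary_df, comparisons, regressions = stats_stage(
        ds, cfg, viral, abundance, activity, final, pairs, per_host, votu_clusters
    )
    evaluation = evaluate_against_truth(ds, final) if ds.truth is not None else None

    # ---- write the bundle ----
    write_tsv(candidates_to_frame(final + rejected), outdir / "candidates.tsv")
    write_tsv(
        pd.DataFrame(
            [
                {
                    "votu_id": p.votu_id,
                    "population_id": p.population_id,
                    "condition": p.condition,
                    "replicate_support": ",".join(sorted(p.replicate_support)),
                    "n_replicates": len(p.replicate_support),
                    "host_range_class": p.host_range_class,
                }
                for p in pairs
            ]
        ),
        outdir / "infection_pairs.tsv",
    )
    write_tsv(per_host, outdir / "vph_per_host.tsv")
    write_tsv(summary_df, outdir / "detection_summary.tsv")
    write_tsv(prom_report, outdir / "promiscuity_report.tsv")
    inf = nets["infection"]
    write_tsv(
        pd.DataFrame(
            [
                {
                    "votu_id": a if inf.nodes[a]["kind"] == "votu" else b,
                    "population_id": b if inf.nodes[a]["kind"] == "votu" else a,
                    "weight": d["weight"],
                    "support": json.dumps(d["support"], sort_keys=True),
                }
                for a, b, d in sorted(inf.edges(data=True))
            ]
        ),
        outdir / "infection_network_edges.tsv",
    )
    inf_graphml = inf.copy()
    for _a, _b, d in inf_graphml.edges(data=True):
        d["support"] = json.dumps(d["support"], sort_keys=True)
    nx.write_graphml(inf_graphml, outdir / "infection_network.graphml")
    for name, net in nets["cooccurrence"].items():
        rows = [
            {"source": a, "target": b, "weight": d["weight"], "method": name,
             "rule": net.selection_rule}
            for a, b, d in sorted(net.graph.edges(data=True))
        ]
        write_tsv(pd.DataFrame(rows), outdir / f"cooccurrence_{name}_edges.tsv")
        write_tsv(nets["centrality"][name], outdir / f"centrality_{name}.tsv")
        nx.write_graphml(net.graph, outdir / f"cooccurrence_{name}.graphml")

    report = {
        "catalog": {
            "n_viral": len(viral),
            "n_votus": len(votu_clusters),
            "n_populations": len(mag_derep),
        },
        "linkage": audit,
        "roc_thresholds": audit["roc_thresholds"],
        "pairs": {
            "n_pairs": len(pairs),
            "by_condition": {
                c: sum(1 for p in pairs if p.condition == c) for c in ds.conditions
            },
            "multiple_hosts": sum(
                1 for p in pairs if p.host_range_class == "multiple_hosts"
            ),
        },
        "infection_network": {
            "n_nodes": inf.number_of_nodes(),
            "n_edges": inf.number_of_edges(),
        },
        "cooccurrence": {
            name: {
                "n_nodes": net.graph.number_of_nodes(),
                "n_edges": net.graph.number_of_edges(),
                "rule": net.selection_rule,
                "hosts_in_top5_betweenness": nets["cross_reference"][name][
                    "hosts_in_top_betweenness"
                ],
            }
            for name, net in nets["cooccurrence"].items()
        },
        "comparisons": [c.as_dict() for c in comparisons],
        "regressions": {k: v.as_dict() for k, v in regressions.items()},
        "evaluation": evaluation,
    }
    (outdir / "report.json").write_text(
        json.dumps(_jsonable(report), indent=1, sort_keys=True) + "\n"
    )
    manifest = {
        "package": "hicphage",
        "version": __version__,
        "config": dataclasses.asdict(cfg),
        "n_tests_performed": len(comparisons) + len(regressions),
        "inputs": sorted(p.name for p in Path(cfg.data_dir).glob("*.tsv")),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(_jsonable(manifest), indent=1, sort_keys=True) + "\n"
    )
    return report
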