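"""End-to-end driver reproducing the analysis sequence.

Order mirrors the study protocol: network construction (weighted,
thresholded), optional density-range selection from LCC behaviour,
per-participant community detection (Louvain ensemble + consensus),
nodal and global metrics (participation against each participant's own
consensus partition), group-representative partitions and sub-network
labels per condition, hub/role classification of the target node, and
permutation statistics including the behavior correlation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as bio
from .community import (
    Partition,
    consensus_partition,
    group_representative,
    label_subnetworks,
    louvain_ensemble,
    nmi,
)
from .config import PipelineConfig
from .construction import (
    BetaSeriesSet,
    beta_correlation,
    lcc_size,
    proportional_threshold,
    select_density_range,
)
from .hubs import classify_roles, target_vs_nodes_permutation
from .metrics import nodal_metrics
from .stats import (
    behavior_correlation,
    fdr_correct,
    pairwise_permutation,
    rm_permutation_test,
)
from .synthetic import (
    ACTIVE_CONDITIONS,
    CONDITIONS,
    connector_truth,
    default_truth,
    make_node_table,
    sample_cohort,
)

__all__ = ["PipelineResult", "run_pipeline", "stage_seed"]

log = logging.getLogger("betaconn")


def stage_seed(seed: int, stage: str, index: int = 0) -> int:
    """Derive a stage-salted 31-bit seed from the config seed."""
    digest = hashlib.sha256(f"{seed}:{stage}:{index}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineResult:
    config: PipelineConfig
    node_table: pd.DataFrame
    conditions: list[str]
    participants: list[str]
    metric_tables: dict[str, list[pd.DataFrame]]  # condition -> per participant
    global_tables: dict[str, pd.DataFrame]  # measure -> participants x conditions
    participant_partitions: dict[str, list[Partition]]
    group_partitions: dict[str, Partition]
    subnetwork_labels: dict[str, dict[int, str]]
    target_labels: dict[str, str]
    hub_report: object
    stats: dict
    density_report: dict = field(default_factory=dict)
    truth: object | None = None
    manifest: dict = field(default_factory=dict)


def _load_cohort(config: PipelineConfig):
    """Either simulate the configured synthetic cohort or read beta
    matrices, node table and behavior from ``data_dir``."""
    if config.data_dir is None:
        factory = {"default": default_truth, "connector": connector_truth}[
            config.cohort
        ]
        truth = factory(seed=stage_seed(config.seed, "simulate"),
                        **config.cohort_overrides)
        truth.validate()
        cohort = sample_cohort(truth, conditions=config.conditions)
        node_table = make_node_table(truth, seed=stage_seed(config.seed, "nodes"))
        beta = {
            key: BetaSeriesSet(vals, key[0], key[1], node_ids=list(cohort.node_ids))
            for key, vals in cohort.beta.items()
        }
        return beta, node_table, cohort.behavior, truth
    data_dir = Path(config.data_dir)
    node_table = bio.read_node_table(data_dir / "nodes.tsv")
    node_ids = list(node_table["node_id"])
    beta = {}
    for path in sorted((data_dir / "beta").glob("*.tsv")):
        pid, cond = path.stem.split("_", 1)
        cond = cond.replace("plus", "+").replace("minus", "-")
        beta[(pid, cond)] = bio.read_beta_matrix(
            path, participant=pid, condition=cond, node_ids=node_ids
        )
    behavior_path = data_dir / "behavior.tsv"
    behavior = (
        pd.read_csv(behavior_path, sep="\t") if behavior_path.exists() else None
    )
    return beta, node_table, behavior, None


def run_pipeline(config: PipelineConfig, write: bool = True) -> PipelineResult:
    t_start = time.time()
    out = Path(config.out_dir)
    if write:
        (out / "partitions").mkdir(parents=True, exist_ok=True)
        if config.write_matrices:
            (out / "networks").mkdir(parents=True, exist_ok=True)

    beta, node_table, behavior, truth = _load_cohort(config)
    node_ids = list(node_table["node_id"])
    conditions = [c for c in CONDITIONS if any(k[1] == c for k in beta)]
    extra = sorted({k[1] for k in beta} - set(conditions))
    conditions += extra
    participants = sorted({k[0] for k in beta})
    log.info(
        "cohort: %d participants x %d conditions, %d nodes",
        len(participants),
        len(conditions),
        len(node_ids),
    )

    # --- construction
    weighted = {key: beta_correlation(b) for key, b in beta.items()}

    density_report: dict = {}
    if config.select_range:
        cand = list(config.densities)
        rng_ = select_density_range(
            list(weighted.values()),
            cand,
            full_fraction=config.full_fraction,
            step=config.density_step,
            ranking=config.edge_ranking,
        )
        density_report = {
            "d_low": rng_.d_low,
            "d_high": rng_.d_high,
            "fractions": rng_.fractions,
        }

    d = config.primary_density
    binary = {
        key: proportional_threshold(wn, d, ranking=config.edge_ranking)
        for key, wn in weighted.items()
    }
    lcc = {key: lcc_size(bn) for key, bn in binary.items()}

    # --- per-participant communities and metrics
    metric_tables: dict[str, list[pd.DataFrame]] = {c: [] for c in conditions}
    participant_partitions: dict[str, list[Partition]] = {c: [] for c in conditions}
    global_rows: dict[str, dict] = {m: {} for m in (
        "global_efficiency", "mean_clustering", "modularity_q", "n_communities",
        "lcc_size",
    )}
    for cond in conditions:
        for p_idx, pid in enumerate(participants):
            bn = binary[(pid, cond)]
            ens = louvain_ensemble(
                bn,
                gamma=config.gamma,
                n_runs=config.louvain_runs,
                seed=stage_seed(config.seed, f"louvain:{cond}", p_idx),
            )
            part = consensus_partition(
                ens,
                tau=config.tau,
                n_iter=config.louvain_runs,
                seed=stage_seed(config.seed, f"consensus:{cond}", p_idx),
                gamma=config.gamma,
                max_cycles=config.consensus_max_cycles,
                base=bn,
            )
            part.participant, part.condition = pid, cond
            participant_partitions[cond].append(part)
            table = nodal_metrics(bn, part.assignment)
            metric_tables[cond].append(table.nodal)
            global_rows["global_efficiency"].setdefault(pid, {})[cond] = (
                table.global_efficiency
            )
            global_rows["mean_clustering"].setdefault(pid, {})[cond] = (
                table.mean_clustering
            )
            global_rows["modularity_q"].setdefault(pid, {})[cond] = part.q
            global_rows["n_communities"].setdefault(pid, {})[cond] = (
                part.n_communities
            )
            global_rows["lcc_size"].setdefault(pid, {})[cond] = lcc[(pid, cond)]
    global_tables = {
        m: pd.DataFrame.from_dict(rows, orient="index")[conditions]
        for m, rows in global_rows.items()
    }

    # --- group-representative partitions and sub-network labels
    reference = pd.Series(
        node_table["module"].values, index=range(len(node_table))
    )
    if config.target_node is not None:
        reference = reference.drop(config.target_node)
    group_partitions: dict[str, Partition] = {}
    subnetwork_labels: dict[str, dict[int, str]] = {}
    target_labels: dict[str, str] = {}
    for c_idx, cond in enumerate(conditions):
        rep = group_representative(
            participant_partitions[cond],
            tau=config.tau,
            n_iter=config.louvain_runs,
            seed=stage_seed(config.seed, "group", c_idx),
            gamma=config.gamma,
            max_cycles=config.consensus_max_cycles,
        )
        rep.condition = cond
        group_partitions[cond] = rep
        mapping, _ = label_subnetworks(
            rep, reference, target_node=config.target_node
        )
        subnetwork_labels[cond] = mapping
        target_labels[cond] = mapping[int(rep.assignment[config.target_node])]

    # --- hub and role analysis
    hub_report = classify_roles(
        metric_tables,
        target_node=config.target_node,
        fraction=config.hub_fraction,
        conditions=conditions,
    )
    for c_idx, cond in enumerate(conditions):
        values = np.stack(
            [t["participation"].to_numpy() for t in metric_tables[cond]]
        )
        hub_report.nodewise_p[(cond, "participation")] = (
            target_vs_nodes_permutation(
                values,
                config.target_node,
                n_perm=min(config.n_perm, 2000),
                seed=stage_seed(config.seed, "nodewise", c_idx),
            )
        )

    # --- statistics
    stats: dict = {"global": {}, "pairwise": {}, "participation": {}, "nmi": {}}
    for m in ("global_efficiency", "mean_clustering", "modularity_q",
              "n_communities"):
        res = rm_permutation_test(
            global_tables[m],
            n_perm=config.n_perm,
            seed=stage_seed(config.seed, f"rm:{m}"),
        )
        stats["global"][m] = {"statistic": res.statistic, "p": res.p,
                              "n_perm": res.n_perm}
        if "baseline" in conditions:
            stats["pairwise"][m] = {}
            for cond in conditions:
                if cond == "baseline":
                    continue
                pres = pairwise_permutation(
                    global_tables[m][cond].to_numpy(),
                    global_tables[m]["baseline"].to_numpy(),
                    n_perm=config.n_perm,
                    seed=stage_seed(config.seed, f"pair:{m}:{cond}"),
                )
                stats["pairwise"][m][cond] = {
                    "statistic": pres.statistic, "p": pres.p,
                    "exhaustive": pres.exhaustive,
                }

    # target participation across conditions (omnibus + post hoc)
    t_idx = config.target_node
    part_table = pd.DataFrame(
        {
            cond: [t["participation"].iloc[t_idx] for t in metric_tables[cond]]
            for cond in conditions
        },
        index=participants,
    )
    active = [c for c in conditions if c != "baseline"]
    if len(active) >= 2:
        res = rm_permutation_test(
            part_table[active],
            n_perm=config.n_perm,
            seed=stage_seed(config.seed, "rm:participation"),
        )
        stats["participation"]["omnibus"] = {"statistic": res.statistic,
                                             "p": res.p}
        stats["participation"]["posthoc"] = {}
        for c1 in active:
            for c2 in active:
                if c1 >= c2:
                    continue
                pres = pairwise_permutation(
                    part_table[c1].to_numpy(),
                    part_table[c2].to_numpy(),
                    n_perm=config.n_perm,
                    seed=stage_seed(config.seed, f"pair:participation:{c1}:{c2}"),
                )
                stats["participation"]["posthoc"][f"{c1} vs {c2}"] = {
                    "statistic": pres.statistic, "p": pres.p,
                }

    # partition similarity across conditions
    for c1 in conditions:
        for c2 in conditions:
            if c1 >= c2:
                continue
            stats["nmi"][f"{c1} vs {c2}"] = nmi(
                group_partitions[c1], group_partitions[c2]
            )

    # brain-behavior correlation per condition
    if behavior is not None and len(behavior):
        stats["behavior"] = {}
        for cond in active:
            sub = behavior[behavior["condition"] == cond].set_index("participant")
            if not len(sub):
                continue
            rt = sub.loc[participants, "rt"].to_numpy()
            try:
                r, p = behavior_correlation(part_table[cond].to_numpy(), rt)
            except ValueError as exc:  # e.g. degenerate participation
                stats["behavior"][cond] = {"error": str(exc)}
                continue
            stats["behavior"][cond] = {"pearson_r": r, "p": p}

    result = PipelineResult(
        config=config,
        node_table=node_table,
        conditions=conditions,
        participants=participants,
        metric_tables=metric_tables,
        global_tables=global_tables,
        participant_partitions=participant_partitions,
        group_partitions=group_partitions,
        subnetwork_labels=subnetwork_labels,
        target_labels=target_labels,
        hub_report=hub_report,
        stats=stats,
        density_report=density_report,
        truth=truth,
    )

    if write:
        _write_outputs(result, weighted, binary, out,
                       write_matrices=config.write_matrices)
    result.manifest = {
        "seed": config.seed,
        "primary_density": config.primary_density,
        "louvain_runs": config.louvain_runs,
        "n_perm": config.n_perm,
        "participants": len(participants),
        "conditions": conditions,
        "elapsed_s": round(time.time() - t_start, 1),
        "config_hash": hashlib.sha256(
            json.dumps(config.__dict__, sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
    }
    if write:
        bio.write_json(out / "manifest.json", result.manifest)
    return result


def _write_outputs(
    result: PipelineResult, weighted, binary, out: Path,
    write_matrices: bool = False,
) -> None:
    node_ids = list(result.node_table["node_id"])
    bio.write_node_table(out / "nodes.tsv", result.node_table)
    if write_matrices:
        for (pid, cond), wn in weighted.items():
            safe = cond.replace("+", "plus").replace("-", "minus")
            bio.write_matrix(out / "networks" / f"{pid}_{safe}_weighted.tsv",
                             wn.w, node_ids)
            bio.write_matrix(out / "networks" / f"{pid}_{safe}_binary.tsv",
                             binary[(pid, cond)].a, node_ids)
    for cond in result.conditions:
        safe = cond.replace("+", "plus").replace("-", "minus")
        bio.write_partition(
            out / "partitions" / f"group_{safe}.tsv",
            result.group_partitions[cond], node_ids,
        )
    for m, table in result.global_tables.items():
        table.to_csv(out / f"global_{m}.tsv", sep="\t")
    bio.write_json(out / "density_report.json", result.density_report)
    bio.write_json(
        out / "hub_report.json",
        {
            "target_node": result.hub_report.target_node,
            "hub_fraction": result.hub_report.hub_fraction,
            "target_ranks": {
                c: {m: int(v) for m, v in row.items()}
                for c, row in result.hub_report.target_ranks.iterrows()
            },
            "roles": {c: sorted(r) for c, r in result.hub_report.roles.items()},
            "target_subnetwork": result.target_labels,
        },
    )
    bio.write_json(out / "stats.json", result.stats)
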