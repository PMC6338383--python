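"""End-to-end orchestration: cohort in, full tabular report bundle out.

For each analysis group the pipeline produces the endorsement-frequency
table, the theoretical and observed configuration census, the symptom-count
cross-tab, the unthresholded and FWE-thresholded phi networks (edge lists +
GraphML + deterministic layout coordinates), the centrality table, the
symptom-score table, and the outcome-association battery.  A JSON manifest
records every parameter and seed so any output is reproducible from it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import configural, data_io, graph_metrics, network, outcome_stats, scoring
from .data_io import CohortTable
from .symptoms import DOMAINS, SYMPTOMS
from .synthetic import SimulationConfig, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Everything the pipeline needs; serialized into the output manifest."""

    cohort_path: str | None = None          # CSV input; None -> simulate
    simulation: SimulationConfig | None = None
    schema: dict[str, str] | None = None
    alpha: float = 0.05
    bootstrap_B: int = 2000
    seed: int = 0
    groups: tuple[str, ...] = ("ADHD", "control", "combined")
    weights_group: str = "ADHD"             # network supplying score weights
    weights_thresholded: bool = False
    metrics_on_thresholded: bool = False
    out_dir: str = "sympnet_report"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.bootstrap_B < 100:
            raise ValueError("bootstrap_B must be >= 100")


def endorsement_frequencies(cohort: CohortTable) -> pd.DataFrame:
    """Percent endorsement per symptom per group, ordered within domain by
    descending ADHD-group frequency."""
    rows = []
    for group in ("ADHD", "control"):
        profiles = cohort.group_profiles(group)
        if len(profiles) == 0:
            logger.warning("group %s empty; skipped in endorsement table", group)
            continue
        pct = 100.0 * profiles.mean(axis=0)
        for sym, value in zip(SYMPTOMS, pct):
            rows.append(
                {"group": group, "symptom": sym, "domain": DOMAINS[sym], "percent": value}
            )
    table = pd.DataFrame(rows)
    adhd = (
        table[table["group"] == "ADHD"]
        .set_index("symptom")["percent"]
        .to_dict()
    )
    table["_order"] = table["symptom"].map(lambda s: -adhd.get(s, 0.0))
    table = (
        table.sort_values(["group", "domain", "_order", "symptom"])
        .drop(columns="_order")
        .reset_index(drop=True)
    )
    return table


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run every stage and write the report bundle; returns the manifest.

    Stage failures abort with the stage name in the raised error.  Reruns
    with the same inputs, config and seed write byte-identical numerics.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": _config_dict(config), "stages": {}}

    stage = "load"
    try:
        if config.cohort_path:
            cohort = data_io.read_cohort(config.cohort_path, schema=config.schema)
        else:
            sim = config.simulation or SimulationConfig(seed=config.seed)
            cohort = generate_cohort(sim)
            manifest["config"]["simulation"] = _config_dict(sim)
        data_io.write_cohort(cohort, out / "cohort.csv")
        group_sizes = cohort.data["group"].value_counts().to_dict()
        logger.info("cohort loaded: %s", group_sizes)
        manifest["stages"]["load"] = {"n": cohort.n, "groups": group_sizes}

        stage = "endorsement"
        endo = endorsement_frequencies(cohort)
        data_io.write_table(endo, out / "endorsement_frequencies.csv")

        stage = "census"
        theoretical = configural.count_diagnostic_configurations(cohort.rule)
        (out / "configuration_counts.json").write_text(
            json.dumps(theoretical, indent=2)
        )
        adhd_n = int((cohort.data["group"] == "ADHD").sum())
        census_info = {"theoretical": theoretical}
        if adhd_n:
            census = configural.pattern_census(cohort, group="ADHD")
            pd.DataFrame(
                sorted(census.frequencies.items()), columns=["pattern", "frequency"]
            ).to_csv(out / "pattern_census_adhd.csv", index=False)
            census_info["observed"] = {
                "n": census.n,
                "n_unique": census.n_unique,
                "prop_unique": census.prop_unique,
                "modal_frequency": census.modal_frequency,
                "modal_patterns": list(census.modal_patterns),
            }
        manifest["stages"]["census"] = census_info

        stage = "crosstab"
        data_io.write_table(
            configural.domain_count_crosstab(cohort), out / "symptom_count_crosstab.csv"
        )

        stage = "network"
        nets: dict[str, network.SymptomNetwork] = {}
        net_info = {}
        for group in config.groups:
            profiles = cohort.group_profiles(group)
            if len(profiles) < 2:
                logger.warning("group %s too small for a network; skipped", group)
                continue
            net = network.build_network(profiles, group=group)
            net.layout = network.fr_layout(net, seed=config.seed)
            thr = network.threshold_network(net, alpha=config.alpha)
            tag = group.lower()
            data_io.write_network(net, out / f"network_{tag}_full.csv")
            data_io.write_network(thr, out / f"network_{tag}_thresholded.csv")
            data_io.write_network(net, out / f"network_{tag}_full.graphml", format="graphml")
            np.savetxt(out / f"layout_{tag}.csv", net.layout, delimiter=",")
            nets[group] = thr if config.metrics_on_thresholded else net
            n_full = int((net.weights != 0).sum() // 2)
            n_kept = int((thr.weights != 0).sum() // 2)
            n_degen = int(net.degenerate.sum())
            logger.info(
                "network %s: %d edges, %d survive FWE alpha=%.3g, %d degenerate node(s)",
                group, n_full, n_kept, config.alpha, n_degen,
            )
            net_info[group] = {
                "edges": n_full,
                "edges_surviving": n_kept,
                "degenerate_nodes": n_degen,
            }
        manifest["stages"]["network"] = net_info

        stage = "metrics"
        tables = {}
        for group, net in nets.items():
            table = graph_metrics.centrality_table(net)
            tables[group] = table
            data_io.write_table(table, out / f"centrality_{group.lower()}.csv")

        stage = "scores"
        weights_group = config.weights_group if config.weights_group in nets else next(iter(nets))
        weights_net = nets[weights_group]
        centrality = tables[weights_group]
        scores = scoring.score_cohort(
            cohort,
            centrality,
            weights_group=weights_net.group,
            thresholded=config.metrics_on_thresholded,
        )
        data_io.write_table(scores, out / "scores.csv")

        stage = "outcomes"
        if cohort.outcome_columns and adhd_n >= 3:
            results = outcome_stats.association_battery(
                scores,
                cohort,
                B=config.bootstrap_B,
                seed=config.seed,
                group=config.weights_group,
            )
            data_io.write_table(
                outcome_stats.battery_frame(results), out / "outcome_associations.csv"
            )
            manifest["stages"]["outcomes"] = {"n_results": len(results)}
        else:
            logger.info("no outcomes to analyze")
    except Exception as err:
        logger.error("pipeline stage %r failed: %s", stage, err)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _config_dict(cfg) -> dict:
    d = {}
    for f in dataclasses.fields(cfg):
        v = getattr(cfg, f.name)
        if isinstance(v, np.ndarray):
            v = v.tolist()
        elif dataclasses.is_dataclass(v):
            v = _config_dict(v)
        d[f.name] = v
    return d
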