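"""Configuration-driven orchestration of the full analysis.

Stages: synthesize (or load) a connectome cohort and genotype panel; compute
network metrics and the redundancy screen; identify hubs and class
connectivities; build the PRS grid; run the association scan.  Every stage
writes tab-delimited outputs plus a JSON run manifest, and reruns with the
same config are file-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics, stats
from .hubs import classify_edges, class_connectivity
from .networks import (SUBNETWORKS, THRESHOLD_SWEEP, ConnectomeError,
                       apply_streamline_threshold, load_atlas, load_connectome,
                       threshold_with_mask)
from .prs import P_THRESHOLDS, build_score_panel
from .synthetic import (Cohort, CohortConfig, GenotypePanelConfig, PlantedEffect,
                        cohort_hub_partition, generate_cohort,
                        generate_genotype_panel, plant_prs_effect,
                        resolve_phenotype, simulate_score_panel)

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


class ConfigError(ValueError):
    """Raised when a run configuration fails validation."""


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    output_dir: str = "connectoprs_out"
    cohort: dict = field(default_factory=dict)
    genotype_panel: dict | None = field(default_factory=dict)
    connectome_dir: str | None = None
    covariate_file: str | None = None
    weightings: tuple[str, ...] = ("NS", "FA")
    threshold: int = 5
    sweep: tuple[int, ...] = ()
    subnetworks: tuple[str, ...] = SUBNETWORKS
    redundancy_cutoff: float = 0.85
    hub_sample: int | None = None
    clump_r2: float = 0.1
    planted_effects: tuple[dict, ...] = ()
    score_source: str = "genotypes"  # or "simulated"
    q: float = 0.05
    n_perm: int = 1000
    minp: str = "flagged"
    cooks_factor: float | None = 3.0
    ancestry_components: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.subnetworks) - set(SUBNETWORKS)
        if unknown:
            raise ConfigError(f"unknown subnetwork name(s): {sorted(unknown)}")
        if any(w not in ("NS", "FA") for w in self.weightings):
            raise ConfigError(f"weightings must be NS/FA, got {self.weightings}")
        if self.threshold not in THRESHOLD_SWEEP:
            raise ConfigError("threshold must lie in 1..12")
        if any(t not in THRESHOLD_SWEEP for t in self.sweep):
            raise ConfigError("sweep thresholds must lie in 1..12")
        if self.score_source not in ("genotypes", "simulated"):
            raise ConfigError("score_source must be 'genotypes' or 'simulated'")
        if self.minp not in ("all", "flagged", "none"):
            raise ConfigError("minp must be 'all', 'flagged' or 'none'")
        try:
            CohortConfig(**{**self.cohort, "seed": 0})
        except Exception as exc:
            raise ConfigError(f"invalid cohort spec: {exc}") from exc


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _load_cohort_from_files(cfg: RunConfig) -> Cohort:
    cov = pd.read_csv(cfg.covariate_file, sep="\t", index_col=0)
    ns_mats, fa_mats = [], []
    base = Path(cfg.connectome_dir)
    for pid in cov.index:
        ns = load_connectome(base / f"{pid}_NS.txt", "NS", participant_id=str(pid))
        fa_path = base / f"{pid}_FA.txt"
        if fa_path.exists():
            fa = load_connectome(fa_path, "FA", node_labels=ns.node_labels,
                                 participant_id=str(pid))
        else:
            raise ConnectomeError(f"missing FA matrix for participant {pid}")
        ns_mats.append(ns)
        fa_mats.append(fa)
    cohort_cfg = CohortConfig(n_participants=max(len(cov), 3),
                              n_nodes=ns_mats[0].n_nodes, seed=cfg.seed)
    return Cohort(ns_mats, fa_mats, cov, (), cohort_cfg)


def stage_simulate(cfg: RunConfig) -> Cohort:
    if cfg.connectome_dir:
        return _load_cohort_from_files(cfg)
    cohort_cfg = CohortConfig(**{"seed": cfg.seed, **cfg.cohort})
    return generate_cohort(cohort_cfg)


def _thresholded_matrix(cohort: Cohort, i: int, weighting: str, t: int):
    if weighting == "NS":
        return apply_streamline_threshold(cohort.ns_matrices[i], t, override=True)
    return threshold_with_mask(cohort.fa_matrices[i], cohort.ns_matrices[i], t,
                               override=True)


def stage_metrics(cohort: Cohort, cfg: RunConfig, threshold: int | None = None):
    """Per-network summary-metric tables and redundancy screens.

    Returns ``(summaries, screens)``: ``summaries[(weighting, network)]`` is a
    participant-by-metric table; ``screens`` the matching redundancy screens.
    """
    t = cfg.threshold if threshold is None else threshold
    atlas = load_atlas() if cohort.ns_matrices[0].n_nodes == 90 else None
    summaries: dict[tuple[str, str], pd.DataFrame] = {}
    screens = {}
    for weighting in cfg.weightings:
        nets = cfg.subnetworks if atlas is not None else ("whole_brain",)
        rows: dict[str, list[dict]] = {net: [] for net in nets}
        for i in range(len(cohort.ns_matrices)):
            m = _thresholded_matrix(cohort, i, weighting, t)
            for net in nets:
                sub = m if net == "whole_brain" else _extract(m, atlas, net)
                rows[net].append(metrics.network_summary(sub))
        for net in nets:
            df = pd.DataFrame(rows[net], index=cohort.participant_ids)
            summaries[(weighting, net)] = df
            screens[(weighting, net)] = metrics.metric_redundancy_prune(
                df[list(metrics.SUMMARY_METRICS)], cutoff=cfg.redundancy_cutoff)
    return summaries, screens


def _extract(m, atlas, net):
    from .networks import extract_subnetwork
    return extract_subnetwork(m, atlas.subnetwork(net))


def stage_hubs(cohort: Cohort, cfg: RunConfig, threshold: int | None = None):
    """Hub partitions per weighting plus per-participant class connectivities."""
    t = cfg.threshold if threshold is None else threshold
    partitions, conn = {}, {}
    for weighting in cfg.weightings:
        part = cohort_hub_partition(cohort, weighting, t, hub_sample=cfg.hub_sample)
        partitions[weighting] = part
        records = []
        for i, pid in enumerate(cohort.participant_ids):
            m = _thresholded_matrix(cohort, i, weighting, t)
            records.append(class_connectivity(m, part))
        conn[weighting] = pd.DataFrame(records, index=cohort.participant_ids)
    return partitions, conn


def stage_prs(cfg: RunConfig, cohort: Cohort):
    """Score panel: genotype-based scoring or direct simulation, with planting."""
    planted = {}
    planted_meta = []
    for spec in cfg.planted_effects:
        eff = PlantedEffect(spec["target_phenotype"], spec["effect_r"])
        score_name = spec.get("score", "genome_wide")
        pheno = resolve_phenotype(cohort, eff.target_phenotype,
                                  threshold=cfg.threshold,
                                  hub_sample=cfg.hub_sample)
        planted[score_name] = plant_prs_effect(pheno, eff, seed=cfg.seed + 1000)
        planted_meta.append({**spec, "score": score_name})
    if cfg.score_source == "simulated" or cfg.genotype_panel is None:
        scores = simulate_score_panel(cohort.participant_ids, planted,
                                      seed=cfg.seed + 2000)
        return scores, planted_meta
    panel_cfg = GenotypePanelConfig(**{
        "seed": cfg.seed + 3000,
        "n_individuals": len(cohort.participant_ids),
        **cfg.genotype_panel,
    })
    result = generate_genotype_panel(panel_cfg)
    panel = build_score_panel(result.sumstats, result.genotypes,
                              clump_r2=cfg.clump_r2)
    scores = panel.scores.set_axis(cohort.participant_ids, axis=0)
    for name, vec in planted.items():
        from .prs import PRSConfig
        for pt in P_THRESHOLDS:
            for apoe in (True, False):
                scores[PRSConfig(name, apoe, pt).column] = vec.to_numpy()
    return scores, planted_meta


def build_phenotype_table(summaries, screens, conn, weighting: str) -> pd.DataFrame:
    """Retained metrics of every network plus the three class connectivities."""
    blocks = []
    for (w, net), df in summaries.items():
        if w != weighting:
            continue
        retained = screens[(w, net)].retained
        blocks.append(df[list(retained)].rename(
            columns={m: f"{net}_{m}" for m in retained}))
    conn_df = conn[weighting].rename(columns={c: f"{c}_connectivity"
                                              for c in conn[weighting].columns})
    blocks.append(conn_df)
    return pd.concat(blocks, axis=1)


def stage_scan(phenotypes: pd.DataFrame, scores: pd.DataFrame,
               covariates: pd.DataFrame, cfg: RunConfig) -> stats.ScanResult:
    return stats.run_scan(phenotypes, scores, covariates, q=cfg.q,
                          cooks_factor=cfg.cooks_factor, n_perm=cfg.n_perm,
                          seed=cfg.seed + 4000, minp=cfg.minp)


def ancestry_components_table(index, n_components: int, seed: int = 0) -> pd.DataFrame:
    """Synthetic ancestry principal components (standard-normal surrogate PCs)."""
    rng = np.random.default_rng(seed)
    cols = {f"PC{i + 1}": rng.standard_normal(len(index))
            for i in range(n_components)}
    return pd.DataFrame(cols, index=index)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run(cfg: RunConfig) -> dict:
    """Execute every stage and write the output bundle.

    Outputs: metric tables and correlation screens per network, retained-
    metric lists, hub lists, edge-class maps, class connectivities, the score
    panel, association tables (per NS threshold if a sweep is configured) and
    a JSON run manifest.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings = {}

    def _stage(name, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except ConfigError:
            raise
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        timings[name] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s done in %.2fs", name, timings[name])
        return result

    cohort = _stage("simulate", stage_simulate, cfg)
    cohort.covariates.to_csv(out / "covariates.tsv", sep="\t")

    summaries, screens = _stage("metrics", stage_metrics, cohort, cfg)
    for (w, net), df in summaries.items():
        df.to_csv(out / f"metrics_{w}_{net}.tsv", sep="\t", float_format=_FLOAT_FMT)
        screens[(w, net)].correlations.to_csv(
            out / f"metric_correlations_{w}_{net}.tsv", sep="\t",
            float_format=_FLOAT_FMT)
    retained_rows = [{"weighting": w, "network": net,
                      "retained": ",".join(screens[(w, net)].retained)}
                     for (w, net) in screens]
    pd.DataFrame(retained_rows).to_csv(out / "retained_metrics.tsv", sep="\t",
                                       index=False)

    partitions, conn = _stage("hubs", stage_hubs, cohort, cfg)
    for w, part in partitions.items():
        part.mean_hubness.rename("mean_hubness").to_csv(
            out / f"hubness_{w}.tsv", sep="\t", float_format=_FLOAT_FMT)
        pd.Series(part.hub_nodes, name="hub").to_csv(
            out / f"hubs_{w}.tsv", sep="\t", index=False)
        classify_edges(part).to_csv(out / f"edge_classes_{w}.tsv", sep="\t",
                                    index=False)
        conn[w].to_csv(out / f"class_connectivity_{w}.tsv", sep="\t",
                       float_format=_FLOAT_FMT)

    scores, planted_meta = _stage("prs", stage_prs, cfg, cohort)
    scores.to_csv(out / "score_panel.tsv", sep="\t", float_format=_FLOAT_FMT)

    scan_results = {}
    sensitivity_results = {}
    for w in cfg.weightings:
        phenos = build_phenotype_table(summaries, screens, conn, w)
        res = _stage(f"scan_{w}", stage_scan, phenos, scores,
                     cohort.covariates, cfg)
        res.table.to_csv(out / f"associations_{w}.tsv", sep="\t", index=False,
                         float_format=_FLOAT_FMT)
        scan_results[w] = res
        if cfg.ancestry_components > 0:
            # sensitivity re-run: append ancestry principal components to the
            # covariates and re-execute the scan (population-stratification check)
            pcs = ancestry_components_table(cohort.participant_ids,
                                            cfg.ancestry_components,
                                            seed=cfg.seed + 5000)
            cov_ext = pd.concat([cohort.covariates, pcs], axis=1)
            sens = _stage(f"scan_{w}_ancestry", stage_scan, phenos, scores,
                          cov_ext, cfg)
            sens.table.to_csv(out / f"associations_{w}_ancestry.tsv", sep="\t",
                              index=False, float_format=_FLOAT_FMT)
            sensitivity_results[w] = sens

    sweep_results = {}
    for t in cfg.sweep:
        summaries_t, screens_t = _stage(f"metrics_t{t}", stage_metrics, cohort, cfg, t)
        _, conn_t = _stage(f"hubs_t{t}", stage_hubs, cohort, cfg, t)
        for w in cfg.weightings:
            phenos = build_phenotype_table(summaries_t, screens_t, conn_t, w)
            res = _stage(f"scan_{w}_t{t}", stage_scan, phenos, scores,
                         cohort.covariates, cfg)
            res.table.to_csv(out / f"associations_{w}_t{t}.tsv", sep="\t",
                             index=False, float_format=_FLOAT_FMT)
            sweep_results[(w, t)] = res

    manifest = {
        "config": _jsonable(asdict(cfg)),
        "planted_effects": planted_meta,
        "n_participants": int(len(cohort.participant_ids)),
        "hubs": {w: list(p.hub_nodes) for w, p in partitions.items()},
        "timings_s": timings,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {"cohort": cohort, "summaries": summaries, "screens": screens,
            "partitions": partitions, "class_connectivity": conn,
            "scores": scores, "scan": scan_results, "sweep": sweep_results,
            "sensitivity": sensitivity_results, "manifest": manifest}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
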