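"""End-to-end orchestration of the repositioning pipeline.

Stages run in the workflow order — (1) paired differential expression,
(2) machine-learning consensus filter, (3) topological classification,
(4) common-pathway analysis, (5) drug screening and meta-analysis,
(6) target mapping — separately for each disease stage label (early,
late). Every stage reads and writes plain TSV/JSON under the working
directory, so any stage can be rerun from its persisted inputs or fed
real data in place of the simulated tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io
from .deg import degs_to_frame, paired_differential_expression, split_and_floor_signature
from .drug_meta import ScreenReport, ScreenThresholds, jaccard_index, meta_results_to_frame, screen_drugs
from .enrichment import common_pathways, hypergeometric_ora
from .errors import ConfigurationError, InputError
from .ml_consensus import extract_gene_features, intersect_dataset_predictions, train_and_vote
from .synthetic import (
    STAGES,
    GroundTruth,
    SimulationConfig,
    planted_deg_sets,
    simulate_drug_library,
    simulate_expression_study,
    simulate_gene_set_collection,
    simulate_ppi_and_annotations,
)
from .target_mapping import map_drug_targets, rank_hub_neighbors
from .topology import build_regulated_network, cards_to_frame, compute_topological_parameters, score_and_select_key_genes

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Thresholds and paths of one pipeline run.

    All probability thresholds must lie in (0, 1); the config is
    serialized (with its hash) into every run report.
    """

    workdir: Path = Path("metasig_run")
    alpha_deg: float = 0.05
    moderation: bool = False
    fc_floor: float = 5.64
    top_frac: float = 0.2
    ora_alpha: float = 0.05
    cmap_p_strict: float = 0.1
    cmap_p_loose: float = 0.5
    p_ma_strict: float = 0.05
    p_ma_loose: float = 0.1
    topo_drug_p: float = 0.05
    min_datasets: int = 2
    i2_model_p: float = 0.1
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        self.workdir = Path(self.workdir)
        for name in (
            "alpha_deg",
            "top_frac",
            "ora_alpha",
            "cmap_p_strict",
            "cmap_p_loose",
            "p_ma_strict",
            "p_ma_loose",
            "topo_drug_p",
            "i2_model_p",
        ):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigurationError(f"{name} must lie in (0, 1), got {v}")
        if self.min_datasets < 1:
            raise ConfigurationError("min_datasets must be >= 1")
        if not isinstance(self.simulation, SimulationConfig):
            self.simulation = SimulationConfig(**dict(self.simulation))
        self.simulation = self.simulation.with_seed(self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["workdir"] = str(self.workdir)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", {})
        cfg = cls(**raw)
        if sim:
            cfg.simulation = SimulationConfig(**{**sim, "seed": cfg.seed})
        return cfg

    def thresholds(self) -> ScreenThresholds:
        return ScreenThresholds(
            cmap_p_strict=self.cmap_p_strict,
            cmap_p_loose=self.cmap_p_loose,
            p_ma_strict=self.p_ma_strict,
            p_ma_loose=self.p_ma_loose,
            topo_p=self.topo_drug_p,
            min_datasets=self.min_datasets,
            model_p_threshold=self.i2_model_p,
        )

    # canonical artifact paths -------------------------------------------
    def inputs_dir(self) -> Path:
        return self.workdir / "inputs"

    def stage_dir(self, stage: str) -> Path:
        return self.workdir / stage


# --- stage: simulate ------------------------------------------------------

def stage_simulate(config: PipelineConfig) -> GroundTruth:
    """Generate every pipeline input with known ground truth.

    Drug connectivity records stand in for per-dataset connectivity-map
    output and are generated against the *planted* per-dataset signatures,
    so downstream stages consume them purely as data.
    """
    sim = config.simulation
    inputs = config.inputs_dir()
    inputs.mkdir(parents=True, exist_ok=True)
    truth = GroundTruth()

    ppi, domains, labels, t = simulate_ppi_and_annotations(sim)
    truth = truth.merge(t)
    io.write_edge_list(ppi, inputs / "ppi.tsv")
    io.write_domains(domains, inputs / "domains.tsv")
    io.write_labels(labels, inputs / "labels.tsv")

    for stage in STAGES:
        sdir = inputs / stage
        sdir.mkdir(parents=True, exist_ok=True)
        signatures = {}
        for d in range(sim.n_datasets):
            study, t = simulate_expression_study(sim, d, stage)
            truth = truth.merge(t)
            io.write_expression_study(study, sdir / study.dataset_id)
            signatures[study.dataset_id] = t.deg_genes
        records, targets, t = simulate_drug_library(sim, signatures, stage)
        truth = truth.merge(t)
        io.write_drug_records(records, sdir / "drug_records.tsv")
        io.write_drug_targets(targets, sdir / "drug_targets.tsv")
        io.write_gmt(simulate_gene_set_collection(sim, stage), sdir / "genesets.gmt")

    io.write_ground_truth(truth, inputs / "ground_truth.json")
    logger.info("synthetic inputs written under %s", inputs)
    return truth


def _dataset_ids(config: PipelineConfig, stage: str) -> list[str]:
    sdir = config.inputs_dir() / stage
    ids = sorted(p.name[: -len(".expr.tsv")] for p in sdir.glob("*.expr.tsv"))
    if not ids:
        raise InputError(f"no expression studies found under {sdir}")
    return ids


# --- stage: differential expression --------------------------------------

def stage_deg(config: PipelineConfig, stage: str) -> dict[str, dict]:
    out = config.stage_dir(stage)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict[str, dict] = {}
    for ds in _dataset_ids(config, stage):
        study = io.read_expression_study(config.inputs_dir() / stage / ds)
        degs = paired_differential_expression(study, config.alpha_deg, config.moderation)
        degs_to_frame(degs).to_csv(out / f"deg_{ds}.tsv", sep="\t", index=False)
        if degs:
            sig = split_and_floor_signature(degs, config.fc_floor)
            io.write_gene_list(sig.up, out / f"signature_up_{ds}.txt")
            io.write_gene_list(sig.down, out / f"signature_down_{ds}.txt")
            summary[ds] = {"n_deg": len(degs), "n_up": len(sig.up), "n_down": len(sig.down)}
        else:
            summary[ds] = {"n_deg": 0, "n_up": 0, "n_down": 0}
    return summary


def _read_deg_sets(config: PipelineConfig, stage: str) -> dict[str, dict[str, set[str]]]:
    import pandas as pd

    out = config.stage_dir(stage)
    per_ds: dict[str, dict[str, set[str]]] = {}
    for ds in _dataset_ids(config, stage):
        frame = pd.read_csv(out / f"deg_{ds}.tsv", sep="\t")
        if frame.empty:
            per_ds[ds] = {"up": set(), "down": set()}
            continue
        per_ds[ds] = {
            "up": set(frame.loc[frame["direction"] == "up", "gene"].astype(str)),
            "down": set(frame.loc[frame["direction"] == "down", "gene"].astype(str)),
        }
    return per_ds


# --- stage: machine-learning consensus -----------------------------------

def stage_ml(config: PipelineConfig, stage: str) -> dict:
    inputs = config.inputs_dir()
    out = config.stage_dir(stage)
    ppi = io.read_edge_list(inputs / "ppi.tsv")
    domains = io.read_domains(inputs / "domains.tsv")
    labels = io.read_labels(inputs / "labels.tsv")
    per_ds = _read_deg_sets(config, stage)

    all_degs = set().union(*(s["up"] | s["down"] for s in per_ds.values()))
    features = extract_gene_features(set(ppi.nodes), ppi, domains, labels)
    usable = {f.gene for f in features}
    result = train_and_vote(
        features, candidates=sorted(all_degs & usable), seed=config.seed
    )
    result.metrics.to_csv(out / "ml_metrics.tsv", sep="\t")

    selections = []
    rows = []
    for ds in sorted(per_ds):
        degs = per_ds[ds]["up"] | per_ds[ds]["down"]
        net = degs & usable
        predicted = result.selected & net
        selections.append(predicted)
        io.write_gene_list(predicted, out / f"ml_predicted_{ds}.txt")
        rows.append(
            {
                "dataset": ds,
                "n_deg": len(degs),
                "excluded": len(degs - usable),
                "net": len(net),
                "predicted": len(predicted),
            }
        )
    common = intersect_dataset_predictions(selections)
    io.write_gene_list(common, out / "ml_key_genes.txt")

    import pandas as pd

    table2 = pd.DataFrame(rows)
    table2["common"] = len(common)
    table2.to_csv(out / "ml_summary.tsv", sep="\t", index=False)
    return {"per_dataset": rows, "n_key_genes": len(common)}


# --- stage: topological classification -----------------------------------

def stage_topo(config: PipelineConfig, stage: str) -> dict:
    inputs = config.inputs_dir()
    out = config.stage_dir(stage)
    ppi = io.read_edge_list(inputs / "ppi.tsv")
    per_ds = _read_deg_sets(config, stage)

    key_genes: set[str] = set()
    counts = {}
    for direction in ("up", "down"):
        common = set.intersection(*(per_ds[ds][direction] for ds in per_ds))
        counts[f"common_{direction}"] = len(common)
        if not common & set(ppi.nodes):
            logger.warning("no common %s-regulated DEG maps to the PPI", direction)
            counts[f"key_{direction}"] = 0
            continue
        net, deg_nodes = build_regulated_network(common, ppi)
        cards = compute_topological_parameters(net, deg_nodes)
        selected, _ = score_and_select_key_genes(cards, config.top_frac)
        cards_to_frame(cards).to_csv(out / f"topo_scorecard_{direction}.tsv", sep="\t")
        counts[f"key_{direction}"] = len(selected)
        key_genes |= selected
    io.write_gene_list(key_genes, out / "topo_key_genes.txt")
    return {**counts, "n_key_genes": len(key_genes)}


# --- stage: enrichment ----------------------------------------------------

def stage_enrich(config: PipelineConfig, stage: str) -> dict:
    inputs = config.inputs_dir()
    out = config.stage_dir(stage)
    collection = io.read_gmt(inputs / stage / "genesets.gmt")
    # universe: all genes measured in the stage's expression studies
    ds0 = _dataset_ids(config, stage)[0]
    study = io.read_expression_study(inputs / stage / ds0)
    universe = set(map(str, study.genes))

    tables = {}
    for route in ("ml", "topo"):
        genes = io.read_gene_list(out / f"{route}_key_genes.txt") & universe
        if not genes:
            logger.warning("%s route produced no key genes; enrichment skipped", route)
            import pandas as pd

            tables[route] = pd.DataFrame(
                columns=["pathway", "overlap", "set_size", "query_size", "universe_size", "p", "adj_p"]
            )
        else:
            tables[route] = hypergeometric_ora(genes, collection, universe, config.ora_alpha)
        tables[route].to_csv(out / f"enrichment_{route}.tsv", sep="\t", index=False)
    common = common_pathways(tables["ml"], tables["topo"])
    common.to_csv(out / "common_pathways.tsv", sep="\t", index=False)
    return {
        "n_enriched_ml": int(len(tables["ml"])),
        "n_enriched_topo": int(len(tables["topo"])),
        "n_common_pathways": int(len(common)),
    }


# --- stage: drug screening ------------------------------------------------

def stage_drugs(config: PipelineConfig, stage: str) -> dict:
    inputs = config.inputs_dir()
    out = config.stage_dir(stage)
    records = io.read_drug_records(inputs / stage / "drug_records.tsv")
    report = screen_drugs(records, config.thresholds())

    meta_results_to_frame(report.meta.values()).to_csv(out / "drug_meta.tsv", sep="\t")
    for label, drugs in sorted(report.condition_sets.items()):
        io.write_gene_list(drugs, out / f"drugs_condition_{label}.txt")
    io.write_gene_list(report.ml_drugs, out / "drugs_ml.txt")
    io.write_gene_list(report.topo_drugs, out / "drugs_topo.txt")
    io.write_gene_list(report.common_drugs, out / "drugs_common.txt")

    sets = {**report.condition_sets, "ml": report.ml_drugs, "topo": report.topo_drugs}
    names = sorted(sets)
    ji = {
        a: {b: round(jaccard_index(sets[a], sets[b]), 3) for b in names} for a in names
    }
    overlap = {
        a: {b: len(sets[a] & sets[b]) for b in names} for a in names
    }
    io.write_json({"jaccard": ji, "overlap": overlap}, out / "drug_set_comparison.json")

    counts = {f"condition_{c}": len(s) for c, s in sorted(report.condition_sets.items())}
    counts.update(
        n_ml=len(report.ml_drugs),
        n_topo=len(report.topo_drugs),
        n_common=len(report.common_drugs),
    )
    return counts


# --- stage: target mapping ------------------------------------------------

def stage_targets(config: PipelineConfig, stage: str) -> dict:
    inputs = config.inputs_dir()
    out = config.stage_dir(stage)
    ppi = io.read_edge_list(inputs / "ppi.tsv")
    targets = io.read_drug_targets(inputs / stage / "drug_targets.tsv")
    common_drugs = io.read_gene_list(out / "drugs_common.txt")
    key_genes = io.read_gene_list(out / "ml_key_genes.txt") | io.read_gene_list(
        out / "topo_key_genes.txt"
    )

    table = map_drug_targets(common_drugs, targets, key_genes)
    table.to_csv(out / "drug_targets_ranked.tsv", sep="\t", index=False)
    result = {"n_targets": int(len(table)), "top_neighbors": []}
    if not table.empty:
        ranking, sub = rank_hub_neighbors(set(table["gene"]), ppi)
        ranking.to_csv(out / "hub_neighbors.tsv", sep="\t", index=False)
        io.write_edge_list(sub, out / "target_subgraph.tsv")
        result["top_neighbors"] = [
            {"gene": str(r.gene), "n_targets": int(r.n_targets), "rank": int(r.rank)}
            for r in ranking.itertuples(index=False)
        ]
    return result


# --- full run -------------------------------------------------------------

STAGE_ORDER = ("deg", "ml", "topo", "enrich", "drugs", "targets")

_STAGE_FUNCS = {
    "deg": stage_deg,
    "ml": stage_ml,
    "topo": stage_topo,
    "enrich": stage_enrich,
    "drugs": stage_drugs,
    "targets": stage_targets,
}


def run_pipeline(config: PipelineConfig, simulate: bool = True) -> dict:
    """Run every stage for both disease-stage labels; return the run report.

    The report (also written to ``<workdir>/report.json``) is a
    deterministic function of the configuration and seed: rerunning with
    the same config yields a byte-identical file.
    """
    report: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    if simulate:
        stage_simulate(config)
    for stage in STAGES:
        report["stages"][stage] = {}
        for name in STAGE_ORDER:
            logger.info("running stage %s (%s)", name, stage)
            try:
                report["stages"][stage][name] = _STAGE_FUNCS[name](config, stage)
            except Exception as exc:
                raise RuntimeError(
                    f"pipeline stage {name!r} failed for stage label {stage!r}: {exc}"
                ) from exc
    io.write_json(report, config.workdir / "report.json")
    return report
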