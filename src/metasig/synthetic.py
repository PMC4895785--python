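"""Synthetic inputs for the drug-repositioning pipeline.

Everything the pipeline consumes — paired tumor/normal expression studies,
a protein–protein interaction (PPI) network with domain and cancer-label
annotations, gene-set collections, and a drug library of per-dataset
connectivity records — can be generated here with known ground truth, so
parameter-recovery tests can compare pipeline output against what was
planted.

The statistical structure mirrors the assumptions of the downstream
analysis:

* expression studies are paired (tumor and normal tissue from the same
  patient), with differentially expressed genes planted at a fixed log2
  fold-change and a shared per-dataset batch shift — the between-study
  heterogeneity that the meta-analysis Q/I² machinery is meant to detect;
* the PPI graph has a heavy-tailed (preferential-attachment) degree
  distribution with one post-hoc planted hub wired to the planted
  differential genes, emulating a high-degree connector such as UBC;
* a known subset of drugs is "effective": their reversal gene sets are
  seeded from the planted signature, so their enrichment scores are
  negative and reproducible across datasets, while null drugs carry random
  reversal sets and calibrated (uniform) permutation p-values.

All generators are deterministic functions of ``SimulationConfig.seed``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

STAGES = ("early", "late")

# rng stream tags: one per generator so adding a generator never perturbs
# the draws of another
_TAG_DEG_PLANT = 100
_TAG_EXPRESSION = 101
_TAG_PPI = 202
_TAG_DRUGS = 303
_TAG_GENESETS = 404


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the simulated study.

    Defaults describe the stated world of the pipeline's verification
    suite: four microarray-sized datasets of 20 tumor/normal pairs, 10%
    of genes differentially expressed at |log2FC| = 2 with measurement
    noise sd 0.3, and a 500-drug library of which 4% reverse the planted
    signature.
    """

    n_genes: int = 2000
    n_pairs: int = 20
    n_datasets: int = 4
    frac_deg: float = 0.1
    effect_log2fc: float = 2.0
    noise_sd: float = 0.3
    batch_sd: float = 0.2
    frac_cancer_genes: float = 0.1
    n_drugs: int = 500
    frac_effective_drugs: float = 0.04
    reversal_overlap: float = 0.8
    es_noise_sd: float = 0.05
    n_permutations: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_pairs", "n_datasets", "n_drugs", "n_permutations"):
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(f"{name} must be a positive integer")
        for name in ("frac_deg", "frac_cancer_genes", "frac_effective_drugs"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigurationError(f"{name} must lie strictly in (0, 1)")
        if not 0.0 < self.reversal_overlap <= 1.0:
            raise ConfigurationError("reversal_overlap must lie in (0, 1]")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if self.batch_sd < 0 or self.es_noise_sd < 0:
            raise ConfigurationError("batch_sd and es_noise_sd must be non-negative")
        if self.frac_deg * self.n_genes < 1:
            raise ConfigurationError("frac_deg * n_genes must plant at least one DEG")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=int(seed))


@dataclass
class GroundTruth:
    """What was planted, for parameter-recovery tests."""

    deg_up: set[str] = field(default_factory=set)
    deg_down: set[str] = field(default_factory=set)
    cancer_genes: set[str] = field(default_factory=set)
    effective_drugs: set[str] = field(default_factory=set)
    hub_gene: str | None = None

    @property
    def deg_genes(self) -> set[str]:
        return self.deg_up | self.deg_down

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        return GroundTruth(
            deg_up=self.deg_up | other.deg_up,
            deg_down=self.deg_down | other.deg_down,
            cancer_genes=self.cancer_genes | other.cancer_genes,
            effective_drugs=self.effective_drugs | other.effective_drugs,
            hub_gene=other.hub_gene or self.hub_gene,
        )

    def to_dict(self) -> dict:
        return {
            "deg_up": sorted(self.deg_up),
            "deg_down": sorted(self.deg_down),
            "cancer_genes": sorted(self.cancer_genes),
            "effective_drugs": sorted(self.effective_drugs),
            "hub_gene": self.hub_gene,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            deg_up=set(d.get("deg_up", ())),
            deg_down=set(d.get("deg_down", ())),
            cancer_genes=set(d.get("cancer_genes", ())),
            effective_drugs=set(d.get("effective_drugs", ())),
            hub_gene=d.get("hub_gene"),
        )


@dataclass
class ExpressionStudy:
    """Paired tumor/normal log2 expression matrix for one dataset."""

    dataset_id: str
    stage: str
    matrix: pd.DataFrame  # genes x samples, log2 scale
    pairs: list[tuple[str, str, str]]  # (pair id, tumor column, normal column)

    def __post_init__(self) -> None:
        cols = set(self.matrix.columns)
        for pid, tcol, ncol in self.pairs:
            if tcol not in cols or ncol not in cols:
                raise InputError(f"pair {pid} references missing columns")
        if self.matrix.isna().any().any():
            raise InputError("expression matrix contains missing values")
        if self.stage not in STAGES:
            raise InputError(f"stage must be one of {STAGES}")

    @property
    def genes(self) -> pd.Index:
        return self.matrix.index

    def paired_differences(self) -> pd.DataFrame:
        """Tumor − normal log2 differences, one column per pair."""
        t = self.matrix[[p[1] for p in self.pairs]].to_numpy()
        n = self.matrix[[p[2] for p in self.pairs]].to_numpy()
        return pd.DataFrame(
            t - n, index=self.matrix.index, columns=[p[0] for p in self.pairs]
        )


def gene_universe(config: SimulationConfig) -> list[str]:
    return [f"G{i:05d}" for i in range(config.n_genes)]


def drug_universe(config: SimulationConfig) -> list[str]:
    return [f"drug{i:04d}" for i in range(config.n_drugs)]


def _stage_code(stage: str) -> int:
    if stage not in STAGES:
        raise InputError(f"unknown stage {stage!r}")
    return STAGES.index(stage)


def planted_deg_sets(config: SimulationConfig, stage: str) -> tuple[set[str], set[str]]:
    """The (up, down) gene sets planted for a stage, shared by all its datasets."""
    rng = np.random.default_rng([config.seed, _TAG_DEG_PLANT, _stage_code(stage)])
    genes = gene_universe(config)
    n_deg = int(round(config.frac_deg * config.n_genes))
    chosen = rng.choice(config.n_genes, size=n_deg, replace=False)
    half = n_deg // 2
    up = {genes[i] for i in chosen[:half]} if half else set()
    down = {genes[i] for i in chosen[half:]}
    return up, down


def dataset_batch_shift(config: SimulationConfig, dataset_index: int, stage: str) -> float:
    """The per-dataset additive shift on planted effects (the heterogeneity source)."""
    rng = np.random.default_rng(
        [config.seed, _TAG_EXPRESSION, _stage_code(stage), int(dataset_index), 7]
    )
    return float(rng.normal(0.0, config.batch_sd)) if config.batch_sd > 0 else 0.0


def simulate_expression_study(
    config: SimulationConfig, dataset_index: int, stage: str = "early"
) -> tuple[ExpressionStudy, GroundTruth]:
    """Simulate one paired tumor/normal dataset with planted fold-changes.

    Planted genes get a tumor − normal mean shift of ±``effect_log2fc``
    plus a shared per-dataset batch shift (sd ``batch_sd``); every other
    gene has zero mean shift. Measurement noise is i.i.d. Gaussian with sd
    ``noise_sd`` on the log2 scale, independently for tumor and normal
    columns.
    """
    if not 0 <= dataset_index < config.n_datasets:
        raise ConfigurationError(
            f"dataset_index {dataset_index} out of range [0, {config.n_datasets})"
        )
    sc = _stage_code(stage)
    up, down = planted_deg_sets(config, stage)
    genes = gene_universe(config)
    rng = np.random.default_rng([config.seed, _TAG_EXPRESSION, sc, int(dataset_index)])

    n_g, n_p = config.n_genes, config.n_pairs
    baseline = rng.normal(7.0, 1.0, size=n_g)
    shift = dataset_batch_shift(config, dataset_index, stage)
    delta = np.zeros(n_g)
    up_mask = np.fromiter((g in up for g in genes), bool, count=n_g)
    down_mask = np.fromiter((g in down for g in genes), bool, count=n_g)
    delta[up_mask] = config.effect_log2fc + shift
    delta[down_mask] = -config.effect_log2fc + shift

    normal = baseline[:, None] + rng.normal(0.0, config.noise_sd, size=(n_g, n_p))
    tumor = (
        baseline[:, None]
        + delta[:, None]
        + rng.normal(0.0, config.noise_sd, size=(n_g, n_p))
    )

    pairs = [(f"P{i:02d}", f"P{i:02d}_T", f"P{i:02d}_N") for i in range(n_p)]
    cols: dict[str, np.ndarray] = {}
    for i, (_, tcol, ncol) in enumerate(pairs):
        cols[tcol] = tumor[:, i]
        cols[ncol] = normal[:, i]
    matrix = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
    study = ExpressionStudy(
        dataset_id=f"DS{dataset_index}", stage=stage, matrix=matrix, pairs=pairs
    )
    return study, GroundTruth(deg_up=up, deg_down=down)


def simulate_ppi_and_annotations(
    config: SimulationConfig, hub_degree: int | None = None
) -> tuple[nx.Graph, dict[str, tuple[str, ...]], dict[str, str], GroundTruth]:
    """Simulate a PPI network plus domain and cancer-label annotations.

    The graph is a preferential-attachment (Barabási–Albert) graph over the
    gene universe with one post-hoc planted hub: a non-differential gene
    rewired to every planted differential gene of both stages (and padded
    with random partners until it strictly dominates all other degrees).
    Cancer labels are grown over neighborhoods, and cancer genes draw their
    protein domains preferentially from a small "cancer domain" pool, so
    the downstream classifier features (CLD, DFS, DDI propensity) are
    informative.

    Returns ``(graph, domains, labels, truth)`` where ``domains`` maps
    gene → tuple of 1–4 domain ids and ``labels`` maps gene →
    ``{"cancer", "non-cancer", "unknown"}``.
    """
    if config.n_genes < 10:
        raise ConfigurationError("need at least 10 genes to build a PPI network")
    if hub_degree is not None and hub_degree > config.n_genes - 1:
        raise ConfigurationError(
            f"requested hub degree {hub_degree} exceeds n_genes - 1"
        )
    genes = gene_universe(config)
    rng = np.random.default_rng([config.seed, _TAG_PPI])
    ba_seed = int(rng.integers(0, 2**31 - 1))
    graph = nx.barabasi_albert_graph(config.n_genes, m=3, seed=ba_seed)
    graph = nx.relabel_nodes(graph, dict(enumerate(genes)))

    planted: set[str] = set()
    for stage in STAGES:
        up, down = planted_deg_sets(config, stage)
        planted |= up | down

    non_deg = [g for g in genes if g not in planted]
    hub = non_deg[int(rng.integers(len(non_deg)))]
    graph.add_edges_from((hub, g) for g in planted if g != hub)
    target_deg = hub_degree or 0
    others = [g for g in genes if g != hub]
    candidates = [g for g in others if not graph.has_edge(hub, g)]
    rng.shuffle(candidates)
    # pad until the hub strictly dominates every other degree (an added edge
    # also raises its endpoint's degree, so re-check after every addition)
    for g in candidates:
        max_other = max(graph.degree(u) for u in others)
        if graph.degree(hub) >= max(target_deg, max_other + 1):
            break
        graph.add_edge(hub, g)
    if graph.degree(hub) <= max(graph.degree(u) for u in others):
        raise ConfigurationError("could not plant a strictly dominant hub")

    # cancer labels: seed from planted DEGs, then grow over neighborhoods
    n_cancer = int(round(config.frac_cancer_genes * config.n_genes))
    cancer: set[str] = set()
    seed_pool = sorted(planted)
    rng.shuffle(seed_pool)
    cancer.update(seed_pool[: max(1, n_cancer // 3)])
    frontier = sorted(cancer)
    while len(cancer) < n_cancer:
        src = frontier[int(rng.integers(len(frontier)))]
        nbrs = [u for u in graph.neighbors(src) if u not in cancer and u != hub]
        if nbrs:
            pick = nbrs[int(rng.integers(len(nbrs)))]
        else:
            pool = [g for g in genes if g not in cancer and g != hub]
            pick = pool[int(rng.integers(len(pool)))]
        cancer.add(pick)
        frontier.append(pick)
    cancer = set(sorted(cancer)[:n_cancer])

    n_domains = max(20, config.n_genes // 10)
    all_domains = [f"D{i:04d}" for i in range(n_domains)]
    cancer_domains = all_domains[: max(2, n_domains // 10)]
    domains: dict[str, tuple[str, ...]] = {}
    for g in genes:
        k = int(rng.integers(1, 5))
        pool = cancer_domains if (g in cancer and rng.random() < 0.7) else all_domains
        picked = rng.choice(len(pool), size=min(k, len(pool)), replace=False)
        domains[g] = tuple(sorted(pool[i] for i in picked))

    labels: dict[str, str] = {}
    for g in genes:
        if g in cancer:
            labels[g] = "cancer"
        else:
            labels[g] = "non-cancer" if rng.random() < 0.8 else "unknown"

    truth = GroundTruth(cancer_genes=cancer, hub_gene=hub)
    return graph, domains, labels, truth


def _normalize_signatures(
    signatures: dict[str, object],
) -> dict[str, frozenset[str]]:
    """Accept per-dataset signatures as a set or an (up, down) pair."""
    out: dict[str, frozenset[str]] = {}
    for ds, sig in signatures.items():
        if isinstance(sig, tuple) and len(sig) == 2:
            merged = frozenset(sig[0]) | frozenset(sig[1])
        else:
            merged = frozenset(sig)  # type: ignore[arg-type]
        if not merged:
            raise InputError(f"signature for dataset {ds} is empty")
        out[ds] = merged
    if not out:
        raise InputError("no dataset signatures supplied")
    return out


@dataclass(frozen=True)
class DrugSignatureRecord:
    """One (drug, dataset) connectivity record: the meta-analysis unit."""

    drug: str
    dataset: str
    es: float  # enrichment score in [-1, 1]; negative = signature reversal
    p: float  # permutation p-value in (0, 1]
    n: int  # sample size behind the record, for V_z = 1/(n-3)


def simulate_drug_library(
    config: SimulationConfig,
    signatures: dict[str, object],
    stage: str = "early",
) -> tuple[list[DrugSignatureRecord], dict[str, set[str]], GroundTruth]:
    """Simulate per-dataset drug connectivity records and a drug→target table.

    Each *effective* drug carries a reversal gene set seeded with
    ``reversal_overlap`` of the (union) planted signature; per dataset its
    enrichment score is ``-(|reversal ∩ signature| / |signature|)`` plus the
    dataset's heterogeneity shift and Gaussian noise, clipped to [−1, 1].
    Null drugs carry random reversal sets of the same size. The p-value is
    a label-permutation p with the add-one correction ``(b+1)/(B+1)``; the
    permutation null is sampled through the equivalent hypergeometric
    overlap distribution, with the same noise and dataset shift applied, so
    null p-values are calibrated (approximately uniform).

    Effective drugs get 1–3 target genes from the planted signature; null
    drugs get random targets.
    """
    if config.n_permutations < 20:
        raise ConfigurationError(
            "n_permutations must be at least 20 for usable p-value resolution"
        )
    sigs = _normalize_signatures(signatures)
    sc = _stage_code(stage)
    rng = np.random.default_rng([config.seed, _TAG_DRUGS, sc])
    genes = gene_universe(config)
    drugs = drug_universe(config)
    n_eff = max(1, int(round(config.frac_effective_drugs * config.n_drugs)))
    eff_idx = rng.choice(config.n_drugs, size=n_eff, replace=False)
    effective = {drugs[i] for i in eff_idx}

    union_sig = sorted(frozenset().union(*sigs.values()))
    n_seed = max(1, int(math.ceil(config.reversal_overlap * len(union_sig))))
    rev_size = min(len(genes), n_seed + 5)

    reversal: dict[str, frozenset[str]] = {}
    for d in drugs:
        if d in effective:
            seeded = rng.choice(len(union_sig), size=n_seed, replace=False)
            rev = {union_sig[i] for i in seeded}
            extra = rng.choice(config.n_genes, size=rev_size - len(rev), replace=False)
            rev |= {genes[i] for i in extra}
        else:
            picked = rng.choice(config.n_genes, size=rev_size, replace=False)
            rev = {genes[i] for i in picked}
        reversal[d] = frozenset(rev)

    # per-dataset heterogeneity shift on ES, scaled to the score's range
    ds_ids = sorted(sigs)
    es_shift = {
        ds: float(rng.normal(0.0, 0.5 * config.batch_sd)) if config.batch_sd else 0.0
        for ds in ds_ids
    }

    n_arrays = 2 * config.n_pairs
    B = config.n_permutations
    records: list[DrugSignatureRecord] = []
    for ds in ds_ids:
        sig = sigs[ds]
        m = len(sig)
        for d in drugs:
            rev = reversal[d]
            obs = (
                -(len(rev & sig) / m)
                + es_shift[ds]
                + float(rng.normal(0.0, config.es_noise_sd))
            )
            es = float(np.clip(obs, -1.0, 1.0))
            null_ov = rng.hypergeometric(m, config.n_genes - m, len(rev), size=B)
            null_es = np.clip(
                -(null_ov / m) + es_shift[ds] + rng.normal(0.0, config.es_noise_sd, B),
                -1.0,
                1.0,
            )
            p = (int(np.sum(null_es <= es)) + 1) / (B + 1)
            records.append(DrugSignatureRecord(d, ds, es, float(p), n_arrays))

    targets: dict[str, set[str]] = {}
    for d in drugs:
        k = int(rng.integers(1, 4))
        if d in effective:
            picked = rng.choice(len(union_sig), size=min(k, len(union_sig)), replace=False)
            targets[d] = {union_sig[i] for i in picked}
        else:
            picked = rng.choice(config.n_genes, size=k, replace=False)
            targets[d] = {genes[i] for i in picked}

    return records, targets, GroundTruth(effective_drugs=effective)


def simulate_gene_set_collection(
    config: SimulationConfig, stage: str = "early", n_sets: int = 50
) -> dict[str, set[str]]:
    """Named gene sets (a GMT-style collection) over the gene universe.

    A handful of sets are enriched with planted differential genes so
    over-representation analysis has signal to find; the rest are random.
    """
    rng = np.random.default_rng([config.seed, _TAG_GENESETS, _stage_code(stage)])
    genes = gene_universe(config)
    up, down = planted_deg_sets(config, stage)
    planted = sorted(up | down)
    collection: dict[str, set[str]] = {}
    for i in range(n_sets):
        size = int(rng.integers(10, 101))
        name = f"PATHWAY_{i:03d}"
        if i < max(3, n_sets // 10) and planted:
            n_sig = min(len(planted), max(3, size // 2))
            sig_part = rng.choice(len(planted), size=n_sig, replace=False)
            members = {planted[j] for j in sig_part}
            pad = rng.choice(config.n_genes, size=size - len(members), replace=False)
            members |= {genes[j] for j in pad}
        else:
            picked = rng.choice(config.n_genes, size=size, replace=False)
            members = {genes[j] for j in picked}
        collection[name] = members
    return collection
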