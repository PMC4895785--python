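"""Plain-text readers and writers for every pipeline artifact.

All stage I/O is TSV, GMT or JSON so any stage can be rerun from its
persisted inputs, or fed real data (e.g. genuine connectivity-map exports)
in place of the simulated tables.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from .errors import InputError
from .synthetic import DrugSignatureRecord, ExpressionStudy, GroundTruth


# --- expression -----------------------------------------------------------

def write_expression_study(study: ExpressionStudy, prefix: Path) -> None:
    """Write ``<prefix>.expr.tsv`` (genes x samples) and ``<prefix>.samples.tsv``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    study.matrix.to_csv(f"{prefix}.expr.tsv", sep="\t")
    rows = []
    for pid, tcol, ncol in study.pairs:
        rows.append((tcol, pid, "tumor", study.stage, study.dataset_id))
        rows.append((ncol, pid, "normal", study.stage, study.dataset_id))
    pd.DataFrame(
        rows, columns=["column", "pair_id", "tissue", "stage", "dataset_id"]
    ).to_csv(f"{prefix}.samples.tsv", sep="\t", index=False)


def read_expression_study(prefix: Path) -> ExpressionStudy:
    prefix = Path(prefix)
    matrix = pd.read_csv(f"{prefix}.expr.tsv", sep="\t", index_col=0)
    if matrix.isna().any().any():
        raise InputError(f"{prefix}.expr.tsv contains missing values")
    sidecar = pd.read_csv(f"{prefix}.samples.tsv", sep="\t")
    pairs = []
    for pid, grp in sidecar.groupby("pair_id", sort=True):
        tumor = grp.loc[grp["tissue"] == "tumor", "column"]
        normal = grp.loc[grp["tissue"] == "normal", "column"]
        if len(tumor) != 1 or len(normal) != 1:
            raise InputError(f"pair {pid} must have exactly one tumor and one normal column")
        pairs.append((str(pid), tumor.iloc[0], normal.iloc[0]))
    return ExpressionStudy(
        dataset_id=str(sidecar["dataset_id"].iloc[0]),
        stage=str(sidecar["stage"].iloc[0]),
        matrix=matrix,
        pairs=pairs,
    )


# --- network and annotations ---------------------------------------------

def write_edge_list(graph: nx.Graph, path: Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{a}\t{b}\n")


def read_edge_list(path: Path) -> nx.Graph:
    frame = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    g.add_edges_from(zip(frame.iloc[:, 0].astype(str), frame.iloc[:, 1].astype(str)))
    g.remove_edges_from(nx.selfloop_edges(g))
    return g


def write_domains(domains: dict[str, tuple[str, ...]], path: Path) -> None:
    rows = [(g, d) for g in sorted(domains) for d in domains[g]]
    pd.DataFrame(rows, columns=["gene", "domain"]).to_csv(path, sep="\t", index=False)


def read_domains(path: Path) -> dict[str, tuple[str, ...]]:
    frame = pd.read_csv(path, sep="\t")
    out: dict[str, list[str]] = {}
    for g, d in zip(frame["gene"].astype(str), frame["domain"].astype(str)):
        out.setdefault(g, []).append(d)
    return {g: tuple(sorted(ds)) for g, ds in out.items()}


def write_labels(labels: dict[str, str], path: Path) -> None:
    pd.DataFrame(
        sorted(labels.items()), columns=["gene", "label"]
    ).to_csv(path, sep="\t", index=False)


def read_labels(path: Path) -> dict[str, str]:
    frame = pd.read_csv(path, sep="\t")
    return dict(zip(frame["gene"].astype(str), frame["label"].astype(str)))


# --- gene sets (GMT) ------------------------------------------------------

def write_gmt(collection: dict[str, set[str]], path: Path, source: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for name in sorted(collection):
            members = sorted(collection[name])
            if not members:
                raise InputError(f"gene set {name} is empty")
            fh.write("\t".join([name, source, *members]) + "\n")


def read_gmt(path: Path) -> dict[str, set[str]]:
    collection: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise InputError(f"malformed GMT line: {line[:60]!r}")
            collection[fields[0]] = set(fields[2:])
    return collection


# --- drugs ----------------------------------------------------------------

def write_drug_records(records: Iterable[DrugSignatureRecord], path: Path) -> None:
    pd.DataFrame(
        [(r.drug, r.dataset, r.es, r.p, r.n) for r in records],
        columns=["drug", "dataset", "es", "p", "n"],
    ).to_csv(path, sep="\t", index=False)


def read_drug_records(path: Path) -> list[DrugSignatureRecord]:
    frame = pd.read_csv(path, sep="\t")
    return [
        DrugSignatureRecord(str(r.drug), str(r.dataset), float(r.es), float(r.p), int(r.n))
        for r in frame.itertuples(index=False)
    ]


def write_drug_targets(targets: dict[str, set[str]], path: Path) -> None:
    rows = [(d, g) for d in sorted(targets) for g in sorted(targets[d])]
    pd.DataFrame(rows, columns=["drug", "target"]).to_csv(path, sep="\t", index=False)


def read_drug_targets(path: Path) -> dict[str, set[str]]:
    frame = pd.read_csv(path, sep="\t")
    out: dict[str, set[str]] = {}
    for d, g in zip(frame["drug"].astype(str), frame["target"].astype(str)):
        out.setdefault(d, set()).add(g)
    return out


# --- misc -----------------------------------------------------------------

def write_gene_list(genes: Iterable[str], path: Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(set(genes))))


def read_gene_list(path: Path) -> set[str]:
    return {line.strip() for line in Path(path).read_text().splitlines() if line.strip()}


def write_ground_truth(truth: GroundTruth, path: Path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=2, sort_keys=True))


def read_ground_truth(path: Path) -> GroundTruth:
    return GroundTruth.from_dict(json.loads(Path(path).read_text()))


def write_json(obj, path: Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))
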