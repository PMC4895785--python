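"""Machine-learning key-gene filter with strict uniform voting.

Candidate genes (per-dataset DEGs) are described by three network/annotation
features and scored by five classifiers of distinct families; a gene is
selected only when *all five* predict it to be a cancer protein ("strictly
uniform voting"). Per-dataset selections are then intersected across
datasets to give the ML-route key genes.

Features per gene:

``cld``
    cancer linker degree — the number of PPI partners labelled cancer
    (``cld_frac`` is the fraction of partners so labelled).
``dfs``
    weighted domain frequency score — the mean, over the gene's domains
    ``d``, of ``c_d / (c_d + n_d)`` where ``c_d`` and ``n_d`` count
    labelled cancer / non-cancer proteins carrying ``d`` (0 when neither
    carries it). ``max`` aggregation is available as an option.
``ddi_propensity``
    of the domain-pair types (d, d') formed between the gene's domains and
    its neighbors' domains, the fraction for which some observed
    interacting carrier pair is cancer/cancer.

Genes without domain annotation or PPI membership are excluded from
candidacy (and logged); genes with unknown labels are never used for
training, only scored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

LABELS = ("cancer", "non-cancer", "unknown")
FEATURE_COLUMNS = ("cld", "cld_frac", "dfs", "ddi_propensity")


@dataclass(frozen=True)
class GeneFeatureVector:
    gene: str
    cld: int
    cld_frac: float
    dfs: float
    ddi_propensity: float
    label: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise InputError(f"unknown label {self.label!r} for gene {self.gene}")
        if not (0.0 <= self.dfs <= 1.0 and 0.0 <= self.ddi_propensity <= 1.0):
            raise InputError(f"feature out of [0, 1] for gene {self.gene}")


def _cancer_ddi_types(
    ppi: nx.Graph, domains: dict[str, Sequence[str]], labels: dict[str, str]
) -> set[tuple[str, str]]:
    """Domain-pair types observed on at least one cancer/cancer interaction.

    Pair types are unordered (stored sorted) and collected over every edge
    of the network whose two endpoints are both labelled cancer.
    """
    types: set[tuple[str, str]] = set()
    for a, b in ppi.edges():
        if labels.get(a) == "cancer" and labels.get(b) == "cancer":
            for da in domains.get(a, ()):
                for db in domains.get(b, ()):
                    types.add((da, db) if da <= db else (db, da))
    return types


def extract_gene_features(
    genes: Iterable[str],
    ppi: nx.Graph,
    domains: dict[str, Sequence[str]],
    labels: dict[str, str],
    dfs_aggregate: str = "mean",
) -> list[GeneFeatureVector]:
    """Compute CLD / DFS / DDI-propensity features for ``genes``.

    Genes missing from the PPI network or lacking domain annotation are
    excluded and logged, mirroring the pipeline's stated exclusion rule.
    Output order follows sorted gene id, so feature extraction is
    independent of the input ordering.
    """
    if dfs_aggregate not in ("mean", "max"):
        raise ConfigurationError("dfs_aggregate must be 'mean' or 'max'")

    # domain occurrence counts among labelled proteins
    c_count: dict[str, int] = {}
    n_count: dict[str, int] = {}
    for g, doms in domains.items():
        lab = labels.get(g, "unknown")
        if lab == "cancer":
            for d in set(doms):
                c_count[d] = c_count.get(d, 0) + 1
        elif lab == "non-cancer":
            for d in set(doms):
                n_count[d] = n_count.get(d, 0) + 1

    cancer_types = _cancer_ddi_types(ppi, domains, labels)

    out: list[GeneFeatureVector] = []
    excluded = 0
    for g in sorted(set(genes)):
        if g not in ppi:
            excluded += 1
            logger.debug("gene %s excluded: not in the PPI network", g)
            continue
        doms = tuple(domains.get(g, ()))
        if not doms:
            excluded += 1
            logger.debug("gene %s excluded: no domain annotation", g)
            continue
        nbrs = list(ppi.neighbors(g))
        cld = sum(1 for u in nbrs if labels.get(u) == "cancer")
        cld_frac = cld / len(nbrs) if nbrs else 0.0

        scores = []
        for d in set(doms):
            c, n = c_count.get(d, 0), n_count.get(d, 0)
            scores.append(c / (c + n) if (c + n) else 0.0)
        dfs = (max(scores) if dfs_aggregate == "max" else float(np.mean(scores))) if scores else 0.0

        pair_types: set[tuple[str, str]] = set()
        for u in nbrs:
            for da in doms:
                for db in domains.get(u, ()):
                    pair_types.add((da, db) if da <= db else (db, da))
        ddi = (
            sum(1 for t in pair_types if t in cancer_types) / len(pair_types)
            if pair_types
            else 0.0
        )
        out.append(
            GeneFeatureVector(
                gene=g,
                cld=cld,
                cld_frac=cld_frac,
                dfs=dfs,
                ddi_propensity=ddi,
                label=labels.get(g, "unknown"),
            )
        )
    if excluded:
        logger.info("%d gene(s) excluded for missing PPI or domain data", excluded)
    return out


def features_to_frame(features: list[GeneFeatureVector]) -> pd.DataFrame:
    return pd.DataFrame(
        [(f.gene, f.cld, f.cld_frac, f.dfs, f.ddi_propensity, f.label) for f in features],
        columns=["gene", *FEATURE_COLUMNS, "label"],
    ).set_index("gene")


def default_classifiers(seed: int = 0) -> dict[str, object]:
    """Five classifier families behind a common fit/predict contract.

    tree (CART-like decision tree), rule (depth-1 stump, a one-rule
    learner), locally-weighted (distance-weighted kNN), ensemble-of-trees
    (random forest) and regularized linear (L2 logistic regression).
    """
    return {
        "tree": DecisionTreeClassifier(random_state=seed),
        "rule": DecisionTreeClassifier(max_depth=1, random_state=seed),
        "locally_weighted": Pipeline(
            [
                ("scale", StandardScaler()),
                ("knn", KNeighborsClassifier(n_neighbors=5, weights="distance")),
            ]
        ),
        "ensemble_trees": RandomForestClassifier(n_estimators=100, random_state=seed),
        "regularized_linear": Pipeline(
            [
                ("scale", StandardScaler()),
                ("logit", LogisticRegression(C=1.0, max_iter=1000, random_state=seed)),
            ]
        ),
    }


@dataclass
class VotingResult:
    selected: set[str]  # genes predicted cancer by every classifier
    per_classifier: dict[str, set[str]]  # classifier name -> positive genes
    metrics: pd.DataFrame  # cross-validated hit ratio / F1 / AUC per classifier
    n_train_per_class: int


def train_and_vote(
    features: list[GeneFeatureVector],
    candidates: Iterable[str] | None = None,
    balance: bool = True,
    folds: int = 10,
    seed: int = 0,
    classifiers: dict[str, object] | None = None,
    min_class_size: int = 20,
) -> VotingResult:
    """Train five classifiers on labelled genes and vote on candidates.

    Training uses only genes labelled cancer / non-cancer, down-sampled to
    equal class counts when ``balance`` is set (seeded). Hit ratio
    (accuracy), F1 and AUC are cross-validated with ``folds`` stratified
    folds on the balanced training set. Candidates (default: every input
    gene) are selected iff all five classifiers predict "cancer".
    """
    frame = features_to_frame(features)
    if candidates is None:
        cand = list(frame.index)
    else:
        cand = sorted(set(candidates) & set(frame.index))

    labelled = frame[frame["label"].isin(["cancer", "non-cancer"])]
    pos = labelled[labelled["label"] == "cancer"]
    neg = labelled[labelled["label"] == "non-cancer"]
    if len(pos) == 0 or len(neg) == 0:
        raise InputError("both cancer and non-cancer labels are required for training")

    rng = np.random.default_rng(seed)
    if balance:
        n = min(len(pos), len(neg))
        pos = pos.iloc[np.sort(rng.choice(len(pos), size=n, replace=False))]
        neg = neg.iloc[np.sort(rng.choice(len(neg), size=n, replace=False))]
    if min(len(pos), len(neg)) < min_class_size:
        raise InputError(
            f"need at least {min_class_size} labelled genes per class after "
            f"balancing; got {min(len(pos), len(neg))}"
        )

    train = pd.concat([pos, neg])
    X = train[list(FEATURE_COLUMNS)].to_numpy(float)
    y = (train["label"] == "cancer").to_numpy(int)
    Xc = frame.loc[cand, list(FEATURE_COLUMNS)].to_numpy(float)

    models = classifiers if classifiers is not None else default_classifiers(seed)
    if len(models) != 5:
        raise ConfigurationError(
            f"strict uniform voting expects 5 classifier families, got {len(models)}"
        )

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    metric_rows = []
    per_clf: dict[str, set[str]] = {}
    for name, model in models.items():
        y_pred = np.empty_like(y)
        y_score = np.empty(len(y), float)
        for tr_idx, te_idx in skf.split(X, y):
            m = clone(model)
            m.fit(X[tr_idx], y[tr_idx])
            y_pred[te_idx] = m.predict(X[te_idx])
            if hasattr(m, "predict_proba"):
                y_score[te_idx] = m.predict_proba(X[te_idx])[:, 1]
            else:
                y_score[te_idx] = y_pred[te_idx]
        metric_rows.append(
            {
                "classifier": name,
                "hit_ratio": float(np.mean(y_pred == y)),
                "f1": float(f1_score(y, y_pred)),
                "auc": float(roc_auc_score(y, y_score)),
            }
        )
        model.fit(X, y)
        positive = model.predict(Xc).astype(bool)
        per_clf[name] = {g for g, flag in zip(cand, positive) if flag}

    selected = set(cand)
    for s in per_clf.values():
        selected &= s
    return VotingResult(
        selected=selected,
        per_classifier=per_clf,
        metrics=pd.DataFrame(metric_rows).set_index("classifier"),
        n_train_per_class=int(min(len(pos), len(neg))),
    )


def intersect_dataset_predictions(
    per_dataset_selections: Sequence[set[str]],
) -> set[str]:
    """Key genes common to every dataset's consensus selection."""
    if not per_dataset_selections:
        raise InputError("at least one dataset selection is required")
    common = set(per_dataset_selections[0])
    for s in per_dataset_selections[1:]:
        common &= set(s)
    if not common:
        logger.warning("no key gene is common to all datasets")
    return common
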