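"""Paired differential expression and query-signature export.

Each dataset pairs a tumor sample with a normal sample from the same
patient, so genes are tested on the per-pair log2 differences with a
paired t-test, followed by Benjamini–Hochberg adjustment across genes.
Input matrices are assumed already log2-normalized. Optional variance
moderation shrinks each gene's difference variance halfway toward the
across-gene mean variance — a lightweight stand-in for empirical-Bayes
moderation that stabilizes small-sample statistics.

The exported query signature splits significant genes by direction and
floors the *exported* linear fold-change magnitude at 5.64, a convention
of connectivity-map searches; the floor never touches the log2FC used
anywhere else in the pipeline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from .synthetic import ExpressionStudy

logger = logging.getLogger(__name__)

#: weight of the pooled (across-gene mean) variance under moderation
MODERATION_PRIOR_WEIGHT = 0.5

#: exported linear fold-change floor for connectivity-map style queries
DEFAULT_FC_FLOOR = 5.64

_P_FLOOR = 1e-300


@dataclass(frozen=True)
class DEGRecord:
    gene: str
    log2fc: float  # mean paired tumor - normal difference
    t: float
    p: float
    adj_p: float
    direction: str  # "up" iff log2fc > 0

    def __post_init__(self) -> None:
        if (self.direction == "up") != (self.log2fc > 0):
            raise InputError(f"direction/log2FC sign mismatch for {self.gene}")


def paired_differential_expression(
    study: ExpressionStudy, alpha: float = 0.05, moderation: bool = False
) -> list[DEGRecord]:
    """Call differentially expressed genes from one paired study.

    Returns only genes with BH-adjusted p < ``alpha``, each labelled
    up/down by the sign of the mean paired difference. Genes with exactly
    zero mean difference are never called (their direction is undefined).

    A gene whose paired differences have zero variance but a nonzero mean
    is reported at the machine p-value floor with a warning, with the t
    statistic set to ±inf.
    """
    if not 0.0 < alpha < 1.0:
        raise InputError("alpha must lie in (0, 1)")
    if len(study.pairs) < 3:
        raise InputError("paired testing requires at least 3 tumor/normal pairs")

    diffs = study.paired_differences().to_numpy()
    n = diffs.shape[1]
    mean = diffs.mean(axis=1)
    var = diffs.var(axis=1, ddof=1)
    if moderation:
        var = MODERATION_PRIOR_WEIGHT * var.mean() + (1 - MODERATION_PRIOR_WEIGHT) * var

    zero_var = var == 0.0
    degenerate = zero_var & (mean != 0.0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} gene(s) with zero difference variance and "
            "nonzero mean; p-value set to the machine floor",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    t_degenerate = np.where(mean > 0, np.inf, np.where(mean < 0, -np.inf, 0.0))
    t = np.where(zero_var, t_degenerate, t)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p = np.where(degenerate, _P_FLOOR, p)
    p = np.where(zero_var & ~degenerate, 1.0, p)  # all-zero differences: no evidence
    p = np.clip(p, _P_FLOOR, 1.0)

    adj_p = multipletests(p, method="fdr_bh")[1]
    records = []
    genes = study.genes
    for i in np.flatnonzero((adj_p < alpha) & (mean != 0.0)):
        records.append(
            DEGRecord(
                gene=str(genes[i]),
                log2fc=float(mean[i]),
                t=float(t[i]),
                p=float(p[i]),
                adj_p=float(adj_p[i]),
                direction="up" if mean[i] > 0 else "down",
            )
        )
    logger.info(
        "dataset %s (%s): %d/%d genes significant at adjusted p < %g",
        study.dataset_id,
        study.stage,
        len(records),
        len(genes),
        alpha,
    )
    return records


@dataclass(frozen=True)
class QuerySignature:
    """Up/down gene sets plus the exported (floored) linear fold-changes."""

    up: frozenset[str]
    down: frozenset[str]
    exported_fc: dict[str, float]  # gene -> floored linear |FC|

    @property
    def genes(self) -> frozenset[str]:
        return self.up | self.down


def split_and_floor_signature(
    degs: list[DEGRecord], floor: float = DEFAULT_FC_FLOOR
) -> QuerySignature:
    """Split DEGs by direction and floor the exported fold-change magnitude.

    The exported linear magnitude is ``max(2**|log2FC|, floor)``; the
    original log2FC is left untouched for every other use.
    """
    if not degs:
        raise InputError("cannot build a query signature from an empty DEG list")
    up = frozenset(r.gene for r in degs if r.direction == "up")
    down = frozenset(r.gene for r in degs if r.direction == "down")
    if not up or not down:
        warnings.warn("query signature has an empty up or down set", stacklevel=2)
    exported = {r.gene: max(2.0 ** abs(r.log2fc), floor) for r in degs}
    return QuerySignature(up=up, down=down, exported_fc=exported)


def degs_to_frame(degs: list[DEGRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.gene, r.log2fc, r.t, r.p, r.adj_p, r.direction) for r in degs],
        columns=["gene", "log2FC", "t", "p", "adj_p", "direction"],
    )
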