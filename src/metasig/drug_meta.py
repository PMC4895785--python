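"""Meta-analysis of per-dataset drug connectivity records and drug screening.

Each drug carries one (ES, p, n) record per dataset, where ES in [-1, 1]
is a connectivity-map style enrichment score (negative = the drug profile
reverses the disease signature) and p is the per-dataset p-value. The
records of one drug are combined two ways:

* Fisher's method pools the per-dataset p-values:
  F = -2 * sum(ln p_j), referred to a chi-square with 2k degrees of
  freedom;
* an effect-size meta-analysis treats ES like a correlation coefficient,
  Fisher z-transforms it (z = arctanh ES, variance 1/(n-3)), and combines
  the z values with inverse-variance weights. Cochran's Q (squared
  deviations), I2 = max(0, (Q - df)/Q) * 100 and the chi-square p of Q
  choose between the fixed-effect model (Q p-value >= 0.1) and a
  DerSimonian-Laird random-effects model.

The weighted Z statistic is sum(W_i Y_i) / sqrt(sum(W_i^2)) — the form
that reduces to the unweighted Z = M / SE_M when all study variances are
equal — and the one-tailed meta p-value (p_MA) comes from its lower
normal tail, because drug efficacy is encoded as negative ES throughout.

Screening applies four filter conditions on the records:

    A  ES < 0 and per-dataset p < 0.1, meta over surviving records
    B  ES < 0 and per-dataset p < 0.5, meta over surviving records
    C  ES < 0, meta over all negative records, keep p_MA < 0.05
    D  ES < 0, meta over all negative records, keep p_MA < 0.1

The ML-route drug set is the union of the four conditions (A and B also
require survival in >= ``min_datasets`` datasets and p_MA < 0.05); the
topology route keeps drugs with ES < 0 and p < 0.05 in >= ``min_datasets``
datasets. Set overlap is quantified with the Jaccard index.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .synthetic import DrugSignatureRecord

logger = logging.getLogger(__name__)

_ES_CLIP = 1.0 - 1e-6


def fisher_combined_p(p_values: Sequence[float]) -> tuple[float, float]:
    """Fisher's combined probability: F = -2 sum(ln p), chi-square(2k) tail."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise InputError("no p-values to combine")
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise InputError("p-values must lie in (0, 1]")
    F = float(-2.0 * np.sum(np.log(p)))
    return F, float(stats.chi2.sf(F, df=2 * p.size))


def es_z_transform(es: float) -> float:
    """Fisher z-transform of an enrichment score, z = arctanh(ES).

    |ES| >= 1 is clipped just inside the open interval with a warning
    (the transform diverges at the endpoints).
    """
    if abs(es) > 1.0:
        raise InputError(f"enrichment score {es} outside [-1, 1]")
    if abs(es) >= _ES_CLIP:
        warnings.warn(f"ES = {es} clipped to +/-{_ES_CLIP} before z-transform", stacklevel=2)
        es = math.copysign(_ES_CLIP, es)
    return float(np.arctanh(es))


def z_to_es(z: float) -> float:
    """Inverse of :func:`es_z_transform`."""
    return float(np.tanh(z))


@dataclass
class MetaResult:
    drug: str
    k: int
    F: float
    fisher_p: float
    M: float
    V_M: float
    SE_M: float
    LL_M: float
    UL_M: float
    Z_unweighted: float
    Z_weighted: float
    p_MA: float
    Q: float
    df: int
    I2: float
    q_p: float
    model: str  # "fixed" | "random"
    tau2: float
    M_backtransformed: float


def _weighted_summary(Y: np.ndarray, W: np.ndarray) -> tuple[float, float, float]:
    M = float(np.sum(W * Y) / np.sum(W))
    V_M = float(1.0 / np.sum(W))
    return M, V_M, math.sqrt(V_M)


def effect_size_meta(
    records: Sequence[DrugSignatureRecord], model_p_threshold: float = 0.1
) -> MetaResult:
    """Combine one drug's per-dataset records into a :class:`MetaResult`.

    Heterogeneity is judged by the chi-square upper tail of Cochran's Q
    (squared deviations): the fixed-effect model is kept when that p is at
    least ``model_p_threshold`` (default 0.1), else DerSimonian-Laird
    random effects re-weight the summary. A single record yields Q = 0,
    df = 0, I2 = 0 and the fixed model by convention.
    """
    recs = list(records)
    if not recs:
        raise InputError("no records to meta-analyze")
    drug = recs[0].drug
    if any(r.drug != drug for r in recs):
        raise InputError("records mix several drugs")
    if any(r.n < 4 for r in recs):
        raise InputError("each record needs n >= 4 so that 1/(n-3) is positive")

    k = len(recs)
    Y = np.array([es_z_transform(r.es) for r in recs])
    V = np.array([1.0 / (r.n - 3) for r in recs])
    W = 1.0 / V

    M, V_M, SE_M = _weighted_summary(Y, W)
    if k == 1:
        Q, df, I2, q_p = 0.0, 0, 0.0, 1.0
        logger.debug("drug %s: single record, heterogeneity undefined", drug)
    else:
        df = k - 1
        Q = float(np.sum(W * (Y - M) ** 2))
        I2 = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0
        q_p = float(stats.chi2.sf(Q, df=df))

    if q_p >= model_p_threshold:
        model, tau2 = "fixed", 0.0
        W_used = W
    else:
        model = "random"
        c = float(np.sum(W) - np.sum(W**2) / np.sum(W))
        tau2 = max(0.0, (Q - df) / c) if c > 0 else 0.0
        W_used = 1.0 / (V + tau2)
    M, V_M, SE_M = _weighted_summary(Y, W_used)

    LL_M, UL_M = M - 1.96 * SE_M, M + 1.96 * SE_M
    # unweighted Z: all weights unity -> M_u / SE_u
    M_u = float(np.mean(Y))
    Z_unweighted = M_u / math.sqrt(1.0 / k)
    Z_weighted = float(np.sum(W_used * Y) / math.sqrt(np.sum(W_used**2)))
    p_MA = float(stats.norm.cdf(Z_weighted))  # lower tail: efficacy = negative ES

    F, fisher_p = fisher_combined_p([r.p for r in recs])
    return MetaResult(
        drug=drug,
        k=k,
        F=F,
        fisher_p=fisher_p,
        M=M,
        V_M=V_M,
        SE_M=SE_M,
        LL_M=LL_M,
        UL_M=UL_M,
        Z_unweighted=Z_unweighted,
        Z_weighted=Z_weighted,
        p_MA=p_MA,
        Q=Q,
        df=df if k > 1 else 0,
        I2=I2,
        q_p=q_p,
        model=model,
        tau2=tau2,
        M_backtransformed=z_to_es(M),
    )


@dataclass
class ScreenThresholds:
    """Per-condition thresholds of the drug screen (pipeline defaults)."""

    cmap_p_strict: float = 0.1  # condition A per-dataset p
    cmap_p_loose: float = 0.5  # condition B per-dataset p
    p_ma_strict: float = 0.05  # conditions A/B/C retention
    p_ma_loose: float = 0.1  # condition D retention
    topo_p: float = 0.05  # topology-route per-dataset p
    min_datasets: int = 2
    model_p_threshold: float = 0.1


@dataclass
class ScreenReport:
    condition_sets: dict[str, set[str]]  # "A".."D" -> drugs
    ml_drugs: set[str]  # union of the four conditions
    topo_drugs: set[str]
    common_drugs: set[str]
    meta: dict[str, MetaResult]  # per drug, over its negative-ES records


def _by_drug(records: Iterable[DrugSignatureRecord]) -> dict[str, list[DrugSignatureRecord]]:
    groups: dict[str, list[DrugSignatureRecord]] = {}
    for r in records:
        groups.setdefault(r.drug, []).append(r)
    return groups


def screen_drugs(
    records: Iterable[DrugSignatureRecord],
    thresholds: ScreenThresholds | None = None,
) -> ScreenReport:
    """Run both screening routes over the full drug-record table."""
    th = thresholds or ScreenThresholds()
    groups = _by_drug(records)
    if not groups:
        raise InputError("no drug records supplied")

    cond: dict[str, set[str]] = {c: set() for c in "ABCD"}
    meta_cache: dict[str, MetaResult] = {}
    topo: set[str] = set()

    for drug in sorted(groups):
        recs = groups[drug]
        negative = [r for r in recs if r.es < 0]
        if not negative:
            continue  # a drug with no signature-reversing record is never screened in

        # conditions A/B: per-dataset filter, then meta over survivors
        for label, p_cut in (("A", th.cmap_p_strict), ("B", th.cmap_p_loose)):
            surviving = [r for r in negative if r.p < p_cut]
            if len({r.dataset for r in surviving}) >= th.min_datasets:
                res = effect_size_meta(surviving, th.model_p_threshold)
                if res.p_MA < th.p_ma_strict:
                    cond[label].add(drug)

        # conditions C/D: meta over all negative records
        res = effect_size_meta(negative, th.model_p_threshold)
        meta_cache[drug] = res
        if res.p_MA < th.p_ma_strict:
            cond["C"].add(drug)
        if res.p_MA < th.p_ma_loose:
            cond["D"].add(drug)

        # topology route: per-dataset significance only
        topo_hits = {r.dataset for r in negative if r.p < th.topo_p}
        if len(topo_hits) >= th.min_datasets:
            topo.add(drug)

    ml = set().union(*cond.values())
    return ScreenReport(
        condition_sets=cond,
        ml_drugs=ml,
        topo_drugs=topo,
        common_drugs=ml & topo,
        meta=meta_cache,
    )


def jaccard_index(a: Iterable[str], b: Iterable[str]) -> float:
    """|A ∩ B| / (|A| + |B| − |A ∩ B|); 0 when both sets are empty."""
    A, B = set(a), set(b)
    union = len(A) + len(B) - len(A & B)
    return len(A & B) / union if union else 0.0


def jaccard_from_counts(size_a: int, size_b: int, overlap: int) -> float:
    """Jaccard index from set cardinalities alone."""
    if overlap > min(size_a, size_b) or min(size_a, size_b, overlap) < 0:
        raise InputError("overlap must lie in [0, min(|A|, |B|)]")
    union = size_a + size_b - overlap
    return overlap / union if union else 0.0


def meta_results_to_frame(results: Iterable[MetaResult]) -> pd.DataFrame:
    rows = [vars(r) for r in results]
    return pd.DataFrame(rows).set_index("drug") if rows else pd.DataFrame()
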