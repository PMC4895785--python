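"""Fisher pooling, effect-size meta-analysis, screening, Jaccard."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from metasig import (
    DrugSignatureRecord,
    InputError,
    ScreenThresholds,
    effect_size_meta,
    es_z_transform,
    fisher_combined_p,
    jaccard_index,
    screen_drugs,
    z_to_es,
)


def rec(drug, dataset, es, p, n=40):
    return DrugSignatureRecord(drug, dataset, es, p, n)


def from_z(drug, dataset, z, v, p=0.5):
    """A record with Fisher-z effect ``z`` and variance ``v`` (= 1/(n-3))."""
    return rec(drug, dataset, math.tanh(z), p, n=round(1 / v) + 3)


# --- Fisher combined probability ----------------------------------------

def test_fisher_single_p_identity():
    F, p = fisher_combined_p([0.05])
    assert F == pytest.approx(5.991464547107982)
    assert p == pytest.approx(0.05)


def test_fisher_two_p_closed_form():
    """p = (0.1, 0.1): F = 9.2103 and the chi-square(4) tail exp(-F/2)(1+F/2)."""
    F, p = fisher_combined_p([0.1, 0.1])
    assert F == pytest.approx(9.210340371976182)
    assert p == pytest.approx(math.exp(-F / 2) * (1 + F / 2))
    assert p == pytest.approx(0.0560517, abs=1e-6)


def test_fisher_boundaries_and_guards():
    F, p = fisher_combined_p([1.0, 1.0])
    assert F == 0.0 and p == 1.0
    for bad in ([0.0], [-0.1], [1.2], []):
        with pytest.raises(InputError):
            fisher_combined_p(bad)


# --- Fisher z transform ---------------------------------------------------

def test_z_transform_values_and_roundtrip():
    assert es_z_transform(0.0) == 0.0
    assert es_z_transform(0.5) == pytest.approx(0.5 * math.log(3.0))
    rng = np.random.default_rng(0)
    for es in rng.uniform(-0.99, 0.99, size=1000):
        assert z_to_es(es_z_transform(float(es))) == pytest.approx(float(es), abs=1e-12)
    with pytest.warns(UserWarning, match="clipped"):
        z = es_z_transform(1.0)
    assert np.isfinite(z)
    with pytest.raises(InputError):
        es_z_transform(1.5)


# --- effect-size meta-analysis -------------------------------------------

def test_single_study_meta():
    """k=1: M = z(-0.5), V_M = 1/17, fixed model by convention."""
    res = effect_size_meta([rec("d", "DS0", -0.5, 0.01, n=20)])
    assert res.M == pytest.approx(es_z_transform(-0.5))
    assert res.V_M == pytest.approx(1 / 17)
    assert res.LL_M == pytest.approx(res.M - 1.96 * math.sqrt(1 / 17))
    assert res.UL_M == pytest.approx(res.M + 1.96 * math.sqrt(1 / 17))
    assert (res.Q, res.df, res.I2, res.model, res.q_p) == (0.0, 0, 0.0, "fixed", 1.0)
    assert res.M_backtransformed == pytest.approx(-0.5)


def test_two_study_fixed_effect_hand_arithmetic():
    """Y=(0.2, 0.6), V=(0.1, 0.2): W=(10,5), M=1/3, V_M=1/15, Q=0.5333, I2=0."""
    records = [from_z("d", "DS0", 0.2, 0.1), from_z("d", "DS1", 0.6, 0.2)]
    res = effect_size_meta(records)
    assert res.M == pytest.approx(1 / 3)
    assert res.V_M == pytest.approx(1 / 15)
    assert res.Q == pytest.approx(10 * (0.2 - 1 / 3) ** 2 + 5 * (0.6 - 1 / 3) ** 2)
    assert res.Q == pytest.approx(0.53333, abs=1e-5)
    assert res.I2 == 0.0  # Q < df truncates to zero
    assert res.model == "fixed"
    assert res.LL_M <= res.M <= res.UL_M


def test_two_study_random_effects_hand_arithmetic():
    """Y=(0, 4), V=(1, 1): Q=8 (p≈0.0047) selects random; tau2=7; M=2."""
    records = [from_z("d", "DS0", 0.0, 1.0), from_z("d", "DS1", 4.0, 1.0)]
    res = effect_size_meta(records)
    assert res.Q == pytest.approx(8.0)
    assert res.q_p == pytest.approx(stats.chi2.sf(8.0, 1))
    assert res.q_p < 0.1 and res.model == "random"
    assert res.tau2 == pytest.approx(7.0)
    assert res.M == pytest.approx(2.0)
    assert res.I2 == pytest.approx((8 - 1) / 8 * 100)


def test_random_with_zero_tau2_equals_fixed():
    """Forcing the random model on near-homogeneous data (Q < df, so
    tau2 = 0) reproduces the fixed-effect summary exactly."""
    records = [from_z("d", "DS0", 0.3, 0.1), from_z("d", "DS1", 0.32, 0.2)]
    fixed = effect_size_meta(records, model_p_threshold=1e-9)
    random = effect_size_meta(records, model_p_threshold=0.99)
    assert fixed.model == "fixed" and random.model == "random"
    assert random.tau2 == 0.0  # Q below df truncates tau2 to zero
    assert random.M == pytest.approx(fixed.M)
    assert random.V_M == pytest.approx(fixed.V_M)
    assert (random.LL_M, random.UL_M) == pytest.approx((fixed.LL_M, fixed.UL_M))

    identical = [from_z("d", "DS0", 0.3, 0.1), from_z("d", "DS1", 0.3, 0.2)]
    res = effect_size_meta(identical)
    assert res.Q == pytest.approx(0.0, abs=1e-12) and res.I2 == 0.0


def test_weighted_z_equals_unweighted_with_equal_variances():
    records = [from_z("d", f"DS{i}", z, 0.25) for i, z in enumerate((-0.4, -0.1, -0.6))]
    res = effect_size_meta(records)
    assert res.Z_weighted == pytest.approx(res.Z_unweighted)


def test_meta_guards():
    with pytest.raises(InputError):
        effect_size_meta([])
    with pytest.raises(InputError):
        effect_size_meta([rec("a", "DS0", -0.5, 0.1), rec("b", "DS1", -0.5, 0.1)])
    with pytest.raises(InputError):
        effect_size_meta([rec("a", "DS0", -0.5, 0.1, n=3)])


# --- screening ------------------------------------------------------------

def _toy_table():
    rng = np.random.default_rng(23)
    records = []
    for i in range(10):
        for d in range(3):
            records.append(
                rec(f"t{i:02d}", f"DS{d}", float(rng.uniform(-0.9, 0.5)),
                    float(rng.uniform(0.001, 1.0)))
            )
    # always-positive ES: excluded from every condition
    records += [rec("pos", f"DS{d}", 0.3, 0.001) for d in range(3)]
    # strongly negative, significant everywhere: caught by every condition
    records += [rec("hit", f"DS{d}", -0.8, 0.005) for d in range(3)]
    return records


def _oracle_screen(records, th: ScreenThresholds):
    """Literal transcription of the four filter conditions + topo route."""

    def meta_p(recs):
        Y = np.array([math.atanh(r.es) for r in recs])
        V = np.array([1.0 / (r.n - 3) for r in recs])
        W = 1.0 / V
        M = (W * Y).sum() / W.sum()
        if len(recs) == 1:
            q_p = 1.0
        else:
            Q = (W * (Y - M) ** 2).sum()
            q_p = stats.chi2.sf(Q, len(recs) - 1)
            if q_p < th.model_p_threshold:
                c = W.sum() - (W**2).sum() / W.sum()
                tau2 = max(0.0, (Q - (len(recs) - 1)) / c)
                W = 1.0 / (V + tau2)
        Z = (W * Y).sum() / math.sqrt((W**2).sum())
        return stats.norm.cdf(Z)

    by_drug = {}
    for r in records:
        by_drug.setdefault(r.drug, []).append(r)
    out = {c: set() for c in "ABCD"}
    topo = set()
    for drug, recs in by_drug.items():
        neg = [r for r in recs if r.es < 0]
        if not neg:
            continue
        for cond, cut in (("A", th.cmap_p_strict), ("B", th.cmap_p_loose)):
            surv = [r for r in neg if r.p < cut]
            if len({r.dataset for r in surv}) >= th.min_datasets:
                if meta_p(surv) < th.p_ma_strict:
                    out[cond].add(drug)
        p_ma = meta_p(neg)
        if p_ma < th.p_ma_strict:
            out["C"].add(drug)
        if p_ma < th.p_ma_loose:
            out["D"].add(drug)
        if len({r.dataset for r in neg if r.p < th.topo_p}) >= th.min_datasets:
            topo.add(drug)
    return out, topo


def test_screen_matches_brute_force_oracle():
    records = _toy_table()
    th = ScreenThresholds()
    report = screen_drugs(records, th)
    oracle_sets, oracle_topo = _oracle_screen(records, th)
    assert report.condition_sets == oracle_sets
    assert report.topo_drugs == oracle_topo
    assert report.ml_drugs == set().union(*oracle_sets.values())
    assert report.common_drugs == report.ml_drugs & report.topo_drugs


def test_screen_structural_properties():
    report = screen_drugs(_toy_table())
    assert "pos" not in report.ml_drugs and "pos" not in report.topo_drugs
    assert "hit" in report.condition_sets["A"]
    assert all("hit" in s for s in report.condition_sets.values())
    assert report.condition_sets["C"] <= report.condition_sets["D"]  # threshold nesting


# --- Jaccard index --------------------------------------------------------

def test_jaccard_identities():
    assert jaccard_index({"a", "b"}, {"a", "b"}) == 1.0
    assert jaccard_index({"a"}, {"b"}) == 0.0
    assert jaccard_index(set(), set()) == 0.0


@settings(deadline=None, derandomize=True, max_examples=200)
@given(
    st.sets(st.integers(0, 40), max_size=30),
    st.sets(st.integers(0, 40), max_size=30),
)
def test_jaccard_matches_set_arithmetic(a, b):
    expected = len(a & b) / len(a | b) if (a | b) else 0.0
    assert jaccard_index(a, b) == pytest.approx(expected)
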