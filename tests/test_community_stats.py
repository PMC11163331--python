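"""Distances, dbRDA + permutation ANOVA, chi-square, prevalence, strains."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency

import symbiomark as sm
from symbiomark.community_stats import exhaustive_permutation_p
from conftest import make_table


# --- distances -------------------------------------------------------------

def test_distance_examples():
    # presence sets {A,B,C} vs {B,C,D}: Jaccard 0.5
    t = make_table({
        "A": {"s1": 3, "s2": 0}, "B": {"s1": 1, "s2": 2},
        "C": {"s1": 4, "s2": 1}, "D": {"s1": 0, "s2": 5},
    })
    dm = sm.distance_matrix(t, "jaccard")
    assert dm.frame.loc["s1", "s2"] == pytest.approx(0.5)
    # counts (2,0) vs (0,2): Bray-Curtis 1.0
    t2 = make_table({"x": {"a": 2, "b": 0}, "y": {"a": 0, "b": 2}})
    assert sm.distance_matrix(t2, "bray_curtis").frame.loc["a", "b"] == pytest.approx(1.0)
    # identical samples: both metrics zero
    t3 = make_table({"x": {"a": 2, "b": 2}, "y": {"a": 1, "b": 1}})
    for metric in ("jaccard", "bray_curtis"):
        assert sm.distance_matrix(t3, metric).frame.loc["a", "b"] == 0.0


def test_distance_matrix_axioms_and_brute_force(rng):
    counts = pd.DataFrame(
        rng.integers(0, 50, size=(8, 6)),
        index=[f"f{i}" for i in range(8)],
        columns=[f"s{i}" for i in range(6)],
    )
    counts.iloc[0, :] += 1  # no all-zero samples
    t = make_table({f: counts.loc[f].to_dict() for f in counts.index})
    for metric in ("jaccard", "bray_curtis"):
        dm = sm.distance_matrix(t, metric)
        M = dm.values()
        assert np.allclose(M, M.T) and np.allclose(np.diag(M), 0)
        assert (M >= 0).all() and (M <= 1).all()
    bc = sm.distance_matrix(t, "bray_curtis").frame
    jc = sm.distance_matrix(t, "jaccard").frame
    for a in counts.columns:
        for b in counts.columns:
            x, y = counts[a].to_numpy(), counts[b].to_numpy()
            assert bc.loc[a, b] == pytest.approx(np.abs(x - y).sum() / (x + y).sum())
            A, B = set(np.where(x > 0)[0]), set(np.where(y > 0)[0])
            assert jc.loc[a, b] == pytest.approx(1 - len(A & B) / len(A | B))


def test_distance_matrix_rejects_empty_sample():
    t = make_table({"x": {"a": 2, "b": 0}})
    with pytest.raises(ValueError, match="b"):
        sm.distance_matrix(t, "jaccard")


# --- dbRDA -----------------------------------------------------------------

def _clustered_table(rng, n_per=6, sep=True):
    """Two groups of samples with disjoint (sep) or identical feature use."""
    rows = {}
    samples = [f"g1_{i}" for i in range(n_per)] + [f"g2_{i}" for i in range(n_per)]
    for f in range(6):
        rows[f"f{f}"] = {}
        for s in samples:
            g1 = s.startswith("g1")
            hi = (f < 3) == g1 if sep else f < 3
            rows[f"f{f}"][s] = int(rng.integers(50, 100)) if hi else 0
    t = make_table(rows)
    factors = pd.DataFrame(
        {"group": ["A"] * n_per + ["B"] * n_per}, index=samples
    )
    return t, factors


def test_constrained_variance_intercept_only(rng):
    t, factors = _clustered_table(rng)
    factors["group"] = "same"  # constant factor: intercept-only design
    dm = sm.distance_matrix(t, "jaccard")
    res = sm.constrained_variance(dm, factors, n_perm=49, seed=1)
    assert res.variance_explained_fraction == 0.0


def test_constrained_variance_separated_clusters(rng):
    """Two perfectly separated clusters: the 2-level factor explains nearly
    all variance and the permutation p is significant."""
    t, factors = _clustered_table(rng, sep=True)
    dm = sm.distance_matrix(t, "jaccard")
    res = sm.constrained_variance(dm, factors, n_perm=999, seed=1)
    assert res.variance_explained_fraction > 0.95
    assert res.anova["p"].iloc[0] <= 0.05


def test_constrained_variance_sample_reordering_invariance(rng):
    t, factors = _clustered_table(rng)
    dm = sm.distance_matrix(t, "bray_curtis")
    res1 = sm.constrained_variance(dm, factors, n_perm=9, seed=0)
    order = list(dm.frame.index)[::-1]
    dm2 = sm.DistanceMatrix(dm.metric, dm.frame.loc[order, order])
    res2 = sm.constrained_variance(dm2, factors, n_perm=9, seed=0)
    assert res1.variance_explained_fraction == pytest.approx(
        res2.variance_explained_fraction
    )


def test_permutation_p_matches_exhaustive_enumeration(rng):
    """Monte-Carlo p on a 6-sample instance agrees with full enumeration of
    all 720 label permutations."""
    counts = {
        f"f{i}": {f"s{j}": int(rng.integers(0, 30)) + (10 if (i < 2) == (j < 3) else 0)
                  for j in range(6)}
        for i in range(4)
    }
    t = make_table(counts)
    factors = pd.DataFrame({"g": ["A", "A", "A", "B", "B", "B"]},
                           index=[f"s{j}" for j in range(6)])
    dm = sm.distance_matrix(t, "bray_curtis")
    exact = exhaustive_permutation_p(dm, factors)[0]
    res = sm.constrained_variance(dm, factors, n_perm=1999, seed=5)
    mc = res.anova["p"].iloc[0]
    se = np.sqrt(exact * (1 - exact) / 2000) + 1e-3
    assert abs(mc - exact) < 4 * se + 0.01


def test_permutation_p_uniform_under_null(rng):
    """With labels independent of the data, permutation p-values are
    roughly uniform (coarse Kolmogorov-Smirnov bound over replicates)."""
    from scipy.stats import kstest

    pvals = []
    for rep in range(60):
        counts = {f"f{i}": {f"s{j}": int(rng.integers(1, 40)) for j in range(8)}
                  for i in range(5)}
        t = make_table(counts)
        labels = rng.permutation(["A"] * 4 + ["B"] * 4)
        factors = pd.DataFrame({"g": labels}, index=[f"s{j}" for j in range(8)])
        dm = sm.distance_matrix(t, "bray_curtis")
        res = sm.constrained_variance(dm, factors, n_perm=99, seed=int(rng.integers(2**31)))
        pvals.append(res.anova["p"].iloc[0])
    assert kstest(pvals, "uniform").pvalue > 1e-4


# --- chi-square ------------------------------------------------------------

def test_chi_square_closed_form_examples():
    res = sm.chi_square_2x2([[10, 20], [20, 10]])
    assert res.chi2 == pytest.approx(6.6667, abs=1e-4)
    assert res.df == 1
    assert sm.chi_square_2x2([[10, 10], [10, 10]]).chi2 == 0.0
    # N-linearity: scaling the table doubles the statistic
    base = sm.chi_square_2x2([[5, 3], [2, 6]]).chi2
    assert sm.chi_square_2x2([[10, 6], [4, 12]]).chi2 == pytest.approx(2 * base)


def test_chi_square_zero_margin_rejected():
    with pytest.raises(ValueError, match="margin"):
        sm.chi_square_2x2([[0, 0], [5, 5]])


@settings(deadline=None, max_examples=50)
@given(st.lists(st.integers(1, 200), min_size=4, max_size=4))
def test_chi_square_matches_scipy(cells):
    table = np.array(cells).reshape(2, 2)
    ours = sm.chi_square_2x2(table)
    ref = chi2_contingency(table, correction=False)
    assert ours.chi2 == pytest.approx(ref.statistic, abs=1e-10)
    assert ours.p == pytest.approx(ref.pvalue, abs=1e-10)
    with_cc = sm.chi_square_2x2(table, correction=True)
    ref_cc = chi2_contingency(table, correction=True)
    assert with_cc.chi2 == pytest.approx(ref_cc.statistic, abs=1e-10)


# --- concordance -----------------------------------------------------------

def test_detection_concordance_counts_and_exclusions():
    detected = {"a": True, "b": False, "c": True, "d": False}
    labels = {"a": "positive", "b": "positive", "c": "negative", "d": ""}
    tab = sm.detection_concordance(detected, labels)
    assert tab.counts.tolist() == [[1, 1], [1, 0]]
    assert tab.cells[(True, True)] == ["a"]
    assert tab.excluded == ["d"]
    all_pos = sm.detection_concordance({"x": True}, {"x": "positive"})
    assert all_pos.counts.tolist() == [[1, 0], [0, 0]]


# --- prevalence ------------------------------------------------------------

def test_prevalence_simple_group():
    t = make_table(
        {"z1": {"a": 10, "b": 0, "c": 3, "d": 0}},
        taxonomy={"z1": "Bacteria;;;;;Wolbachia;"},
    )
    groups = {s: ("laevis", "PL") for s in "abcd"}
    out = sm.prevalence(t, groups)
    row = out[out.taxon == "Wolbachia"].iloc[0]
    assert row.prevalence == pytest.approx(0.5)
    assert row.n == 4


def test_prevalence_missing_group_is_nan_not_zero():
    t = make_table({"z1": {"a": 10}}, taxonomy={"z1": "Bacteria;;;;;X;"})
    out = sm.prevalence(t, {})
    assert len(out) == 0 or out["prevalence"].isna().all()


# --- strain grouping -------------------------------------------------------

def test_operon_variants_fifty_fifty_is_single_strain(rng):
    samples = [f"s{i}" for i in range(12)]
    base = rng.integers(400, 600, size=12)
    t = make_table({
        "op1": dict(zip(samples, base)),
        "op2": dict(zip(samples, (base * rng.uniform(0.95, 1.05, 12)).astype(int))),
    })
    groups = sm.group_operon_variants(t)
    assert groups[0].members == ["op1", "op2"]
    assert groups[0].verdict == "single_strain_candidate"


def test_operon_variants_disjoint_features_independent():
    t = make_table({
        "x": {"s1": 100, "s2": 120, "s3": 0, "s4": 0},
        "y": {"s1": 0, "s2": 0, "s3": 90, "s4": 80},
    })
    groups = sm.group_operon_variants(t)
    assert all(g.verdict == "independent" for g in groups)
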