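"""Quantitation primitives against independent oracles."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apmspipe.design_io import CountMatrix, Mod, MethylState, PeptideEvidence
from apmspipe.quantitation import (
    bh_adjust,
    compute_exclusive_counts,
    fisher_enrichment,
    fold_change_over_control,
    hypergeom_tail_p,
    occam_group_proteins,
)


def _matrix(counts, proteins, samples):
    df = pd.DataFrame(counts, index=proteins, columns=samples, dtype=np.int64)
    df.index.name = "protein_id"
    return CountMatrix(df=df)


def _ev(pid, pep, sample, n):
    return PeptideEvidence(
        protein_id=pid,
        protein_prob=1.0,
        peptide_seq=pep,
        peptide_prob=1.0,
        start_index=1,
        stop_index=len(pep),
        sample_id=sample,
        n_mod_spectra=0,
        n_total_spectra=n,
    )


# --- exclusive counts -------------------------------------------------------


def test_shared_peptide_contributes_to_neither_protein():
    grouping = {"PEPA": {"A"}, "PEPB": {"B"}, "SHARED": {"A", "B"}}
    evidence = [
        _ev("A", "PEPA", "s1", 3),
        _ev("B", "PEPB", "s1", 2),
        _ev("A", "SHARED", "s1", 5),
    ]
    m = compute_exclusive_counts(evidence, grouping)
    assert m.df.loc["A", "s1"] == 3
    assert m.df.loc["B", "s1"] == 2


def test_all_unique_peptides_gives_identity():
    grouping = {f"PEP{i}": {f"P{i}"} for i in range(4)}
    evidence = [_ev(f"P{i}", f"PEP{i}", "s1", i + 1) for i in range(4)]
    m = compute_exclusive_counts(evidence, grouping)
    for i in range(4):
        assert m.df.loc[f"P{i}", "s1"] == i + 1


def test_identical_peptide_sets_merge_with_concatenated_id():
    grouping = {"PEPX": {"A", "B"}, "PEPY": {"A", "B"}}
    groups = occam_group_proteins(grouping)
    assert groups == {"A": "A+B", "B": "A+B"}
    m = compute_exclusive_counts([_ev("A", "PEPX", "s1", 4)], grouping)
    assert m.df.loc["A+B", "s1"] == 4  # unique to the merged group


def test_subsumed_protein_merges_into_superset():
    grouping = {"P1": {"A", "B"}, "P2": {"A"}}
    groups = occam_group_proteins(grouping)
    # B's peptide set {P1} is strictly inside A's {P1, P2}
    assert groups["B"] == groups["A"] == "A+B"


def test_exclusive_counts_match_brute_force_recount():
    """Random 10-protein / 30-peptide instance vs direct enumeration of
    every (peptide, protein) incidence."""
    rng = np.random.default_rng(5)
    proteins = [f"P{i}" for i in range(10)]
    peptides = [f"PEPTIDE{chr(65 + i)}" for i in range(30)]
    grouping = {
        pep: set(rng.choice(proteins, size=rng.integers(1, 3), replace=False))
        for pep in peptides
    }
    samples = ["s1", "s2"]
    evidence = [
        _ev(rng.choice(proteins), pep, s, int(rng.integers(0, 6)))
        for pep in peptides
        for s in samples
    ]
    m = compute_exclusive_counts(evidence, grouping)

    # oracle: recompute groups from scratch, count per (group, sample)
    groups = occam_group_proteins(grouping)
    expected: dict[tuple[str, str], int] = {}
    for ev in evidence:
        gset = {groups[p] for p in grouping[ev.peptide_seq]}
        if len(gset) == 1:
            key = (next(iter(gset)), ev.sample_id)
            expected[key] = expected.get(key, 0) + ev.n_total_spectra
    for (gid, sid), n in expected.items():
        assert m.df.loc[gid, sid] == n
    assert int(m.df.to_numpy().sum()) == sum(expected.values())


def test_peptide_missing_from_grouping_errors():
    with pytest.raises(Exception, match="grouping"):
        compute_exclusive_counts([_ev("A", "GHOST", "s1", 1)], {"PEPA": {"A"}})


# --- fold change ------------------------------------------------------------


@pytest.mark.parametrize(
    "bait, ctrl, expected",
    [
        ([10, 10], [0, 0], 100.0),  # floor forces 10 / 0.1
        ([4, 4], [2, 2], 2.0),
        ([0, 0], [0, 0], 1.0),  # both floored: 0.1 / 0.1
    ],
)
def test_fold_change_floor_rules(bait, ctrl, expected):
    m = _matrix([[bait[0], bait[1], ctrl[0], ctrl[1]]], ["A"], ["b1", "b2", "c1", "c2"])
    (rec,) = fold_change_over_control(m, ["b1", "b2"], ["c1", "c2"])
    assert rec.fold_change == pytest.approx(expected)


def test_fold_change_monotone_in_counts():
    """More bait spectra never lower the ratio; more control never raise it."""
    rng = np.random.default_rng(0)
    base = rng.integers(0, 8, size=(6, 4))
    m = _matrix(base, [f"P{i}" for i in range(6)], ["b1", "b2", "c1", "c2"])
    fc0 = {r.protein_id: r.fold_change for r in fold_change_over_control(m, ["b1", "b2"], ["c1", "c2"])}
    bumped = base.copy()
    bumped[:, 0] += 3  # raise a bait sample
    m2 = _matrix(bumped, [f"P{i}" for i in range(6)], ["b1", "b2", "c1", "c2"])
    fc1 = {r.protein_id: r.fold_change for r in fold_change_over_control(m2, ["b1", "b2"], ["c1", "c2"])}
    assert all(fc1[p] >= fc0[p] for p in fc0)
    bumped2 = base.copy()
    bumped2[:, 2] += 3  # raise a control sample
    m3 = _matrix(bumped2, [f"P{i}" for i in range(6)], ["b1", "b2", "c1", "c2"])
    fc2 = {r.protein_id: r.fold_change for r in fold_change_over_control(m3, ["b1", "b2"], ["c1", "c2"])}
    assert all(fc2[p] <= fc0[p] for p in fc0)


def test_fold_change_empty_subset_errors(small_matrix):
    with pytest.raises(Exception, match="non-empty"):
        fold_change_over_control(small_matrix, [], ["igg_1"])


# --- Fisher exact enrichment ------------------------------------------------


from _oracles import exact_upper_tail


def test_fisher_no_evidence_gives_p_one():
    m = _matrix([[0, 0], [5, 5]], ["A", "BG"], ["b1", "c1"])
    rec = {r.protein_id: r for r in fisher_enrichment(m, ["b1"], ["c1"])}
    assert rec["A"].p_value == pytest.approx(1.0)


def test_fisher_matches_enumeration_on_stated_examples():
    # 5 of 100 bait spectra vs 0 of 100 control spectra
    m = _matrix([[5, 0], [95, 100]], ["A", "BG"], ["b1", "c1"])
    rec = {r.protein_id: r for r in fisher_enrichment(m, ["b1"], ["c1"])}
    assert rec["A"].table == ((5, 95), (0, 100))
    assert rec["A"].p_value == pytest.approx(float(exact_upper_tail(5, 100, 0, 100)))

    # identical proportions on a 20-spectrum toy: p must exceed 0.5
    m2 = _matrix([[2, 2], [8, 8]], ["A", "BG"], ["b1", "c1"])
    rec2 = {r.protein_id: r for r in fisher_enrichment(m2, ["b1"], ["c1"])}
    oracle = float(exact_upper_tail(2, 10, 2, 10))
    assert rec2["A"].p_value == pytest.approx(oracle)
    assert rec2["A"].p_value > 0.5


def test_fisher_all_zero_matrix_errors():
    m = _matrix([[0, 0]], ["A"], ["b1", "c1"])
    with pytest.raises(Exception, match="no spectra"):
        fisher_enrichment(m, ["b1"], ["c1"])


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.integers(0, 25),
    st.integers(0, 25),
    st.integers(0, 25),
    st.integers(0, 25),
)
def test_hypergeom_tail_matches_exact_enumeration(a, b, c, d):
    p = float(hypergeom_tail_p(a, a + b, c, c + d))
    assert p == pytest.approx(float(exact_upper_tail(a, a + b, c, c + d)), abs=1e-12)


# --- BH adjustment ----------------------------------------------------------


def test_bh_hand_computed_step_up():
    assert list(bh_adjust([0.01, 0.02, 0.03])) == pytest.approx([0.03, 0.03, 0.03])
    # order preserved for unsorted input
    out = bh_adjust([0.03, 0.01])
    assert out[1] <= out[0]


@pytest.mark.parametrize("p", [[0.5], [1.0, 1.0, 1.0]])
def test_bh_fixed_points(p):
    assert list(bh_adjust(p)) == pytest.approx(p)


def test_bh_rejects_out_of_range():
    with pytest.raises(Exception, match=r"\[0, 1\]"):
        bh_adjust([0.1, 1.5])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=20))
def test_bh_matches_manual_step_up(ps):
    """BH equals the textbook step-up (sort, p*(m/rank), cumulative min from
    the largest), never shrinks a p-value, caps at 1, and preserves order."""
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    adj_sorted = [min(1.0, ps[i] * m / (r + 1)) for r, i in enumerate(order)]
    for r in range(m - 2, -1, -1):
        adj_sorted[r] = min(adj_sorted[r], adj_sorted[r + 1])
    manual = [0.0] * m
    for r, i in enumerate(order):
        manual[i] = adj_sorted[r]
    out = bh_adjust(ps)
    assert list(out) == pytest.approx(manual, abs=1e-12)
    assert all(q >= p - 1e-12 and q <= 1.0 for p, q in zip(ps, out))
    for i in range(m):
        for j in range(m):
            if ps[i] <= ps[j]:
                assert out[i] <= out[j] + 1e-12
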