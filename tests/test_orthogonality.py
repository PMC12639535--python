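"""Replicate aggregation, the Orthogonality Score, and enrichment profiles."""

import itertools
import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mycscreen import (AggregateProfile, BinarizedProfile, OrthogonalityCriterion,
                       ScreenConfig, aggregate_signature, orthogonality_enrichment_profile,
                       orthogonality_score, orthogonality_screen,
                       simulate_orthogonal_pair, simulate_reference)
from mycscreen.exceptions import UndefinedScoreError, ValidationError


def _profiles(universe, *rows):
    idx = pd.Index(universe)
    return [BinarizedProfile(idx, np.asarray(r, np.int8), f"r{i}")
            for i, r in enumerate(rows)]


def mode_oracle(values):
    """Most frequent of {-1,0,+1}; any tie for the top count -> 0."""
    counts = Counter(values)
    best = max(counts.values())
    winners = [v for v, c in counts.items() if c == best]
    return winners[0] if len(winners) == 1 else 0


# -------------------------------------------------------------- aggregation

@pytest.mark.parametrize("reps,expected", [
    ([[1], [1], [0]], 1),
    ([[1], [-1]], 0),
    ([[-1]], -1),
])
def test_aggregate_examples(reps, expected):
    agg = aggregate_signature(_profiles(["g"], *reps))
    assert agg.values[0] == expected


def test_aggregate_exhaustive_multisets():
    """Mode with tie->0 vs enumeration of every replicate tuple of size <= 4."""
    for size in (1, 2, 3, 4):
        for combo in itertools.product((-1, 0, 1), repeat=size):
            agg = aggregate_signature(_profiles(["g"], *[[v] for v in combo]))
            assert agg.values[0] == mode_oracle(combo), combo


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 32 - 1))
def test_aggregate_replicate_order_invariant(seed):
    rng = np.random.default_rng(seed)
    reps = rng.integers(-1, 2, size=(4, 10))
    a = aggregate_signature(_profiles(range(10), *reps))
    b = aggregate_signature(_profiles(range(10), *reps[::-1]))
    assert (a.values == b.values).all()
    # idempotent on identical replicates
    c = aggregate_signature(_profiles(range(10), reps[0], reps[0], reps[0]))
    assert (c.values == reps[0]).all()


def test_aggregate_empty_list_rejected():
    with pytest.raises(ValidationError):
        aggregate_signature([])


# ----------------------------------------------------------------------- OS

@pytest.mark.parametrize("nt,nd,expected", [
    (0.0, 1.0, 0.0),
    (0.6, 0.2, 1.0),
    (1.0, -1.0, math.sqrt(5)),
])
def test_orthogonality_score_closed_forms(nt, nd, expected):
    assert orthogonality_score(nt, nd) == pytest.approx(expected, abs=1e-12)


def test_orthogonality_score_domain():
    with pytest.raises(ValidationError):
        orthogonality_score(1.2, 0.0)
    with pytest.raises(ValidationError):
        orthogonality_score(0.0, -1.2)


def test_orthogonality_score_monotonicity_grid():
    grid = np.linspace(-1, 1, 101)
    for nd in (-1.0, -0.3, 0.4, 1.0):
        vals = [orthogonality_score(abs(nt), nd) for nt in grid]
        assert np.all(np.diff(np.abs(grid)) * np.diff(vals) >= -1e-12)
    for nt in (-1.0, 0.0, 0.7):
        vals = [orthogonality_score(nt, nd) for nd in grid]
        assert np.all(np.diff(vals) <= 1e-12)
    assert all(0 <= orthogonality_score(a, b) <= math.sqrt(5)
               for a in grid[::10] for b in grid[::10])


# ------------------------------------------------------------------- screen

def test_candidate_identical_to_anchor_collapses(small_reference):
    cfg = ScreenConfig(n_genes=200, n_deg=60, seed=11)
    a, b, _ = simulate_orthogonal_pair(small_reference, cfg)
    clone = AggregateProfile("clone", a.gene_universe, a.values.copy(), 1)
    res = orthogonality_screen(small_reference, a, [clone]).iloc[0]
    assert res.ncr_drug == 1.0
    assert res.os == pytest.approx(abs(res.ncr_target))


def test_disjoint_support_candidate(small_reference):
    cfg = ScreenConfig(n_genes=200, n_deg=60, seed=11)
    a, b, truth = simulate_orthogonal_pair(small_reference, cfg)
    res = orthogonality_screen(small_reference, a, [b]).iloc[0]
    assert res.ncr_drug == 0.0
    assert res.ncr_target == pytest.approx(truth["ortho_B"]["expected_ncr_target"])
    assert res.os == pytest.approx(math.sqrt(res.ncr_target ** 2 + 1))


def test_orthogonal_partner_outranks_clone_and_nulls(small_reference):
    cfg = ScreenConfig(n_genes=200, n_deg=60, seed=13)
    a, b, _ = simulate_orthogonal_pair(small_reference, cfg)
    rng = np.random.default_rng(0)
    nulls = [AggregateProfile(f"null{i}", a.gene_universe,
                              rng.integers(-1, 2, len(a.gene_universe)).astype(np.int8), 1)
             for i in range(5)]
    clone = AggregateProfile("clone", a.gene_universe, a.values.copy(), 1)
    res = orthogonality_screen(small_reference, a, [b, clone] + nulls)
    best = res.sort_values("os", ascending=False).iloc[0]
    assert best.candidate_id == "ortho_B"


def test_anchor_as_reference_consistency(small_reference):
    """With the reference itself as anchor, ncr_drug == ncr_target everywhere."""
    anchor = AggregateProfile("ref", small_reference.gene_universe,
                              small_reference.values.copy(), 1)
    rng = np.random.default_rng(1)
    cands = [AggregateProfile(f"c{i}", small_reference.gene_universe,
                              rng.integers(-1, 2, len(small_reference.gene_universe)
                                           ).astype(np.int8), 1) for i in range(4)]
    res = orthogonality_screen(small_reference, anchor, cands)
    assert np.allclose(res.ncr_drug, res.ncr_target)


def test_anchor_errors(small_reference):
    empty = AggregateProfile("e", small_reference.gene_universe,
                             np.zeros(len(small_reference.gene_universe)), 1)
    with pytest.raises(UndefinedScoreError):
        orthogonality_screen(small_reference, empty, [])
    anchor = AggregateProfile("a", small_reference.gene_universe,
                              small_reference.values.copy(), 1)
    with pytest.raises(ValidationError, match="excluded"):
        orthogonality_screen(small_reference, anchor, [anchor])


# -------------------------------------------------- enrichment profile matrix

def _os_frame(rows):
    return pd.DataFrame(rows, columns=["anchor_id", "candidate_id",
                                       "ncr_target", "ncr_drug", "os"])


def test_identical_candidates_give_zero_matrix():
    rows = [(a, c, 0.0, 1.0, 0.0) for a in ("A", "B") for c in ("x", "y", "z")]
    mat = orthogonality_enrichment_profile(_os_frame(rows))
    assert mat.shape == (2, 3)
    assert (mat.to_numpy() == 0).all()


def test_single_orthogonal_cell():
    rows = [("A", "x", 0.1, 0.9, 0.15), ("A", "y", 0.8, 0.0, 1.28),
            ("A", "z", 0.1, 0.8, 0.22),
            ("B", "x", 0.1, 0.9, 0.15), ("B", "y", 0.1, 0.9, 0.15),
            ("B", "z", 0.1, 0.9, 0.15)]
    mat = orthogonality_enrichment_profile(_os_frame(rows),
                                           OrthogonalityCriterion(quantile=0.75))
    assert mat.loc["A", "y"] == 1
    assert mat.to_numpy().sum() == 1


def test_enriched_candidate_gate():
    rows = [("A", "x", 0.8, 0.0, 1.28), ("A", "y", 0.1, 0.9, 0.15),
            ("A", "z", 0.1, 0.9, 0.15)]
    crit = OrthogonalityCriterion(quantile=0.5, enriched_candidates={"y"})
    mat = orthogonality_enrichment_profile(_os_frame(rows), crit)
    assert mat.to_numpy().sum() == 0  # x passes OS but is not target-enriched
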