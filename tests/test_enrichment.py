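"""Compound-level KS enrichment, NES/p, and the recurrence filter."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mycscreen import (ScreenConfig, ScreenTable, compound_enrichment,
                       enriched_compounds, enrichment_score, pathway_enriched_compounds,
                       rank_by_score, recurrent_hits, running_sum, screen_cell_line,
                       simulate_gene_sets, simulate_multi_cell_line)
from mycscreen.enrichment import _es_from_positions
from mycscreen.exceptions import UndefinedScoreError, ValidationError
from mycscreen.pipeline import ScreenParams


def brute_force_es(n: int, member_positions: set[int]) -> float:
    """Oracle: explicit running-sum enumeration in exact rational arithmetic;
    a tie between equal +/- peaks resolves to the positive one."""
    from fractions import Fraction
    m = len(member_positions)
    cur, hi, lo = Fraction(0), Fraction(0), Fraction(0)
    for i in range(n):
        cur += Fraction(1, m) if i in member_positions else -Fraction(1, n - m)
        hi, lo = max(hi, cur), min(lo, cur)
    return float(hi if hi >= -lo else lo)


def _screen_table(scores, compounds=None, pvals=None):
    n = len(scores)
    df = pd.DataFrame({
        "signature_id": [f"s{i:03d}" for i in range(n)],
        "compound_id": compounds if compounds is not None else [f"c{i}" for i in range(n)],
        "cell_line": "L", "ncr": scores, "n_overlap": 1, "n_concordant": 1,
        "n_discordant": 0, "p_value": pvals if pvals is not None else [0.5] * n,
        "q_value": 0.5})
    return ScreenTable(df)


# ------------------------------------------------------------------ ranking

def test_rank_by_score_order_and_ties():
    t = _screen_table([0.3, 0.9, 0.1])
    assert rank_by_score(t) == ["s001", "s000", "s002"]
    t2 = _screen_table([0.5, 0.5], pvals=[0.2, 0.1])
    assert rank_by_score(t2) == ["s001", "s000"]


def test_rank_matches_sort_oracle():
    rng = np.random.default_rng(9)
    scores = rng.uniform(-1, 1, size=1000)
    t = _screen_table(scores)
    ids = [f"s{i:03d}" for i in range(1000)]
    oracle = [s for _, s in sorted(zip(scores, ids), key=lambda kv: (-kv[0], kv[1]))]
    assert rank_by_score(t) == oracle


# ---------------------------------------------------------------------- ES

def test_es_members_at_top_and_bottom():
    ranked = [f"s{i}" for i in range(10)]
    assert enrichment_score(ranked, {"s0", "s1"}) == pytest.approx(1.0)
    assert enrichment_score(ranked, {"s8", "s9"}) == pytest.approx(-1.0)


def test_es_hand_enumeration_n4():
    """N=4, m=2, members at ranks 1 and 3: running sum [0.5, 0, 0.5, 0]."""
    ranked = ["a", "b", "c", "d"]
    s = running_sum(ranked, {"a", "c"})
    assert s == pytest.approx([0.5, 0.0, 0.5, 0.0])
    assert enrichment_score(ranked, {"a", "c"}) == pytest.approx(0.5)


def test_running_sum_terminates_at_zero():
    rng = np.random.default_rng(1)
    ranked = [f"s{i}" for i in range(50)]
    members = set(rng.choice(ranked, size=7, replace=False))
    assert abs(running_sum(ranked, members)[-1]) < 1e-12


def test_es_reflection_symmetry():
    """ES on the reversed ranking equals the negated ES of the mirrored pattern."""
    rng = np.random.default_rng(2)
    ranked = [f"s{i}" for i in range(20)]
    for _ in range(20):
        members = set(rng.choice(ranked, size=4, replace=False))
        pos = sorted(ranked.index(s) for s in members)
        mirrored = {ranked[19 - p] for p in pos}
        a = enrichment_score(ranked, members)
        b = enrichment_score(list(reversed(ranked)), members)
        assert b == pytest.approx(enrichment_score(ranked, mirrored))
        # mirrored-pattern ES negates, up to the positive tie preference
        assert abs(b) == pytest.approx(abs(-a)) or b == pytest.approx(-a)


def test_es_exhaustive_oracle_small_n():
    """Closed-form and running-sum ES agree with enumeration for all subsets, N <= 8."""
    for n in range(2, 9):
        ranked = [f"s{i}" for i in range(n)]
        for m in range(1, n):
            for pos in itertools.combinations(range(n), m):
                want = brute_force_es(n, set(pos))
                assert enrichment_score(ranked, {ranked[p] for p in pos}) == \
                    pytest.approx(want)
                got = _es_from_positions(np.array(pos)[None, :], n)[0]
                assert got == pytest.approx(want)


def test_es_error_paths():
    with pytest.raises(UndefinedScoreError):
        enrichment_score(["a", "b"], {"a", "b"})
    with pytest.raises(ValidationError):
        enrichment_score(["a", "b"], {"zz"})


# ---------------------------------------------------------------- compounds

def test_top_compound_is_enriched():
    rng = np.random.default_rng(3)
    scores = np.sort(rng.uniform(-1, 1, 100))[::-1]
    compounds = ["hit"] * 3 + [f"null{i // 3}" for i in range(97)]
    res = compound_enrichment(_screen_table(scores, compounds), n_perm=500, seed=0)
    row = res.set_index("compound_id").loc["hit"]
    assert row.nes > 0
    assert row.p_value == pytest.approx(1 / 501)


def test_null_screen_rejects_nothing():
    rng = np.random.default_rng(4)
    scores = rng.uniform(-1, 1, size=400)
    compounds = [f"c{i // 2}" for i in range(400)]  # 200 compounds x 2 replicates
    res = compound_enrichment(_screen_table(scores, compounds), n_perm=500, seed=1)
    assert len(enriched_compounds(res, 0.05)) <= 2


def test_enrichment_deterministic_and_order_invariant():
    rng = np.random.default_rng(5)
    scores = rng.uniform(-1, 1, size=60)
    compounds = [f"c{i // 3}" for i in range(60)]
    t = _screen_table(scores, compounds)
    r1 = compound_enrichment(t, n_perm=200, seed=7)
    r2 = compound_enrichment(t, n_perm=200, seed=7)
    pd.testing.assert_frame_equal(r1, r2)
    shuffled = ScreenTable(t.table.sample(frac=1, random_state=0).reset_index(drop=True))
    r3 = compound_enrichment(shuffled, n_perm=200, seed=7)
    pd.testing.assert_frame_equal(r1, r3)


def test_nes_stable_under_replicate_duplication():
    """Duplicating every compound's replicates (rank structure fixed) rescales
    NES by one common null factor: pairwise NES ordering and signs are
    preserved, so cross-compound comparisons are replicate-count sane."""
    rng = np.random.default_rng(6)
    scores = np.sort(rng.uniform(-1, 1, size=40))[::-1]
    compounds = [f"c{i // 2}" for i in range(40)]
    t = _screen_table(scores, compounds)
    base = compound_enrichment(t, n_perm=2000, seed=0).set_index("compound_id")
    dup_scores = np.repeat(scores, 2) - np.tile([0, 1e-9], 40)
    dup_compounds = np.repeat(compounds, 2)
    td = _screen_table(dup_scores, dup_compounds)
    dup = compound_enrichment(td, n_perm=2000, seed=0).set_index("compound_id")
    strong = base[base.es.abs() > 0.5]
    ratios = (dup.loc[strong.index, "nes"] / strong["nes"]).to_numpy()
    assert np.all(ratios > 0)                       # signs preserved
    assert ratios.max() / ratios.min() < 1.1        # one common rescale
    order_base = strong["nes"].sort_values().index
    order_dup = dup.loc[strong.index, "nes"].sort_values().index
    assert list(order_base) == list(order_dup)


def test_compound_owning_whole_list_is_an_error():
    t = _screen_table([0.5, 0.1], ["c", "c"])
    with pytest.raises(UndefinedScoreError):
        compound_enrichment(t, n_perm=10, seed=0)


# ---------------------------------------------------------------- recurrence

def _enr(compounds, nes, q):
    return pd.DataFrame({"compound_id": compounds, "n_signatures": 2,
                         "es": nes, "nes": nes, "p_value": q, "q_value": q})


def _pw(compounds, nes, q, set_name="P0"):
    df = _enr(compounds, nes, q)
    df.insert(0, "set_name", set_name)
    return df


def test_recurrence_boundary_and_conjunction():
    lines = {}
    for i in range(10):
        hit = i < 3  # enriched by both methods in exactly 3 lines
        lines[f"L{i}"] = (
            _enr(["a", "b"], [1.0 if hit else -1.0, 1.0], [0.01, 0.01]),
            _pw(["a", "b"], [1.0 if hit else -1.0, -1.0], [0.01, 0.01]))
    res = recurrent_hits(lines, min_lines=3).set_index("compound_id")
    assert bool(res.loc["a", "passes"])          # 3 of 10 lines, boundary
    assert res.loc["b", "n_enriched"] == 0       # full-method only: not counted
    assert not bool(res.loc["b", "passes"])


def test_pathway_label_aggregation_rules():
    df = pd.concat([_pw(["a", "b"], [1.0, 1.0], [0.01, 0.5], "P0"),
                    _pw(["a", "b"], [1.0, 1.0], [0.01, 0.01], "P1"),
                    _pw(["a", "b"], [-1.0, 1.0], [0.01, 0.01], "P2")])
    assert pathway_enriched_compounds(df, rule="any") == {"a", "b"}
    assert pathway_enriched_compounds(df, rule="majority") == {"a", "b"}
    assert pathway_enriched_compounds(df, rule="all") == set()


def test_multi_line_planted_recovery_small():
    """4-line synthetic screen: recurrence recovers exactly the planted set."""
    cfg = ScreenConfig(n_genes=300, n_deg=120, n_compounds=40,
                       replicates_per_compound=3, n_cell_lines=4,
                       n_antagonists=3, n_line_decoys=1, n_low_tas_decoys=3, seed=21)
    reference, bundle = simulate_multi_cell_line(cfg)
    gene_sets = simulate_gene_sets(reference, cfg, n_sets=4)
    params = ScreenParams(n_perm=300, seed=21, min_lines=3)
    per_line = {}
    for line, mat in bundle.matrices.items():
        _, _, ef, ep = screen_cell_line(reference, mat, gene_sets, params)
        per_line[line] = (ef, ep)
    res = recurrent_hits(per_line, min_lines=3)
    got = set(res.loc[res.passes, "compound_id"])
    assert got == bundle.expected_recurrent(3) == set(bundle.pan_antagonists)
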