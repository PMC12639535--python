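"""Compound-level enrichment over a ranked concordance screen.

A compound with several replicate signatures is called a hit when those
replicates cluster at the top of the screen-wide concordance ranking.  The
statistic is the unweighted Kolmogorov-Smirnov running sum: walking down the
ranked list, the sum rises by ``1/m`` at each of the compound's ``m``
replicates and falls by ``1/(N-m)`` otherwise; the enrichment score (ES) is
the signed maximum deviation from zero, so ES is in [-1, 1] and the sum
returns to 0 after the last position.  The null redistributes the compound's
``m`` member labels uniformly over the ``N`` rank positions; the normalized
score (NES) divides ES by the mean |null ES| of matching sign, and the
add-one permutation p is taken in the observed direction, BH-adjusted across
compounds.

The null ES distribution depends only on ``(N, m)``, so one null sample per
distinct replicate count is drawn per screen (seeded from the screen seed and
``(N, m)``, hence independent of compound order) and shared by all compounds
with that count.

A recurrence filter then keeps compounds that are enriched (NES > 0, FDR at
or below threshold) under *both* the full-profile and the pathway-restricted
method in at least ``min_lines`` cell lines.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .concordance import ScreenTable, bh_adjust
from .exceptions import UndefinedScoreError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    compound_id: str
    n_signatures: int
    es: float
    nes: float
    p_value: float
    q_value: float


@dataclass
class RecurrenceSummary:
    compound_id: str
    cell_lines_enriched: set[str]
    n_enriched: int
    passes: bool


def rank_by_score(table: ScreenTable) -> list[str]:
    """Signature ids in screening order: descending NCR, ties broken by
    ascending p-value then lexicographic signature id (deterministic)."""
    df = table.table
    if df.empty:
        raise ValidationError("cannot rank an empty screen table")
    order = df.sort_values(["ncr", "p_value", "signature_id"],
                           ascending=[False, True, True], kind="mergesort")
    return list(order["signature_id"])


def _integer_steps(ranked: Sequence[str], members: set[str]) -> tuple[np.ndarray, int, int]:
    n = len(ranked)
    m = sum(1 for s in ranked if s in members)
    if m == 0:
        raise ValidationError("members do not appear in the ranked list")
    if m == n:
        raise UndefinedScoreError("members cover the whole list (no misses)")
    # exact arithmetic: one unit = 1 / (m * (n - m)), so hits step +(n-m)
    # units and misses step -m units and all partial sums are integers
    steps = np.where([s in members for s in ranked], n - m, -m).astype(np.int64)
    return steps, n, m


def running_sum(ranked: Sequence[str], members: set[str]) -> np.ndarray:
    """The KS running sum over the ranked list (length N array ending at 0)."""
    steps, n, m = _integer_steps(ranked, members)
    return np.cumsum(steps) / (m * (n - m))


def enrichment_score(ranked: Sequence[str], members: set[str]) -> float:
    """Signed maximum absolute excursion of the running sum.

    Computed in exact integer units, so a tie between equal positive and
    negative excursions resolves to the positive one deterministically.
    """
    missing = set(members) - set(ranked)
    if missing:
        raise ValidationError(f"members not in ranked list: {sorted(missing)[:5]}")
    steps, n, m = _integer_steps(ranked, members)
    s = np.cumsum(steps)
    hi, lo = max(0, int(s.max())), min(0, int(s.min()))
    return (hi if hi >= -lo else lo) / (m * (n - m))


def _es_from_positions(positions: np.ndarray, n: int) -> np.ndarray:
    """Vectorized ES for rows of sorted 0-based member positions.

    The running sum's extrema can only occur immediately before or after a
    member position, which gives a closed form over the m member positions
    instead of the full N steps.  Evaluated in integer units (1/(m(n-m))) so
    ties break exactly as in :func:`enrichment_score`.
    """
    p = np.atleast_2d(positions).astype(np.int64)
    m = p.shape[1]
    if m >= n:
        raise UndefinedScoreError("members cover the whole list (no misses)")
    k = np.arange(1, m + 1, dtype=np.int64)
    after = k * (n - m) - (p + 1 - k) * m
    before = (k - 1) * (n - m) - (p - (k - 1)) * m
    hi = np.maximum(after.max(axis=1), np.maximum(before.max(axis=1), 0))
    lo = np.minimum(after.min(axis=1), np.minimum(before.min(axis=1), 0))
    return np.where(hi >= -lo, hi, lo) / (m * (n - m))


def _null_es(n: int, m: int, n_perm: int, seed: int) -> np.ndarray:
    """Null ES sample for m members uniformly placed among n positions."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), n, m, 0x9E3779B9]))
    r = rng.random((n_perm, n))
    idx = np.argpartition(r, m - 1, axis=1)[:, :m] if m > 1 else np.argmin(r, axis=1)[:, None]
    return _es_from_positions(np.sort(idx, axis=1), n)


def compound_enrichment(table: ScreenTable, n_perm: int = 1000, seed: int = 0,
                        nes_method: str = "sign_mean") -> pd.DataFrame:
    """Per-compound ES / NES / permutation p / BH q over a screen ranking.

    ``nes_method='sign_mean'`` (default) divides ES by the mean |null ES| of
    matching sign; ``'zscore'`` standardizes ES against the null mean and SD.
    Deterministic given ``seed`` and invariant to compound order.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if nes_method not in ("sign_mean", "zscore"):
        raise ValidationError(f"unknown nes_method {nes_method!r}")
    df = table.table
    if df["compound_id"].isna().any():
        raise ValidationError("every signature must map to exactly one compound")
    ranked = rank_by_score(table)
    pos_of = {sig: i for i, sig in enumerate(ranked)}
    n = len(ranked)
    groups = df.groupby("compound_id")["signature_id"].apply(list).sort_index()

    null_cache: dict[int, np.ndarray] = {}
    rows = []
    for compound, sigs in groups.items():
        m = len(sigs)
        if m == n:
            raise UndefinedScoreError(
                f"compound {compound!r} owns every ranked signature; ES undefined")
        p_sorted = np.sort([pos_of[s] for s in sigs])
        es = float(_es_from_positions(p_sorted[None, :], n)[0])
        if m not in null_cache:
            null_cache[m] = _null_es(n, m, n_perm, seed)
        null = null_cache[m]
        if es >= 0:
            hits = int((null >= es).sum())
            same = np.abs(null[null > 0])
        else:
            hits = int((null <= es).sum())
            same = np.abs(null[null < 0])
        p_value = (1 + hits) / (1 + n_perm)
        if nes_method == "zscore":
            sd = float(null.std())
            nes = 0.0 if sd == 0 else (es - float(null.mean())) / sd
        else:
            if same.size == 0:
                warnings.warn(f"no matching-sign null ES for {compound!r}; "
                              "normalizing by mean |null ES|")
                same = np.abs(null)
            nes = 0.0 if es == 0 else es / float(same.mean())
        rows.append((compound, m, es, nes, p_value))

    out = pd.DataFrame(rows, columns=["compound_id", "n_signatures", "es", "nes", "p_value"])
    out["q_value"] = bh_adjust(out["p_value"])
    out.attrs["context"] = {**table.context, "n_perm_enrichment": n_perm,
                            "nes_method": nes_method, "n_ranked": n}
    return out


def enriched_compounds(results: pd.DataFrame, fdr_max: float = 0.05) -> set[str]:
    """Compounds classified as enriched: NES > 0 and q at or below ``fdr_max``."""
    mask = (results["nes"] > 0) & (results["q_value"] <= fdr_max)
    return set(results.loc[mask, "compound_id"])


def pathway_enrichment(pathway_tables: Mapping[str, ScreenTable], n_perm: int = 1000,
                       seed: int = 0, nes_method: str = "sign_mean") -> pd.DataFrame:
    """Compound enrichment computed on each pathway-restricted ranking;
    returns the concatenated results with a ``set_name`` column."""
    frames = []
    for set_name, screen in pathway_tables.items():
        res = compound_enrichment(screen, n_perm=n_perm, seed=seed, nes_method=nes_method)
        res.insert(0, "set_name", set_name)
        frames.append(res)
    return pd.concat(frames, ignore_index=True)


def pathway_enriched_compounds(pathway_results: pd.DataFrame, fdr_max: float = 0.05,
                               rule: str = "any") -> set[str]:
    """Aggregate per-pathway enrichment into one compound-level label.

    ``rule`` is ``any`` (enriched in at least one pathway, default),
    ``majority`` (more than half of the pathways scored) or ``all``.
    """
    if rule not in ("any", "majority", "all"):
        raise ValidationError(f"unknown aggregation rule {rule!r}")
    df = pathway_results.copy()
    df["hit"] = (df["nes"] > 0) & (df["q_value"] <= fdr_max)
    agg = df.groupby("compound_id")["hit"].agg(["sum", "count"])
    if rule == "any":
        mask = agg["sum"] >= 1
    elif rule == "majority":
        mask = agg["sum"] > agg["count"] / 2
    else:
        mask = agg["sum"] == agg["count"]
    return set(agg.index[mask])


def recurrent_hits(results_by_cell_line: Mapping[str, tuple[pd.DataFrame, pd.DataFrame]],
                   min_lines: int = 3, fdr_max: float = 0.05,
                   pathway_rule: str = "any") -> pd.DataFrame:
    """Cross-cell-line recurrence filter.

    ``results_by_cell_line`` maps a cell line to its (full-method enrichment,
    per-pathway enrichment) result frames.  A compound counts as enriched in a
    cell line iff NES > 0 and q <= ``fdr_max`` under *both* methods; it passes
    when that holds in at least ``min_lines`` lines.  Returns one row per
    compound seen in any line, sorted by (-n_enriched, compound_id).
    """
    if min_lines < 1:
        raise ValidationError("min_lines must be >= 1")
    lines_of: dict[str, set[str]] = {}
    seen: set[str] = set()
    for line, (full_res, pw_res) in results_by_cell_line.items():
        seen |= set(full_res["compound_id"])
        both = enriched_compounds(full_res, fdr_max) & \
            pathway_enriched_compounds(pw_res, fdr_max, rule=pathway_rule)
        for compound in both:
            lines_of.setdefault(compound, set()).add(str(line))
    rows = []
    for compound in sorted(seen):
        lines = lines_of.get(compound, set())
        rows.append((compound, ";".join(sorted(lines)), len(lines), len(lines) >= min_lines))
    out = pd.DataFrame(rows, columns=["compound_id", "cell_lines_enriched",
                                      "n_enriched", "passes"])
    return out.sort_values(["n_enriched", "compound_id"],
                           ascending=[False, True], kind="mergesort").reset_index(drop=True)
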