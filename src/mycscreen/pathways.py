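"""Pathway-restricted concordance screening and method comparison.

Restricting the reference to a pathway's genes raises the functional
resolution of the screen: |A| becomes the DEGs inside the pathway, so a drug
that reverses one transcriptional program scores near the theoretical limits
there even if its full-profile concordance is modest.  Each pathway is its own
multiple-testing family (BH across signatures within a pathway).  The module
also summarises a screen as a concordance rate and cross-tabulates the
"enriched" labels of two screening methods with a Fisher exact test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .concordance import ScreenTable, screen_multi
from .exceptions import EmptyScreenError, ValidationError
from .io import GeneSetCollection, ReferenceProfile, SignatureMatrix

logger = logging.getLogger(__name__)


@dataclass
class PathwayConcordanceProfile:
    """Per-signature multidimensional concordance: set name -> (ncr, p, q)."""

    signature_id: str
    scores: dict[str, tuple[float, float, float]]


@dataclass
class AgreementResult:
    """2x2 agreement between two enrichment-labelling methods."""

    table: np.ndarray
    odds_ratio: float
    p_value: float
    corrected: bool = False


def restrict_reference(reference: ReferenceProfile, gene_set: set[str],
                       name: str | None = None) -> ReferenceProfile:
    """Zero every reference call outside ``gene_set``; |A| becomes the DEG
    count inside the set.  Raises :class:`EmptyScreenError` when no DEG
    survives (the caller skips that pathway)."""
    if not gene_set:
        raise ValidationError("gene_set is empty")
    mask = reference.gene_universe.isin(gene_set)
    vals = np.where(mask, reference.values, 0).astype(np.int8)
    if not vals.any():
        raise EmptyScreenError(
            f"pathway {name or '<set>'} contains no reference DEGs (|A| = 0)")
    return ReferenceProfile(reference.gene_universe, vals, reference.fc,
                            reference.pval, reference.thresholds,
                            name or f"{reference.name}|restricted")


def pathway_screen(reference: ReferenceProfile, matrix: SignatureMatrix,
                   gene_sets: GeneSetCollection, z_threshold: float = 1.0,
                   n_perm: int = 1000, seed: int = 0,
                   alternative: str = "greater") -> dict[str, ScreenTable]:
    """One pathway-restricted concordance screen per gene set.

    Pathways without any reference DEG are skipped with a log entry.  BH is
    applied within each pathway across signatures; permutations are shared
    across pathways per signature, so a screen on the universe set is
    bit-identical to the unrestricted screen at the same seed.
    """
    refs: dict[str, ReferenceProfile] = {}
    for set_name, genes in gene_sets:
        try:
            refs[set_name] = restrict_reference(reference, genes, name=set_name)
        except EmptyScreenError as exc:
            logger.warning("skipping pathway %s: %s", set_name, exc)
    if not refs:
        raise EmptyScreenError("every pathway was skipped (no reference DEGs)")
    return screen_multi(refs, matrix, z_threshold=z_threshold, n_perm=n_perm,
                        seed=seed, alternative=alternative)


def pathway_profiles(results: Mapping[str, ScreenTable]) -> list[PathwayConcordanceProfile]:
    """Pivot per-pathway screen tables into per-signature concordance profiles."""
    by_sig: dict[str, dict[str, tuple[float, float, float]]] = {}
    for set_name, screen in results.items():
        for row in screen.table.itertuples():
            by_sig.setdefault(row.signature_id, {})[set_name] = (
                row.ncr, row.p_value, row.q_value)
    return [PathwayConcordanceProfile(sig, scores) for sig, scores in by_sig.items()]


def concordance_rate(table: ScreenTable, q_max: float = 0.05) -> float:
    """Proportion of signatures that are significantly concordant:
    ``#{ncr > 0 and q <= q_max} / #rows``."""
    df = table.table
    if df.empty:
        raise ValidationError("concordance rate is undefined on an empty table")
    hits = ((df["ncr"] > 0) & (df["q_value"] <= q_max)).sum()
    return float(hits) / len(df)


def compare_methods(labels_full: Mapping[str, bool],
                    labels_pathway: Mapping[str, bool]) -> AgreementResult:
    """Cross-tabulate two boolean labelings of the same compounds.

    Returns the 2x2 table ``[[both, full only], [pathway only, neither]]``,
    the sample odds ratio (Haldane-Anscombe +0.5 in every cell when any cell
    is zero, flagged via ``corrected``) and the two-sided Fisher exact p.
    """
    if set(labels_full) != set(labels_pathway):
        raise ValidationError("the two labelings cover different id sets")
    ids = sorted(labels_full)
    a = sum(1 for i in ids if labels_full[i] and labels_pathway[i])
    b = sum(1 for i in ids if labels_full[i] and not labels_pathway[i])
    c = sum(1 for i in ids if not labels_full[i] and labels_pathway[i])
    d = len(ids) - a - b - c
    table = np.array([[a, b], [c, d]], dtype=np.int64)
    corrected = bool((table == 0).any())
    t = table + 0.5 if corrected else table.astype(float)
    odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    p = stats.fisher_exact(table, alternative="two-sided")[1]
    return AgreementResult(table, float(odds), float(p), corrected)
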