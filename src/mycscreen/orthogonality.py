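"""Orthogonality scoring for drug-combination nomination.

No single compound reverses the whole target program, so the screen looks for
pairs whose concordant gene sets are complementary.  Replicate signatures of a
compound (at a fixed dose/time in one cell line) are first collapsed to an
aggregate profile by the per-gene mode of their binarized calls (ties -> 0).
Against an anchor drug, a candidate's Orthogonality Score is

    OS = sqrt(NCR_target^2 + (1 - NCR_drug)^2)

where NCR_target is its concordance with the reference target profile and
NCR_drug its concordance with the anchor's profile (the anchor's nonzero
calls play the role of the reference DEG set A).  OS is high when the
candidate mimics the target phenotype through genes the anchor does not
touch — the signature of a potentially synergistic partner.  OS lies in
[0, sqrt(5)].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .concordance import ncr_values
from .exceptions import UndefinedScoreError, ValidationError
from .io import BinarizedProfile, ReferenceProfile, SignatureMatrix, binarize_values

SQRT5 = math.sqrt(5.0)


@dataclass
class AggregateProfile:
    """Per-compound consensus trinary profile (mode of binarized replicates)."""

    compound_id: str
    gene_universe: pd.Index
    values: np.ndarray
    n_replicates: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if not np.isin(self.values, (-1, 0, 1)).all():
            raise ValidationError("aggregate calls must lie in {-1, 0, +1}")

    @property
    def calls(self) -> dict[str, int]:
        return dict(zip(self.gene_universe, (int(v) for v in self.values)))


@dataclass
class OrthogonalityResult:
    anchor_id: str
    candidate_id: str
    ncr_target: float
    ncr_drug: float
    os: float


def aggregate_signature(replicates: Sequence[BinarizedProfile],
                        compound_id: str = "aggregate") -> AggregateProfile:
    """Per-gene mode of the replicate calls; any tie for the most frequent
    value resolves to 0 (no majority direction -> non-significant)."""
    if not replicates:
        raise ValidationError("need at least one replicate profile")
    universe = pd.Index(replicates[0].gene_universe)
    stack = []
    for rep in replicates:
        if not universe.equals(pd.Index(rep.gene_universe)):
            raise ValidationError("replicates do not share a gene universe")
        stack.append(rep.values)
    arr = np.stack(stack)  # replicates x genes
    counts = np.stack([(arr == v).sum(axis=0) for v in (-1, 0, 1)])  # 3 x genes
    top = counts.max(axis=0)
    winners = (counts == top).sum(axis=0)
    mode = np.array([-1, 0, 1], dtype=np.int8)[counts.argmax(axis=0)]
    mode[winners > 1] = 0
    return AggregateProfile(compound_id, universe, mode, len(replicates))


def aggregate_compounds(matrix: SignatureMatrix,
                        z_threshold: float = 1.0) -> dict[str, AggregateProfile]:
    """Aggregate every compound's signatures in a (pre-filtered) matrix."""
    calls = binarize_values(matrix.values, z_threshold)
    out: dict[str, AggregateProfile] = {}
    for compound, sub in matrix.meta.groupby("compound_id", sort=True):
        cols = matrix.signature_ids.get_indexer(sub.index)
        reps = [BinarizedProfile(matrix.gene_ids, calls[:, j], str(matrix.signature_ids[j]))
                for j in cols]
        out[str(compound)] = aggregate_signature(reps, compound_id=str(compound))
    return out


def orthogonality_score(ncr_target: float, ncr_drug: float) -> float:
    """OS = sqrt(ncr_target^2 + (1 - ncr_drug)^2); inputs must lie in [-1, 1]."""
    if not (-1.0 <= ncr_target <= 1.0 and -1.0 <= ncr_drug <= 1.0):
        raise ValidationError("NCR inputs must lie in [-1, 1]")
    return math.sqrt(ncr_target ** 2 + (1.0 - ncr_drug) ** 2)


def orthogonality_screen(reference: ReferenceProfile, anchor: AggregateProfile,
                         candidates: Sequence[AggregateProfile]) -> pd.DataFrame:
    """Score every candidate against one anchor.

    ``ncr_target`` uses the reference DEG set as A; ``ncr_drug`` uses the
    anchor's nonzero calls as A.  The anchor itself must not appear among the
    candidates.  All profiles must share the reference's gene universe.
    """
    if not anchor.values.any():
        raise UndefinedScoreError(f"anchor {anchor.compound_id!r} has no nonzero calls")
    rows = []
    for cand in candidates:
        if cand.compound_id == anchor.compound_id:
            raise ValidationError("anchor must be excluded from the candidate list")
        if not reference.gene_universe.equals(pd.Index(cand.gene_universe)):
            raise ValidationError("candidate gene universe differs from the reference")
        ncr_t, _ = ncr_values(reference.values, cand.values)
        ncr_d, _ = ncr_values(anchor.values, cand.values)
        rows.append((anchor.compound_id, cand.compound_id, ncr_t, ncr_d,
                     orthogonality_score(ncr_t, ncr_d)))
    return pd.DataFrame(rows, columns=["anchor_id", "candidate_id",
                                       "ncr_target", "ncr_drug", "os"])


@dataclass
class OrthogonalityCriterion:
    """Criterion behind the binary orthogonality-enrichment call.

    A candidate is orthogonality-enriched against an anchor when its OS
    exceeds that anchor's screen-wide OS quantile (default: top 25%) and,
    when ``enriched_candidates`` is supplied, the candidate is itself a
    target-profile hit.  Every exported matrix records the criterion used.
    """

    quantile: float = 0.75
    enriched_candidates: set[str] | None = None

    def describe(self) -> str:
        extra = "" if self.enriched_candidates is None else " & target-enriched"
        return f"os > per-anchor quantile {self.quantile:g}{extra}"


def orthogonality_enrichment_profile(os_results: pd.DataFrame,
                                     criterion: OrthogonalityCriterion | None = None,
                                     ) -> pd.DataFrame:
    """Binary anchors x candidates matrix of orthogonality-enrichment calls.

    ``os_results`` is the concatenation of :func:`orthogonality_screen` frames
    over all anchors.  The anchor==candidate diagonal is excluded (zero).
    """
    criterion = criterion or OrthogonalityCriterion()
    anchors = sorted(os_results["anchor_id"].unique())
    candidates = sorted(os_results["candidate_id"].unique())
    mat = pd.DataFrame(0, index=pd.Index(anchors, name="anchor_id"),
                       columns=pd.Index(candidates, name="candidate_id"), dtype=np.int8)
    for anchor, grp in os_results.groupby("anchor_id"):
        cutoff = grp["os"].quantile(criterion.quantile)
        hit = grp[grp["os"] > cutoff]
        for row in hit.itertuples():
            if row.candidate_id == anchor:
                continue
            if (criterion.enriched_candidates is not None
                    and row.candidate_id not in criterion.enriched_candidates):
                continue
            mat.loc[anchor, row.candidate_id] = 1
    mat.attrs["criterion"] = criterion.describe()
    return mat
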