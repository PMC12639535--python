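"""Normalized Concordance Ratio screening with a label-permutation null.

For trinary profiles A (reference) and B (drug) over a shared gene universe,
with O the genes nonzero in both, C the genes of O where the calls agree and
D = O \\ C,

    NCR = (|C| - |D|) / |A|,

where |A| is the reference DEG count.  NCR ranges from -1 (B is the
sign-flipped reference) to +1 (B reproduces the reference on every DEG).
Because calls live in {-1, 0, +1}, |C| - |D| is the integer dot product
A . B and |O| is |A| . |B| elementwise; the permutation null (uniform
relabelings of the drug calls, which preserve the up/down counts by
construction) is therefore a matrix product of permuted call vectors against
the reference — this is what lets a 1,000-permutation screen over hundreds of
signatures run in seconds.

Significance is the one-sided upper tail by default (the screen looks for
concordance with the target profile) with the add-one correction
``p = (1 + #{perm >= obs}) / (1 + n_perm)``; Benjamini-Hochberg adjustment is
applied across the signatures of a screen.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .exceptions import UndefinedScoreError, ValidationError
from .io import BinarizedProfile, ReferenceProfile, SignatureMatrix, binarize_values

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ["signature_id", "compound_id", "cell_line", "ncr", "n_overlap",
                  "n_concordant", "n_discordant", "p_value", "q_value"]


@dataclass
class ConcordanceResult:
    signature_id: str
    ncr: float
    n_overlap: int
    n_concordant: int
    n_discordant: int
    p_value: float
    q_value: float

    def __post_init__(self) -> None:
        if self.n_concordant + self.n_discordant != self.n_overlap:
            raise ValidationError("|C| + |D| must equal |O|")
        if not -1.0 <= self.ncr <= 1.0:
            raise ValidationError(f"NCR {self.ncr} outside [-1, 1]")


@dataclass
class ScreenTable:
    """Per-signature screen results plus the context that produced them."""

    table: pd.DataFrame
    context: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.table["signature_id"].duplicated().any():
            dups = self.table.loc[self.table["signature_id"].duplicated(), "signature_id"]
            raise ValidationError(f"duplicate signature ids in table: {list(dups)[:5]}")

    def __len__(self) -> int:
        return len(self.table)


def _counts(ref_values: np.ndarray, drug_values: np.ndarray) -> tuple[int, int, int, int]:
    """Return (score |C|-|D|, |O|, |C|, |D|) for aligned trinary vectors."""
    a = np.asarray(ref_values, dtype=np.int64)
    b = np.asarray(drug_values, dtype=np.int64)
    score = int(a @ b)
    n_overlap = int(np.abs(a) @ np.abs(b))
    n_conc = (n_overlap + score) // 2
    return score, n_overlap, n_conc, n_overlap - n_conc


def ncr_values(ref_values: np.ndarray, drug_values: np.ndarray,
               n_deg: int | None = None) -> tuple[float, tuple[int, int, int]]:
    """NCR between two aligned trinary call vectors.

    ``n_deg`` overrides the denominator |A| (used when the reference DEG count
    should refer to a wider universe than the aligned one).
    """
    a = np.asarray(ref_values)
    if a.shape != np.shape(drug_values):
        raise ValidationError("profiles do not share a gene universe")
    n_a = int(np.count_nonzero(a)) if n_deg is None else int(n_deg)
    if n_a == 0:
        raise UndefinedScoreError("reference DEG set is empty (|A| = 0)")
    score, n_overlap, n_conc, n_disc = _counts(a, drug_values)
    return score / n_a, (n_overlap, n_conc, n_disc)


def ncr(reference: ReferenceProfile, drug: BinarizedProfile,
        n_deg: int | None = None) -> tuple[float, tuple[int, int, int]]:
    """NCR between a reference profile and a binarized drug profile.

    Returns ``(ncr, (|O|, |C|, |D|))``.  Both profiles must be defined over the
    same gene universe (align the reference first when they differ).
    """
    if not reference.gene_universe.equals(pd.Index(drug.gene_universe)):
        raise ValidationError("reference and drug gene universes differ; align first")
    return ncr_values(reference.values, drug.values, n_deg=n_deg)


def _signature_rng(seed: int, signature_id: str) -> np.random.Generator:
    """Per-signature RNG derived by stable hashing, so screen results do not
    depend on signature order."""
    h = hashlib.sha256(signature_id.encode("utf-8")).digest()
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), int.from_bytes(h[:8], "big")]))


def _null_scores(drug_values: np.ndarray, ref_matrix: np.ndarray,
                 n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Integer null scores A.T @ perm(B): shape (n_perm, n_refs).

    ``ref_matrix`` is genes x n_refs float32.  Products are exact in float32
    (integer-valued, magnitude < 2**24), so rounding recovers the integers.
    """
    perms = rng.permuted(
        np.broadcast_to(drug_values, (n_perm, len(drug_values))).copy(), axis=1)
    null = perms.astype(np.float32) @ ref_matrix
    return np.rint(null).astype(np.int64)


def permutation_test(reference: ReferenceProfile, drug: BinarizedProfile,
                     n_perm: int = 1000, seed: int = 0,
                     alternative: str = "greater") -> tuple[float, float]:
    """NCR plus a gene-label permutation p-value for one drug profile.

    Each permutation redistributes the drug's multiset of calls uniformly over
    the gene universe (up/down counts preserved); the reference is never
    permuted.  One-sided upper tail by default, ``alternative='two-sided'``
    counts permutations at least as extreme in absolute value.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    value, _ = ncr(reference, drug)
    if not drug.values.any():
        warnings.warn("drug profile is all-zero; permutation null is degenerate (p = 1)")
        return value, 1.0
    rng = _signature_rng(seed, drug.signature_id or "signature")
    ref_col = reference.values.astype(np.float32)[:, None]
    null = _null_scores(drug.values, ref_col, n_perm, rng)[:, 0]
    obs = _counts(reference.values, drug.values)[0]
    if alternative == "greater":
        hits = int((null >= obs).sum())
    elif alternative == "two-sided":
        hits = int((np.abs(null) >= abs(obs)).sum())
    else:
        raise ValidationError(f"unknown alternative {alternative!r}")
    return value, (1 + hits) / (1 + n_perm)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def screen_multi(references: Mapping[str, ReferenceProfile], matrix: SignatureMatrix,
                 z_threshold: float = 1.0, n_perm: int = 1000, seed: int = 0,
                 alternative: str = "greater") -> dict[str, ScreenTable]:
    """Screen every signature against several references in one pass.

    All references share the permutations drawn for each signature (one
    permuted-call matrix per signature scores every reference by a single
    matrix product), so screening one reference or twelve pathway-restricted
    ones yields bit-identical per-reference results.  BH adjustment is applied
    per reference across signatures.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    names = list(references)
    aligned = {n: r.align(matrix.gene_ids) for n, r in references.items()}
    universe = aligned[names[0]].gene_universe
    sub = matrix.subset_genes(list(universe))
    calls = binarize_values(sub.values, z_threshold)

    ref_mat = np.column_stack([aligned[n].values for n in names]).astype(np.float32)
    n_deg = np.array([aligned[n].n_deg for n in names], dtype=float)
    if (n_deg == 0).any():
        empty = [n for n, d in zip(names, n_deg) if d == 0]
        raise UndefinedScoreError(f"references with empty DEG set: {empty}")

    obs = np.rint(calls.T.astype(np.float32) @ ref_mat).astype(np.int64)  # sigs x refs
    overlap = np.rint(np.abs(calls.T).astype(np.float32) @ np.abs(ref_mat)).astype(np.int64)

    n_sig = calls.shape[1]
    hits = np.zeros((n_sig, len(names)), dtype=np.int64)
    for j, sig in enumerate(sub.signature_ids):
        b = calls[:, j]
        if not b.any():
            hits[j] = n_perm  # degenerate null: p = 1
            continue
        rng = _signature_rng(seed, str(sig))
        null = _null_scores(b, ref_mat, n_perm, rng)
        if alternative == "greater":
            hits[j] = (null >= obs[j]).sum(axis=0)
        elif alternative == "two-sided":
            hits[j] = (np.abs(null) >= np.abs(obs[j])).sum(axis=0)
        else:
            raise ValidationError(f"unknown alternative {alternative!r}")
    pvals = (1 + hits) / (1 + n_perm)

    out: dict[str, ScreenTable] = {}
    meta = sub.meta
    for k, name in enumerate(names):
        df = pd.DataFrame({
            "signature_id": sub.signature_ids,
            "compound_id": meta["compound_id"].to_numpy(),
            "cell_line": meta["cell_line"].to_numpy(),
            "ncr": obs[:, k] / n_deg[k],
            "n_overlap": overlap[:, k],
            "n_concordant": (overlap[:, k] + obs[:, k]) // 2,
            "n_discordant": (overlap[:, k] - obs[:, k]) // 2,
            "p_value": pvals[:, k],
        })
        df["q_value"] = bh_adjust(df["p_value"])
        out[name] = ScreenTable(df.reset_index(drop=True), context={
            "reference": aligned[name].name, "n_deg": int(n_deg[k]),
            "z_threshold": z_threshold, "n_perm": n_perm, "seed": seed,
            "alternative": alternative, "deg_space": "shared",
        })
    return out


def screen_concordance(reference: ReferenceProfile, matrix: SignatureMatrix,
                       z_threshold: float = 1.0, n_perm: int = 1000, seed: int = 0,
                       alternative: str = "greater") -> ScreenTable:
    """Binarize every signature, score NCR + permutation p against the
    reference, and BH-adjust across the screen.  Deterministic given ``seed``
    and invariant to signature order."""
    return screen_multi({"full": reference}, matrix, z_threshold=z_threshold,
                        n_perm=n_perm, seed=seed, alternative=alternative)["full"]
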