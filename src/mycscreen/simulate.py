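"""Synthetic screens with planted ground truth.

The generator emulates the shape of an L1000-style screen — a reference
differential-expression profile with a fixed number of up/down DEGs, and a
drug-signature matrix of per-gene Z-scores with replicate structure, per-
signature metadata (compound, cell line, dose, time, TAS) and a population of
compounds — while planting known signal:

* *antagonists* copy a controllable fraction of the reference DEG calls
  concordantly (and a smaller fraction discordantly) into Z-scores past the
  binarization boundary, so a replicate's expected NCR is approximately
  ``overlap - discordant_rate``;
* *orthogonal pairs* are concordant on disjoint blocks of the DEG set;
* *null compounds* carry calls independent of the reference at the same
  marginal nonzero rate as planted ones, so permutation nulls are exercised at
  matched sparsity;
* a held-out fraction of low-TAS decoy signatures exercises the quality
  filter.

Planted Z-magnitudes are drawn uniform in [1.2, 3] — beyond the |Z| >= 1
boundary with margin, so Gaussian noise with SD <= 0.1 cannot flip a call.
Every generated object comes with a truth table; downstream tests read their
expected outcomes from it.  All generation is reproducible from
``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import GeneSetCollection, ReferenceProfile, SignatureMatrix, build_reference
from .orthogonality import AggregateProfile

CALL_LO, CALL_HI = 1.2, 3.0  # planted |Z| magnitudes


@dataclass
class ScreenConfig:
    """Study conditions for a synthetic screen.

    Defaults mirror the screened corpus: 978 landmark genes, a 728-gene
    reference DEG set, 10 cell lines at 10 uM / 24 h, TAS-filtered signatures,
    and planted antagonists at overlap 0.5 / discordant rate 0.1 (expected
    replicate NCR around 0.4, the scale of the strongest real single agents).
    """

    n_genes: int = 978
    n_deg: int = 728
    frac_up: float = 0.5
    fc_threshold: float = 1.0
    p_threshold: float = 0.05
    n_compounds: int = 200
    replicates_per_compound: int = 3
    n_cell_lines: int = 10
    antagonist_ids: tuple[str, ...] | None = None
    n_antagonists: int = 5
    antagonist_overlap: float = 0.5
    discordant_rate: float = 0.1
    background_nonzero_rate: float = 0.15
    n_low_tas_decoys: int = 10
    n_line_decoys: int = 2
    antagonist_lines: int | None = None
    noise_sd: float = 0.1
    dose: str = "10uM"
    time: str = "24h"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_deg > self.n_genes:
            raise ValidationError("n_deg cannot exceed n_genes")
        for name in ("frac_up", "antagonist_overlap", "discordant_rate",
                     "background_nonzero_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.antagonist_overlap + self.discordant_rate > 1.0:
            raise ValidationError("overlap + discordant_rate cannot exceed 1")

    @property
    def compound_ids(self) -> list[str]:
        return [f"drug_{i:03d}" for i in range(self.n_compounds)]

    def planted_antagonists(self) -> list[str]:
        if self.antagonist_ids is not None:
            unknown = set(self.antagonist_ids) - set(self.compound_ids)
            if unknown:
                raise ValidationError(f"antagonist_ids not among compounds: {sorted(unknown)}")
            return list(self.antagonist_ids)
        return self.compound_ids[: self.n_antagonists]


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:04d}" for i in range(n)]


def simulate_reference(config: ScreenConfig,
                       rng: np.random.Generator | None = None) -> ReferenceProfile:
    """Reference profile with exactly ``n_deg`` DEGs, ``round(frac_up*n_deg)``
    of them upregulated; fold changes land beyond the (strict) threshold for
    DEGs and inside it otherwise, p-values below / above threshold likewise."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    genes = pd.Index(_gene_ids(config.n_genes))
    n_up = round(config.frac_up * config.n_deg)
    deg_idx = rng.choice(config.n_genes, size=config.n_deg, replace=False)
    signs = np.zeros(config.n_genes, dtype=np.int8)
    signs[deg_idx[:n_up]] = 1
    signs[deg_idx[n_up:]] = -1
    fc = rng.uniform(-config.fc_threshold * 0.95, config.fc_threshold * 0.95,
                     size=config.n_genes)
    mag = config.fc_threshold + rng.uniform(0.1, 3.0, size=config.n_deg)
    fc[deg_idx] = signs[deg_idx] * mag
    pval = rng.uniform(0.0, 1.0, size=config.n_genes)
    pval[deg_idx] = rng.uniform(0.0, config.p_threshold * 0.99, size=config.n_deg)
    return build_reference(pd.Series(fc, index=genes), pd.Series(pval, index=genes),
                           fc_threshold=config.fc_threshold,
                           p_threshold=config.p_threshold, name="synthetic-target")


def _planted_replicate(ref_values: np.ndarray, config: ScreenConfig,
                       rng: np.random.Generator, antagonist: bool) -> np.ndarray:
    """One replicate Z-score vector (before noise is meaningful on calls)."""
    n_genes = len(ref_values)
    deg_pos = np.flatnonzero(ref_values)
    non_deg = np.flatnonzero(ref_values == 0)
    z = rng.normal(0.0, config.noise_sd, size=n_genes)
    n_conc = round(config.antagonist_overlap * len(deg_pos))
    n_disc = round(config.discordant_rate * len(deg_pos))
    if antagonist:
        picked = rng.choice(deg_pos, size=n_conc + n_disc, replace=False)
        conc, disc = picked[:n_conc], picked[n_conc:]
        z[conc] = ref_values[conc] * rng.uniform(CALL_LO, CALL_HI, size=n_conc)
        z[disc] = -ref_values[disc] * rng.uniform(CALL_LO, CALL_HI, size=n_disc)
        n_bg = round(config.background_nonzero_rate * len(non_deg))
        bg = rng.choice(non_deg, size=n_bg, replace=False)
        z[bg] = rng.choice([-1, 1], size=n_bg) * rng.uniform(CALL_LO, CALL_HI, size=n_bg)
    else:
        # matched marginal sparsity, independent of the reference
        n_nz = round(n_conc + n_disc + config.background_nonzero_rate * len(non_deg))
        nz = rng.choice(n_genes, size=n_nz, replace=False)
        z[nz] = rng.choice([-1, 1], size=n_nz) * rng.uniform(CALL_LO, CALL_HI, size=n_nz)
    return z


def simulate_drug_matrix(reference: ReferenceProfile, config: ScreenConfig,
                         rng: np.random.Generator | None = None,
                         cell_line: str = "LINE_00",
                         antagonist_ids: Sequence[str] | None = None,
                         ) -> tuple[SignatureMatrix, pd.DataFrame]:
    """Drug-signature matrix for one cell line plus its truth table.

    Planted antagonists copy ``antagonist_overlap`` of the reference DEG calls
    concordantly and ``discordant_rate`` discordantly per replicate; the rest
    of the population is independent of the reference at matched sparsity.
    ``n_low_tas_decoys`` extra null signatures carry TAS < 0.4 and should fall
    to the quality filter.  The truth table has one row per signature.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    antagonists = set(config.planted_antagonists() if antagonist_ids is None
                      else antagonist_ids)
    cols, zs, meta_rows, truth_rows = [], [], [], []

    def add_signature(sig_id: str, compound: str, is_antagonist: bool, tas: float) -> None:
        z = _planted_replicate(reference.values, config, rng, is_antagonist)
        cols.append(sig_id)
        zs.append(z)
        meta_rows.append((sig_id, compound, cell_line, config.dose, config.time, tas))
        truth_rows.append((sig_id, compound, cell_line, is_antagonist, tas >= 0.4,
                           (config.antagonist_overlap - config.discordant_rate)
                           if is_antagonist else 0.0))

    for compound in config.compound_ids:
        for rep in range(config.replicates_per_compound):
            add_signature(f"{cell_line}:{compound}:rep{rep}", compound,
                          compound in antagonists, float(rng.uniform(0.4, 1.0)))
    decoy_hosts = rng.choice(config.compound_ids, size=config.n_low_tas_decoys)
    for k, compound in enumerate(decoy_hosts):
        add_signature(f"{cell_line}:{compound}:lowtas{k}", str(compound), False,
                      float(rng.uniform(0.0, 0.399)))

    values = pd.DataFrame(np.column_stack(zs), index=reference.gene_universe,
                          columns=cols)
    meta = pd.DataFrame(meta_rows, columns=["signature_id", "compound_id", "cell_line",
                                            "dose", "time", "tas"]).set_index("signature_id")
    truth = pd.DataFrame(truth_rows, columns=["signature_id", "compound_id", "cell_line",
                                              "is_antagonist", "tas_pass", "expected_ncr"])
    return SignatureMatrix(values, meta), truth


def simulate_gene_sets(reference: ReferenceProfile, config: ScreenConfig,
                       n_sets: int = 12, extra_per_set: int = 20,
                       rng: np.random.Generator | None = None) -> GeneSetCollection:
    """Pathway-style gene sets: the reference DEGs split into ``n_sets``
    blocks, each padded with non-DEG genes; direction tags follow the majority
    call sign inside each set."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    degs = np.array(sorted(reference.deg_set))
    rng.shuffle(degs)
    non_deg = np.array(sorted(set(reference.gene_universe) - reference.deg_set))
    blocks = np.array_split(degs, n_sets)
    sets, tags = {}, {}
    calls = pd.Series(reference.values, index=reference.gene_universe)
    for i, block in enumerate(blocks):
        extra = rng.choice(non_deg, size=min(extra_per_set, len(non_deg)), replace=False)
        name = f"PATHWAY_{i:02d}"
        sets[name] = set(block) | set(extra)
        tags[name] = "up" if calls[block].sum() >= 0 else "down"
    return GeneSetCollection(sets, tags)


def simulate_orthogonal_pair(reference: ReferenceProfile, config: ScreenConfig,
                             partition: tuple[set[str], set[str]] | None = None,
                             rng: np.random.Generator | None = None,
                             ) -> tuple[AggregateProfile, AggregateProfile, dict]:
    """Two aggregate profiles concordant on disjoint blocks of the DEG set.

    With the default partition (a random equal split of the DEGs) each
    compound's expected NCR against the target is ~0.5 while their mutual
    drug-vs-drug NCR is 0 (disjoint supports).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    degs = sorted(reference.deg_set)
    if partition is None:
        perm = rng.permutation(len(degs))
        half = len(degs) // 2
        partition = ({degs[i] for i in perm[:half]}, {degs[i] for i in perm[half:]})
    block1, block2 = partition
    if block1 & block2:
        raise ValidationError("partition blocks overlap")
    universe = reference.gene_universe
    truth = {}
    profiles = []
    for cid, block in (("ortho_A", block1), ("ortho_B", block2)):
        mask = universe.isin(block)
        vals = np.where(mask, reference.values, 0).astype(np.int8)
        profiles.append(AggregateProfile(cid, universe, vals, 1))
        truth[cid] = {"block_size": int(np.count_nonzero(vals)),
                      "expected_ncr_target": np.count_nonzero(vals) / reference.n_deg}
    truth["expected_mutual_ncr"] = 0.0
    return profiles[0], profiles[1], truth


@dataclass
class MultiLineBundle:
    """Per-cell-line synthetic matrices plus the planted truth."""

    matrices: dict[str, SignatureMatrix]
    truth: pd.DataFrame
    pan_antagonists: list[str]
    line_decoys: dict[str, list[str]]

    def expected_recurrent(self, min_lines: int) -> set[str]:
        per_compound = (self.truth[self.truth["is_antagonist"]]
                        .groupby("compound_id")["cell_line"].nunique())
        return set(per_compound.index[per_compound >= min_lines])


def simulate_multi_cell_line(config: ScreenConfig,
                             reference: ReferenceProfile | None = None,
                             ) -> tuple[ReferenceProfile, MultiLineBundle]:
    """A multi-cell-line screen with pan-line antagonists and line-specific decoys.

    Pan-line antagonists are planted in ``antagonist_lines`` of the
    ``n_cell_lines`` lines (all of them when None); each line additionally
    gets ``n_line_decoys`` compounds planted as antagonists in that line only.
    """
    master = np.random.default_rng(config.seed)
    reference = reference if reference is not None else simulate_reference(config, master)
    lines = [f"LINE_{i:02d}" for i in range(config.n_cell_lines)]
    pan = config.planted_antagonists()
    n_lines_each = config.antagonist_lines or config.n_cell_lines
    if not 1 <= n_lines_each <= config.n_cell_lines:
        raise ValidationError("antagonist_lines out of range")
    present_in = {a: set(master.choice(lines, size=n_lines_each, replace=False))
                  for a in pan}
    others = [c for c in config.compound_ids if c not in set(pan)]
    n_decoys_total = config.n_line_decoys * config.n_cell_lines
    if n_decoys_total > len(others):
        raise ValidationError("not enough compounds for disjoint line-specific decoys")
    decoy_pool = list(master.choice(others, size=n_decoys_total, replace=False))
    matrices, truths, line_decoys = {}, [], {}
    child_seeds = np.random.SeedSequence(config.seed).spawn(config.n_cell_lines)
    for k, (line, ss) in enumerate(zip(lines, child_seeds)):
        rng = np.random.default_rng(ss)
        decoys = decoy_pool[k * config.n_line_decoys:(k + 1) * config.n_line_decoys]
        line_decoys[line] = decoys
        active = [a for a in pan if line in present_in[a]] + decoys
        mat, truth = simulate_drug_matrix(reference, config, rng=rng,
                                          cell_line=line, antagonist_ids=active)
        matrices[line] = mat
        truths.append(truth)
    bundle = MultiLineBundle(matrices, pd.concat(truths, ignore_index=True),
                             list(pan), line_decoys)
    return reference, bundle


def simulate_community_profiles(n_blocks: int = 6, per_block: int = 10,
                                profile_len: int | None = None, n_flips: int = 2,
                                seed: int = 0) -> tuple[dict[str, np.ndarray],
                                                        dict[str, int]]:
    """Binary partner profiles with planted block-community structure.

    Emulates the orthogonality-enrichment profiles of a compound population in
    which each community shares one characteristic on-pattern: block ``b``'s
    members carry that block's indicator segment with ``n_flips`` random bit
    flips each, so within-block Jaccard similarity is far above between-block.
    Returns ``(profiles, planted_labels)``; the labels are the ground truth
    for community-recovery tests.
    """
    profile_len = profile_len if profile_len is not None else n_blocks * per_block
    if profile_len < n_blocks:
        raise ValidationError("profile_len must be at least n_blocks")
    rng = np.random.default_rng(seed)
    seg = profile_len // n_blocks
    profiles: dict[str, np.ndarray] = {}
    labels: dict[str, int] = {}
    for b in range(n_blocks):
        base = np.zeros(profile_len, dtype=np.int8)
        base[b * seg:(b + 1) * seg] = 1
        for k in range(per_block):
            vec = base.copy()
            flips = rng.choice(profile_len, size=n_flips, replace=False)
            vec[flips] ^= 1
            node = f"b{b}n{k:02d}"
            profiles[node] = vec
            labels[node] = b
    return profiles, labels


def config_with(config: ScreenConfig, **overrides) -> ScreenConfig:
    """A copy of ``config`` with fields replaced (dataclasses.replace wrapper)."""
    return replace(config, **overrides)
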