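"""End-to-end orchestration: filter -> concordance -> pathways -> enrichment
-> recurrence -> orthogonality -> network, with deterministic file outputs.

:func:`run_screen` executes the whole screen on in-memory objects and returns
a :class:`ScreenResults`; :func:`run_full_screen` wraps it with file I/O — it
reads a :class:`RunConfig` (YAML/JSON), loads the reference TSV, signature
GCTs, GMT and optional MoA table, and writes every intermediate table under
the output directory.  Each output file carries a header comment with the
config hash and seed; identical configs reproduce every file bit-exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .concordance import ScreenTable, screen_multi
from .enrichment import (compound_enrichment, enriched_compounds, pathway_enrichment,
                         pathway_enriched_compounds, recurrent_hits)
from .exceptions import MycScreenError, ValidationError
from .io import (GeneSetCollection, ReferenceProfile, SignatureMatrix, build_reference,
                 filter_signatures, read_gct, read_gmt, read_reference_tsv, write_gct,
                 write_gmt, write_reference_tsv)
from .network import (SimilarityMatrix, annotate_moa, build_network, centrality,
                      detect_communities, jaccard_matrix)
from .orthogonality import (OrthogonalityCriterion, aggregate_compounds,
                            orthogonality_enrichment_profile, orthogonality_screen)
from .pathways import AgreementResult, compare_methods, restrict_reference

logger = logging.getLogger(__name__)

FULL_KEY = "__full__"


@dataclass
class ScreenParams:
    """Screen-wide thresholds; defaults mirror the published screen
    (|Z| >= 1, TAS >= 0.4 at 10 uM / 24 h, 1000 permutations, FDR 0.05,
    recurrence in >= 3 cell lines)."""

    z_threshold: float = 1.0
    tas_min: float = 0.4
    dose: str | None = "10uM"
    time: str | None = "24h"
    n_perm: int = 1000
    fdr_max: float = 0.05
    min_lines: int = 3
    edge_threshold: float = 0.0
    os_quantile: float = 0.75
    pathway_rule: str = "any"
    ortho_cell_line: str | None = None
    seed: int = 0


@dataclass
class RunConfig:
    """File-level run configuration (parsed from YAML or JSON)."""

    reference: str
    signatures: list[str]
    gene_sets: str
    outdir: str
    moa: str | None = None
    fc_threshold: float = 1.0
    p_threshold: float = 0.05
    params: ScreenParams = field(default_factory=ScreenParams)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        params = ScreenParams(**raw.pop("params", {}))
        return cls(params=params, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class ScreenResults:
    concordance: dict[str, ScreenTable]
    pathway: dict[str, dict[str, ScreenTable]]
    enrichment_full: dict[str, pd.DataFrame]
    enrichment_pathway: dict[str, pd.DataFrame]
    recurrence: pd.DataFrame
    agreement: AgreementResult
    ortho: pd.DataFrame | None = None
    ortho_matrix: pd.DataFrame | None = None
    similarity: SimilarityMatrix | None = None
    graph: nx.Graph | None = None
    communities: dict[str, int] | None = None
    centrality: pd.DataFrame | None = None
    moa_abundance: pd.DataFrame | None = None


def screen_cell_line(reference: ReferenceProfile, matrix: SignatureMatrix,
                     gene_sets: GeneSetCollection, params: ScreenParams,
                     ) -> tuple[ScreenTable, dict[str, ScreenTable], pd.DataFrame, pd.DataFrame]:
    """Concordance + pathway screens and both enrichment methods for one line."""
    filtered = filter_signatures(matrix, dose=params.dose, time=params.time,
                                 tas_min=params.tas_min)
    refs: dict[str, ReferenceProfile] = {FULL_KEY: reference}
    for set_name, genes in gene_sets:
        try:
            refs[set_name] = restrict_reference(reference, genes, name=set_name)
        except MycScreenError as exc:
            logger.warning("skipping pathway %s: %s", set_name, exc)
    tables = screen_multi(refs, filtered, z_threshold=params.z_threshold,
                          n_perm=params.n_perm, seed=params.seed)
    full_table = tables.pop(FULL_KEY)
    enr_full = compound_enrichment(full_table, n_perm=params.n_perm, seed=params.seed)
    enr_pw = pathway_enrichment(tables, n_perm=params.n_perm, seed=params.seed)
    return full_table, tables, enr_full, enr_pw


def run_screen(reference: ReferenceProfile, matrices: Mapping[str, SignatureMatrix],
               gene_sets: GeneSetCollection, params: ScreenParams,
               moa: Mapping[str, str] | None = None) -> ScreenResults:
    """Execute the full screen on in-memory inputs.

    ``matrices`` maps cell line -> signature matrix.  Anchors for the
    orthogonality stage are the compounds passing the recurrence filter;
    aggregation happens in ``params.ortho_cell_line`` (first line by default).
    """
    concordance, pathway = {}, {}
    enr_full, enr_pw = {}, {}
    labels_full: dict[str, bool] = {}
    labels_pw: dict[str, bool] = {}
    for line in sorted(matrices):
        full_table, pw_tables, ef, ep = screen_cell_line(
            reference, matrices[line], gene_sets, params)
        concordance[line] = full_table
        pathway[line] = pw_tables
        enr_full[line] = ef
        enr_pw[line] = ep
        full_set = enriched_compounds(ef, params.fdr_max)
        pw_set = pathway_enriched_compounds(ep, params.fdr_max, rule=params.pathway_rule)
        for compound in ef["compound_id"]:
            labels_full[f"{line}:{compound}"] = compound in full_set
            labels_pw[f"{line}:{compound}"] = compound in pw_set

    recurrence = recurrent_hits(
        {line: (enr_full[line], enr_pw[line]) for line in enr_full},
        min_lines=params.min_lines, fdr_max=params.fdr_max,
        pathway_rule=params.pathway_rule)
    agreement = compare_methods(labels_full, labels_pw)
    results = ScreenResults(concordance, pathway, enr_full, enr_pw,
                            recurrence, agreement)

    anchors = list(recurrence.loc[recurrence["passes"], "compound_id"])
    ortho_line = params.ortho_cell_line or sorted(matrices)[0]
    if not anchors:
        logger.warning("no recurrent hits: orthogonality/network stages skipped")
        return results

    mat = filter_signatures(matrices[ortho_line], dose=params.dose,
                            time=params.time, tas_min=params.tas_min)
    ref_aligned = reference.align(mat.gene_ids)
    sub = mat.subset_genes(list(ref_aligned.gene_universe))
    aggregates = aggregate_compounds(sub, z_threshold=params.z_threshold)
    anchors = [a for a in anchors if a in aggregates]
    frames = []
    for anchor in anchors:
        candidates = [p for c, p in aggregates.items() if c != anchor]
        frames.append(orthogonality_screen(ref_aligned, aggregates[anchor], candidates))
    os_results = pd.concat(frames, ignore_index=True)
    criterion = OrthogonalityCriterion(
        quantile=params.os_quantile,
        enriched_candidates=enriched_compounds(enr_full[ortho_line], params.fdr_max))
    ortho_matrix = orthogonality_enrichment_profile(os_results, criterion)
    results.ortho = os_results
    results.ortho_matrix = ortho_matrix

    if len(anchors) < 2:
        logger.warning("fewer than two anchors: network stage skipped")
        return results
    profiles = ortho_matrix.loc[anchors]
    sim = jaccard_matrix(profiles)
    graph = build_network(sim, edge_threshold=params.edge_threshold)
    communities = detect_communities(graph)
    graph, abundance = annotate_moa(graph, dict(moa or {}), communities)
    results.similarity = sim
    results.graph = graph
    results.communities = communities
    results.centrality = centrality(graph)
    results.moa_abundance = abundance
    return results


# ---------------------------------------------------------------------------
# File-level pipeline
# ---------------------------------------------------------------------------

def _write_tsv(df: pd.DataFrame, path: Path, header: str, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=index)


def write_screen_inputs(reference: ReferenceProfile, matrices: Mapping[str, SignatureMatrix],
                        gene_sets: GeneSetCollection, outdir: str | Path,
                        truth: pd.DataFrame | None = None) -> dict[str, str]:
    """Write a simulated screen to disk in the formats the pipeline consumes;
    returns the path map usable as the skeleton of a :class:`RunConfig`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref_path = outdir / "reference.tsv"
    write_reference_tsv(reference.fc, reference.pval, ref_path)
    gmt_path = outdir / "gene_sets.gmt"
    write_gmt(gene_sets, gmt_path)
    sig_paths = []
    for line in sorted(matrices):
        p = outdir / f"signatures_{line}.gct"
        write_gct(matrices[line], p)
        sig_paths.append(str(p))
    if truth is not None:
        truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return {"reference": str(ref_path), "signatures": sig_paths,
            "gene_sets": str(gmt_path)}


def run_full_screen(config: RunConfig) -> ScreenResults:
    """Load inputs, run the screen, and write every stage's tables.

    Outputs land in ``config.outdir``; every TSV starts with a header comment
    carrying the config hash and seed, and ``manifest.json`` records the
    config, hash, seed and package version.  A stage failure aborts with the
    stage name in the exception message.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    head = f"# mycscreen config_hash={config.hash()} seed={config.params.seed}\n"

    def stage(name):
        def wrap(fn, *a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as exc:
                raise MycScreenError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    fc, pval = stage("read_reference")(read_reference_tsv, config.reference)
    reference = build_reference(fc, pval, fc_threshold=config.fc_threshold,
                                p_threshold=config.p_threshold)
    gene_sets = stage("read_gene_sets")(read_gmt, config.gene_sets)
    matrices: dict[str, SignatureMatrix] = {}
    for path in config.signatures:
        m = stage("read_signatures")(read_gct, path)
        for line, meta in m.meta.groupby("cell_line"):
            ids = list(meta.index)
            part = SignatureMatrix(m.values[ids], m.meta.loc[ids])
            if line in matrices:
                raise ValidationError(f"cell line {line!r} appears in multiple files")
            matrices[str(line)] = part
    moa: dict[str, str] = {}
    if config.moa:
        moa_df = pd.read_csv(config.moa, sep="\t", comment="#")
        moa = dict(zip(moa_df.iloc[:, 0].astype(str), moa_df.iloc[:, 1].astype(str)))

    results = run_screen(reference, matrices, gene_sets, config.params, moa)

    for line, table in results.concordance.items():
        _write_tsv(table.table, outdir / f"concordance_{line}.tsv", head)
        pw = pd.concat([t.table.assign(set_name=n) for n, t in results.pathway[line].items()],
                       ignore_index=True)
        _write_tsv(pw, outdir / f"pathway_{line}.tsv", head)
        _write_tsv(results.enrichment_full[line],
                   outdir / f"enrichment_full_{line}.tsv", head)
        _write_tsv(results.enrichment_pathway[line],
                   outdir / f"enrichment_pathway_{line}.tsv", head)
    _write_tsv(results.recurrence, outdir / "recurrence.tsv", head)
    agg = results.agreement
    with open(outdir / "agreement.json", "w") as fh:
        json.dump({"table": agg.table.tolist(), "odds_ratio": agg.odds_ratio,
                   "p_value": agg.p_value, "corrected": agg.corrected}, fh, indent=1)
        fh.write("\n")
    if results.ortho is not None:
        _write_tsv(results.ortho, outdir / "orthogonality.tsv", head)
        _write_tsv(results.ortho_matrix, outdir / "ortho_matrix.tsv", head, index=True)
    if results.graph is not None:
        _write_tsv(results.similarity.to_frame(), outdir / "similarity.tsv", head, index=True)
        nx.write_graphml(results.graph, outdir / "network.graphml")
        comm = pd.DataFrame(sorted(results.communities.items()),
                            columns=["compound_id", "community"])
        _write_tsv(comm, outdir / "communities.tsv", head)
        _write_tsv(results.centrality, outdir / "centrality.tsv", head)
        _write_tsv(results.moa_abundance, outdir / "moa_abundance.tsv", head)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump({"config": config.to_dict(), "config_hash": config.hash(),
                   "seed": config.params.seed, "version": __version__}, fh,
                  indent=1, sort_keys=True)
        fh.write("\n")
    return results
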