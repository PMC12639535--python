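"""Orthogonality screen for combination nomination.

Aggregates each compound's replicates (per-gene mode of binarized calls) in
the anchor cell line, scores every candidate against each recurrent-hit
anchor with OS = sqrt(NCR_target^2 + (1 - NCR_drug)^2), and binarizes the
anchor x candidate matrix (top-quartile OS per anchor, candidate must itself
be target-enriched).  Writes results/orthogonality.tsv and
results/ortho_matrix.tsv."""

import pandas as pd
from screen_setup import CELL_LINES, INPUTS, PARAMS, RESULTS

from mycscreen import (OrthogonalityCriterion, aggregate_compounds, build_reference,
                       enriched_compounds, filter_signatures,
                       orthogonality_enrichment_profile, orthogonality_screen,
                       read_gct, read_reference_tsv)


def main() -> None:
    line = CELL_LINES[0]
    fc, pval = read_reference_tsv(INPUTS / "reference.tsv")
    reference = build_reference(fc, pval)
    matrix = filter_signatures(read_gct(INPUTS / f"signatures_{line}.gct"),
                               dose=PARAMS.dose, time=PARAMS.time,
                               tas_min=PARAMS.tas_min)
    ref_aligned = reference.align(matrix.gene_ids)
    aggregates = aggregate_compounds(matrix.subset_genes(list(ref_aligned.gene_universe)),
                                     z_threshold=PARAMS.z_threshold)

    rec = pd.read_csv(RESULTS / "recurrence.tsv", sep="\t")
    anchors = [a for a in rec.loc[rec.passes, "compound_id"] if a in aggregates]
    frames = [orthogonality_screen(ref_aligned, aggregates[a],
                                   [p for c, p in aggregates.items() if c != a])
              for a in anchors]
    os_results = pd.concat(frames, ignore_index=True)
    os_results.to_csv(RESULTS / "orthogonality.tsv", sep="\t", index=False)

    enriched = enriched_compounds(
        pd.read_csv(RESULTS / f"enrichment_full_{line}.tsv", sep="\t"), PARAMS.fdr_max)
    criterion = OrthogonalityCriterion(quantile=PARAMS.os_quantile,
                                       enriched_candidates=enriched)
    mat = orthogonality_enrichment_profile(os_results, criterion)
    mat.to_csv(RESULTS / "ortho_matrix.tsv", sep="\t")

    print(f"anchors: {anchors} (cell line {line})")
    top = os_results.nlargest(5, "os")
    print("top anchor-candidate pairs by OS:")
    print(top.round(3).to_string(index=False))
    print(f"orthogonality-enrichment calls: {int(mat.to_numpy().sum())} "
          f"of {mat.size} anchor x candidate cells "
          f"(criterion: {mat.attrs['criterion']})")

    # positive control: a planted complementary pair (concordant on disjoint
    # halves of the DEG set) should maximize OS against each other
    from screen_setup import CONFIG
    from mycscreen import AggregateProfile, simulate_orthogonal_pair
    a, b, truth = simulate_orthogonal_pair(reference, CONFIG)
    clone = AggregateProfile("clone_of_A", a.gene_universe, a.values.copy(), 1)
    ctrl = orthogonality_screen(reference, a, [b, clone])
    print("\nplanted complementary pair vs a clone of the anchor:")
    print(ctrl.round(3).to_string(index=False))
    best = ctrl.sort_values("os", ascending=False).iloc[0]
    print(f"complementary partner tops the OS ranking: {best.candidate_id == b.compound_id}")


if __name__ == "__main__":
    main()
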