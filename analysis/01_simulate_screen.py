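"""Generate the synthetic screen: reference profile, per-cell-line drug
signature matrices with planted antagonists, pathway gene sets, and the
ground-truth table.  Writes everything under results/inputs/."""

from screen_setup import CONFIG, INPUTS

from mycscreen import simulate_gene_sets, simulate_multi_cell_line, write_screen_inputs


def main() -> None:
    reference, bundle = simulate_multi_cell_line(CONFIG)
    gene_sets = simulate_gene_sets(reference, CONFIG)
    paths = write_screen_inputs(reference, bundle.matrices, gene_sets, INPUTS,
                                truth=bundle.truth)
    n_sigs = sum(m.shape[1] for m in bundle.matrices.values())
    print(f"reference: {reference.n_deg} DEGs over {len(reference.gene_universe)} genes")
    print(f"signatures: {n_sigs} across {len(bundle.matrices)} cell lines")
    print(f"planted pan-line antagonists: {bundle.pan_antagonists}")
    print(f"line-specific decoys: {bundle.line_decoys}")
    print(f"inputs written under {INPUTS}")
    assert paths["signatures"]


if __name__ == "__main__":
    main()
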