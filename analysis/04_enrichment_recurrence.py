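"""Compound-level enrichment, method agreement, and the recurrence filter.

Reads the per-line concordance and pathway tables written by drivers 02/03,
collapses them to compound-level enrichment calls (KS running sum, 300
permutations, NES > 0 & FDR <= 0.05), cross-tabulates the two methods'
labels (Fisher exact), and keeps compounds enriched by BOTH methods in at
least 2 of the 3 cell lines.  Writes enrichment, agreement and recurrence
tables and reports whether the planted antagonists are recovered exactly."""

import json

import pandas as pd
from screen_setup import CELL_LINES, INPUTS, PARAMS, RESULTS

from mycscreen import (ScreenTable, compare_methods, compound_enrichment,
                       enriched_compounds, pathway_enriched_compounds,
                       pathway_enrichment, recurrent_hits)


def load_tables(line: str):
    full = ScreenTable(pd.read_csv(RESULTS / f"concordance_{line}.tsv", sep="\t"))
    pw_df = pd.read_csv(RESULTS / f"pathway_{line}.tsv", sep="\t")
    pw = {name: ScreenTable(g.drop(columns="set_name").reset_index(drop=True))
          for name, g in pw_df.groupby("set_name")}
    return full, pw


def main() -> None:
    per_line, labels_full, labels_pw = {}, {}, {}
    for line in CELL_LINES:
        full, pw = load_tables(line)
        ef = compound_enrichment(full, n_perm=PARAMS.n_perm, seed=PARAMS.seed)
        ep = pathway_enrichment(pw, n_perm=PARAMS.n_perm, seed=PARAMS.seed)
        ef.to_csv(RESULTS / f"enrichment_full_{line}.tsv", sep="\t", index=False)
        ep.to_csv(RESULTS / f"enrichment_pathway_{line}.tsv", sep="\t", index=False)
        per_line[line] = (ef, ep)
        fset = enriched_compounds(ef, PARAMS.fdr_max)
        pset = pathway_enriched_compounds(ep, PARAMS.fdr_max, PARAMS.pathway_rule)
        for c in ef.compound_id:
            labels_full[f"{line}:{c}"] = c in fset
            labels_pw[f"{line}:{c}"] = c in pset
        print(f"{line}: {len(fset)} full-method, {len(pset)} pathway-method hits")

    agreement = compare_methods(labels_full, labels_pw)
    with open(RESULTS / "agreement.json", "w") as fh:
        json.dump({"table": agreement.table.tolist(),
                   "odds_ratio": agreement.odds_ratio,
                   "p_value": agreement.p_value}, fh, indent=1)
    print(f"method agreement: odds ratio {agreement.odds_ratio:.1f} "
          f"(p = {agreement.p_value:.2e})")

    rec = recurrent_hits(per_line, min_lines=PARAMS.min_lines,
                         fdr_max=PARAMS.fdr_max, pathway_rule=PARAMS.pathway_rule)
    rec.to_csv(RESULTS / "recurrence.tsv", sep="\t", index=False)
    truth = pd.read_csv(INPUTS / "truth.tsv", sep="\t")
    planted = set(truth[truth.is_antagonist].groupby("compound_id")["cell_line"]
                  .nunique().loc[lambda s: s >= PARAMS.min_lines].index)
    got = set(rec.loc[rec.passes, "compound_id"])
    print(f"recurrent hits (>= {PARAMS.min_lines} lines, both methods): {sorted(got)}")
    print(f"planted truth recovered exactly: {got == planted}")


if __name__ == "__main__":
    main()
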