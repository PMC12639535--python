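# Methods

## Model and procedure

The screen treats both sides of the comparison as trinary calls over a
shared gene universe. The reference (target) profile comes from
differential-expression statistics: gene g is called sign(log2FC_g) when
|log2FC_g| > 1 **and** p_g <= 0.05, else 0. Drug signatures are
replicate-averaged Z-scores (L1000 Level 5 style); gene g is called
sign(Z_g) when |Z_g| >= 1. The two boundary conventions differ on purpose:
the strict `>` belongs to the DEG definition on the reference side while the
inclusive `>=` belongs to the cross-platform binarization rule, and
`build_reference` exposes an `inclusive` flag for users who want one
convention throughout.

Scoring is the Normalized Concordance Ratio NCR = (|C| − |D|)/|A| with A the
reference DEG set, O the genes nonzero in both profiles, C the agreeing and
D the disagreeing part of O. Because calls live in {−1, 0, +1},
|C| − |D| is the integer dot product of the two call vectors and |O| the dot
product of their absolute values; the implementation exploits this
throughout and compares permutation statistics as exact integers, never as
floats.

**Gene-universe handling.** The drug matrix and the reference rarely share a
gene space; profiles are intersected before scoring and |A| is recomputed
within the intersection (the dropped DEG count is logged). The screen table
records `deg_space = "shared"`. Scoring against the full, partly unmeasured
DEG set is available by passing `n_deg` explicitly to `ncr`.

**Permutation null.** 1,000 uniform relabelings of the drug call vector per
signature (the reference is never permuted); up/down counts are preserved by
construction. The p-value is the one-sided upper tail with the add-one
correction p = (1 + #{NCR_perm >= NCR_obs})/(1 + n_perm) — the screen's
question is concordance with the target; a two-sided option exists.
Benjamini–Hochberg adjustment (statsmodels) is applied across the
signatures of a screen. Each signature's permutation stream is seeded by
hashing its id together with the screen seed, so results are invariant to
signature order, and one permuted-call matrix per signature scores all
references at once via a float32 matrix product (products are
integer-valued and < 2^24, hence exact). A pathway-restricted screen on the
whole universe is therefore bit-identical to the unrestricted screen.

**Pathway screen.** The reference is restricted to each gene set (|A|
becomes the DEGs inside the set); pathways with no reference DEG are
skipped with a log entry. BH runs per pathway across signatures — each
pathway is its own family, since pooling would couple unrelated tests.

**Compound enrichment.** Signatures are ranked by NCR (ties: ascending p,
then id). The unweighted KS running sum steps +1/m at a compound's m
replicates and −1/(N−m) elsewhere; ES is the signed maximum deviation,
evaluated in integer units of 1/(m(N−m)) so the ±tie resolves to the
positive excursion deterministically. The null redistributes the m member
labels uniformly over the N positions. Because that null depends only on
(N, m), one n_perm-sized null sample per distinct replicate count is drawn
per screen (seeded from the screen seed and (N, m), hence order-invariant)
and shared by all compounds with that count — distributionally identical to
per-compound draws and an order of magnitude cheaper. NES divides ES by the
mean |null ES| of matching sign (a z-score variant is available and recorded
in the output metadata). Note NES is *not* numerically invariant to
doubling every compound's replicate count — the null tightens — but the
rescaling is common to all compounds, so orderings, signs and enrichment
calls are stable; the tests assert exactly that.

**Method agreement and recurrence.** Enrichment labels (NES > 0, FDR <=
0.05) from the full-profile and the pathway method are cross-tabulated per
(cell line, compound) and summarised by the sample odds ratio
(Haldane–Anscombe +0.5 when a zero cell occurs, flagged) with a two-sided
Fisher exact p. A compound's pathway-method label aggregates over pathways
by the `any` rule by default (`majority`/`all` are options): enriched in at
least one pathway counts. The recurrence filter keeps compounds enriched by
*both* methods in at least `min_lines` (default 3) cell lines.

**Orthogonality.** Replicates are aggregated per compound (fixed dose/time,
one cell line) by the per-gene mode of binarized calls; a tie among
{−1, 0, +1} resolves to 0 (no majority direction means no call). Against an
anchor, OS = sqrt(NCR_target² + (1 − NCR_drug)²), where NCR_drug uses the
anchor's nonzero calls as the normalizing set A. The binary
orthogonality-enrichment call has no canonical published threshold; the
default criterion is "OS above the anchor's 75th percentile AND the
candidate is itself target-enriched", it is pluggable, and every exported
matrix records the criterion used.

**Network.** Jaccard similarity of binary partner profiles (a pair of
all-zero profiles is defined as similarity 1, logged); edges above a
threshold (default 0: every positive similarity becomes a weighted edge,
letting modularity down-weight weak edges rather than discarding them);
greedy modularity communities on edge weights with nodes inserted in sorted
order and community ids assigned by decreasing size then smallest member,
so outputs are diff-stable; betweenness on unweighted hops by default
(distance = 1/weight optional) and plain degree.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `fc_threshold` / `p_threshold` | 1.0 / 0.05 | reference DEG rule (log2 units / probability) |
| `z_threshold` | 1.0 | drug-signature call boundary (Z units, inclusive) |
| `tas_min` | 0.4 | minimum Transcriptional Activity Score; missing TAS is excluded when the filter is on |
| `dose`, `time` | 10 uM, 24 h | exact condition match after unit canonicalization |
| `n_perm` | 1000 | permutations for both nulls |
| `fdr_max` | 0.05 | BH threshold for "enriched" |
| `min_lines` | 3 | recurrence requirement across cell lines |
| `os_quantile` | 0.75 | per-anchor OS cut for the binary profile |
| `edge_threshold` | 0.0 | minimum Jaccard similarity for a network edge |

## Synthetic data

The generator emulates the *shape* of the screened corpus — 978 landmark
genes, a 728-gene reference DEG set (half up), compounds with replicate
structure, per-signature metadata at 10 uM / 24 h, TAS in [0.4, 1] for
retained signatures plus a held-out low-TAS decoy fraction — and plants
signal with known truth: antagonists copy a fraction `antagonist_overlap`
(default 0.5) of the reference DEG calls concordantly and
`discordant_rate` (0.1) discordantly per replicate, so a replicate's
expected NCR is overlap − discordant ≈ 0.4, the scale of the strongest
real single agents; null compounds are independent of the reference at the
same marginal nonzero rate, so permutation nulls are exercised at matched
sparsity. Planted |Z| magnitudes are uniform in [1.2, 3], beyond the call
boundary with margin, so Gaussian noise with SD <= 0.1 cannot flip a call.
Complementary pairs are concordant on disjoint DEG blocks; community
structure in shared-partner space is planted as per-block indicator
profiles with a few random bit flips.

What the generator does **not** emulate: probe-level L1000 deconvolution,
inferred-gene imputation error, correlated off-target transcription,
batch/plate effects, or realistic TAS–effect-size dependence. Passing tests
therefore demonstrate the pipeline's statistical correctness and its
sensitivity/specificity under clean planted signal, not performance on real
CMAP data.

## Numerical choices

- Integer score comparisons for both permutation nulls (no float-tie
  artifacts); ES in exact integer units with the positive-excursion tie rule.
- Add-one p-values keep BH well defined at finite n_perm.
- All-zero drug profile: p = 1 with a warning (degenerate null).
- |A| = 0 (empty or fully-restricted reference) is an error, not a NaN.
- Aggregation ties → 0 (conservative: no majority, no call).
- GCT/GMT writers emit `repr`-round-trip floats; the reader parses with
  Python `float`, so write→read→write is bit-stable.

## Problem sizes in the checked-in analyses

The numbered drivers run 3 cell lines × 60 compounds × 3 replicates at 300
permutations; the acceptance tests run the permutation-calibration at the
full 978-gene / 728-DEG scale (500 null profiles × 1000 permutations) and
planted-antagonist recovery at 10 lines × 200 compounds × 3 replicates ×
1000 permutations, with the determinism check at 3 lines × 60 compounds.
These sizes are the package's own desk-scale rendition of the study
conditions; all of them are configurable.

## Known limitations

- The orthogonality-enrichment criterion is a package convention (the
  quantity has no published threshold); downstream counts depend on it and
  it is always recorded in the output.
- NES normalization is the sign-conditioned mean; published screens using a
  different normalization will not match numerically (the z-score variant
  is provided).
- No gene-identifier alias mapping is built in; identifiers are opaque
  case-sensitive strings and a user-supplied mapping must be applied
  upstream.
- GCTX/HDF5 binary inputs, probe-level processing and TAS computation from
  raw replicates are out of scope; TAS is consumed as given.
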