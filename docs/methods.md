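# Methods

## Model and procedure

The package operationalises knockdown-mimicry repositioning: a drug is scored
as a candidate inhibitor of a target gene when its perturbation signature is
highly rank-correlated with the signature of knocking that gene down in the
same cell line. The unit of analysis is the signature — one genome-wide
vector of differential-expression scores per (perturbation, cell line, dose,
time) — and all inference is rank-based, so the method is invariant to any
monotone transform of the scores and insensitive to their absolute scale.

The pipeline runs in five stages.

**Target triage.** Hub genes are screened with strict inequalities
(logFC > 0 and FDR < 0.05); a gene qualifies if it passes in at least one
brain region. Boundary values (FDR exactly 0.05, logFC exactly 0) are
excluded by the strict rule. Genes then need at least one knockdown
signature in the compendium. Essentiality scores are summarised per lineage
group (median and type-7 linear-interpolation IQR, stated so hand-checks are
reproducible) and classified against the anchors −1 / −0.5 / 0 by nearest
anchor. The anchor interpretation is given by the screening literature but no
numeric bin edges are; the midpoints −0.75 and −0.25 are the natural
nearest-anchor boundaries, with ties resolved toward the less essential
category and any positive score read as proliferation-suggestive.

**Correlation engine.** Spearman's ρ is computed as Pearson correlation of
mid-ranks (average ranks on ties); constant vectors are an explicit error,
not NaN. All knockdown × drug-signature pairs in a cell line are computed at
once by rank-standardising each column to zero mean and unit norm, so the
whole block is a single matrix product. Multiple knockdown replicate
signatures are reduced by the maximum ρ (the same maximisation the optimal
dose/time selection applies; mean reduction is available via `kd_reduce`).
Per drug, the (dose, time, replicate) row with the highest ρ is kept; ties
break toward lower dose, earlier time, then replicate label, so the
selection is deterministic and row-order invariant. Ranks are descending-ρ
with ties broken by drug label, and the top-1 % flag is count-based:
⌈top_fraction · n⌉ drugs, which stays well-defined under ties (a
percentile-threshold alternative does not). Consensus: SET1 takes every drug
flagged in ≥ `set1_min_lines` cell lines; SET2 takes, among the remaining
drugs flagged in ≥ `set2_min_lines` lines, the `n_top` with the smallest
median rank over the lines where the drug was actually assayed (compendium
coverage is uneven; absent lines contribute no rank), ties by mean rank then
label.

**Enrichment and aggregation.** Preranked GSEA uses the classic weighted
KS running sum with weight exponent 1 (the field default) and pathway-size
bounds 5–500 on the overlap with the ranked universe. The null is gene-set
permutation: ES of `nperm` random same-size sets (default 10 000). Because
that null depends only on the ranked statistics and the set size, it is
computed once per distinct size and shared — this is purely an
implementation economy and changes no p-value. One-sided p-values use a +1
pseudocount within the same-sign null, which is slightly conservative;
NES = ES / mean |same-sign null ES|. No adaptive multilevel p-refinement is
attempted: plain permutation p at nperm = 10 000 resolves p down to ~10⁻⁴,
sufficient for FDR control at 0.05 over a few hundred pathways.

Cross-cell-line combination treats each profile's BH-adjusted p as the input
to the weighted Fisher (Lancaster) method — contribution
Gamma(k·wᵢ/Σw, scale 2) upper quantile, total referred to Gamma(k, scale 2)
— and each profile's NES as a z-score for the Stouffer combination
Σwᵢzᵢ/√Σwᵢ². Equal weights reduce the former exactly to Fisher's χ²(2k) and
the latter to √k growth for k identical inputs; both identities are tested.
Weights default to equal per cell line; a per-line profile-count weighting is
available. After combination a second BH runs across pathways
(combine-then-adjust, the default; `second_adjust=False` skips it), the
combined NES is zeroed wherever the final adjusted combined p exceeds 0.05
— the p-value combination is the more powerful test, so NES display is muted
where it disagrees — and Reliability = −log₁₀(padj), base 10 being the
convention for significance-scaled plot axes.

**Interactome.** Undirected simple graph; compound and protein node types
inferred from edge types, DPI edges joining compound↔protein and PPI edges
protein↔protein; duplicate edges merge with unioned source provenance; an
identifier typed both ways is a hard error. MOA subnetworks retain every
simple path from a member drug to the target gene with at most `max_edges`
edges whose first hop is a DPI and later hops PPIs. The default bound is 3
edges = 4 nodes, matching the drug ⇔ drug target ⇔ neighbour ⇔ target-gene
chain; a "4 edges" reading is available by passing `max_edges=4`. Simple
paths only — node revisits add no mechanistic information and explode the
enumeration. Extraction is validated against exhaustive bounded-depth DFS
on random graphs up to 300 nodes.

**Assays.** CT formulas as printed above; replicate wells are averaged
before the formulas and the well SD is propagated to a CT standard error by
the delta method. Raw CT is always reported and clamping into [0, 100]
applies only to the summary column. Drug efficacy divides glutamate
concentration by relative *viability* (MTT AbsS/AbsC): dividing by relative
cytotoxicity would diverge as CT → 0 and would reward toxic rather than
potent compounds; the literal cytotoxicity denominator remains available as
`literal_ct=True`.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *rank structure* the analysis consumes, not the
physics of the assay platform. Signature values are standard normal plus
planted components: replicate-collapsed compendium scores are z-like, and
since every downstream statistic is rank-based, distributional realism
beyond ranks is irrelevant by design. Defaults are the study conditions:
seven cell lines (A375, A549, HA1E, HEPG2, HT29, MCF7, PC3), 3 knockdown
replicates per line, a 2 × 2 dose/time grid, 300 drugs, and a 1 000-gene
universe for desk-scale work (the real compendium's 12 328-gene universe is
honoured when reading GCT/GCTX inputs). A mimic drug's signature at its
optimal condition is a·kd + √(1−a²)·ε with the weight a solved by bisection
on the *empirical* Spearman correlation against the first knockdown
replicate (the bivariate-normal closed form 2·sin(πρ/6) only hits the
population value; the contract tolerance is ±0.1 and the numerical solve
lands within one rank-step). Not emulated: landmark-gene inference, batch
effects, quality-control flags, uneven drug coverage across lines, and
correlated off-target structure. Passing tests therefore demonstrate the
statistical machinery recovers planted structure under the stated noise
model — not that any particular real drug would be recovered from the real
compendium.

Plate simulation inverts the CT formulas exactly at zero noise (control OD
1.0 for MTT; low/high controls 0.1/1.1 for LDH, typical kit ranges), which
makes the assay arithmetic testable as a round trip.

## Numerical choices

- Zero p-values are clamped to 1e-300 (warned) before log/Gamma transforms.
- ES ties between the positive and negative extremum resolve to the positive
  branch; GSEA input ties are impossible for continuous signatures and gene
  label breaks residual ordering ties.
- All generators derive per-stream seeds via `numpy.random.SeedSequence`, so
  a single integer seed yields bit-identical outputs.
- `mergesort` (stable) backs every pandas sort that feeds a tie-break chain.
- Essentiality IQR uses type-7 (linear interpolation) quartiles.

## Problem sizes

Tests and the acceptance script run the full seven-line study conditions
(1 000 genes × 1 203 signatures per line, 20 seeded replicates) for the
planted-recovery check, nperm = 10 000 GSEA on a 500-gene universe with 200
pathways for calibration, and 50 random ≤ 300-node interactomes for the
path-mining oracle; the complete suite finishes in about a minute on one
CPU.

## Known limitations

- The GSEA null is gene-set permutation, not phenotype permutation; with
  strongly correlated gene modules it is anti-conservative in the usual way.
- The weighted Fisher combination assumes independent inputs; profiles from
  the same cell line share biology, which equal weighting does not model.
- `read_gctx` supports the standard compendium HDF5 layout only (row/column
  ids under `/0/META`, matrix under `/0/DATA/0`).
- No dose–response (IC50) fitting, network propagation scoring, or
  pharmacokinetic prediction; identifier mapping must happen upstream.
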