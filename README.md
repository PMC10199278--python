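# kdmimic

Knockdown-mimicry drug repositioning at desk scale.

## The problem

When a disease is driven by over-expression of a single gene — the motivating
case is glutaminase (*GLS*) in Alzheimer's disease — one route to a therapy is
to find an already-approved drug whose transcriptomic effect *mimics knocking
that gene down*. Perturbation compendia such as the Connectivity Map record
genome-wide differential-expression signatures for thousands of compound
treatments and shRNA knockdowns across human cell lines. If a drug's signature
correlates strongly, in rank space, with the signature of knocking down the
target gene, the drug plausibly inhibits the target.

`kdmimic` implements that analysis end to end as a tested, reusable library:

1. **Target triage** (`kdmimic.targets`) — filter hub genes to those
   significantly up-regulated (logFC > 0, FDR < 0.05) in at least one brain
   region, check which have knockdown signatures available, and summarise /
   classify CRISPR gene-essentiality (Chronos) scores against the anchors
   −1 (obliteration), −0.5 (depletion), 0 (non-essential), > 0
   (proliferation-suggestive).
2. **Repositioning engine** (`kdmimic.repositioning`) — per cell line,
   Spearman correlations ρ(drug signature, knockdown signature) over the
   shared gene universe; per drug, the optimal (dose, time) condition with the
   highest ρ; descending-ρ ranks with the top 1 % flagged
   (⌈0.01 n⌉ drugs); and two consensus sets across cell lines — SET1: top-1 %
   in ≥ 6 lines; SET2: among the rest, top-1 % in ≥ 2 lines with the best
   median rank.
3. **Pathway enrichment** (`kdmimic.enrichment`) — preranked GSEA (weighted
   Kolmogorov–Smirnov running sum, gene-set permutation null, BH adjustment),
   then per-pathway meta-combination across cell lines: adjusted p-values by
   the weighted Fisher (Lancaster) method, NES by the weighted Z (Stouffer)
   method Σwᵢzᵢ/√Σwᵢ²; combined NES with adjusted p > 0.05 is zeroed and
   Reliability = −log₁₀(padj) sizes the bubbles.
4. **Interactome mining** (`kdmimic.interactome`) — merge DPI and PPI edge
   lists into one undirected, provenance-tracked graph and extract
   mechanism-of-action subnetworks: all simple drug → target paths of ≤ 3
   edges (the drug ⇔ drug target ⇔ neighbour ⇔ target-gene chain) whose first
   hop is a drug–protein edge; export as SIF / GraphML / edge-TSV.
5. **Assay arithmetic** (`kdmimic.assays`) — MTT cytotoxicity
   CT = 100·(AbsC − AbsS)/AbsC, LDH cytotoxicity
   CT = 100·(AbsS − AbsLC)/(AbsHC − AbsLC), glutamate quantitation against a
   linear standard curve, viability-normalised drug efficacy, and relative
   Western-blot band intensities.
6. **Synthetic data** (`kdmimic.synthetic`) — seeded generators for every
   input: signature compendia with mimic drugs planted at a chosen Spearman
   correlation, gene sets enriched in a signature's tails, interactomes with
   planted drug → target paths, lineage-centred essentiality scores, and assay
   plates whose noiseless absorbances invert the CT formulas exactly. Real
   GCT/GCTX/GMT/TSV inputs drop in through `kdmimic.io`.

## Worked example

```python
from kdmimic import SimulationConfig, simulate_signature_compendium, reposition

cfg = SimulationConfig(          # 7 cell lines, 1000 genes, 300 drugs x 2 doses x 2 times,
    mimic_drugs={"mimic": 0.6},  # 3 knockdown replicates; one drug planted at rho = 0.6
    seed=7,
)
mats, meta = simulate_signature_compendium(cfg)
cons = reposition(mats, meta, kd_target="GLS")["consensus"]
print(cons.head(3)[["drug", "n_lines_top1", "median_rank", "set_label"]])
```

prints

```
       drug  n_lines_top1  median_rank set_label
0     mimic             7          1.0      SET1
1  drug0170             2        184.0      SET2
2  drug0031             0         47.0      none
```

The planted mimic is the top-ranked drug in all 7 cell lines and is the sole
SET1 member, exactly what the consensus rules should recover; `drug0170` is
the only decoy reaching the top 1 % in ≥ 2 lines by chance, so it heads SET2,
and the remaining drugs are unlabelled. The same steps are exposed on the command line
(`kdmimic reposition | enrich | network | assays`).

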