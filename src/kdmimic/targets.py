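"""Target-gene triage: up-regulation filter, knockdown availability, essentiality.

Candidate druggable targets are hub genes that are significantly up-regulated
in at least one brain region (logFC > 0 and FDR < 0.05, strict inequalities),
have at least one shRNA/knockout signature in the perturbation compendium,
and — for a neurodegeneration indication — are dispensable for proliferation
of nervous-system cell lineages in CRISPR fitness screens.

Fitness (Chronos-style) scores are read against three anchors: -1 knockdown
obliteration, -0.5 knockdown-dependent depletion, 0 non-essential; positive
scores suggest proliferation on knockdown.  Classification is
nearest-anchor, with ties resolved toward the less essential category.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TargetCandidate",
    "filter_upregulated_hubs",
    "check_knockdown_availability",
    "summarize_essentiality",
    "classify_essentiality",
    "triage_targets",
]

#: boundaries between essentiality categories (midpoints of the anchors)
OBLITERATION_BOUND = -0.75
DEPLETION_BOUND = -0.25


@dataclass
class TargetCandidate:
    gene: str
    regions_upregulated: list[str]
    knockdown_cell_lines: list[str]
    essentiality_summary: dict | None

    @property
    def has_knockdown_profiles(self) -> bool:
        return len(self.knockdown_cell_lines) > 0


def filter_upregulated_hubs(
    hub_genes: list[str],
    de_table: pd.DataFrame,
    logfc_min: float = 0.0,
    fdr_max: float = 0.05,
) -> list[str]:
    """Hub genes significantly up-regulated in at least one region.

    Keeps a hub gene when some row of the differential-expression table has
    ``logFC > logfc_min`` and ``FDR < fdr_max`` (both strict).  Hub genes
    absent from the table are excluded with a warning.  Output preserves the
    input gene order.
    """
    if de_table.empty:
        raise ValueError("empty differential-expression table")
    if ((de_table["FDR"] < 0) | (de_table["FDR"] > 1)).any():
        raise ValueError("FDR values must lie in [0, 1]")
    known = set(de_table["gene"])
    passing = set(
        de_table.loc[
            (de_table["logFC"] > logfc_min) & (de_table["FDR"] < fdr_max), "gene"
        ]
    )
    kept = []
    for gene in hub_genes:
        if gene not in known:
            logger.warning("hub gene %s absent from DE table; excluded", gene)
        elif gene in passing:
            kept.append(gene)
    return kept


def regions_upregulated(
    gene: str,
    de_table: pd.DataFrame,
    logfc_min: float = 0.0,
    fdr_max: float = 0.05,
) -> list[str]:
    """Regions where ``gene`` passes the up-regulation filter (sorted)."""
    hit = de_table[
        (de_table["gene"] == gene)
        & (de_table["logFC"] > logfc_min)
        & (de_table["FDR"] < fdr_max)
    ]
    return sorted(hit["region"].unique())


def check_knockdown_availability(
    genes: list[str], meta: pd.DataFrame
) -> dict[str, list[str]]:
    """Map each gene to the cell lines holding >= 1 knockdown signature for it.

    ``meta`` must carry ``pert_type`` and ``pert_target`` columns; knockdown
    rows are those with pert_type "knockdown" (shRNA or knockout).  Genes
    with no knockdown rows map to an empty list.
    """
    for col in ("pert_type", "pert_target", "cell_line"):
        if col not in meta.columns:
            raise ValueError(f"metadata lacks required column {col!r}")
    kd = meta[meta["pert_type"] == "knockdown"]
    by_gene = kd.groupby("pert_target")["cell_line"].agg(lambda s: sorted(set(s)))
    return {g: list(by_gene.get(g, [])) for g in genes}


def summarize_essentiality(
    gene: str,
    records: pd.DataFrame,
    lineage_filter: list[str] | None = None,
) -> dict | None:
    """Order-invariant summary of one gene's fitness scores.

    Filters the long table (columns ``gene, cell_line, lineage, score``) to
    ``gene`` and, when given, to ``lineage_filter``; returns
    ``{"n", "median", "iqr", "fraction_positive"}``.  Quartiles use linear
    interpolation (type 7), so for scores {-0.1, 0, 0.1} the IQR is 0.1.
    Returns None when no records survive the filter.
    """
    sel = records[records["gene"] == gene]
    if lineage_filter is not None:
        sel = sel[sel["lineage"].isin(lineage_filter)]
    if sel.empty:
        return None
    scores = sel["score"].to_numpy(dtype=float)
    q1, q3 = np.percentile(scores, [25, 75])  # linear interpolation (type 7)
    return {
        "n": int(scores.size),
        "median": float(np.median(scores)),
        "iqr": float(q3 - q1),
        "fraction_positive": float(np.mean(scores > 0)),
    }


def classify_essentiality(score: float) -> str:
    """Nearest-anchor category of a fitness score.

    Anchors: -1 obliteration, -0.5 depletion, 0 non-essential; any positive
    score is proliferation-suggestive.  Boundary scores (-0.75, -0.25, 0)
    resolve toward the less essential category.
    """
    if not math.isfinite(score):
        raise ValueError("score must be finite")
    if score > 0:
        return "proliferation-suggestive"
    if score < OBLITERATION_BOUND:
        return "obliteration"
    if score < DEPLETION_BOUND:
        return "depletion"
    return "non-essential"


def triage_targets(
    hub_genes: list[str],
    de_table: pd.DataFrame,
    meta: pd.DataFrame,
    essentiality: pd.DataFrame | None = None,
    lineage_filter: list[str] | None = None,
    logfc_min: float = 0.0,
    fdr_max: float = 0.05,
) -> list[TargetCandidate]:
    """Full triage: up-regulated hubs with available knockdown profiles.

    Returns one :class:`TargetCandidate` per hub gene that passes the
    up-regulation filter AND has at least one knockdown signature, with its
    up-regulated regions, knockdown cell lines, and (when an essentiality
    table is given) per-lineage-group score summary.
    """
    upregulated = filter_upregulated_hubs(hub_genes, de_table, logfc_min, fdr_max)
    availability = check_knockdown_availability(upregulated, meta)
    candidates = []
    for gene in upregulated:
        lines = availability[gene]
        if not lines:
            continue
        summary = (
            summarize_essentiality(gene, essentiality, lineage_filter)
            if essentiality is not None
            else None
        )
        candidates.append(
            TargetCandidate(
                gene=gene,
                regions_upregulated=regions_upregulated(
                    gene, de_table, logfc_min, fdr_max
                ),
                knockdown_cell_lines=lines,
                essentiality_summary=summary,
            )
        )
    return candidates
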