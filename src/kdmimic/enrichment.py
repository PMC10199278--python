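"""Preranked GSEA and cross-cell-line meta-combination.

Pathway enrichment is computed per perturbation profile with the classic
weighted Kolmogorov-Smirnov running-sum statistic, a gene-set permutation
null, and Benjamini-Hochberg adjustment across pathways.  Per-profile results
from different cell lines are then combined per pathway:

* adjusted p-values by the weighted Fisher (Lancaster) method — each profile
  contributes a Gamma(shape = k*w_i/sum(w), scale = 2) quantile and the sum is
  referred to Gamma(shape = k, scale = 2); with equal weights this reduces
  exactly to Fisher's chi-square method on 2k degrees of freedom;
* normalised enrichment scores (NES) by the weighted Z (Stouffer) method,
  sum(w_i * NES_i) / sqrt(sum(w_i^2)).

Combined NES values whose final adjusted combined p exceeds 0.05 are set to
zero (low-strength calls are muted rather than displayed), and the adjusted
combined p is reported as Reliability = -log10(padj) for bubble-plot sizing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "enrichment_score",
    "gsea_preranked",
    "bh_adjust",
    "combine_pvalues_wfisher",
    "combine_nes_weighted_z",
    "aggregate_profiles",
    "bubble_table",
]

#: smallest p-value substituted for an exact zero before taking logs
P_FLOOR = 1e-300

#: default pathway size bounds for GSEA (overlap with the ranked universe)
MIN_SET_SIZE = 5
MAX_SET_SIZE = 500


@dataclass
class GeneSetCollection:
    """Named collection of gene sets (a GMT file in memory)."""

    name: str
    sets: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, genes in self.sets.items():
            if not genes:
                raise ValueError(f"empty gene set: {label!r}")
            self.sets[label] = set(genes)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


# ---------------------------------------------------------------------------
# Enrichment score
# ---------------------------------------------------------------------------

def enrichment_score(
    ranked_stats: pd.Series, gene_set: set[str], weight_exponent: float = 1.0
) -> float:
    """Weighted Kolmogorov-Smirnov enrichment score of one gene set.

    ``ranked_stats`` maps gene labels to statistics, sorted descending.  The
    running sum gains ``|stat|^weight_exponent / sum_set |stat|^exponent`` at
    each set gene ("hit") and loses ``1/(N - n_hits)`` at each other gene
    ("miss"); the ES is the extremum of largest magnitude, sign preserved.
    """
    stats = np.asarray(ranked_stats.values, dtype=float)
    genes = list(ranked_stats.index)
    if np.any(np.diff(stats) > 0):
        raise ValueError("ranked_stats must be sorted descending")
    hits = np.fromiter((g in gene_set for g in genes), dtype=bool, count=len(genes))
    n_hits = int(hits.sum())
    if n_hits == 0:
        raise ValueError("gene set has no overlap with the ranked universe")
    if n_hits == len(genes):
        raise ValueError("gene set covers the whole universe; ES undefined")
    w = np.abs(stats) ** weight_exponent
    hit_gain = np.where(hits, w, 0.0)
    total = hit_gain.sum()
    if total == 0:
        raise ValueError("all set genes have zero statistic")
    running = np.cumsum(hit_gain / total - (~hits) / (len(genes) - n_hits))
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def _es_from_hit_indices(sorted_w: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """ES for many same-size gene sets given as sorted hit-index rows.

    ``sorted_w`` are the |stat|^exponent weights in ranked order; ``idx`` is
    0-based and ascending per row.  The running sum only needs evaluating
    just after each hit (candidate maxima) and just before each hit
    (candidate minima); between hits it decreases linearly.
    """
    n = sorted_w.size
    m = idx.shape[1]
    miss_step = 1.0 / (n - m)
    hit_w = sorted_w[idx]
    denom = hit_w.sum(axis=1, keepdims=True)
    denom = np.where(denom == 0, 1.0, denom)
    cum_hit = np.cumsum(hit_w, axis=1) / denom
    j = np.arange(m)
    # after hit j: cumulative hit mass minus all misses seen so far
    after = cum_hit - (idx - j) * miss_step
    # just before hit j: previous hit mass minus misses up to position idx-1
    before = np.concatenate(
        [np.zeros((idx.shape[0], 1)), cum_hit[:, :-1]], axis=1
    ) - (idx - j) * miss_step
    es_pos = after.max(axis=1)
    es_neg = np.minimum(before.min(axis=1), 0.0)
    return np.where(es_pos >= -es_neg, es_pos, es_neg)


def _null_es(
    sorted_w: np.ndarray, set_size: int, nperm: int, rng: np.random.Generator
) -> np.ndarray:
    """Gene-set permutation null: ES of ``nperm`` random same-size sets."""
    n = sorted_w.size
    # vectorised sampling without replacement: argpartition of uniforms
    u = rng.random((nperm, n))
    idx = np.argpartition(u, set_size, axis=1)[:, :set_size]
    idx.sort(axis=1)
    return _es_from_hit_indices(sorted_w, idx)


def gsea_preranked(
    signature: pd.Series,
    collection: GeneSetCollection,
    nperm: int = 10000,
    seed: int = 0,
    weight_exponent: float = 1.0,
    min_size: int = MIN_SET_SIZE,
    max_size: int = MAX_SET_SIZE,
) -> pd.DataFrame:
    """Preranked GSEA of one signature against a gene-set collection.

    The null distribution for each pathway is the ES of ``nperm`` random
    gene sets of the same size drawn from the ranked universe (shared across
    pathways of equal size — the null depends only on the ranked statistics
    and the set size).  One-sided p-values use a +1 pseudocount,

        p = (1 + #{same-sign null |ES| >= |ES|}) / (1 + #same-sign nulls),

    NES = ES / mean |same-sign null ES|, and BH adjustment runs across the
    pathways of the collection.

    Returns a DataFrame with columns
    ``pathway, size, ES, NES, pval, padj`` sorted by pathway label.
    """
    if nperm < 100:
        raise ValueError("nperm < 100 is too unstable; refuse to run")
    order = np.argsort(
        np.rec.fromarrays([-signature.values, signature.index.astype(str)])
    )
    ranked = signature.iloc[order]
    genes = ranked.index
    universe = set(genes)
    sorted_w = np.abs(ranked.values.astype(float)) ** weight_exponent

    sizes_needed: dict[int, list[tuple[str, float]]] = {}
    for label, gene_set in collection:
        overlap = len(gene_set & universe)
        if overlap < min_size or overlap > max_size:
            logger.warning(
                "pathway %s skipped: overlap %d outside [%d, %d]",
                label, overlap, min_size, max_size,
            )
            continue
        es = enrichment_score(ranked, gene_set, weight_exponent)
        sizes_needed.setdefault(overlap, []).append((label, es))

    rng = np.random.default_rng(seed)
    rows = []
    for size in sorted(sizes_needed):
        null = _null_es(sorted_w, size, nperm, rng)
        pos = null[null > 0]
        neg = null[null < 0]
        for label, es in sizes_needed[size]:
            same = pos if es >= 0 else neg
            k = same.size
            exceed = int(np.sum(np.abs(same) >= abs(es)))
            pval = (1 + exceed) / (1 + k)
            mean_abs = float(np.mean(np.abs(same))) if k else np.nan
            nes = es / mean_abs if k and mean_abs > 0 else 0.0
            rows.append((label, size, es, nes, pval))
    df = pd.DataFrame(rows, columns=["pathway", "size", "ES", "NES", "pval"])
    df = df.sort_values("pathway", kind="mergesort").reset_index(drop=True)
    df["padj"] = bh_adjust(df["pval"].values) if len(df) else []
    return df


# ---------------------------------------------------------------------------
# Multiple testing and meta-combination
# ---------------------------------------------------------------------------

def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def combine_pvalues_wfisher(pvals, weights=None) -> float:
    """Weighted Fisher (Lancaster) combination of k p-values.

    Each p_i contributes the upper-tail quantile of a
    Gamma(shape = k*w_i/sum(w), scale = 2) distribution; the sum of
    contributions is referred to the upper tail of Gamma(shape = k,
    scale = 2).  Equal weights recover Fisher's classic chi-square method on
    2k degrees of freedom.  Zero p-values are clamped to ``P_FLOOR`` with a
    warning.
    """
    p = np.atleast_1d(np.asarray(pvals, dtype=float))
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if weights is None:
        w = np.ones_like(p)
    else:
        w = np.atleast_1d(np.asarray(weights, dtype=float))
    if w.shape != p.shape:
        raise ValueError("pvals and weights must have equal length")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    if np.any(p > 1) or np.any(p < 0):
        raise ValueError("p-values must lie in (0, 1]")
    if np.any(p == 0):
        logger.warning("zero p-value clamped to %.0e before combination", P_FLOOR)
        p = np.maximum(p, P_FLOOR)
    k = p.size
    shapes = k * w / w.sum()
    t = gamma_dist.isf(p, a=shapes, scale=2.0).sum()
    return float(gamma_dist.sf(t, a=k, scale=2.0))


def combine_nes_weighted_z(nes, weights=None) -> float:
    """Weighted Z (Stouffer) combination: sum(w*z) / sqrt(sum(w^2))."""
    z = np.atleast_1d(np.asarray(nes, dtype=float))
    if z.size == 0:
        raise ValueError("no NES values to combine")
    w = (
        np.ones_like(z)
        if weights is None
        else np.atleast_1d(np.asarray(weights, dtype=float))
    )
    if w.shape != z.shape:
        raise ValueError("nes and weights must have equal length")
    denom = math.sqrt(float(w @ w))
    if denom == 0:
        raise ValueError("all-zero weights")
    return float(w @ z / denom)


def aggregate_profiles(
    records: list[tuple[str, pd.DataFrame]],
    weights: dict[str, float] | None = None,
    alpha: float = 0.05,
    second_adjust: bool = True,
) -> pd.DataFrame:
    """Combine per-profile enrichment records across cell lines per pathway.

    Parameters
    ----------
    records
        List of (cell_line, per-profile GSEA table) pairs; each table must
        carry ``pathway, NES, padj`` columns.  A pathway missing from some
        profiles is combined over the profiles that report it (reduced k,
        logged).
    weights
        Optional per-cell-line positive weights; default equal.
    alpha
        Significance level for the NES-zeroing rule.
    second_adjust
        If True (default: combine-then-adjust), a second BH adjustment runs
        across pathways on the combined p-values; if False the combined
        p-values are used directly.

    Returns a DataFrame with columns ``pathway, n_profiles, combined_padj,
    combined_NES, reliability, significant``; non-significant pathways have
    combined_NES exactly 0 and reliability = -log10(combined_padj) always.
    """
    if not records:
        raise ValueError("no profiles to aggregate")
    weights = weights or {}
    per_pathway: dict[str, list[tuple[float, float, float]]] = {}
    n_profiles = len(records)
    for cell_line, df in records:
        w = float(weights.get(cell_line, 1.0))
        if w <= 0:
            raise ValueError(f"non-positive weight for cell line {cell_line!r}")
        for pathway, nes, padj in zip(df["pathway"], df["NES"], df["padj"]):
            per_pathway.setdefault(pathway, []).append((w, float(nes), float(padj)))

    rows = []
    for pathway in sorted(per_pathway):
        entries = per_pathway[pathway]
        if len(entries) < n_profiles:
            logger.warning(
                "pathway %s present in %d/%d profiles; combining available ones",
                pathway, len(entries), n_profiles,
            )
        ws = [e[0] for e in entries]
        nes = [e[1] for e in entries]
        ps = [min(max(e[2], P_FLOOR), 1.0) for e in entries]
        rows.append(
            (
                pathway,
                len(entries),
                combine_pvalues_wfisher(ps, ws),
                combine_nes_weighted_z(nes, ws),
            )
        )
    agg = pd.DataFrame(
        rows, columns=["pathway", "n_profiles", "combined_p", "combined_NES"]
    )
    final_p = (
        bh_adjust(np.maximum(agg["combined_p"].values, P_FLOOR))
        if second_adjust
        else agg["combined_p"].values
    )
    agg["combined_padj"] = final_p
    agg["significant"] = agg["combined_padj"] <= alpha
    agg.loc[~agg["significant"], "combined_NES"] = 0.0
    agg["reliability"] = -np.log10(np.maximum(agg["combined_padj"], P_FLOOR))
    return agg[
        ["pathway", "n_profiles", "combined_padj", "combined_NES",
         "reliability", "significant"]
    ]


def bubble_table(aggregates: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Long-format table for bubble plots of aggregated enrichments.

    One row per (perturbagen, pathway); ``shape`` is "circle" for significant
    calls and "triangle" otherwise, mirroring the display convention where
    bubble size encodes Reliability and colour encodes combined NES.
    """
    if not aggregates:
        raise ValueError("no aggregates supplied")
    frames = []
    for perturbagen, agg in aggregates.items():
        frames.append(
            pd.DataFrame(
                {
                    "perturbagen": perturbagen,
                    "pathway": agg["pathway"],
                    "NES": agg["combined_NES"],
                    "reliability": agg["reliability"],
                    "significant": agg["significant"],
                    "shape": np.where(agg["significant"], "circle", "triangle"),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
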