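"""Knockdown-mimicry correlation engine.

A drug is hypothesised to inhibit a target gene when its transcriptomic
perturbation signature correlates positively, in rank space, with the
signature of an shRNA knockdown of that gene.  This module matches knockdown
signatures to drug signatures within each cell line, picks the optimal
(dose, time) condition per drug, ranks drugs by their best Spearman
correlation, flags the top 1 %, and intersects the per-cell-line flags into
two consensus candidate sets:

* SET1 — drugs in the top 1 % of at least ``set1_min_lines`` cell lines
  (the stringent set);
* SET2 — among the remaining drugs in the top 1 % of at least
  ``set2_min_lines`` cell lines, the ``n_top`` with the best (smallest)
  median rank.

All reductions and tie-breaks are deterministic so that the consensus is
invariant to input row order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "SignatureMatrix",
    "ConstantVectorError",
    "spearman_rho",
    "correlate_profiles",
    "select_optimal_condition",
    "rank_and_flag_top",
    "build_consensus",
]

#: metadata columns expected on a signature-annotation table
META_COLUMNS = ["sig_id", "pert_type", "pert_target", "cell_line", "dose_um", "time_h"]


class ConstantVectorError(ValueError):
    """Spearman correlation is undefined for a constant vector."""


@dataclass
class SignatureMatrix:
    """Genes x signatures matrix of differential-expression scores.

    One instance holds the signatures of a single cell line over a fixed,
    shared gene universe.  Invariants: unique gene ids, unique signature ids,
    finite values.
    """

    gene_ids: list[str]
    sig_ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sig_ids = list(self.sig_ids)
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids in signature matrix")
        if len(set(self.sig_ids)) != len(self.sig_ids):
            raise ValueError("duplicate signature ids in signature matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sig_ids)):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sig_ids)} signatures"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("signature matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_signatures(self) -> int:
        return len(self.sig_ids)

    def column(self, sig_id: str) -> np.ndarray:
        """Return one signature as a 1-D vector (gene order preserved)."""
        return self.values[:, self.sig_ids.index(sig_id)]

    def subset(self, sig_ids: list[str]) -> "SignatureMatrix":
        """Column subset in the requested order; gene universe unchanged."""
        idx = [self.sig_ids.index(s) for s in sig_ids]
        return SignatureMatrix(self.gene_ids, list(sig_ids), self.values[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sig_ids)

    def series(self, sig_id: str) -> pd.Series:
        return pd.Series(self.column(sig_id), index=self.gene_ids, name=sig_id)


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation of two vectors.

    Computed as the Pearson correlation of mid-ranks (ties receive their
    average rank).  Symmetric in its arguments and invariant under any
    strictly monotone transform of either input.

    Raises
    ------
    ConstantVectorError
        If either vector is constant (correlation undefined).
    ValueError
        If the vectors differ in length or are shorter than 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantVectorError("Spearman correlation undefined for constant vector")
    rx = rankdata(x)
    ry = rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))


def _rank_standardise(values: np.ndarray) -> np.ndarray:
    """Column-wise mid-ranks, centred and scaled to unit norm.

    With columns in this form, Spearman correlations between any two columns
    reduce to a plain dot product, which lets ``correlate_profiles`` compute
    the full knockdown x drug block as one matrix product.
    """
    ranked = rankdata(values, axis=0)
    ranked -= ranked.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(ranked, axis=0)
    if np.any(norms == 0):
        raise ConstantVectorError("constant signature column")
    return ranked / norms


def correlate_profiles(
    kd_sigs: SignatureMatrix,
    drug_sigs: SignatureMatrix,
    meta: pd.DataFrame,
) -> pd.DataFrame:
    """All pairwise Spearman correlations between knockdown and drug signatures.

    Both matrices must share the identical gene universe and belong to a
    single cell line.  ``meta`` supplies drug identity, dose and time for the
    drug signature columns.

    Returns
    -------
    DataFrame with one row per (drug signature, knockdown signature) pair and
    columns ``cell_line, drug, dose_um, time_h, drug_sig_id, kd_sig_id, rho``.
    """
    if kd_sigs.gene_ids != drug_sigs.gene_ids:
        raise ValueError("knockdown and drug signatures use different gene universes")
    m = meta.set_index("sig_id")
    cell_lines = set(m.loc[drug_sigs.sig_ids, "cell_line"]) | set(
        m.loc[kd_sigs.sig_ids, "cell_line"]
    )
    if len(cell_lines) != 1:
        raise ValueError(f"signatures span multiple cell lines: {sorted(cell_lines)}")
    (cell_line,) = cell_lines

    rho = _rank_standardise(kd_sigs.values).T @ _rank_standardise(drug_sigs.values)

    rows = []
    for j, dsig in enumerate(drug_sigs.sig_ids):
        drug = m.at[dsig, "pert_target"]
        dose = m.at[dsig, "dose_um"]
        time = m.at[dsig, "time_h"]
        for i, ksig in enumerate(kd_sigs.sig_ids):
            rows.append((cell_line, drug, dose, time, dsig, ksig, rho[i, j]))
    return pd.DataFrame(
        rows,
        columns=["cell_line", "drug", "dose_um", "time_h", "drug_sig_id", "kd_sig_id", "rho"],
    )


# ---------------------------------------------------------------------------
# Optimal condition, ranking, consensus
# ---------------------------------------------------------------------------

def select_optimal_condition(
    corr: pd.DataFrame, kd_reduce: str = "max"
) -> pd.DataFrame:
    """Best (dose, time) per drug: the row of maximal rho.

    Knockdown replicates are reduced by ``kd_reduce`` ("max" keeps the single
    best-correlated replicate, "mean" averages rho over replicates before the
    maximisation).  Ties in rho are broken toward the lower dose, then the
    earlier time, then the lexicographically first knockdown signature id, so
    the selection is order-stable.
    """
    if corr.empty:
        raise ValueError("empty correlation table")
    if kd_reduce not in ("max", "mean"):
        raise ValueError(f"unknown kd_reduce: {kd_reduce!r}")
    df = corr
    if kd_reduce == "mean":
        df = (
            df.groupby(["cell_line", "drug", "dose_um", "time_h"], as_index=False)
            .agg(rho=("rho", "mean"))
        )
        df["kd_sig_id"] = ""
    df = df.sort_values(
        by=["drug", "rho", "dose_um", "time_h", "kd_sig_id"],
        ascending=[True, False, True, True, True],
        kind="mergesort",
    )
    best = df.groupby("drug", as_index=False).first()
    return best.rename(
        columns={"rho": "best_rho", "dose_um": "best_dose", "time_h": "best_time"}
    )[["cell_line", "drug", "best_rho", "best_dose", "best_time"]]


def top_n_for(n_drugs: int, top_fraction: float = 0.01) -> int:
    """Number of drugs flagged by the top-fraction rule: ceil(f * n)."""
    return math.ceil(top_fraction * n_drugs)


def rank_and_flag_top(
    best: pd.DataFrame, top_fraction: float = 0.01
) -> pd.DataFrame:
    """Rank drugs of one cell line by descending best rho and flag the top 1 %.

    Ranks 1..n are assigned by descending ``best_rho`` with ties broken by
    drug label; ``top1`` marks ranks <= ceil(top_fraction * n).
    """
    if best.empty:
        raise ValueError("no drugs to rank")
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must lie in (0, 1]")
    if not np.all(np.isfinite(best["best_rho"])):
        raise ValueError("non-finite correlation in rank input")
    out = best.sort_values(
        by=["best_rho", "drug"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    out["top1"] = out["rank"] <= top_n_for(len(out), top_fraction)
    return out


def build_consensus(
    rank_tables: dict[str, pd.DataFrame],
    set1_min_lines: int = 6,
    set2_min_lines: int = 2,
    n_top: int = 4,
) -> pd.DataFrame:
    """Cross-cell-line consensus candidate sets.

    Parameters
    ----------
    rank_tables
        Mapping cell line -> output of :func:`rank_and_flag_top`.
    set1_min_lines, set2_min_lines, n_top
        SET1 takes every drug flagged top-1 % in at least ``set1_min_lines``
        cell lines.  SET2 takes, among the remaining drugs flagged in at
        least ``set2_min_lines`` lines, the ``n_top`` with the smallest
        median rank (median over the lines where the drug was assayed; ties
        broken by mean rank, then label).

    Returns
    -------
    DataFrame with columns ``drug, n_lines_top1, ranks_per_line,
    median_rank, mean_rank, set_label`` sorted by set label then median rank.
    """
    if len(rank_tables) < set1_min_lines:
        raise ValueError(
            f"need at least set1_min_lines={set1_min_lines} cell lines, "
            f"got {len(rank_tables)}"
        )
    if len(rank_tables) < set2_min_lines:
        raise ValueError("fewer cell lines than set2_min_lines")

    ranks: dict[str, dict[str, int]] = {}
    top1_counts: dict[str, int] = {}
    for line in sorted(rank_tables):
        tbl = rank_tables[line]
        for drug, rank, top1 in zip(tbl["drug"], tbl["rank"], tbl["top1"]):
            ranks.setdefault(drug, {})[line] = int(rank)
            if top1:
                top1_counts[drug] = top1_counts.get(drug, 0) + 1

    rows = []
    for drug in sorted(ranks):
        per_line = ranks[drug]
        rows.append(
            {
                "drug": drug,
                "n_lines_top1": top1_counts.get(drug, 0),
                "ranks_per_line": dict(sorted(per_line.items())),
                "median_rank": float(np.median(list(per_line.values()))),
                "mean_rank": float(np.mean(list(per_line.values()))),
            }
        )
    df = pd.DataFrame(rows)

    set1 = df["n_lines_top1"] >= set1_min_lines
    df["set_label"] = np.where(set1, "SET1", "none")

    eligible = df[~set1 & (df["n_lines_top1"] >= set2_min_lines)]
    chosen = eligible.sort_values(
        by=["median_rank", "mean_rank", "drug"], kind="mergesort"
    ).head(n_top)
    df.loc[chosen.index, "set_label"] = "SET2"

    order = df["set_label"].map({"SET1": 0, "SET2": 1, "none": 2})
    return (
        df.assign(_o=order)
        .sort_values(by=["_o", "median_rank", "mean_rank", "drug"], kind="mergesort")
        .drop(columns="_o")
        .reset_index(drop=True)
    )


def reposition(
    matrices: dict[str, SignatureMatrix],
    meta: pd.DataFrame,
    kd_target: str,
    top_fraction: float = 0.01,
    set1_min_lines: int = 6,
    set2_min_lines: int = 2,
    n_top: int = 4,
    kd_reduce: str = "max",
) -> dict:
    """End-to-end repositioning over a per-cell-line signature compendium.

    Splits each cell line's matrix into knockdown signatures of ``kd_target``
    and compound signatures, correlates, selects optimal conditions, ranks,
    and builds the consensus.  Returns the per-line correlation and rank
    tables along with the consensus table.
    """
    rank_tables: dict[str, pd.DataFrame] = {}
    corr_tables: dict[str, pd.DataFrame] = {}
    for line, mat in matrices.items():
        mline = meta[meta["sig_id"].isin(mat.sig_ids)]
        kd_ids = mline.loc[
            (mline["pert_type"] == "knockdown") & (mline["pert_target"] == kd_target),
            "sig_id",
        ].tolist()
        drug_ids = mline.loc[mline["pert_type"] == "compound", "sig_id"].tolist()
        if not kd_ids:
            continue
        corr = correlate_profiles(mat.subset(kd_ids), mat.subset(drug_ids), mline)
        corr_tables[line] = corr
        best = select_optimal_condition(corr, kd_reduce=kd_reduce)
        rank_tables[line] = rank_and_flag_top(best, top_fraction)
    consensus = build_consensus(rank_tables, set1_min_lines, set2_min_lines, n_top)
    return {"correlations": corr_tables, "ranks": rank_tables, "consensus": consensus}
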