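"""Synthetic inputs with the statistical structure the pipeline assumes.

Every input the analysis consumes can be generated here at desk scale: a
per-cell-line signature compendium over a fixed gene universe (knockdown
replicates plus drug signatures on a dose x time grid, with designated
"mimic" drugs planted at a chosen Spearman correlation to the knockdown
signature), gene-set collections with sets enriched in chosen signatures,
random DPI/PPI interactomes with planted drug->target paths, lineage-centred
gene-essentiality scores, and assay plates whose noiseless absorbances
invert the MTT/LDH cytotoxicity formulas exactly.

Signature values are continuous z-like scores, standard normal plus planted
components: only their ranks matter downstream (Spearman, preranked GSEA),
so rank structure is the realism target.  All generators are bit-reproducible
for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import rankdata

from .repositioning import META_COLUMNS, SignatureMatrix, spearman_rho
from .enrichment import GeneSetCollection

__all__ = [
    "SimulationConfig",
    "InteractomeSimConfig",
    "simulate_signature_compendium",
    "simulate_gene_sets",
    "simulate_interactome",
    "simulate_essentiality",
    "simulate_assay_plate",
]

MTT_WAVELENGTH = 590
LDH_WAVELENGTH = 450
MTT_CONTROL_OD = 1.0
LDH_LOW_OD = 0.1
LDH_HIGH_OD = 1.1


@dataclass
class SimulationConfig:
    """Study conditions for the signature compendium generator."""

    n_genes: int = 1000
    cell_lines: list[str] = field(
        default_factory=lambda: ["A375", "A549", "HA1E", "HEPG2", "HT29", "MCF7", "PC3"]
    )
    n_drugs: int = 300
    doses: list[float] = field(default_factory=lambda: [1.0, 10.0])
    times: list[float] = field(default_factory=lambda: [6.0, 24.0])
    n_kd_replicates: int = 3
    target_gene: str = "GLS"
    mimic_drugs: dict[str, float] = field(default_factory=dict)
    mimic_condition: tuple[float, float] | None = None
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise ValueError("n_genes must be at least 10")
        if not self.cell_lines:
            raise ValueError("cell-line list must be non-empty")
        if len(set(self.cell_lines)) != len(self.cell_lines):
            raise ValueError("cell-line labels must be unique")
        if self.n_drugs < 1 or self.n_kd_replicates < 1:
            raise ValueError("n_drugs and n_kd_replicates must be positive")
        if not self.doses or not self.times:
            raise ValueError("dose and time grids must be non-empty")
        for label, rho in self.mimic_drugs.items():
            if not -1.0 <= rho <= 1.0:
                raise ValueError(f"mimic correlation for {label!r} outside [-1, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    @property
    def drug_labels(self) -> list[str]:
        """Drug roster: mimic labels first, filled with generated labels."""
        mimics = list(self.mimic_drugs)
        if len(mimics) > self.n_drugs:
            raise ValueError("more mimic drugs than n_drugs")
        fill = (f"drug{i:04d}" for i in range(1, self.n_drugs * 2))
        roster = list(mimics)
        for label in fill:
            if len(roster) == self.n_drugs:
                break
            if label not in self.mimic_drugs:
                roster.append(label)
        return roster

    @property
    def optimal_condition(self) -> tuple[float, float]:
        """(dose, time) at which mimic drugs carry the planted correlation."""
        if self.mimic_condition is not None:
            if (
                self.mimic_condition[0] not in self.doses
                or self.mimic_condition[1] not in self.times
            ):
                raise ValueError("mimic_condition outside the dose/time grid")
            return self.mimic_condition
        return (self.doses[0], self.times[0])


def _solve_mix_weight(kd: np.ndarray, noise: np.ndarray, target: float) -> float:
    """Mixing weight a such that Spearman(a*kd + sqrt(1-a^2)*noise, kd) = target.

    Solved numerically on the empirical rank correlation of the fixed
    vectors (a bivariate-normal closed form would only hit the population
    value).  The empirical Spearman is a nondecreasing step function of a,
    so bisection lands within one rank-step of the target.
    """
    if target == 0.0:
        return 0.0

    def f(a: float) -> float:
        mix = a * kd + np.sqrt(max(1.0 - a * a, 0.0)) * noise
        return spearman_rho(mix, kd) - target

    lo, hi = (0.0, 1.0) if target > 0 else (-1.0, 0.0)
    if f(lo) * f(hi) > 0:  # degenerate noise vector already correlated
        return lo if abs(f(lo)) < abs(f(hi)) else hi
    return brentq(f, lo, hi, xtol=1e-6)


def simulate_signature_compendium(
    config: SimulationConfig,
) -> tuple[dict[str, SignatureMatrix], pd.DataFrame]:
    """Generate the per-cell-line signature compendium and its metadata.

    For each cell line: ``n_kd_replicates`` knockdown signatures of the
    target gene (a shared latent profile plus replicate noise of sd
    ``noise_sd``) and one drug signature per (drug, dose, time) cell.
    Non-mimic drug signatures are independent standard normals; each mimic
    drug's signature at the optimal condition is a mixture of the first
    knockdown replicate and fresh noise whose weight is solved so the
    empirical Spearman correlation matches the configured value (contract
    tolerance +-0.1); its other conditions are independent noise.

    Returns (mapping cell line -> SignatureMatrix, metadata table with
    columns sig_id, pert_type, pert_target, cell_line, dose_um, time_h).
    """
    roster = config.drug_labels
    dose, time = config.optimal_condition
    root = np.random.SeedSequence(config.seed)
    matrices: dict[str, SignatureMatrix] = {}
    meta_rows: list[tuple] = []
    genes = [f"G{i:05d}" for i in range(1, config.n_genes + 1)]

    for line, ss in zip(config.cell_lines, root.spawn(len(config.cell_lines))):
        rng = np.random.default_rng(ss)
        kd_base = rng.standard_normal(config.n_genes)
        columns: list[np.ndarray] = []
        sig_ids: list[str] = []
        for r in range(1, config.n_kd_replicates + 1):
            rep = kd_base + config.noise_sd * rng.standard_normal(config.n_genes)
            columns.append(rep)
            sig_id = f"{line}:KD:{config.target_gene}:{r}"
            sig_ids.append(sig_id)
            meta_rows.append(
                (sig_id, "knockdown", config.target_gene, line, np.nan, np.nan)
            )
        kd_ref = columns[0]  # mimic correlations are planted against this
        for drug in roster:
            for d in config.doses:
                for t in config.times:
                    vec = rng.standard_normal(config.n_genes)
                    if drug in config.mimic_drugs and (d, t) == (dose, time):
                        a = _solve_mix_weight(
                            kd_ref, vec, config.mimic_drugs[drug]
                        )
                        vec = a * kd_ref + np.sqrt(max(1 - a * a, 0.0)) * vec
                    sig_id = f"{line}:{drug}:{d}uM:{t}h"
                    columns.append(vec)
                    sig_ids.append(sig_id)
                    meta_rows.append((sig_id, "compound", drug, line, d, t))
        matrices[line] = SignatureMatrix(
            genes, sig_ids, np.column_stack(columns)
        )
    meta = pd.DataFrame(meta_rows, columns=META_COLUMNS)
    return matrices, meta


def simulate_gene_sets(
    n_sets: int,
    size_range: tuple[int, int],
    enriched_sets: dict[str, float] | None = None,
    universe: list[str] | None = None,
    seed: int = 0,
    signature: pd.Series | None = None,
    name: str = "synthetic",
) -> GeneSetCollection:
    """Random gene sets, optionally enriched in a companion signature's tails.

    ``enriched_sets`` maps set labels to a signed strength s: the set's genes
    are drawn without replacement with probability proportional to
    exp(s * z), z being the signature's standardised score, so positive
    strengths crowd the top tail and negative ones the bottom tail; strength
    0 is uniform.  ``signature`` is required whenever a nonzero strength is
    requested.  Labels: enriched labels first, filled with ``set###``.
    """
    enriched_sets = enriched_sets or {}
    if n_sets == 0:
        return GeneSetCollection(name=name, sets={})
    if universe is None or len(universe) == 0:
        raise ValueError("gene universe required")
    lo, hi = size_range
    if lo < 2 or hi > len(universe) or lo > hi:
        raise ValueError("size_range must lie within [2, |universe|]")
    if len(enriched_sets) > n_sets:
        raise ValueError("more enriched sets than n_sets")
    if any(s != 0 for s in enriched_sets.values()) and signature is None:
        raise ValueError("companion signature required for enriched sets")

    labels = list(enriched_sets)
    fill = (f"set{i:03d}" for i in range(1, n_sets * 2))
    for label in fill:
        if len(labels) == n_sets:
            break
        if label not in enriched_sets:
            labels.append(label)

    rng = np.random.default_rng(seed)
    universe = list(universe)
    if signature is not None:
        z = signature.reindex(universe).to_numpy(dtype=float)
        if np.any(~np.isfinite(z)):
            raise ValueError("signature must cover the universe")
        z = (z - z.mean()) / (z.std() or 1.0)
    sets: dict[str, set[str]] = {}
    for label in labels:
        size = int(rng.integers(lo, hi + 1))
        strength = enriched_sets.get(label, 0.0)
        if strength and signature is not None:
            p = np.exp(strength * z)
            p /= p.sum()
            members = rng.choice(universe, size=size, replace=False, p=p)
        else:
            members = rng.choice(universe, size=size, replace=False)
        sets[label] = set(members.tolist())
    return GeneSetCollection(name=name, sets=sets)


@dataclass
class InteractomeSimConfig:
    """Study conditions for the random-interactome generator."""

    n_proteins: int = 50
    n_compounds: int = 10
    ppi_density: float = 0.05
    target_gene: str = "GLS"
    planted_paths: list[tuple[str, int]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 2 or self.n_compounds < 1:
            raise ValueError("need >= 2 proteins and >= 1 compound")
        if not 0 <= self.ppi_density < 1:
            raise ValueError("ppi_density must lie in [0, 1)")
        for drug, k in self.planted_paths:
            if k not in (1, 2, 3):
                raise ValueError(f"planted path edge-count {k} not in {{1,2,3}}")
        if len({d for d, _ in self.planted_paths}) > self.n_compounds:
            raise ValueError("planted drug not among compounds (roster too small)")

    @property
    def protein_labels(self) -> list[str]:
        others = [f"P{i:04d}" for i in range(1, self.n_proteins)]
        return [self.target_gene.upper()] + others

    @property
    def compound_labels(self) -> list[str]:
        planted = list(dict.fromkeys(d for d, _ in self.planted_paths))
        fill = (f"CPD{i:04d}" for i in range(1, self.n_compounds * 2))
        roster = [p.upper() for p in planted]
        for label in fill:
            if len(roster) == self.n_compounds:
                break
            if label not in roster:
                roster.append(label)
        return roster


def simulate_interactome(
    config: InteractomeSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random DPI/PPI edge lists with planted drug->target paths.

    Each planted (drug, k) guarantees a k-edge path drug -> target gene whose
    first edge is a DPI and later edges are PPIs, with fresh intermediate
    proteins.  Background: every non-planted compound receives 1-3 random
    DPI partners; protein pairs join at ``ppi_density``.

    Returns (DPI table: compound_id, protein_symbol, source;
    PPI table: protein_a, protein_b, source).
    """
    rng = np.random.default_rng(config.seed)
    proteins = config.protein_labels
    compounds = config.compound_labels
    target = config.target_gene.upper()
    non_target = [p for p in proteins if p != target]

    dpi_edges: set[tuple[str, str]] = set()
    ppi_edges: set[frozenset] = set()

    for drug, k in config.planted_paths:
        drug = drug.upper()
        if k == 1:
            dpi_edges.add((drug, target))
            continue
        mids = list(rng.choice(non_target, size=k - 1, replace=False))
        dpi_edges.add((drug, mids[0]))
        chain = mids + [target]
        for a, b in zip(chain, chain[1:]):
            ppi_edges.add(frozenset((a, b)))

    planted_drugs = {d.upper() for d, _ in config.planted_paths}
    for drug in compounds:
        if drug in planted_drugs:
            continue
        n_partners = int(rng.integers(1, 4))
        for p in rng.choice(proteins, size=n_partners, replace=False):
            dpi_edges.add((drug, p))

    if config.ppi_density > 0:
        n = len(proteins)
        iu = np.triu_indices(n, k=1)
        mask = rng.random(iu[0].size) < config.ppi_density
        for i, j in zip(iu[0][mask], iu[1][mask]):
            ppi_edges.add(frozenset((proteins[i], proteins[j])))

    dpi = pd.DataFrame(
        sorted(dpi_edges), columns=["compound_id", "protein_symbol"]
    ).assign(source="simDPI")
    ppi = pd.DataFrame(
        sorted(tuple(sorted(e)) for e in ppi_edges),
        columns=["protein_a", "protein_b"],
    ).assign(source="simPPI")
    return dpi, ppi


def simulate_essentiality(
    genes: list[str],
    lineage_means: dict[str, float],
    n_lines_per_lineage: int = 10,
    sd: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene x cell-line fitness scores drawn around per-lineage means.

    Returns a long table (gene, cell_line, lineage, score) with
    score ~ Normal(lineage mean, sd); one record per gene and cell line.
    """
    if not genes:
        raise ValueError("empty gene list")
    if sd <= 0:
        raise ValueError("sd must be positive")
    if n_lines_per_lineage < 1:
        raise ValueError("n_lines_per_lineage must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for lineage, mean in lineage_means.items():
        for i in range(1, n_lines_per_lineage + 1):
            cell_line = f"{lineage}_{i:03d}"
            scores = rng.normal(mean, sd, size=len(genes))
            rows.extend(
                (g, cell_line, lineage, s) for g, s in zip(genes, scores)
            )
    return pd.DataFrame(rows, columns=["gene", "cell_line", "lineage", "score"])


def simulate_assay_plate(
    true_ct_by_dose: dict[float, float],
    n_replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
    drug: str = "drug",
    day: int = 1,
) -> pd.DataFrame:
    """Assay plate whose noiseless absorbances invert the CT formulas exactly.

    For each dose with true cytotoxicity CT%% the generator emits MTT wells
    (control OD 1.0, sample OD = control*(1 - CT/100), read at 590 nm) and
    LDH wells (low control 0.1, high control 1.1, sample OD = low +
    CT/100*(high-low), read at 450 nm), ``n_replicates`` of each, plus the
    shared control wells.  Gaussian OD noise of ``noise_sd`` is added to
    every well; absorbances are floored at 0.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    for dose, ct in true_ct_by_dose.items():
        if not 0 <= ct <= 100:
            raise ValueError(f"true CT at dose {dose} outside [0, 100]")
    if n_replicates < 1:
        raise ValueError("n_replicates must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    well = iter(f"{r}{c:02d}" for r in "ABCDEFGHIJKLMNOP" for c in range(1, 25))

    def emit(role, drug_label, dose, od, wavelength):
        noisy = od + (rng.normal(0, noise_sd) if noise_sd else 0.0)
        rows.append(
            (next(well), role, drug_label, dose, day, max(noisy, 0.0), wavelength)
        )

    for _ in range(n_replicates):
        emit("control", None, None, MTT_CONTROL_OD, MTT_WAVELENGTH)
        emit("low_control", None, None, LDH_LOW_OD, LDH_WAVELENGTH)
        emit("high_control", None, None, LDH_HIGH_OD, LDH_WAVELENGTH)
    for dose, ct in true_ct_by_dose.items():
        mtt_od = MTT_CONTROL_OD * (1 - ct / 100.0)
        ldh_od = LDH_LOW_OD + ct / 100.0 * (LDH_HIGH_OD - LDH_LOW_OD)
        for _ in range(n_replicates):
            emit("sample", drug, dose, mtt_od, MTT_WAVELENGTH)
            emit("sample", drug, dose, ldh_od, LDH_WAVELENGTH)
    return pd.DataFrame(
        rows,
        columns=["well", "role", "drug", "dose_um", "day", "absorbance",
                 "wavelength_nm"],
    )
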