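"""In-vitro assay arithmetic: cytotoxicity, glutamate quantitation, efficacy.

MTT (tetrazolium reduction, 590 nm) measures metabolic activity of surviving
cells, so cytotoxicity is the fractional drop of sample absorbance against
drug-free controls:

    CT = 100 * (AbsC - AbsS) / AbsC

LDH release (450 nm) measures membrane damage between a low control (intact
cells) and a high control (fully lysed cells):

    CT = 100 * (AbsS - AbsLC) / (AbsHC - AbsLC)

Glutamate content is read off a linear standard curve fitted on
background-subtracted OD, and drug efficacy is the glutamate concentration
normalised by the relative viability (MTT AbsS/AbsC) of the treated wells.
Western-blot band intensities are expressed relative to the DMSO reference,
which maps to exactly 1.00.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .synthetic import LDH_WAVELENGTH, MTT_WAVELENGTH

logger = logging.getLogger(__name__)

__all__ = [
    "StandardCurve",
    "mtt_cytotoxicity",
    "ldh_cytotoxicity",
    "fit_standard_curve",
    "glutamate_concentration",
    "drug_efficacy",
    "relative_band_intensity",
    "summarize_plate",
]


def mtt_cytotoxicity(abs_control: float, abs_sample: float) -> dict[str, float]:
    """MTT cytotoxicity percentage; viability = 100 - CT reported alongside."""
    if abs_control <= 0:
        raise ValueError("control absorbance must be positive")
    ct = 100.0 * (abs_control - abs_sample) / abs_control
    return {"ct": ct, "viability": 100.0 - ct}


def ldh_cytotoxicity(abs_sample: float, abs_low: float, abs_high: float) -> float:
    """LDH-release cytotoxicity percentage between low and high controls."""
    if abs_high <= abs_low:
        raise ValueError("high-control absorbance must exceed low control")
    return 100.0 * (abs_sample - abs_low) / (abs_high - abs_low)


@dataclass
class StandardCurve:
    """Linear OD-vs-concentration fit on background-subtracted standards."""

    slope: float
    intercept: float
    points: list[tuple[float, float]]

    def concentration(self, od: float) -> float:
        if self.slope == 0:
            raise ValueError("degenerate standard curve (zero slope)")
        return (od - self.intercept) / self.slope


def fit_standard_curve(
    concentrations, ods, background_od: float = 0.0
) -> StandardCurve:
    """Least-squares line through (concentration, OD - background) points."""
    conc = np.asarray(concentrations, dtype=float)
    od = np.asarray(ods, dtype=float) - background_od
    if np.unique(conc).size < 2:
        raise ValueError("need at least 2 distinct standard concentrations")
    fit = linregress(conc, od)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        points=list(zip(conc.tolist(), od.tolist())),
    )


def glutamate_concentration(
    sample_od: float, background_od: float, curve: StandardCurve
) -> float:
    """Invert the standard curve on background-subtracted sample OD.

    Sample ODs below background (and negative concentration estimates, which
    only arise from noise) clamp to 0 with a warning.
    """
    net = sample_od - background_od
    if net < 0:
        logger.warning("sample OD below background; clamping to 0")
        return 0.0
    conc = curve.concentration(net)
    if conc < 0:
        logger.warning("negative concentration estimate clamped to 0")
        return 0.0
    return conc


def drug_efficacy(
    glutamate_conc: float, relative_viability: float, literal_ct: bool = False
) -> float:
    """Viability-normalised glutamate content (nmol per viable-cell fraction).

    Default divides by relative viability (MTT AbsS/AbsC), expressing
    glutamate per unit of surviving cells; ``literal_ct=True`` divides by
    relative cytotoxicity (1 - viability) instead.
    """
    if not 0 < relative_viability <= 1:
        raise ValueError("relative_viability must lie in (0, 1]")
    denom = (1.0 - relative_viability) if literal_ct else relative_viability
    if denom <= 0:
        raise ValueError("zero cytotoxicity: literal form undefined")
    return glutamate_conc / denom


def relative_band_intensity(
    sample_intensity: float, reference_intensity: float
) -> float:
    """Band intensity relative to the DMSO reference (reference -> 1.00)."""
    if reference_intensity <= 0:
        raise ValueError("reference intensity must be positive")
    if sample_intensity < 0:
        raise ValueError("negative band intensity")
    return sample_intensity / reference_intensity


def summarize_plate(plate: pd.DataFrame, clamp: bool = True) -> pd.DataFrame:
    """Per (drug, dose, day) cytotoxicity from an assay-plate well table.

    Replicate wells are averaged before the formulas; the per-well SD is
    propagated to an SE of the CT estimate by the delta method.  Raw CT is
    always reported; ``ct`` is clamped into [0, 100] unless ``clamp=False``.
    MTT wells are those read at 590 nm, LDH wells at 450 nm.
    """
    def mean_sd(sel):
        vals = sel["absorbance"].to_numpy(dtype=float)
        return vals.mean(), (vals.std(ddof=1) if vals.size > 1 else 0.0), vals.size

    rows = []
    for day in sorted(plate["day"].unique()):
        p = plate[plate["day"] == day]
        mtt = p[p["wavelength_nm"] == MTT_WAVELENGTH]
        ldh = p[p["wavelength_nm"] == LDH_WAVELENGTH]
        controls = {
            "control": mtt[mtt["role"] == "control"],
            "low_control": ldh[ldh["role"] == "low_control"],
            "high_control": ldh[ldh["role"] == "high_control"],
        }
        samples = p[p["role"] == "sample"]
        for (drug, dose), grp in samples.groupby(["drug", "dose_um"], sort=True):
            for assay, wavelength in (("MTT", MTT_WAVELENGTH), ("LDH", LDH_WAVELENGTH)):
                wells = grp[grp["wavelength_nm"] == wavelength]
                if wells.empty:
                    continue
                s_mean, s_sd, n = mean_sd(wells)
                if assay == "MTT":
                    if controls["control"].empty:
                        raise ValueError("MTT wells present but no control wells")
                    c_mean, c_sd, nc = mean_sd(controls["control"])
                    raw = mtt_cytotoxicity(c_mean, s_mean)["ct"]
                    # delta method: CT = 100(1 - S/C)
                    se = 100.0 / c_mean * np.sqrt(
                        s_sd**2 / n + (s_mean * c_sd / c_mean) ** 2 / nc
                    )
                else:
                    if controls["low_control"].empty or controls["high_control"].empty:
                        raise ValueError("LDH wells present but controls missing")
                    lc, lc_sd, nl = mean_sd(controls["low_control"])
                    hc, hc_sd, nh = mean_sd(controls["high_control"])
                    raw = ldh_cytotoxicity(s_mean, lc, hc)
                    se = 100.0 / (hc - lc) * np.sqrt(
                        s_sd**2 / n + lc_sd**2 / nl + hc_sd**2 / nh
                    )
                rows.append(
                    {
                        "drug": drug,
                        "dose_um": dose,
                        "day": day,
                        "assay": assay,
                        "n_wells": n,
                        "ct_raw": raw,
                        "ct": float(np.clip(raw, 0.0, 100.0)) if clamp else raw,
                        "ct_se": float(se),
                    }
                )
    return pd.DataFrame(rows)
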