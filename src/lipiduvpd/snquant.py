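"""Stage 4: sn-isomer quantification via the CID/CID/UVPD dioxolane route.

Collisional activation of a sodiated glycerophospholipid expels the neutral
head group and closes a five-membered dioxolane ring over the glycerol
backbone. UVPD of the reisolated sodiated dioxolane cleaves across the
ring, yielding cross-ring fragments whose masses depend on which fatty
acyl sits at sn-1. The quantified sn-1-diagnostic fragment is the sodiated
[FA + C3H4] species (m/z 319 for FA 16:0, 345 for FA 18:1).

For a lipid whose chains are known (say 16:0 and 18:1), the intensity
ratio R = I_a / (I_a + I_b) of the two sn-1 fragments scales linearly with
the fraction of the a-at-sn-1 isomer; a calibration line fitted on
standard mixtures (e.g. POPC/OPPC) converts an observed R into isomer
fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .chem import (
    ELECTRON_MASS,
    AcylChain,
    ElementalFormula,
    LipidIon,
    _monoisotopic,
)
from .spectra import CentroidSpectrum, match_peak

__all__ = [
    "CalibrationModel",
    "SnQuantResult",
    "HEADGROUP_LOSS",
    "dioxolane_mz",
    "sn1_crossring_mz",
    "fit_calibration",
    "quantify_sn",
    "ratio_from_spectrum",
]

# Neutral head-group losses from sodiated precursors on dioxolane formation.
HEADGROUP_LOSS = {
    "PE": ElementalFormula.parse("C2H8NO4P"),   # 141.019
    "PG": ElementalFormula.parse("C3H9O6P"),    # 172.014
    "PC": ElementalFormula.parse("C5H14NO4P"),  # 183.066
}

_C3H4 = ElementalFormula.parse("C3H4")
_NA_CATION = _monoisotopic("Na") - ELECTRON_MASS


def dioxolane_mz(ion: LipidIon) -> float:
    """m/z of the sodiated dioxolane, [M+Na - head group]+.

    The head-group loss is class-specific but the product only retains the
    diacylglycerol core, so PE, PG and PC with the same chains give the
    same dioxolane.
    """
    if ion.adduct != "+Na":
        raise ValueError("dioxolane formation requires a sodiated precursor")
    cls = ion.species.lipid_class
    if cls not in HEADGROUP_LOSS:
        raise ValueError(f"no dioxolane head-group loss defined for {cls}")
    return ion.theoretical_mz - HEADGROUP_LOSS[cls].mass


def sn1_crossring_mz(fa: AcylChain) -> float:
    """m/z of the quantified sn-1-diagnostic sodiated cross-ring fragment.

    Composition: free fatty acid + C3H4 (the glycerol-derived ring
    remnant) + Na, as a cation.
    """
    return fa.mass + _C3H4.mass + _NA_CATION


@dataclass(frozen=True)
class CalibrationModel:
    """Linear calibration R = slope * f + intercept of the sn-1 fragment
    intensity ratio against the isomer fraction f in [0, 1]."""

    slope: float
    intercept: float
    rms_error: float
    n_points: int

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration must be strictly increasing (slope > 0)")

    def predict(self, fraction: float) -> float:
        return self.slope * fraction + self.intercept

    def invert(self, ratio: float) -> float:
        return float(np.clip((ratio - self.intercept) / self.slope, 0.0, 1.0))


def fit_calibration(
    points: Sequence[tuple[float, Sequence[float]]],
    scaling_factor: float = 1.0,
) -> CalibrationModel:
    """Ordinary least squares on replicate-mean ratios per known fraction.

    ``points`` is a list of ``(fraction, replicate_ratios)``. An optional
    multiplicative ``scaling_factor`` is applied to all ratios before the
    fit, absorbing stock-concentration differences between the two isomer
    standards.
    """
    fractions = np.array([f for f, _ in points], dtype=float)
    if len(points) < 2 or np.ptp(fractions) < 1e-12:
        raise ValueError("calibration needs >= 2 distinct fractions")
    means = np.array([np.mean(list(r)) * scaling_factor for _, r in points])
    slope, intercept = np.polyfit(fractions, means, 1)
    residuals = means - (slope * fractions + intercept)
    rms = float(np.sqrt(np.mean(residuals**2)))
    return CalibrationModel(float(slope), float(intercept), rms, len(points))


@dataclass(frozen=True)
class SnQuantResult:
    """Relative quantification of the two sn-isomers of a diacyl lipid."""

    observed_ratio: float
    fraction_a_sn1: float  # isomer with chain_a at sn-1
    fraction_b_sn1: float
    uncertainty: float  # propagated from calibration RMS
    call: str  # shorthand chain part, slash or underscore

    def __post_init__(self) -> None:
        total = self.fraction_a_sn1 + self.fraction_b_sn1
        if abs(total - 1.0) > 1e-9:
            raise ValueError("isomer fractions must sum to 1")


def quantify_sn(
    ratio: float,
    model: CalibrationModel,
    chain_a: AcylChain,
    chain_b: AcylChain,
    dominance_threshold: float = 0.9,
) -> SnQuantResult:
    """Convert an observed intensity ratio into sn-isomer fractions.

    ``ratio`` is I_a/(I_a + I_b) where I_a is the sn-1 fragment carrying
    ``chain_a``. The major isomer is reported in slash notation when its
    fraction reaches ``dominance_threshold``; otherwise the mixture is
    reported with an underscore.
    """
    if not 0.0 <= ratio <= 1.0:
        raise ValueError(f"intensity ratio must lie in [0, 1], got {ratio}")
    f = model.invert(ratio)
    sigma = model.rms_error / model.slope if model.slope else float("nan")
    if f >= dominance_threshold:
        call = f"{chain_a.label()}/{chain_b.label()}"
    elif (1 - f) >= dominance_threshold:
        call = f"{chain_b.label()}/{chain_a.label()}"
    else:
        call = f"{chain_a.label()}_{chain_b.label()}"
    return SnQuantResult(
        observed_ratio=ratio,
        fraction_a_sn1=f,
        fraction_b_sn1=1.0 - f,
        uncertainty=sigma,
        call=call,
    )


def ratio_from_spectrum(
    ms4: CentroidSpectrum,
    chain_a: AcylChain,
    chain_b: AcylChain,
    tol: float = 0.3,
) -> float:
    """I_a/(I_a + I_b) of the two sn-1 cross-ring fragments in an MS4
    UVPD spectrum of the sodiated dioxolane."""
    i_a = match_peak(ms4, sn1_crossring_mz(chain_a), tol)
    i_b = match_peak(ms4, sn1_crossring_mz(chain_b), tol)
    inten_a = float(ms4.intensity[i_a]) if i_a is not None else 0.0
    inten_b = float(ms4.intensity[i_b]) if i_b is not None else 0.0
    if inten_a + inten_b == 0:
        raise ValueError("neither sn-1 cross-ring fragment found in spectrum")
    return inten_a / (inten_a + inten_b)
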